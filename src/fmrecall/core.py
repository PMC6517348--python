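"""Generative core of the feature model of immediate serial recall.

Items are vectors of binary (+1/-1) features split into a modality-dependent
segment (tied to physical presentation: voice, font, location) and a
modality-independent segment (produced by internal categorisation).  Each
item lays down two traces: a degradable *primary memory* (PM) cue and an
intact *secondary memory* (SM) target.  Forgetting is similarity-based
retroactive interference: a PM feature matched by the corresponding feature
of the following item is overwritten to 0, and internally generated activity
after the final item overwrites its modality-independent features.  At
recall each PM cue samples an SM target through the Luce choice rule over
exponentiated negative feature distances, recovery of a sampled item decays
exponentially with the number of times it has already been sampled, and
order errors come from an Estes-style perturbation random walk over
positional codes.

The public single-trace operations mirror the model's conceptual steps and
are convenient for inspection and testing; :func:`simulate_trials` is the
batch engine (vectorised over trials) that the fitting machinery uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .designs import ConditionSpec

__all__ = [
    "Trace",
    "ModelParams",
    "SerialPositionCurve",
    "generate_item_trace",
    "overwrite_adjacent",
    "end_of_list_interference",
    "compute_distance",
    "similarity",
    "luce_probabilities",
    "luce_sample",
    "recovery_probability",
    "perturbation_step_matrix",
    "positional_uncertainty",
    "sample_output_order",
    "simulate_trial",
    "simulate_trials",
    "simulate_curve",
]

# Internal batch cap: keeps the (trials, items, items, features) mismatch
# tensor comfortably in memory for large n_trials.
_MAX_BATCH = 16384


@dataclass(frozen=True)
class Trace:
    """One item's memory representation.

    Parameters
    ----------
    md : ndarray
        Modality-dependent feature values.
    mi : ndarray
        Modality-independent feature values.

    Values are +1/-1 at creation; degradation (overwriting) sets primary
    memory features to 0 and is one-way.  Secondary-memory traces are never
    degraded and therefore contain no zeros.
    """

    md: np.ndarray
    mi: np.ndarray

    def __post_init__(self) -> None:
        md = np.asarray(self.md, dtype=np.int8)
        mi = np.asarray(self.mi, dtype=np.int8)
        object.__setattr__(self, "md", md)
        object.__setattr__(self, "mi", mi)
        values = self.values
        if values.size == 0:
            raise ValueError("a trace needs at least one feature")
        if not np.isin(values, (-1, 0, 1)).all():
            raise ValueError("trace features must be in {-1, 0, +1}")

    @property
    def values(self) -> np.ndarray:
        """Concatenated feature vector (md segment first)."""
        return np.concatenate([self.md, self.mi])

    @property
    def n_features(self) -> int:
        return self.md.size + self.mi.size


@dataclass(frozen=True)
class ModelParams:
    """Numeric parameters of the feature model.

    Attributes
    ----------
    a_spatial, a_verbal : float
        Distance scaling constants (one per task domain); larger values
        sharpen the Luce choice and raise accuracy.
    c : float
        Recovery scaling: a sampled item is recovered with probability
        ``exp(-c * r)`` where ``r`` counts its prior samplings this trial.
    theta : float
        Per-opportunity perturbation probability of a positional code.
    pi : int
        Number of perturbation opportunities per trial.
    b : float
        Attention bias weighting every feature in the distance sum; fixed
        at 1 here (it then has no influence).
    F_tapping, F_suppression : float
        Feature-adoption counts: how many modality-independent features the
        concurrent task sets to +1 across list items.
    F_dissociation : float
        Additive extra adoption applied when the concurrent task's domain
        matches the primary task's domain; 0 means no selective
        interference.
    """

    a_spatial: float = 20.0
    a_verbal: float = 20.0
    c: float = 2.0
    theta: float = 0.05
    pi: int = 10
    b: float = 1.0
    F_tapping: float = 0.0
    F_suppression: float = 0.0
    F_dissociation: float = 0.0

    def __post_init__(self) -> None:
        if self.a_spatial <= 0 or self.a_verbal <= 0:
            raise ValueError("distance scalings a must be positive")
        if self.c < 0:
            raise ValueError("recovery scaling c must be non-negative")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.pi < 0 or int(self.pi) != self.pi:
            raise ValueError("pi must be a non-negative integer")
        for name in ("F_tapping", "F_suppression", "F_dissociation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def a_for(self, task_domain: str) -> float:
        if task_domain == "spatial":
            return self.a_spatial
        if task_domain == "verbal":
            return self.a_verbal
        raise ValueError(f"unknown task domain {task_domain!r}")

    def with_updates(self, **kwargs: float) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class SerialPositionCurve:
    """Proportion correct-in-position per output position for one condition."""

    condition: str
    n_items: int
    proportions: np.ndarray
    n_observations: int = 0

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (self.n_items,):
            raise ValueError(
                f"condition {self.condition!r}: expected {self.n_items} "
                f"proportions, got shape {self.proportions.shape}"
            )
        if ((self.proportions < 0) | (self.proportions > 1)).any():
            raise ValueError(
                f"condition {self.condition!r}: proportions must lie in [0, 1]"
            )


# ---------------------------------------------------------------------------
# encoding and interference
# ---------------------------------------------------------------------------

def generate_item_trace(n_md: int, n_mi: int, rng: np.random.Generator) -> Trace:
    """Draw a fresh item trace with independent +1/-1 features.

    Each of the ``n_md + n_mi`` features is +1 or -1 with probability 1/2.
    """
    if n_md < 0 or n_mi < 0:
        raise ValueError("feature counts must be non-negative")
    if n_md + n_mi < 1:
        raise ValueError("a trace needs at least one feature")
    vals = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_md + n_mi)
    return Trace(md=vals[:n_md], mi=vals[n_md:])


def overwrite_adjacent(pm_prev: Trace, next_item: Trace) -> Trace:
    """Retroactive interference from the following list item.

    Every feature of ``pm_prev`` (both segments) whose value equals the
    corresponding feature of ``next_item`` is set to 0; non-matching and
    already-zero features are untouched.
    """
    if pm_prev.md.size != next_item.md.size or pm_prev.mi.size != next_item.mi.size:
        raise ValueError("traces must have identical segment lengths")
    md = np.where(pm_prev.md == next_item.md, 0, pm_prev.md).astype(np.int8)
    mi = np.where(pm_prev.mi == next_item.mi, 0, pm_prev.mi).astype(np.int8)
    return Trace(md=md, mi=mi)


def end_of_list_interference(pm_last: Trace, rng: np.random.Generator) -> Trace:
    """Post-list internally generated activity degrading the final item.

    A random +1/-1 pseudo-item is applied through the match-and-zero rule to
    the modality-independent segment only; modality-dependent features are
    returned untouched.  This is what makes a modality-dependent segment
    protect the recency position.
    """
    n_mi = pm_last.mi.size
    if n_mi == 0:
        return pm_last
    pseudo = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_mi)
    mi = np.where(pm_last.mi == pseudo, 0, pm_last.mi).astype(np.int8)
    return Trace(md=pm_last.md, mi=mi)


# ---------------------------------------------------------------------------
# retrieval primitives
# ---------------------------------------------------------------------------

def compute_distance(pm: Trace, sm: Trace, a: float, b: float = 1.0) -> float:
    """Psychological distance ``d = (a/N) * sum_k b * M_k``.

    ``M_k`` is 1 where feature k of the PM cue differs from feature k of the
    SM target (an overwritten 0 in PM counts as a mismatch against any +1/-1
    in SM), else 0; ``N`` is the total number of compared features.
    """
    if pm.md.size != sm.md.size or pm.mi.size != sm.mi.size:
        raise ValueError("traces must have identical segment lengths")
    if a <= 0:
        raise ValueError("distance scaling a must be positive")
    n = pm.n_features
    mismatches = int((pm.values != sm.values).sum())
    return (a / n) * b * mismatches


def similarity(d: float) -> float:
    """Shepard similarity ``s = exp(-d)``, strictly decreasing in distance."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return float(np.exp(-d))


def luce_probabilities(
    pm: Trace, sm_set: Sequence[Trace], a: float, b: float = 1.0
) -> np.ndarray:
    """Luce choice rule: P(SM_j | PM_i) = s(i,j) / sum_k s(i,k)."""
    if len(sm_set) == 0:
        raise ValueError("secondary-memory search set must be non-empty")
    sims = np.array([similarity(compute_distance(pm, sm, a, b)) for sm in sm_set])
    return sims / sims.sum()


def _sample_rows(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One index per row, drawn proportional to that row's weights.

    Inverse-CDF sampling shared by the retrieval step and the positional
    sampler; rows need not be normalised.
    """
    cum = weights.cumsum(axis=1)
    u = rng.random(weights.shape[0]) * cum[:, -1]
    return (u[:, None] < cum).argmax(axis=1)


def luce_sample(
    pm: Trace,
    sm_set: Sequence[Trace],
    a: float,
    b: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Sample ``size`` secondary-memory indices under the Luce choice rule.

    Uses the same categorical sampler as the trial engine, so long-run
    frequencies can be checked against :func:`luce_probabilities`.
    """
    probs = luce_probabilities(pm, sm_set, a, b)
    return _sample_rows(np.broadcast_to(probs, (size, probs.size)), rng)


def recovery_probability(r: int, c: float) -> float:
    """Output interference: P(recover) = exp(-c * r).

    ``r`` is the number of times the sampled item has already been sampled
    this trial; never-sampled items are always recovered.
    """
    if r < 0:
        raise ValueError("sampling count r must be non-negative")
    if c < 0:
        raise ValueError("recovery scaling c must be non-negative")
    return float(np.exp(-c * r))


# ---------------------------------------------------------------------------
# positional perturbation
# ---------------------------------------------------------------------------

def perturbation_step_matrix(n_items: int, theta: float) -> np.ndarray:
    """One opportunity of the positional random walk, as a transition matrix.

    Interior positions keep their mass with probability ``1 - theta`` and
    pass ``theta/2`` to each neighbour; the first and last positions keep
    ``1 - theta/2`` and pass ``theta/2`` to their single neighbour, so no
    mass drifts beyond the list ends.
    """
    if n_items < 1:
        raise ValueError("need at least one item")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    if n_items == 1:
        return np.ones((1, 1))
    step = np.zeros((n_items, n_items))
    half = theta / 2.0
    for p in range(n_items):
        if p == 0 or p == n_items - 1:
            step[p, p] = 1.0 - half
        else:
            step[p, p] = 1.0 - theta
        if p > 0:
            step[p, p - 1] = half
        if p < n_items - 1:
            step[p, p + 1] = half
    return step


def positional_uncertainty(n_items: int, theta: float, pi: int) -> np.ndarray:
    """Positional-uncertainty matrix after ``pi`` perturbation opportunities.

    Entry (i, p) is the probability that the item presented at position i is
    currently coded at position p.  Starts from the identity and applies the
    one-step kernel ``pi`` times; rows stay stochastic and with ``theta = 0``
    (or ``pi = 0``) the result is the identity.
    """
    if pi < 0 or int(pi) != pi:
        raise ValueError("pi must be a non-negative integer")
    step = perturbation_step_matrix(n_items, theta)
    out = np.eye(n_items)
    for _ in range(int(pi)):
        out = out @ step
    return out


def sample_output_order(
    uncertainty: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample a cueing order from the positional-uncertainty distributions.

    Each item draws a perturbed position from its own row; items are then
    cued in order of sampled position, ties broken uniformly at random.
    Returns the item indices to cue at output positions 1..n.
    """
    uncertainty = np.asarray(uncertainty, dtype=float)
    pos = _sample_rows(uncertainty, rng)
    jitter = rng.random(pos.size)  # uniform tie-break among equal positions
    return np.argsort(pos + jitter, kind="stable")


# ---------------------------------------------------------------------------
# trial simulation (batch engine)
# ---------------------------------------------------------------------------

def _adoption_for(cond: "ConditionSpec", params: ModelParams) -> float:
    from .designs import effective_adoption  # local import: designs builds on core

    return effective_adoption(cond, params)


def _simulate_batch(
    cond: "ConditionSpec",
    params: ModelParams,
    n_trials: int,
    rng: np.random.Generator,
    disable_overwriting: bool,
    disable_perturbation: bool,
) -> np.ndarray:
    n = cond.list_length
    n_md, n_mi = cond.n_md, cond.n_mi
    n_feat = n_md + n_mi
    a = params.a_for(cond.task_domain)

    def _pm_ones(shape):
        return (rng.integers(0, 2, size=shape, dtype=np.int8) << 1) - 1

    sm = _pm_ones((n_trials, n, n_feat))
    pm = sm.copy()

    # Feature adoption: the concurrent task writes +1 into the leading
    # modality-independent features of every PM trace.  A fractional count F
    # is realised per trial as floor(F) features plus one more w.p. F-floor(F).
    f_adopt = _adoption_for(cond, params)
    if f_adopt > 0 and n_mi > 0:
        base = int(np.floor(f_adopt))
        frac = f_adopt - base
        k = base + (rng.random(n_trials) < frac)
        mask = np.arange(n_mi)[None, :] < k[:, None]  # (trials, n_mi)
        mi_view = pm[:, :, n_md:]
        pm[:, :, n_md:] = np.where(mask[:, None, :], np.int8(1), mi_view)

    if not disable_overwriting:
        if n > 1:
            # Each item is overwritten by its immediate follower, using the
            # follower's undegraded (post-adoption) values: the survival
            # mask is computed from the whole array before any zeroing.
            keep = pm[:, :-1, :] != pm[:, 1:, :]
            pm[:, :-1, :] *= keep
        if n_mi > 0:
            pseudo = _pm_ones((n_trials, n_mi))
            last_mi = pm[:, -1, n_md:]
            pm[:, -1, n_md:] = np.where(last_mi == pseudo, np.int8(0), last_mi)

    # PM-to-SM mismatch counts are fixed once encoding is done.  With
    # features in {-1, 0, +1} and SM in {-1, +1}, the count of mismatches
    # (a PM 0 mismatching either SM value) is (N - <pm, sm> + #zeros) / 2.
    pm_f = pm.astype(np.float32)
    sm_f = sm.astype(np.float32)
    dot = pm_f @ sm_f.transpose(0, 2, 1)  # (trials, cue, target)
    zeros = (pm == 0).sum(axis=2, dtype=np.float32)
    mismatch = (n_feat - dot + zeros[:, :, None]) / 2.0
    sims = np.exp(-(a / n_feat) * params.b * mismatch)  # (trials, cue, target)

    if disable_perturbation or params.theta == 0.0 or params.pi == 0:
        order = np.broadcast_to(np.arange(n), (n_trials, n))
    else:
        uncertainty = positional_uncertainty(n, params.theta, params.pi)
        cum = uncertainty.cumsum(axis=1)
        u = rng.random((n_trials, n)) * cum[None, :, -1]  # guard fp rounding
        pos = (u[:, :, None] < cum[None, :, :]).argmax(axis=2)
        jitter = rng.random((n_trials, n))
        order = np.argsort(pos + jitter, axis=1, kind="stable")

    rows = np.arange(n_trials)
    available = np.ones((n_trials, n), dtype=bool)
    r_counts = np.zeros((n_trials, n), dtype=np.int64)
    correct = np.zeros((n_trials, n), dtype=bool)

    for out_pos in range(n):
        cue = order[:, out_pos]
        s = sims[rows, cue, :] * available  # zero out already-recalled items
        # extreme a can underflow every available similarity to 0; the Luce
        # rule then degenerates to a uniform choice among available items
        dead = s.sum(axis=1) == 0.0
        if dead.any():
            s[dead] = available[dead]
        sampled = _sample_rows(s, rng)
        p_recover = np.exp(-params.c * r_counts[rows, sampled])
        success = rng.random(n_trials) < p_recover
        r_counts[rows, sampled] += 1
        # recovered items leave the search set; failures stay (omission here)
        available[rows, sampled] &= ~success
        correct[:, out_pos] = success & (sampled == out_pos)
    return correct


def simulate_trials(
    cond: "ConditionSpec",
    params: ModelParams,
    n_trials: int,
    rng: np.random.Generator,
    *,
    disable_overwriting: bool = False,
    disable_perturbation: bool = False,
) -> np.ndarray:
    """Simulate ``n_trials`` trials of one condition.

    Returns a boolean (n_trials, list_length) matrix; entry (t, p) is 1 iff
    the item presented at position p was emitted at output position p on
    trial t.  The two ``disable_*`` hooks exist for limit-case tests only
    and are never used in fitting runs.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    out = np.empty((n_trials, cond.list_length), dtype=bool)
    done = 0
    while done < n_trials:
        size = min(_MAX_BATCH, n_trials - done)
        out[done : done + size] = _simulate_batch(
            cond, params, size, rng, disable_overwriting, disable_perturbation
        )
        done += size
    return out


def simulate_trial(
    cond: "ConditionSpec",
    params: ModelParams,
    rng: np.random.Generator,
    *,
    disable_overwriting: bool = False,
    disable_perturbation: bool = False,
) -> np.ndarray:
    """Simulate a single trial; returns the binary correct-in-position vector."""
    return simulate_trials(
        cond,
        params,
        1,
        rng,
        disable_overwriting=disable_overwriting,
        disable_perturbation=disable_perturbation,
    )[0]


def simulate_curve(
    cond: "ConditionSpec",
    params: ModelParams,
    n_trials: int,
    rng: np.random.Generator,
) -> SerialPositionCurve:
    """Aggregate simulated trials into a serial-position curve."""
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    trials = simulate_trials(cond, params, n_trials, rng)
    return SerialPositionCurve(
        condition=cond.id,
        n_items=cond.list_length,
        proportions=trials.mean(axis=0),
        n_observations=n_trials,
    )
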