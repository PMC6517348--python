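"""Likelihood-free fitting by sequential Monte Carlo ABC with partial
rejection control (ABC-PRC).

The model is a simulator, so fitting proceeds by comparing simulated to
observed group serial-position curves through a root-mean-square summary
distance.  Generation 1 is rejection sampling from the prior at a pilot
tolerance; later generations resample a weighted particle, perturb it with
an independent Gaussian kernel, re-simulate, and accept when the simulated
distance beats the generation's tolerance, with the PRC importance weight
prior(proposal)/prior(source).  Tolerances follow an adaptive quantile
schedule.  Posteriors are summarised by weighted means and 95% highest
density intervals (shortest contiguous interval holding the mass).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import ModelParams, SerialPositionCurve, simulate_curve, simulate_trials
from .designs import ExperimentSpec

__all__ = [
    "ScaledBeta",
    "Uniform",
    "TruncatedNormal",
    "PriorSpec",
    "default_priors",
    "ABCConfig",
    "FitResult",
    "ToleranceScheduleError",
    "summary_distance",
    "weighted_hdi",
    "abc_prc_fit",
    "posterior_predictive",
    "simulate_experiment",
]


class ToleranceScheduleError(RuntimeError):
    """Raised when no proposal is accepted within the attempt budget."""


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaledBeta:
    """``scale * Beta(alpha, beta)`` on [0, scale]."""

    alpha: float
    beta: float
    scale: float

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, self.scale)

    def rvs(self, rng: np.random.Generator) -> float:
        return float(self.scale * rng.beta(self.alpha, self.beta))

    def pdf(self, x: float) -> float:
        if not 0.0 <= x <= self.scale:
            return 0.0
        return float(stats.beta.pdf(x / self.scale, self.alpha, self.beta) / self.scale)


@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float

    @property
    def support(self) -> tuple[float, float]:
        return (self.lo, self.hi)

    def rvs(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lo, self.hi))

    def pdf(self, x: float) -> float:
        if not self.lo <= x <= self.hi:
            return 0.0
        return 1.0 / (self.hi - self.lo)


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) truncated to [lo, inf) and renormalised."""

    mean: float
    sd: float
    lo: float = 0.0

    @property
    def support(self) -> tuple[float, float]:
        return (self.lo, np.inf)

    def _dist(self):
        a = (self.lo - self.mean) / self.sd
        return stats.truncnorm(a, np.inf, loc=self.mean, scale=self.sd)

    def rvs(self, rng: np.random.Generator) -> float:
        # inverse-CDF draw keeps everything on the caller's Generator
        u = rng.random()
        return float(self._dist().ppf(u))

    def pdf(self, x: float) -> float:
        if x < self.lo:
            return 0.0
        return float(self._dist().pdf(x))


@dataclass(frozen=True)
class PointMass:
    """Degenerate prior; useful for conditioning a parameter in tests."""

    value: float

    @property
    def support(self) -> tuple[float, float]:
        return (self.value, self.value)

    def rvs(self, rng: np.random.Generator) -> float:
        return self.value

    def pdf(self, x: float) -> float:
        return 1.0 if x == self.value else 0.0


class PriorSpec(Mapping[str, object]):
    """Ordered, named collection of independent 1-D priors."""

    def __init__(self, priors: Mapping[str, object]):
        self._priors = dict(priors)
        self.names = tuple(self._priors)

    def __getitem__(self, name: str):
        return self._priors[name]

    def __iter__(self):
        return iter(self._priors)

    def __len__(self) -> int:
        return len(self._priors)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([self._priors[n].rvs(rng) for n in self.names])

    def density(self, theta: np.ndarray) -> float:
        out = 1.0
        for name, x in zip(self.names, theta):
            out *= self._priors[name].pdf(float(x))
            if out == 0.0:
                return 0.0
        return out

    def in_support(self, theta: np.ndarray) -> bool:
        for name, x in zip(self.names, theta):
            lo, hi = self._priors[name].support
            if not lo <= x <= hi:
                return False
        return True


def default_priors(n_mi: int = 20, null: bool = False) -> PriorSpec:
    """The standard five-parameter prior (four when ``null``).

    Distance scalings: Normal(20, 10) truncated at 0.  Adoption rates:
    ``n_mi * Beta(2, 2)`` — a weak expectation that adoption affects some
    but not all modality-independent features.  The dissociation boost:
    Uniform(0, n_mi), no prior stance on the presence of a dissociation.
    The null model pins F_dissociation at zero and fits four parameters.
    """
    priors: dict[str, object] = {
        "a_spatial": TruncatedNormal(20.0, 10.0),
        "a_verbal": TruncatedNormal(20.0, 10.0),
        "F_tapping": ScaledBeta(2.0, 2.0, float(n_mi)),
        "F_suppression": ScaledBeta(2.0, 2.0, float(n_mi)),
    }
    if not null:
        priors["F_dissociation"] = Uniform(0.0, float(n_mi))
    return PriorSpec(priors)


# ---------------------------------------------------------------------------
# configuration / results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ABCConfig:
    """Settings for one ABC-PRC run.

    n_sim_trials is the number of simulated trials per condition per
    distance evaluation; pilot_samples prior-predictive simulations set the
    first tolerance at ``first_epsilon_quantile``; later tolerances are the
    ``epsilon_quantile`` of the previous generation's accepted distances.
    """

    n_particles: int = 500
    n_generations: int = 6
    n_sim_trials: int = 1000
    kernel_factor: float = 2.0
    pilot_samples: int = 500
    first_epsilon_quantile: float = 0.2
    epsilon_quantile: float = 0.5
    ess_fraction: float = 0.5
    max_attempts: int = 50_000

    def __post_init__(self) -> None:
        for name in ("n_particles", "n_generations", "n_sim_trials",
                     "pilot_samples", "max_attempts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.first_epsilon_quantile <= 1:
            raise ValueError("first_epsilon_quantile must be in (0, 1]")
        if not 0 < self.epsilon_quantile <= 1:
            raise ValueError("epsilon_quantile must be in (0, 1]")


@dataclass
class FitResult:
    """Weighted posterior sample from ABC-PRC, with summaries."""

    param_names: tuple[str, ...]
    particles: np.ndarray          # (n_particles, n_params)
    weights: np.ndarray            # normalised
    distances: np.ndarray
    epsilons: list[float]
    acceptance_rates: list[float]
    config: ABCConfig
    seed: int
    fixed_params: dict[str, float]

    @property
    def posterior_means(self) -> dict[str, float]:
        means = self.weights @ self.particles
        return dict(zip(self.param_names, map(float, means)))

    @property
    def posterior_sds(self) -> dict[str, float]:
        means = self.weights @ self.particles
        var = self.weights @ (self.particles - means) ** 2
        return dict(zip(self.param_names, map(float, np.sqrt(var))))

    def hdi(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        return {
            name: weighted_hdi(self.particles[:, j], self.weights, level)
            for j, name in enumerate(self.param_names)
        }

    def params_at_posterior_mean(self, base: ModelParams | None = None) -> ModelParams:
        base = base or ModelParams()
        return base.with_updates(**{**self.fixed_params, **self.posterior_means})

    def to_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "particles": self.particles.tolist(),
            "weights": self.weights.tolist(),
            "distances": self.distances.tolist(),
            "epsilons": self.epsilons,
            "acceptance_rates": self.acceptance_rates,
            "posterior_means": self.posterior_means,
            "hdi_95": {k: list(v) for k, v in self.hdi(0.95).items()},
            "config": asdict(self.config),
            "seed": self.seed,
            "fixed_params": self.fixed_params,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, payload: dict) -> "FitResult":
        return cls(
            param_names=tuple(payload["param_names"]),
            particles=np.asarray(payload["particles"], dtype=float),
            weights=np.asarray(payload["weights"], dtype=float),
            distances=np.asarray(payload["distances"], dtype=float),
            epsilons=list(payload["epsilons"]),
            acceptance_rates=list(payload["acceptance_rates"]),
            config=ABCConfig(**payload["config"]),
            seed=int(payload["seed"]),
            fixed_params=dict(payload["fixed_params"]),
        )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summary_distance(
    sim: Iterable[SerialPositionCurve], obs: Iterable[SerialPositionCurve]
) -> float:
    """RMS difference of proportion correct over all (condition, position)
    cells, every cell weighted equally."""
    sim_by_id = {c.condition: c for c in sim}
    obs_by_id = {c.condition: c for c in obs}
    if set(sim_by_id) != set(obs_by_id):
        missing = set(obs_by_id) ^ set(sim_by_id)
        raise ValueError(f"condition sets differ: {sorted(missing)}")
    sq, cells = 0.0, 0
    for cond_id, o in obs_by_id.items():
        s = sim_by_id[cond_id]
        if s.n_items != o.n_items:
            raise ValueError(f"condition {cond_id!r}: curve lengths differ")
        diff = s.proportions - o.proportions
        sq += float(diff @ diff)
        cells += o.n_items
    return float(np.sqrt(sq / cells))


def weighted_hdi(
    samples: np.ndarray, weights: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Shortest contiguous interval over the sorted sample whose cumulative
    weight reaches ``level``; ties go to the shortest then lowest window."""
    samples = np.asarray(samples, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample")
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("weights must have positive sum")
    order = np.argsort(samples, kind="stable")
    x = samples[order]
    w = weights[order] / wsum
    cum = np.concatenate([[0.0], np.cumsum(w)])
    n = x.size
    best = (np.inf, 0, n - 1)
    j = 0
    for i in range(n):
        if j < i:
            j = i
        # smallest j with mass(x[i..j]) >= level
        while j < n and cum[j + 1] - cum[i] < level - 1e-12:
            j += 1
        if j >= n:
            break
        width = x[j] - x[i]
        if width < best[0] - 1e-15:
            best = (width, i, j)
    if not np.isfinite(best[0]):
        return (float(x[0]), float(x[-1]))
    return (float(x[best[1]]), float(x[best[2]]))


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _params_from_theta(
    names: Sequence[str], theta: np.ndarray, fixed: Mapping[str, float]
) -> ModelParams:
    updates = dict(fixed)
    updates.update({n: float(v) for n, v in zip(names, theta)})
    return ModelParams(**updates)


def simulate_experiment(
    spec: ExperimentSpec,
    params: ModelParams,
    n_trials: int,
    rng: np.random.Generator,
) -> list[SerialPositionCurve]:
    """Simulate every condition of an experiment at one parameter vector."""
    return [simulate_curve(c, params, n_trials, rng) for c in spec.conditions]


def _distance_at(
    theta: np.ndarray,
    names: Sequence[str],
    fixed: Mapping[str, float],
    spec: ExperimentSpec,
    obs: Sequence[SerialPositionCurve],
    n_trials: int,
    rng: np.random.Generator,
) -> float:
    params = _params_from_theta(names, theta, fixed)
    sim = simulate_experiment(spec, params, n_trials, rng)
    return summary_distance(sim, obs)


def abc_prc_fit(
    obs: Sequence[SerialPositionCurve],
    spec: ExperimentSpec,
    priors: PriorSpec,
    config: ABCConfig | None = None,
    seed: int = 0,
    fixed_params: Mapping[str, float] | None = None,
    log: Callable[[str], None] | None = None,
) -> FitResult:
    """Fit the feature model to observed curves by ABC-PRC.

    Parameters
    ----------
    obs : sequence of SerialPositionCurve
        One group curve per condition of ``spec`` (matched by condition id).
    priors : PriorSpec
        Independent priors over the free parameters; anything not named
        here stays at ``fixed_params`` / ModelParams defaults.
    fixed_params : mapping, optional
        Non-fitted ModelParams fields (e.g. ``{"c": 2.0}``) applied to every
        simulation.
    """
    config = config or ABCConfig()
    fixed = dict(fixed_params or {})
    rng = np.random.default_rng(seed)
    names = priors.names

    obs_ids = {c.condition for c in obs}
    spec_ids = set(spec.condition_ids)
    if obs_ids != spec_ids:
        raise ValueError(
            f"observed conditions {sorted(obs_ids)} do not match experiment "
            f"conditions {sorted(spec_ids)}"
        )

    def _say(msg: str) -> None:
        if log is not None:
            log(msg)

    # pilot run sets the first tolerance
    pilot = np.empty(config.pilot_samples)
    for i in range(config.pilot_samples):
        theta = priors.sample(rng)
        pilot[i] = _distance_at(
            theta, names, fixed, spec, obs, config.n_sim_trials, rng
        )
    epsilon = float(np.quantile(pilot, config.first_epsilon_quantile))

    n = config.n_particles
    dim = len(names)
    particles = np.empty((n, dim))
    weights = np.full(n, 1.0 / n)
    distances = np.empty(n)
    epsilons: list[float] = []
    acceptance: list[float] = []

    for gen in range(1, config.n_generations + 1):
        if gen > 1:
            epsilon = float(np.quantile(distances, config.epsilon_quantile))
        epsilons.append(epsilon)
        new_particles = np.empty_like(particles)
        new_weights = np.empty(n)
        new_distances = np.empty(n)
        attempts = 0
        if gen > 1:
            means = weights @ particles
            sds = np.sqrt(weights @ (particles - means) ** 2)
            # a zero-spread component (degenerate prior or collapsed cloud)
            # is proposed unperturbed so it stays inside its support; snap
            # rounding-level spread to exactly zero
            sds[sds <= 1e-12 * np.maximum(1.0, np.abs(means))] = 0.0
            kernel_sd = config.kernel_factor * sds
            cum_w = np.cumsum(weights)
        for i in range(n):
            accepted = False
            for _ in range(config.max_attempts):
                attempts += 1
                if gen == 1:
                    theta = priors.sample(rng)
                    src_density = None
                else:
                    src = int(np.searchsorted(cum_w, rng.random() * cum_w[-1]))
                    src = min(src, n - 1)
                    theta = particles[src] + kernel_sd * rng.standard_normal(dim)
                    if not priors.in_support(theta):
                        continue
                    src_density = priors.density(particles[src])
                d = _distance_at(
                    theta, names, fixed, spec, obs, config.n_sim_trials, rng
                )
                if d <= epsilon:
                    new_particles[i] = theta
                    new_distances[i] = d
                    if gen == 1:
                        new_weights[i] = 1.0
                    else:
                        # PRC importance weight
                        new_weights[i] = priors.density(theta) / max(
                            src_density, 1e-300
                        )
                    accepted = True
                    break
            if not accepted:
                raise ToleranceScheduleError(
                    f"generation {gen}: no acceptance within "
                    f"{config.max_attempts} attempts at epsilon={epsilon:.4g}"
                )
        particles = new_particles
        distances = new_distances
        weights = new_weights / new_weights.sum()
        acceptance.append(n / attempts)
        ess = 1.0 / float(weights @ weights)
        _say(
            f"gen {gen}: epsilon={epsilon:.4f} acceptance={n / attempts:.3f} "
            f"ESS={ess:.1f}"
        )
        if ess < config.ess_fraction * n:
            idx = rng.choice(n, size=n, replace=True, p=weights)
            particles = particles[idx]
            distances = distances[idx]
            weights = np.full(n, 1.0 / n)

    return FitResult(
        param_names=tuple(names),
        particles=particles,
        weights=weights,
        distances=distances,
        epsilons=epsilons,
        acceptance_rates=acceptance,
        config=config,
        seed=seed,
        fixed_params=fixed,
    )


def posterior_predictive(
    fit: FitResult,
    spec: ExperimentSpec,
    config: ABCConfig | None = None,
    seed: int = 0,
    n_boot: int = 1000,
    level: float = 0.95,
) -> dict[str, dict[str, np.ndarray]]:
    """Simulate at the posterior means with bootstrap intervals per position.

    Returns, per condition id, the point proportions and the lower/upper
    bootstrap percentile bounds over simulated trials.
    """
    config = config or fit.config
    rng = np.random.default_rng(seed)
    params = fit.params_at_posterior_mean()
    alpha = (1.0 - level) / 2.0
    out: dict[str, dict[str, np.ndarray]] = {}
    for cond in spec.conditions:
        trials = simulate_trials(cond, params, config.n_sim_trials, rng)
        point = trials.mean(axis=0)
        idx = rng.integers(0, trials.shape[0], size=(n_boot, trials.shape[0]))
        boot_means = trials[idx].mean(axis=1)
        lo = np.quantile(boot_means, alpha, axis=0)
        hi = np.quantile(boot_means, 1.0 - alpha, axis=0)
        out[cond.id] = {
            "proportions": point,
            "lower": np.minimum(lo, point),
            "upper": np.maximum(hi, point),
        }
    return out
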