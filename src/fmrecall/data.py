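"""Synthetic group data and the serial-position-curve exchange format.

The generator emulates the group structure of the two shipped designs:
between-subjects groups of 24 participants, each scoring 13 trials per
condition, so a group curve is a mean over participant means and its
sampling noise is participant-averaged binomial — the structure the group
fits assume.

Exchange format: CSV with columns ``experiment, group, condition,
task_domain, dual_task, n_items, position, prop_correct, n_participants,
n_trials`` (1-based positions, as serial-position curves are universally
reported).  Synthetic files carry a provenance comment line (``# provenance:
{...}``) holding the generating parameters and seed; readers preserve it.
Deposited datasets with other column names can be read through the same
reader after a one-time column mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import ModelParams, SerialPositionCurve, simulate_trials
from .designs import ExperimentSpec

__all__ = [
    "GroupDataset",
    "generate_group_data",
    "write_curves",
    "read_curves",
    "recovery_report",
    "CSV_COLUMNS",
]

CSV_COLUMNS = (
    "experiment",
    "group",
    "condition",
    "task_domain",
    "dual_task",
    "n_items",
    "position",
    "prop_correct",
    "n_participants",
    "n_trials",
)

_REQUIRED = ("condition", "n_items", "position", "prop_correct")


@dataclass
class GroupDataset:
    """Group serial-position curves plus design metadata and provenance."""

    experiment: str
    curves: list[SerialPositionCurve]
    n_participants: int
    n_trials_per_participant: int
    condition_meta: dict[str, dict] = field(default_factory=dict)
    provenance: dict | None = None

    @property
    def condition_ids(self) -> tuple[str, ...]:
        return tuple(c.condition for c in self.curves)

    def curve(self, cond_id: str) -> SerialPositionCurve:
        for c in self.curves:
            if c.condition == cond_id:
                return c
        raise KeyError(cond_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.curves:
            meta = self.condition_meta.get(c.condition, {})
            for pos in range(c.n_items):
                rows.append(
                    {
                        "experiment": self.experiment,
                        "group": meta.get("group", ""),
                        "condition": c.condition,
                        "task_domain": meta.get("task_domain", ""),
                        "dual_task": meta.get("dual_task", ""),
                        "n_items": c.n_items,
                        "position": pos + 1,
                        "prop_correct": c.proportions[pos],
                        "n_participants": self.n_participants,
                        "n_trials": self.n_trials_per_participant,
                    }
                )
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def generate_group_data(
    spec: ExperimentSpec,
    true_params: ModelParams,
    n_participants: int = 24,
    n_trials: int = 13,
    seed: int = 0,
) -> GroupDataset:
    """Simulate a group experiment from known parameters.

    Each participant contributes ``n_trials`` simulated trials per
    condition; the group curve is the mean over participant means (equal to
    the pooled trial mean when every participant has the same trial count).
    """
    if n_participants < 1 or n_trials < 1:
        raise ValueError("participant and trial counts must be positive")
    rng = np.random.default_rng(seed)
    curves = []
    meta = {}
    for cond in spec.conditions:
        trials = simulate_trials(cond, true_params, n_participants * n_trials, rng)
        by_participant = trials.reshape(n_participants, n_trials, cond.list_length)
        group = by_participant.mean(axis=1).mean(axis=0)
        curves.append(
            SerialPositionCurve(
                condition=cond.id,
                n_items=cond.list_length,
                proportions=group,
                n_observations=n_participants * n_trials,
            )
        )
        meta[cond.id] = {
            "group": cond.group,
            "task_domain": cond.task_domain,
            "dual_task": cond.dual_task,
        }
    from dataclasses import asdict

    return GroupDataset(
        experiment=spec.name,
        curves=curves,
        n_participants=n_participants,
        n_trials_per_participant=n_trials,
        condition_meta=meta,
        provenance={
            "synthetic": True,
            "true_params": asdict(true_params),
            "seed": seed,
        },
    )


def write_curves(dataset: GroupDataset, path) -> None:
    """Write a dataset to CSV (provenance as a leading comment line)."""
    frame = dataset.to_frame()
    with open(path, "w", newline="") as fh:
        if dataset.provenance is not None:
            fh.write(f"# provenance: {json.dumps(dataset.provenance, sort_keys=True)}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_curves(path, column_map: Mapping[str, str] | None = None) -> GroupDataset:
    """Read a curves CSV back into a :class:`GroupDataset`.

    ``column_map`` renames foreign column names onto the package schema
    (``{"their_name": "our_name"}``) before validation; unknown extra
    columns are ignored but preserved in the returned frame-building path.
    Malformed rows raise with the 1-based file line number.
    """
    provenance = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = json.loads(first.split(":", 1)[1])
            header_line = 2
            frame = pd.read_csv(fh, float_precision="round_trip")
        else:
            header_line = 1
            fh.seek(0)
            frame = pd.read_csv(fh, float_precision="round_trip")
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    for idx, row in frame.iterrows():
        line = header_line + 1 + int(idx)
        p = row["prop_correct"]
        if not np.isfinite(p) or p < 0 or p > 1:
            raise ValueError(
                f"{path}, line {line}: prop_correct={p!r} outside [0, 1]"
            )
        pos, n_items = int(row["position"]), int(row["n_items"])
        if not 1 <= pos <= n_items:
            raise ValueError(
                f"{path}, line {line}: position {pos} outside 1..{n_items}"
            )

    curves = []
    meta: dict[str, dict] = {}
    for cond_id, block in frame.groupby("condition", sort=False):
        block = block.sort_values("position")
        n_items = int(block["n_items"].iloc[0])
        positions = block["position"].to_numpy()
        if not np.array_equal(positions, np.arange(1, n_items + 1)):
            raise ValueError(
                f"{path}: condition {cond_id!r} does not cover positions "
                f"1..{n_items} exactly once"
            )
        curves.append(
            SerialPositionCurve(
                condition=str(cond_id),
                n_items=n_items,
                proportions=block["prop_correct"].to_numpy(dtype=float),
                n_observations=int(
                    block.get("n_participants", pd.Series([0])).iloc[0]
                    * block.get("n_trials", pd.Series([0])).iloc[0]
                ),
            )
        )
        meta[str(cond_id)] = {
            key: (str(block[key].iloc[0]) if key in block.columns else "")
            for key in ("group", "task_domain", "dual_task")
        }
    return GroupDataset(
        experiment=str(frame["experiment"].iloc[0]) if "experiment" in frame else "",
        curves=curves,
        n_participants=int(frame["n_participants"].iloc[0])
        if "n_participants" in frame
        else 0,
        n_trials_per_participant=int(frame["n_trials"].iloc[0])
        if "n_trials" in frame
        else 0,
        condition_meta=meta,
        provenance=provenance,
    )


def recovery_report(
    spec: ExperimentSpec,
    true_params: ModelParams,
    config=None,
    n_replicates: int = 10,
    seed: int = 0,
    n_participants: int = 24,
    n_trials: int = 13,
    priors=None,
    log=None,
) -> pd.DataFrame:
    """Parameter-recovery study: repeat generate -> fit and summarise.

    Returns one row per fitted parameter with the true value, mean posterior
    mean, bias, RMSE, and the fraction of replicates whose 95% HDI covers
    the truth.
    """
    from .abc import ABCConfig, abc_prc_fit, default_priors

    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    config = config or ABCConfig()
    priors = priors or default_priors()
    names = priors.names
    estimates = {name: [] for name in names}
    covered = {name: [] for name in names}
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.generate_state(2 * n_replicates) % (2**31)
    for rep in range(n_replicates):
        data = generate_group_data(
            spec,
            true_params,
            n_participants=n_participants,
            n_trials=n_trials,
            seed=int(child_seeds[2 * rep]),
        )
        fit = abc_prc_fit(
            data.curves,
            spec,
            priors,
            config,
            seed=int(child_seeds[2 * rep + 1]),
        )
        means = fit.posterior_means
        hdis = fit.hdi(0.95)
        for name in names:
            truth = getattr(true_params, name)
            estimates[name].append(means[name])
            lo, hi = hdis[name]
            covered[name].append(lo <= truth <= hi)
        if log is not None:
            log(f"replicate {rep + 1}/{n_replicates} done")
    rows = []
    for name in names:
        truth = getattr(true_params, name)
        est = np.asarray(estimates[name])
        rows.append(
            {
                "parameter": name,
                "true_value": truth,
                "mean_estimate": est.mean(),
                "bias": est.mean() - truth,
                "rmse": float(np.sqrt(((est - truth) ** 2).mean())),
                "hdi95_coverage": float(np.mean(covered[name])),
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)
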