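"""Experiment designs and the dual-task feature-adoption mapping.

A :class:`ConditionSpec` describes one primary-task x dual-task cell; an
:class:`ExperimentSpec` bundles the cells that are fitted simultaneously.
Two presets ship with the package:

``exp1_brooks``
    Auditory Brooks matrix tasks, between-subjects: a spatial group (7-item
    lists) and a verbal group (5-item lists), each run alone, under
    articulatory suppression, and under spatial tapping — six curves, five
    free parameters (a_spatial, a_verbal, F_tapping, F_suppression,
    F_dissociation).

``gt_exp2``
    Visual order-reconstruction tasks (Guerard & Tremblay design): two
    groups, each doing verbal and spatial 7-item tasks alone and with one
    dual task (suppression for one group, tapping for the other) — eight
    curves, the same five free parameters, with 2 modality-dependent and
    20 modality-independent features (the model's standard visual setting).

Feature adoption is the mechanism linking dual task to recall: the
concurrent task's output is incorporated into every list item's primary
trace as shared +1 features, which raises inter-item similarity and hence
overwriting.  When the dual task's domain matches the primary task's
(tapping<->spatial, suppression<->verbal) the adoption count is boosted by
F_dissociation — that boost is what produces single and double
dissociations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ModelParams, Trace

__all__ = [
    "TASK_DOMAINS",
    "DUAL_TASKS",
    "ConditionSpec",
    "ExperimentSpec",
    "effective_adoption",
    "apply_feature_adoption",
    "preset_experiment",
    "PRESET_NAMES",
]

TASK_DOMAINS = ("verbal", "spatial")
DUAL_TASKS = ("none", "articulatory_suppression", "tapping")

# dual task -> (adoption-rate parameter, domain receiving the dissociation boost)
_ADOPTION_RULE = {
    "none": (None, None),
    "tapping": ("F_tapping", "spatial"),
    "articulatory_suppression": ("F_suppression", "verbal"),
}


@dataclass(frozen=True)
class ConditionSpec:
    """One primary-task x dual-task cell of an experiment."""

    id: str
    task_domain: str
    dual_task: str
    list_length: int
    n_md: int
    n_mi: int
    group: str = ""

    def __post_init__(self) -> None:
        if self.task_domain not in TASK_DOMAINS:
            raise ValueError(
                f"condition {self.id!r}: unknown task domain {self.task_domain!r}"
            )
        if self.dual_task not in DUAL_TASKS:
            raise ValueError(
                f"condition {self.id!r}: unknown dual task {self.dual_task!r}"
            )
        if self.list_length < 1:
            raise ValueError(f"condition {self.id!r}: list_length must be >= 1")
        if self.n_md < 0 or self.n_mi < 0 or self.n_md + self.n_mi < 1:
            raise ValueError(f"condition {self.id!r}: invalid feature counts")


@dataclass(frozen=True)
class ExperimentSpec:
    """An ordered set of conditions fitted simultaneously.

    The distance scaling ``a`` is tied to each condition's task domain
    (a_spatial or a_verbal); the three F parameters are shared across all
    conditions, so every preset has exactly five free parameters.
    """

    name: str
    conditions: tuple[ConditionSpec, ...]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("an experiment needs at least one condition")
        ids = [c.id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise ValueError("condition ids must be unique")

    @property
    def condition_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.conditions)

    def condition(self, cond_id: str) -> ConditionSpec:
        for c in self.conditions:
            if c.id == cond_id:
                return c
        raise KeyError(cond_id)

    @property
    def n_cells(self) -> int:
        """Total number of (condition, position) cells."""
        return sum(c.list_length for c in self.conditions)


def effective_adoption(cond: ConditionSpec, params: ModelParams) -> float:
    """Feature-adoption count for a condition under the matched-pair rule.

    No dual task adopts nothing; tapping adopts F_tapping, articulatory
    suppression adopts F_suppression; the matched pairing
    (tapping<->spatial, suppression<->verbal) adds F_dissociation.  The
    result is clamped to [0, n_mi] since only modality-independent features
    are adopted.
    """
    if cond.dual_task not in _ADOPTION_RULE:
        raise ValueError(f"unknown dual task {cond.dual_task!r}")
    rate_name, boosted_domain = _ADOPTION_RULE[cond.dual_task]
    if rate_name is None:
        return 0.0
    f = getattr(params, rate_name)
    if cond.task_domain == boosted_domain:
        f += params.F_dissociation
    return float(np.clip(f, 0.0, cond.n_mi))


def apply_feature_adoption(
    pm_traces: Sequence[Trace], F: float, rng: np.random.Generator
) -> list[Trace]:
    """Write adopted +1 features into every primary-memory trace.

    The leading ``k`` modality-independent features of each trace are set to
    +1, where ``k = floor(F)`` plus one more with probability ``F -
    floor(F)`` (one draw per call, i.e. per trial).  Secondary-memory traces
    are never touched.
    """
    if not pm_traces:
        return []
    n_mi = pm_traces[0].mi.size
    if F < 0 or F > n_mi:
        raise ValueError(f"adoption count F={F} outside [0, {n_mi}]")
    k = int(np.floor(F))
    if rng.random() < F - k:
        k += 1
    if k == 0:
        return list(pm_traces)
    out = []
    for tr in pm_traces:
        mi = tr.mi.copy()
        mi[:k] = 1
        out.append(Trace(md=tr.md, mi=mi))
    return out


def _exp1_brooks() -> ExperimentSpec:
    conds = []
    for domain, length in (("spatial", 7), ("verbal", 5)):
        for dual, tag in (
            ("none", "control"),
            ("tapping", "tapping"),
            ("articulatory_suppression", "suppression"),
        ):
            conds.append(
                ConditionSpec(
                    id=f"{domain}_{tag}",
                    task_domain=domain,
                    dual_task=dual,
                    list_length=length,
                    n_md=20,
                    n_mi=20,
                    group=domain,
                )
            )
    return ExperimentSpec(name="exp1_brooks", conditions=tuple(conds))


def _gt_exp2() -> ExperimentSpec:
    conds = []
    for group, dual, tag in (
        ("suppression_group", "articulatory_suppression", "suppression"),
        ("tapping_group", "tapping", "tapping"),
    ):
        for domain in ("verbal", "spatial"):
            conds.append(
                ConditionSpec(
                    id=f"{group}_{domain}_control",
                    task_domain=domain,
                    dual_task="none",
                    list_length=7,
                    n_md=2,
                    n_mi=20,
                    group=group,
                )
            )
            conds.append(
                ConditionSpec(
                    id=f"{group}_{domain}_{tag}",
                    task_domain=domain,
                    dual_task=dual,
                    list_length=7,
                    n_md=2,
                    n_mi=20,
                    group=group,
                )
            )
    return ExperimentSpec(name="gt_exp2", conditions=tuple(conds))


_PRESETS = {"exp1_brooks": _exp1_brooks, "gt_exp2": _gt_exp2}
PRESET_NAMES = tuple(_PRESETS)


def preset_experiment(name: str) -> ExperimentSpec:
    """Return a shipped experiment preset (``exp1_brooks`` or ``gt_exp2``)."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return factory()


def experiment_from_dict(payload: dict) -> ExperimentSpec:
    """Build an ExperimentSpec from a plain mapping (YAML config shape)."""
    conds = tuple(
        ConditionSpec(
            id=c["id"],
            task_domain=c["task_domain"],
            dual_task=c.get("dual_task", "none"),
            list_length=int(c["list_length"]),
            n_md=int(c["n_md"]),
            n_mi=int(c["n_mi"]),
            group=c.get("group", ""),
        )
        for c in payload["conditions"]
    )
    return ExperimentSpec(name=payload.get("name", "custom"), conditions=conds)
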