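"""Model/Results front end for fitting the feature model to group curves.

Follows the familiar two-object pattern: build a :class:`SerialRecallModel`
from observed serial-position curves and an experiment design, call
``fit()`` to run the ABC-PRC sampler, and work with the returned
:class:`SerialRecallResults` — posterior means, 95% HDIs, a ``summary()``
table, posterior-predictive simulation and plotting, and a
``compare_null()`` Bayes factor against the no-dissociation null model.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import abc as _abc
from .abc import ABCConfig, FitResult, PriorSpec, default_priors, weighted_hdi
from .compare import ModelComparisonResult, bayes_factor
from .core import ModelParams, SerialPositionCurve
from .data import GroupDataset, read_curves
from .designs import ExperimentSpec, preset_experiment

__all__ = ["SerialRecallModel", "SerialRecallResults"]


class SerialRecallModel:
    """Feature model of immediate serial recall, bound to observed data.

    Parameters
    ----------
    data : GroupDataset or sequence of SerialPositionCurve
        Observed group curves, one per condition of ``design``.
    design : ExperimentSpec or str
        The experiment design (or the name of a shipped preset).
    priors : PriorSpec, optional
        Priors over the free parameters; defaults to the standard
        five-parameter scheme (four under ``null=True``).
    null : bool
        Fit the null model (dissociation boost fixed at 0).
    fixed_params : mapping, optional
        Non-fitted ModelParams fields (recovery scaling c, perturbation
        settings theta/pi, ...) applied to every simulation.

    Examples
    --------
    >>> from fmrecall import SerialRecallModel, generate_group_data
    >>> from fmrecall import preset_experiment, ModelParams
    >>> design = preset_experiment("exp1_brooks")
    >>> data = generate_group_data(design, ModelParams(a_spatial=30.0), seed=1)
    >>> res = SerialRecallModel(data, design).fit(seed=1)   # doctest: +SKIP
    >>> print(res.summary())                                # doctest: +SKIP
    """

    def __init__(
        self,
        data: GroupDataset | Sequence[SerialPositionCurve],
        design: ExperimentSpec | str,
        priors: PriorSpec | None = None,
        null: bool = False,
        fixed_params: Mapping[str, float] | None = None,
    ):
        if isinstance(design, str):
            design = preset_experiment(design)
        self.design = design
        if isinstance(data, GroupDataset):
            self.data = data
            curves = data.curves
        else:
            curves = list(data)
            self.data = None
        self.curves = curves
        self.null = null
        n_mi = max(c.n_mi for c in design.conditions)
        self.priors = priors or default_priors(n_mi=n_mi, null=null)
        self.fixed_params = dict(fixed_params or {})
        if null and "F_dissociation" not in self.fixed_params:
            self.fixed_params["F_dissociation"] = 0.0
        obs_ids = {c.condition for c in curves}
        want = set(design.condition_ids)
        if obs_ids != want:
            missing = sorted(want - obs_ids)
            extra = sorted(obs_ids - want)
            raise ValueError(
                f"data/design condition mismatch (missing {missing}, extra {extra})"
            )

    @classmethod
    def from_csv(
        cls,
        path,
        design: ExperimentSpec | str,
        column_map: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "SerialRecallModel":
        return cls(read_curves(path, column_map=column_map), design, **kwargs)

    def simulate(
        self, params: ModelParams, n_trials: int = 1000, seed: int = 0
    ) -> list[SerialPositionCurve]:
        """Forward-simulate every condition of the design at ``params``."""
        rng = np.random.default_rng(seed)
        return _abc.simulate_experiment(self.design, params, n_trials, rng)

    def fit(
        self,
        config: ABCConfig | None = None,
        seed: int = 0,
        log=None,
    ) -> "SerialRecallResults":
        """Run the ABC-PRC sampler and wrap the posterior sample."""
        fit = _abc.abc_prc_fit(
            self.curves,
            self.design,
            self.priors,
            config,
            seed=seed,
            fixed_params=self.fixed_params,
            log=log,
        )
        return SerialRecallResults(self, fit)

    def compare_null(
        self,
        config: ABCConfig | None = None,
        seed: int = 0,
        log=None,
    ) -> ModelComparisonResult:
        """Bayes factor for the full model over the no-dissociation null."""
        if self.null:
            raise ValueError("compare_null needs the full model as the base")
        return bayes_factor(
            self.curves,
            self.design,
            self.priors,
            config,
            seed=seed,
            fixed_params=self.fixed_params,
            log=log,
        )


class SerialRecallResults:
    """Posterior sample and summaries from a fitted serial-recall model."""

    def __init__(self, model: SerialRecallModel, fit: FitResult):
        self.model = model
        self.fit = fit

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.fit.param_names

    @property
    def params(self) -> pd.Series:
        """Weighted posterior means."""
        return pd.Series(self.fit.posterior_means, name="posterior_mean")

    @property
    def bse(self) -> pd.Series:
        """Weighted posterior standard deviations."""
        return pd.Series(self.fit.posterior_sds, name="posterior_sd")

    def hdi(self, level: float = 0.95) -> pd.DataFrame:
        intervals = self.fit.hdi(level)
        return pd.DataFrame(
            {name: list(iv) for name, iv in intervals.items()},
            index=["lower", "upper"],
        ).T

    @property
    def params_object(self) -> ModelParams:
        """ModelParams at the posterior means (fixed fields included)."""
        return self.fit.params_at_posterior_mean()

    def summary(self, level: float = 0.95) -> str:
        hdi = self.hdi(level)
        lines = [
            "Feature model of immediate serial recall — ABC-PRC fit",
            f"design: {self.model.design.name}   "
            f"model: {'null (no dissociation)' if self.model.null else 'full'}",
            f"particles: {self.fit.config.n_particles}   "
            f"generations: {self.fit.config.n_generations}   "
            f"sim trials/condition: {self.fit.config.n_sim_trials}   "
            f"seed: {self.fit.seed}",
            f"final tolerance: {self.fit.epsilons[-1]:.4f}   "
            f"final acceptance: {self.fit.acceptance_rates[-1]:.3f}",
            "",
            f"{'parameter':<16}{'mean':>9}{'sd':>9}"
            f"{f'{level:.0%} HDI':>22}",
        ]
        means, sds = self.fit.posterior_means, self.fit.posterior_sds
        for name in self.param_names:
            lo, hi = hdi.loc[name, "lower"], hdi.loc[name, "upper"]
            lines.append(
                f"{name:<16}{means[name]:>9.2f}{sds[name]:>9.2f}"
                f"{f'[{lo:.2f}, {hi:.2f}]':>22}"
            )
        for name, value in sorted(self.fit.fixed_params.items()):
            lines.append(f"{name:<16}{value:>9.2f}   (fixed)")
        return "\n".join(lines)

    def posterior_predictive(
        self, seed: int = 0, n_boot: int = 1000, level: float = 0.95
    ) -> dict[str, dict[str, np.ndarray]]:
        """Simulated curves at the posterior means, with bootstrap HDIs."""
        return _abc.posterior_predictive(
            self.fit, self.model.design, self.fit.config, seed=seed,
            n_boot=n_boot, level=level,
        )

    def plot(self, seed: int = 0, ax=None):
        """Observed vs posterior-predictive serial-position curves."""
        import matplotlib.pyplot as plt

        pred = self.posterior_predictive(seed=seed)
        conds = self.model.design.conditions
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 5))
        obs_by_id = {c.condition: c for c in self.model.curves}
        for cond in conds:
            x = np.arange(1, cond.list_length + 1)
            obs = obs_by_id[cond.id]
            line, = ax.plot(x, obs.proportions, "o-", label=f"{cond.id} (obs)")
            p = pred[cond.id]
            ax.errorbar(
                x,
                p["proportions"],
                yerr=[p["proportions"] - p["lower"], p["upper"] - p["proportions"]],
                fmt="s--",
                color=line.get_color(),
                alpha=0.6,
            )
        ax.set_xlabel("serial position")
        ax.set_ylabel("proportion correct in position")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=7)
        return ax
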