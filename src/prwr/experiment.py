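"""End-to-end surrogate evaluation: replicate splits, fit, predict, score.

One replicate mimics a planner with inventories for q% of sites: draw the
q% sample, compute its RWR with subset-internal occupancies, fit the
forest, predict PRWR for the whole landscape, and measure SAI of the PRWR
ranking against the (precomputed, shared) optimal and random baselines.

A sweep repeats this for ``n_replicates`` independent samples at each q,
then summarizes the replicate SAI distribution by its mean and a
distribution-free 95% percentile interval; a q level is flagged
significant when that interval excludes zero.

Everything is a pure function of (inputs, master seed): per-replicate seeds
are derived by a counter scheme over (q index, replicate index, stage), so
re-running a sweep with the same master seed is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import STAGE_MODEL, STAGE_SPLIT, STAGE_TIEBREAK, child_seed
from .core_data import EnvironmentTable, OccurrenceMatrix, sample_split
from .env_selection import PredictorSet, pca_factors, select_predictors
from .errors import ConfigError, PrwrError
from .representation import (
    DEFAULT_FRACTIONS,
    AccumulationCurve,
    accumulation_curve,
    expected_random_curve,
    greedy_optimal_curve,
    sai,
)
from .rwr import compute_rwr, rarity_weights
from .surrogate import ModelConfig, fit_rwr_model, predict_prwr

__all__ = [
    "ExperimentConfig",
    "ReplicateResult",
    "SaiSummary",
    "run_replicate",
    "sweep",
    "summary_table",
    "summarize",
]

logger = logging.getLogger(__name__)

DEFAULT_Q = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60)


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings for a q-sweep.

    ``q_values`` defaults to 5..60% in steps of 5; ``n_replicates`` to 100.
    ``pca_sites`` chooses whether predictor selection sees the full
    landscape's environment ("all", the default — covariates are assumed
    known everywhere) or only each replicate's inventoried sites
    ("inventoried", which moves PCA inside the replicate loop).
    """

    q_values: tuple = DEFAULT_Q
    n_replicates: int = 100
    fractions: tuple = DEFAULT_FRACTIONS
    model: ModelConfig = field(default_factory=ModelConfig)
    master_seed: int = 0
    pca_sites: str = "all"

    def __post_init__(self) -> None:
        object.__setattr__(self, "q_values", tuple(self.q_values))
        object.__setattr__(self, "fractions", tuple(self.fractions))
        if not self.q_values:
            raise ConfigError("q_values is empty")
        for q in self.q_values:
            if not 0 < q < 100:
                raise ConfigError(f"q must be in (0, 100), got {q}")
        if self.n_replicates < 2:
            raise ConfigError(f"n_replicates must be >= 2, got {self.n_replicates}")
        if self.pca_sites not in ("all", "inventoried"):
            raise ConfigError(f"pca_sites must be 'all' or 'inventoried', got {self.pca_sites!r}")


@dataclass(frozen=True)
class ReplicateResult:
    """Outcome of one split-fit-predict-evaluate cycle."""

    q: float
    seed: int
    mean_sai: float
    oob_mse: float
    oob_r2: float
    n_inventoried: int


@dataclass(frozen=True)
class SaiSummary:
    """Replicate SAI distribution at one q: mean, 95% percentile CI, and
    the significance flag (CI excludes zero)."""

    q: float
    values: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    significant: bool

    @classmethod
    def from_values(cls, q: float, values: Sequence[float]) -> "SaiSummary":
        v = np.asarray(values, dtype=float)
        # inverted-CDF quantiles: for 2 replicates the CI is exactly min..max
        lo = float(np.quantile(v, 0.025, method="inverted_cdf"))
        hi = float(np.quantile(v, 0.975, method="inverted_cdf"))
        return cls(
            q=q, values=v, mean=float(v.mean()), ci_low=lo, ci_high=hi,
            significant=not (lo <= 0.0 <= hi),
        )


def run_replicate(
    occ: OccurrenceMatrix,
    env: EnvironmentTable,
    predictors: PredictorSet | None,
    q: float,
    seed: int,
    cfg: ExperimentConfig,
    optimal: AccumulationCurve | None = None,
    random_curve: AccumulationCurve | None = None,
) -> ReplicateResult:
    """One replicate: split -> subset RWR -> fit -> PRWR -> SAI.

    ``occ`` and ``env`` must already be aligned.  ``predictors`` may be
    None only when ``cfg.pca_sites == 'inventoried'``, in which case PCA
    and selection run on the replicate's own inventoried environment.
    The optimal and random curves depend only on ``occ`` and are passed in
    precomputed by :func:`sweep`; if omitted they are computed here.
    """
    try:
        split = sample_split(occ, q, child_seed(seed, STAGE_SPLIT))
        sub_occ = occ.subset_sites(split.inventoried)
        sub_scores = compute_rwr(sub_occ, rarity_weights(sub_occ))
        if predictors is None:
            if cfg.pca_sites != "inventoried":
                raise ConfigError("predictors=None requires pca_sites='inventoried'")
            sub_env = env.subset_sites(split.inventoried)
            predictors = select_predictors(sub_env, pca_factors(sub_env))
        model = fit_rwr_model(
            env, sub_scores, predictors,
            replace(cfg.model, seed=child_seed(seed, STAGE_MODEL)),
        )
        prwr = predict_prwr(model, env)
        surrogate_curve = accumulation_curve(
            occ, prwr, seed=child_seed(seed, STAGE_TIEBREAK)
        )
        if optimal is None:
            optimal = greedy_optimal_curve(occ)
        if random_curve is None:
            random_curve = expected_random_curve(occ)
        value = sai(surrogate_curve, optimal, random_curve, cfg.fractions)
    except PrwrError as exc:
        raise type(exc)(f"replicate (q={q}, seed={seed}) failed: {exc}") from exc
    return ReplicateResult(
        q=q, seed=seed, mean_sai=value.mean_sai,
        oob_mse=model.oob_mse, oob_r2=model.oob_r2,
        n_inventoried=len(split.inventoried),
    )


def sweep(
    occ: OccurrenceMatrix, env: EnvironmentTable, cfg: ExperimentConfig
) -> tuple[dict, pd.DataFrame]:
    """Run the full q-sweep; returns ({q: SaiSummary}, replicate log).

    The optimal and random curves depend only on the occurrence matrix and
    are computed once and shared across all replicates; PCA predictor
    selection likewise happens once on the full environment table (unless
    ``pca_sites='inventoried'``).  Any replicate failure aborts the sweep —
    silently dropping replicates would bias the confidence intervals.
    """
    optimal = greedy_optimal_curve(occ)
    random_curve = expected_random_curve(occ)
    predictors = None
    if cfg.pca_sites == "all":
        predictors = select_predictors(env, pca_factors(env))

    summaries: dict = {}
    log_rows = []
    for qi, q in enumerate(cfg.q_values):
        values = []
        for rep in range(cfg.n_replicates):
            rep_seed = child_seed(cfg.master_seed, qi, rep)
            result = run_replicate(
                occ, env, predictors, q, rep_seed, cfg,
                optimal=optimal, random_curve=random_curve,
            )
            values.append(result.mean_sai)
            log_rows.append(
                {
                    "q": q, "replicate": rep, "seed": result.seed,
                    "oob_mse": result.oob_mse, "mean_sai": result.mean_sai,
                }
            )
            logger.info(
                "q=%s replicate=%d seed=%d oob_mse=%.5f mean_sai=%.4f",
                q, rep, result.seed, result.oob_mse, result.mean_sai,
            )
        summaries[q] = SaiSummary.from_values(q, values)
    return summaries, pd.DataFrame(log_rows)


def summary_table(summaries: dict) -> pd.DataFrame:
    """Tidy per-q table: q, mean, CI_low, CI_high, significant."""
    rows = [
        {
            "q": s.q, "mean": s.mean, "CI_low": s.ci_low,
            "CI_high": s.ci_high, "significant": s.significant,
        }
        for s in (summaries[q] for q in sorted(summaries))
    ]
    return pd.DataFrame(rows)


def summarize(
    summaries: dict, out_csv: str | Path, out_plot: str | Path | None = None
) -> pd.DataFrame:
    """Write the tidy summary CSV and (optionally) an SAI-vs-q figure with
    95% CI bars."""
    table = summary_table(summaries)
    table.to_csv(out_csv, index=False)
    if out_plot is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        yerr = np.vstack(
            [table["mean"] - table["CI_low"], table["CI_high"] - table["mean"]]
        )
        ax.errorbar(
            table["q"], table["mean"], yerr=yerr, fmt="o-", capsize=3, color="black"
        )
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("q (% of sites inventoried)")
        ax.set_ylabel("SAI (mean over top fractions)")
        ax.set_title("Surrogate efficiency of PRWR vs inventory effort")
        fig.tight_layout()
        fig.savefig(out_plot, dpi=150)
        plt.close(fig)
    return table
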