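"""Diagnostics for predictive-uncertainty quality.

Confidence is the inverse of predicted variance: the confidence-error curve
reports the test error over the top-q% most confident predictions as q
sweeps a percentile grid, so a well-calibrated model shows error falling as
confidence rises. The variance-error Spearman correlation summarises the
same ranking in one number. The bias probe compares predicted-uncertainty
distributions between in-domain and out-of-domain (e.g. held-out scaffold)
molecules: a model that knows what it does not know inflates its
uncertainty on the held-out chemotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import UncertainPrediction

DEFAULT_GRID: tuple[float, ...] = tuple(range(5, 101, 5))

_KINDS = ("total", "epistemic", "aleatoric")


def _variance_of_kind(preds: UncertainPrediction, kind: str) -> np.ndarray:
    if kind == "total":
        return preds.var_total
    if kind == "epistemic":
        return preds.var_epistemic
    if kind == "aleatoric":
        return preds.var_aleatoric
    raise ValueError(f"unknown variance kind {kind!r}; expected one of {_KINDS}")


@dataclass
class ConfidenceErrorCurve:
    """Error over the top-q% most confident predictions per grid point q.

    ``rmse_at[i]`` is the error over the ceil(q_i% * n) lowest-variance
    predictions; at q = 100 it equals the full test-set error exactly.
    Ties in variance are broken by stable input order.
    """

    percentiles: np.ndarray
    rmse_at: np.ndarray
    ranking_variance_kind: str
    metric: str = "rmse"

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: columns percentile, rmse, variance_kind."""
        return pd.DataFrame(
            {
                "percentile": self.percentiles,
                self.metric: self.rmse_at,
                "variance_kind": self.ranking_variance_kind,
            }
        )


def _error(residuals: np.ndarray, metric: str) -> float:
    if metric == "rmse":
        return float(np.sqrt(np.mean(residuals**2)))
    if metric == "mae":
        return float(np.mean(np.abs(residuals)))
    raise ValueError(f"unknown metric {metric!r}")


def confidence_error_curve(
    preds: UncertainPrediction,
    truths: np.ndarray,
    kind: str = "total",
    grid: tuple[float, ...] = DEFAULT_GRID,
    metric: str = "rmse",
) -> ConfidenceErrorCurve:
    """Error as a function of confidence percentile.

    Predictions are sorted ascending by the chosen variance (stable sort,
    so ties keep input order); for each q in the grid the error is computed
    over the ceil(q% * n) most confident items.
    """
    truths = np.asarray(truths, dtype=float)
    if len(preds) == 0 or len(truths) == 0:
        raise ValueError("empty predictions or truths")
    if len(preds) != len(truths):
        raise ValueError("predictions and truths are not aligned")
    grid_arr = np.asarray(grid, dtype=float)
    if (grid_arr <= 0).any() or (grid_arr > 100).any():
        raise ValueError("percentile grid must lie in (0, 100]")
    variance = _variance_of_kind(preds, kind)
    order = np.argsort(variance, kind="stable")
    abs_err_sorted = (preds.mean - truths)[order]
    n = len(truths)
    rmse_at = np.empty_like(grid_arr)
    for i, q in enumerate(grid_arr):
        k = int(np.ceil(q / 100.0 * n))
        rmse_at[i] = _error(abs_err_sorted[:k], metric)
    return ConfidenceErrorCurve(
        percentiles=grid_arr,
        rmse_at=rmse_at,
        ranking_variance_kind=kind,
        metric=metric,
    )


def variance_error_spearman(
    preds: UncertainPrediction, truths: np.ndarray, kind: str = "total"
) -> float:
    """Spearman rank correlation between predicted variance and |error|.

    Ties receive average ranks. Returns NaN when either ranking is
    degenerate (constant), where the correlation is undefined.
    """
    truths = np.asarray(truths, dtype=float)
    if len(preds) < 3:
        raise ValueError("need at least 3 points for a rank correlation")
    variance = _variance_of_kind(preds, kind)
    abs_err = np.abs(preds.mean - truths)
    if np.ptp(variance) == 0 or np.ptp(abs_err) == 0:
        return float("nan")
    rho = stats.spearmanr(variance, abs_err).statistic
    return float(rho)


def ablate_uncertainty_sources(
    preds: UncertainPrediction,
    truths: np.ndarray,
    grid: tuple[float, ...] = DEFAULT_GRID,
    metric: str = "rmse",
) -> dict[str, ConfidenceErrorCurve]:
    """Confidence-error curves ranked by total, epistemic-only and
    aleatoric-only variance."""
    return {
        kind: confidence_error_curve(preds, truths, kind, grid, metric)
        for kind in _KINDS
    }


@dataclass
class BiasProbeResult:
    """Uncertainty-shift summary between in-domain and out-of-domain inputs.

    The substantive claim is the *direction* of the shift (out-of-domain
    uncertainty larger), not its magnitude; the rank-sum test is reported
    as a single planned comparison without multiplicity correction.
    """

    median_in: float
    median_out: float
    statistic: float
    p_value: float
    variances_in: np.ndarray
    variances_out: np.ndarray

    @property
    def shifted_up(self) -> bool:
        return self.median_out > self.median_in


def bias_probe(
    preds_in: UncertainPrediction,
    preds_out: UncertainPrediction,
    kind: str = "total",
) -> BiasProbeResult:
    """Compare predicted-uncertainty distributions across two input groups."""
    v_in = _variance_of_kind(preds_in, kind)
    v_out = _variance_of_kind(preds_out, kind)
    if len(v_in) == 0 or len(v_out) == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = stats.mannwhitneyu(v_out, v_in, alternative="two-sided")
    return BiasProbeResult(
        median_in=float(np.median(v_in)),
        median_out=float(np.median(v_out)),
        statistic=float(stat),
        p_value=float(p),
        variances_in=v_in,
        variances_out=v_out,
    )
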