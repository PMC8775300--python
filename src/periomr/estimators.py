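"""Two-sample MR estimators on harmonized summary statistics.

All three pooled estimators operate on per-SNP Wald ratios
``r_j = beta_outcome_j / beta_exposure_j`` with first-order standard
errors ``se(r_j) = se_outcome_j / |beta_exposure_j|`` (exposure-side
sampling error ignored — the NOME assumption, defensible for
genome-wide-significant instruments).

* **IVW** — inverse-variance-weighted mean of the ratios; algebraically
  identical to weighted regression of outcome on exposure effects through
  the origin with weights 1/se_outcome^2. Consistent only when every
  instrument is valid. The default multiplicative random-effects mode
  inflates the standard error by ``max(1, sqrt(Q/(J-1)))`` so that
  between-instrument heterogeneity widens, and can never narrow, the
  interval.
* **MR-Egger** — the same regression with a free intercept after
  orienting every instrument to a non-negative exposure effect. The slope
  estimates the causal effect under the InSIDE assumption; the intercept
  estimates the average directional pleiotropic effect, with intercept = 0
  expected in its absence. Inference uses the t distribution with J-2
  degrees of freedom and the same multiplicative residual-SD floor.
* **Weighted median** — the weighted 50th percentile of the ordered
  ratios; consistent when instruments carrying at least half the weight
  are valid. Its standard error comes from a parametric bootstrap with a
  mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedPair

__all__ = [
    "WaldEstimate",
    "MREstimate",
    "InsufficientInstrumentsError",
    "UndefinedRatioError",
    "SingularDesignError",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "cochran_q",
]

_Z95 = 1.959963984540054  # standard-normal 97.5% quantile
_TINY_P = 5e-324  # smallest subnormal float; keeps p in (0, 1]


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator's minimum."""


class UndefinedRatioError(ValueError):
    """Wald ratio undefined (zero exposure effect)."""


class SingularDesignError(ValueError):
    """Egger design matrix has no exposure-effect spread."""


@dataclass(frozen=True)
class WaldEstimate:
    """Per-SNP causal estimate: outcome effect over exposure effect."""

    snp_id: str
    ratio: float
    se: float


@dataclass(frozen=True)
class MREstimate:
    """One pooled method's causal estimate with its uncertainty.

    ``intercept`` fields are populated only for MR-Egger; ``q_*`` fields
    carry Cochran heterogeneity diagnostics where defined.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_p: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.theta <= self.ci_high):
            raise ValueError("confidence interval must bracket theta")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("pvalue must lie in (0, 1]")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")


def wald_ratio(pair: HarmonizedPair) -> WaldEstimate:
    """Single-SNP causal estimate with first-order standard error."""
    if pair.beta_exposure == 0:
        raise UndefinedRatioError(f"{pair.snp_id}: zero exposure effect")
    return WaldEstimate(
        snp_id=pair.snp_id,
        ratio=pair.beta_outcome / pair.beta_exposure,
        se=pair.se_outcome / abs(pair.beta_exposure),
    )


def _ratio_arrays(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray]:
    estimates = [wald_ratio(p) for p in pairs]
    r = np.array([e.ratio for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    return r, se


def _two_sided_normal_p(z: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), _TINY_P, 1.0))


def ivw(pairs: Sequence[HarmonizedPair], mode: str = "random") -> MREstimate:
    """Inverse-variance-weighted pooled estimate.

    ``mode="fixed"`` uses the fixed-effect standard error
    ``(sum w_j)^(-1/2)``; ``mode="random"`` (default) multiplies it by
    ``max(1, sqrt(Q/(J-1)))``. With a single instrument both modes reduce
    to the Wald ratio.
    """
    if mode not in ("fixed", "random"):
        raise ValueError("mode must be 'fixed' or 'random'")
    if len(pairs) < 1:
        raise InsufficientInstrumentsError("IVW requires >= 1 instrument")
    r, se_r = _ratio_arrays(pairs)
    w = se_r**-2.0
    theta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    j = len(pairs)
    q_stat = q_df = q_p = None
    se = se_fixed
    if j >= 2:
        q = float(np.sum(w * (r - theta) ** 2))
        q_stat, q_df = q, j - 1
        q_p = float(np.clip(stats.chi2.sf(q, j - 1), _TINY_P, 1.0))
        if mode == "random":
            se = se_fixed * max(1.0, float(np.sqrt(q / (j - 1))))
    return MREstimate(
        method="IVW",
        theta=theta,
        se=se,
        ci_low=theta - _Z95 * se,
        ci_high=theta + _Z95 * se,
        pvalue=_two_sided_normal_p(theta / se),
        n_snps=j,
        q_stat=q_stat,
        q_df=q_df,
        q_p=q_p,
    )


def egger(pairs: Sequence[HarmonizedPair]) -> MREstimate:
    """MR-Egger regression: slope = causal effect, intercept = average
    directional pleiotropy.

    Every pair is first oriented so the exposure effect is non-negative
    (both betas negated where needed); the regression of outcome on
    exposure effects uses weights 1/se_outcome^2 and a free intercept.
    Standard errors carry the multiplicative residual-SD floor
    ``max(1, sigma)``; p-values and the 95% CI use the t distribution with
    J-2 degrees of freedom.
    """
    j = len(pairs)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger requires >= 3 instruments")
    bx = np.array([p.beta_exposure for p in pairs], dtype=float)
    by = np.array([p.beta_outcome for p in pairs], dtype=float)
    se_y = np.array([p.se_outcome for p in pairs], dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0.0:
        raise SingularDesignError("no spread in exposure effects")
    fit = sm.WLS(by, sm.add_constant(bx), weights=se_y**-2.0).fit()
    sigma = float(np.sqrt(fit.scale))
    # unit-scale SEs from (X'WX)^-1, then the multiplicative max(1, sigma) floor;
    # robust to the exact-fit case sigma = 0
    se_unit = np.sqrt(np.diag(fit.normalized_cov_params))
    intercept, slope = (float(v) for v in fit.params)
    se_intercept, se_slope = (float(v) * max(1.0, sigma) for v in se_unit)
    df = j - 2
    t_crit = float(stats.t.ppf(0.975, df))

    def _t_p(est: float, se: float) -> float:
        return float(np.clip(2.0 * stats.t.sf(abs(est / se), df), _TINY_P, 1.0))

    return MREstimate(
        method="MR-Egger",
        theta=slope,
        se=se_slope,
        ci_low=slope - t_crit * se_slope,
        ci_high=slope + t_crit * se_slope,
        pvalue=_t_p(slope, se_slope),
        n_snps=j,
        intercept=intercept,
        intercept_se=se_intercept,
        intercept_p=_t_p(intercept, se_intercept),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted 50th percentile of the ordered ratios.

    With cumulative weights S_j, the standardized midpoints
    p_j = (S_j - w_j/2) / S_total define a piecewise-linear quantile
    function; the estimate is its value at p = 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    cum = np.cumsum(w)
    p = (cum - w / 2.0) / cum[-1]
    return float(np.interp(0.5, p, r))


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median pooled estimate with parametric-bootstrap SE.

    The bootstrap redraws each beta from a normal centred on its observed
    value with its stated standard error, recomputes the weighted median,
    and takes the standard deviation over ``n_boot`` replicates. The seed
    is mandatory for reproducibility of the stochastic standard error.
    """
    j = len(pairs)
    if j < 3:
        raise InsufficientInstrumentsError("weighted median requires >= 3 instruments")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if seed is None:
        raise ValueError("an explicit seed is required")
    r, se_r = _ratio_arrays(pairs)
    w = se_r**-2.0
    theta = _weighted_median(r, w)

    bx = np.array([p.beta_exposure for p in pairs], dtype=float)
    by = np.array([p.beta_outcome for p in pairs], dtype=float)
    se_x = np.array([p.se_exposure for p in pairs], dtype=float)
    se_y = np.array([p.se_outcome for p in pairs], dtype=float)
    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, se_x, size=(n_boot, j))
    by_star = rng.normal(by, se_y, size=(n_boot, j))
    with np.errstate(divide="ignore", invalid="ignore"):
        r_star = by_star / bx_star
        w_star = (bx_star / se_y) ** 2
    boot = np.empty(n_boot)
    for b in range(n_boot):  # np.interp is 1-D; the per-row loop is cheap
        boot[b] = _weighted_median(r_star[b], w_star[b])
    se = float(np.std(boot, ddof=1))
    return MREstimate(
        method="weighted-median",
        theta=theta,
        se=se,
        ci_low=theta - _Z95 * se,
        ci_high=theta + _Z95 * se,
        pvalue=_two_sided_normal_p(theta / se),
        n_snps=j,
    )


def cochran_q(
    pairs: Sequence[HarmonizedPair], theta: float
) -> tuple[float, int, float]:
    """Cochran heterogeneity statistic of the Wald ratios about ``theta``.

    Returns ``(Q, df, p)`` with ``Q = sum w_j (r_j - theta)^2``,
    ``df = J - 1`` and a chi-square upper-tail p-value.
    """
    if len(pairs) < 2:
        raise InsufficientInstrumentsError("Cochran Q requires >= 2 instruments")
    r, se_r = _ratio_arrays(pairs)
    w = se_r**-2.0
    q = float(np.sum(w * (r - theta) ** 2))
    df = len(pairs) - 1
    return q, df, float(np.clip(stats.chi2.sf(q, df), _TINY_P, 1.0))
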