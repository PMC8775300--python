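"""Shared test utilities: pair builders and independent oracles.

The oracles here (closed-form normal equations, hand interpolation)
deliberately avoid the code paths they check.
"""

from __future__ import annotations

import numpy as np

from periomr.harmonize import HarmonizedPair


def make_pair(
    snp_id: str = "rs1",
    bx: float = 1.0,
    by: float = 0.0,
    sey: float = 0.1,
    sex: float = 0.01,
) -> HarmonizedPair:
    return HarmonizedPair(
        snp_id=snp_id,
        effect_allele="a",
        beta_exposure=bx,
        se_exposure=sex,
        beta_outcome=by,
        se_outcome=sey,
    )


def ratio_pairs(ratios, ses) -> list[HarmonizedPair]:
    """Pairs with unit exposure effect, so Wald ratio = by and se(r) = sey."""
    return [
        make_pair(f"rs{i}", 1.0, r, s) for i, (r, s) in enumerate(zip(ratios, ses))
    ]


def random_pairs(rng: np.random.Generator, j: int) -> list[HarmonizedPair]:
    bx = rng.uniform(0.02, 0.3, j) * rng.choice([-1.0, 1.0], j)
    by = rng.normal(0.1 * bx, 0.02)
    sey = rng.uniform(0.005, 0.05, j)
    return [
        make_pair(f"rs{i}", float(bx[i]), float(by[i]), float(sey[i]))
        for i in range(j)
    ]


def egger_normal_equations(pairs) -> tuple[float, float, float, float]:
    """MR-Egger via explicit weighted normal equations.

    Returns (intercept, slope, se_intercept, se_slope) with the same
    orientation and residual-SD-floor conventions as the estimator, but
    computed from scratch with basic linear algebra.
    """
    bx = np.array([p.beta_exposure for p in pairs])
    by = np.array([p.beta_outcome for p in pairs])
    sey = np.array([p.se_outcome for p in pairs])
    s = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * s, by * s
    w = sey**-2.0
    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = x.T @ (w[:, None] * x)
    coef = np.linalg.solve(xtwx, x.T @ (w * by))
    resid = by - x @ coef
    dof = len(pairs) - 2
    sigma2 = float(np.sum(w * resid**2) / dof)
    cov_unit = np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov_unit)) * max(1.0, np.sqrt(sigma2))
    return float(coef[0]), float(coef[1]), float(ses[0]), float(ses[1])


def weighted_median_by_hand(ratios, weights) -> float:
    """Hand interpolation of the cumulative-weight step function."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    total = w.sum()
    cum = np.cumsum(w)
    p = (cum - w / 2) / total
    if 0.5 <= p[0]:
        return float(r[0])
    for k in range(1, len(r)):
        if p[k] >= 0.5:
            frac = (0.5 - p[k - 1]) / (p[k] - p[k - 1])
            return float(r[k - 1] + frac * (r[k] - r[k - 1]))
    return float(r[-1])
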