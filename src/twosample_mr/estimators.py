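"""Causal-effect estimators and diagnostics for two-sample MR.

Given J harmonized instruments with exposure effects beta_X, SE(beta_X) and
outcome effects beta_Y, SE(beta_Y), the per-SNP Wald ratio is
theta_j = beta_Yj / beta_Xj. The estimators combine these ratios:

* fixed-effect IVW — inverse-variance-weighted mean with weights
  w_j = beta_Xj^2 / SE(beta_Yj)^2; algebraically the slope of the
  zero-intercept weighted regression of beta_Y on beta_X with weights
  1/SE(beta_Y)^2.
* simple / weighted median — (weighted) median of the ratios; robust to up
  to 50% invalid instruments (by count / by weight). SEs come from a seeded
  parametric bootstrap.
* MR-Egger — the same weighted regression with a free intercept; a nonzero
  intercept estimates the average directional pleiotropic effect, and the
  slope remains a consistent causal estimate when pleiotropy is independent
  of instrument strength.
* Cochran's Q / I² — heterogeneity of the ratios around a reference value.

All estimates carry normal-theory 95% CIs except MR-Egger, which uses
t(J - 2) and inflates SEs by the residual scale (clamped below at 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    ValidationError,
)
from .harmonize import HarmonizedInstrument

__all__ = [
    "MREstimate",
    "EggerResult",
    "HeterogeneityResult",
    "ORTriple",
    "wald_ratio",
    "ivw_fixed",
    "simple_median",
    "weighted_median",
    "mr_egger",
    "heterogeneity",
    "to_or",
    "Z95",
]

#: standard-normal quantile for the fixed 95% confidence level
Z95 = float(stats.norm.ppf(0.975))

_TINY = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate (outcome units per unit exposure; log-OR for binary outcomes)."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope plus the directional-pleiotropy intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float
    scale_factor: float


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square p and the I² percentage."""

    Q: float
    df: int
    pvalue: float
    I2: float


class ORTriple(NamedTuple):
    or_: float
    ci_low: float
    ci_high: float


def _arrays(hs: Sequence[HarmonizedInstrument]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([h.beta_exp for h in hs], dtype=float)
    sx = np.array([h.se_exp for h in hs], dtype=float)
    by = np.array([h.beta_out for h in hs], dtype=float)
    sy = np.array([h.se_out for h in hs], dtype=float)
    zero = np.flatnonzero(bx == 0.0)
    if zero.size:
        raise DegenerateInstrumentError(
            f"zero exposure effect for {', '.join(hs[i].snp_id for i in zero)}"
        )
    return bx, sx, by, sy


def _normal_estimate(method: str, theta: float, se: float, n_snps: int) -> MREstimate:
    z = theta / se
    p = max(2.0 * stats.norm.sf(abs(z)), _TINY)
    return MREstimate(method, theta, se, theta - Z95 * se, theta + Z95 * se, min(p, 1.0), n_snps)


def wald_ratio(h: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Single-SNP causal estimate beta_Y / beta_X.

    The default SE is the first-order delta method SE(beta_Y)/|beta_X|;
    ``second_order`` adds the exposure-side term
    beta_Y^2 SE(beta_X)^2 / beta_X^4.
    """
    if h.beta_exp == 0.0:
        raise DegenerateInstrumentError(f"{h.snp_id}: zero exposure effect")
    theta = h.beta_out / h.beta_exp
    var = h.se_out**2 / h.beta_exp**2
    if second_order:
        var += h.beta_out**2 * h.se_exp**2 / h.beta_exp**4
    return _normal_estimate("wald", theta, float(np.sqrt(var)), 1)


def ivw_fixed(hs: Sequence[HarmonizedInstrument], random_effects: bool = False) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    ``random_effects`` applies the multiplicative random-effects variant:
    the SE is inflated by max(1, sqrt(Q / (J - 1))) — never deflated.
    """
    if not hs:
        raise InsufficientInstrumentsError("IVW needs at least 1 instrument")
    bx, _, by, sy = _arrays(hs)
    w = bx**2 / sy**2
    ratios = by / bx
    sw = float(w.sum())
    theta = float((w * ratios).sum() / sw)
    se = sw**-0.5
    if random_effects and len(hs) > 1:
        q = float((w * (ratios - theta) ** 2).sum())
        se *= max(1.0, np.sqrt(q / (len(hs) - 1)))
    return _normal_estimate("ivw_fe", theta, se, len(hs))


def _weighted_median_value(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    s = np.cumsum(w)
    p = (s - 0.5 * w) / s[-1]
    return float(np.interp(0.5, p, r))


def _bootstrap_se(
    hs: Sequence[HarmonizedInstrument], n_boot: int, seed: int, weighted: bool
) -> float:
    """Parametric bootstrap: redraw every beta from N(observed, SE^2), recompute the median."""
    bx, sx, by, sy = _arrays(hs)
    rng = np.random.default_rng(seed)
    bx_rep = rng.normal(bx, sx, size=(n_boot, len(hs)))
    by_rep = rng.normal(by, sy, size=(n_boot, len(hs)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = by_rep / bx_rep
    if not weighted:
        return float(np.std(np.median(ratios, axis=1), ddof=1))
    w_rep = bx_rep**2 / sy**2
    thetas = np.empty(n_boot)
    for i in range(n_boot):
        thetas[i] = _weighted_median_value(ratios[i], w_rep[i])
    return float(np.std(thetas, ddof=1))


def simple_median(hs: Sequence[HarmonizedInstrument], n_boot: int = 5000, seed: int = 0) -> MREstimate:
    """Median of the per-SNP Wald ratios; SE by seeded parametric bootstrap."""
    if len(hs) < 3:
        raise InsufficientInstrumentsError("simple median needs at least 3 instruments")
    bx, _, by, _ = _arrays(hs)
    theta = float(np.median(by / bx))
    se = _bootstrap_se(hs, n_boot, seed, weighted=False)
    return _normal_estimate("simple_median", theta, se, len(hs))


def weighted_median(hs: Sequence[HarmonizedInstrument], n_boot: int = 5000, seed: int = 0) -> MREstimate:
    """Inverse-variance weighted median of the Wald ratios.

    Ratios are ordered; with running weight sums S_j the standardized
    midpoints are p_j = (S_j - w_j/2) / S_J, and theta interpolates the
    ratios linearly at p = 0.5. Consistent when valid instruments carry
    more than half of the total weight.
    """
    if len(hs) < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 instruments")
    bx, _, by, sy = _arrays(hs)
    theta = _weighted_median_value(by / bx, bx**2 / sy**2)
    se = _bootstrap_se(hs, n_boot, seed, weighted=True)
    return _normal_estimate("weighted_median", theta, se, len(hs))


def mr_egger(hs: Sequence[HarmonizedInstrument]) -> EggerResult:
    """Weighted regression of outcome on exposure effects with a free intercept.

    Instruments are first oriented so every beta_X >= 0 (both betas negated
    where needed) — the intercept is only interpretable relative to the
    exposure-increasing allele. SEs are inflated by max(1, residual scale)
    and p-values use t(J - 2).
    """
    j = len(hs)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    bx, _, by, sy = _arrays(hs)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign

    w = 1.0 / sy**2
    sw, swx, swy = w.sum(), (w * bx).sum(), (w * by).sum()
    swxx, swxy = (w * bx * bx).sum(), (w * bx * by).sum()
    denom = sw * swxx - swx**2
    if denom <= 0 or np.isclose(denom / (sw * swxx), 0.0):
        raise ValidationError("MR-Egger: no variance in exposure effects (collinear instruments)")

    slope = (sw * swxy - swx * swy) / denom
    intercept = (swxx * swy - swx * swxy) / denom
    resid = by - intercept - slope * bx
    sigma = float(np.sqrt((w * resid**2).sum() / (j - 2)))
    scale = max(1.0, sigma)

    se_slope = float(np.sqrt(sw / denom)) * scale
    se_int = float(np.sqrt(swxx / denom)) * scale
    tdist = stats.t(df=j - 2)
    tq = float(tdist.ppf(0.975))

    p_slope = max(float(2.0 * tdist.sf(abs(slope / se_slope))), _TINY)
    p_int = max(float(2.0 * tdist.sf(abs(intercept / se_int))), _TINY)
    est = MREstimate(
        "egger_slope",
        float(slope),
        se_slope,
        float(slope - tq * se_slope),
        float(slope + tq * se_slope),
        min(p_slope, 1.0),
        j,
    )
    return EggerResult(est, float(intercept), se_int, min(p_int, 1.0), scale)


def heterogeneity(hs: Sequence[HarmonizedInstrument], theta_ref: float) -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios around ``theta_ref`` and the I² percentage."""
    if len(hs) < 2:
        raise InsufficientInstrumentsError("heterogeneity needs at least 2 instruments")
    bx, _, by, sy = _arrays(hs)
    w = bx**2 / sy**2
    q = float((w * (by / bx - theta_ref) ** 2).sum())
    df = len(hs) - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(q, df, max(p, _TINY), i2)


def to_or(est: MREstimate, level: float = 0.95, outcome_type: str = "binary") -> ORTriple:
    """Exponentiate a log-OR estimate into an odds ratio with its CI."""
    if outcome_type != "binary":
        raise TypeError("odds ratios are only defined for binary outcomes")
    if not est.se > 0:
        raise ValidationError("se must be > 0")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return ORTriple(
        float(np.exp(est.theta)),
        float(np.exp(est.theta - z * est.se)),
        float(np.exp(est.theta + z * est.se)),
    )
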