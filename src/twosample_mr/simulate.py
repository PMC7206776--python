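"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generative model mirrors the standard two-sample MR setting: per-SNP
true exposure effects gamma_j, estimated with sampling noise in an exposure
sample of size n1, and outcome effects theta * gamma_j (+ optional
pleiotropy alpha_j) estimated independently in an outcome sample of size
n2. Standard errors follow the usual GWAS scaling
1 / sqrt(2 * EAF * (1 - EAF) * n). Allele corruption modes (strand
complementation, effect/other swap, palindromic alleles) exercise the
harmonization layer.

Directional pleiotropy is expressed relative to the exposure-increasing
allele (beta_out gains sign(gamma_j) * alpha_j): allele orientation in a
summary table is arbitrary, and only under this convention does "mean
pleiotropic effect alpha" survive the re-orientation that MR-Egger (and any
directional statement) requires. Balanced pleiotropy is symmetric, so the
convention is immaterial there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .gwas_io import InstrumentSet, VariantAssociation

__all__ = ["SimulationParams", "SyntheticTruth", "simulate_two_sample", "calibration_experiment"]

_PLEIOTROPY_MODES = ("none", "balanced", "directional")
_CORRUPTIONS = ("none", "strand_flip", "allele_swap", "palindromic")

# non-palindromic allele pairs (effect, other)
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters for one synthetic two-sample dataset.

    Defaults emulate a well-powered biobank-scale design: 50 common
    variants, exposure GWAS of 250k and outcome GWAS of 180k individuals,
    per-allele effects of SD 0.05 trait-SD (mean instrument F well above
    100), no pleiotropy, no allele corruption.
    """

    n_snps: int = 50
    causal_effect: float = 0.0
    exposure_n: int = 250_000
    outcome_n: int = 180_000
    eaf_range: tuple[float, float] = (0.1, 0.9)
    exposure_effect_sd: float = 0.05
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.01
    pleiotropy_mean: float = 0.0
    invalid_fraction: float = 0.0
    corrupt: str = "none"
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if self.exposure_n < 2 or self.outcome_n < 2:
            raise ValidationError("sample sizes must be >= 2")
        lo, hi = self.eaf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("eaf_range must satisfy 0 < lo <= hi < 1")
        if self.exposure_effect_sd <= 0:
            raise ValidationError("exposure_effect_sd must be > 0")
        if self.pleiotropy_mode not in _PLEIOTROPY_MODES:
            raise ValidationError(f"pleiotropy_mode must be one of {_PLEIOTROPY_MODES}")
        if self.pleiotropy_sd < 0:
            raise ValidationError("pleiotropy_sd must be >= 0")
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ValidationError("invalid_fraction must be in [0, 1]")
        if self.corrupt not in _CORRUPTIONS:
            raise ValidationError(f"corrupt must be one of {_CORRUPTIONS}")


@dataclass(frozen=True)
class SyntheticTruth:
    """A simulated dataset paired with the parameters that generated it."""

    params: SimulationParams
    exposure_set: InstrumentSet
    outcome_assocs: InstrumentSet
    per_snp_pleiotropy: tuple[float, ...]


def _gwas_se(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, np.finfo(float).tiny)


def simulate_two_sample(params: SimulationParams) -> SyntheticTruth:
    """Draw one two-sample summary-statistics dataset under ``params``.

    Regenerating with the same seed reproduces every value bit-exactly.
    Corruption is applied to the outcome table only, after drawing, so the
    uncorrupted and corrupted datasets of a given seed are identical up to
    allele bookkeeping.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    j = params.n_snps

    eaf = rng.uniform(*params.eaf_range, size=j)
    gamma = rng.normal(0.0, params.exposure_effect_sd, size=j)
    se_exp = _gwas_se(eaf, params.exposure_n)
    beta_exp = rng.normal(gamma, se_exp)

    alpha = np.zeros(j)
    if params.pleiotropy_mode != "none" and params.invalid_fraction > 0:
        n_invalid = int(round(params.invalid_fraction * j))
        which = rng.choice(j, size=n_invalid, replace=False)
        mean = params.pleiotropy_mean if params.pleiotropy_mode == "directional" else 0.0
        alpha[which] = rng.normal(mean, params.pleiotropy_sd, size=n_invalid)

    se_out = _gwas_se(eaf, params.outcome_n)
    orient = np.where(gamma < 0, -1.0, 1.0)  # exposure-increasing-allele convention
    beta_out = rng.normal(params.causal_effect * gamma + orient * alpha, se_out)

    if params.corrupt == "palindromic":
        pair_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=j)
        pairs = [_PALINDROMIC_PAIRS[i] for i in pair_idx]
    else:
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=j)
        pairs = [_ALLELE_PAIRS[i] for i in pair_idx]

    def variant(i: int, beta: float, se: float, trait: str, n: int, ea: str, oa: str, eaf_i: float) -> VariantAssociation:
        return VariantAssociation(
            snp_id=f"rs{i + 1}",
            effect_allele=ea,
            other_allele=oa,
            beta=float(beta),
            se=float(se),
            eaf=float(eaf_i),
            chrom=str(1 + i % 22),
            pos=1_000_000 * (1 + i),
            n=n,
            pvalue=float(_pvalues(np.array([beta]), np.array([se]))[0]),
            trait=trait,
        )

    exposure = InstrumentSet(
        trait="sim_exposure",
        variants=tuple(
            variant(i, beta_exp[i], se_exp[i], "sim_exposure", params.exposure_n, *pairs[i], eaf[i])
            for i in range(j)
        ),
        exposure_type="continuous",
        source="synthetic",
    )

    out_variants = []
    for i in range(j):
        ea, oa = pairs[i]
        b, f = beta_out[i], eaf[i]
        if params.corrupt == "strand_flip":
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        elif params.corrupt == "allele_swap":
            ea, oa, b, f = oa, ea, -b, 1.0 - f
        out_variants.append(
            variant(i, b, se_out[i], "sim_outcome", params.outcome_n, ea, oa, f)
        )
    outcome = InstrumentSet(
        trait="sim_outcome",
        variants=tuple(out_variants),
        exposure_type="continuous",
        source="synthetic",
    )
    return SyntheticTruth(params, exposure, outcome, tuple(float(a) for a in alpha))


def calibration_experiment(
    grid: Sequence[SimulationParams],
    reps: int,
    seed: int,
    methods: Sequence[str] = ("ivw_fe", "egger_slope"),
) -> pd.DataFrame:
    """Monte-Carlo calibration summary over a grid of scenarios.

    For each scenario and method: mean bias, empirical SE of the estimate,
    mean estimated SE, 95% CI coverage of the true causal effect, and the
    rejection rate of the method's null test at 0.05 (for MR-Egger, also
    the intercept test's rejection rate and mean intercept).
    """
    from . import estimators as est
    from .harmonize import harmonize_set, usable

    if reps < 1:
        raise ValidationError("reps must be >= 1")
    seed_rng = np.random.default_rng(seed)
    rows = []
    for s_idx, base in enumerate(grid):
        rep_seeds = seed_rng.integers(0, 2**31 - 1, size=reps)
        acc: dict[str, dict[str, list[float]]] = {m: {"theta": [], "se": [], "cover": [], "reject": []} for m in methods}
        egger_int: list[float] = []
        egger_int_reject: list[float] = []
        theta_true = base.causal_effect
        for r in range(reps):
            truth = simulate_two_sample(replace(base, seed=int(rep_seeds[r])))
            hs, _ = harmonize_set(truth.exposure_set, truth.outcome_assocs)
            hs = usable(hs)
            for m in methods:
                if m == "ivw_fe":
                    e = est.ivw_fixed(hs)
                elif m == "egger_slope":
                    er = est.mr_egger(hs)
                    e = er.slope
                    egger_int.append(er.intercept)
                    egger_int_reject.append(float(er.intercept_p < 0.05))
                elif m == "simple_median":
                    e = est.simple_median(hs, n_boot=500, seed=int(rep_seeds[r]))
                elif m == "weighted_median":
                    e = est.weighted_median(hs, n_boot=500, seed=int(rep_seeds[r]))
                else:
                    raise ValidationError(f"unknown method {m!r}")
                acc[m]["theta"].append(e.theta)
                acc[m]["se"].append(e.se)
                acc[m]["cover"].append(float(e.ci_low <= theta_true <= e.ci_high))
                acc[m]["reject"].append(float(e.pvalue < 0.05))
        for m in methods:
            thetas = np.array(acc[m]["theta"])
            row = {
                "scenario": s_idx,
                "pleiotropy_mode": base.pleiotropy_mode,
                "causal_effect": theta_true,
                "method": m,
                "reps": reps,
                "mean_theta": float(thetas.mean()),
                "bias": float(thetas.mean() - theta_true),
                "empirical_se": float(thetas.std(ddof=1)) if reps > 1 else float("nan"),
                "mean_se": float(np.mean(acc[m]["se"])),
                "coverage": float(np.mean(acc[m]["cover"])),
                "rejection_rate": float(np.mean(acc[m]["reject"])),
            }
            if m == "egger_slope":
                row["mean_egger_intercept"] = float(np.mean(egger_int))
                row["egger_intercept_rejection"] = float(np.mean(egger_int_reject))
            rows.append(row)
    return pd.DataFrame(rows)
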