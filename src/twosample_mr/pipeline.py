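"""Orchestration of the exposure x outcome analysis grid.

For each exposure-outcome pair: harmonize instruments, run every configured
estimator that has enough instruments, attach heterogeneity and MR-Egger
pleiotropy diagnostics, and classify the pair against a Bonferroni-corrected
family-wise threshold (significant: primary-method p below alpha/n_tests;
suggestive: below 0.05 but above the corrected threshold; null otherwise).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import estimators as est
from .errors import ConfigurationError, MRError, ValidationError
from .gwas_io import InstrumentSet, OutcomeMeta
from .harmonize import (
    DEFAULT_EAF_FLIP_TOL,
    DEFAULT_PALINDROME_WINDOW,
    HarmonizationLog,
    harmonize_set,
    usable,
)

__all__ = ["AnalysisConfig", "PairResult", "bonferroni_threshold", "run_pair", "run_grid"]

#: estimators needing at least 3 instruments (sensitivity analyses)
_J3_METHODS = ("simple_median", "weighted_median", "egger")
_KNOWN_METHODS = ("ivw_fe",) + _J3_METHODS
PRIMARY_METHOD = "ivw_fe"


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis settings; defaults follow the package's conventions."""

    methods: tuple[str, ...] = _KNOWN_METHODS
    alpha: float = 0.05
    n_tests: int | None = None  # derived from the grid when None
    palindrome_eaf_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW
    eaf_flip_tol: float = DEFAULT_EAF_FLIP_TOL
    n_boot: int = 5000
    seed: int = 0
    decimals: int = 2
    ivw_random_effects: bool = False

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in _KNOWN_METHODS:
                raise ConfigurationError(f"unknown method {m!r}; known: {_KNOWN_METHODS}")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_tests is not None and self.n_tests < 1:
            raise ConfigurationError("n_tests must be >= 1")

    def alpha_bonf(self, n_tests: int | None = None) -> float:
        n = n_tests if n_tests is not None else (self.n_tests or 1)
        return self.alpha / n


@dataclass
class PairResult:
    """All estimates and diagnostics for one exposure-outcome pair."""

    exposure: str
    outcome: str
    outcome_type: str
    estimates: dict[str, est.MREstimate] = field(default_factory=dict)
    egger: est.EggerResult | None = None
    het: est.HeterogeneityResult | None = None
    n_snps_used: int = 0
    harmonization_log: HarmonizationLog | None = None
    significance: str = "null"
    skipped: dict[str, str] = field(default_factory=dict)
    error: str | None = None


def bonferroni_threshold(alpha: float, n_exposures: int, n_outcomes: int) -> float:
    """Family-wise significance threshold alpha / (exposures x outcomes)."""
    if alpha <= 0 or n_exposures <= 0 or n_outcomes <= 0:
        raise ValidationError("alpha and grid dimensions must be positive")
    return alpha / (n_exposures * n_outcomes)


def _pair_seed(base_seed: int, exposure: str, outcome: str) -> int:
    """Stable per-pair bootstrap seed, independent of grid position."""
    return (base_seed + zlib.crc32(f"{exposure}|{outcome}".encode())) % (2**31 - 1)


def _classify(pvalue: float | None, alpha: float, alpha_bonf: float) -> str:
    if pvalue is None:
        return "null"
    if pvalue < alpha_bonf:
        return "significant"
    if pvalue < alpha:
        return "suggestive"
    return "null"


def run_pair(
    exp_set: InstrumentSet,
    out_assocs: InstrumentSet,
    meta: OutcomeMeta,
    cfg: AnalysisConfig,
    n_tests: int | None = None,
) -> PairResult:
    """Harmonize and analyse one exposure-outcome pair.

    Estimators that need more instruments than survive harmonization are
    skipped with a logged reason (the study situation where a small
    instrument set "provides insufficient data" for sensitivity analyses);
    per-method failures are recorded, not fatal.
    """
    result = PairResult(exposure=exp_set.trait, outcome=meta.outcome, outcome_type=meta.outcome_type)
    harmonized, log = harmonize_set(
        exp_set, out_assocs, cfg.palindrome_eaf_window, cfg.eaf_flip_tol
    )
    hs = usable(harmonized)
    result.harmonization_log = log
    result.n_snps_used = len(hs)
    if not hs:
        result.error = "all instruments dropped during harmonization"
        return result

    seed = _pair_seed(cfg.seed, exp_set.trait, meta.outcome)
    for method in cfg.methods:
        try:
            if method == "ivw_fe":
                result.estimates[method] = est.ivw_fixed(hs, random_effects=cfg.ivw_random_effects)
            elif method in _J3_METHODS and len(hs) < 3:
                result.skipped[method] = (
                    f"insufficient instruments for sensitivity analysis ({len(hs)} < 3)"
                )
            elif method == "simple_median":
                result.estimates[method] = est.simple_median(hs, cfg.n_boot, seed)
            elif method == "weighted_median":
                result.estimates[method] = est.weighted_median(hs, cfg.n_boot, seed + 1)
            elif method == "egger":
                result.egger = est.mr_egger(hs)
                result.estimates["egger_slope"] = result.egger.slope
        except MRError as exc:
            result.skipped[method] = str(exc)

    ivw = result.estimates.get(PRIMARY_METHOD)
    if ivw is not None and len(hs) >= 2:
        result.het = est.heterogeneity(hs, ivw.theta)
    result.significance = _classify(
        ivw.pvalue if ivw is not None else None, cfg.alpha, cfg.alpha_bonf(n_tests)
    )
    return result


def run_grid(
    exposures: Sequence[InstrumentSet],
    outcomes: Sequence[tuple[OutcomeMeta, InstrumentSet]],
    cfg: AnalysisConfig,
) -> list[PairResult]:
    """Run the full Cartesian exposure x outcome grid, exposure-major order.

    ``n_tests`` for the Bonferroni threshold is the grid size unless the
    config overrides it (a mismatch triggers a warning). A failing pair is
    reported as a :class:`PairResult` with ``error`` set; the run aborts
    only if every pair fails.
    """
    if not exposures or not outcomes:
        raise ValidationError("exposure and outcome lists must be non-empty")
    grid_n = len(exposures) * len(outcomes)
    n_tests = cfg.n_tests if cfg.n_tests is not None else grid_n
    if cfg.n_tests is not None and cfg.n_tests != grid_n:
        warnings.warn(
            f"n_tests={cfg.n_tests} overrides the grid size {grid_n}; "
            "the Bonferroni threshold no longer matches the analysis grid",
            stacklevel=2,
        )
    results: list[PairResult] = []
    for exp_set in exposures:
        for meta, out_assocs in outcomes:
            try:
                results.append(run_pair(exp_set, out_assocs, meta, cfg, n_tests=n_tests))
            except MRError as exc:
                results.append(
                    PairResult(
                        exposure=exp_set.trait,
                        outcome=meta.outcome,
                        outcome_type=meta.outcome_type,
                        error=str(exc),
                    )
                )
    if all(r.error for r in results):
        raise MRError("every exposure-outcome pair failed; see per-pair errors")
    return results
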