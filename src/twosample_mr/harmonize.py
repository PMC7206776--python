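"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR requires the exposure and outcome effects of every SNP to be
expressed per copy of the *same* effect allele. Consortium tables disagree
on which allele carries the effect and occasionally on strand, so each SNP
is reconciled by allele matching, sign flipping, strand complementation,
and — for strand-ambiguous palindromic (A/T, G/C) SNPs — allele-frequency
comparison. SNPs that cannot be reconciled are dropped (never silently
passed to estimators) and every decision is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from .errors import NoOverlapError
from .gwas_io import InstrumentSet, VariantAssociation

__all__ = [
    "HarmonizedInstrument",
    "HarmonizationLog",
    "align_alleles",
    "harmonize_set",
    "AS_IS",
    "FLIPPED",
    "COMPLEMENTED",
    "PALINDROMIC_KEPT",
    "DROPPED",
]

AS_IS = "as_is"
FLIPPED = "flipped_sign"
COMPLEMENTED = "strand_complemented"
PALINDROMIC_KEPT = "palindromic_kept"
DROPPED = "dropped"

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_PALINDROME_WINDOW = (0.42, 0.58)
DEFAULT_EAF_FLIP_TOL = 0.08


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects of one SNP on a common effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    effect_allele: str
    action: str
    reason: str = ""

    @property
    def usable(self) -> bool:
        return self.action != DROPPED


@dataclass
class HarmonizationLog:
    """Per-SNP actions plus summary counts for one exposure-outcome pair."""

    records: list[tuple[str, str, str]] = field(default_factory=list)
    counts: dict[str, int] = field(
        default_factory=lambda: {
            "matched": 0,
            "flipped": 0,
            "complemented": 0,
            "dropped": 0,
            "absent_from_outcome": 0,
        }
    )

    def add(self, snp_id: str, action: str, reason: str = "") -> None:
        self.records.append((snp_id, action, reason))
        if action in (AS_IS, PALINDROMIC_KEPT):
            self.counts["matched"] += 1
        elif action == FLIPPED:
            self.counts["flipped"] += 1
        elif action == COMPLEMENTED:
            self.counts["complemented"] += 1
        elif action == DROPPED:
            self.counts["dropped"] += 1
        elif action == "absent_from_outcome":
            self.counts["absent_from_outcome"] += 1

    def to_tsv(self, stream: IO[str]) -> None:
        stream.write("snp_id\taction\treason\n")
        for snp_id, action, reason in self.records:
            stream.write(f"{snp_id}\t{action}\t{reason}\n")


def _is_palindromic(a: str | None, b: str | None) -> bool:
    return a is not None and b is not None and _COMPLEMENT.get(a) == b


def _in_window(eaf: float | None, window: tuple[float, float]) -> bool:
    return eaf is not None and window[0] <= eaf <= window[1]


def _build(exp: VariantAssociation, out: VariantAssociation, flip: bool, action: str, reason: str = "") -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=-out.beta if flip else out.beta,
        se_out=out.se,
        effect_allele=exp.effect_allele,
        action=action,
        reason=reason,
    )


def _drop(exp: VariantAssociation, out: VariantAssociation, reason: str) -> HarmonizedInstrument:
    return _build(exp, out, False, DROPPED, reason)


def align_alleles(
    exp: VariantAssociation,
    out: VariantAssociation,
    palindrome_eaf_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW,
    eaf_flip_tol: float = DEFAULT_EAF_FLIP_TOL,
) -> HarmonizedInstrument:
    """Express one SNP's outcome effect on the exposure's effect allele.

    Palindromic SNPs (effect/other alleles complementary) are resolved by
    allele frequency: ambiguous frequencies (either EAF inside
    ``palindrome_eaf_window``) drop the SNP; outside the window the SNP is
    kept, sign-flipped when the frequencies are discordant. A window of
    ``(0.5, 0.5)`` disables dropping. Non-palindromic SNPs are matched
    as-is, by swap (sign flip), or after A<->T / C<->G complementation.
    When the exposure's other allele is unrecorded, a swap is also
    recognised from ``out.eaf ~ 1 - exp.eaf`` within ``eaf_flip_tol``.
    """
    if exp.snp_id != out.snp_id:
        raise ValueError(f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")

    ea_x, oa_x = exp.effect_allele, exp.other_allele
    ea_y, oa_y = out.effect_allele, out.other_allele

    palindromic = _is_palindromic(ea_x, oa_x) or (
        oa_x is None and _is_palindromic(ea_y, oa_y) and ea_x in (ea_y, oa_y)
    )
    if palindromic:
        if exp.eaf is None or out.eaf is None:
            return _drop(exp, out, "palindromic SNP without allele frequencies")
        if _in_window(exp.eaf, palindrome_eaf_window) or _in_window(out.eaf, palindrome_eaf_window):
            return _drop(
                exp, out,
                f"palindromic with EAF inside ambiguity window {palindrome_eaf_window}",
            )
        concordant = (exp.eaf < 0.5) == (out.eaf < 0.5)
        if concordant:
            return _build(exp, out, False, PALINDROMIC_KEPT, "frequencies concordant")
        return _build(exp, out, True, PALINDROMIC_KEPT, "frequencies discordant; sign flipped")

    def match(ey: str, oy: str | None) -> str | None:
        """'same'/'swap'/None for outcome alleles (ey, oy) vs the exposure pair."""
        if ey == ea_x and (oa_x is None or oy is None or oy == oa_x):
            return "same"
        if oa_x is not None:
            if ey == oa_x and (oy is None or oy == ea_x):
                return "swap"
        else:
            if oy == ea_x:
                return "swap"
            if (
                ey != ea_x
                and exp.eaf is not None
                and out.eaf is not None
                and abs(out.eaf - (1.0 - exp.eaf)) <= eaf_flip_tol
            ):
                return "swap"
        return None

    m = match(ea_y, oa_y)
    if m == "same":
        reason = ""
        if oa_x is None and oa_y is None and exp.eaf is None:
            reason = "unverifiable: other allele and EAF missing on both sides; kept as-is"
        return _build(exp, out, False, AS_IS, reason)
    if m == "swap":
        return _build(exp, out, True, FLIPPED)

    cea, coa = _COMPLEMENT[ea_y], (None if oa_y is None else _COMPLEMENT[oa_y])
    m = match(cea, coa)
    if m == "same":
        return _build(exp, out, False, COMPLEMENTED)
    if m == "swap":
        return _build(exp, out, True, COMPLEMENTED, "complemented and sign flipped")

    return _drop(
        exp, out,
        f"irreconcilable alleles: exposure {ea_x}/{oa_x or '?'} vs outcome {ea_y}/{oa_y or '?'}",
    )


def harmonize_set(
    exp_set: InstrumentSet,
    out_set: InstrumentSet,
    palindrome_eaf_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW,
    eaf_flip_tol: float = DEFAULT_EAF_FLIP_TOL,
) -> tuple[list[HarmonizedInstrument], HarmonizationLog]:
    """Harmonize every exposure instrument found in the outcome table.

    Returns the full list of :class:`HarmonizedInstrument` (dropped SNPs
    included, flagged by ``action``) and a log whose counts cover the whole
    exposure set, instruments absent from the outcome included.
    """
    log = HarmonizationLog()
    out_by_id = out_set.by_id()
    harmonized: list[HarmonizedInstrument] = []
    n_common = 0
    for exp in exp_set:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            log.add(exp.snp_id, "absent_from_outcome", "instrument not in outcome table")
            continue
        n_common += 1
        h = align_alleles(exp, out, palindrome_eaf_window, eaf_flip_tol)
        log.add(h.snp_id, h.action, h.reason)
        harmonized.append(h)
    if n_common == 0:
        raise NoOverlapError("no overlapping instruments between exposure and outcome tables")
    return harmonized, log


def usable(instruments: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """Instruments that survived harmonization (dropped ones never reach estimators)."""
    return [h for h in instruments if h.usable]
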