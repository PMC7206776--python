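"""Reading, writing and filtering GWAS summary-statistic tables.

Summary statistics are exchanged as headered TSV/CSV tables; a column map
(canonical field -> source column name) adapts arbitrary consortium layouts.
A packaged fixture ships the genetic instruments for four lifestyle
exposures (moderate-to-vigorous physical activity, vigorous physical
activity, sedentary behaviours, sleep duration) drawn from published
UK Biobank and CHARGE GWAS, exactly as printed at source.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import IO, Iterator, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "VariantAssociation",
    "InstrumentSet",
    "OutcomeMeta",
    "FIXTURE_TRAITS",
    "read_associations",
    "write_associations",
    "load_instrument_fixture",
    "apply_selection_filters",
    "write_results_table",
]

_BASES = frozenset("ACGT")

#: canonical field names understood by column maps
CANONICAL_FIELDS = (
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "n",
    "pvalue",
    "chrom",
    "pos",
)
REQUIRED_FIELDS = ("snp_id", "effect_allele", "beta", "se")


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele effect in the trait's units (log-OR
    for binary traits); optional fields default to ``None`` (missing).
    """

    snp_id: str
    effect_allele: str
    beta: float
    se: float
    other_allele: str | None = None
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None
    n: int | None = None
    pvalue: float | None = None
    trait: str = ""
    ancestry: str = ""
    gene: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se!r}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: beta must be finite")
        if self.effect_allele not in _BASES:
            raise ValidationError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} is not a "
                "single base (multi-allelic or indel records are rejected)"
            )
        if self.other_allele is not None:
            if self.other_allele not in _BASES:
                raise ValidationError(
                    f"{self.snp_id}: other allele {self.other_allele!r} is not a single base"
                )
            if self.other_allele == self.effect_allele:
                raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.snp_id}: eaf {self.eaf!r} outside [0, 1]")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"{self.snp_id}: pvalue {self.pvalue!r} outside (0, 1]")
        if self.n is not None and self.n <= 0:
            raise ValidationError(f"{self.snp_id}: sample size must be positive")


@dataclass(frozen=True)
class InstrumentSet:
    """An ordered collection of instruments for one trait."""

    trait: str
    variants: tuple[VariantAssociation, ...]
    exposure_type: str = "continuous"  # continuous | binary
    source: str = ""

    def __post_init__(self) -> None:
        if self.exposure_type not in ("continuous", "binary"):
            raise ValidationError(f"unknown exposure_type {self.exposure_type!r}")
        seen: set[str] = set()
        for v in self.variants:
            if v.snp_id in seen:
                raise ValidationError(f"duplicate snp_id {v.snp_id} in set {self.trait!r}")
            seen.add(v.snp_id)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.variants)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(v.snp_id for v in self.variants)

    def by_id(self) -> dict[str, VariantAssociation]:
        return {v.snp_id: v for v in self.variants}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(v) for v in self.variants])


@dataclass(frozen=True)
class OutcomeMeta:
    """Provenance of an outcome GWAS: consortium, year, case/control counts."""

    outcome: str
    outcome_type: str  # binary | continuous
    n_cases: int | None = None
    n_controls: int | None = None
    n_total: int | None = None
    source: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if self.outcome_type not in ("binary", "continuous"):
            raise ValidationError(f"unknown outcome_type {self.outcome_type!r}")
        if self.outcome_type == "binary" and (self.n_cases is None or self.n_controls is None):
            raise ValidationError(f"{self.outcome}: binary outcomes require n_cases and n_controls")
        if self.outcome_type == "continuous" and self.n_total is None:
            raise ValidationError(f"{self.outcome}: continuous outcomes require n_total")


def _sniff_delimiter(header: str) -> str:
    # auto-detection is deliberately limited to tab and comma
    return "\t" if "\t" in header else ","


def _as_text(stream: str | IO[str]) -> str:
    if hasattr(stream, "read"):
        return stream.read()
    with open(stream, "r", encoding="utf-8") as fh:
        return fh.read()


def _parse_float(raw: object, field_name: str, row: int) -> float:
    try:
        return float(str(raw).replace(",", ""))
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: non-numeric {field_name} {raw!r}") from None


def read_associations(
    stream: str | IO[str],
    column_map: Mapping[str, str],
    trait: str,
    *,
    exposure_type: str = "continuous",
    source: str = "",
    delimiter: str | None = None,
) -> InstrumentSet:
    """Parse a delimited summary-statistics table into an :class:`InstrumentSet`.

    ``column_map`` maps canonical field names (``snp_id``, ``effect_allele``,
    ``beta``, ``se`` required; ``other_allele``, ``eaf``, ``n``, ``pvalue``,
    ``chrom``, ``pos`` optional) to the source table's column names. Fields
    without a mapped column are stored as missing.
    """
    for key in column_map:
        if key not in CANONICAL_FIELDS:
            raise ConfigurationError(f"unknown canonical field {key!r} in column map")
    for key in REQUIRED_FIELDS:
        if key not in column_map:
            raise ConfigurationError(f"column map must provide {key!r}")

    text = _as_text(stream)
    sep = delimiter if delimiter is not None else _sniff_delimiter(text.splitlines()[0] if text else "")
    frame = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)

    missing = [col for col in column_map.values() if col not in frame.columns]
    if missing:
        raise ConfigurationError(f"mapped column(s) {missing} absent from input header")

    def cell(row: pd.Series, key: str) -> str | None:
        if key not in column_map:
            return None
        raw = row[column_map[key]]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
            return None
        return str(raw).strip()

    variants: list[VariantAssociation] = []
    seen: set[str] = set()
    for i, (_, row) in enumerate(frame.iterrows()):
        snp_id = cell(row, "snp_id")
        if snp_id is None:
            raise ValidationError(f"row {i}: missing snp_id")
        if snp_id in seen:
            raise ValidationError(f"duplicate snp_id {snp_id}")
        seen.add(snp_id)
        eaf = cell(row, "eaf")
        n = cell(row, "n")
        pvalue = cell(row, "pvalue")
        pos = cell(row, "pos")
        try:
            variants.append(
                VariantAssociation(
                    snp_id=snp_id,
                    effect_allele=(cell(row, "effect_allele") or "").upper(),
                    other_allele=(lambda a: a.upper() if a else None)(cell(row, "other_allele")),
                    beta=_parse_float(cell(row, "beta"), "beta", i),
                    se=_parse_float(cell(row, "se"), "se", i),
                    eaf=None if eaf is None else _parse_float(eaf, "eaf", i),
                    chrom=cell(row, "chrom"),
                    pos=None if pos is None else int(_parse_float(pos, "pos", i)),
                    n=None if n is None else int(_parse_float(n, "n", i)),
                    pvalue=None if pvalue is None else _parse_float(pvalue, "pvalue", i),
                    trait=trait,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
    return InstrumentSet(trait=trait, variants=tuple(variants), exposure_type=exposure_type, source=source)


def write_associations(iset: InstrumentSet, stream: IO[str]) -> None:
    """Write an instrument set as TSV at full floating-point precision."""
    cols = ("snp_id", "chrom", "pos", "gene", "effect_allele", "other_allele", "eaf", "beta", "se", "n", "pvalue")
    stream.write("\t".join(cols) + "\n")
    for v in iset:
        row = [getattr(v, c) for c in cols]
        stream.write("\t".join("" if x is None else repr(x) if isinstance(x, float) else str(x) for x in row) + "\n")


#: trait label -> exposure scale of the packaged instruments
FIXTURE_TRAITS: dict[str, str] = {
    "MVPA": "continuous",
    "VPA": "binary",
    "sedentary": "continuous",
    "sleep_duration": "continuous",
}


def load_instrument_fixture(trait: str) -> InstrumentSet:
    """Return the packaged instruments for one lifestyle exposure.

    Values are stored exactly as printed at source (betas for sleep duration
    are minutes/night per allele; VPA is a binary trait, so its downstream
    estimates read "per 1 unit higher log odds"). The source table carries
    no non-effect allele, so ``other_allele`` is missing and allele
    resolution is deferred to harmonization.
    """
    if trait not in FIXTURE_TRAITS:
        raise KeyError(f"unknown trait {trait!r}; valid traits: {sorted(FIXTURE_TRAITS)}")
    with resources.files("twosample_mr.data").joinpath("lifestyle_instruments.tsv").open("r") as fh:
        frame = pd.read_csv(fh, sep="\t", dtype=str)
    rows = frame[frame["trait"] == trait]
    variants = tuple(
        VariantAssociation(
            snp_id=r["snp_id"],
            effect_allele=r["effect_allele"],
            beta=float(r["beta"]),
            se=float(r["se"]),
            eaf=float(r["eaf"]),
            chrom=r["chrom"],
            pos=int(r["pos"]),
            n=int(r["n"]),
            pvalue=float(r["pvalue"]),
            trait=trait,
            ancestry=r["ancestry"],
            gene=r["gene"],
        )
        for _, r in rows.iterrows()
    )
    return InstrumentSet(
        trait=trait,
        variants=variants,
        exposure_type=FIXTURE_TRAITS[trait],
        source=rows["source"].iloc[0],
    )


def apply_selection_filters(
    iset: InstrumentSet,
    p_threshold: float = 5e-8,
    locus_window_bp: int = 500_000,
) -> InstrumentSet:
    """Keep genome-wide-significant variants, one per locus.

    Variants with ``pvalue >= p_threshold`` are dropped. Surviving variants
    on the same chromosome are chained into loci (single linkage: adjacent
    positions closer than ``locus_window_bp``); only the lowest-p variant
    per locus is retained, ties broken by smaller SE then rsID. This is
    bookkeeping for "lowest p per LD cluster" — no reference-panel LD is
    computed.
    """
    for v in iset:
        if v.pvalue is None or v.chrom is None or v.pos is None:
            raise ValidationError(f"{v.snp_id}: selection filters need pvalue, chrom and pos")
    retained = [v for v in iset if v.pvalue < p_threshold]
    retained.sort(key=lambda v: (str(v.chrom), v.pos))

    kept: list[VariantAssociation] = []
    cluster: list[VariantAssociation] = []

    def flush() -> None:
        if cluster:
            kept.append(min(cluster, key=lambda v: (v.pvalue, v.se, v.snp_id)))

    for v in retained:
        if cluster and (v.chrom != cluster[-1].chrom or v.pos - cluster[-1].pos >= locus_window_bp):
            flush()
            cluster.clear()
        cluster.append(v)
    flush()

    order = {s: i for i, s in enumerate(iset.snp_ids)}
    kept.sort(key=lambda v: order[v.snp_id])
    return replace(iset, variants=tuple(kept))


def _fmt(x: float | None, decimals: int) -> str:
    return "" if x is None else f"{x:.{decimals}f}"


def write_results_table(results: Sequence, stream: IO[str], decimals: int = 2) -> None:
    """Render pipeline results as a deterministic TSV, one row per (pair, method).

    Binary outcomes are printed on the odds-ratio scale, continuous outcomes
    as effect sizes; the ``scale`` column records which ("OR" or "ES").
    """
    from .estimators import to_or  # local import to avoid a cycle

    if not results:
        raise ValidationError("no results")
    header = (
        "exposure\toutcome\tmethod\tn_snps\testimate\tse\tci_low\tci_high\tpvalue\tscale\tsignificance\n"
    )
    stream.write(header)
    for pr in results:
        if getattr(pr, "error", None):
            stream.write(
                f"{pr.exposure}\t{pr.outcome}\tERROR\t0\t\t\t\t\t\t\t{pr.error}\n"
            )
            continue
        binary = pr.outcome_type == "binary"
        for method, est in pr.estimates.items():
            if binary:
                or_, lo, hi = to_or(est)
                point, cl, ch, scale = or_, lo, hi, "OR"
            else:
                point, cl, ch, scale = est.theta, est.ci_low, est.ci_high, "ES"
            stream.write(
                f"{pr.exposure}\t{pr.outcome}\t{method}\t{est.n_snps}\t"
                f"{_fmt(point, decimals)}\t{est.se:.4f}\t{_fmt(cl, decimals)}\t{_fmt(ch, decimals)}\t"
                f"{est.pvalue:.3g}\t{scale}\t{pr.significance}\n"
            )
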