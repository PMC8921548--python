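"""Domain model and TSV I/O for the cardiomyopathy variant-triage pipeline.

The pipeline operates on three flat tables, all tab-delimited with a
mandatory header row:

* a **variant table** — one row per patient-variant observation, carrying
  the annotations a diagnostic lab records after panel sequencing
  (gene, variant class, population frequency, in-silico and phenotype
  flags, the lab's prior five-tier classification);
* a **gene-constraint table** — one row per (gene, cardiomyopathy
  subtype, variant class, optional protein region), carrying published
  burden-test results (case-excess significance, etiological fraction
  with optional CI) and gnomAD-style constraint metrics (pLI, mis_z);
* a **burden-counts table** — raw carrier counts in cases versus a
  population reference, from which case excess and etiological fraction
  can be recomputed.

Missing values are encoded as an empty cell or ``NA``; a bare ``.`` is a
validation error, not a missing value.  All readers validate every row
against the type invariants and report the offending (1-based) data row
and field on failure.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "Subtype",
    "ANY_SUBTYPE",
    "VariantClass",
    "PriorClass",
    "VariantObservation",
    "GeneConstraintEntry",
    "BurdenCounts",
    "Thresholds",
    "ValidationError",
    "read_variant_table",
    "read_constraint_table",
    "read_burden_table",
    "write_variant_table",
    "write_constraint_table",
    "write_burden_table",
]


class Subtype(str, Enum):
    """Cardiomyopathy subtype of the referred patient."""

    HCM = "HCM"
    DCM = "DCM"
    ACM = "ACM"
    LVNC = "LVNC"
    CM_UNCLASSIFIED = "CM_unclassified"


#: Sentinel token for constraint entries that apply to every subtype.
ANY_SUBTYPE = "ANY"


class VariantClass(str, Enum):
    """Broad functional class of a variant.

    ``truncating`` covers frameshift, nonsense and canonical splice
    donor/acceptor variants; ``non_truncating`` covers missense and
    in-frame insertions/deletions.  Anything else is ``other`` and is
    never matched by constraint entries.
    """

    TRUNCATING = "truncating"
    NON_TRUNCATING = "non_truncating"
    OTHER = "other"


class PriorClass(IntEnum):
    """Five-tier diagnostic classification (benign ... pathogenic)."""

    B = 1
    LB = 2
    VUS = 3
    LP = 4
    P = 5


_PRIOR_TOKENS = {c.name: c for c in PriorClass}
_PRIOR_TOKENS.update({str(c.value): c for c in PriorClass})


class ValidationError(ValueError):
    """Raised when a table row violates a type invariant.

    Carries the 1-based data-row number and the field name so the error
    message pinpoints the offending cell.
    """

    def __init__(self, message: str, row: Optional[int] = None, field: Optional[str] = None):
        self.row = row
        self.field = field
        prefix = ""
        if row is not None:
            prefix += f"row {row}"
        if field is not None:
            prefix += f"{', ' if prefix else ''}field {field}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


@dataclass(frozen=True)
class VariantObservation:
    """One patient-variant observation from the diagnostic cohort."""

    patient_id: str
    family_id: str
    subtype: Subtype
    gene: str
    variant_id: str
    variant_class: VariantClass
    popmax_af: Optional[float] = None
    protein_position: Optional[int] = None
    insilico_support: bool = False
    phenotype_specific: bool = False
    proband_count: int = 0
    segregating_meioses: int = 0
    prior_class: PriorClass = PriorClass.VUS
    founder_flag: bool = False

    def __post_init__(self) -> None:
        if self.popmax_af is not None and not (0.0 <= self.popmax_af <= 1.0):
            raise ValidationError(
                f"popmax_af must be in [0, 1], got {self.popmax_af}", field="popmax_af"
            )
        if self.protein_position is not None and self.protein_position < 1:
            raise ValidationError(
                f"protein_position must be positive, got {self.protein_position}",
                field="protein_position",
            )
        if self.proband_count < 0:
            raise ValidationError("proband_count must be non-negative", field="proband_count")
        if self.segregating_meioses < 0:
            raise ValidationError(
                "segregating_meioses must be non-negative", field="segregating_meioses"
            )


@dataclass(frozen=True)
class GeneConstraintEntry:
    """Published constraint record for a (gene, subtype, variant class).

    ``subtype is None`` means the entry applies to any subtype (written
    as ``ANY`` in the TSV).  ``region_start``/``region_end`` restrict the
    entry to a closed protein-residue interval; both missing means the
    entry is gene-wide.  An entry may carry case-excess/EF results, or
    gnomAD metrics (pLI/mis_z), or both.
    """

    gene: str
    subtype: Optional[Subtype]
    variant_class: VariantClass
    has_case_excess: bool = False
    ef: Optional[float] = None
    ef_ci_low: Optional[float] = None
    ef_ci_high: Optional[float] = None
    region_start: Optional[int] = None
    region_end: Optional[int] = None
    pli: Optional[float] = None
    mis_z: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("ef", "ef_ci_low", "ef_ci_high", "pli"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}", field=name)
        if (
            self.ef is not None
            and self.ef_ci_low is not None
            and self.ef_ci_high is not None
            and not (self.ef_ci_low <= self.ef <= self.ef_ci_high)
        ):
            raise ValidationError(
                f"ef CI [{self.ef_ci_low}, {self.ef_ci_high}] does not bracket ef={self.ef}",
                field="ef",
            )
        if (self.region_start is None) != (self.region_end is None):
            raise ValidationError(
                "region_start and region_end must be given together", field="region_start"
            )
        if self.region_start is not None and self.region_start > self.region_end:
            raise ValidationError(
                f"region_start {self.region_start} > region_end {self.region_end}",
                field="region_start",
            )

    @property
    def is_region_restricted(self) -> bool:
        return self.region_start is not None

    def region_contains(self, position: Optional[int]) -> bool:
        """Closed-interval containment test in protein-residue coordinates."""
        if not self.is_region_restricted or position is None:
            return False
        return self.region_start <= position <= self.region_end

    @property
    def is_ce_route(self) -> bool:
        """True when the gene/class was analysed in a case-excess study.

        A gene belongs to the case-excess/EF analysis when the entry
        records either a significant case excess or an etiological
        fraction estimate (genes analysed without significant excess
        keep their EF point estimate).  Entries that carry only gnomAD
        metrics are screenable but not CE-analysed.
        """
        return self.has_case_excess or self.ef is not None

    def key(self) -> tuple:
        return (
            self.gene,
            self.subtype.value if self.subtype else ANY_SUBTYPE,
            self.variant_class.value,
            self.region_start,
            self.region_end,
        )


@dataclass(frozen=True)
class BurdenCounts:
    """Raw carrier counts for one (gene, subtype, variant class) stratum."""

    gene: str
    subtype: Optional[Subtype]
    variant_class: VariantClass
    case_carriers: int
    case_n: int
    control_carriers: int
    control_n: int

    def __post_init__(self) -> None:
        if self.case_n <= 0 or self.control_n <= 0:
            raise ValidationError("sample sizes must be positive", field="case_n")
        if not (0 <= self.case_carriers <= self.case_n):
            raise ValidationError(
                f"case_carriers {self.case_carriers} exceeds case_n {self.case_n}",
                field="case_carriers",
            )
        if not (0 <= self.control_carriers <= self.control_n):
            raise ValidationError(
                f"control_carriers {self.control_carriers} exceeds control_n {self.control_n}",
                field="control_carriers",
            )


@dataclass(frozen=True)
class Thresholds:
    """All tunable cut-offs of the triage framework.

    Defaults follow the adapted ACMG rule set for cardiomyopathy genes:
    EF bands 0.8/0.9/0.95 for supporting/moderate/strong hotspot
    evidence, rarity below 0.004% for PM2, pLI > 0.90 and mis_z > 3 for
    the gnomAD intolerance screen, >=15 probands for PS4 and 3/5/7
    segregating meioses for the tiered co-segregation criterion.
    """

    rare_maf: float = 1e-4
    pm2_maf: float = 4e-5
    ef_reclass: float = 0.90
    ef_supporting_low: float = 0.80
    ef_moderate_low: float = 0.90
    ef_strong_low: float = 0.95
    pli_cut: float = 0.90
    mis_z_cut: float = 3.0
    ps4_probands: int = 15
    pp1_supporting: int = 3
    pp1_moderate: int = 5
    pp1_strong: int = 7
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.ef_supporting_low < self.ef_moderate_low < self.ef_strong_low <= 1.0):
            raise ValidationError(
                "EF bands must satisfy supporting < moderate < strong <= 1",
                field="ef_supporting_low",
            )
        for name in ("rare_maf", "pm2_maf", "ef_reclass", "ef_supporting_low",
                     "ef_moderate_low", "ef_strong_low", "pli_cut", "alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}", field=name)
        if not (0 < self.pp1_supporting <= self.pp1_moderate <= self.pp1_strong):
            raise ValidationError("PP1 tiers must be increasing", field="pp1_supporting")

    @classmethod
    def from_dict(cls, overrides: dict) -> "Thresholds":
        """Build thresholds from a (JSON) config dict; unknown keys error."""
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(overrides) - valid
        if unknown:
            raise ValidationError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**overrides)


# ---------------------------------------------------------------------------
# TSV parsing helpers


_MISSING_TOKENS = {"", "NA"}


def _parse_missing(token: str) -> bool:
    return token in _MISSING_TOKENS


def _parse_float(token: str, row: int, field: str) -> Optional[float]:
    if _parse_missing(token):
        return None
    try:
        value = float(token)
    except ValueError:
        raise ValidationError(f"cannot parse {token!r} as a number", row=row, field=field)
    if math.isnan(value):
        raise ValidationError("NaN is not a valid value", row=row, field=field)
    return value


def _parse_int(token: str, row: int, field: str) -> Optional[int]:
    if _parse_missing(token):
        return None
    try:
        return int(token)
    except ValueError:
        raise ValidationError(f"cannot parse {token!r} as an integer", row=row, field=field)


_BOOL_TOKENS = {
    "true": True, "false": False, "1": True, "0": False, "yes": True, "no": False,
}


def _parse_bool(token: str, row: int, field: str, default: Optional[bool] = None) -> bool:
    if _parse_missing(token):
        if default is None:
            raise ValidationError("boolean field may not be missing", row=row, field=field)
        return default
    try:
        return _BOOL_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValidationError(f"cannot parse {token!r} as a boolean", row=row, field=field)


def _parse_subtype(token: str, row: int, field: str, allow_any: bool = False):
    if allow_any and token == ANY_SUBTYPE:
        return None
    try:
        return Subtype(token)
    except ValueError:
        raise ValidationError(f"unknown subtype token {token!r}", row=row, field=field)


def _parse_class(token: str, row: int, field: str) -> VariantClass:
    try:
        return VariantClass(token)
    except ValueError:
        raise ValidationError(f"unknown variant class token {token!r}", row=row, field=field)


def _parse_prior(token: str, row: int, field: str) -> PriorClass:
    try:
        return _PRIOR_TOKENS[token]
    except KeyError:
        raise ValidationError(f"unknown prior class token {token!r}", row=row, field=field)


def _read_frame(path: Union[str, Path], required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError:
        raise
    except Exception as exc:  # malformed TSV
        raise ValidationError(f"cannot parse {path} as TSV: {exc}")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return frame


_VARIANT_COLUMNS = [
    "patient_id", "family_id", "subtype", "gene", "variant_id", "variant_class",
    "popmax_af", "protein_position", "insilico_support", "phenotype_specific",
    "proband_count", "segregating_meioses", "prior_class", "founder_flag",
]


def read_variant_table(
    path: Union[str, Path], thresholds: Optional[Thresholds] = None
) -> list[VariantObservation]:
    """Read and validate a variant observation table.

    Row order is preserved.  ``(patient_id, variant_id)`` must be unique.
    """
    frame = _read_frame(path, _VARIANT_COLUMNS)
    out: list[VariantObservation] = []
    seen: set[tuple[str, str]] = set()
    for i, rec in enumerate(frame.itertuples(index=False), start=1):
        row = rec._asdict()
        try:
            obs = VariantObservation(
                patient_id=row["patient_id"],
                family_id=row["family_id"],
                subtype=_parse_subtype(row["subtype"], i, "subtype"),
                gene=row["gene"],
                variant_id=row["variant_id"],
                variant_class=_parse_class(row["variant_class"], i, "variant_class"),
                popmax_af=_parse_float(row["popmax_af"], i, "popmax_af"),
                protein_position=_parse_int(row["protein_position"], i, "protein_position"),
                insilico_support=_parse_bool(row["insilico_support"], i, "insilico_support", False),
                phenotype_specific=_parse_bool(row["phenotype_specific"], i, "phenotype_specific", False),
                proband_count=_parse_int(row["proband_count"], i, "proband_count") or 0,
                segregating_meioses=_parse_int(row["segregating_meioses"], i, "segregating_meioses") or 0,
                prior_class=_parse_prior(row["prior_class"], i, "prior_class"),
                founder_flag=_parse_bool(row["founder_flag"], i, "founder_flag", False),
            )
        except ValidationError as exc:
            if exc.row is None:
                raise ValidationError(str(exc.args[0]).split(": ", 1)[-1], row=i, field=exc.field)
            raise
        key = (obs.patient_id, obs.variant_id)
        if key in seen:
            raise ValidationError(
                f"duplicate (patient_id, variant_id) pair {key}", row=i, field="variant_id"
            )
        seen.add(key)
        out.append(obs)
    return out


_CONSTRAINT_COLUMNS = [
    "gene", "subtype", "variant_class", "has_case_excess", "ef", "ef_ci_low",
    "ef_ci_high", "region_start", "region_end", "pli", "mis_z",
]


def read_constraint_table(path: Union[str, Path]) -> list[GeneConstraintEntry]:
    """Read and validate a gene-constraint table.

    ``(gene, subtype, variant_class, region)`` must be unique.
    """
    frame = _read_frame(path, _CONSTRAINT_COLUMNS)
    out: list[GeneConstraintEntry] = []
    seen: set[tuple] = set()
    for i, rec in enumerate(frame.itertuples(index=False), start=1):
        row = rec._asdict()
        try:
            entry = GeneConstraintEntry(
                gene=row["gene"],
                subtype=_parse_subtype(row["subtype"], i, "subtype", allow_any=True),
                variant_class=_parse_class(row["variant_class"], i, "variant_class"),
                has_case_excess=_parse_bool(row["has_case_excess"], i, "has_case_excess", False),
                ef=_parse_float(row["ef"], i, "ef"),
                ef_ci_low=_parse_float(row["ef_ci_low"], i, "ef_ci_low"),
                ef_ci_high=_parse_float(row["ef_ci_high"], i, "ef_ci_high"),
                region_start=_parse_int(row["region_start"], i, "region_start"),
                region_end=_parse_int(row["region_end"], i, "region_end"),
                pli=_parse_float(row["pli"], i, "pli"),
                mis_z=_parse_float(row["mis_z"], i, "mis_z"),
            )
        except ValidationError as exc:
            if exc.row is None:
                raise ValidationError(str(exc.args[0]).split(": ", 1)[-1], row=i, field=exc.field)
            raise
        key = entry.key()
        if key in seen:
            raise ValidationError(
                f"duplicate constraint key {key}", row=i, field="gene"
            )
        seen.add(key)
        out.append(entry)
    return out


_BURDEN_COLUMNS = [
    "gene", "subtype", "variant_class", "case_carriers", "case_n",
    "control_carriers", "control_n",
]


def read_burden_table(path: Union[str, Path]) -> list[BurdenCounts]:
    """Read and validate a raw burden-counts table."""
    frame = _read_frame(path, _BURDEN_COLUMNS)
    out: list[BurdenCounts] = []
    for i, rec in enumerate(frame.itertuples(index=False), start=1):
        row = rec._asdict()
        try:
            counts = BurdenCounts(
                gene=row["gene"],
                subtype=_parse_subtype(row["subtype"], i, "subtype", allow_any=True),
                variant_class=_parse_class(row["variant_class"], i, "variant_class"),
                case_carriers=_parse_int(row["case_carriers"], i, "case_carriers"),
                case_n=_parse_int(row["case_n"], i, "case_n"),
                control_carriers=_parse_int(row["control_carriers"], i, "control_carriers"),
                control_n=_parse_int(row["control_n"], i, "control_n"),
            )
        except ValidationError as exc:
            if exc.row is None:
                raise ValidationError(str(exc.args[0]).split(": ", 1)[-1], row=i, field=exc.field)
            raise
        except TypeError:
            raise ValidationError("count fields may not be missing", row=i, field="case_carriers")
        out.append(counts)
    return out


# ---------------------------------------------------------------------------
# Writers (field-level lossless round-trip with the readers above)


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, PriorClass):
        return value.name
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _fmt_subtype(subtype: Optional[Subtype]) -> str:
    return subtype.value if subtype is not None else ANY_SUBTYPE


def write_variant_table(path: Union[str, Path], observations: Iterable[VariantObservation]) -> None:
    rows = [
        {
            "patient_id": o.patient_id,
            "family_id": o.family_id,
            "subtype": _fmt(o.subtype),
            "gene": o.gene,
            "variant_id": o.variant_id,
            "variant_class": _fmt(o.variant_class),
            "popmax_af": _fmt(o.popmax_af),
            "protein_position": _fmt(o.protein_position),
            "insilico_support": _fmt(o.insilico_support),
            "phenotype_specific": _fmt(o.phenotype_specific),
            "proband_count": _fmt(o.proband_count),
            "segregating_meioses": _fmt(o.segregating_meioses),
            "prior_class": _fmt(o.prior_class),
            "founder_flag": _fmt(o.founder_flag),
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_constraint_table(path: Union[str, Path], entries: Iterable[GeneConstraintEntry]) -> None:
    rows = [
        {
            "gene": e.gene,
            "subtype": _fmt_subtype(e.subtype),
            "variant_class": _fmt(e.variant_class),
            "has_case_excess": _fmt(e.has_case_excess),
            "ef": _fmt(e.ef),
            "ef_ci_low": _fmt(e.ef_ci_low),
            "ef_ci_high": _fmt(e.ef_ci_high),
            "region_start": _fmt(e.region_start),
            "region_end": _fmt(e.region_end),
            "pli": _fmt(e.pli),
            "mis_z": _fmt(e.mis_z),
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=_CONSTRAINT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_burden_table(path: Union[str, Path], counts: Iterable[BurdenCounts]) -> None:
    rows = [
        {
            "gene": c.gene,
            "subtype": _fmt_subtype(c.subtype),
            "variant_class": _fmt(c.variant_class),
            "case_carriers": _fmt(c.case_carriers),
            "case_n": _fmt(c.case_n),
            "control_carriers": _fmt(c.control_carriers),
            "control_n": _fmt(c.control_n),
        }
        for c in counts
    ]
    pd.DataFrame(rows, columns=_BURDEN_COLUMNS).to_csv(path, sep="\t", index=False)
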