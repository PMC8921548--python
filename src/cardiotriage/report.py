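"""Cohort-level reporting: diagnostic yield, concordance and triage tallies.

The report has one row per cardiomyopathy subtype plus a TOTAL row whose
count columns equal the column-wise sums of the subtype rows; every
percentage is recomputed from raw counts (never summed or averaged) and
rounded half-up at the displayed precision — integers for concordance
and the gnomAD-route fraction, one decimal for the cohort-level yields.

Patient-level and unique-variant tallies are kept side by side: a
patient is counted once per tally regardless of how many qualifying
variants they carry, while variant tallies deduplicate by variant id
across carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import pandas as pd

from .model import GeneConstraintEntry, PriorClass, Subtype, VariantObservation
from .triage import (
    Action,
    ConcordanceResult,
    Route,
    RouteTally,
    TOTAL_KEY,
    TriageDecision,
)

__all__ = ["SubtypeRow", "CohortReport", "build_report", "render_report", "pct_half_up"]

_SUBTYPE_KEYS = ["HCM", "DCM", "ACM", "CM_unclassified", "LVNC"]
_SUBTYPE_LABELS = {"CM_unclassified": "CM"}


def pct_half_up(numerator: int, denominator: int, decimals: int) -> Optional[float]:
    """Exact percentage of two integers, rounded half-up.

    Computed in decimal arithmetic so e.g. 354/378 -> 94, 12/22 -> 55,
    25/2002 -> 1.2, 19/2002 -> 1 (at integer precision), 113/2002 -> 5.6.
    Returns None for an empty denominator.
    """
    if denominator == 0:
        return None
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, ROUND_HALF_UP)
    return float(value)


@dataclass
class SubtypeRow:
    """One subtype row of the report (or the TOTAL row)."""

    n_genes_with_ce: int = 0
    n_patients_rdc_lp: int = 0
    n_variants_rdc_lp: int = 0
    n_patients_ce_ef_lp: int = 0
    n_variants_ce_ef_lp: int = 0
    concordance_pct: Optional[float] = None  # integer-rounded
    n_patients_prioritized_ce: int = 0       # all patients with CE-selected VUSs
    n_prioritized_no_diagnosis: int = 0      # undiagnosed among them
    n_reclassified_no_diagnosis: int = 0     # undiagnosed gaining a first (L)P
    n_gnomad_route_patients: int = 0         # undiagnosed with gnomAD-prioritized VUSs


@dataclass
class CohortReport:
    rows: dict[str, SubtypeRow]
    total_patients: int
    n_diagnosed: int
    n_reclassified_patients: int          # all patients with >=1 reclassified VUS
    n_reclassified_new_diagnosis: int     # those gaining a first (L)P
    n_unique_reclassified: int
    n_unique_prioritized: int
    n_combined_selected_patients: int     # undiagnosed with any selected VUS
    diagnostic_yield_pct: Optional[float]
    yield_increase_pct: Optional[float]
    prioritized_pct: Optional[float]          # undiagnosed CE-selected / cohort
    gnomad_route_pct: Optional[float]         # undiagnosed gnomAD-selected / cohort
    prioritized_unique_vus_pct: Optional[float]
    combined_selected_pct: Optional[float]


def _subtype_of_patients(cohort: Sequence[VariantObservation]) -> dict[str, str]:
    out: dict[str, str] = {}
    for obs in cohort:
        out.setdefault(obs.patient_id, obs.subtype.value)
    return out


def build_report(
    cohort: Sequence[VariantObservation],
    decisions: Sequence[TriageDecision],
    concordance: ConcordanceResult,
    constraints: Sequence[GeneConstraintEntry],
) -> CohortReport:
    """Assemble the cohort report from triage decisions and concordance.

    The decisions and concordance must have been computed on the same
    cohort.  A patient counts as *diagnosed* when they carry at least
    one prior (L)P observation; the yield increase counts patients whose
    first (L)P arrives through reclassification.
    """
    patient_subtype = _subtype_of_patients(cohort)
    total_patients = len(patient_subtype)

    diagnosed = {
        o.patient_id for o in cohort if o.prior_class in (PriorClass.LP, PriorClass.P)
    }

    ce_selected: dict[str, set[str]] = {}        # subtype -> patients
    reclassified: dict[str, set[str]] = {}
    gnomad_selected: dict[str, set[str]] = {}
    reclassified_variants: set[str] = set()
    prioritized_variants: set[str] = set()
    reclassified_patients: set[str] = set()

    for d in decisions:
        sub = patient_subtype.get(d.patient_id)
        if d.route is Route.CE_EF_GENE and d.action in (
            Action.PRIORITIZE, Action.RECLASSIFY_LP,
        ):
            ce_selected.setdefault(sub, set()).add(d.patient_id)
        if d.action is Action.RECLASSIFY_LP:
            reclassified.setdefault(sub, set()).add(d.patient_id)
            reclassified_variants.add(d.variant_id)
            reclassified_patients.add(d.patient_id)
        elif d.action is Action.PRIORITIZE:
            prioritized_variants.add(d.variant_id)
            if d.route is Route.GNOMAD_GENE:
                gnomad_selected.setdefault(sub, set()).add(d.patient_id)
    # a variant reclassified for any carrier is counted as reclassified only
    prioritized_variants -= reclassified_variants

    genes_ce: dict[str, set[str]] = {}
    all_genes_ce: set[str] = set()
    for e in constraints:
        if e.has_case_excess:
            all_genes_ce.add(e.gene)
            if e.subtype is not None:
                genes_ce.setdefault(e.subtype.value, set()).add(e.gene)

    rows: dict[str, SubtypeRow] = {}
    for key in _SUBTYPE_KEYS + [TOTAL_KEY]:
        if key == TOTAL_KEY:
            ce_tally = concordance.ce[TOTAL_KEY]
            sel = set().union(*ce_selected.values()) if ce_selected else set()
            rec = set().union(*reclassified.values()) if reclassified else set()
            gno = set().union(*gnomad_selected.values()) if gnomad_selected else set()
            n_genes = len(all_genes_ce)
        else:
            ce_tally = concordance.ce.get(key, RouteTally())
            sel = ce_selected.get(key, set())
            rec = reclassified.get(key, set())
            gno = gnomad_selected.get(key, set())
            n_genes = len(genes_ce.get(key, set()))
        rows[key] = SubtypeRow(
            n_genes_with_ce=n_genes,
            n_patients_rdc_lp=ce_tally.n_rdc_lp_patients,
            n_variants_rdc_lp=ce_tally.n_rdc_lp_variants,
            n_patients_ce_ef_lp=ce_tally.n_concordant_patients,
            n_variants_ce_ef_lp=ce_tally.n_concordant_variants,
            concordance_pct=pct_half_up(
                ce_tally.n_concordant_variants, ce_tally.n_rdc_lp_variants, 0
            ),
            n_patients_prioritized_ce=len(sel),
            n_prioritized_no_diagnosis=len(sel - diagnosed),
            n_reclassified_no_diagnosis=len(rec - diagnosed),
            n_gnomad_route_patients=len(gno - diagnosed),
        )

    total = rows[TOTAL_KEY]
    ce_undiag = total.n_prioritized_no_diagnosis
    gn_undiag = total.n_gnomad_route_patients
    combined_sets = [s for s in list(ce_selected.values()) + list(gnomad_selected.values())]
    combined_undiag = (set().union(*combined_sets) if combined_sets else set()) - diagnosed
    new_diagnoses = reclassified_patients - diagnosed

    return CohortReport(
        rows=rows,
        total_patients=total_patients,
        n_diagnosed=len(diagnosed),
        n_reclassified_patients=len(reclassified_patients),
        n_reclassified_new_diagnosis=len(new_diagnoses),
        n_unique_reclassified=len(reclassified_variants),
        n_unique_prioritized=len(prioritized_variants),
        n_combined_selected_patients=len(combined_undiag),
        diagnostic_yield_pct=pct_half_up(len(diagnosed), total_patients, 1),
        yield_increase_pct=pct_half_up(len(new_diagnoses), total_patients, 1),
        prioritized_pct=pct_half_up(ce_undiag, total_patients, 1),
        gnomad_route_pct=pct_half_up(gn_undiag, total_patients, 0),
        prioritized_unique_vus_pct=pct_half_up(
            len(prioritized_variants), total_patients, 1
        ),
        combined_selected_pct=pct_half_up(len(combined_undiag), total_patients, 1),
    )


def _fmt_pct(value: Optional[float], decimals: int = 0) -> str:
    if value is None:
        return "NA"
    return f"{value:.{decimals}f}%"


def render_report(report: CohortReport, format: str = "text") -> str:
    """Render the report as a human-readable table or machine-readable TSV."""
    records = []
    for key in _SUBTYPE_KEYS + [TOTAL_KEY]:
        row = report.rows[key]
        records.append(
            {
                "subtype": _SUBTYPE_LABELS.get(key, key),
                "genes_with_ce": row.n_genes_with_ce,
                "rdc_lp_patients": row.n_patients_rdc_lp,
                "rdc_lp_variants": row.n_variants_rdc_lp,
                "ce_ef_lp_patients": row.n_patients_ce_ef_lp,
                "ce_ef_lp_variants": row.n_variants_ce_ef_lp,
                "concordance_pct": "NA" if row.concordance_pct is None else int(row.concordance_pct),
                "prioritized_ce_patients": row.n_patients_prioritized_ce,
                "prioritized_no_diagnosis": row.n_prioritized_no_diagnosis,
                "reclassified_no_diagnosis": row.n_reclassified_no_diagnosis,
                "gnomad_route_patients": row.n_gnomad_route_patients,
            }
        )
    frame = pd.DataFrame(records)

    summary_pairs = [
        ("total_patients", report.total_patients),
        ("diagnosed_patients", report.n_diagnosed),
        ("diagnostic_yield_pct", _fmt_pct(report.diagnostic_yield_pct, 1)),
        ("reclassified_patients", report.n_reclassified_patients),
        ("reclassified_new_diagnoses", report.n_reclassified_new_diagnosis),
        ("yield_increase_pct", _fmt_pct(report.yield_increase_pct, 1)),
        ("unique_vus_reclassified", report.n_unique_reclassified),
        ("unique_vus_prioritized", report.n_unique_prioritized),
        ("prioritized_ce_no_diagnosis_pct", _fmt_pct(report.prioritized_pct, 1)),
        ("gnomad_route_no_diagnosis_pct", _fmt_pct(report.gnomad_route_pct, 0)),
        ("prioritized_unique_vus_pct", _fmt_pct(report.prioritized_unique_vus_pct, 1)),
        ("combined_selected_patients", report.n_combined_selected_patients),
        ("combined_selected_pct", _fmt_pct(report.combined_selected_pct, 1)),
    ]

    if format == "tsv":
        lines = [frame.to_csv(sep="\t", index=False).rstrip("\n"), ""]
        lines += [f"{k}\t{v}" for k, v in summary_pairs]
        return "\n".join(lines) + "\n"
    if format == "text":
        lines = ["Cohort report", "=" * 13, "", frame.to_string(index=False), ""]
        width = max(len(k) for k, _ in summary_pairs)
        lines += [f"{k.ljust(width)}  {v}" for k, v in summary_pairs]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")
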