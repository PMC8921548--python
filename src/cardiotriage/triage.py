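"""The decision flow: validate (L)P concordance, then triage VUSs.

Two routes exist for every observation, depending on what the
constraint table knows about its (gene, subtype, variant class):

* the **CE/EF route** — the gene/class was analysed in a case-excess
  burden study, so an etiological fraction is available.  VUSs in
  strata with significant case excess are *selected*: immediately
  reclassified to likely pathogenic when EF >= 0.90 and the rarity
  (PM2), in-silico (PP3) and phenotype (PP4) gates all hold and the
  ACMG combining rules independently reach (L)P; otherwise prioritized
  for co-segregation or functional follow-up.
* the **gnomAD route** — only population-constraint metrics (pLI,
  mis_z) are available.  VUSs passing the intolerance screen in genes
  established for the patient's subtype are prioritized, never
  reclassified: constraint metrics alone are insufficient evidence for
  an immediate (L)P call.

Variants matching neither route are left untouched.  The pipeline only
moves variants in the VUS -> LP direction; prior classifications are
never downgraded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .acmg import AcmgClass, Criterion, EvidenceSet, assign_evidence, combine
from .constraint import gnomad_screen, lookup_constraint
from .model import (
    GeneConstraintEntry,
    PriorClass,
    Subtype,
    Thresholds,
    ValidationError,
    VariantObservation,
)

__all__ = [
    "Route",
    "Action",
    "TriageDecision",
    "RouteTally",
    "ConcordanceResult",
    "validate_lp_concordance",
    "triage_vus",
    "apply_pp1_upgrade",
    "write_decisions",
    "read_decisions",
]


class Route(str, Enum):
    CE_EF_GENE = "ce_ef_gene"
    GNOMAD_GENE = "gnomad_gene"
    UNMATCHED = "unmatched"


class Action(str, Enum):
    RECLASSIFY_LP = "reclassify_LP"
    PRIORITIZE = "prioritize"
    NONE = "none"


@dataclass
class TriageDecision:
    """Outcome of triaging one VUS observation, with its rationale trail."""

    patient_id: str
    variant_id: str
    route: Route
    action: Action
    new_class: Optional[AcmgClass]
    evidence: EvidenceSet
    rationale: list[str] = field(default_factory=list)
    # retained so PP1 upgrades can re-run evidence assignment; not serialised
    obs: Optional[VariantObservation] = field(default=None, repr=False, compare=False)
    entry: Optional[GeneConstraintEntry] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.action is Action.NONE and self.new_class is not None:
            raise ValueError("a 'none' decision carries no new class")


# ---------------------------------------------------------------------------
# Validation of prior (L)P classifications against the constraint metrics


@dataclass
class RouteTally:
    """Unique-variant and patient tallies for one route/subtype cell."""

    n_rdc_lp_variants: int = 0
    n_concordant_variants: int = 0
    n_rdc_lp_patients: int = 0
    n_concordant_patients: int = 0

    @property
    def concordance_pct(self) -> Optional[float]:
        """Raw variant-level concordance percentage; None when empty."""
        if self.n_rdc_lp_variants == 0:
            return None
        return 100.0 * self.n_concordant_variants / self.n_rdc_lp_variants


_SUBTYPE_ORDER = [
    Subtype.HCM, Subtype.DCM, Subtype.ACM, Subtype.CM_UNCLASSIFIED, Subtype.LVNC,
]
TOTAL_KEY = "TOTAL"


@dataclass
class ConcordanceResult:
    """Per-subtype and pooled concordance between prior (L)P calls and
    what the constraint metrics would have concluded."""

    ce: dict[str, RouteTally]
    gnomad: dict[str, RouteTally]
    founder_discordant_pct: Optional[float]


def _route_of(entry: Optional[GeneConstraintEntry]) -> Route:
    if entry is None:
        return Route.UNMATCHED
    return Route.CE_EF_GENE if entry.is_ce_route else Route.GNOMAD_GENE


def validate_lp_concordance(
    cohort: Sequence[VariantObservation],
    table: Sequence[GeneConstraintEntry],
    t: Thresholds = Thresholds(),
) -> ConcordanceResult:
    """Check prior (L)P variants against the constraint metrics.

    A CE/EF-route variant is concordant when its matched stratum has
    significant case excess; a gnomAD-route variant when it passes the
    intolerance screen.  Variant tallies deduplicate by ``variant_id``
    (a variant shared by several carriers counts once); patient tallies
    count patients with at least one (route) variant.  Founder-flagged
    discordant variants are reported as a percentage of the CE-route
    unique-variant total.
    """
    # per route: subtype -> {variant_id -> concordant}, subtype -> patient sets
    variants: dict[Route, dict[str, dict[str, bool]]] = {
        Route.CE_EF_GENE: {}, Route.GNOMAD_GENE: {},
    }
    patients: dict[Route, dict[str, set[str]]] = {Route.CE_EF_GENE: {}, Route.GNOMAD_GENE: {}}
    conc_patients: dict[Route, dict[str, set[str]]] = {
        Route.CE_EF_GENE: {}, Route.GNOMAD_GENE: {},
    }
    founder_variants: set[str] = set()

    for obs in cohort:
        if obs.prior_class not in (PriorClass.LP, PriorClass.P):
            continue
        entry = lookup_constraint(obs, table)
        route = _route_of(entry)
        if route is Route.UNMATCHED:
            continue
        if route is Route.CE_EF_GENE:
            concordant = entry.has_case_excess
            if not concordant and obs.founder_flag:
                founder_variants.add(obs.variant_id)
        else:
            concordant = gnomad_screen(obs, entry, t)
        sub = obs.subtype.value
        variants[route].setdefault(sub, {})
        variants[route][sub][obs.variant_id] = (
            variants[route][sub].get(obs.variant_id, False) or concordant
        )
        patients[route].setdefault(sub, set()).add(obs.patient_id)
        if concordant:
            conc_patients[route].setdefault(sub, set()).add(obs.patient_id)

    def tallies(route: Route) -> dict[str, RouteTally]:
        out: dict[str, RouteTally] = {}
        all_variants: dict[str, bool] = {}
        all_patients: set[str] = set()
        all_conc_patients: set[str] = set()
        for sub in _SUBTYPE_ORDER:
            key = sub.value
            vmap = variants[route].get(key, {})
            for vid, conc in vmap.items():
                all_variants[vid] = all_variants.get(vid, False) or conc
            pset = patients[route].get(key, set())
            cset = conc_patients[route].get(key, set())
            all_patients |= pset
            all_conc_patients |= cset
            out[key] = RouteTally(
                n_rdc_lp_variants=len(vmap),
                n_concordant_variants=sum(vmap.values()),
                n_rdc_lp_patients=len(pset),
                n_concordant_patients=len(cset),
            )
        out[TOTAL_KEY] = RouteTally(
            n_rdc_lp_variants=len(all_variants),
            n_concordant_variants=sum(all_variants.values()),
            n_rdc_lp_patients=len(all_patients),
            n_concordant_patients=len(all_conc_patients),
        )
        return out

    ce = tallies(Route.CE_EF_GENE)
    gn = tallies(Route.GNOMAD_GENE)
    founder_pct = (
        100.0 * len(founder_variants) / ce[TOTAL_KEY].n_rdc_lp_variants
        if ce[TOTAL_KEY].n_rdc_lp_variants
        else None
    )
    return ConcordanceResult(ce=ce, gnomad=gn, founder_discordant_pct=founder_pct)


# ---------------------------------------------------------------------------
# VUS triage


def _triage_one(
    obs: VariantObservation,
    table: Sequence[GeneConstraintEntry],
    t: Thresholds,
) -> TriageDecision:
    rationale: list[str] = []

    if obs.popmax_af is not None and obs.popmax_af > t.rare_maf:
        rationale.append(
            f"popmax_af={obs.popmax_af:g} > rare_maf={t.rare_maf:g}: "
            "not rare enough for constraint-based selection"
        )
        return TriageDecision(
            obs.patient_id, obs.variant_id, Route.UNMATCHED, Action.NONE,
            None, EvidenceSet(), rationale, obs=obs,
        )

    entry = lookup_constraint(obs, table)
    if entry is None:
        rationale.append("no constraint entry matches gene/class/subtype")
        return TriageDecision(
            obs.patient_id, obs.variant_id, Route.UNMATCHED, Action.NONE,
            None, EvidenceSet(), rationale, obs=obs,
        )

    scope = (
        f" residues {entry.region_start}-{entry.region_end}"
        if entry.is_region_restricted
        else ""
    )
    rationale.append(
        f"matched constraint entry {entry.gene}/"
        f"{entry.subtype.value if entry.subtype else 'ANY'}/"
        f"{entry.variant_class.value}{scope}"
    )

    if entry.is_ce_route and entry.has_case_excess:
        ev = assign_evidence(obs, entry, t)
        rationale.append("significant case excess in matched stratum")
        rationale.extend(ev.provenance)
        pm2 = Criterion.PM2 in ev
        pp3 = Criterion.PP3 in ev
        pp4 = Criterion.PP4 in ev
        ef = entry.ef
        ef_ok = ef is not None and ef >= t.ef_reclass
        rationale.append(
            f"EF={'NA' if ef is None else format(ef, 'g')} "
            f"{'>=' if ef_ok else '<'} ef_reclass={t.ef_reclass:g}"
        )
        for name, ok in (("PM2", pm2), ("PP3", pp3), ("PP4", pp4)):
            rationale.append(f"{name} {'met' if ok else 'not met'}")
        combined = combine(ev)
        rationale.append(f"combined ACMG class: {combined.value}")
        if ef_ok and pm2 and pp3 and pp4 and combined in (
            AcmgClass.LIKELY_PATHOGENIC, AcmgClass.PATHOGENIC,
        ):
            rationale.append("action: immediately reclassified to LP")
            return TriageDecision(
                obs.patient_id, obs.variant_id, Route.CE_EF_GENE,
                Action.RECLASSIFY_LP, AcmgClass.LIKELY_PATHOGENIC, ev, rationale,
                obs=obs, entry=entry,
            )
        rationale.append("action: prioritized for co-segregation/functional follow-up")
        return TriageDecision(
            obs.patient_id, obs.variant_id, Route.CE_EF_GENE, Action.PRIORITIZE,
            None, ev, rationale, obs=obs, entry=entry,
        )

    if gnomad_screen(obs, entry, t) and entry.subtype is not None:
        ev = assign_evidence(obs, entry, t)
        metric = (
            f"pLI={entry.pli:g} > {t.pli_cut:g}"
            if obs.variant_class.value == "truncating"
            else f"mis_z={entry.mis_z:g} > {t.mis_z_cut:g}"
        )
        rationale.append(f"gnomAD intolerance screen passed ({metric})")
        rationale.append(
            f"gene established for subtype {entry.subtype.value}; "
            "constraint metrics alone cannot support immediate (L)P classification"
        )
        rationale.append("action: prioritized for co-segregation/functional follow-up")
        return TriageDecision(
            obs.patient_id, obs.variant_id, Route.GNOMAD_GENE, Action.PRIORITIZE,
            None, ev, rationale, obs=obs, entry=entry,
        )

    rationale.append("no selection gate passed")
    return TriageDecision(
        obs.patient_id, obs.variant_id, Route.UNMATCHED, Action.NONE,
        None, EvidenceSet(), rationale, obs=obs, entry=entry,
    )


def triage_vus(
    cohort: Sequence[VariantObservation],
    table: Sequence[GeneConstraintEntry],
    t: Thresholds = Thresholds(),
) -> list[TriageDecision]:
    """Triage every VUS in the cohort, in input order.

    Returns one decision per prior-VUS observation.  Identical inputs
    produce identical decision lists; serialising them yields
    byte-identical tables.
    """
    return [
        _triage_one(obs, table, t)
        for obs in cohort
        if obs.prior_class is PriorClass.VUS
    ]


def apply_pp1_upgrade(
    decision: TriageDecision, meioses: int, t: Thresholds = Thresholds()
) -> TriageDecision:
    """Fold newly observed co-segregation into a triage decision.

    Re-runs evidence assignment with the given number of segregating
    meioses and re-combines; a prioritized decision is upgraded to
    reclassification only when the combined class reaches (L)P.
    Already-reclassified and untouched decisions pass through unchanged.
    """
    if decision.action is not Action.PRIORITIZE or decision.obs is None:
        return decision
    obs = dataclasses.replace(decision.obs, segregating_meioses=meioses)
    ev = assign_evidence(obs, decision.entry, t)
    combined = combine(ev)
    if combined not in (AcmgClass.LIKELY_PATHOGENIC, AcmgClass.PATHOGENIC):
        return decision
    rationale = list(decision.rationale)
    rationale.append(
        f"co-segregation update: {meioses} meioses; re-combined ACMG class: {combined.value}"
    )
    rationale.append("action: upgraded to reclassify_LP after co-segregation")
    return TriageDecision(
        decision.patient_id, decision.variant_id, decision.route,
        Action.RECLASSIFY_LP, AcmgClass.LIKELY_PATHOGENIC, ev, rationale,
        obs=obs, entry=decision.entry,
    )


# ---------------------------------------------------------------------------
# Decisions TSV (round-trips with read_decisions)

_DECISION_COLUMNS = [
    "patient_id", "variant_id", "route", "action", "new_class", "evidence", "rationale",
]
_RATIONALE_SEP = " | "


def write_decisions(path: Union[str, Path], decisions: Iterable[TriageDecision]) -> None:
    """Write decisions as TSV, one row per decision with the full rationale."""
    rows = [
        {
            "patient_id": d.patient_id,
            "variant_id": d.variant_id,
            "route": d.route.value,
            "action": d.action.value,
            "new_class": d.new_class.value if d.new_class else "NA",
            "evidence": d.evidence.tokens(),
            "rationale": _RATIONALE_SEP.join(d.rationale),
        }
        for d in decisions
    ]
    pd.DataFrame(rows, columns=_DECISION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_decisions(path: Union[str, Path]) -> list[TriageDecision]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _DECISION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    out = []
    for rec in frame.itertuples(index=False):
        row = rec._asdict()
        out.append(
            TriageDecision(
                patient_id=row["patient_id"],
                variant_id=row["variant_id"],
                route=Route(row["route"]),
                action=Action(row["action"]),
                new_class=None if row["new_class"] in ("", "NA") else AcmgClass(row["new_class"]),
                evidence=EvidenceSet.from_tokens(row["evidence"]),
                rationale=row["rationale"].split(_RATIONALE_SEP) if row["rationale"] else [],
            )
        )
    return out
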