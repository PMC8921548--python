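"""ACMG/AMP evidence assignment and rule combination.

Implements the standard five-tier classification over the published
combining table, extended with the EF-banded hotspot criterion used for
cardiomyopathy genes: a variant in a gene, protein region or variant
class with an established etiological fraction activates PM1 at

* supporting strength for 0.80 <= EF < 0.90,
* moderate strength for 0.90 <= EF < 0.95,
* strong strength for EF >= 0.95,

for both non-truncating and truncating variants, within the subtype for
which the EF was determined.  Criteria may therefore contribute at a
strength other than their native level; the combining rules always count
*effective* strengths (an upgraded PM1 at strong counts as a strong
criterion).

The benign-side rules (BA1/BS/BP) are implemented for engine
completeness; the triage pipeline never emits them because no variant
class in the cardiomyopathy panels shows significant depletion in cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .model import GeneConstraintEntry, Thresholds, VariantObservation

__all__ = [
    "Criterion",
    "Strength",
    "Evidence",
    "EvidenceSet",
    "AcmgClass",
    "ef_to_pm1",
    "assign_evidence",
    "combine",
]


class Criterion(str, Enum):
    PVS1 = "PVS1"
    PS1 = "PS1"
    PS2 = "PS2"
    PS3 = "PS3"
    PS4 = "PS4"
    PM1 = "PM1"
    PM2 = "PM2"
    PM3 = "PM3"
    PM4 = "PM4"
    PM5 = "PM5"
    PM6 = "PM6"
    PP1 = "PP1"
    PP2 = "PP2"
    PP3 = "PP3"
    PP4 = "PP4"
    PP5 = "PP5"
    BA1 = "BA1"
    BS1 = "BS1"
    BS2 = "BS2"
    BS3 = "BS3"
    BS4 = "BS4"
    BP1 = "BP1"
    BP2 = "BP2"
    BP3 = "BP3"
    BP4 = "BP4"
    BP5 = "BP5"
    BP6 = "BP6"
    BP7 = "BP7"

    @property
    def is_pathogenic_side(self) -> bool:
        return self.value[0] == "P"


class Strength(str, Enum):
    STANDALONE = "standalone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


def _native_strength(criterion: Criterion) -> Strength:
    name = criterion.value
    if name == "PVS1":
        return Strength.VERY_STRONG
    if name == "BA1":
        return Strength.STANDALONE
    if name.startswith("PS") or name.startswith("BS"):
        return Strength.STRONG
    if name.startswith("PM"):
        return Strength.MODERATE
    return Strength.SUPPORTING  # PP / BP


@dataclass(frozen=True)
class Evidence:
    """An activated criterion, optionally at an overridden strength."""

    criterion: Criterion
    strength: Optional[Strength] = None

    @property
    def native_strength(self) -> Strength:
        return _native_strength(self.criterion)

    @property
    def effective_strength(self) -> Strength:
        return self.strength if self.strength is not None else self.native_strength

    @property
    def is_overridden(self) -> bool:
        return self.strength is not None and self.strength is not self.native_strength

    def token(self) -> str:
        """Serialisation token, e.g. ``PM1:strong`` or ``PM2``."""
        if self.is_overridden:
            return f"{self.criterion.value}:{self.effective_strength.value}"
        return self.criterion.value

    @classmethod
    def from_token(cls, token: str) -> "Evidence":
        name, _, strength = token.partition(":")
        return cls(Criterion(name), Strength(strength) if strength else None)


class EvidenceSet:
    """A set of activated criteria with a human-readable rationale trail.

    Each criterion appears at most once; adding a duplicate is an error.
    """

    def __init__(self, items: Iterable[Evidence] = (), provenance: Iterable[str] = ()):
        self._items: dict[Criterion, Evidence] = {}
        self.provenance: list[str] = list(provenance)
        for ev in items:
            self.add(ev)

    def add(self, evidence: Evidence, reason: Optional[str] = None) -> None:
        if evidence.criterion in self._items:
            raise ValueError(f"duplicate criterion {evidence.criterion.value}")
        self._items[evidence.criterion] = evidence
        if reason:
            self.provenance.append(reason)

    def __contains__(self, criterion: Criterion) -> bool:
        return criterion in self._items

    def __iter__(self):
        return iter(self._items.values())

    def __len__(self) -> int:
        return len(self._items)

    def get(self, criterion: Criterion) -> Optional[Evidence]:
        return self._items.get(criterion)

    def tokens(self) -> str:
        return ",".join(ev.token() for ev in sorted(self, key=lambda e: e.criterion.value))

    @classmethod
    def from_tokens(cls, text: str) -> "EvidenceSet":
        if not text:
            return cls()
        return cls(Evidence.from_token(tok) for tok in text.split(","))

    def __repr__(self) -> str:
        return f"EvidenceSet({self.tokens()!r})"


class AcmgClass(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


def ef_to_pm1(ef: Optional[float], t: Thresholds = Thresholds()) -> Optional[Evidence]:
    """Map an etiological fraction to the banded hotspot criterion.

    Bands are left-closed: EF >= 0.95 -> strong, 0.90 <= EF < 0.95 ->
    moderate, 0.80 <= EF < 0.90 -> supporting, below 0.80 -> no
    criterion.
    """
    if ef is None:
        return None
    if ef >= t.ef_strong_low:
        return Evidence(Criterion.PM1, Strength.STRONG)
    if ef >= t.ef_moderate_low:
        return Evidence(Criterion.PM1, Strength.MODERATE)
    if ef >= t.ef_supporting_low:
        return Evidence(Criterion.PM1, Strength.SUPPORTING)
    return None


def assign_evidence(
    obs: VariantObservation,
    entry: Optional[GeneConstraintEntry],
    t: Thresholds = Thresholds(),
) -> EvidenceSet:
    """Activate the criteria this pipeline can assess for one observation.

    Emits PM1 (EF-banded, from the region-resolved constraint entry),
    PM2 (absent or rarer than the PM2 frequency cut in population data;
    a missing allele frequency counts as absent), PP3/PP4 from the
    in-silico and phenotype input flags, PS4 from the proband count, and
    the highest applicable PP1 co-segregation tier.  Absent inputs
    simply yield no criterion.
    """
    ev = EvidenceSet()

    if entry is not None and entry.ef is not None:
        pm1 = ef_to_pm1(entry.ef, t)
        if pm1 is not None:
            scope = (
                f"residues {entry.region_start}-{entry.region_end}"
                if entry.is_region_restricted
                else "gene-wide"
            )
            ev.add(
                pm1,
                f"PM1@{pm1.effective_strength.value}: EF={entry.ef:g} ({scope}, "
                f"{entry.variant_class.value}) within bands "
                f"{t.ef_supporting_low:g}/{t.ef_moderate_low:g}/{t.ef_strong_low:g}",
            )

    if obs.popmax_af is None:
        ev.add(Evidence(Criterion.PM2), "PM2: absent from large population studies")
    elif obs.popmax_af < t.pm2_maf:
        ev.add(
            Evidence(Criterion.PM2),
            f"PM2: popmax_af={obs.popmax_af:g} < {t.pm2_maf:g}",
        )

    if obs.insilico_support:
        ev.add(Evidence(Criterion.PP3), "PP3: computational evidence supports deleterious effect")
    if obs.phenotype_specific:
        ev.add(Evidence(Criterion.PP4), "PP4: phenotype highly specific for the gene")

    if obs.proband_count >= t.ps4_probands:
        ev.add(
            Evidence(Criterion.PS4),
            f"PS4: identified in {obs.proband_count} probands (>= {t.ps4_probands})",
        )

    # Highest applicable co-segregation tier only; tiers are nested.
    m = obs.segregating_meioses
    if m >= t.pp1_strong:
        ev.add(Evidence(Criterion.PP1, Strength.STRONG), f"PP1@strong: {m} segregating meioses")
    elif m >= t.pp1_moderate:
        ev.add(Evidence(Criterion.PP1, Strength.MODERATE), f"PP1@moderate: {m} segregating meioses")
    elif m >= t.pp1_supporting:
        ev.add(Evidence(Criterion.PP1, Strength.SUPPORTING), f"PP1@supporting: {m} segregating meioses")

    return ev


def _strength_counts(ev: EvidenceSet, pathogenic_side: bool) -> dict[Strength, int]:
    counts = {s: 0 for s in Strength}
    for item in ev:
        if item.criterion.is_pathogenic_side == pathogenic_side:
            counts[item.effective_strength] += 1
    return counts


def combine(ev: EvidenceSet) -> AcmgClass:
    """Evaluate the published combining rules over effective strengths.

    Pathogenic rules take precedence over likely-pathogenic; when both a
    pathogenic-side and a benign-side classification fire, the evidence
    is contradictory and the variant stays of uncertain significance,
    as it does when no rule fires at all.
    """
    pc = _strength_counts(ev, pathogenic_side=True)
    bc = _strength_counts(ev, pathogenic_side=False)
    vs, s, m, p = (
        pc[Strength.VERY_STRONG],
        pc[Strength.STRONG],
        pc[Strength.MODERATE],
        pc[Strength.SUPPORTING],
    )
    ba, bs, bp = bc[Strength.STANDALONE], bc[Strength.STRONG], bc[Strength.SUPPORTING]

    pathogenic = (
        (vs >= 2)
        or (vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2))
        or (s >= 2)
        or (s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)))
    )
    likely_pathogenic = (
        (vs >= 1 and m >= 1)
        or (s >= 1 and 1 <= m <= 2)
        or (s >= 1 and p >= 2)
        or (m >= 3)
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_class = (
        AcmgClass.PATHOGENIC
        if pathogenic
        else AcmgClass.LIKELY_PATHOGENIC
        if likely_pathogenic
        else None
    )
    benign_class = (
        AcmgClass.BENIGN if benign else AcmgClass.LIKELY_BENIGN if likely_benign else None
    )

    if path_class is not None and benign_class is not None:
        return AcmgClass.VUS
    if path_class is not None:
        return path_class
    if benign_class is not None:
        return benign_class
    return AcmgClass.VUS
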