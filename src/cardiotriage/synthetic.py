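"""Synthetic diagnostic cohorts and the exact reference cohort.

Two generators live here:

* :func:`generate_cohort` simulates a diagnostic cardiomyopathy cohort
  with the statistical structure the triage pipeline assumes — a
  subtype mix over HCM/DCM/ACM/LVNC/unclassified CM, per-gene
  etiological fractions drawn from a Beta distribution, Poisson VUS
  multiplicity per patient, Bernoulli rarity/in-silico/phenotype flags,
  planted prior (L)P classifications and founder contamination.  It is
  fully reproducible from a single integer seed.

* :func:`reference_cohort` builds, by explicit deterministic tally
  allocation (no simulation), a 2,002-patient cohort plus matching
  constraint table whose pipeline outputs hit an exact set of reference
  tallies: 430 diagnosed patients; 378 unique (L)P variants in 369
  patients on the case-excess route, 354 of them concordant (94%); 22
  gnomAD-route (L)Ps with 12 concordant (55%); 92 unique selected VUSs
  in 143 patients on the CE route (113 without a diagnosis); 23 unique
  VUSs reclassified in 28 patients, 25 of whom gain a first diagnosis;
  and 37 unique gnomAD-route VUSs in 42 patients (19 undiagnosed).

A small parameter-recovery experiment quantifies bias, CI coverage and
EF-band misassignment of the etiological-fraction estimator at
realistic cohort sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constraint import compute_burden
from .model import (
    BurdenCounts,
    GeneConstraintEntry,
    PriorClass,
    Subtype,
    VariantClass,
    VariantObservation,
)

__all__ = [
    "SimConfig",
    "generate_cohort",
    "reference_cohort",
    "parameter_recovery_experiment",
]


# ---------------------------------------------------------------------------
# Seeded simulation


@dataclass
class SimConfig:
    """Configuration of the cohort simulator.

    Defaults emulate a consecutive diagnostic cardiomyopathy cohort:
    2,002 referred patients dominated by HCM and DCM, 33 genes with
    established case excess, per-gene EF drawn from Beta(8, 1.5)
    (mean ~0.84, most mass above the 0.8 supporting band), a ~21.5%
    prior diagnostic yield mostly inside CE-analysed genes, about one
    reportable VUS per patient, high rarity pass rates and a 4% founder
    rate among planted (L)Ps.
    """

    seed: int
    n_patients: int = 2002
    subtype_mix: dict = field(
        default_factory=lambda: {
            Subtype.HCM: 0.35,
            Subtype.DCM: 0.325,
            Subtype.ACM: 0.06,
            Subtype.CM_UNCLASSIFIED: 0.145,
            Subtype.LVNC: 0.12,
        }
    )
    n_genes_ce: int = 33
    ef_distribution: tuple[float, float] = (8.0, 1.5)  # Beta(a, b)
    p_ce_significant: float = 1.0
    vus_per_patient: float = 1.0
    p_pm2_pass: float = 0.9
    p_pp3: float = 0.7
    p_pp4: float = 0.6
    founder_rate: float = 0.04
    p_lp: float = 0.215
    p_lp_in_ce: float = 0.88

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.subtype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype_mix must sum to 1, got {total}")
        if self.n_patients <= 0 or self.n_genes_ce <= 0:
            raise ValueError("n_patients and n_genes_ce must be positive")
        for name in ("p_ce_significant", "p_pm2_pass", "p_pp3", "p_pp4",
                     "founder_rate", "p_lp", "p_lp_in_ce"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


_CE_SUBTYPE_CYCLE = [Subtype.HCM, Subtype.DCM, Subtype.ACM]


def generate_cohort(
    cfg: SimConfig,
) -> tuple[list[VariantObservation], list[GeneConstraintEntry]]:
    """Simulate a cohort and its constraint table, reproducibly.

    CE genes cycle over HCM/DCM/ACM with alternating variant classes;
    each gets a Beta-distributed EF and is flagged significant with
    probability ``p_ce_significant``.  Eight gnomAD-only genes (two per
    subtype including LVNC) carry metrics above the intolerance cuts.
    Each patient receives a Bernoulli(p_lp) prior (L)P — placed in a
    CE gene with probability ``p_lp_in_ce`` — and Poisson-distributed
    VUS observations with independent rarity/PP3/PP4 flags.  LVNC
    patients can only be served by the gnomAD route, mirroring the
    absence of LVNC burden studies.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    entries: list[GeneConstraintEntry] = []
    ce_by_subtype: dict[Subtype, list[GeneConstraintEntry]] = {}
    a, b = cfg.ef_distribution
    for i in range(cfg.n_genes_ce):
        subtype = _CE_SUBTYPE_CYCLE[i % len(_CE_SUBTYPE_CYCLE)]
        vclass = VariantClass.TRUNCATING if i % 2 == 0 else VariantClass.NON_TRUNCATING
        ef = float(np.clip(rng.beta(a, b), 0.0, 1.0))
        significant = bool(rng.random() < cfg.p_ce_significant)
        entry = GeneConstraintEntry(
            gene=f"SYN_CE_{i + 1:03d}",
            subtype=subtype,
            variant_class=vclass,
            has_case_excess=significant,
            ef=round(ef, 4),
        )
        entries.append(entry)
        ce_by_subtype.setdefault(subtype, []).append(entry)

    gnomad_entries: dict[Subtype, list[GeneConstraintEntry]] = {}
    gnomad_cycle = [Subtype.HCM, Subtype.DCM, Subtype.ACM, Subtype.LVNC]
    for i in range(8):
        subtype = gnomad_cycle[i % 4]
        vclass = VariantClass.TRUNCATING if i % 2 == 0 else VariantClass.NON_TRUNCATING
        entry = GeneConstraintEntry(
            gene=f"SYN_GN_{i + 1:03d}",
            subtype=subtype,
            variant_class=vclass,
            pli=0.97 if vclass is VariantClass.TRUNCATING else None,
            mis_z=3.5 if vclass is VariantClass.NON_TRUNCATING else None,
        )
        entries.append(entry)
        gnomad_entries.setdefault(subtype, []).append(entry)

    other_genes = [f"SYN_OTHER_{i + 1:03d}" for i in range(5)]

    subtypes = list(cfg.subtype_mix.keys())
    weights = np.array([cfg.subtype_mix[s] for s in subtypes], dtype=float)
    weights = weights / weights.sum()

    observations: list[VariantObservation] = []
    variant_counter = 0

    def new_variant(gene: str) -> str:
        nonlocal variant_counter
        variant_counter += 1
        return f"{gene}:c.{variant_counter}A>G"

    def eligible_ce(subtype: Subtype) -> list[GeneConstraintEntry]:
        if subtype is Subtype.CM_UNCLASSIFIED:
            return [e for lst in ce_by_subtype.values() for e in lst]
        return ce_by_subtype.get(subtype, [])

    def eligible_gnomad(subtype: Subtype) -> list[GeneConstraintEntry]:
        if subtype is Subtype.CM_UNCLASSIFIED:
            return [e for lst in gnomad_entries.values() for e in lst]
        return gnomad_entries.get(subtype, [])

    for i in range(cfg.n_patients):
        pid = f"S{i + 1:05d}"
        subtype = subtypes[int(rng.choice(len(subtypes), p=weights))]

        def emit(gene, vclass, prior, founder=False, af=None, insilico=False, pheno=False):
            observations.append(
                VariantObservation(
                    patient_id=pid,
                    family_id=f"F{i + 1:05d}",
                    subtype=subtype,
                    gene=gene,
                    variant_id=new_variant(gene),
                    variant_class=vclass,
                    popmax_af=af,
                    insilico_support=insilico,
                    phenotype_specific=pheno,
                    prior_class=prior,
                    founder_flag=founder,
                )
            )

        if rng.random() < cfg.p_lp:
            ce_pool = eligible_ce(subtype)
            founder = bool(rng.random() < cfg.founder_rate)
            if ce_pool and rng.random() < cfg.p_lp_in_ce:
                host = ce_pool[int(rng.integers(len(ce_pool)))]
                emit(host.gene, host.variant_class, PriorClass.LP, founder=founder)
            else:
                gn_pool = eligible_gnomad(subtype)
                if gn_pool and rng.random() < 0.5:
                    host = gn_pool[int(rng.integers(len(gn_pool)))]
                    emit(host.gene, host.variant_class, PriorClass.LP, founder=founder)
                else:
                    gene = other_genes[int(rng.integers(len(other_genes)))]
                    emit(gene, VariantClass.NON_TRUNCATING, PriorClass.LP, founder=founder)

        n_vus = int(rng.poisson(cfg.vus_per_patient))
        for _ in range(n_vus):
            af = None if rng.random() < cfg.p_pm2_pass else 1e-4
            insilico = bool(rng.random() < cfg.p_pp3)
            pheno = bool(rng.random() < cfg.p_pp4)
            r = rng.random()
            ce_pool = eligible_ce(subtype)
            if r < 0.6 and ce_pool:
                host = ce_pool[int(rng.integers(len(ce_pool)))]
                emit(host.gene, host.variant_class, PriorClass.VUS,
                     af=af, insilico=insilico, pheno=pheno)
            elif r < 0.8:
                gn_pool = eligible_gnomad(subtype)
                if gn_pool:
                    host = gn_pool[int(rng.integers(len(gn_pool)))]
                    emit(host.gene, host.variant_class, PriorClass.VUS,
                         af=af, insilico=insilico, pheno=pheno)
            else:
                gene = other_genes[int(rng.integers(len(other_genes)))]
                emit(gene, VariantClass.NON_TRUNCATING, PriorClass.VUS,
                     af=af, insilico=insilico, pheno=pheno)

    return observations, entries


# ---------------------------------------------------------------------------
# Deterministic reference cohort (explicit tally allocation)


def reference_cohort() -> tuple[list[VariantObservation], list[GeneConstraintEntry]]:
    """Build the exact 2,002-patient reference cohort and constraint table.

    Constructed by explicit allocation, not simulation, so every derived
    tally (concordance, yields, triage counts) is exact and byte-stable
    across runs.  Variant multiplicities use the minimal allocation
    consistent with the patient/unique-variant tallies listed in the
    module docstring.
    """
    entries = _fixture_constraints()
    obs: list[VariantObservation] = []
    patient_counter = [0]
    variant_counters: dict[str, int] = {}

    def new_patient() -> str:
        patient_counter[0] += 1
        return f"P{patient_counter[0]:04d}"

    def variant(gene: str, n: Optional[int] = None) -> str:
        if n is None:
            variant_counters[gene] = variant_counters.get(gene, 0) + 1
            n = variant_counters[gene]
        return f"{gene}:c.{n}G>A"

    def add(pid, subtype, gene, vid, vclass, prior, *, founder=False, af=None,
            pos=None, insilico=False, pheno=False):
        obs.append(
            VariantObservation(
                patient_id=pid,
                family_id=f"F{pid[1:]}",
                subtype=subtype,
                gene=gene,
                variant_id=vid,
                variant_class=vclass,
                popmax_af=af,
                protein_position=pos,
                insilico_support=insilico,
                phenotype_specific=pheno,
                prior_class=prior,
                founder_flag=founder,
            )
        )

    T, NT = VariantClass.TRUNCATING, VariantClass.NON_TRUNCATING
    LP, VUS, LB = PriorClass.LP, PriorClass.VUS, PriorClass.LB

    # --- CE-route (L)P carriers -------------------------------------------
    # HCM: 169 patients / 172 unique variants; 158 / 160 concordant.
    hcm_lp: list[str] = []
    conc = [variant("MYBPC3", i + 1) for i in range(160)]
    for k in range(2):  # two patients carry two concordant variants each
        pid = new_patient(); hcm_lp.append(pid)
        add(pid, Subtype.HCM, "MYBPC3", conc[2 * k], T, LP)
        add(pid, Subtype.HCM, "MYBPC3", conc[2 * k + 1], T, LP)
    for v in conc[4:]:
        pid = new_patient(); hcm_lp.append(pid)
        add(pid, Subtype.HCM, "MYBPC3", v, T, LP)
    disc = [variant("MYH6", i + 1) for i in range(12)]  # not significant: discordant
    pid = new_patient()
    add(pid, Subtype.HCM, "MYH6", disc[0], NT, LP, founder=True)
    add(pid, Subtype.HCM, "MYH6", disc[1], NT, LP, founder=True)
    for i, v in enumerate(disc[2:], start=2):
        pid = new_patient()
        add(pid, Subtype.HCM, "MYH6", v, NT, LP, founder=(i < 8))

    # DCM: 181 / 186; 178 / 177 concordant (one variant shared by two carriers).
    dcm_lp: list[str] = []
    conc = [variant("TTN", i + 1) for i in range(177)]
    for _ in range(2):
        pid = new_patient(); dcm_lp.append(pid)
        add(pid, Subtype.DCM, "TTN", conc[0], T, LP)
    for v in conc[1:]:
        pid = new_patient(); dcm_lp.append(pid)
        add(pid, Subtype.DCM, "TTN", v, T, LP)
    disc = [variant("MYPN", i + 1) for i in range(9)]
    for k in range(3):  # three patients, three discordant variants each
        pid = new_patient()
        for j in range(3):
            add(pid, Subtype.DCM, "MYPN", disc[3 * k + j], NT, LP,
                founder=(3 * k + j < 6))

    # ACM: 19 / 20; 17 / 17 concordant.
    for i in range(17):
        add(new_patient(), Subtype.ACM, "PKP2", variant("PKP2", i + 1), T, LP)
    disc = [variant("CTNNA3", i + 1) for i in range(3)]
    pid = new_patient()
    add(pid, Subtype.ACM, "CTNNA3", disc[0], NT, LP, founder=True)
    add(pid, Subtype.ACM, "CTNNA3", disc[1], NT, LP)
    add(new_patient(), Subtype.ACM, "CTNNA3", disc[2], NT, LP)

    # --- gnomAD-route (L)P carriers: 22 patients / 22 variants, 12 concordant.
    lvnc_gn_lp = [new_patient() for _ in range(4)]
    for pid in lvnc_gn_lp:
        add(pid, Subtype.LVNC, "HCN4", variant("HCN4"), T, LP)
    for _ in range(3):
        add(new_patient(), Subtype.DCM, "PRDM16", variant("PRDM16"), NT, LP)
    for _ in range(3):
        add(new_patient(), Subtype.ACM, "RYR2", variant("RYR2"), NT, LP)
    for _ in range(2):
        add(new_patient(), Subtype.CM_UNCLASSIFIED, "RYR2", variant("RYR2"), NT, LP)
    for _ in range(4):  # mis_z below cut: discordant
        add(new_patient(), Subtype.DCM, "ABCC9", variant("ABCC9"), NT, LP)
    for _ in range(3):  # pLI below cut: discordant
        add(new_patient(), Subtype.DCM, "LDB3", variant("LDB3"), T, LP)
    for _ in range(3):  # mis_z missing: screen inconclusive, discordant
        add(new_patient(), Subtype.HCM, "MYOZ2", variant("MYOZ2"), NT, LP)

    # --- (L)Ps in genes without any constraint entry: 39 patients ---------
    unmatched_cm: list[str] = []
    unmatched_lvnc: list[str] = []
    for subtype, n in (
        (Subtype.HCM, 10), (Subtype.DCM, 10),
        (Subtype.CM_UNCLASSIFIED, 10), (Subtype.LVNC, 9),
    ):
        for _ in range(n):
            pid = new_patient()
            add(pid, subtype, "OBSCN", variant("OBSCN"), NT, LP)
            if subtype is Subtype.CM_UNCLASSIFIED:
                unmatched_cm.append(pid)
            elif subtype is Subtype.LVNC:
                unmatched_lvnc.append(pid)

    # --- CE-route selected VUSs: 92 unique in 143 patients ----------------
    def vus_kwargs():
        return dict(af=None, insilico=True, pheno=True)

    def spread(variants: list[str], n_rows: int) -> list[str]:
        """First variants carried twice, remainder once; len == n_rows."""
        n_shared = n_rows - len(variants)
        out = []
        for v in variants[:n_shared]:
            out += [v, v]
        out += variants[n_shared:]
        assert len(out) == n_rows
        return out

    # HCM reclassified: MYH7 hotspot (residues 181-937, EF 0.96):
    # 17 unique / 21 rows; 19 undiagnosed + 2 already-diagnosed patients.
    rows = spread([variant("MYH7", i + 1) for i in range(17)], 21)
    carriers = [new_patient() for _ in range(19)] + hcm_lp[:2]
    for pid, vid in zip(carriers, rows):
        add(pid, Subtype.HCM, "MYH7", vid, NT, VUS, pos=500, **vus_kwargs())

    # HCM prioritized: TNNT2 (EF 0.85): 25 unique / 40 rows; 25 + 15.
    rows = spread([variant("TNNT2", i + 1) for i in range(25)], 40)
    carriers = [new_patient() for _ in range(25)] + hcm_lp[2:17]
    for pid, vid in zip(carriers, rows):
        add(pid, Subtype.HCM, "TNNT2", vid, NT, VUS, **vus_kwargs())

    # DCM reclassified: DSP truncating (EF 0.93): 6 unique / 7 rows; 6 + 1.
    rows = spread([variant("DSP", i + 1) for i in range(6)], 7)
    carriers = [new_patient() for _ in range(6)] + dcm_lp[:1]
    for pid, vid in zip(carriers, rows):
        add(pid, Subtype.DCM, "DSP", vid, T, VUS, **vus_kwargs())

    # DCM prioritized: RBM20 (EF 0.85): 25 unique / 48 rows; 40 + 8.
    rows = spread([variant("RBM20", i + 1) for i in range(25)], 48)
    carriers = [new_patient() for _ in range(40)] + dcm_lp[1:9]
    for pid, vid in zip(carriers, rows):
        add(pid, Subtype.DCM, "RBM20", vid, NT, VUS, **vus_kwargs())

    # ACM prioritized: DSG2 (EF 0.84): 1 unique / 1 row, undiagnosed.
    add(new_patient(), Subtype.ACM, "DSG2", variant("DSG2", 100), NT, VUS, **vus_kwargs())

    # Unclassified CM prioritized via DCM entry: LMNA (EF 0.82):
    # 18 unique / 26 rows; 22 undiagnosed + 4 diagnosed (unmatched-gene carriers).
    rows = spread([variant("LMNA", i + 1) for i in range(18)], 26)
    carriers = [new_patient() for _ in range(22)] + unmatched_cm[:4]
    for pid, vid in zip(carriers, rows):
        add(pid, Subtype.CM_UNCLASSIFIED, "LMNA", vid, NT, VUS, **vus_kwargs())

    # --- gnomAD-route selected VUSs: 37 unique in 42 patients -------------
    # DCM / PRDM16 (mis_z 3.4): 9 unique / 10 rows; 2 undiagnosed + 8 diagnosed.
    rows = spread([variant("PRDM16", 100 + i) for i in range(9)], 10)
    carriers = [new_patient() for _ in range(2)] + dcm_lp[9:17]
    for pid, vid in zip(carriers, rows):
        add(pid, Subtype.DCM, "PRDM16", vid, NT, VUS, af=None)
    # LVNC / HCN4 (pLI 0.97): 8 unique / 8 rows; 6 undiagnosed + 2 diagnosed.
    rows = [variant("HCN4", 100 + i) for i in range(8)]
    carriers = [new_patient() for _ in range(6)] + unmatched_lvnc[:2]
    for pid, vid in zip(carriers, rows):
        add(pid, Subtype.LVNC, "HCN4", vid, T, VUS, af=None)
    # CM / RYR2 (mis_z 3.8): 11 unique / 14 rows; 11 undiagnosed + 3 diagnosed.
    rows = spread([variant("RYR2", 100 + i) for i in range(11)], 14)
    carriers = [new_patient() for _ in range(11)] + unmatched_cm[4:7]
    for pid, vid in zip(carriers, rows):
        add(pid, Subtype.CM_UNCLASSIFIED, "RYR2", vid, NT, VUS, af=None)
    # HCM / TRIM63 (pLI 0.96): 9 unique / 10 rows; all 10 already diagnosed.
    rows = spread([variant("TRIM63", 100 + i) for i in range(9)], 10)
    carriers = hcm_lp[17:27]
    for pid, vid in zip(carriers, rows):
        add(pid, Subtype.HCM, "TRIM63", vid, T, VUS, af=None)

    # --- remaining patients: one common likely-benign finding each --------
    filler_mix = [
        (Subtype.HCM, 474), (Subtype.DCM, 400), (Subtype.ACM, 100),
        (Subtype.CM_UNCLASSIFIED, 250), (Subtype.LVNC, 216),
    ]
    for subtype, n in filler_mix:
        for _ in range(n):
            pid = new_patient()
            add(pid, subtype, "NPPA", variant("NPPA"), VariantClass.OTHER, LB, af=0.01)

    assert patient_counter[0] == 2002, patient_counter[0]
    return obs, entries


def _fixture_constraints() -> list[GeneConstraintEntry]:
    T, NT = VariantClass.TRUNCATING, VariantClass.NON_TRUNCATING
    e: list[GeneConstraintEntry] = []

    def ce(gene, subtype, vclass, ef, significant=True, region=None):
        e.append(
            GeneConstraintEntry(
                gene=gene, subtype=subtype, variant_class=vclass,
                has_case_excess=significant, ef=ef,
                region_start=region[0] if region else None,
                region_end=region[1] if region else None,
            )
        )

    def gnomad(gene, subtype, vclass, pli=None, mis_z=None):
        e.append(
            GeneConstraintEntry(
                gene=gene, subtype=subtype, variant_class=vclass, pli=pli, mis_z=mis_z
            )
        )

    # HCM: 14 genes with case excess; MYH7 has a sharper hotspot estimate.
    ce("MYH7", Subtype.HCM, NT, 0.96, region=(181, 937))
    ce("MYH7", Subtype.HCM, NT, 0.91)
    ce("MYBPC3", Subtype.HCM, T, 0.97)
    ce("TNNT2", Subtype.HCM, NT, 0.85)
    for gene in ("TNNI3", "TPM1", "ACTC1", "MYL2", "MYL3", "CSRP3",
                 "TNNC1", "JPH2", "FHOD3", "PLN", "ALPK3"):
        ce(gene, Subtype.HCM, NT, 0.85)
    ce("MYH6", Subtype.HCM, NT, 0.30, significant=False)  # analysed, no excess

    # DCM: 14 genes with case excess.
    ce("TTN", Subtype.DCM, T, 0.96)
    ce("DSP", Subtype.DCM, T, 0.93)
    ce("RBM20", Subtype.DCM, NT, 0.85)
    ce("LMNA", Subtype.DCM, NT, 0.82)
    for gene in ("SCN5A", "BAG3", "FLNC", "DES", "NEXN", "TCAP",
                 "VCL", "ACTN2", "PLEKHM2", "TBX20"):
        ce(gene, Subtype.DCM, NT, 0.85)
    ce("MYPN", Subtype.DCM, NT, 0.25, significant=False)

    # ACM: 5 genes with case excess.
    ce("PKP2", Subtype.ACM, T, 0.95)
    ce("DSG2", Subtype.ACM, NT, 0.84)
    for gene in ("JUP", "DSC2", "TMEM43"):
        ce(gene, Subtype.ACM, NT, 0.85)
    ce("CTNNA3", Subtype.ACM, NT, 0.20, significant=False)

    # gnomAD-only genes (no burden analysis available).
    gnomad("HCN4", Subtype.LVNC, T, pli=0.97)
    gnomad("PRDM16", Subtype.DCM, NT, mis_z=3.4)
    gnomad("RYR2", Subtype.ACM, NT, mis_z=3.8)
    gnomad("TRIM63", Subtype.HCM, T, pli=0.96)
    gnomad("ABCC9", Subtype.DCM, NT, mis_z=1.2)
    gnomad("LDB3", Subtype.DCM, T, pli=0.30)
    gnomad("MYOZ2", Subtype.HCM, NT, pli=0.95)  # no mis_z: screen inconclusive

    return e


# ---------------------------------------------------------------------------
# EF estimator calibration


def parameter_recovery_experiment(
    true_ef: float = 0.9,
    case_n: int = 1000,
    control_n: int = 60706,
    f_ctrl: float = 0.01,
    n_reps: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    boundaries: tuple[float, ...] = (0.8, 0.9, 0.95),
    f_case: Optional[float] = None,
) -> dict:
    """Quantify bias, CI coverage and band misassignment of the EF estimator.

    Simulates carrier counts under a known true etiological fraction
    (case carrier frequency ``f_ctrl / (1 - true_ef)`` unless ``f_case``
    is given explicitly, e.g. for the zero-control-frequency corner),
    runs :func:`compute_burden` on each replicate and summarises the
    sampling behaviour of the estimate.  CI coverage is evaluated on
    replicates where all four table cells are positive.
    """
    if not (0.0 <= true_ef <= 1.0):
        raise ValueError("true_ef must be in [0, 1]")
    if f_case is None:
        if true_ef >= 1.0:
            raise ValueError("true_ef = 1 requires an explicit f_case")
        f_case = f_ctrl / (1.0 - true_ef)
    if f_case > 1.0:
        raise ValueError("implied case frequency exceeds 1")
    rng = np.random.default_rng(seed)

    efs: list[float] = []
    covered = 0
    n_ci = 0
    misbinned = 0
    true_band = sum(true_ef >= b for b in boundaries)
    for _ in range(n_reps):
        a = int(rng.binomial(case_n, f_case))
        b = int(rng.binomial(control_n, f_ctrl))
        result = compute_burden(
            BurdenCounts(
                gene="SIM", subtype=None, variant_class=VariantClass.TRUNCATING,
                case_carriers=a, case_n=case_n,
                control_carriers=b, control_n=control_n,
            ),
            alpha=alpha,
        )
        if result.ef is None:
            continue
        efs.append(result.ef)
        if sum(result.ef >= b for b in boundaries) != true_band:
            misbinned += 1
        if result.ef_ci_low is not None and result.ef_ci_high is not None:
            n_ci += 1
            if result.ef_ci_low <= true_ef <= result.ef_ci_high:
                covered += 1

    efs_arr = np.asarray(efs)
    mean_ef = float(efs_arr.mean()) if len(efs) else float("nan")
    sd = float(efs_arr.std(ddof=1)) if len(efs) > 1 else float("nan")
    return {
        "true_ef": true_ef,
        "n_reps": n_reps,
        "n_defined": len(efs),
        "mean_ef": mean_ef,
        "bias": mean_ef - true_ef,
        "sd": sd,
        "mc_se": sd / math.sqrt(len(efs)) if len(efs) else float("nan"),
        "ci_coverage": covered / n_ci if n_ci else float("nan"),
        "n_ci": n_ci,
        "misbin_rate": misbinned / len(efs) if efs else float("nan"),
        "boundaries": boundaries,
    }
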