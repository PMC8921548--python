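"""Triage decision flow: selection, reclassification gates, upgrades,
concordance validation, and determinism of serialised output."""

import pytest

from cardiotriage import (
    AcmgClass,
    Action,
    Criterion,
    GeneConstraintEntry,
    PriorClass,
    Route,
    Subtype,
    Thresholds,
    VariantClass,
    VariantObservation,
    apply_pp1_upgrade,
    read_decisions,
    triage_vus,
    validate_lp_concordance,
    write_decisions,
)

T, NT = VariantClass.TRUNCATING, VariantClass.NON_TRUNCATING


def _vus(gene="DSP", vclass=T, subtype=Subtype.DCM, af=None, pid="P1", vid=None,
         insilico=True, pheno=True, pos=None, meioses=0):
    return VariantObservation(
        patient_id=pid, family_id="F" + pid, subtype=subtype, gene=gene,
        variant_id=vid or f"{gene}:c.1del", variant_class=vclass, popmax_af=af,
        protein_position=pos, insilico_support=insilico, phenotype_specific=pheno,
        segregating_meioses=meioses, prior_class=PriorClass.VUS,
    )


def _ce_entry(gene="DSP", vclass=T, subtype=Subtype.DCM, ef=0.93, significant=True):
    return GeneConstraintEntry(gene, subtype, vclass, has_case_excess=significant, ef=ef)


class TestTriageVus:
    def test_high_ef_with_all_gates_reclassifies(self):
        [d] = triage_vus([_vus()], [_ce_entry(ef=0.93)])
        assert d.action is Action.RECLASSIFY_LP
        assert d.route is Route.CE_EF_GENE
        assert d.new_class is AcmgClass.LIKELY_PATHOGENIC
        assert Criterion.PM1 in d.evidence and Criterion.PM2 in d.evidence

    def test_significant_but_moderate_ef_prioritizes(self):
        [d] = triage_vus([_vus()], [_ce_entry(ef=0.85)])
        assert d.action is Action.PRIORITIZE
        assert d.route is Route.CE_EF_GENE
        assert d.new_class is None

    def test_population_frequency_above_pm2_cut_blocks_reclassification(self):
        # 0.01% carrier frequency: still rare enough for selection, too
        # common for the PM2-gated immediate reclassification
        [d] = triage_vus([_vus(af=1e-4)], [_ce_entry(ef=0.93)])
        assert d.action is Action.PRIORITIZE

    def test_missing_pp3_or_pp4_blocks_reclassification(self):
        [d] = triage_vus([_vus(insilico=False)], [_ce_entry(ef=0.93)])
        assert d.action is Action.PRIORITIZE
        [d] = triage_vus([_vus(pheno=False)], [_ce_entry(ef=0.93)])
        assert d.action is Action.PRIORITIZE

    def test_gnomad_route_prioritizes_never_reclassifies(self):
        entry = GeneConstraintEntry("HCN4", Subtype.LVNC, T, pli=0.95)
        obs = _vus(gene="HCN4", subtype=Subtype.LVNC)
        [d] = triage_vus([obs], [entry])
        assert d.route is Route.GNOMAD_GENE
        assert d.action is Action.PRIORITIZE

    def test_gnomad_route_requires_subtype_established_gene(self):
        entry = GeneConstraintEntry("HCN4", None, T, pli=0.95)  # ANY subtype
        [d] = triage_vus([_vus(gene="HCN4", subtype=Subtype.LVNC)], [entry])
        assert d.action is Action.NONE

    def test_unmatched_gene_is_left_untouched(self):
        [d] = triage_vus([_vus(gene="OBSCN")], [_ce_entry()])
        assert d.action is Action.NONE
        assert d.route is Route.UNMATCHED

    def test_common_variant_not_selected(self):
        [d] = triage_vus([_vus(af=5e-4)], [_ce_entry(ef=0.93)])
        assert d.action is Action.NONE

    def test_ce_analysed_but_not_significant_not_selected(self):
        [d] = triage_vus([_vus()], [_ce_entry(ef=0.3, significant=False)])
        assert d.action is Action.NONE

    def test_region_resolved_ef_governs_reclassification(self):
        region = GeneConstraintEntry("MYH7", Subtype.HCM, NT, has_case_excess=True,
                                     ef=0.96, region_start=181, region_end=937)
        wide = GeneConstraintEntry("MYH7", Subtype.HCM, NT, has_case_excess=True, ef=0.85)
        inside = _vus(gene="MYH7", vclass=NT, subtype=Subtype.HCM, pos=500)
        outside = _vus(gene="MYH7", vclass=NT, subtype=Subtype.HCM, pos=50)
        [d_in] = triage_vus([inside], [region, wide])
        [d_out] = triage_vus([outside], [region, wide])
        assert d_in.action is Action.RECLASSIFY_LP
        assert d_out.action is Action.PRIORITIZE

    def test_only_vus_rows_are_triaged(self):
        lp = VariantObservation("P9", "F9", Subtype.DCM, "DSP", "DSP:c.9del", T,
                                prior_class=PriorClass.LP)
        decisions = triage_vus([lp, _vus()], [_ce_entry()])
        assert len(decisions) == 1
        assert decisions[0].patient_id == "P1"

    def test_reclassification_rationale_names_every_gate(self):
        [d] = triage_vus([_vus()], [_ce_entry(ef=0.93)])
        text = " | ".join(d.rationale)
        assert "EF=0.93 >= ef_reclass=0.9" in text
        assert "PM2 met" in text and "PP3 met" in text and "PP4 met" in text
        assert "likely_pathogenic" in text

    def test_reclassify_implies_engine_agreement(self, reference_cohort):
        from cardiotriage import combine
        cohort, table = reference_cohort
        for d in triage_vus(cohort, table):
            if d.action is Action.RECLASSIFY_LP:
                assert combine(d.evidence) in (
                    AcmgClass.LIKELY_PATHOGENIC, AcmgClass.PATHOGENIC
                )
                assert d.entry.ef >= 0.90
                text = " ".join(d.rationale)
                assert "PM2 met" in text and "PP3 met" in text and "PP4 met" in text


class TestPp1Upgrade:
    def _prioritized(self, ef=0.85):
        [d] = triage_vus([_vus()], [_ce_entry(ef=ef)])
        assert d.action is Action.PRIORITIZE
        return d

    def test_five_meioses_upgrade_supporting_hotspot_to_lp(self):
        # PM1@supporting + PM2 + PP1@moderate + PP3 + PP4: two moderates
        # and three supportings reach likely pathogenic
        up = apply_pp1_upgrade(self._prioritized(), meioses=5)
        assert up.action is Action.RECLASSIFY_LP
        assert up.new_class is AcmgClass.LIKELY_PATHOGENIC
        assert up.evidence.get(Criterion.PP1).effective_strength.value == "moderate"

    def test_two_meioses_change_nothing(self):
        d = self._prioritized()
        assert apply_pp1_upgrade(d, meioses=2) is d

    def test_already_reclassified_is_idempotent(self):
        [d] = triage_vus([_vus()], [_ce_entry(ef=0.93)])
        assert d.action is Action.RECLASSIFY_LP
        assert apply_pp1_upgrade(d, meioses=7) is d


class TestConcordance:
    def test_empty_cohort_gives_empty_result(self):
        result = validate_lp_concordance([], [_ce_entry()])
        assert result.ce["TOTAL"].n_rdc_lp_variants == 0
        assert result.ce["TOTAL"].concordance_pct is None
        assert result.founder_discordant_pct is None

    def test_cohort_without_lp_gives_zero_tallies(self):
        result = validate_lp_concordance([_vus()], [_ce_entry()])
        assert result.ce["TOTAL"].n_rdc_lp_patients == 0
        assert result.gnomad["TOTAL"].n_rdc_lp_patients == 0

    def test_routes_split_by_table_knowledge(self):
        ce_lp = VariantObservation("P1", "F1", Subtype.DCM, "DSP", "v1", T,
                                   prior_class=PriorClass.LP)
        gn_lp = VariantObservation("P2", "F2", Subtype.LVNC, "HCN4", "v2", T,
                                   prior_class=PriorClass.P)
        table = [_ce_entry(), GeneConstraintEntry("HCN4", Subtype.LVNC, T, pli=0.95)]
        result = validate_lp_concordance([ce_lp, gn_lp], table)
        assert result.ce["TOTAL"].n_rdc_lp_variants == 1
        assert result.ce["TOTAL"].n_concordant_variants == 1
        assert result.gnomad["TOTAL"].n_rdc_lp_variants == 1
        assert result.gnomad["TOTAL"].n_concordant_variants == 1

    def test_shared_variant_counted_once_per_route(self):
        rows = [
            VariantObservation(f"P{i}", f"F{i}", Subtype.DCM, "DSP", "shared", T,
                               prior_class=PriorClass.LP)
            for i in range(1, 4)
        ]
        result = validate_lp_concordance(rows, [_ce_entry()])
        assert result.ce["TOTAL"].n_rdc_lp_variants == 1
        assert result.ce["TOTAL"].n_rdc_lp_patients == 3


class TestDeterminism:
    def test_triage_output_is_byte_identical_across_runs(self, tmp_path, reference_cohort):
        cohort, table = reference_cohort
        paths = []
        for name in ("a.tsv", "b.tsv"):
            decisions = triage_vus(cohort, table)
            p = tmp_path / name
            write_decisions(p, decisions)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_decisions_round_trip(self, tmp_path):
        decisions = triage_vus([_vus(), _vus(pid="P2", af=1e-4)], [_ce_entry(ef=0.93)])
        p = tmp_path / "d.tsv"
        write_decisions(p, decisions)
        back = read_decisions(p)
        assert len(back) == len(decisions)
        for orig, rt in zip(decisions, back):
            assert rt.patient_id == orig.patient_id
            assert rt.variant_id == orig.variant_id
            assert rt.route is orig.route
            assert rt.action is orig.action
            assert rt.new_class == orig.new_class
            assert rt.rationale == orig.rationale
            assert rt.evidence.tokens() == orig.evidence.tokens()
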