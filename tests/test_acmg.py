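"""ACMG engine: EF banding, evidence assignment, and the combining rules
checked subset-by-subset against a transliterated rule-table oracle."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from cardiotriage import (
    AcmgClass,
    Criterion,
    Evidence,
    EvidenceSet,
    GeneConstraintEntry,
    PriorClass,
    Strength,
    Subtype,
    Thresholds,
    VariantClass,
    VariantObservation,
    assign_evidence,
    combine,
    ef_to_pm1,
)

NT = VariantClass.NON_TRUNCATING


# ---------------------------------------------------------------------------
# Oracle: a direct transliteration of the published combining table as an
# explicit rule list (min counts of very-strong/strong/moderate/supporting on
# the pathogenic side, standalone/strong/supporting on the benign side).

_PATHOGENIC_RULES = [  # (very_strong, strong, moderate, supporting)
    (2, 0, 0, 0),
    (1, 1, 0, 0), (1, 0, 2, 0), (1, 0, 1, 1), (1, 0, 0, 2),
    (0, 2, 0, 0),
    (0, 1, 3, 0), (0, 1, 2, 2), (0, 1, 1, 4),
]
_LIKELY_PATHOGENIC_RULES = [
    (1, 0, 1, 0),
    (0, 1, 1, 0), (0, 1, 2, 0),  # 1 strong and 1-2 moderate
    (0, 1, 0, 2),                # 1 strong and >=2 supporting
    (0, 0, 3, 0),                # >=3 moderate
    (0, 0, 2, 2),                # 2 moderate and >=2 supporting
    (0, 0, 1, 4),                # 1 moderate and >=4 supporting
]
_BENIGN_RULES = [(1, 0, 0), (0, 2, 0)]          # (standalone, strong, supporting)
_LIKELY_BENIGN_RULES = [(0, 1, 1), (0, 0, 2)]


def _oracle(evidences):
    path = {s: 0 for s in Strength}
    ben = {s: 0 for s in Strength}
    for ev in evidences:
        bucket = path if ev.criterion.is_pathogenic_side else ben
        bucket[ev.effective_strength] += 1
    pvec = (path[Strength.VERY_STRONG], path[Strength.STRONG],
            path[Strength.MODERATE], path[Strength.SUPPORTING])
    bvec = (ben[Strength.STANDALONE], ben[Strength.STRONG], ben[Strength.SUPPORTING])

    def fires(rules, vec):
        return any(all(v >= r for v, r in zip(vec, rule)) for rule in rules)

    p_class = (AcmgClass.PATHOGENIC if fires(_PATHOGENIC_RULES, pvec)
               else AcmgClass.LIKELY_PATHOGENIC if fires(_LIKELY_PATHOGENIC_RULES, pvec)
               else None)
    b_class = (AcmgClass.BENIGN if fires(_BENIGN_RULES, bvec)
               else AcmgClass.LIKELY_BENIGN if fires(_LIKELY_BENIGN_RULES, bvec)
               else None)
    if p_class and b_class:
        return AcmgClass.VUS
    return p_class or b_class or AcmgClass.VUS


# ---------------------------------------------------------------------------
# EF banding


class TestEfBands:
    @pytest.mark.parametrize(
        "ef,strength",
        [
            (0.97, Strength.STRONG), (0.95, Strength.STRONG),
            (0.92, Strength.MODERATE), (0.90, Strength.MODERATE),
            (0.9499, Strength.MODERATE),
            (0.85, Strength.SUPPORTING), (0.80, Strength.SUPPORTING),
            (0.8999, Strength.SUPPORTING),
        ],
    )
    def test_band_assignment(self, ef, strength):
        evidence = ef_to_pm1(ef)
        assert evidence is not None
        assert evidence.criterion is Criterion.PM1
        assert evidence.effective_strength is strength

    @pytest.mark.parametrize("ef", [0.7999, 0.5, 0.0, None])
    def test_below_supporting_band_yields_nothing(self, ef):
        assert ef_to_pm1(ef) is None

    def test_step_function_edges_are_left_closed(self):
        eps = 1e-12
        assert ef_to_pm1(0.95).effective_strength is Strength.STRONG
        assert ef_to_pm1(0.95 - eps).effective_strength is Strength.MODERATE
        assert ef_to_pm1(0.90).effective_strength is Strength.MODERATE
        assert ef_to_pm1(0.90 - eps).effective_strength is Strength.SUPPORTING
        assert ef_to_pm1(0.80).effective_strength is Strength.SUPPORTING
        assert ef_to_pm1(0.80 - eps) is None


# ---------------------------------------------------------------------------
# Evidence assignment


def _obs(**overrides):
    base = dict(
        patient_id="P1", family_id="F1", subtype=Subtype.HCM, gene="MYH7",
        variant_id="v1", variant_class=NT, popmax_af=None,
        insilico_support=False, phenotype_specific=False,
        prior_class=PriorClass.VUS,
    )
    base.update(overrides)
    return VariantObservation(**base)


def _entry(ef=None, **kw):
    return GeneConstraintEntry("MYH7", Subtype.HCM, NT, has_case_excess=ef is not None,
                               ef=ef, **kw)


class TestAssignEvidence:
    def test_reclassification_combination(self):
        """Absent from population data + in-silico + phenotype + EF 0.93
        activates exactly the moderate-hotspot reclassification set."""
        ev = assign_evidence(
            _obs(insilico_support=True, phenotype_specific=True), _entry(ef=0.93)
        )
        tokens = {e.token() for e in ev}
        assert tokens == {"PM1", "PM2", "PP3", "PP4"}
        assert ev.get(Criterion.PM1).effective_strength is Strength.MODERATE
        assert combine(ev) is AcmgClass.LIKELY_PATHOGENIC

    def test_af_above_pm2_cut_blocks_pm2(self):
        # 0.005% is above the 0.004% rarity cut
        ev = assign_evidence(_obs(popmax_af=5e-5), _entry(ef=0.93))
        assert Criterion.PM2 not in ev

    def test_af_just_below_pm2_cut_passes(self):
        ev = assign_evidence(_obs(popmax_af=3.9e-5), None)
        assert Criterion.PM2 in ev

    @pytest.mark.parametrize(
        "meioses,expected",
        [(7, Strength.STRONG), (8, Strength.STRONG), (5, Strength.MODERATE),
         (6, Strength.MODERATE), (3, Strength.SUPPORTING), (4, Strength.SUPPORTING),
         (2, None), (0, None)],
    )
    def test_pp1_tiers_highest_only(self, meioses, expected):
        ev = assign_evidence(_obs(segregating_meioses=meioses), None)
        pp1 = ev.get(Criterion.PP1)
        if expected is None:
            assert pp1 is None
        else:
            assert pp1.effective_strength is expected

    def test_ps4_proband_threshold(self):
        assert Criterion.PS4 in assign_evidence(_obs(proband_count=15), None)
        assert Criterion.PS4 not in assign_evidence(_obs(proband_count=14), None)

    def test_provenance_records_each_trigger(self):
        ev = assign_evidence(
            _obs(insilico_support=True, phenotype_specific=True), _entry(ef=0.96)
        )
        text = " ".join(ev.provenance)
        for tag in ("PM1", "PM2", "PP3", "PP4"):
            assert tag in text


# ---------------------------------------------------------------------------
# Combining rules


class TestCombine:
    def test_strong_plus_moderates_and_supportings_is_lp(self):
        ev = EvidenceSet([Evidence(Criterion.PM1, Strength.STRONG),
                          Evidence(Criterion.PM2),
                          Evidence(Criterion.PP3), Evidence(Criterion.PP4)])
        assert combine(ev) is AcmgClass.LIKELY_PATHOGENIC

    def test_two_moderates_two_supportings_is_lp(self):
        ev = EvidenceSet([Evidence(Criterion.PM1, Strength.MODERATE),
                          Evidence(Criterion.PM2),
                          Evidence(Criterion.PP3), Evidence(Criterion.PP4)])
        assert combine(ev) is AcmgClass.LIKELY_PATHOGENIC

    def test_empty_set_is_vus(self):
        assert combine(EvidenceSet()) is AcmgClass.VUS

    def test_pathogenic_precedence_over_lp(self):
        ev = EvidenceSet([Evidence(Criterion.PVS1), Evidence(Criterion.PS4)])
        assert combine(ev) is AcmgClass.PATHOGENIC

    def test_conflicting_evidence_is_vus(self):
        ev = EvidenceSet([Evidence(Criterion.PVS1), Evidence(Criterion.PS4),
                          Evidence(Criterion.BA1)])
        assert combine(ev) is AcmgClass.VUS

    def test_benign_rules(self):
        assert combine(EvidenceSet([Evidence(Criterion.BA1)])) is AcmgClass.BENIGN
        assert combine(EvidenceSet([Evidence(Criterion.BS1), Evidence(Criterion.BS2)])) is AcmgClass.BENIGN
        assert combine(EvidenceSet([Evidence(Criterion.BS1), Evidence(Criterion.BP4)])) is AcmgClass.LIKELY_BENIGN
        assert combine(EvidenceSet([Evidence(Criterion.BP4), Evidence(Criterion.BP7)])) is AcmgClass.LIKELY_BENIGN

    def test_duplicate_criterion_rejected(self):
        ev = EvidenceSet([Evidence(Criterion.PM2)])
        with pytest.raises(ValueError):
            ev.add(Evidence(Criterion.PM2))

    def test_matches_oracle_on_all_subsets_with_overrides(self):
        """Every subset of {PVS1, PS4, PM1, PM2, PP1, PP3} (k <= 6), with PM1
        and PP1 at every strength they can take, agrees with the rule table."""
        pm1_variants = [None, Strength.SUPPORTING, Strength.MODERATE, Strength.STRONG]
        pp1_variants = [None, Strength.MODERATE, Strength.STRONG]
        fixed = [Criterion.PVS1, Criterion.PS4, Criterion.PM2, Criterion.PP3]
        n_checked = 0
        for r in range(len(fixed) + 1):
            for subset in itertools.combinations(fixed, r):
                for with_pm1 in (False, True):
                    for with_pp1 in (False, True):
                        pm1_opts = pm1_variants if with_pm1 else [False]
                        pp1_opts = pp1_variants if with_pp1 else [False]
                        for pm1_s in pm1_opts:
                            for pp1_s in pp1_opts:
                                items = [Evidence(c) for c in subset]
                                if with_pm1:
                                    items.append(Evidence(Criterion.PM1, pm1_s or None))
                                if with_pp1:
                                    items.append(Evidence(Criterion.PP1, pp1_s or None))
                                ev = EvidenceSet(items)
                                assert combine(ev) is _oracle(items), ev.tokens()
                                n_checked += 1
        assert n_checked == 320  # 16 subsets x 5 PM1 options x 4 PP1 options

    def test_matches_oracle_with_benign_mixtures(self):
        path_pool = [Evidence(Criterion.PS4), Evidence(Criterion.PM2),
                     Evidence(Criterion.PP3)]
        benign_pool = [Evidence(Criterion.BA1), Evidence(Criterion.BS1),
                       Evidence(Criterion.BS2), Evidence(Criterion.BP4)]
        for rp in range(len(path_pool) + 1):
            for rb in range(len(benign_pool) + 1):
                for ps in itertools.combinations(path_pool, rp):
                    for bs in itertools.combinations(benign_pool, rb):
                        items = list(ps) + list(bs)
                        assert combine(EvidenceSet(items)) is _oracle(items)

    @settings(derandomize=True, max_examples=200)
    @given(data=st.data())
    def test_adding_pathogenic_evidence_is_monotone(self, data):
        """Without benign-side criteria, adding a pathogenic criterion never
        moves the class away from pathogenic."""
        order = {AcmgClass.VUS: 0, AcmgClass.LIKELY_PATHOGENIC: 1, AcmgClass.PATHOGENIC: 2}
        pool = [Criterion.PVS1, Criterion.PS1, Criterion.PS4, Criterion.PM1,
                Criterion.PM2, Criterion.PM4, Criterion.PP1, Criterion.PP3,
                Criterion.PP4]
        chosen = data.draw(st.lists(st.sampled_from(pool), unique=True, max_size=6))
        extra = data.draw(st.sampled_from([c for c in pool if c not in chosen]))
        base = [Evidence(c) for c in chosen]
        before = combine(EvidenceSet(base))
        after = combine(EvidenceSet(base + [Evidence(extra)]))
        assert order[after] >= order[before]

    @settings(derandomize=True, max_examples=100)
    @given(data=st.data())
    def test_permutation_invariance(self, data):
        pool = [Evidence(Criterion.PS4), Evidence(Criterion.PM1, Strength.STRONG),
                Evidence(Criterion.PM2), Evidence(Criterion.PP3),
                Evidence(Criterion.BP4)]
        chosen = data.draw(st.lists(st.sampled_from(range(len(pool))),
                                    unique=True, max_size=5))
        items = [pool[i] for i in chosen]
        perm = data.draw(st.permutations(items))
        assert combine(EvidenceSet(items)) is combine(EvidenceSet(perm))


def test_evidence_token_round_trip():
    ev = EvidenceSet([Evidence(Criterion.PM1, Strength.STRONG),
                      Evidence(Criterion.PM2), Evidence(Criterion.PP3)])
    assert ev.tokens() == "PM1:strong,PM2,PP3"
    back = EvidenceSet.from_tokens(ev.tokens())
    assert {e.token() for e in back} == {e.token() for e in ev}
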