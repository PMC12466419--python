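"""Hard filters, genotype-pattern matching and allele-ratio validation."""

import numpy as np
import pytest

from famase.classifier import (
    ASECall,
    ASECategory,
    RefinedCategory,
    call_gene,
)
from famase.core import (
    ExpressionState as S,
    GeneModel,
    GenotypeClass as G,
    VariantRecord,
)
from famase.variants import (
    HardFilterSpec,
    Orientation,
    Zone,
    allele_ratio_check,
    apply_hard_filters,
    expected_maternal_fraction,
    expected_parent_pattern,
    genotype_to_state,
    match_variant,
    mendelian_consistent,
    resolve_orientation,
    scan_gene,
)
from conftest import make_variant


# ---------------------------------------------------------------------------
# hard filters
# ---------------------------------------------------------------------------

def test_snp_qd_below_threshold_fails():
    v = VariantRecord("chr1", 10, "A", "G", info={"QD": 1.5}, qual=50.0)
    assert apply_hard_filters(v).filter_status == "QD2"


def test_values_exactly_at_thresholds_pass():
    v = VariantRecord(
        "chr1", 10, "A", "G", qual=30.0,
        info={"QD": 2.0, "SOR": 3.0, "FS": 60.0, "MQ": 40.0,
              "MQRankSum": -12.5, "ReadPosRankSum": -8.0},
    )
    assert apply_hard_filters(v).filter_status == "PASS"


def test_indel_uses_indel_thresholds():
    v = VariantRecord("chr1", 10, "A", "AT", info={"FS": 250.0}, qual=50.0)
    assert apply_hard_filters(v).filter_status == "FS200"
    snp = VariantRecord("chr1", 10, "A", "G", info={"FS": 100.0}, qual=50.0)
    assert apply_hard_filters(snp).filter_status == "FS60"


def test_missing_annotation_skips_that_test():
    v = VariantRecord("chr1", 10, "A", "G", info={}, qual=None)
    assert apply_hard_filters(v).filter_status == "PASS"


def test_multiple_failures_joined():
    v = VariantRecord("chr1", 10, "A", "G", info={"QD": 1.0, "FS": 99.0},
                      qual=10.0)
    assert apply_hard_filters(v).filter_status == "QD2;QUAL30;FS60"


def test_empty_spec_is_identity():
    v = VariantRecord("chr1", 10, "A", "G", info={"QD": 0.1}, qual=1.0)
    assert apply_hard_filters(v, HardFilterSpec(snp=(), indel=())).filter_status == "PASS"


# ---------------------------------------------------------------------------
# parent patterns and genotype -> state
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "cat,mother,father,expected",
    [
        (ASECategory.H_L, G.HOM_REF, G.HOM_ALT, True),
        (ASECategory.H_L, G.HET, G.HET, False),
        (ASECategory.H_L, G.HOM_REF, G.HOM_REF, False),
        (ASECategory.M_M, G.HET, G.HET, True),
        (ASECategory.M_M, G.HET, G.HOM_REF, False),
        (ASECategory.HM_or_ML, G.HET, G.HOM_ALT, True),
        (ASECategory.HM_or_ML, G.HOM_REF, G.HET, True),
        (ASECategory.HM_or_ML, G.HET, G.HET, False),
    ],
)
def test_expected_parent_pattern(cat, mother, father, expected):
    assert expected_parent_pattern(cat)(mother, father) is expected


def test_genotype_to_state():
    assert genotype_to_state(G.HET, Orientation.REF_HIGH) is S.M
    assert genotype_to_state(G.HET, Orientation.ALT_HIGH) is S.M
    assert genotype_to_state(G.HOM_REF, Orientation.REF_HIGH) is S.H
    assert genotype_to_state(G.HOM_REF, Orientation.ALT_HIGH) is S.L
    assert genotype_to_state(G.MISSING, Orientation.REF_HIGH) is S.UNASSIGNED


def test_mendelian_consistency():
    from famase.core import FamilyDesign

    fam = FamilyDesign("m", "f", ("o1",))
    ok = make_variant(fam, G.HOM_REF, G.HOM_ALT, [G.HET])
    assert mendelian_consistent(ok, fam)
    bad = make_variant(fam, G.HOM_REF, G.HOM_ALT, [G.HOM_REF])
    assert not mendelian_consistent(bad, fam)


# ---------------------------------------------------------------------------
# match_variant: worked family examples
# ---------------------------------------------------------------------------

BDH2_STATES = [S.L, S.L, S.M, S.M, S.L, S.M, S.L, S.L]
BDH2_GTS = [G.HOM_REF, G.HOM_REF, G.HET, G.HET, G.HOM_REF, G.HET,
            G.HOM_REF, G.HOM_REF]


def _bdh2_call(family):
    # mother in the L band but above -1, so the two-group rule applies
    lfc = {family.mother_id: -0.9, family.father_id: 0.0}
    off = [-1.2, -1.1, 0.1, 0.0, -1.3, 0.2, -1.05, -1.15]
    lfc.update(dict(zip(family.offspring_ids, off)))
    return call_gene("BDH2", lfc, family)


def test_bdh2_variant_matches_with_full_consistency(family):
    call = _bdh2_call(family)
    assert call.category is ASECategory.LM_or_MH
    v = make_variant(family, G.HOM_REF, G.HET, BDH2_GTS)
    m = match_variant(v, call, family)
    assert m is not None and m.n_consistent == 8
    assert m.refined is RefinedCategory.L_M  # the HET parent is the M parent
    assert resolve_orientation(call, [m]) is RefinedCategory.L_M
    assert call.resolved is RefinedCategory.L_M


def test_single_offspring_flip_breaks_match(family):
    call = _bdh2_call(family)
    gts = list(BDH2_GTS)
    gts[1] = G.HET  # offspring 2 now inconsistent
    assert match_variant(make_variant(family, G.HOM_REF, G.HET, gts),
                         call, family) is None


def test_mother_het_variant_gives_mh_reading(family):
    call = _bdh2_call(family)
    # mother HET, father HOM: M_H reading; offspring matching the mother's
    # band (the L group) must be HET, the father-like group HOM
    gts = [G.HET, G.HET, G.HOM_REF, G.HOM_REF, G.HET, G.HOM_REF, G.HET, G.HET]
    m = match_variant(make_variant(family, G.HET, G.HOM_REF, gts), call, family)
    assert m is not None and m.refined is RefinedCategory.M_H


def test_conflicting_orientations_stay_ambiguous(family):
    call = _bdh2_call(family)
    m1 = match_variant(make_variant(family, G.HOM_REF, G.HET, BDH2_GTS),
                       call, family)
    gts = [G.HET, G.HET, G.HOM_REF, G.HOM_REF, G.HET, G.HOM_REF, G.HET, G.HET]
    m2 = match_variant(make_variant(family, G.HET, G.HOM_REF, gts), call, family)
    assert resolve_orientation(call, [m1, m2]) is None
    assert call.resolved is None


def test_hl_match_requires_all_offspring_het(family):
    lfc = {family.mother_id: 1.5, family.father_id: 0.0}
    lfc.update({o: 0.7 for o in family.offspring_ids})
    call = call_gene("g", lfc, family)
    assert call.category is ASECategory.H_L
    good = make_variant(family, G.HOM_ALT, G.HOM_REF, [G.HET] * 8)
    m = match_variant(good, call, family)
    assert m is not None and m.orientation is Orientation.ALT_HIGH
    bad = make_variant(family, G.HOM_ALT, G.HOM_REF,
                       [G.HET] * 7 + [G.HOM_REF])
    assert match_variant(bad, call, family) is None


def test_match_invariant_under_allele_relabeling(family):
    """Swapping ref<->alt genotypes flips the orientation but never the
    match decision."""
    swap = {G.HOM_REF: G.HOM_ALT, G.HOM_ALT: G.HOM_REF, G.HET: G.HET}
    call = _bdh2_call(family)
    v = make_variant(family, G.HOM_REF, G.HET, BDH2_GTS)
    m = match_variant(v, call, family)
    v2 = make_variant(
        family, swap[v.gt(family.mother_id)], swap[v.gt(family.father_id)],
        [swap[v.gt(o)] for o in family.offspring_ids],
    )
    m2 = match_variant(v2, call, family)
    assert (m is None) == (m2 is None)
    assert m2.orientation is m.orientation.flipped


def test_mm_match_recovers_planted_orientation(family, rng):
    from famase.simulate import mendelian_offspring

    lfc = {family.mother_id: 0.0, family.father_id: 0.0}
    for _ in range(20):
        gts = mendelian_offspring(G.HET, G.HET, 8, rng)
        # plant orientation ALT_HIGH: states from alt-allele dosage
        dosage = {G.HOM_REF: S.L, G.HET: S.M, G.HOM_ALT: S.H}
        states = {o: dosage[g] for o, g in zip(family.offspring_ids, gts)}
        if len(set(states.values())) < 2:
            continue
        call = ASECall("g", ASECategory.M_M, states=dict(states),
                       mother_log2fc=0.0)
        call.states[family.mother_id] = S.M
        call.states[family.father_id] = S.M
        m = match_variant(make_variant(family, G.HET, G.HET, gts), call, family)
        assert m is not None
        if S.H in states.values() or S.L in states.values():
            assert m.orientation is Orientation.ALT_HIGH


# ---------------------------------------------------------------------------
# scan_gene: zones and brute-force equivalence
# ---------------------------------------------------------------------------

def _states_oracle_match(v, call, family):
    """Independent oracle: enumerate both orientations and compare every
    family member's genotype-implied state with the call's letters."""
    letters = {
        ASECategory.H_L: ("H", "L"),
        ASECategory.L_H: ("L", "H"),
        ASECategory.HM_or_ML: [("H", "M"), ("M", "L")],
        ASECategory.LM_or_MH: [("L", "M"), ("M", "H")],
        ASECategory.M_M: ("M", "M"),
    }

    def st(g, alt_high):
        if g is G.HET:
            return "M"
        hom_alt = g is G.HOM_ALT
        return "H" if hom_alt == alt_high else "L"

    readings = letters[call.category]
    if isinstance(readings, tuple):
        readings = [readings]
    mstate = call.states[family.mother_id].value
    for alt_high in (False, True):
        for m_letter, f_letter in readings:
            if st(v.gt(family.mother_id), alt_high) != m_letter:
                continue
            if st(v.gt(family.father_id), alt_high) != f_letter:
                continue
            ok = True
            for o in family.offspring_ids:
                want = call.states[o].value
                if call.category in (ASECategory.HM_or_ML, ASECategory.LM_or_MH):
                    want = m_letter if call.states[o].value == mstate else f_letter
                if st(v.gt(o), alt_high) != want:
                    ok = False
                    break
            if ok and call.category in (ASECategory.HM_or_ML,
                                        ASECategory.LM_or_MH):
                if len({v.gt(o) for o in family.offspring_ids}) < 2:
                    ok = False
            if ok:
                return True
    return False


def test_scan_gene_zones_and_bruteforce_equivalence(family, gene, rng):
    from famase.simulate import mendelian_offspring

    lfc = {family.mother_id: 1.5, family.father_id: 0.0}
    lfc.update({o: 0.7 for o in family.offspring_ids})
    call = call_gene(gene.gene_id, lfc, family)

    positions = [95_000, 100_500, 105_000, 109_000, 113_000, 118_000, 125_000]
    parent_cfgs = [(G.HOM_ALT, G.HOM_REF), (G.HET, G.HET), (G.HET, G.HOM_REF),
                   (G.HOM_REF, G.HOM_ALT), (G.HOM_REF, G.HOM_REF)]
    variants = []
    for i, pos0 in enumerate(positions):
        mg, fg = parent_cfgs[i % len(parent_cfgs)]
        off = mendelian_offspring(mg, fg, 8, rng)
        variants.append(
            make_variant(family, mg, fg, off, pos=pos0 + 1,
                         info={"QD": 20.0}, qual=100.0)
        )
    matches = scan_gene(call, variants, gene, family)
    got = {m.variant.pos for m in matches}
    expected = set()
    for v in variants:
        if mendelian_consistent(v, family) and _states_oracle_match(v, call, family):
            expected.add(v.pos)
    assert got == expected
    zone_by_pos = {m.variant.pos: m.zone for m in matches}
    for pos, z in zone_by_pos.items():
        pos0 = pos - 1
        if gene.contains_exonic(pos0):
            assert z is Zone.EXON
        elif gene.contains(pos0):
            assert z is Zone.INTRON
        else:
            assert z is Zone.FLANK


def test_scan_gene_flank_and_exon_zones(family, gene):
    lfc = {family.mother_id: 1.5, family.father_id: 0.0}
    lfc.update({o: 0.7 for o in family.offspring_ids})
    call = call_gene(gene.gene_id, lfc, family)
    flank_v = make_variant(family, G.HOM_ALT, G.HOM_REF, [G.HET] * 8,
                           pos=gene.start - 5000 + 1, qual=100.0)
    exon_v = make_variant(family, G.HOM_ALT, G.HOM_REF, [G.HET] * 8,
                          pos=108_500 + 1, qual=100.0)
    far_v = make_variant(family, G.HOM_ALT, G.HOM_REF, [G.HET] * 8,
                         pos=gene.end + 50_000, qual=100.0)
    matches = scan_gene(call, [flank_v, exon_v, far_v], gene, family)
    assert {m.variant.pos: m.zone for m in matches} == {
        flank_v.pos: Zone.FLANK, exon_v.pos: Zone.EXON
    }


def test_scan_gene_skips_non_pass_by_default(family, gene):
    lfc = {family.mother_id: 1.5, family.father_id: 0.0}
    lfc.update({o: 0.7 for o in family.offspring_ids})
    call = call_gene(gene.gene_id, lfc, family)
    v = make_variant(family, G.HOM_ALT, G.HOM_REF, [G.HET] * 8,
                     pos=105_001, info={"QD": 1.0}, qual=100.0)
    apply_hard_filters(v)
    assert scan_gene(call, [v], gene, family) == []
    assert len(scan_gene(call, [v], gene, family, pass_only=False)) == 1


def test_zero_matches_means_unconfirmed(family, gene):
    lfc = {family.mother_id: 1.5, family.father_id: 0.0}
    lfc.update({o: 0.7 for o in family.offspring_ids})
    call = call_gene(gene.gene_id, lfc, family)
    assert scan_gene(call, [], gene, family) == []


# ---------------------------------------------------------------------------
# allele ratios
# ---------------------------------------------------------------------------

def test_expected_maternal_fraction_closed_forms():
    assert expected_maternal_fraction(1.0) == pytest.approx(2 / 3)
    assert expected_maternal_fraction(0.0) == pytest.approx(0.5)
    assert expected_maternal_fraction(2.0) == pytest.approx(0.8)


def test_allele_ratio_check_binomial_simulation(family, rng):
    """Offspring of an H_L gene with a 4:1 expression ratio show a
    maternal-allele frequency near 0.8 at depth 200."""
    mother_lfc = 2.0  # R = 4
    f_true = 0.8
    depths = {}
    for o in family.offspring_ids:
        total = rng.poisson(200)
        mat = rng.binomial(total, f_true)
        depths[o] = (total - mat, mat)  # maternal allele is ALT
    v = make_variant(family, G.HOM_ALT, G.HOM_REF, [G.HET] * 8,
                     allele_depths=depths)
    call = ASECall("g", ASECategory.H_L, mother_log2fc=mother_lfc)
    res = allele_ratio_check(v, call, family, tol=0.15)
    observed = [r.f_obs for r in res if r.f_obs is not None]
    assert len(observed) == 8
    assert abs(np.mean(observed) - f_true) < 0.05
    assert all(r.consistent for r in res)


def test_allele_ratio_skips_non_het_and_low_depth(family):
    depths = {o: (2, 3) for o in family.offspring_ids}  # below min_depth
    gts = [G.HET] * 7 + [G.HOM_ALT]
    v = make_variant(family, G.HOM_ALT, G.HOM_REF, gts, allele_depths=depths)
    call = ASECall("g", ASECategory.H_L, mother_log2fc=1.0)
    res = allele_ratio_check(v, call, family, min_depth=10)
    assert all(r.f_obs is None for r in res)
    reasons = {r.individual: r.reason for r in res}
    assert "not HET" in reasons["offspring_8"]
    assert "depth" in reasons["offspring_1"]
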