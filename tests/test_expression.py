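"""Normalization, fold changes, significance gate and coverage filter."""

import numpy as np
import pytest

from famase.core import GeneModel
from famase.expression import (
    CountMatrix,
    exon_coverage_filter,
    log2fc_table,
    low_count_filter,
    significance_gate,
    size_factors,
)
from famase.simulate import ScenarioSpec, simulate_counts


def _matrix(counts, genes=None, samples=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(genes=genes, samples=samples, counts=counts)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_size_factors_identical_columns_are_one():
    m = _matrix(np.tile([[10], [40], [400]], (1, 4)))
    assert np.allclose(list(size_factors(m).values()), 1.0)


def test_size_factors_scale_equivariance():
    base = np.array([[10, 10], [40, 40], [400, 400]])
    doubled = base.copy()
    doubled[:, 1] *= 2
    f = size_factors(_matrix(doubled))
    assert f["s1"] / f["s0"] == pytest.approx(2.0)


def _brute_force_size_factors(counts):
    """Naive median-of-ratios: per-gene geometric means via explicit
    products, medians over genes expressed everywhere."""
    n_genes, n_samples = counts.shape
    geomeans = []
    for g in range(n_genes):
        prod = 1.0
        for s in range(n_samples):
            prod *= counts[g, s]
        geomeans.append(prod ** (1.0 / n_samples))
    out = []
    for s in range(n_samples):
        ratios = [
            counts[g, s] / geomeans[g]
            for g in range(n_genes)
            if geomeans[g] > 0
        ]
        out.append(float(np.median(ratios)))
    return out


def test_size_factors_match_brute_force(rng):
    counts = rng.poisson(50, size=(50, 6)) + 1
    f = size_factors(_matrix(counts))
    expected = _brute_force_size_factors(counts.astype(float))
    assert np.allclose(list(f.values()), expected, atol=1e-12)


def test_size_factors_invariant_under_reordering(rng):
    counts = rng.poisson(30, size=(20, 5)) + 1
    m = _matrix(counts)
    f = size_factors(m)
    perm = rng.permutation(20)
    m2 = CountMatrix(
        genes=[m.genes[i] for i in perm], samples=m.samples, counts=counts[perm]
    )
    assert size_factors(m2) == pytest.approx(f)
    cperm = [3, 1, 4, 0, 2]
    m3 = CountMatrix(
        genes=m.genes, samples=[m.samples[j] for j in cperm],
        counts=counts[:, cperm],
    )
    f3 = size_factors(m3)
    assert all(f3[s] == pytest.approx(f[s]) for s in m.samples)


def test_size_factors_need_universally_expressed_gene():
    with pytest.raises(ValueError, match="pre-filter"):
        size_factors(_matrix([[0, 5], [5, 0]]))


# ---------------------------------------------------------------------------
# log2fc table
# ---------------------------------------------------------------------------

def _two_person_family():
    from famase.core import FamilyDesign

    return FamilyDesign(
        "mother", "father", ("offspring_1",),
        sample_map={
            "m1": "mother", "m2": "mother",
            "f1": "father", "f2": "father",
            "o1": "offspring_1", "o2": "offspring_1",
        },
    )


def test_log2fc_father_is_zero_and_closed_form():
    fam = _two_person_family()
    # one differential gene over a stable background so size factors stay 1
    counts = np.vstack(
        [[200, 200, 100, 100, 100, 100]] + [[50] * 6] * 10
    )
    m = _matrix(counts, samples=["m1", "m2", "f1", "f2", "o1", "o2"])
    t = log2fc_table(m, fam, pseudocount=1e-9, backend="none")
    assert (t.log2fc["father"] == 0.0).all()
    assert t.log2fc.loc["g0", "mother"] == pytest.approx(1.0, abs=1e-6)
    assert t.log2fc.loc["g0", "offspring_1"] == pytest.approx(0.0, abs=1e-6)


def test_log2fc_antisymmetry_on_swap(rng):
    fam = _two_person_family()
    counts = rng.poisson(100, size=(10, 6)) + 1
    samples = ["m1", "m2", "f1", "f2", "o1", "o2"]
    m = _matrix(counts, samples=samples)
    t = log2fc_table(m, fam, backend="none")
    swapped = counts[:, [2, 3, 0, 1, 4, 5]]  # mother <-> father columns
    t2 = log2fc_table(_matrix(swapped, samples=samples), fam, backend="none")
    assert np.allclose(
        t2.log2fc["mother"], -t.log2fc["mother"], atol=1e-12
    )


def test_log2fc_recovers_true_ratio_under_nb_noise():
    """NB counts at dispersion 0.05, 4 replicates: the mother-vs-father
    estimate averages to the true log2FC within +/-0.2."""
    # transcriptome-like panel: differential genes are a minority and the
    # categories are mirrored, as median-of-ratios normalization assumes
    specs = [
        ScenarioSpec(category="H_L", n_genes=100),
        ScenarioSpec(category="L_H", n_genes=100),
        ScenarioSpec(category="NONE", n_genes=600),
    ]
    m, truths, fam = simulate_counts(specs, seed=5)
    t = log2fc_table(m, fam, backend="none")
    hl = [tr.gene_id for tr in truths if tr.scenario == "H_L"]
    lh = [tr.gene_id for tr in truths if tr.scenario == "L_H"]
    assert abs(t.log2fc.loc[hl, "mother"].mean() - 1.5) < 0.2
    assert abs(t.log2fc.loc[lh, "mother"].mean() + 1.5) < 0.2


def test_excluded_replicates_are_ignored(family):
    from famase.core import FamilyDesign

    fam = FamilyDesign(
        family.mother_id, family.father_id, family.offspring_ids,
        sample_map=family.sample_map, excluded_samples=("mother_r1",),
    )
    samples = list(family.sample_map)
    counts = np.full((1, len(samples)), 100)
    counts[0, samples.index("mother_r1")] = 100_000  # outlier replicate
    t = log2fc_table(_matrix(counts, samples=samples), fam, backend="none")
    assert t.log2fc.loc["g0", "mother"] == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# significance gate
# ---------------------------------------------------------------------------

def _table_from(lfc_rows, padj_rows, genes):
    import pandas as pd

    cols = ["mother", "offspring_1"]
    return type(
        "T", (),
        {
            "log2fc": pd.DataFrame(lfc_rows, index=genes, columns=cols),
            "padj": pd.DataFrame(padj_rows, index=genes, columns=cols),
        },
    )()


def test_significance_gate_rules():
    t = _table_from(
        [[0.9, 0.3], [1.5, 0.2], [2.0, 2.0]],
        [[0.001, 0.001], [0.01, 0.5], [0.2, 0.2]],
        ["below_lfc", "hit", "not_significant"],
    )
    assert significance_gate(t) == {"hit"}


def test_significance_gate_monotone_in_thresholds(rng):
    lfc = rng.normal(0, 1.2, size=(50, 2))
    padj = rng.uniform(0, 0.2, size=(50, 2))
    t = _table_from(lfc, padj, [f"g{i}" for i in range(50)])
    assert significance_gate(t, 1.0, 0.05) <= significance_gate(t, 0.5, 0.1)


# ---------------------------------------------------------------------------
# internal test backend
# ---------------------------------------------------------------------------

def test_internal_backend_flags_large_effects():
    specs = [
        ScenarioSpec(category="H_L", n_genes=30),
        ScenarioSpec(category="L_H", n_genes=30),
        ScenarioSpec(category="NONE", n_genes=240),
    ]
    m, truths, fam = simulate_counts(specs, seed=9)
    t = log2fc_table(m, fam, backend="internal")
    gated = significance_gate(t)
    hl = {tr.gene_id for tr in truths if tr.scenario == "H_L"}
    none = {tr.gene_id for tr in truths if tr.scenario == "NONE"}
    assert len(gated & hl) >= 0.9 * len(hl)
    assert len(gated & none) <= 0.1 * len(none)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def test_low_count_filter():
    m = _matrix([[100, 100, 100, 100], [5, 5, 5, 100], [5, 5, 100, 100]])
    kept = low_count_filter(m, min_total=10, min_samples=3)
    assert kept.genes == ["g0", "g2"]


def _gene_with_exons(*exons):
    start = min(s for s, _ in exons)
    end = max(e for _, e in exons)
    return GeneModel("g", "chr1", start, end, exons=tuple(exons))


def test_exon_coverage_uniform_depth_above_threshold_passes():
    g = _gene_with_exons((10, 20))
    assert exon_coverage_filter(g, {p: 6 for p in range(10, 20)})


def test_exon_coverage_single_low_base_fails_strictly():
    g = _gene_with_exons((10, 20))
    depth = {p: 100 for p in range(10, 20)}
    depth[15] = 5  # strictly-greater rule: 5 is not > 5
    assert not exon_coverage_filter(g, depth)


def test_exon_coverage_existential_over_exons():
    g = _gene_with_exons((0, 5), (10, 15))
    depth = {p: 10 for p in range(10, 15)}  # first exon all zero (absent)
    assert exon_coverage_filter(g, depth)


def test_exon_coverage_no_exons_fails():
    g = GeneModel("g", "chr1", 0, 100)
    assert not exon_coverage_filter(g, {})


def test_exon_coverage_monotone_in_min_depth():
    g = _gene_with_exons((0, 10))
    depth = {p: 8 for p in range(10)}
    assert exon_coverage_filter(g, depth, min_depth=5)
    assert not exon_coverage_filter(g, depth, min_depth=8)
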