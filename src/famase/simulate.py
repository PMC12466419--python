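"""Synthetic family datasets with planted cis-regulatory variants.

The generator emulates the study design: a two-parent, eight-offspring
family, four RNA-seq replicates per individual, a causal biallelic
regulatory variant per gene, Mendelian transmission, genotype-dependent
negative-binomial read counts, allelic read depths at heterozygous
exonic markers, and a conserved TFBS interval over each causal variant.

Genetic model.  The causal variant has a high allele (per-copy
expression level h) and a low allele (level l); an individual's mean
expression is the sum of its two allele levels (2h, h+l or 2l).  Counts
are negative binomial with constant per-gene dispersion, matching the
distributional assumption of standard RNA-seq differential-expression
models, and each replicate carries a log-normal library-size factor to
exercise normalization.

Scenario levels.  Defaults plant a true log2 fold change of +/-1.5 on
the contrast that defines each scenario: h/l = 2**1.5 for H_L and L_H
(mother vs father are the two homozygotes) and h/l = 2**2.5 - 1 for the
het-vs-hom scenarios and M_M (the homozygous-low genotype sits 1.5 below
the heterozygous father baseline).  Because expression is additive in
the alleles, a homozygous-high genotype can never exceed the
heterozygous baseline by a full 2-fold, so the H_M and M_H
configurations are structurally compressed below the +1 anchor on a
father-baseline scale; their observable counterparts in the simulator
are M_L and L_M, where the baseline parent is the extreme one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from famase.core import (
    FamilyDesign,
    GeneModel,
    GenotypeClass,
    VariantRecord,
    write_vcf,
)
from famase.expression import CountMatrix

logger = logging.getLogger(__name__)

#: scenario -> (mother high-allele copies, father high-allele copies)
SCENARIO_PARENTS = {
    "H_L": (2, 0),
    "L_H": (0, 2),
    "H_M": (2, 1),
    "M_L": (1, 0),
    "L_M": (0, 1),
    "M_H": (1, 2),
    "M_M": (1, 1),
    "NONE": (1, 1),
}

#: scenario -> the expression-observable category it plants
OBSERVABLE_CATEGORY = {
    "H_L": "H_L",
    "L_H": "L_H",
    "H_M": "H_M_or_M_L",
    "M_L": "H_M_or_M_L",
    "L_M": "L_M_or_M_H",
    "M_H": "L_M_or_M_H",
    "M_M": "M_M",
    "NONE": "NONE",
}

PARENT_RATIO = 2.0 ** 1.5  # h/l for the two-homozygote scenarios
HET_RATIO = 2.0 ** 2.5 - 1.0  # h/l putting the low homozygote 1.5 below a het


def default_levels(scenario: str, base: float = 300.0) -> tuple[float, float]:
    """Default per-allele expression levels (h, l) for a scenario."""
    if scenario == "NONE":
        return base * 2, base * 2
    r = PARENT_RATIO if scenario in ("H_L", "L_H") else HET_RATIO
    return base * r, base


@dataclass(frozen=True)
class ScenarioSpec:
    """One planted gene scenario.

    h and l are the per-allele expression levels of the high and low
    regulatory alleles, in expected-count units at size factor 1.
    ``n_genes`` repeats the scenario across that many genes.
    """

    category: str
    h: Optional[float] = None
    l: Optional[float] = None
    dispersion: float = 0.05
    n_replicates: int = 4
    depth_exonic: int = 200
    genotype_error_rate: float = 0.0
    recombination_rate: float = 0.0
    n_genes: int = 1

    def __post_init__(self) -> None:
        if self.category not in SCENARIO_PARENTS:
            raise ValueError(f"unknown scenario {self.category!r}")
        h, l = self.levels
        if self.category == "NONE":
            if h != l:
                raise ValueError("NONE scenario requires h == l")
        elif not (h > l > 0):
            raise ValueError("ASE scenarios require h > l > 0")
        if not 0 <= self.genotype_error_rate < 1:
            raise ValueError("genotype_error_rate must be in [0, 1)")

    @property
    def levels(self) -> tuple[float, float]:
        if self.h is not None and self.l is not None:
            return float(self.h), float(self.l)
        return default_levels(self.category)


@dataclass
class TruthRecord:
    """Planted truth for one simulated gene."""

    gene_id: str
    scenario: str
    true_category: str  # observable category realized by the drawn genotypes
    causal_pos: int  # 1-based
    orientation: str  # REF_HIGH / ALT_HIGH
    offspring_n_high: tuple[int, ...]  # high-allele copies per offspring
    offspring_states: tuple[str, ...]  # noiseless H/M/L letters
    maternal_high: tuple[bool, ...]  # per offspring: maternal allele is high
    paternal_high: tuple[bool, ...]

    def as_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "scenario": self.scenario,
            "true_category": self.true_category,
            "causal_pos": self.causal_pos,
            "orientation": self.orientation,
            "offspring_n_high": ",".join(map(str, self.offspring_n_high)),
            "offspring_states": ",".join(self.offspring_states),
            "maternal_high": ",".join("1" if x else "0" for x in self.maternal_high),
            "paternal_high": ",".join("1" if x else "0" for x in self.paternal_high),
        }


def default_family(n_offspring: int = 8, n_replicates: int = 4) -> FamilyDesign:
    """The study family: mother, father, eight offspring, four replicates
    per individual."""
    offspring = tuple(f"offspring_{i}" for i in range(1, n_offspring + 1))
    individuals = ("mother", "father") + offspring
    sample_map = {
        f"{ind}_r{k}": ind
        for ind in individuals
        for k in range(1, n_replicates + 1)
    }
    return FamilyDesign(
        mother_id="mother",
        father_id="father",
        offspring_ids=offspring,
        sample_map=sample_map,
    )


# ---------------------------------------------------------------------------
# Elementary draws
# ---------------------------------------------------------------------------

def _transmit(n_high: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """High-allele (1) vs low-allele (0) transmissions from one parent
    with ``n_high`` high copies."""
    if n_high == 2:
        return np.ones(n, dtype=int)
    if n_high == 0:
        return np.zeros(n, dtype=int)
    return rng.integers(0, 2, size=n)


def mendelian_offspring(
    mother_gt: GenotypeClass,
    father_gt: GenotypeClass,
    n: int,
    rng: np.random.Generator,
) -> list[GenotypeClass]:
    """Draw offspring genotype classes: one uniformly chosen allele from
    each parent, independently."""
    copies = {
        GenotypeClass.HOM_REF: 0,
        GenotypeClass.HET: 1,
        GenotypeClass.HOM_ALT: 2,
    }
    m = _transmit(copies[mother_gt], n, rng)
    f = _transmit(copies[father_gt], n, rng)
    n_alt = m + f  # here 1 = alt allele
    classes = [GenotypeClass.HOM_REF, GenotypeClass.HET, GenotypeClass.HOM_ALT]
    return [classes[k] for k in n_alt]


def nb_counts(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draws with mean mu and Var = mu + dispersion*mu^2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    p = shape / (shape + mu)
    return rng.negative_binomial(shape, p)


def expression_counts(
    n_high: int,
    spec: ScenarioSpec,
    rng: np.random.Generator,
    size_factors: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Replicate counts for one individual carrying ``n_high`` high alleles."""
    h, l = spec.levels
    mu = n_high * h + (2 - n_high) * l
    if size_factors is None:
        size_factors = np.ones(spec.n_replicates)
    return nb_counts(mu * size_factors, spec.dispersion, rng)


def allelic_depths(
    maternal_high: bool,
    paternal_high: bool,
    spec: ScenarioSpec,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """(maternal, paternal) read counts at a heterozygous exonic marker.

    Total depth is Poisson; the maternal share follows the expression
    level of the maternally inherited regulatory allele.
    """
    h, l = spec.levels
    hm = h if maternal_high else l
    hp = h if paternal_high else l
    f = hm / (hm + hp)
    total = int(rng.poisson(spec.depth_exonic))
    maternal = int(rng.binomial(total, f)) if total > 0 else 0
    return maternal, total - maternal


# ---------------------------------------------------------------------------
# Gene-level simulation
# ---------------------------------------------------------------------------

def _noiseless_state(lfc: float) -> str:
    """H/M/L letter of a noiseless log2FC under the default bands, with
    gap-zone values snapped to the nearest band."""
    if lfc >= 0.6:
        return "H"
    if lfc <= -0.6:
        return "L"
    return "M"


def _true_category(
    scenario: str, m_copies: int, f_copies: int, offspring_n_high: np.ndarray
) -> str:
    """Observable category actually realized by the drawn genotypes.

    The scenario's category is only planted when the offspring draw
    realizes it: the het-vs-hom categories need both offspring genotype
    groups non-empty, and M_M needs a homozygous-low offspring (the only
    genotype a full unit below the heterozygous baseline) plus
    segregation.  H_M and M_H are structurally compressed under the
    additive model (see module docstring) and never classifiable.
    """
    if scenario == "NONE":
        return "NONE"
    if scenario in ("H_L", "L_H"):
        return scenario
    if scenario in ("H_M", "M_H"):
        return "NONE"
    groups = set(offspring_n_high.tolist())
    if scenario in ("M_L", "L_M"):
        return OBSERVABLE_CATEGORY[scenario] if len(groups) >= 2 else "NONE"
    # M_M
    if 0 in groups and len(groups) >= 2:
        return "M_M"
    return "NONE"


@dataclass
class SimulatedGene:
    gene: GeneModel
    truth: TruthRecord
    counts: np.ndarray  # (n_individuals, n_replicates)
    wgs_variants: list[VariantRecord] = field(default_factory=list)
    rna_variants: list[VariantRecord] = field(default_factory=list)
    tfbs_line: Optional[tuple] = None
    site_sequence: Optional[tuple[str, str]] = None  # (key, plus-strand seq)


#: per-gene layout, relative to gene start (gene length 20 kb)
GENE_LENGTH = 20_000
GENE_SPACING = 60_000
FIRST_GENE_START = 50_000
EXONS_REL = ((0, 3_000), (8_000, 11_000), (17_000, 20_000))
CAUSAL_REL = 5_000  # intron 1
MARKER_REL = 1_500  # exon 1
DECOY_REL = (12_000, 13_500)  # intron 2
FLANK_DECOY_REL = -5_000
PHASING_REL = (500, 2_500, 6_000, 9_500, 14_000, 18_500)

#: 12-mer around the causal variant: ref scores 10/12 against the nuclear
#: hormone receptor dimer consensus, alt (G->A at offset 5) scores 11/12.
SITE_REF_SEQ = "AGGTCGCGGTCA"
SITE_CONSENSUS = "RGGTCARGGTCA"
CAUSAL_SITE_OFFSET = 5  # position of the variant inside the site


def _pass_info(rng: np.random.Generator) -> dict[str, float]:
    return {
        "QD": float(rng.uniform(15, 30)),
        "FS": float(rng.uniform(0, 5)),
        "MQ": 60.0,
        "SOR": float(rng.uniform(0.5, 1.5)),
        "MQRankSum": 0.0,
        "ReadPosRankSum": 0.0,
    }


def _gt_from_alt_copies(k: int) -> GenotypeClass:
    return (GenotypeClass.HOM_REF, GenotypeClass.HET, GenotypeClass.HOM_ALT)[k]


def simulate_gene(
    gene_index: int,
    spec: ScenarioSpec,
    family: FamilyDesign,
    rng: np.random.Generator,
    sample_factors: Optional[np.ndarray] = None,
    with_variants: bool = True,
    chrom: str = "chr1",
) -> SimulatedGene:
    """Simulate one gene: genotypes, counts and (optionally) the variant,
    marker, decoy, phasing-site and TFBS tracks."""
    start = FIRST_GENE_START + gene_index * GENE_SPACING
    gene = GeneModel(
        gene_id=f"gene_{gene_index + 1:04d}",
        chrom=chrom,
        start=start,
        end=start + GENE_LENGTH,
        strand="+",
        exons=tuple((start + s, start + e) for s, e in EXONS_REL),
    )
    n_off = len(family.offspring_ids)
    m_copies, f_copies = SCENARIO_PARENTS[spec.category]
    m_trans = _transmit(m_copies, n_off, rng)  # 1 = high allele
    f_trans = _transmit(f_copies, n_off, rng)
    n_high = m_trans + f_trans

    h, l = spec.levels
    baseline = f_copies * h + (2 - f_copies) * l
    lfcs = np.log2((n_high * h + (2 - n_high) * l) / baseline)
    states = tuple(_noiseless_state(x) for x in lfcs)
    alt_is_high = bool(rng.integers(0, 2))
    orientation = "ALT_HIGH" if alt_is_high else "REF_HIGH"

    truth = TruthRecord(
        gene_id=gene.gene_id,
        scenario=spec.category,
        true_category=_true_category(spec.category, m_copies, f_copies, n_high),
        causal_pos=start + CAUSAL_REL + 1,
        orientation=orientation,
        offspring_n_high=tuple(int(x) for x in n_high),
        offspring_states=states,
        maternal_high=tuple(bool(x) for x in m_trans),
        paternal_high=tuple(bool(x) for x in f_trans),
    )

    # counts: individuals x replicates
    n_rep = spec.n_replicates
    if sample_factors is None:
        sample_factors = np.ones(len(family.individuals) * n_rep)
    counts = np.empty((len(family.individuals), n_rep), dtype=int)
    copies_by_ind = {family.mother_id: m_copies, family.father_id: f_copies}
    copies_by_ind.update(
        {o: int(k) for o, k in zip(family.offspring_ids, n_high)}
    )
    for i, ind in enumerate(family.individuals):
        sf = sample_factors[i * n_rep : (i + 1) * n_rep]
        counts[i] = expression_counts(copies_by_ind[ind], spec, rng, sf)

    sim = SimulatedGene(gene=gene, truth=truth, counts=counts)
    if not with_variants:
        return sim

    def high_to_alt(copies_high: int) -> int:
        return copies_high if alt_is_high else 2 - copies_high

    def genotypes(m_k: int, f_k: int, off_k: Sequence[int]) -> dict:
        gts = {
            family.mother_id: _gt_from_alt_copies(m_k),
            family.father_id: _gt_from_alt_copies(f_k),
        }
        gts.update(
            {
                o: _gt_from_alt_copies(int(k))
                for o, k in zip(family.offspring_ids, off_k)
            }
        )
        return gts

    def maybe_err(gts: dict) -> dict:
        if spec.genotype_error_rate <= 0:
            return gts
        out = dict(gts)
        for o in family.offspring_ids:
            if rng.random() < spec.genotype_error_rate:
                others = [
                    g
                    for g in (
                        GenotypeClass.HOM_REF,
                        GenotypeClass.HET,
                        GenotypeClass.HOM_ALT,
                    )
                    if g is not out[o]
                ]
                out[o] = others[rng.integers(0, len(others))]
        return out

    # causal variant (intron 1), inside the TFBS
    causal_pos0 = start + CAUSAL_REL
    sim.wgs_variants.append(
        VariantRecord(
            chrom=chrom,
            pos=causal_pos0 + 1,
            ref=SITE_REF_SEQ[CAUSAL_SITE_OFFSET],
            alt="A" if SITE_REF_SEQ[CAUSAL_SITE_OFFSET] != "A" else "T",
            info=_pass_info(rng),
            genotypes=genotypes(
                high_to_alt(m_copies),
                high_to_alt(f_copies),
                [high_to_alt(int(k)) for k in n_high],
            ),
            qual=1000.0,
        )
    )
    site_start = causal_pos0 - CAUSAL_SITE_OFFSET
    sim.tfbs_line = (
        chrom, site_start, site_start + len(SITE_REF_SEQ), "ESRRA", 0, "+",
        SITE_CONSENSUS,
    )
    sim.site_sequence = (
        f"{chrom}:{site_start}-{site_start + len(SITE_REF_SEQ)}",
        SITE_REF_SEQ,
    )

    # exonic marker, parents homozygous-different: all offspring HET with
    # allele-specific depths; maternal allele is the ALT (mother HOM_ALT)
    marker_pos0 = start + MARKER_REL
    marker_gts = genotypes(2, 0, [1] * n_off)
    depths = {}
    for i, o in enumerate(family.offspring_ids):
        mat, pat = allelic_depths(bool(m_trans[i]), bool(f_trans[i]), spec, rng)
        depths[o] = (pat, mat)  # (ref, alt); maternal allele is alt
    for parent, is_mother in ((family.mother_id, True), (family.father_id, False)):
        total = int(rng.poisson(spec.depth_exonic))
        depths[parent] = (0, total) if is_mother else (total, 0)
    sim.rna_variants.append(
        VariantRecord(
            chrom=chrom,
            pos=marker_pos0 + 1,
            ref="A",
            alt="G",
            info=_pass_info(rng),
            genotypes=marker_gts,
            allele_depths=depths,
            qual=1000.0,
        )
    )

    # decoys: parent configurations foreign to this scenario's pattern
    if spec.category in ("H_L", "L_H"):
        decoy_parent_cfgs = [(1, 0), (1, 1)]
    elif spec.category == "M_M":
        decoy_parent_cfgs = [(2, 0), (1, 0)]
    else:
        decoy_parent_cfgs = [(2, 0), (1, 1)]
    for rel, (dm, df) in zip(DECOY_REL, decoy_parent_cfgs):
        off = np.asarray(_transmit(dm, n_off, rng)) + np.asarray(
            _transmit(df, n_off, rng)
        )
        sim.wgs_variants.append(
            VariantRecord(
                chrom=chrom,
                pos=start + rel + 1,
                ref="C",
                alt="T",
                info=_pass_info(rng),
                genotypes=genotypes(dm, df, off),
                qual=500.0,
            )
        )
    # flank decoy: same pattern as causal but failing the QD hard filter
    bad_info = _pass_info(rng)
    bad_info["QD"] = 1.0
    sim.wgs_variants.append(
        VariantRecord(
            chrom=chrom,
            pos=start + FLANK_DECOY_REL + 1,
            ref="G",
            alt="C",
            info=bad_info,
            genotypes=genotypes(
                high_to_alt(m_copies),
                high_to_alt(f_copies),
                [high_to_alt(int(k)) for k in n_high],
            ),
            qual=500.0,
        )
    )

    # informative phasing sites linked to the causal variant (complete LD:
    # the het parent's alt allele rides the high haplotype)
    for parent, copies, trans, shift in (
        (family.mother_id, m_copies, m_trans, 0),
        (family.father_id, f_copies, f_trans, 250),
    ):
        if copies != 1:
            continue
        other = (
            family.father_id if parent == family.mother_id else family.mother_id
        )
        for rel in (r + shift for r in PHASING_REL):
            gts = {parent: GenotypeClass.HET, other: GenotypeClass.HOM_REF}
            gts.update(
                {
                    o: (GenotypeClass.HET if t else GenotypeClass.HOM_REF)
                    for o, t in zip(family.offspring_ids, trans)
                }
            )
            gts = maybe_err(gts)
            sim.wgs_variants.append(
                VariantRecord(
                    chrom=chrom,
                    pos=start + rel + 1,
                    ref="T",
                    alt="G",
                    info=_pass_info(rng),
                    genotypes=gts,
                    qual=800.0,
                )
            )
    sim.wgs_variants.sort(key=lambda v: v.pos)
    return sim


# ---------------------------------------------------------------------------
# Whole-dataset emission
# ---------------------------------------------------------------------------

def simulate_counts(
    specs: Sequence[ScenarioSpec],
    seed: int,
    family: Optional[FamilyDesign] = None,
) -> tuple[CountMatrix, list[TruthRecord], FamilyDesign]:
    """Fast path: counts matrix plus truth, without variant tracks."""
    rng = np.random.default_rng(seed)
    if family is None:
        n_rep = specs[0].n_replicates if specs else 4
        family = default_family(n_replicates=n_rep)
    n_rep = specs[0].n_replicates if specs else 4
    samples = [
        f"{ind}_r{k}"
        for ind in family.individuals
        for k in range(1, n_rep + 1)
    ]
    sample_factors = np.exp(rng.normal(0.0, 0.1, size=len(samples)))
    rows, gene_ids, truths = [], [], []
    index = 0
    for spec in specs:
        for _ in range(spec.n_genes):
            sim = simulate_gene(
                index, spec, family, rng, sample_factors, with_variants=False
            )
            rows.append(sim.counts.reshape(-1))
            gene_ids.append(sim.gene.gene_id)
            truths.append(sim.truth)
            index += 1
    counts = CountMatrix(
        genes=gene_ids,
        samples=samples,
        counts=np.vstack(rows) if rows else np.zeros((0, len(samples)), int),
    )
    return counts, truths, family


def emit_dataset(
    specs: Sequence[ScenarioSpec],
    out_dir: str,
    seed: int,
    family: Optional[FamilyDesign] = None,
    exon_depth: int = 30,
) -> dict[str, str]:
    """Write a complete synthetic dataset parseable by every module.

    Emits family.yaml, genes.gtf, counts.tsv, wgs.vcf, rna.vcf, tfbs.bed,
    sites.fa, depth.tsv and truth.tsv into ``out_dir``; returns the path
    of each file.  Byte-identical across runs for a fixed seed.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if family is None:
        n_rep = specs[0].n_replicates if specs else 4
        family = default_family(n_replicates=n_rep)
    n_rep = specs[0].n_replicates if specs else 4
    samples = [
        f"{ind}_r{k}"
        for ind in family.individuals
        for k in range(1, n_rep + 1)
    ]
    sample_factors = np.exp(rng.normal(0.0, 0.1, size=len(samples)))

    sims: list[SimulatedGene] = []
    index = 0
    for spec in specs:
        for _ in range(spec.n_genes):
            sims.append(
                simulate_gene(index, spec, family, rng, sample_factors)
            )
            index += 1

    n_genes = len(sims)
    chrom = "chr1"
    chrom_len = FIRST_GENE_START + max(n_genes, 1) * GENE_SPACING + 50_000
    paths = {}

    # family.yaml
    paths["family"] = str(out / "family.yaml")
    with open(paths["family"], "w") as fh:
        yaml.safe_dump(
            {
                "mother_id": family.mother_id,
                "father_id": family.father_id,
                "offspring_ids": list(family.offspring_ids),
                "sample_map": {s: family.sample_map[s] for s in samples},
                "excluded_samples": list(family.excluded_samples),
            },
            fh,
            sort_keys=False,
        )

    # genes.gtf (1-based inclusive on disk)
    paths["gtf"] = str(out / "genes.gtf")
    with open(paths["gtf"], "w") as fh:
        for sim in sims:
            g = sim.gene
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )

    # counts.tsv
    paths["counts"] = str(out / "counts.tsv")
    counts = CountMatrix(
        genes=[s.gene.gene_id for s in sims],
        samples=samples,
        counts=(
            np.vstack([s.counts.reshape(-1) for s in sims])
            if sims
            else np.zeros((0, len(samples)), int)
        ),
    )
    counts.to_tsv(paths["counts"])

    # VCFs
    contigs = {chrom: chrom_len}
    paths["wgs_vcf"] = str(out / "wgs.vcf")
    write_vcf(
        paths["wgs_vcf"],
        [v for s in sims for v in s.wgs_variants],
        family,
        contigs=contigs,
    )
    paths["rna_vcf"] = str(out / "rna.vcf")
    write_vcf(
        paths["rna_vcf"],
        [v for s in sims for v in s.rna_variants],
        family,
        contigs=contigs,
    )

    # TFBS bed + site sequences
    paths["tfbs"] = str(out / "tfbs.bed")
    with open(paths["tfbs"], "w") as fh:
        for sim in sims:
            if sim.tfbs_line:
                fh.write("\t".join(map(str, sim.tfbs_line)) + "\n")
    paths["sites_fa"] = str(out / "sites.fa")
    with open(paths["sites_fa"], "w") as fh:
        for sim in sims:
            if sim.site_sequence:
                key, seq = sim.site_sequence
                fh.write(f">{key}\n{seq}\n")

    # per-base exon depth (uniform, clears the coverage filter)
    paths["depth"] = str(out / "depth.tsv")
    with open(paths["depth"], "w") as fh:
        fh.write("chrom\tpos\tdepth\n")
        for sim in sims:
            s0, e0 = sim.gene.exons[0]
            for p in range(s0, e0):
                fh.write(f"{chrom}\t{p}\t{exon_depth}\n")

    # truth table
    import pandas as pd

    paths["truth"] = str(out / "truth.tsv")
    pd.DataFrame([s.truth.as_row() for s in sims]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths


# ---------------------------------------------------------------------------
# Transmission chains for phasing experiments
# ---------------------------------------------------------------------------

def simulate_transmission_chain(
    family: FamilyDesign,
    n_sites: int,
    seed: int,
    chrom: str = "chr1",
    start: int = 10_000,
    spacing: int = 2_000,
    het_parent: Optional[str] = None,
    crossover_index: Optional[dict[str, int]] = None,
    error_rate: float = 0.0,
) -> tuple[list[VariantRecord], dict[str, int], list[tuple[str, int]]]:
    """A chain of informative sites for one heterozygous parent.

    Each offspring inherits haplotype 0 or 1 from the het parent;
    ``crossover_index`` optionally plants one crossover per offspring
    *before* the given site index.  Genotype errors flip the offspring's
    observed genotype at a site with probability ``error_rate``.  Returns
    (variants, inherited starting haplotype per offspring, list of
    (offspring, site_index) error injections).
    """
    rng = np.random.default_rng(seed)
    if het_parent is None:
        het_parent = family.mother_id
    other = (
        family.father_id if het_parent == family.mother_id else family.mother_id
    )
    hap0 = {o: int(rng.integers(0, 2)) for o in family.offspring_ids}
    crossover_index = crossover_index or {}
    variants = []
    errors: list[tuple[str, int]] = []
    for i in range(n_sites):
        gts = {het_parent: GenotypeClass.HET, other: GenotypeClass.HOM_REF}
        for o in family.offspring_ids:
            hap = hap0[o]
            if o in crossover_index and i >= crossover_index[o]:
                hap = 1 - hap
            observed = GenotypeClass.HET if hap == 1 else GenotypeClass.HOM_REF
            if error_rate > 0 and rng.random() < error_rate:
                observed = (
                    GenotypeClass.HOM_REF
                    if observed is GenotypeClass.HET
                    else GenotypeClass.HET
                )
                errors.append((o, i))
            gts[o] = observed
        variants.append(
            VariantRecord(
                chrom=chrom,
                pos=start + i * spacing + 1,
                ref="A",
                alt="C",
                genotypes=gts,
                qual=100.0,
            )
        )
    return variants, hap0, errors
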