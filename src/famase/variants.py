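"""Genotype-pattern matching of family variants against ASE categories.

A cis-regulatory variant with alleles A (high) and B (low) produces three
expression phenotypes: AA -> H, AB -> M, BB -> L.  A variant therefore
supports a gene's predicted ASE category when, for some assignment of
ref/alt to high/low (the *orientation*), every family member's genotype
maps to that member's expression state:

* H_L / L_H - parents homozygous for different alleles; all offspring
  heterozygous (hence all M).
* H_M / M_L / L_M / M_H - one parent heterozygous (the M parent), the
  other homozygous; every offspring's genotype-derived state equals its
  expression state and both genotype classes occur among the offspring.
* M_M - both parents heterozygous; each offspring's genotype-derived
  state equals its observed state under one of the two orientations.

Variants are searched in the gene body plus symmetric flanks (10 kb by
default) and annotated by zone: EXON (merged exons), INTRON (gene body
outside exons), FLANK (outside the gene body).  Matches on the ambiguous
categories identify the heterozygous parent and thereby resolve the
orientation (e.g. father HET under L_M_or_M_H means the father is the M
parent, so the gene is L_M).

Hard filters replicate the conventional short-variant annotation
thresholds (QD, QUAL, SOR, FS, MQ, MQRankSum, ReadPosRankSum for SNPs;
QD, QUAL, FS, ReadPosRankSum for indels); a test whose annotation is
absent from the record is skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from famase.classifier import (
    ASECall,
    ASECategory,
    PARENT_STATES,
    REFINEMENTS,
    RefinedCategory,
)
from famase.core import (
    ExpressionState,
    FamilyDesign,
    GeneModel,
    GenotypeClass,
    VariantRecord,
    flank_region,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hard filtering
# ---------------------------------------------------------------------------

#: (info_key, comparator, threshold, filter_name); "<" fails when value < t.
SNP_FILTERS: tuple[tuple[str, str, float, str], ...] = (
    ("QD", "<", 2.0, "QD2"),
    ("QUAL", "<", 30.0, "QUAL30"),
    ("SOR", ">", 3.0, "SOR3"),
    ("FS", ">", 60.0, "FS60"),
    ("MQ", "<", 40.0, "MQ40"),
    ("MQRankSum", "<", -12.5, "MQRankSum-12.5"),
    ("ReadPosRankSum", "<", -8.0, "ReadPosRankSum-8"),
)

INDEL_FILTERS: tuple[tuple[str, str, float, str], ...] = (
    ("QD", "<", 2.0, "QD2"),
    ("QUAL", "<", 30.0, "QUAL30"),
    ("FS", ">", 200.0, "FS200"),
    ("ReadPosRankSum", "<", -20.0, "ReadPosRankSum-20"),
)


@dataclass(frozen=True)
class HardFilterSpec:
    """Per-class hard-filter expressions for SNPs and INDEL/MIXED records."""

    snp: tuple[tuple[str, str, float, str], ...] = SNP_FILTERS
    indel: tuple[tuple[str, str, float, str], ...] = INDEL_FILTERS


def apply_hard_filters(
    v: VariantRecord, spec: HardFilterSpec = HardFilterSpec()
) -> VariantRecord:
    """Set ``filter_status`` to PASS or the semicolon-joined failing
    filter names.  The record is retained either way."""
    rules = spec.snp if v.is_snp else spec.indel
    failing = []
    for key, op, threshold, name in rules:
        if key == "QUAL":
            value = v.qual
        else:
            value = v.info.get(key)
        if value is None:
            continue
        try:
            value = float(value)
        except (TypeError, ValueError):
            logger.warning(
                "non-numeric %s at %s:%d; filter %s skipped", key, v.chrom, v.pos, name
            )
            continue
        if (op == "<" and value < threshold) or (op == ">" and value > threshold):
            failing.append(name)
    v.filter_status = ";".join(failing) if failing else "PASS"
    return v


# ---------------------------------------------------------------------------
# Pattern matching
# ---------------------------------------------------------------------------

class Zone(Enum):
    EXON = "EXON"
    INTRON = "INTRON"
    FLANK = "FLANK"


class Orientation(Enum):
    """Which allele carries the high-expression regulatory state."""

    REF_HIGH = "REF_HIGH"
    ALT_HIGH = "ALT_HIGH"

    @property
    def flipped(self) -> "Orientation":
        return (
            Orientation.ALT_HIGH
            if self is Orientation.REF_HIGH
            else Orientation.REF_HIGH
        )


@dataclass
class PatternMatch:
    """A variant whose family genotype pattern matches an ASE call."""

    variant: VariantRecord
    gene_id: str
    zone: Zone
    orientation: Orientation
    consistency: tuple[bool, ...]
    refined: Optional[RefinedCategory] = None

    @property
    def n_consistent(self) -> int:
        return sum(self.consistency)


def expected_parent_pattern(category: ASECategory):
    """Predicate on (mother, father) genotype classes for a category."""
    if category is ASECategory.NONE:
        raise ValueError("no parent pattern for category NONE")
    hom = (GenotypeClass.HOM_REF, GenotypeClass.HOM_ALT)

    if category in (ASECategory.H_L, ASECategory.L_H):
        def pred(mother: GenotypeClass, father: GenotypeClass) -> bool:
            return mother in hom and father in hom and mother is not father
    elif category in REFINEMENTS:
        def pred(mother: GenotypeClass, father: GenotypeClass) -> bool:
            return (mother is GenotypeClass.HET) != (father is GenotypeClass.HET) and (
                mother in hom or father in hom
            )
    else:  # M_M
        def pred(mother: GenotypeClass, father: GenotypeClass) -> bool:
            return mother is GenotypeClass.HET and father is GenotypeClass.HET
    return pred


def genotype_to_state(
    genotype: GenotypeClass, orientation: Orientation
) -> ExpressionState:
    """Expression state implied by a genotype under an orientation."""
    if genotype is GenotypeClass.MISSING:
        return ExpressionState.UNASSIGNED
    if genotype is GenotypeClass.HET:
        return ExpressionState.M
    ref_is_high = orientation is Orientation.REF_HIGH
    if genotype is GenotypeClass.HOM_REF:
        return ExpressionState.H if ref_is_high else ExpressionState.L
    return ExpressionState.L if ref_is_high else ExpressionState.H


def mendelian_consistent(
    v: VariantRecord, family: FamilyDesign
) -> bool:
    """True iff every offspring genotype is possible given the parents.

    MISSING parents make every offspring possible; a MISSING offspring is
    not a violation.
    """
    transmissible = {
        GenotypeClass.HOM_REF: {0},
        GenotypeClass.HET: {0, 1},
        GenotypeClass.HOM_ALT: {1},
        GenotypeClass.MISSING: {0, 1},
    }
    m_alleles = transmissible[v.gt(family.mother_id)]
    f_alleles = transmissible[v.gt(family.father_id)]
    possible = {
        (min(a, b), max(a, b)) for a in m_alleles for b in f_alleles
    }
    as_pair = {
        GenotypeClass.HOM_REF: (0, 0),
        GenotypeClass.HET: (0, 1),
        GenotypeClass.HOM_ALT: (1, 1),
    }
    for o in family.offspring_ids:
        g = v.gt(o)
        if g is GenotypeClass.MISSING:
            continue
        if as_pair[g] not in possible:
            return False
    return True


def _refined_reading(
    category: ASECategory,
    het_parent_is_mother: bool,
) -> RefinedCategory:
    """The refined category implied by which parent is heterozygous:
    the HET parent is the M parent."""
    if category is ASECategory.HM_or_ML:
        return RefinedCategory.M_L if het_parent_is_mother else RefinedCategory.H_M
    if category is ASECategory.LM_or_MH:
        return RefinedCategory.M_H if het_parent_is_mother else RefinedCategory.L_M
    raise ValueError(f"category {category} is not ambiguous")


def match_variant(
    v: VariantRecord, call: ASECall, family: FamilyDesign
) -> Optional[PatternMatch]:
    """Test one variant's family genotype pattern against an ASE call.

    Returns a PatternMatch (with resolved orientation, and for ambiguous
    categories the refined reading) when every offspring is consistent,
    else None.  The zone is filled in by the caller.
    """
    category = call.category
    if category is ASECategory.NONE:
        raise ValueError("cannot match against category NONE")
    mother_gt = v.gt(family.mother_id)
    father_gt = v.gt(family.father_id)
    if any(
        v.gt(i) is GenotypeClass.MISSING for i in family.individuals
    ):
        return None
    if not expected_parent_pattern(category)(mother_gt, father_gt):
        return None

    if category in (ASECategory.H_L, ASECategory.L_H):
        # mother's homozygous allele carries the mother's state
        mother_is_high = category is ASECategory.H_L
        if (mother_gt is GenotypeClass.HOM_REF) == mother_is_high:
            orientation = Orientation.REF_HIGH
        else:
            orientation = Orientation.ALT_HIGH
        consistency = tuple(
            v.gt(o) is GenotypeClass.HET for o in family.offspring_ids
        )
        if all(consistency):
            return PatternMatch(
                variant=v,
                gene_id=call.gene_id,
                zone=Zone.FLANK,
                orientation=orientation,
                consistency=consistency,
            )
        return None

    if category in REFINEMENTS:
        if not call.states:
            return None
        het_is_mother = mother_gt is GenotypeClass.HET
        reading = _refined_reading(category, het_is_mother)
        m_state, f_state = PARENT_STATES[reading]
        # Offspring group membership (mother-like vs father-like) is the
        # reading-independent information in call.states; expected states
        # re-letter the groups under this variant's implied reading.
        expected = {
            o: (
                m_state
                if call.states[o] is call.states[family.mother_id]
                else f_state
            )
            for o in family.offspring_ids
        }
        for orientation in Orientation:
            if genotype_to_state(mother_gt, orientation) is not m_state:
                continue
            if genotype_to_state(father_gt, orientation) is not f_state:
                continue
            consistency = tuple(
                genotype_to_state(v.gt(o), orientation) is expected[o]
                for o in family.offspring_ids
            )
            classes = {v.gt(o) for o in family.offspring_ids}
            if all(consistency) and len(classes) >= 2:
                return PatternMatch(
                    variant=v,
                    gene_id=call.gene_id,
                    zone=Zone.FLANK,
                    orientation=orientation,
                    consistency=consistency,
                    refined=reading,
                )
        return None

    # M_M: both orientations tried against the observed states
    if not call.states:
        return None
    for orientation in Orientation:
        consistency = tuple(
            genotype_to_state(v.gt(o), orientation) is call.states[o]
            for o in family.offspring_ids
        )
        if all(consistency):
            return PatternMatch(
                variant=v,
                gene_id=call.gene_id,
                zone=Zone.FLANK,
                orientation=orientation,
                consistency=consistency,
            )
    return None


def zone_of(gene: GeneModel, pos0: int) -> Zone:
    """EXON > INTRON > FLANK precedence using the merged-exon model."""
    if gene.contains_exonic(pos0):
        return Zone.EXON
    if gene.contains(pos0):
        return Zone.INTRON
    return Zone.FLANK


def scan_gene(
    call: ASECall,
    variants: Iterable[VariantRecord],
    gene: GeneModel,
    family: FamilyDesign,
    flank_bp: int = 10_000,
    pass_only: bool = True,
) -> list[PatternMatch]:
    """Scan a gene's body and flanks for pattern-matching variants.

    ``variants`` must be coordinate-sorted.  Mendelian-inconsistent
    variants are excluded from matching and logged.  Returns matches with
    zones annotated; an empty list means the call is genetically
    unconfirmed.
    """
    start, end = flank_region(gene, flank_bp)
    matches: list[PatternMatch] = []
    n_mendel_errors = 0
    for v in variants:
        if v.chrom != gene.chrom or not (start <= v.pos0 < end):
            continue
        if pass_only and v.filter_status != "PASS":
            continue
        if not mendelian_consistent(v, family):
            n_mendel_errors += 1
            continue
        m = match_variant(v, call, family)
        if m is not None:
            m.zone = zone_of(gene, v.pos0)
            matches.append(m)
    if n_mendel_errors:
        logger.info(
            "gene %s: %d Mendelian-inconsistent variants excluded",
            gene.gene_id,
            n_mendel_errors,
        )
    return matches


def resolve_orientation(
    call: ASECall, matches: Sequence[PatternMatch]
) -> Optional[RefinedCategory]:
    """Refine an ambiguous category from its matches' HET parent.

    The heterozygous parent of a matching variant must be the M parent.
    Conflicting matches (different HET parents) leave the category
    ambiguous; the conflict is logged and None returned.
    """
    if call.category not in REFINEMENTS:
        raise ValueError(f"category {call.category} is not ambiguous")
    readings = {m.refined for m in matches if m.refined is not None}
    if not readings:
        return None
    if len(readings) > 1:
        logger.warning(
            "gene %s: conflicting orientation evidence %s; left unresolved",
            call.gene_id,
            sorted(r.value for r in readings),
        )
        return None
    (reading,) = readings
    call.resolved = reading
    return reading


# ---------------------------------------------------------------------------
# Allele-ratio validation from RNA-seq allelic depths
# ---------------------------------------------------------------------------

@dataclass
class AlleleRatioResult:
    """Observed vs expected maternal-allele frequency for one offspring."""

    individual: str
    f_obs: Optional[float]
    f_exp: float
    consistent: Optional[bool]
    reason: str = ""


def expected_maternal_fraction(mother_log2fc: float) -> float:
    """Expected maternal-allele read fraction in a HET offspring.

    Under the cis model the offspring expresses one maternal-type and one
    paternal-type allele, so with R = 2**mother_log2fc (the mother:father
    expression ratio) the maternal fraction is R / (1 + R).
    """
    r = 2.0 ** mother_log2fc
    return r / (1.0 + r)


def allele_ratio_check(
    v: VariantRecord,
    call: ASECall,
    family: FamilyDesign,
    mother_log2fc: Optional[float] = None,
    tol: float = 0.15,
    min_depth: int = 10,
) -> list[AlleleRatioResult]:
    """Compare offspring allelic read fractions with the expression model.

    Requires the variant to carry RNA-seq allele depths and the parents
    to identify the maternal allele (parents homozygous and different).
    Offspring that are not HET or are below ``min_depth`` total reads are
    reported as skipped.
    """
    if mother_log2fc is None:
        mother_log2fc = call.mother_log2fc
    f_exp = expected_maternal_fraction(mother_log2fc)
    mother_gt = v.gt(family.mother_id)
    if mother_gt not in (GenotypeClass.HOM_REF, GenotypeClass.HOM_ALT):
        raise ValueError("maternal allele is only defined for homozygous parents")
    maternal_is_alt = mother_gt is GenotypeClass.HOM_ALT
    out = []
    for o in family.offspring_ids:
        if v.gt(o) is not GenotypeClass.HET:
            out.append(
                AlleleRatioResult(o, None, f_exp, None, reason="offspring not HET")
            )
            continue
        ad = v.allele_depths.get(o)
        if ad is None:
            out.append(
                AlleleRatioResult(o, None, f_exp, None, reason="no allele depths")
            )
            continue
        total = ad[0] + ad[1]
        if total < min_depth:
            out.append(
                AlleleRatioResult(
                    o, None, f_exp, None, reason=f"depth {total} < {min_depth}"
                )
            )
            continue
        maternal = ad[1] if maternal_is_alt else ad[0]
        f_obs = maternal / total
        out.append(
            AlleleRatioResult(o, f_obs, f_exp, abs(f_obs - f_exp) <= tol)
        )
    return out


# ---------------------------------------------------------------------------
# Summary table (matched-variant counts per category and zone)
# ---------------------------------------------------------------------------

def summarize_matches(
    calls: Mapping[str, ASECall],
    matches: Mapping[str, Sequence[PatternMatch]],
):
    """Count genes with at least one match, per category and zone.

    Rows DNA_EXON / DNA_INTRON / DNA_Outside / Unique, columns the five
    ASE categories.
    """
    import pandas as pd

    cats = [c for c in ASECategory if c is not ASECategory.NONE]
    zone_row = {Zone.EXON: "DNA_EXON", Zone.INTRON: "DNA_INTRON",
                Zone.FLANK: "DNA_Outside"}
    rows = ["DNA_EXON", "DNA_INTRON", "DNA_Outside", "Unique"]
    table = pd.DataFrame(0, index=rows, columns=[c.value for c in cats])
    for gene_id, call in calls.items():
        if call.category is ASECategory.NONE:
            continue
        ms = matches.get(gene_id, ())
        zones = {m.zone for m in ms}
        for z in zones:
            table.loc[zone_row[z], call.category.value] += 1
        if ms:
            table.loc["Unique", call.category.value] += 1
    return table
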