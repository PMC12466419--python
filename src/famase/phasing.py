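"""Haplotype phasing by Mendelian transmission within the family.

At a site where one parent is heterozygous and the other homozygous (an
*informative site*), the allele each offspring received from the
heterozygous parent is forced: if the homozygous parent carries allele c,
a HOM(c) offspring received c from the heterozygous parent, a HET
offspring received the other allele, and a HOM(non-c) offspring is a
Mendelian error.

Chaining informative sites along a region groups the offspring by which
parental chromosome (label A or B) they inherited.  Allele indices at
different sites are not comparable a priori, so each successive site's
partition is oriented (identity or label flip) to maximize agreement
with the running per-offspring consensus - a greedy transmission-phasing
chain.  A label switch supported by at least ``switch_support``
consecutive sites becomes a recombination breakpoint; an isolated
discordant site is flagged as a probable genotype error instead.  The
A/B labels are a gauge freedom: only the offspring partition is
meaningful, and all comparisons respect a global label swap.

When a gene has too few informative sites for a parent, the phasing
window is grown symmetrically in steps until enough sites are found or a
maximum extension is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from famase.classifier import (
    ASECall,
    ASECategory,
    PARENT_STATES,
    REFINEMENTS,
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

UNKNOWN = -1  # transmitted-allele sentinel for Mendelian-error offspring


@dataclass
class InformativeSite:
    """A site heterozygous in one parent and homozygous in the other,
    with the transmitted het-parent allele deduced per offspring."""

    variant: VariantRecord
    het_parent: str
    transmitted_allele: dict[str, int]  # offspring -> 0 / 1 / UNKNOWN

    @property
    def pos0(self) -> int:
        return self.variant.pos0


@dataclass
class Block:
    """A run of consecutive informative sites with one haplotype label."""

    start: int  # 0-based position of first supporting site
    end: int  # 0-based position of last supporting site (inclusive)
    label: str  # "A" or "B"
    n_sites: int = 0


@dataclass
class OffspringPhase:
    blocks: list[Block] = field(default_factory=list)
    breakpoints: list[tuple[int, int]] = field(default_factory=list)
    flagged_errors: list[int] = field(default_factory=list)  # site positions


@dataclass
class HaplotypeBlocks:
    """Per-offspring haplotype labels along a region, for one parent."""

    parent: str
    chrom: str
    phases: dict[str, OffspringPhase] = field(default_factory=dict)
    n_sites: int = 0
    n_mendelian_errors: int = 0
    window: Optional[tuple[int, int]] = None
    resolved: bool = True

    def labels_at(self, pos0: int) -> dict[str, Optional[str]]:
        """Haplotype label of each offspring at a position (None outside
        any block)."""
        out: dict[str, Optional[str]] = {}
        for o, ph in self.phases.items():
            out[o] = None
            for b in ph.blocks:
                if b.start <= pos0 <= b.end:
                    out[o] = b.label
                    break
            else:
                # position outside the supported span: use nearest block
                if ph.blocks:
                    nearest = min(
                        ph.blocks,
                        key=lambda b: min(abs(b.start - pos0), abs(b.end - pos0)),
                    )
                    out[o] = nearest.label
        return out

    def partition(self, pos0: int) -> frozenset[str]:
        """Gauge-invariant offspring partition at a position: the
        offspring set carrying the lexicographically smaller side."""
        labels = self.labels_at(pos0)
        a = frozenset(o for o, l in labels.items() if l == "A")
        b = frozenset(o for o, l in labels.items() if l == "B")
        return min(a, b, key=lambda s: (len(s), sorted(s)))


def transmitted_from_het_parent(
    offspring_gt: GenotypeClass, hom_parent_allele: int
) -> int:
    """Allele index the offspring received from the heterozygous parent."""
    pair = {
        GenotypeClass.HOM_REF: (0, 0),
        GenotypeClass.HET: (0, 1),
        GenotypeClass.HOM_ALT: (1, 1),
    }.get(offspring_gt)
    if pair is None:
        return UNKNOWN
    a, b = pair
    if a == b:
        # homozygous: one copy must come from each parent
        return a if a == hom_parent_allele else UNKNOWN
    # heterozygous: the het parent gave the allele the hom parent lacks
    return 1 - hom_parent_allele


def find_informative_sites(
    variants: Iterable[VariantRecord],
    family: FamilyDesign,
    parent: str,
    region: Optional[tuple[int, int]] = None,
    pass_only: bool = True,
) -> list[InformativeSite]:
    """All usable sites where ``parent`` is HET and the other parent HOM.

    Mendelian-error offspring are kept with UNKNOWN transmission and
    counted by the caller.
    """
    other = (
        family.father_id if parent == family.mother_id else family.mother_id
    )
    sites = []
    for v in variants:
        if region is not None and not (region[0] <= v.pos0 < region[1]):
            continue
        if pass_only and v.filter_status != "PASS":
            continue
        if v.gt(parent) is not GenotypeClass.HET:
            continue
        other_gt = v.gt(other)
        if other_gt is GenotypeClass.HOM_REF:
            hom_allele = 0
        elif other_gt is GenotypeClass.HOM_ALT:
            hom_allele = 1
        else:
            continue
        transmitted = {
            o: transmitted_from_het_parent(v.gt(o), hom_allele)
            for o in family.offspring_ids
        }
        sites.append(
            InformativeSite(
                variant=v, het_parent=parent, transmitted_allele=transmitted
            )
        )
    return sites


def _orient_sites(
    sites: Sequence[InformativeSite], offspring: Sequence[str]
) -> list[dict[str, int]]:
    """Greedy chain orientation: flip each site's allele labels to agree
    with the running per-offspring consensus (majority vote; ties keep
    the identity orientation)."""
    oriented: list[dict[str, int]] = []
    consensus: dict[str, int] = {}
    for site in sites:
        t = site.transmitted_allele
        agree = sum(
            1
            for o in offspring
            if t.get(o, UNKNOWN) != UNKNOWN
            and o in consensus
            and t[o] == consensus[o]
        )
        disagree = sum(
            1
            for o in offspring
            if t.get(o, UNKNOWN) != UNKNOWN
            and o in consensus
            and t[o] != consensus[o]
        )
        flip = disagree > agree
        labels = {
            o: ((1 - t[o]) if flip else t[o])
            for o in offspring
            if t.get(o, UNKNOWN) != UNKNOWN
        }
        oriented.append(labels)
        consensus.update(labels)
    return oriented


def phase_parent(
    sites: Sequence[InformativeSite],
    family: FamilyDesign,
    min_sites: int = 2,
    switch_support: int = 2,
) -> HaplotypeBlocks:
    """Phase one parent's transmission over a chain of informative sites.

    Raises ValueError when fewer than ``min_sites`` sites are available
    (the caller should extend the region).
    """
    if len(sites) < min_sites:
        raise ValueError(
            f"only {len(sites)} informative sites (< {min_sites}); extend region"
        )
    parent = sites[0].het_parent
    chrom = sites[0].variant.chrom
    offspring = family.offspring_ids
    oriented = _orient_sites(sites, offspring)
    positions = [s.pos0 for s in sites]
    n_mendel = sum(
        1
        for s in sites
        for o in offspring
        if s.transmitted_allele.get(o, UNKNOWN) == UNKNOWN
    )
    result = HaplotypeBlocks(
        parent=parent, chrom=chrom, n_sites=len(sites),
        n_mendelian_errors=n_mendel,
    )
    label_str = {0: "A", 1: "B"}
    for o in offspring:
        seq = [
            (pos, labels[o])
            for pos, labels in zip(positions, oriented)
            if o in labels
        ]
        phase = OffspringPhase()
        if not seq:
            result.phases[o] = phase
            continue
        i = 0
        cur_label = seq[0][1]
        block = Block(start=seq[0][0], end=seq[0][0], label=label_str[cur_label],
                      n_sites=1)
        i = 1
        while i < len(seq):
            pos, lab = seq[i]
            if lab == cur_label:
                block.end = pos
                block.n_sites += 1
                i += 1
                continue
            # candidate switch: count the run of the new label
            run = 1
            while i + run < len(seq) and seq[i + run][1] == lab:
                run += 1
            if run >= switch_support:
                # accepted recombination breakpoint
                phase.blocks.append(block)
                phase.breakpoints.append((block.end, pos))
                cur_label = lab
                block = Block(start=pos, end=pos, label=label_str[cur_label],
                              n_sites=1)
                i += 1
            else:
                # isolated discordance: probable genotype error
                phase.flagged_errors.extend(p for p, _ in seq[i : i + run])
                i += run
        phase.blocks.append(block)
        result.phases[o] = phase
    return result


def phase_region_with_extension(
    gene: GeneModel,
    variants: Sequence[VariantRecord],
    family: FamilyDesign,
    flank_bp: int = 10_000,
    min_sites: int = 2,
    switch_support: int = 2,
    max_extension: int = 1_000_000,
    step: int = 10_000,
    pass_only: bool = True,
) -> dict[str, HaplotypeBlocks]:
    """Phase both parents over the gene region, growing the window when a
    parent lacks informative sites.

    Starts from gene +/- ``flank_bp`` and extends symmetrically by
    ``step`` until ``min_sites`` sites are found for the parent or the
    extension exceeds ``max_extension``; a still-sparse parent is
    reported with ``resolved=False``.
    """
    out: dict[str, HaplotypeBlocks] = {}
    in_chrom = [v for v in variants if v.chrom == gene.chrom]
    for parent in family.parents:
        extension = 0
        blocks: Optional[HaplotypeBlocks] = None
        while True:
            region = flank_region(gene, flank_bp + extension)
            sites = find_informative_sites(
                in_chrom, family, parent, region=region, pass_only=pass_only
            )
            try:
                blocks = phase_parent(
                    sites, family, min_sites=min_sites,
                    switch_support=switch_support,
                )
                blocks.window = region
                break
            except ValueError:
                if extension >= max_extension:
                    blocks = HaplotypeBlocks(
                        parent=parent, chrom=gene.chrom, n_sites=len(sites),
                        window=region, resolved=False,
                    )
                    logger.info(
                        "gene %s: parent %s unresolved (%d sites within "
                        "max extension %d)",
                        gene.gene_id, parent, len(sites), max_extension,
                    )
                    break
                extension = min(extension + step, max_extension)
        out[parent] = blocks
    return out


def phase_supports_call(
    blocks: Mapping[str, HaplotypeBlocks],
    call: ASECall,
    family: FamilyDesign,
    at_pos0: Optional[int] = None,
) -> Optional[bool]:
    """Whether the inherited-haplotype grouping explains the ASE call.

    Tries every assignment of parental haplotype labels to high/low
    regulatory alleles (labels are a gauge) and checks the implied
    offspring states against the call's states.  Returns True/False, or
    None when the needed parent phase is unresolved (indeterminate).

    The genetic model per category: H_L / L_H - both parents homozygous,
    so all offspring are M regardless of phase; ambiguous categories -
    the heterozygous (M) parent's transmitted haplotype decides whether
    an offspring matches the M parent or the homozygous parent; M_M -
    both parents heterozygous and the offspring state counts inherited
    high alleles (2 -> H, 1 -> M, 0 -> L).
    """
    category = call.category
    if category is ASECategory.NONE:
        raise ValueError("no phase support for category NONE")
    if not call.states:
        return None
    mo, fa = family.mother_id, family.father_id

    if category in (ASECategory.H_L, ASECategory.L_H):
        return all(
            call.states[o] is ExpressionState.M for o in family.offspring_ids
        )

    def offspring_labels(parent: str) -> Optional[dict[str, Optional[str]]]:
        b = blocks.get(parent)
        if b is None or not b.resolved:
            return None
        pos = at_pos0
        if pos is None:
            pos = b.window[0] if b.window else 0
        return b.labels_at(pos)

    if category in REFINEMENTS:
        reading = call.resolved or REFINEMENTS[category][0]
        m_state, f_state = PARENT_STATES[reading]
        het_parent = mo if m_state is ExpressionState.M else fa
        labels = offspring_labels(het_parent)
        if labels is None or any(l is None for l in labels.values()):
            return None
        # The haplotype labels are a gauge, and the state letters depend on
        # the reading; the comparable object is the offspring partition:
        # those sharing the mother's state vs those sharing the father's.
        mother_like = frozenset(
            o
            for o in family.offspring_ids
            if call.states[o] is call.states[mo]
        )
        father_like = frozenset(family.offspring_ids) - mother_like
        hap_a = frozenset(
            o for o in family.offspring_ids if labels[o] == "A"
        )
        return hap_a in (mother_like, father_like)

    # M_M: states from the count of inherited high alleles
    m_labels = offspring_labels(mo)
    f_labels = offspring_labels(fa)
    if (
        m_labels is None
        or f_labels is None
        or any(l is None for l in m_labels.values())
        or any(l is None for l in f_labels.values())
    ):
        return None
    state_by_count = {
        2: ExpressionState.H,
        1: ExpressionState.M,
        0: ExpressionState.L,
    }
    for m_high in ("A", "B"):
        for f_high in ("A", "B"):
            ok = True
            for o in family.offspring_ids:
                n_high = int(m_labels[o] == m_high) + int(f_labels[o] == f_high)
                if call.states[o] is not state_by_count[n_high]:
                    ok = False
                    break
            if ok:
                return True
    return False
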