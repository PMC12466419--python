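"""Candidate regulatory SNPs in conserved transcription-factor binding sites.

Conserved TFBS intervals (already lifted to the target genome) come in as
BED6+, optionally with an IUPAC consensus motif in column 7.  A
pattern-matched variant falling inside a site is scored by substituting
its ref and alt bases into the site sequence and counting positions
compatible with the consensus; an alt allele that completes the motif
scores higher than the ref, nominating the variant as a regulatory SNP
(rSNP) candidate.

Consensus strings use IUPAC ambiguity codes; lowercase letters mark
non-consensus (wildcard) positions, following the convention where
capital letters in a genomic motif denote the consensus-matching bases.
Minus-strand sites are scored on the reverse complement of the genomic
sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from famase.classifier import ASECall
from famase.core import VariantRecord
from famase.variants import PatternMatch, Zone

logger = logging.getLogger(__name__)

#: IUPAC code -> compatible upper-case bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TFBSSite:
    """A conserved binding-site interval with its consensus motif."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    tf_name: str
    strand: str = "+"
    consensus: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.tf_name}: empty interval")
        if self.consensus is not None:
            if len(self.consensus) > self.end - self.start:
                raise ValueError(
                    f"{self.tf_name}: consensus longer than interval"
                )
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"{self.tf_name}: non-IUPAC letters {bad}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RSNPCandidate:
    """A pattern-consistent variant inside a conserved TFBS."""

    gene_id: str
    variant: VariantRecord
    tf_name: str
    zone: Zone
    ref_match_score: Optional[int]
    alt_match_score: Optional[int]
    site: TFBSSite = None
    pattern_consistent: bool = True
    note: str = ""


def load_tfbs_bed(path: str) -> list[TFBSSite]:
    """Read conserved TFBS intervals from a BED6+ file.

    Column 4 carries the TF name; an optional column 7 carries the
    consensus motif.  Malformed lines are skipped with a warning.
    """
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            try:
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                strand = parts[5] if len(parts) > 5 else "+"
                consensus = parts[6] if len(parts) > 6 else None
                sites.append(
                    TFBSSite(
                        chrom=chrom, start=start, end=end, tf_name=name,
                        strand=strand if strand in "+-" else "+",
                        consensus=consensus,
                    )
                )
            except (ValueError, IndexError) as exc:
                logger.warning("skipping malformed BED line %d: %s", lineno, exc)
    sites.sort(key=lambda s: (s.chrom, s.start, s.end, s.tf_name))
    return sites


def consensus_match_count(seq: str, consensus: str) -> int:
    """Number of positions where ``seq`` is compatible with the IUPAC
    consensus.  Case-insensitive on ``seq``; lowercase consensus letters
    are wildcards (they always count as compatible)."""
    if len(seq) != len(consensus):
        raise ValueError(
            f"length mismatch: seq {len(seq)} vs consensus {len(consensus)}"
        )
    n = 0
    for base, code in zip(seq.upper(), consensus):
        if code.islower():
            n += 1
            continue
        if base in IUPAC.get(code.upper(), ""):
            n += 1
    return n


def score_allele_effect(
    site: TFBSSite,
    v: VariantRecord,
    local_sequence: str,
    local_start: Optional[int] = None,
) -> tuple[Optional[int], Optional[int], str]:
    """Consensus match counts for the site with the ref and the alt base.

    ``local_sequence`` is plus-strand genomic sequence containing the
    site, starting at ``local_start`` (defaults to ``site.start``).
    Minus-strand sites are reverse-complemented before matching.  Indels
    or variants spanning the site boundary return (None, None, reason).
    """
    if site.consensus is None:
        return None, None, "site has no consensus motif"
    if not (len(v.ref) == 1 and len(v.alt) == 1):
        return None, None, "indel within site scored UNDEFINED"
    start = site.start if local_start is None else local_start
    off_site = site.start - start
    off_var = v.pos0 - start
    if not (site.start <= v.pos0 < site.end):
        return None, None, "variant outside site"
    if off_site < 0 or off_site + site.length > len(local_sequence):
        return None, None, "local sequence does not cover site"
    site_seq = local_sequence[off_site : off_site + site.length]
    idx = v.pos0 - site.start
    if site_seq[idx].upper() != v.ref.upper():
        logger.warning(
            "reference base mismatch at %s:%d (seq %s vs ref %s)",
            v.chrom, v.pos, site_seq[idx], v.ref,
        )
    ref_seq = site_seq[:idx] + v.ref + site_seq[idx + 1 :]
    alt_seq = site_seq[:idx] + v.alt + site_seq[idx + 1 :]
    if site.strand == "-":
        ref_seq = reverse_complement(ref_seq)
        alt_seq = reverse_complement(alt_seq)
    # consensus may describe only part of the interval; align at its start
    clen = len(site.consensus)
    ref_score = consensus_match_count(ref_seq[:clen], site.consensus)
    alt_score = consensus_match_count(alt_seq[:clen], site.consensus)
    return ref_score, alt_score, ""


def nominate_rsnps(
    calls: Mapping[str, ASECall],
    matches: Mapping[str, Sequence[PatternMatch]],
    tfbs: Sequence[TFBSSite],
    sequences: Optional[Mapping] = None,
) -> list[RSNPCandidate]:
    """Intersect pattern-matched variants with conserved TFBS intervals.

    ``sequences`` supplies plus-strand sequence for scoring, keyed either
    by "chrom:start-end" site keys or by chromosome name (then sliced by
    coordinate); when absent, candidates are emitted without scores.
    Exonic candidates are kept but flagged as unusual.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for site in tfbs:
        trees.setdefault(site.chrom, IntervalTree()).addi(
            site.start, site.end, site
        )
    out: list[RSNPCandidate] = []
    for gene_id, ms in matches.items():
        call = calls.get(gene_id)
        if call is None:
            continue
        for m in ms:
            v = m.variant
            tree = trees.get(v.chrom)
            if tree is None:
                continue
            for iv in sorted(tree.overlap(v.pos0, v.pos0 + 1)):
                site: TFBSSite = iv.data
                ref_s = alt_s = None
                note = ""
                if sequences is not None and site.consensus is not None:
                    seq, start = _site_sequence(sequences, site)
                    if seq is not None:
                        ref_s, alt_s, note = score_allele_effect(
                            site, v, seq, local_start=start
                        )
                    else:
                        note = "no sequence available for site"
                if m.zone is Zone.EXON:
                    note = (note + "; " if note else "") + "exonic TFBS (unusual)"
                out.append(
                    RSNPCandidate(
                        gene_id=gene_id,
                        variant=v,
                        tf_name=site.tf_name,
                        zone=m.zone,
                        ref_match_score=ref_s,
                        alt_match_score=alt_s,
                        site=site,
                        note=note,
                    )
                )
    return out


def _site_sequence(sequences: Mapping, site: TFBSSite):
    """Fetch plus-strand sequence covering a site from a mapping of
    "chrom:start-end" keys or whole-chromosome sequences."""
    key = f"{site.chrom}:{site.start}-{site.end}"
    if key in sequences:
        return str(sequences[key][:]), site.start
    if site.chrom in sequences:
        chrom_seq = sequences[site.chrom]
        return str(chrom_seq[site.start : site.end]), site.start
    return None, None


def summarize_candidates(
    calls: Mapping[str, ASECall], candidates: Sequence[RSNPCandidate]
):
    """Distinct TFs and genes per category for intron vs surrounding
    zones (exonic candidates counted with introns)."""
    import pandas as pd

    from famase.classifier import ASECategory

    cats = [c.value for c in ASECategory if c is not ASECategory.NONE]
    rows = pd.MultiIndex.from_product(
        [["TFs", "Genes"], ["Surrounding_regions", "Introns"]]
    )
    table = pd.DataFrame(0, index=rows, columns=cats)
    seen: dict[tuple, set] = {}
    for c in candidates:
        call = calls[c.gene_id]
        cat = call.category.value
        zone = "Surrounding_regions" if c.zone is Zone.FLANK else "Introns"
        seen.setdefault(("TFs", zone, cat), set()).add(c.tf_name)
        seen.setdefault(("Genes", zone, cat), set()).add(c.gene_id)
    for (kind, zone, cat), vals in seen.items():
        table.loc[(kind, zone), cat] = len(vals)
    return table
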