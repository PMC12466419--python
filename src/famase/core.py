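"""Shared domain types, pedigree model, interval arithmetic and genomic I/O.

Internal coordinates are 0-based half-open everywhere.  VCF stays 1-based
and GTF 1-based inclusive on disk; conversions happen only at the I/O
boundary.  BED is already 0-based half-open and passes through unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pysam

logger = logging.getLogger(__name__)


class GenotypeClass(Enum):
    """Diploid genotype class derived from a VCF GT field.

    Phased ("|") and unphased ("/") separators are equivalent: phase is
    re-derived by transmission in the phasing module rather than trusted
    from the caller.
    """

    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"


class ExpressionState(Enum):
    """Per-individual expression state relative to the father baseline.

    H = high, M = moderate (intermediate), L = low.  UNASSIGNED marks
    log2FC values falling in the gap zones between the moderate band and
    the high/low anchors.
    """

    H = "H"
    M = "M"
    L = "L"
    UNASSIGNED = "UNASSIGNED"


class ConfigurationError(ValueError):
    """Raised for invalid pedigree / threshold / path configuration."""


@dataclass(frozen=True)
class FamilyDesign:
    """Pedigree of one mother, one father and N offspring.

    ``sample_map`` maps each sample column (e.g. an RNA-seq replicate) to
    the individual it was taken from.  ``excluded_samples`` lists replicate
    columns to drop before any computation (e.g. an outlier replicate).
    """

    mother_id: str
    father_id: str
    offspring_ids: tuple[str, ...]
    sample_map: Mapping[str, str] = field(default_factory=dict)
    excluded_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "offspring_ids", tuple(self.offspring_ids))
        object.__setattr__(self, "excluded_samples", tuple(self.excluded_samples))
        if not self.offspring_ids:
            raise ConfigurationError("offspring_ids must be non-empty")
        ids = self.individuals
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"family individual ids are not distinct: {ids}")
        for sample, ind in self.sample_map.items():
            if ind not in ids:
                raise ConfigurationError(
                    f"sample {sample!r} maps to unknown individual {ind!r}"
                )
        if self.sample_map:
            live = {
                ind
                for s, ind in self.sample_map.items()
                if s not in self.excluded_samples
            }
            missing = [i for i in ids if i not in live]
            if missing:
                raise ConfigurationError(
                    f"individuals with no non-excluded sample: {missing}"
                )

    @property
    def individuals(self) -> tuple[str, ...]:
        return (self.mother_id, self.father_id) + self.offspring_ids

    @property
    def parents(self) -> tuple[str, str]:
        return (self.mother_id, self.father_id)

    def samples_of(self, individual: str) -> list[str]:
        """Non-excluded sample columns belonging to one individual."""
        return [
            s
            for s, ind in self.sample_map.items()
            if ind == individual and s not in self.excluded_samples
        ]

    @classmethod
    def from_dict(cls, d: Mapping) -> "FamilyDesign":
        return cls(
            mother_id=d["mother_id"],
            father_id=d["father_id"],
            offspring_ids=tuple(d["offspring_ids"]),
            sample_map=dict(d.get("sample_map", {})),
            excluded_samples=tuple(d.get("excluded_samples", ())),
        )


@dataclass
class VariantRecord:
    """One biallelic variant with per-individual genotype classes.

    ``pos`` follows the VCF convention (1-based).  Multi-allelic input
    records are decomposed into one VariantRecord per alternate allele;
    ``genotypes`` counts copies of *this* alt allele (2 = HOM_ALT,
    1 = HET, 0 = HOM_REF).
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    info: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, GenotypeClass] = field(default_factory=dict)
    allele_depths: dict[str, tuple[int, int]] = field(default_factory=dict)
    filter_status: str = "PASS"
    qual: Optional[float] = None
    vid: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (got {self.pos})")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")

    @property
    def pos0(self) -> int:
        """0-based position of the first reference base."""
        return self.pos - 1

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def gt(self, individual: str) -> GenotypeClass:
        return self.genotypes.get(individual, GenotypeClass.MISSING)


@dataclass
class GeneModel:
    """Gene span plus merged exons, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        self.exons = merge_intervals(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside gene span")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between merged exons, within the gene span."""
        if not self.exons:
            return ()
        out = []
        if self.start < self.exons[0][0]:
            out.append((self.start, self.exons[0][0]))
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1, s2))
        if self.exons[-1][1] < self.end:
            out.append((self.exons[-1][1], self.end))
        return tuple(out)

    def contains_exonic(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


def merge_intervals(
    intervals: Iterable[tuple[int, int]],
) -> tuple[tuple[int, int], ...]:
    """Union of 0-based half-open intervals, sorted and non-overlapping."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if s >= e:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def flank_region(
    gene: GeneModel, flank_bp: int, chrom_length: Optional[int] = None
) -> tuple[int, int]:
    """Gene body extended symmetrically by ``flank_bp``, clipped at the
    chromosome boundaries.  Strand is ignored: flanks are symmetric."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    start = max(0, gene.start - flank_bp)
    end = gene.end + flank_bp
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, end


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def _classify_alleles(alleles: Optional[tuple], alt_index: int) -> GenotypeClass:
    """Genotype class for one decomposed alt from raw integer GT alleles.

    ``alleles`` are the VCF allele indices of the diploid call; the class
    counts copies of allele ``alt_index``.  Any missing allele gives
    MISSING.
    """
    if alleles is None or len(alleles) == 0 or any(a is None for a in alleles):
        return GenotypeClass.MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt >= 2:
        return GenotypeClass.HOM_ALT
    if n_alt == 1:
        return GenotypeClass.HET
    return GenotypeClass.HOM_REF


def read_vcf(
    path: str,
    family: FamilyDesign,
    region: Optional[tuple[str, int, int]] = None,
    drop_any_missing: bool = True,
) -> Iterator[VariantRecord]:
    """Stream VariantRecords for the family from a VCF 4.x file.

    Multi-allelic records are decomposed into one biallelic record per alt
    allele, with genotype classes recomputed per alt.  ``region`` is
    (chrom, start, end) in the internal 0-based half-open convention.

    By default, records where any family member has a missing genotype are
    dropped, mirroring the removal of no-call (./.) sites from the family
    callset; set ``drop_any_missing=False`` to keep them.
    """
    vf = pysam.VariantFile(path)
    header_samples = set(vf.header.samples)
    for ind in family.individuals:
        if ind not in header_samples:
            raise ConfigurationError(
                f"individual {ind!r} not present in VCF header of {path}"
            )
    if region is not None:
        chrom, start, end = region
        it = vf.fetch(chrom, start, end) if vf.index is not None else (
            rec
            for rec in vf
            if rec.chrom == chrom and start < rec.stop and rec.start < end
        )
    else:
        it = iter(vf)

    for rec in it:
        alts = rec.alts or ()
        for ai, alt in enumerate(alts, start=1):
            genotypes: dict[str, GenotypeClass] = {}
            depths: dict[str, tuple[int, int]] = {}
            for ind in family.individuals:
                sample = rec.samples[ind]
                try:
                    alleles = sample.get("GT")
                except (KeyError, ValueError):
                    logger.warning(
                        "malformed GT at %s:%d for %s; set MISSING",
                        rec.chrom,
                        rec.pos,
                        ind,
                    )
                    alleles = None
                genotypes[ind] = _classify_alleles(alleles, ai)
                ad = sample.get("AD")
                if ad is not None and len(ad) > ai and ad[0] is not None:
                    ref_d = int(ad[0]) if ad[0] is not None else 0
                    alt_d = int(ad[ai]) if ad[ai] is not None else 0
                    depths[ind] = (ref_d, alt_d)
            if drop_any_missing and any(
                g is GenotypeClass.MISSING for g in genotypes.values()
            ):
                continue
            info = {}
            for key, val in rec.info.items():
                try:
                    if isinstance(val, (tuple, list)):
                        val = val[min(ai - 1, len(val) - 1)]
                    info[key] = float(val)
                except (TypeError, ValueError):
                    continue
            filt = ";".join(rec.filter.keys()) if list(rec.filter) else "PASS"
            yield VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=str(alt),
                info=info,
                genotypes=genotypes,
                allele_depths=depths,
                filter_status=filt or "PASS",
                qual=rec.qual,
                vid=rec.id,
            )


_GT_STRINGS = {
    GenotypeClass.HOM_REF: "0/0",
    GenotypeClass.HET: "0/1",
    GenotypeClass.HOM_ALT: "1/1",
    GenotypeClass.MISSING: "./.",
}


def write_vcf(
    path: str,
    records: Iterable[VariantRecord],
    family: FamilyDesign,
    contigs: Optional[Mapping[str, int]] = None,
) -> None:
    """Write biallelic VariantRecords to a VCF 4.2 text file.

    Genotype classes are serialized as unphased GT; allele depths, when
    present for every family member, are written to a FORMAT AD field.
    INFO values are written as floats.
    """
    records = list(records)
    info_keys = sorted({k for r in records for k in r.info})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        for key in info_keys:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
            )
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        filters = sorted(
            {
                f
                for r in records
                for f in r.filter_status.split(";")
                if f and f != "PASS"
            }
        )
        for f in filters:
            fh.write(f'##FILTER=<ID={f},Description="{f}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths">\n'
        )
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                "FORMAT"] + list(family.individuals)
        fh.write("\t".join(cols) + "\n")
        for r in sorted(records, key=lambda v: (v.chrom, v.pos, v.alt)):
            info = (
                ";".join(f"{k}={r.info[k]:g}" for k in sorted(r.info))
                if r.info
                else "."
            )
            qual = f"{r.qual:g}" if r.qual is not None else "."
            fmt = "GT:AD" if r.allele_depths else "GT"
            fields = [
                r.chrom,
                str(r.pos),
                r.vid or ".",
                r.ref,
                r.alt,
                qual,
                r.filter_status or "PASS",
                info,
                fmt,
            ]
            for ind in family.individuals:
                gt = _GT_STRINGS[r.gt(ind)]
                if r.allele_depths:
                    ad = r.allele_depths.get(ind)
                    gt += ":" + (f"{ad[0]},{ad[1]}" if ad else ".")
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GTF reading
# ---------------------------------------------------------------------------

def read_gene_models(path: str) -> list[GeneModel]:
    """Parse gene models from a GTF file.

    File coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; exons are merged per gene.  Exons
    extending past their gene span are clipped with a warning; genes with
    no exon features are kept with empty exons and flagged.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    for ex in db.features_of_type("exon"):
        gid = ex.attributes.get("gene_id", [None])[0]
        if gid is not None:
            exons_by_gene.setdefault(gid, []).append((ex.start - 1, ex.end))
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("gene_id", [g.id])[0]
        gstart, gend = g.start - 1, g.end
        exons = []
        for s, e in exons_by_gene.get(gid, []):
            if s < gstart or e > gend:
                logger.warning(
                    "exon [%d,%d) of gene %s outside gene span; clipping", s, e, gid
                )
                s, e = max(s, gstart), min(e, gend)
            if s < e:
                exons.append((s, e))
        if not exons:
            logger.warning("gene %s has no exon features", gid)
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=g.seqid,
                start=gstart,
                end=gend,
                strand=g.strand or ".",
                exons=tuple(exons),
            )
        )
    genes.sort(key=lambda gm: (gm.chrom, gm.start))
    return genes
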