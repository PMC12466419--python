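"""Count normalization, father-baseline log2 fold changes, and filters.

The normalization is the median-of-ratios scheme used for RNA-seq count
matrices: a pseudo-reference sample is built as the per-gene geometric
mean across samples, and each sample's size factor is the median, over
genes expressed in every sample, of its count divided by that reference.

Fold changes are computed per individual against the father: each
individual's replicate counts are normalized, averaged, and compared to
the father's normalized mean on a log2 scale with a pseudocount.  The
father's own log2FC is exactly zero for every gene by construction.

Two significance backends are provided.  The "internal" backend runs a
Welch t-test on log2-transformed normalized replicate counts per contrast
with Benjamini-Hochberg correction, keeping the pipeline self-contained
for simulation work.  The "external" backend reads log2FC/padj columns
produced by a dedicated differential-expression tool (e.g. a negative-
binomial Wald test), which is what one would use on real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from famase.core import ConfigurationError, FamilyDesign, GeneModel

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match gene/sample lists")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")

    @classmethod
    def from_tsv(cls, path: str) -> "CountMatrix":
        """Read a featureCounts-style TSV: first column gene id, one
        column per sample."""
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(
            genes=list(df.index.astype(str)),
            samples=list(df.columns.astype(str)),
            counts=df.to_numpy(),
        )

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.counts, index=self.genes, columns=self.samples).to_csv(
            path, sep="\t", index_label="gene_id"
        )

    def drop_samples(self, excluded: Sequence[str]) -> "CountMatrix":
        keep = [i for i, s in enumerate(self.samples) if s not in set(excluded)]
        return CountMatrix(
            genes=list(self.genes),
            samples=[self.samples[i] for i in keep],
            counts=self.counts[:, keep],
        )


@dataclass
class ExpressionTable:
    """Per gene x individual normalized means, log2FC vs father, padj.

    Backed by three DataFrames indexed by gene id with one column per
    individual.  ``padj`` may be absent (all-NaN) when no test backend
    was run.
    """

    normalized_mean: pd.DataFrame
    log2fc: pd.DataFrame
    padj: pd.DataFrame
    father_id: str

    @property
    def genes(self) -> list[str]:
        return list(self.log2fc.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.log2fc.columns)

    def gene_log2fc(self, gene_id: str) -> dict[str, float]:
        return self.log2fc.loc[gene_id].to_dict()

    def to_tsv(self, path: str) -> None:
        long = pd.concat(
            {
                "normalized_mean": self.normalized_mean.stack(),
                "log2fc": self.log2fc.stack(),
                "padj": self.padj.stack(),
            },
            axis=1,
        )
        long.index.names = ["gene_id", "individual"]
        long.reset_index().to_csv(path, sep="\t", index=False)


def size_factors(m: CountMatrix) -> dict[str, float]:
    """Median-of-ratios size factor per sample.

    Only genes whose geometric mean across samples is positive (i.e.
    counts nonzero in all samples) contribute.
    """
    counts = m.counts.astype(float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    log_geomean = logc.mean(axis=1)
    expressed = np.isfinite(log_geomean)
    if not expressed.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; pre-filter the matrix "
            "or check sample quality"
        )
    ratios = np.exp(logc[expressed] - log_geomean[expressed, None])
    factors = np.median(ratios, axis=0)
    return dict(zip(m.samples, factors))


def low_count_filter(
    m: CountMatrix, min_total: int = 10, min_samples: int = 3
) -> CountMatrix:
    """Drop genes with fewer than ``min_total`` reads in at least
    ``min_samples`` samples."""
    low = (m.counts < min_total).sum(axis=1) >= min_samples
    keep = ~low
    logger.info("low-count pre-filter: %d of %d genes kept", keep.sum(), len(keep))
    return CountMatrix(
        genes=[g for g, k in zip(m.genes, keep) if k],
        samples=list(m.samples),
        counts=m.counts[keep],
    )


def log2fc_table(
    m: CountMatrix,
    family: FamilyDesign,
    pseudocount: float = 1.0,
    backend: str = "internal",
    external: Optional[pd.DataFrame] = None,
) -> ExpressionTable:
    """Normalized means and father-baseline log2 fold changes per individual.

    ``backend`` selects the padj source: "internal" (Welch t-test on log2
    normalized replicate counts, BH-corrected per contrast), "external"
    (a long DataFrame with columns gene_id/individual/log2fc/padj; its
    log2fc and padj override the internal ones), or "none".
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    m = m.drop_samples(family.excluded_samples)
    sample_to_ind = {}
    for s in m.samples:
        ind = family.sample_map.get(s)
        if ind is None:
            raise ConfigurationError(f"sample {s!r} missing from sample_map")
        sample_to_ind[s] = ind
    for ind in family.individuals:
        if not any(i == ind for i in sample_to_ind.values()):
            raise ConfigurationError(f"individual {ind!r} has no usable sample")

    factors = size_factors(m)
    fvec = np.array([factors[s] for s in m.samples])
    norm = m.counts / fvec[None, :]

    cols = {}
    rep_log2: dict[str, np.ndarray] = {}
    for ind in family.individuals:
        idx = [i for i, s in enumerate(m.samples) if sample_to_ind[s] == ind]
        cols[ind] = norm[:, idx].mean(axis=1)
        rep_log2[ind] = np.log2(norm[:, idx] + pseudocount)
    normalized_mean = pd.DataFrame(cols, index=m.genes)

    father = family.father_id
    log2fc = np.log2(normalized_mean.add(pseudocount)).sub(
        np.log2(normalized_mean[father] + pseudocount), axis=0
    )
    log2fc[father] = 0.0

    padj = pd.DataFrame(np.nan, index=m.genes, columns=list(family.individuals))
    if backend == "internal":
        f_reps = rep_log2[father]
        for ind in family.individuals:
            if ind == father:
                continue
            with np.errstate(invalid="ignore"):
                _, pvals = stats.ttest_ind(
                    rep_log2[ind], f_reps, axis=1, equal_var=False
                )
            pvals = np.where(np.isfinite(pvals), pvals, 1.0)
            padj[ind] = multipletests(pvals, method="fdr_bh")[1]
    elif backend == "external":
        if external is None:
            raise ConfigurationError("external backend requires a results table")
        ext = external.set_index(["gene_id", "individual"])
        for ind in family.individuals:
            if ind == father:
                continue
            for gene in m.genes:
                key = (gene, ind)
                if key in ext.index:
                    row = ext.loc[key]
                    log2fc.loc[gene, ind] = float(row["log2fc"])
                    padj.loc[gene, ind] = float(row["padj"])
    elif backend != "none":
        raise ConfigurationError(f"unknown backend {backend!r}")

    return ExpressionTable(
        normalized_mean=normalized_mean,
        log2fc=log2fc,
        padj=padj,
        father_id=father,
    )


def significance_gate(
    t: ExpressionTable, lfc_min: float = 1.0, alpha: float = 0.05
) -> set[str]:
    """Genes where at least one individual has |log2FC| > lfc_min and
    padj < alpha."""
    hit = (t.log2fc.abs() > lfc_min) & (t.padj < alpha)
    return set(t.log2fc.index[hit.any(axis=1)])


def exon_coverage_filter(
    gene: GeneModel,
    depth: Mapping[int, int],
    min_depth: int = 5,
) -> bool:
    """True iff some exon has depth strictly greater than ``min_depth`` at
    every base.

    ``depth`` maps 0-based positions on the gene's chromosome to read
    depth; positions absent from the mapping count as depth 0.
    """
    if not gene.exons:
        logger.warning("gene %s has no exons; coverage filter fails", gene.gene_id)
        return False
    for s, e in gene.exons:
        if all(depth.get(p, 0) > min_depth for p in range(s, e)):
            return True
    return False


def read_depth_tsv(path: str) -> dict[str, dict[int, int]]:
    """Read a per-base depth TSV (columns chrom, pos 0-based, depth) into
    a per-chromosome position->depth mapping."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "pos", "depth"], comment="#")
    if df.iloc[0]["chrom"] == "chrom":  # header row present
        df = df.iloc[1:].astype({"pos": int, "depth": int})
    out: dict[str, dict[int, int]] = {}
    for chrom, sub in df.groupby("chrom"):
        out[str(chrom)] = dict(
            zip(sub["pos"].astype(int), sub["depth"].astype(int))
        )
    return out


def read_external_results(path: str) -> pd.DataFrame:
    """Read an external differential-expression results TSV with columns
    gene_id, individual, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "individual", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"external results missing columns: {missing}")
    return df
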