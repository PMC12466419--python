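"""End-to-end orchestration: expression -> classify -> match -> phase -> TFBS.

Stages communicate through plain TSVs so each is independently runnable;
``run_pipeline`` chains them in memory and writes a combined per-gene
report plus the match and rSNP summary tables.  Every input gene appears
exactly once in the report with a disposition (low_count / gated_out /
coverage_fail / none / classified).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from famase import classifier, expression, phasing, tfbs as tfbs_mod, variants
from famase.classifier import ASECategory, Thresholds
from famase.core import ConfigurationError, FamilyDesign, read_gene_models, read_vcf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and knobs for a full run; loadable from YAML."""

    counts: str
    family: str
    gtf: Optional[str] = None
    vcf: Optional[str] = None
    rna_vcf: Optional[str] = None
    depth: Optional[str] = None
    tfbs: Optional[str] = None
    sites_fasta: Optional[str] = None
    external_results: Optional[str] = None
    out_dir: str = "famase_out"

    backend: str = "internal"
    pseudocount: float = 1.0
    low_count_min_total: int = 10
    low_count_min_samples: int = 3
    lfc_min: float = 1.0
    alpha: float = 0.05
    min_exon_depth: int = 5
    mode: str = "strict"
    thresholds: Thresholds = field(default_factory=Thresholds)
    flank_bp: int = 10_000
    pass_only: bool = True
    min_sites: int = 2
    switch_support: int = 2
    max_extension: int = 1_000_000
    extension_step: int = 10_000
    ratio_tol: float = 0.15
    ratio_min_depth: int = 10

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        th = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if th:
            cfg.thresholds = Thresholds(**th)
        return cfg

    def validate(self) -> None:
        for name in ("counts", "family", "gtf", "vcf", "rna_vcf", "depth",
                     "tfbs", "sites_fasta", "external_results"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")


def load_family(path: str) -> FamilyDesign:
    with open(path) as fh:
        return FamilyDesign.from_dict(yaml.safe_load(fh))


def run_pipeline(cfg: PipelineConfig) -> pd.DataFrame:
    """Run every configured stage; returns the per-gene report and writes
    report.tsv, matches.tsv, match_summary.tsv, rsnp_candidates.tsv and
    rsnp_summary.tsv under ``cfg.out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    family = load_family(cfg.family)

    # --- expression ---
    m_raw = expression.CountMatrix.from_tsv(cfg.counts)
    m = expression.low_count_filter(
        m_raw, cfg.low_count_min_total, cfg.low_count_min_samples
    )
    dropped_low = set(m_raw.genes) - set(m.genes)
    external = (
        expression.read_external_results(cfg.external_results)
        if cfg.external_results
        else None
    )
    table = expression.log2fc_table(
        m,
        family,
        pseudocount=cfg.pseudocount,
        backend=cfg.backend,
        external=external,
    )
    gated = expression.significance_gate(table, cfg.lfc_min, cfg.alpha)
    logger.info("significance gate: %d of %d genes", len(gated), len(m.genes))

    genes = {g.gene_id: g for g in read_gene_models(cfg.gtf)} if cfg.gtf else {}

    depth_by_chrom = (
        expression.read_depth_tsv(cfg.depth) if cfg.depth else None
    )

    # --- classify ---
    calls: dict[str, classifier.ASECall] = {}
    dispositions: dict[str, str] = {g: "low_count" for g in dropped_low}
    for gene_id in m.genes:
        lfc = table.gene_log2fc(gene_id)
        if gene_id not in gated:
            dispositions[gene_id] = "gated_out"
            continue
        gm = genes.get(gene_id)
        if depth_by_chrom is not None and gm is not None:
            depth = depth_by_chrom.get(gm.chrom, {})
            if not expression.exon_coverage_filter(gm, depth, cfg.min_exon_depth):
                dispositions[gene_id] = "coverage_fail"
                continue
        call = classifier.call_gene(
            gene_id, lfc, family, cfg.thresholds, gate_passed=True, mode=cfg.mode
        )
        if call.category is ASECategory.NONE:
            dispositions[gene_id] = "none"
        else:
            dispositions[gene_id] = "classified"
            calls[gene_id] = call

    # --- variant matching ---
    matches: dict[str, list[variants.PatternMatch]] = {}
    phase_support: dict[str, Optional[bool]] = {}
    if cfg.vcf and genes:
        all_variants = [
            variants.apply_hard_filters(v)
            for v in read_vcf(cfg.vcf, family)
        ]
        for gene_id, call in calls.items():
            gm = genes.get(gene_id)
            if gm is None:
                continue
            ms = variants.scan_gene(
                call, all_variants, gm, family,
                flank_bp=cfg.flank_bp, pass_only=cfg.pass_only,
            )
            matches[gene_id] = ms
            if call.category in classifier.REFINEMENTS and ms:
                variants.resolve_orientation(call, ms)
            # --- phasing ---
            blocks = phasing.phase_region_with_extension(
                gm, all_variants, family,
                flank_bp=cfg.flank_bp, min_sites=cfg.min_sites,
                switch_support=cfg.switch_support,
                max_extension=cfg.max_extension, step=cfg.extension_step,
                pass_only=cfg.pass_only,
            )
            phase_support[gene_id] = phasing.phase_supports_call(
                blocks, call, family
            )

    # --- TFBS / rSNP nomination ---
    candidates: list[tfbs_mod.RSNPCandidate] = []
    if cfg.tfbs and matches:
        sites = tfbs_mod.load_tfbs_bed(cfg.tfbs)
        sequences = None
        if cfg.sites_fasta:
            import pyfaidx

            sequences = pyfaidx.Fasta(cfg.sites_fasta)
        candidates = tfbs_mod.nominate_rsnps(calls, matches, sites, sequences)

    # --- report ---
    rows = []
    cand_by_gene: dict[str, int] = {}
    for c in candidates:
        cand_by_gene[c.gene_id] = cand_by_gene.get(c.gene_id, 0) + 1
    for gene_id in m_raw.genes:
        disp = dispositions.get(gene_id, "none")
        call = calls.get(gene_id)
        ms = matches.get(gene_id, [])
        zone_counts = {z: 0 for z in variants.Zone}
        for mm in ms:
            zone_counts[mm.zone] += 1
        rows.append(
            {
                "gene_id": gene_id,
                "disposition": disp,
                "category": call.category.value if call else "NONE",
                "refined": call.resolved.value if call and call.resolved else "",
                "mother_log2fc": (
                    round(call.mother_log2fc, 4) if call else ""
                ),
                "states": (
                    ",".join(
                        call.states[i].value
                        for i in family.individuals
                        if i in call.states
                    )
                    if call and call.states
                    else ""
                ),
                "n_exon": zone_counts[variants.Zone.EXON],
                "n_intron": zone_counts[variants.Zone.INTRON],
                "n_flank": zone_counts[variants.Zone.FLANK],
                "phase_support": {
                    True: "yes", False: "no", None: "indeterminate"
                }[phase_support.get(gene_id)],
                "n_rsnp_candidates": cand_by_gene.get(gene_id, 0),
            }
        )
    report = pd.DataFrame(rows)
    report.to_csv(out / "report.tsv", sep="\t", index=False)

    match_rows = []
    for gene_id, ms in matches.items():
        for mm in ms:
            match_rows.append(
                {
                    "gene_id": gene_id,
                    "category": calls[gene_id].category.value,
                    "refined": mm.refined.value if mm.refined else "",
                    "chrom": mm.variant.chrom,
                    "pos": mm.variant.pos,
                    "ref": mm.variant.ref,
                    "alt": mm.variant.alt,
                    "zone": mm.zone.value,
                    "orientation": mm.orientation.value,
                    "n_consistent": mm.n_consistent,
                }
            )
    pd.DataFrame(
        match_rows,
        columns=["gene_id", "category", "refined", "chrom", "pos", "ref",
                 "alt", "zone", "orientation", "n_consistent"],
    ).to_csv(out / "matches.tsv", sep="\t", index=False)
    variants.summarize_matches(calls, matches).to_csv(
        out / "match_summary.tsv", sep="\t"
    )

    cand_rows = [
        {
            "gene_id": c.gene_id,
            "tf_name": c.tf_name,
            "chrom": c.variant.chrom,
            "pos": c.variant.pos,
            "zone": c.zone.value,
            "ref_match_score": c.ref_match_score,
            "alt_match_score": c.alt_match_score,
            "note": c.note,
        }
        for c in candidates
    ]
    pd.DataFrame(
        cand_rows,
        columns=["gene_id", "tf_name", "chrom", "pos", "zone",
                 "ref_match_score", "alt_match_score", "note"],
    ).to_csv(out / "rsnp_candidates.tsv", sep="\t", index=False)
    tfbs_mod.summarize_candidates(calls, candidates).to_csv(
        out / "rsnp_summary.tsv", sep="\t"
    )
    return report
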