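"""End-to-end orchestration: config validation, staged execution, manifest.

Stage order mirrors the discovery funnel: load inputs -> discard zero-allele
records -> resolve CNV-adjusted nulls -> exact binomial tests + BH -> region
filters -> frequency classification and effect statistics -> LD/GWAS
integration -> optional permutation enrichment.  Every stage logs its
input/output record counts and the run manifest ties each output table to
the inputs (checksums) and parameters that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .annotation_effects import (
    annotate_as_snps,
    annotations_to_frame,
    compare_common_rare_effects,
    tf_detection_coverage,
)
from .as_detection import call_as_snps, resolve_nulls
from .ld_gwas_integration import (
    expand_with_proxies,
    group_into_loci,
    intersect_as_with_catalog,
    permutation_enrichment,
    target_ids_from_expansions,
)
from .region_filters import apply_region_filters, expand_intervals
from .variant_io import (
    read_bed,
    read_catalog,
    read_cnv_regions,
    read_counts_table,
    read_frequency_table,
    read_het_snps,
    read_proxy_table,
    counts_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts_path: str
    het_snps_path: str
    cnv_path: Optional[str] = None
    gap_path: Optional[str] = None
    blacklist_path: Optional[str] = None
    frequency_path: Optional[str] = None
    catalog_path: Optional[str] = None
    proxy_path: Optional[str] = None
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    alpha: float = 0.05
    common_af_threshold: float = 0.01
    r2_threshold: float = 0.8
    locus_window: int = 1_000_000
    gap_flank: int = 1_000_000
    blacklist_flank: int = 100
    n_permutations: int = 0
    seed: int = 0
    bh_family: str = "per_dataset"


def validate_config(config: PipelineConfig) -> list[str]:
    """Return the list of violations; an empty list means the config is ok."""
    v: list[str] = []
    if not (0.0 < config.alpha < 1.0):
        v.append(f"alpha must be in (0, 1), got {config.alpha}")
    if not (0.0 <= config.common_af_threshold <= 1.0):
        v.append(f"common_af_threshold must be in [0, 1], got {config.common_af_threshold}")
    if not (0.0 <= config.r2_threshold < 1.0):
        v.append(f"r2_threshold must be in [0, 1), got {config.r2_threshold}")
    for name in ("locus_window", "gap_flank", "blacklist_flank", "n_permutations"):
        if getattr(config, name) < 0:
            v.append(f"{name} must be >= 0")
    if config.bh_family not in ("per_dataset", "global"):
        v.append(f"bh_family must be per_dataset or global, got {config.bh_family}")
    for name in ("counts_path", "het_snps_path"):
        if not Path(getattr(config, name)).exists():
            v.append(f"{name} does not exist: {getattr(config, name)}")
    for name in ("cnv_path", "gap_path", "blacklist_path", "frequency_path", "catalog_path", "proxy_path"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            v.append(f"{name} does not exist: {p}")
    return v


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, output_dir: str | Path) -> dict:
    """Execute the full AS-SNP discovery funnel and write all result tables.

    Returns the run manifest (also written as ``manifest.json``).  Result
    tables are deterministic under (inputs, config, seed); the manifest
    additionally records a timestamp.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}

    # --- load ---------------------------------------------------------------
    counts = counts_to_frame(read_counts_table(config.counts_path))
    snps = read_het_snps(config.het_snps_path)
    snp_by_id = {s.snp_id: s for s in snps}
    cnvs = read_cnv_regions(config.cnv_path) if config.cnv_path else []
    gaps = read_bed(config.gap_path) if config.gap_path else []
    blacklist = read_bed(config.blacklist_path) if config.blacklist_path else []
    freq = read_frequency_table(config.frequency_path) if config.frequency_path else {}
    catalog = read_catalog(config.catalog_path) if config.catalog_path else []
    proxies = read_proxy_table(config.proxy_path) if config.proxy_path else []
    stage_counts["input_count_records"] = len(counts)
    stage_counts["input_het_snps"] = len(snps)
    logger.info("loaded %d count records at %d het SNPs", len(counts), len(snps))

    # --- nulls, tests, BH ---------------------------------------------------
    nullspecs = resolve_nulls(snps, cnvs)
    results, as_ids, discarded = call_as_snps(
        counts, nullspecs, alpha=config.alpha, bh_family=config.bh_family
    )
    stage_counts["discarded_zero_allele"] = discarded["zero_allele"]
    stage_counts["discarded_not_testable"] = discarded["not_testable"]
    stage_counts["tested_pairs"] = len(results)
    stage_counts["as_snps_pre_filter"] = len(as_ids)
    logger.info("tested %d pairs; %d candidate AS-SNPs", len(results), len(as_ids))
    results.to_csv(outdir / "tests.tsv", sep="\t", index=False)

    # --- region filters on the candidates ------------------------------------
    chrom_sizes = dict(config.chrom_sizes)
    if not chrom_sizes:
        # derive loose bounds from the observed geometry
        for iv in gaps + blacklist + [c.interval for c in cnvs]:
            chrom_sizes[iv.chrom] = max(chrom_sizes.get(iv.chrom, 0), iv.end)
        for s in snps:
            chrom_sizes[s.chrom] = max(chrom_sizes.get(s.chrom, 0), s.pos + 1)
    gap_x = expand_intervals(gaps, config.gap_flank, chrom_sizes)
    black_x = expand_intervals(blacklist, config.blacklist_flank, chrom_sizes)
    candidates = [snp_by_id[i] for i in sorted(as_ids) if i in snp_by_id]
    retained, report = apply_region_filters(candidates, gap_x, black_x, nullspecs)
    stage_counts["as_snps_post_filter"] = len(retained)
    pd.DataFrame(
        [("input", report.input_count)]
        + sorted(report.removed_by_reason.items())
        + [("output", report.output_count)],
        columns=["stage", "count"],
    ).to_csv(outdir / "filter_report.tsv", sep="\t", index=False)

    # --- annotation ----------------------------------------------------------
    retained_ids = {s.snp_id for s in retained}
    kept_results = results[results["snp_id"].isin(retained_ids) | ~results["significant"]]
    cell_line = snps[0].cell_line if snps else "unknown"
    annotations = annotate_as_snps(
        kept_results[kept_results["snp_id"].isin(retained_ids)],
        freq,
        cell_line,
        common_threshold=config.common_af_threshold,
    )
    ann_frame = annotations_to_frame(annotations)
    ann_frame.to_csv(outdir / "as_snps.tsv", sep="\t", index=False)
    stage_counts["annotated_as_snps"] = len(annotations)

    common = [a.effect_ratio for a in annotations if a.freq_class == "common"]
    rare = [a.effect_ratio for a in annotations if a.freq_class == "rare"]
    if len(common) >= 2 and len(rare) >= 2:
        cmp_result = compare_common_rare_effects(common, rare)
        pd.DataFrame(
            [dataclasses.asdict(cmp_result)]
        ).to_csv(outdir / "common_rare_effects.tsv", sep="\t", index=False)

    sig = kept_results[kept_results["snp_id"].isin(retained_ids) & kept_results["significant"]]
    if len(sig):
        tf_detection_coverage(sig).to_csv(outdir / "tf_coverage.tsv", sep="\t", index=False)

    # --- LD / GWAS integration ----------------------------------------------
    if catalog:
        expansions = expand_with_proxies(catalog, proxies, threshold=config.r2_threshold)
        network = intersect_as_with_catalog(retained_ids, expansions)
        pd.DataFrame(
            network.edges, columns=["as_snp", "index_snp", "r2", "trait"]
        ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        stage_counts["catalog_direct_hits"] = network.n_direct_hits
        stage_counts["catalog_ld_hits"] = network.n_ld_hits
        hit_indices = {e[1] for e in network.edges}
        loci = group_into_loci(
            [c for c in catalog if c.snp_id in hit_indices], window=config.locus_window
        )
        pd.DataFrame(
            [
                (l.trait, l.chrom, l.span.start, l.span.end, len(l.member_index_snps), ",".join(l.member_index_snps))
                for l in loci
            ],
            columns=["trait", "chrom", "start", "end", "n_index_snps", "index_snps"],
        ).to_csv(outdir / "loci.tsv", sep="\t", index=False)
        stage_counts["as_loci"] = len(loci)

        if config.n_permutations > 0:
            pool = sorted(set(snp_by_id) - retained_ids)
            enr = permutation_enrichment(
                retained_ids,
                pool,
                target_ids_from_expansions(expansions),
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            pd.DataFrame(
                [
                    {
                        "observed_overlap": enr.observed_overlap,
                        "mean_null_overlap": float(enr.null_overlaps.mean()),
                        "fold": enr.fold,
                        "empirical_p": enr.empirical_p,
                        "n_permutations": enr.n_permutations,
                        "seed": enr.seed,
                    }
                ]
            ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # --- manifest -------------------------------------------------------------
    input_paths = {
        name: getattr(config, name)
        for name in (
            "counts_path", "het_snps_path", "cnv_path", "gap_path",
            "blacklist_path", "frequency_path", "catalog_path", "proxy_path",
        )
        if getattr(config, name) is not None
    }
    manifest = {
        "tool_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": dataclasses.asdict(config),
        "input_checksums": {k: _sha256(v) for k, v in input_paths.items()},
        "stage_counts": stage_counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
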