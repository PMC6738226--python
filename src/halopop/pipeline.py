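"""End-to-end pipeline: simulate -> variants -> LD -> PCA -> trees -> MAT locus.

Runs the full recombination-detection analysis chain on a simulated (or
pre-loaded) haploid dataset and writes a consolidated JSON report with
a stable schema: SNP density, clonal-lineage partition, MSN edge count,
PC1/PC2 percent variance, LD decay summary, majority-split count,
synteny summary, and CAAX hits.  Stages that cannot run (e.g. no
variation when mu = 0) are marked skipped with a reason; every report
key is always present.  Identical config + seed yields an identical
report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from typing import Any

from . import ldstats, matlocus, ordination, simpop, treescan, variants

logger = logging.getLogger("halopop.pipeline")

REPORT_KEYS = [
    "seed",
    "n_samples",
    "n_snps",
    "snp_density_percent",
    "clonal_lineages",
    "msn",
    "pca",
    "ld",
    "gene_trees",
    "synteny",
    "caax",
]


@dataclasses.dataclass
class PipelineConfig:
    """Parameters for one pipeline run (see module docstring)."""

    sim: simpop.SimConfig
    out_dir: str
    clone_threshold: int = 200
    ld_max_distance: int = 10_000
    ld_bin_width: int = 100
    ld_statistic: str = "r2"
    ld_smoother: str = "gam"
    loess_span: float = 0.5
    pca_axes: int = 2
    tree_model: str = "K2P"
    min_alignment_length: int = 200
    min_mean_diff: float = 15.0
    anchor_k: int = 20
    proteins: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(matlocus.PHEROMONE_PRECURSORS)
    )
    log_level: str = "INFO"

    def validate(self) -> None:
        self.sim.validate()
        if self.clone_threshold <= 0:
            raise ValueError("clone_threshold must be positive")
        if self.ld_statistic not in {"r2", "D_prime"}:
            raise ValueError("ld_statistic must be 'r2' or 'D_prime'")
        if self.ld_max_distance < 1 or self.ld_bin_width < 1:
            raise ValueError("LD window and bin width must be positive")
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")
        if self.anchor_k < 8:
            raise ValueError("anchor_k must be >= 8")


def _skipped(reason: str) -> dict[str, Any]:
    return {"skipped": reason}


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages in dependency order and write report.json.

    Returns the report dict. Stage failures that are data-dependent
    (no SNPs, too few LD pairs, no trees passing the filter) are
    recorded as skips, not errors.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict[str, Any] = {k: None for k in REPORT_KEYS}
    report["seed"] = config.sim.seed

    t0 = time.perf_counter()
    dataset = simpop.simulate_population(config.sim)
    simpop.write_dataset(dataset, os.path.join(config.out_dir, "dataset"))
    logger.info("simulate: %.2fs", time.perf_counter() - t0)

    gm = dataset.genotypes
    report["n_samples"] = gm.n_samples
    report["n_snps"] = gm.n_loci
    report["snp_density_percent"] = variants.snp_density(
        gm, config.sim.total_length
    )

    if gm.n_loci == 0:
        no_var = _skipped("no variation")
        report["clonal_lineages"] = no_var
        report["msn"] = no_var
        report["pca"] = no_var
        report["ld"] = no_var
    else:
        t0 = time.perf_counter()
        dist = variants.pairwise_differences(gm)
        clusters = variants.clonal_clusters(dist, config.clone_threshold)
        msn = variants.minimum_spanning_network(dist, config.clone_threshold)
        report["clonal_lineages"] = {
            "threshold": config.clone_threshold,
            "n_lineages": clusters.n_clusters,
            "partition": clusters.partition,
        }
        report["msn"] = {"n_nodes": msn.n_nodes, "n_edges": msn.n_edges}
        logger.info("distances/clusters/msn: %.2fs", time.perf_counter() - t0)

        t0 = time.perf_counter()
        pc = ordination.pca(gm, n_axes=config.pca_axes)
        report["pca"] = {
            "percent_variance": [float(v) for v in pc.percent_variance],
            "n_axes": pc.n_axes,
        }
        logger.info("pca: %.2fs", time.perf_counter() - t0)

        t0 = time.perf_counter()
        bi = ldstats.biallelic_loci(gm)
        pairs = list(
            ldstats.enumerate_pairs(bi, max_distance=config.ld_max_distance)
        )
        if len(pairs) < 20:
            report["ld"] = _skipped(
                f"only {len(pairs)} informative pairs within "
                f"{config.ld_max_distance} bp"
            )
        else:
            est = ldstats.decay_summary(
                pairs,
                statistic=config.ld_statistic,
                bin_width=config.ld_bin_width,
                smoother=config.ld_smoother,
                span=config.loess_span,
                max_distance=config.ld_max_distance,
            )
            report["ld"] = {
                "statistic": config.ld_statistic,
                "n_pairs": len(pairs),
                "max_mean": est.max_mean,
                "half_max": est.half_max,
                "left_border": est.left_border,
                "right_border": est.right_border,
                "decay_distance": est.decay_distance,
                "censored": est.censored,
            }
        logger.info("ld: %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    trees, consensus = treescan.gene_tree_survey(
        dataset.gene_alignments,
        model=config.tree_model,
        min_length=config.min_alignment_length,
        min_mean_diff=config.min_mean_diff,
    )
    if consensus is None:
        report["gene_trees"] = _skipped(
            f"only {len(trees)} alignments passed the filter"
        )
    else:
        topologies = {treescan.topology_key(t) for t in trees}
        report["gene_trees"] = {
            "n_trees": consensus.n_trees,
            "n_distinct_topologies": len(topologies),
            "n_majority_splits": consensus.n_majority_splits,
        }
        consensus.consensus_tree.write(
            path=os.path.join(config.out_dir, "consensus.nwk"),
            schema="newick",
        )
    logger.info("gene trees: %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    inv = [s for s, f in dataset.truth.inverted.items() if f]
    ref = [s for s, f in dataset.truth.inverted.items() if not f]
    if dataset.locus_sequences and inv and ref:
        rep = matlocus.chain_and_report(
            matlocus.find_anchors(
                dataset.locus_sequences[inv[0]],
                dataset.locus_sequences[ref[0]],
                k=config.anchor_k,
            )
        )
        report["synteny"] = {
            "query": inv[0],
            "subject": ref[0],
            **rep.to_dict(),
        }
    else:
        report["synteny"] = _skipped("no two-orientation mating locus")
    logger.info("synteny: %.2fs", time.perf_counter() - t0)

    hits = [
        matlocus.caax_scan(seq, sequence_id=sid)
        for sid, seq in config.proteins.items()
    ]
    report["caax"] = {
        "n_scanned": len(hits),
        "n_caax": sum(h.is_caax for h in hits),
        "hits": [
            {
                "sequence_id": h.sequence_id,
                "is_caax": h.is_caax,
                "terminal_residues": h.terminal_residues,
            }
            for h in hits
        ],
    }

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
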