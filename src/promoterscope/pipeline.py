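"""End-to-end pipeline driver: cluster -> classify -> enrich -> profile."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import cage_tss, chip_signal, occupancy
from .cage_tss import GeneModel
from .chip_signal import StrandedStopTrack
from .config import PipelineConfig
from .errors import PromoterscopeError
from .io_formats import (
    write_bedgraph,
    write_class_results,
    write_clusters_bed,
    write_counts_json,
    write_promoters_tsv,
)
from .promoter_classes import MotifDefinition, classify_set

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except PromoterscopeError as exc:
                raise PromoterscopeError(f"stage {name!r} failed: {exc}") from exc
            return out
        return inner
    return wrap


def run_pipeline(
    genome: Mapping[str, str],
    tags: pd.DataFrame,
    genes: Sequence[GeneModel],
    motifs: Sequence[MotifDefinition],
    outdir,
    config: PipelineConfig | None = None,
    ip_fragments: pd.DataFrame | None = None,
    input_fragments: pd.DataFrame | None = None,
    nexus: StrandedStopTrack | None = None,
) -> dict:
    """Run the full promoter pipeline and write outputs to ``outdir``.

    Always produces re-annotated promoters (``promoters.tsv``,
    ``clusters.bed``), classification (``classes.tsv``, ``counts.json``)
    and the resolved config (``config.yaml``).  When ChIP-seq fragments
    are supplied, adds the SES-scaled log2 enrichment track, heatmap
    matrix, metaprofile and expression-quantile summary; when a nexus
    stop track is supplied, adds stranded metaprofiles and per-class
    score summaries.  Returns a dict of the in-memory results.
    """
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    summary: dict = {"config_hash": cfg.config_hash()}

    # --- stage: cluster-tss
    track = _stage("cluster-tss")(cage_tss.count_five_prime_ends)(tags)
    logger.info("cluster-tss: %d tags in", int(track.total_tags))
    tpm = cage_tss.tpm_normalize(track)
    clusters = cage_tss.cluster_tags(tpm, max_gap=cfg.max_gap)
    filtered = cage_tss.apply_cluster_filters(
        clusters, cfg.singleton_min_tpm, cfg.min_cluster_tpm
    )
    logger.info(
        "cluster-tss: %d clusters, %d after filters", len(clusters), len(filtered)
    )
    promoters = cage_tss.reannotate_gene_tss(
        filtered, genes, cfg.search_upstream, cfg.search_downstream
    )
    active = cage_tss.select_active(promoters, min_tpm=cfg.min_active_tpm)
    logger.info(
        "cluster-tss: %d genes re-annotated, %d active", len(promoters), len(active)
    )
    write_clusters_bed(filtered, outdir / "clusters.bed")
    write_promoters_tsv(active, outdir / "promoters.tsv")
    summary["n_clusters"] = len(filtered)
    summary["n_active_promoters"] = len(active)

    # --- stage: classify
    results, counts = _stage("classify")(classify_set)(active, genome, motifs)
    write_class_results(results, outdir / "classes.tsv")
    write_counts_json(
        counts,
        outdir / "counts.json",
        config_hash=cfg.config_hash(),
        labels_are_per_label=True,
        motif_source=sorted({m.source for m in motifs}),
    )
    labels = {r.gene_id: r.labels for r in results}
    summary["class_counts"] = counts

    # --- stage: enrich + profile (ChIP-seq)
    if ip_fragments is not None and input_fragments is not None:
        ip_cov = _stage("enrich")(chip_signal.coverage_from_fragments)(
            ip_fragments, chrom_sizes
        )
        input_cov = chip_signal.coverage_from_fragments(input_fragments, chrom_sizes)
        scale, k_star = chip_signal.ses_scale(
            ip_cov, input_cov, bin_size=cfg.ses_bin_size
        )
        enrich = chip_signal.log2_enrichment(
            ip_cov, input_cov, scale, pseudocount=cfg.pseudocount
        )
        write_bedgraph(enrich, outdir / "enrich.bedgraph")
        with open(outdir / "ses.json", "w") as fh:
            json.dump({"scale": scale, "k_star": k_star}, fh, indent=2)
        matrix = occupancy.signal_matrix(enrich, active, flank=cfg.heatmap_flank)
        matrix.to_frame().to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
        offsets, profile = occupancy.metaprofile(matrix)
        pd.DataFrame({"offset": offsets, "mean": profile}).to_csv(
            outdir / "metaprofile_chipseq.tsv", sep="\t", index=False
        )
        scores = occupancy.promoter_score_max(
            enrich, active, window=cfg.chipseq_score_window
        )
        scored = [p for p in active if p.gene_id in scores]
        quantiles = occupancy.expression_quantiles(
            scored, scores, n=min(cfg.n_quantiles, max(2, len(scored)))
        )
        pd.DataFrame(
            [
                {"quantile": q.index, "n": len(q.gene_ids),
                 "median": q.median, "q1": q.q1, "q3": q.q3}
                for q in quantiles
            ]
        ).to_csv(outdir / "quantiles_chipseq.tsv", sep="\t", index=False)
        occupancy.per_class_summary(scores, labels).to_csv(
            outdir / "class_summary_chipseq.tsv", sep="\t"
        )
        summary["ses_scale"] = scale
        summary["quantile_medians"] = [q.median for q in quantiles]

    # --- stage: profile (ChIP-nexus)
    if nexus is not None:
        rpm = _stage("profile")(chip_signal.rpm_normalize)(nexus)
        flank = cfg.metaprofile_window // 2
        matrix = occupancy.signal_matrix(rpm, active, flank=flank)
        offs, sense, anti = occupancy.metaprofile(matrix)
        pd.DataFrame(
            {"offset": offs, "sense": sense, "antisense_display": -anti}
        ).to_csv(outdir / "metaprofile_nexus.tsv", sep="\t", index=False)
        nexus_scores = occupancy.promoter_score_sum(
            rpm, active, window=cfg.nexus_score_window
        )
        occupancy.per_class_summary(nexus_scores, labels).to_csv(
            outdir / "class_summary_nexus.tsv", sep="\t"
        )
        summary["n_nexus_scored"] = len(nexus_scores)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return summary
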