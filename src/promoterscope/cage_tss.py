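"""CAGE 5' tag tracks, TSS tag clustering and gene TSS re-annotation.

CAGE (Cap Analysis of Gene Expression) sequences capped transcript 5' ends,
so every aligned read start marks a transcription start position.  This
module turns collections of single-base 5'-end tags into per-strand count
tracks, normalizes them to tags-per-million (TPM), merges nearby positions
into tag clusters with a single-linkage distance rule, applies
expression-level filters, and re-annotates gene model TSSs with the
dominant (highest-TPM) position of the best supporting cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyLibraryError,
    InputError,
    ParameterError,
    ValidationError,
)

STRANDS = ("+", "-")

__all__ = [
    "TssTagTrack",
    "TagCluster",
    "GeneModel",
    "PromoterRecord",
    "count_five_prime_ends",
    "tpm_normalize",
    "cluster_tags",
    "apply_cluster_filters",
    "reannotate_gene_tss",
    "select_active",
]


@dataclass
class TssTagTrack:
    """Per-chromosome, per-strand single-base 5'-tag counts.

    ``data`` maps ``(chrom, strand)`` to parallel sorted ``positions`` /
    ``counts`` arrays; absent positions are zero.  ``normalized`` is False
    for raw tag counts and True once counts are expressed in TPM.
    """

    data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    total_tags: float = 0.0
    normalized: bool = False

    def keys(self) -> Iterable[tuple[str, str]]:
        return self.data.keys()

    def positions(self, chrom: str, strand: str) -> np.ndarray:
        return self.data.get((chrom, strand), (np.empty(0, int), np.empty(0)))[0]

    def counts(self, chrom: str, strand: str) -> np.ndarray:
        return self.data.get((chrom, strand), (np.empty(0, int), np.empty(0)))[1]

    def sum(self) -> float:
        return float(sum(c.sum() for _, c in self.data.values()))

    def n_positions(self) -> int:
        return int(sum(len(p) for p, _ in self.data.values()))


@dataclass
class TagCluster:
    """A run of TSS positions merged by the single-linkage gap rule.

    ``members`` holds genomically sorted positions with their TPM values.
    ``dominant_tss`` is the member with maximal TPM; ties go to the most
    upstream member in gene orientation (smallest coordinate on ``+``,
    largest on ``-``).
    """

    chrom: str
    strand: str
    member_positions: np.ndarray
    member_tpms: np.ndarray

    def __post_init__(self) -> None:
        self.member_positions = np.asarray(self.member_positions, dtype=np.int64)
        self.member_tpms = np.asarray(self.member_tpms, dtype=float)

    @property
    def span_start(self) -> int:
        return int(self.member_positions[0])

    @property
    def span_end(self) -> int:
        return int(self.member_positions[-1])

    @property
    def total_tpm(self) -> float:
        return float(self.member_tpms.sum())

    @property
    def singleton(self) -> bool:
        return len(self.member_positions) == 1

    @property
    def dominant_tss(self) -> int:
        tpms = self.member_tpms
        best = tpms.max()
        tied = self.member_positions[tpms == best]
        # most upstream in gene orientation on ties
        return int(tied.min() if self.strand == "+" else tied.max())

    def __len__(self) -> int:
        return len(self.member_positions)


@dataclass(frozen=True)
class GeneModel:
    """A gene span in 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise InputError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise InputError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end})"
            )

    @property
    def annotated_tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PromoterRecord:
    """A gene promoter with a CAGE re-annotated TSS and expression level."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    expression_tpm: float
    source_cluster: TagCluster | None = None

    def __post_init__(self) -> None:
        if self.expression_tpm < 0:
            raise InputError(
                f"promoter {self.gene_id}: negative expression "
                f"{self.expression_tpm}"
            )


def _tags_to_frame(tags) -> pd.DataFrame:
    if isinstance(tags, pd.DataFrame):
        frame = tags[["chrom", "strand", "pos"]].copy()
    else:
        frame = pd.DataFrame(list(tags), columns=["chrom", "strand", "pos"])
    return frame


def count_five_prime_ends(tags) -> TssTagTrack:
    """Tally single-base 5' ends into a raw :class:`TssTagTrack`.

    ``tags`` is an iterable of ``(chrom, strand, pos)`` tuples or a
    DataFrame with those columns.  Counts equal the multiplicity of each
    ``(chrom, strand, pos)`` triple; ``total_tags`` is the input size.
    """
    frame = _tags_to_frame(tags)
    if len(frame) == 0:
        return TssTagTrack(data={}, total_tags=0.0, normalized=False)

    bad_strand = ~frame["strand"].isin(STRANDS)
    if bad_strand.any():
        i = int(np.flatnonzero(bad_strand.to_numpy())[0])
        rec = frame.iloc[i]
        raise InputError(
            f"tag record {i}: malformed strand {rec['strand']!r} "
            f"(chrom={rec['chrom']}, pos={rec['pos']})"
        )
    pos = frame["pos"].to_numpy()
    if (pos < 0).any():
        i = int(np.flatnonzero(pos < 0)[0])
        rec = frame.iloc[i]
        raise InputError(
            f"tag record {i}: negative position {rec['pos']} "
            f"(chrom={rec['chrom']}, strand={rec['strand']})"
        )

    data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    grouped = frame.groupby(["chrom", "strand"], sort=True)["pos"].value_counts()
    for (chrom, strand), sub in grouped.groupby(level=[0, 1]):
        positions = sub.index.get_level_values("pos").to_numpy(dtype=np.int64)
        counts = sub.to_numpy(dtype=float)
        order = np.argsort(positions)
        data[(chrom, strand)] = (positions[order], counts[order])
    return TssTagTrack(data=data, total_tags=float(len(frame)), normalized=False)


def tpm_normalize(track: TssTagTrack) -> TssTagTrack:
    """Convert raw tag counts to tags per million (count / library * 1e6)."""
    if track.normalized:
        raise UnitErrorAlready()
    if track.total_tags <= 0:
        raise EmptyLibraryError("cannot TPM-normalize an empty library")
    factor = 1e6 / track.total_tags
    data = {
        key: (pos.copy(), counts * factor) for key, (pos, counts) in track.data.items()
    }
    return TssTagTrack(data=data, total_tags=track.total_tags, normalized=True)


class UnitErrorAlready(ParameterError):
    def __init__(self) -> None:
        super().__init__("track is already TPM-normalized")


def cluster_tags(track: TssTagTrack, max_gap: int = 40) -> list[TagCluster]:
    """Single-linkage clustering of TSS positions within ``max_gap`` bp.

    Positions on the same chromosome and strand whose nearest-neighbour
    gap is <= ``max_gap`` are chained into one cluster (the distance rule
    used for CAGE tag clusters).  Requires a TPM-normalized track.
    """
    if max_gap < 0:
        raise ParameterError(f"max_gap must be >= 0, got {max_gap}")
    if not track.normalized:
        raise ParameterError("cluster_tags requires a TPM-normalized track")

    clusters: list[TagCluster] = []
    for (chrom, strand) in sorted(track.data):
        positions, tpms = track.data[(chrom, strand)]
        if len(positions) == 0:
            continue
        breaks = np.flatnonzero(np.diff(positions) > max_gap) + 1
        for seg_pos, seg_tpm in zip(
            np.split(positions, breaks), np.split(tpms, breaks)
        ):
            clusters.append(TagCluster(chrom, strand, seg_pos, seg_tpm))
    return clusters


def apply_cluster_filters(
    clusters: Sequence[TagCluster],
    singleton_min_tpm: float = 5.0,
    min_cluster_tpm: float = 12.0,
) -> list[TagCluster]:
    """Drop weak singleton clusters, then non-expressed clusters.

    Singletons (one TSS position) are discarded unless their TPM is at or
    above ``singleton_min_tpm``; afterwards only clusters with at least
    ``min_cluster_tpm`` summed over all member positions are kept as
    expressed.  Input order is preserved.
    """
    kept = [
        c
        for c in clusters
        if not (c.singleton and c.total_tpm < singleton_min_tpm)
    ]
    return [c for c in kept if c.total_tpm >= min_cluster_tpm]


def _validate_non_overlapping(genes: Sequence[GeneModel]) -> None:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    offenders = []
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.start, g.end))
        for a, b in zip(gs, gs[1:]):
            if b.start < a.end:
                offenders.append((a.gene_id, b.gene_id))
    if offenders:
        raise ValidationError(
            "overlapping gene spans: "
            + ", ".join(f"{a}/{b}" for a, b in offenders)
        )


def reannotate_gene_tss(
    clusters: Sequence[TagCluster],
    genes: Sequence[GeneModel],
    search_upstream: int = 500,
    search_downstream: int = 300,
) -> list[PromoterRecord]:
    """Re-annotate gene TSSs from filtered tag clusters.

    A cluster supports a gene when it lies on the gene's strand and its
    dominant TSS falls within ``search_upstream``/``search_downstream`` bp
    of the annotated TSS, measured in gene orientation.  Each cluster is
    assigned to at most one gene (nearest annotated TSS wins, ties to the
    leftmost gene on the chromosome); each gene then takes the
    highest-total-TPM cluster among those assigned to it.  Genes without a
    supporting cluster are omitted.
    """
    _validate_non_overlapping(genes)

    gene_order = {g.gene_id: i for i, g in enumerate(genes)}
    # cluster -> best gene (distance rule)
    assignment: dict[int, GeneModel] = {}
    candidates: dict[str, list[TagCluster]] = {}
    genes_by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        genes_by_key.setdefault((g.chrom, g.strand), []).append(g)

    for ci, cluster in enumerate(clusters):
        dom = cluster.dominant_tss
        best: tuple[int, int, str] | None = None
        best_gene: GeneModel | None = None
        for g in genes_by_key.get((cluster.chrom, cluster.strand), []):
            tss = g.annotated_tss
            if g.strand == "+":
                lo, hi = tss - search_upstream, tss + search_downstream
            else:
                lo, hi = tss - search_downstream, tss + search_upstream
            if not lo <= dom <= hi:
                continue
            key = (abs(dom - tss), g.start, g.gene_id)
            if best is None or key < best:
                best, best_gene = key, g
        if best_gene is not None:
            assignment[ci] = best_gene

    per_gene: dict[str, list[TagCluster]] = {}
    for ci, g in assignment.items():
        per_gene.setdefault(g.gene_id, []).append(clusters[ci])

    records: list[PromoterRecord] = []
    for g in genes:
        cands = per_gene.get(g.gene_id)
        if not cands:
            continue
        winner = max(
            cands,
            key=lambda c: (c.total_tpm, -abs(c.dominant_tss - g.annotated_tss)),
        )
        records.append(
            PromoterRecord(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand=g.strand,
                tss=winner.dominant_tss,
                expression_tpm=winner.total_tpm,
                source_cluster=winner,
            )
        )
    records.sort(key=lambda r: gene_order[r.gene_id])
    return records


def select_active(
    records: Sequence[PromoterRecord],
    min_tpm: float = 2.0,
    top_n: int | None = None,
) -> list[PromoterRecord]:
    """Keep promoters above ``min_tpm`` (strict), optionally the top N.

    Output is sorted by descending expression; ties break by gene id.
    """
    if top_n is not None and top_n <= 0:
        raise ParameterError(f"top_n must be positive, got {top_n}")
    kept = [r for r in records if r.expression_tpm > min_tpm]
    kept.sort(key=lambda r: (-r.expression_tpm, r.gene_id))
    if top_n is not None:
        kept = kept[:top_n]
    return kept
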