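"""TSS-centered occupancy: matrices, metaprofiles, scores, quantiles.

Everything here works in gene orientation: column offset +k of a matrix is
k bp downstream of the TSS along the direction of transcription, so rows
from minus-strand promoters are flipped (and, for stranded tracks, their
strands swapped) before analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cage_tss import PromoterRecord
from .chip_signal import CoverageTrack, StrandedStopTrack
from .errors import ParameterError, UnitError

logger = logging.getLogger(__name__)

__all__ = [
    "OccupancyMatrix",
    "QuantileSummary",
    "signal_matrix",
    "metaprofile",
    "promoter_score_max",
    "promoter_score_sum",
    "expression_quantiles",
    "sort_rows_by_reference",
    "per_class_summary",
]


@dataclass
class OccupancyMatrix:
    """Promoters x TSS-relative offsets signal matrix.

    ``values`` holds the (sense) signal; for stranded sources
    ``antisense`` holds the opposite-strand signal (stored non-negative —
    any sign flip for display happens at export time).  Row order matches
    the supplied promoter order after dropping out-of-bounds promoters.
    """

    promoter_ids: list[str]
    offsets: np.ndarray
    values: np.ndarray
    antisense: np.ndarray | None = None
    units: str = "raw"

    @property
    def flank(self) -> int:
        return int((len(self.offsets) - 1) // 2)

    def to_frame(self, antisense: bool = False) -> pd.DataFrame:
        data = self.antisense if antisense else self.values
        return pd.DataFrame(data, index=self.promoter_ids, columns=self.offsets)


@dataclass
class QuantileSummary:
    """One expression quantile (1 = highest expression) with its scores."""

    index: int
    gene_ids: list[str]
    scores: np.ndarray
    median: float
    q1: float
    q3: float


def _window_rows(track_values, promoters, flank):
    """Yield (record, window) for promoters whose window fits the contig."""
    for rec in promoters:
        arr = track_values.get(rec.chrom)
        if arr is None:
            continue
        lo, hi = rec.tss - flank, rec.tss + flank
        if lo < 0 or hi >= len(arr):
            yield rec, None
        else:
            yield rec, arr[lo : hi + 1]


def signal_matrix(
    track: CoverageTrack | StrandedStopTrack,
    promoters: Sequence[PromoterRecord],
    flank: int,
) -> OccupancyMatrix:
    """Extract a (2*flank+1)-wide TSS-centered window per promoter.

    Minus-strand rows are reversed into gene orientation; for stranded
    tracks the sense row comes from the promoter's strand and the
    antisense row from the opposite strand.  Promoters whose window runs
    off the contig are dropped (logged).
    """
    if flank < 0:
        raise ParameterError(f"flank must be >= 0, got {flank}")
    offsets = np.arange(-flank, flank + 1)
    stranded = isinstance(track, StrandedStopTrack)
    primary = track.plus if stranded else track.values
    secondary = track.minus if stranded else None

    ids: list[str] = []
    sense_rows: list[np.ndarray] = []
    anti_rows: list[np.ndarray] = []
    dropped = 0
    for rec, win_plus in _window_rows(primary, promoters, flank):
        if win_plus is None:
            dropped += 1
            continue
        if stranded:
            win_minus = secondary[rec.chrom][rec.tss - flank : rec.tss + flank + 1]
            if rec.strand == "+":
                sense, anti = win_plus, win_minus
            else:
                sense, anti = win_minus[::-1], win_plus[::-1]
            anti_rows.append(np.asarray(anti, dtype=float))
        else:
            sense = win_plus if rec.strand == "+" else win_plus[::-1]
        ids.append(rec.gene_id)
        sense_rows.append(np.asarray(sense, dtype=float))
    if dropped:
        logger.info("signal_matrix: dropped %d promoter(s) at contig edges", dropped)

    n = len(ids)
    values = np.vstack(sense_rows) if n else np.empty((0, len(offsets)))
    anti = (
        (np.vstack(anti_rows) if n else np.empty((0, len(offsets))))
        if stranded
        else None
    )
    return OccupancyMatrix(
        promoter_ids=ids,
        offsets=offsets,
        values=values,
        antisense=anti,
        units=track.units,
    )


def metaprofile(matrix: OccupancyMatrix):
    """Per-offset mean across promoters.

    Returns ``(offsets, sense_mean)`` for unstranded matrices and
    ``(offsets, sense_mean, antisense_mean)`` for stranded ones, all
    non-negative; display conventions (antisense below the axis) are
    applied only when exporting.
    """
    if matrix.values.shape[0] == 0:
        raise ParameterError("metaprofile of an empty matrix")
    sense = matrix.values.mean(axis=0)
    if matrix.antisense is not None:
        return matrix.offsets, sense, matrix.antisense.mean(axis=0)
    return matrix.offsets, sense


def _check_odd_window(window: int) -> int:
    if window <= 0 or window % 2 == 0:
        raise ParameterError(
            f"window must be a positive odd width so the TSS is the exact "
            f"center, got {window}"
        )
    return window // 2


def promoter_score_max(
    track: CoverageTrack,
    promoters: Sequence[PromoterRecord],
    window: int = 501,
) -> dict[str, float]:
    """Maximum track value in a TSS-centered odd window per promoter."""
    flank = _check_odd_window(window)
    matrix = signal_matrix(track, promoters, flank)
    return {
        gid: float(row.max())
        for gid, row in zip(matrix.promoter_ids, matrix.values)
    }


def promoter_score_sum(
    track: StrandedStopTrack,
    promoters: Sequence[PromoterRecord],
    window: int = 101,
) -> dict[str, float]:
    """Total plus+minus RPM in a TSS-centered odd window per promoter."""
    if track.units != "RPM":
        raise UnitError(
            f"promoter_score_sum expects an RPM track, got {track.units!r}"
        )
    flank = _check_odd_window(window)
    matrix = signal_matrix(track, promoters, flank)
    return {
        gid: float(s.sum() + a.sum())
        for gid, s, a in zip(matrix.promoter_ids, matrix.values, matrix.antisense)
    }


def expression_quantiles(
    promoters: Sequence[PromoterRecord],
    scores: Mapping[str, float],
    n: int = 10,
) -> list[QuantileSummary]:
    """Split promoters into n expression quantiles and summarize scores.

    Promoters are ranked by descending expression (stable ties by gene id)
    and cut into n near-equal groups — sizes differ by at most one, larger
    groups first — so quantile 1 holds the highest-expressed promoters.
    """
    if n < 2:
        raise ParameterError(f"need at least 2 quantiles, got {n}")
    if n > len(promoters):
        raise ParameterError(
            f"cannot form {n} quantiles from {len(promoters)} promoters"
        )
    ranked = sorted(promoters, key=lambda r: (-r.expression_tpm, r.gene_id))
    base, extra = divmod(len(ranked), n)
    summaries = []
    start = 0
    for q in range(1, n + 1):
        size = base + (1 if q <= extra else 0)
        members = ranked[start : start + size]
        start += size
        vals = np.array([scores[m.gene_id] for m in members], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        summaries.append(
            QuantileSummary(
                index=q,
                gene_ids=[m.gene_id for m in members],
                scores=vals,
                median=float(med),
                q1=float(q1),
                q3=float(q3),
            )
        )
    return summaries


def sort_rows_by_reference(
    matrix: OccupancyMatrix, reference_scores: Mapping[str, float]
) -> OccupancyMatrix:
    """Reorder rows by descending reference score (stable, ties by id).

    Applying the same reference to several factors' matrices keeps rows
    aligned for side-by-side heatmaps.
    """
    missing = [gid for gid in matrix.promoter_ids if gid not in reference_scores]
    if missing:
        raise ParameterError(
            f"reference scores missing for {len(missing)} row(s), "
            f"e.g. {missing[0]!r}"
        )
    order = sorted(
        range(len(matrix.promoter_ids)),
        key=lambda i: (-reference_scores[matrix.promoter_ids[i]], i),
    )
    return OccupancyMatrix(
        promoter_ids=[matrix.promoter_ids[i] for i in order],
        offsets=matrix.offsets,
        values=matrix.values[order],
        antisense=None if matrix.antisense is None else matrix.antisense[order],
        units=matrix.units,
    )


def per_class_summary(
    scores: Mapping[str, float],
    class_labels: Mapping[str, frozenset | set | Sequence[str]],
) -> pd.DataFrame:
    """Median/quartile score per promoter class.

    Multi-label promoters contribute to every class they carry.  Returns a
    DataFrame indexed by class with columns n, median, q1, q3.
    """
    groups: dict[str, list[float]] = {}
    for gid, score in scores.items():
        for label in class_labels.get(gid, ()):
            groups.setdefault(label, []).append(score)
    rows = {}
    for label in sorted(groups):
        vals = np.asarray(groups[label], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows[label] = {"n": len(vals), "median": med, "q1": q1, "q3": q3}
    return pd.DataFrame.from_dict(rows, orient="index")
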