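"""ChIP-seq coverage and ChIP-nexus stop-base tracks, with normalization.

ChIP-seq yields unstranded fragment coverage for an immunoprecipitated
factor plus a matched input control; enrichment is expressed as the log2
ratio of IP over input after SES (signal extraction scaling), which scales
the input so that IP and input agree over the least-enriched (background)
fraction of genomic bins.  ChIP-nexus yields strand-specific single-base
"stop" counts (the lambda-exonuclease barrier at the protein-DNA
boundary), normalized to reads per million (RPM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyLibraryError,
    InputError,
    ParameterError,
    UnitError,
)

__all__ = [
    "CoverageTrack",
    "StrandedStopTrack",
    "coverage_from_fragments",
    "stop_base_track",
    "rpm_normalize",
    "ses_scale",
    "log2_enrichment",
]


@dataclass
class CoverageTrack:
    """Dense per-bp numeric signal per chromosome.

    ``units`` is one of ``raw`` (fragment coverage), ``RPM``, or
    ``log2_ratio``.  ``total_reads`` records the library size used for RPM
    normalization (the number of fragments, not the summed coverage).
    """

    values: dict[str, np.ndarray]
    units: str = "raw"
    total_reads: float | None = None

    @property
    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}


@dataclass
class StrandedStopTrack:
    """Single-base stop counts per strand (ChIP-nexus style)."""

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]
    units: str = "raw"
    total_reads: float = 0.0

    @property
    def total_signal(self) -> float:
        both = list(self.plus.values()) + list(self.minus.values())
        return float(sum(v.sum() for v in both))

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.plus.items()}


def _frame(records, columns) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records[list(columns)]
    return pd.DataFrame(list(records), columns=list(columns))


def coverage_from_fragments(
    fragments, chrom_sizes: Mapping[str, int]
) -> CoverageTrack:
    """Per-bp count of overlapping half-open fragment intervals.

    ``fragments`` is an iterable of ``(chrom, start, end)`` or a DataFrame
    with those columns; intervals must satisfy 0 <= start < end <= contig
    length.
    """
    frame = _frame(fragments, ("chrom", "start", "end"))
    values = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    n_frags = len(frame)
    if n_frags:
        starts = frame["start"].to_numpy()
        ends = frame["end"].to_numpy()
        if (starts >= ends).any():
            i = int(np.flatnonzero(starts >= ends)[0])
            rec = frame.iloc[i]
            raise InputError(
                f"fragment {i}: inverted or empty interval "
                f"[{rec['start']}, {rec['end']}) on {rec['chrom']}"
            )
        if (starts < 0).any():
            raise InputError("fragment with negative start coordinate")
        for chrom, sub in frame.groupby("chrom"):
            if chrom not in values:
                raise InputError(f"fragment on unknown contig {chrom!r}")
            size = chrom_sizes[chrom]
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if (e > size).any():
                raise InputError(f"fragment past end of contig {chrom}")
            diff = np.zeros(size + 1, dtype=float)
            np.add.at(diff, s, 1.0)
            np.add.at(diff, e, -1.0)
            values[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(values=values, units="raw", total_reads=float(n_frags))


def stop_base_track(
    reads, chrom_sizes: Mapping[str, int]
) -> StrandedStopTrack:
    """Tally stranded single-base 5'-end (stop base) counts.

    ``reads`` is an iterable of ``(chrom, strand, pos)`` or a DataFrame
    with those columns.
    """
    frame = _frame(reads, ("chrom", "strand", "pos"))
    plus = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    minus = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    if len(frame):
        bad = ~frame["strand"].isin(("+", "-"))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputError(
                f"read {i}: malformed strand {frame.iloc[i]['strand']!r}"
            )
        if (frame["pos"].to_numpy() < 0).any():
            raise InputError("read with negative position")
        for (chrom, strand), sub in frame.groupby(["chrom", "strand"]):
            target = plus if strand == "+" else minus
            if chrom not in target:
                raise InputError(f"read on unknown contig {chrom!r}")
            pos = sub["pos"].to_numpy()
            if (pos >= chrom_sizes[chrom]).any():
                raise InputError(f"read past end of contig {chrom}")
            np.add.at(target[chrom], pos, 1.0)
    return StrandedStopTrack(
        plus=plus, minus=minus, units="raw", total_reads=float(len(frame))
    )


def rpm_normalize(track):
    """Scale a raw track to reads per million (value * 1e6 / total reads)."""
    if track.units != "raw":
        raise UnitError(f"expected raw units, got {track.units!r}")
    total = track.total_reads
    if not total:
        raise EmptyLibraryError("cannot RPM-normalize an empty library")
    factor = 1e6 / total
    if isinstance(track, StrandedStopTrack):
        return StrandedStopTrack(
            plus={c: v * factor for c, v in track.plus.items()},
            minus={c: v * factor for c, v in track.minus.items()},
            units="RPM",
            total_reads=total,
        )
    return CoverageTrack(
        values={c: v * factor for c, v in track.values.items()},
        units="RPM",
        total_reads=total,
    )


def _bin_sums(track: CoverageTrack, bin_size: int) -> np.ndarray:
    sums = []
    for chrom in sorted(track.values):
        v = track.values[chrom]
        edges = np.arange(0, len(v), bin_size)
        sums.append(np.add.reduceat(v, edges))
    return np.concatenate(sums) if sums else np.empty(0)


def ses_scale(
    ip: CoverageTrack, input_track: CoverageTrack, bin_size: int = 1000
) -> tuple[float, int]:
    """Signal extraction scaling factor for an IP / input track pair.

    The genome is tiled into ``bin_size`` bins; bins are ordered by
    ascending IP sum (ties by ascending input sum, then coordinate) and
    the separation point k* maximizing

        delta(k) = cumInput(k)/totalInput - cumIP(k)/totalIP

    (first maximum) marks the background bin set.  Returns
    ``(r, k_star)`` with ``r = cumIP(k*) / cumInput(k*)``: multiplying the
    input by ``r`` equalizes IP and input over the background bins.  Bins
    empty in both tracks carry no information and are dropped before
    ordering.
    """
    if bin_size <= 0:
        raise ParameterError(f"bin_size must be positive, got {bin_size}")
    for t in (ip, input_track):
        if t.units != "raw":
            raise UnitError("ses_scale expects raw tracks")
    if set(ip.values) != set(input_track.values):
        raise InputError("IP and input tracks cover different contigs")

    ip_sums = _bin_sums(ip, bin_size)
    in_sums = _bin_sums(input_track, bin_size)
    keep = (ip_sums > 0) | (in_sums > 0)
    ip_sums, in_sums = ip_sums[keep], in_sums[keep]
    if len(ip_sums) == 0 or in_sums.sum() == 0 or ip_sums.sum() == 0:
        raise EmptyLibraryError("ses_scale: empty IP or input track")

    coord = np.arange(len(ip_sums))
    order = np.lexsort((coord, in_sums, ip_sums))
    cum_ip = np.cumsum(ip_sums[order]) / ip_sums.sum()
    cum_in = np.cumsum(in_sums[order]) / in_sums.sum()
    delta = cum_in - cum_ip
    k_star = int(np.argmax(delta))  # first maximum
    cum_ip_raw = float(np.cumsum(ip_sums[order])[k_star])
    cum_in_raw = float(np.cumsum(in_sums[order])[k_star])
    if cum_in_raw == 0:
        raise EmptyLibraryError(
            "ses_scale: degenerate background (zero input over background bins)"
        )
    return cum_ip_raw / cum_in_raw, k_star + 1


def log2_enrichment(
    ip: CoverageTrack,
    input_track: CoverageTrack,
    scale: float,
    pseudocount: float = 1.0,
) -> CoverageTrack:
    """Per-bp log2((IP + pc) / (scale * input + pc)) enrichment track."""
    if scale <= 0:
        raise ParameterError(f"scale must be positive, got {scale}")
    if set(ip.values) != set(input_track.values):
        raise InputError("IP and input tracks cover different contigs")
    values = {
        c: np.log2((ip.values[c] + pseudocount)
                   / (scale * input_track.values[c] + pseudocount))
        for c in ip.values
    }
    return CoverageTrack(values=values, units="log2_ratio", total_reads=None)
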