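"""Readers/writers for FASTA, BED, bedGraph, GTF and the package's TSVs.

Tabular formats go through pandas; FASTA through Biopython/pyfaidx.  All
internal coordinates are 0-based half-open; GTF's 1-based inclusive
convention is converted exactly at this boundary.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cage_tss import GeneModel, PromoterRecord, TagCluster
from .chip_signal import CoverageTrack, StrandedStopTrack
from .errors import InputError
from .promoter_classes import ELEMENTS, PromoterClassResult

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tags",
    "write_tags_bed",
    "read_gene_models_gtf",
    "write_gene_models_gtf",
    "read_bed_fragments",
    "write_bed_fragments",
    "read_bedgraph",
    "write_bedgraph",
    "coverage_from_bedgraph",
    "coverage_to_bedgraph_frame",
    "write_promoters_tsv",
    "read_promoters_tsv",
    "write_clusters_bed",
    "write_class_results",
    "write_counts_json",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a chrom -> sequence dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------- CAGE tags

def read_tags(path) -> pd.DataFrame:
    """Read 5'-end tags as a (chrom, strand, pos) frame, one row per tag.

    Accepts single-base BED6 (score column = tag count, positions
    0-based half-open) or a 4-column TSV chrom/strand/pos/count.
    """
    path = Path(path)
    if path.suffix == ".bed":
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        if ((bed["end"] - bed["start"]) != 1).any():
            bad = bed[(bed["end"] - bed["start"]) != 1].index[0]
            raise InputError(f"{path}:{bad + 1}: tag BED records must be single-base")
        frame = bed.rename(columns={"start": "pos", "score": "count"})[
            ["chrom", "strand", "pos", "count"]
        ]
    else:
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "strand", "pos", "count"]
        )
    counts = frame["count"].to_numpy()
    if (counts < 0).any() or (counts != counts.astype(int)).any():
        raise InputError(f"{path}: tag counts must be non-negative integers")
    return frame.loc[frame.index.repeat(counts.astype(int))][
        ["chrom", "strand", "pos"]
    ].reset_index(drop=True)


def write_tags_bed(tags: pd.DataFrame, path) -> None:
    """Write a per-tag frame as single-base BED6 with score = count."""
    counted = (
        tags.groupby(["chrom", "strand", "pos"]).size().reset_index(name="count")
    )
    counted = counted.sort_values(["chrom", "pos", "strand"], kind="stable")
    bed = pd.DataFrame(
        {
            "chrom": counted["chrom"],
            "start": counted["pos"],
            "end": counted["pos"] + 1,
            "name": "tag",
            "score": counted["count"],
            "strand": counted["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------------ GTF

_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_gene_models_gtf(path) -> list[GeneModel]:
    """Read gene features from a GTF (1-based inclusive -> 0-based half-open)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=[
            "seqname", "source", "feature", "start", "end",
            "score", "strand", "frame", "attribute",
        ],
    )
    genes = []
    for i, row in frame[frame["feature"] == "gene"].iterrows():
        m = _GENE_ID_RE.search(row["attribute"])
        if not m:
            raise InputError(f"{path}:{i + 1}: gene record without gene_id")
        genes.append(
            GeneModel(
                gene_id=m.group(1),
                chrom=row["seqname"],
                strand=row["strand"],
                start=int(row["start"]) - 1,
                end=int(row["end"]),
            )
        )
    return genes


def write_gene_models_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\tpromoterscope\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f'{g.strand}\t.\tgene_id "{g.gene_id}";\n'
            )


# ------------------------------------------------------- BED / bedGraph

def read_bed_fragments(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    if (frame["start"] >= frame["end"]).any():
        bad = int(frame.index[frame["start"] >= frame["end"]][0])
        raise InputError(f"{path}:{bad + 1}: inverted or empty interval")
    return frame


def write_bed_fragments(fragments: pd.DataFrame, path) -> None:
    fragments[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    for chrom, sub in frame.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (np.diff(starts) < 0).any():
            raise InputError(f"{path}: bedGraph records for {chrom} not sorted")
        if (starts[1:] < ends[:-1]).any():
            i = int(np.flatnonzero(starts[1:] < ends[:-1])[0])
            raise InputError(
                f"{path}: overlapping bedGraph records on {chrom} near line "
                f"{sub.index[i] + 1}"
            )
    return frame


def coverage_from_bedgraph(
    frame: pd.DataFrame, chrom_sizes: Mapping[str, int], units: str = "raw"
) -> CoverageTrack:
    values = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    for chrom, sub in frame.groupby("chrom"):
        if chrom not in values:
            raise InputError(f"bedGraph record on unknown contig {chrom!r}")
        arr = values[chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[s:e] = v
    return CoverageTrack(values=values, units=units)


def coverage_to_bedgraph_frame(track: CoverageTrack) -> pd.DataFrame:
    """Run-length encode a dense coverage track (zero runs omitted)."""
    rows = []
    for chrom in sorted(track.values):
        v = track.values[chrom]
        if len(v) == 0:
            continue
        change = np.flatnonzero(np.diff(v) != 0) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(v)]])
        for s, e in zip(starts, ends):
            if v[s] != 0:
                rows.append((chrom, int(s), int(e), float(v[s])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(track: CoverageTrack, path) -> None:
    coverage_to_bedgraph_frame(track).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_stop_tracks(path_plus, path_minus, chrom_sizes) -> StrandedStopTrack:
    """Read a stranded bedGraph pair into a raw stop-base track."""
    plus = coverage_from_bedgraph(read_bedgraph(path_plus), chrom_sizes)
    minus = coverage_from_bedgraph(read_bedgraph(path_minus), chrom_sizes)
    total = plus.total_signal + minus.total_signal
    return StrandedStopTrack(
        plus=plus.values, minus=minus.values, units="raw", total_reads=total
    )


# ------------------------------------------------------ package outputs

def write_promoters_tsv(records: Sequence[PromoterRecord], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "chrom": [r.chrom for r in records],
            "strand": [r.strand for r in records],
            "tss": [r.tss for r in records],
            "expression_tpm": [r.expression_tpm for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_promoters_tsv(path) -> list[PromoterRecord]:
    frame = pd.read_csv(path, sep="\t")
    return [
        PromoterRecord(
            gene_id=str(row.gene_id),
            chrom=str(row.chrom),
            strand=str(row.strand),
            tss=int(row.tss),
            expression_tpm=float(row.expression_tpm),
        )
        for row in frame.itertuples()
    ]


def write_clusters_bed(clusters: Sequence[TagCluster], path) -> None:
    """Clusters as BED6+ with total TPM (score) and dominant TSS columns."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            fh.write(
                f"{c.chrom}\t{c.span_start}\t{c.span_end + 1}\tTC{i:05d}\t"
                f"{c.total_tpm:.4f}\t{c.strand}\t{c.dominant_tss}\n"
            )


def write_class_results(results: Sequence[PromoterClassResult], path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                **{f"has_{e}": int(r.element_flags.get(e, False)) for e in ELEMENTS},
                "labels": ",".join(sorted(r.labels)) or ".",
                "hits": ";".join(
                    f"{h.motif}@{h.offset}:{h.matched_seq}" for h in r.hits
                ) or ".",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_counts_json(counts: Mapping[str, int], path, **metadata) -> None:
    payload = {"counts": dict(counts)}
    if metadata:
        payload["metadata"] = dict(metadata)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
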