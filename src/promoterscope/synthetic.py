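"""Synthetic genome, CAGE, ChIP-seq and ChIP-nexus data with known truth.

The generator builds a toy genome whose promoters carry planted
core-promoter elements (one promoter class per record, enforced by
rejection sampling so classification on the synthetic genome is exact by
construction), then simulates the three read types the pipeline consumes:

* CAGE 5' tags — per-promoter tag share proportional to a log-normal
  expression level, positions normally dispersed around the true TSS,
  plus a uniform noise fraction;
* ChIP-seq IP/input fragment pairs — uniform input, IP a mixture of
  uniform background and TSS-centered fragments with per-promoter weight
  proportional to an enrichment level (itself proportional to expression,
  constant, or absent);
* ChIP-nexus stop bases — sense and antisense peaks at class-dependent
  TSS-relative offsets (downstream-weighted for TATA/DPE promoters,
  upstream-weighted for TCT/HK, mirroring known PIC footprint geometry).

Every draw derives from a single integer seed, so all outputs are
bit-reproducible; generator parameters are recorded on the truth table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cage_tss import GeneModel, PromoterRecord
from .chip_signal import StrandedStopTrack, stop_base_track
from .errors import ParameterError
from .promoter_classes import (
    MotifDefinition,
    classify_promoter,
    load_motif_config,
    scan_all,
    scan_span,
)
from .sequences import PromoterSequence

__all__ = [
    "TruthRecord",
    "TruthTable",
    "default_motifs",
    "make_promoter_genome",
    "simulate_cage_tags",
    "simulate_chipseq_pair",
    "simulate_nexus_tracks",
    "reverse_complement_dataset",
    "NEXUS_OFFSETS",
]

CLASS_MOTIFS = {"TATA": ["TATA"], "DPE": ["DPE_O"], "TCT": ["TCT"], "HK": ["DRE"]}

#: (sense, antisense) stop-base peak offsets relative to the TSS per class;
#: TATA/DPE footprints sit downstream of the TSS, TCT/HK upstream.
NEXUS_OFFSETS = {
    "TATA": (20, 35),
    "DPE": (25, 40),
    "TCT": (-25, -8),
    "HK": (-30, -12),
}

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def default_motifs() -> list[MotifDefinition]:
    """The motif config shipped with the package."""
    ref = importlib.resources.files("promoterscope").joinpath(
        "data/default_motifs.yaml"
    )
    with importlib.resources.as_file(ref) as path:
        return load_motif_config(path)


@dataclass
class TruthRecord:
    """Ground truth for one synthetic promoter."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    label: str
    expression: float
    enrichment: float
    nexus_sense_offset: int
    nexus_antisense_offset: int


@dataclass
class TruthTable:
    """All planted promoters plus the generator parameters that made them."""

    records: list[TruthRecord]
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def promoter_records(self) -> list[PromoterRecord]:
        return [
            PromoterRecord(r.gene_id, r.chrom, r.strand, r.tss, r.expression)
            for r in self.records
        ]

    def labels(self) -> dict[str, frozenset]:
        return {r.gene_id: frozenset({r.label}) for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


def _sample_instance(consensus: str, rng: np.random.Generator) -> str:
    from .promoter_classes import IUPAC

    return "".join(rng.choice(list(IUPAC[ch])) for ch in consensus)


def _planted_region(
    label: str,
    motifs: Sequence[MotifDefinition],
    up: int,
    down: int,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> str:
    """Rejection-sample a sense-strand promoter region for one class.

    The class-defining motif is planted at the midpoint of its scan
    window; candidate regions are redrawn until scanning finds exactly the
    planted element flags, which guarantees the classifier recovers the
    class label with no spurious co-labels.
    """
    by_name = {m.name: m for m in motifs}
    expected = {m.element: False for m in motifs}
    for name in CLASS_MOTIFS[label]:
        expected[by_name[name].element] = True
    for _ in range(max_tries):
        region = "".join(rng.choice(("A", "C", "G", "T"), size=up + down + 1))
        chars = list(region)
        for name in CLASS_MOTIFS[label]:
            m = by_name[name]
            offset = (m.window_start + m.window_end) // 2
            inst = _sample_instance(m.model, rng)
            i = offset + up
            chars[i : i + len(inst)] = inst
        region = "".join(chars)
        seq = PromoterSequence(region, up, down)
        flags, _ = scan_all(seq, motifs)
        if {e: v for e, v in flags.items() if e in expected} == expected and not any(
            v for e, v in flags.items() if e not in expected
        ):
            assert classify_promoter(flags) == frozenset({label})
            return region
    raise ParameterError(
        f"could not plant an unambiguous {label} promoter in {max_tries} tries; "
        "check motif windows for irreconcilable overlaps"
    )


def make_promoter_genome(
    n_per_class: int,
    seed: int,
    motifs: Sequence[MotifDefinition] | None = None,
    spacing: int = 2000,
    edge_margin: int = 1500,
    gene_length: int = 800,
    annotation_jitter: int = 200,
    expression_mu: float = 4.6,
    expression_sigma: float = 1.0,
    enrichment_scale: float = 5.0,
    chrom: str = "chrSim",
) -> tuple[dict[str, str], TruthTable, list[GeneModel]]:
    """Build a genome with planted promoters of each class plus gene models.

    Promoters (``n_per_class`` per class, classes shuffled along the
    chromosome) sit ``spacing`` bp apart; background bases are i.i.d.
    uniform ACGT.  Expression is log-normal (``exp(N(mu, sigma))`` TPM
    scale) and per-promoter ChIP enrichment defaults to
    ``enrichment_scale`` times the promoter's expression relative to the
    mean.  Annotated gene TSSs are jittered by up to
    ``annotation_jitter`` bp from the true TSS so re-annotation is
    exercised.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    if motifs is None:
        motifs = default_motifs()
    rng = np.random.default_rng(seed)
    up, down = scan_span(motifs)

    labels = [c for c in CLASS_MOTIFS for _ in range(n_per_class)]
    rng.shuffle(labels)
    n = len(labels)
    size = 2 * edge_margin + (n - 1) * spacing + 1
    genome_arr = rng.choice(("A", "C", "G", "T"), size=size)

    records: list[TruthRecord] = []
    genes: list[GeneModel] = []
    expressions = np.exp(rng.normal(expression_mu, expression_sigma, size=n))
    mean_expr = float(expressions.mean())
    for i, label in enumerate(labels):
        tss = edge_margin + i * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        region = _planted_region(label, motifs, up, down, rng)
        if strand == "+":
            lo = tss - up
            genome_arr[lo : lo + len(region)] = list(region)
        else:
            rc = region.translate(_COMP)[::-1]
            lo = tss - down
            genome_arr[lo : lo + len(rc)] = list(rc)
        jitter = int(rng.integers(-annotation_jitter, annotation_jitter + 1))
        gid = f"g{i:05d}"
        if strand == "+":
            start = tss + jitter
            genes.append(GeneModel(gid, chrom, "+", start, start + gene_length))
        else:
            end = tss + jitter + 1
            genes.append(GeneModel(gid, chrom, "-", end - gene_length, end))
        off_s, off_a = NEXUS_OFFSETS[label]
        records.append(
            TruthRecord(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                tss=tss,
                label=label,
                expression=float(expressions[i]),
                enrichment=enrichment_scale * float(expressions[i]) / mean_expr,
                nexus_sense_offset=off_s,
                nexus_antisense_offset=off_a,
            )
        )

    genome = {chrom: "".join(genome_arr)}
    truth = TruthTable(
        records=records,
        params=dict(
            n_per_class=n_per_class,
            seed=seed,
            spacing=spacing,
            edge_margin=edge_margin,
            gene_length=gene_length,
            annotation_jitter=annotation_jitter,
            expression_mu=expression_mu,
            expression_sigma=expression_sigma,
            enrichment_scale=enrichment_scale,
            chrom_sizes={chrom: size},
        ),
    )
    return genome, truth, genes


def simulate_cage_tags(
    truth: TruthTable,
    depth: int = 1_000_000,
    cluster_sd: float = 2.0,
    noise_fraction: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate CAGE 5'-end tags as a (chrom, strand, pos) DataFrame.

    Exactly ``depth`` tags are emitted: a ``noise_fraction`` share lands
    uniformly on random strands/positions, the rest is multinomially
    split across promoters proportional to expression, with positions
    normally dispersed (sd ``cluster_sd``) around each true TSS.
    """
    if depth <= 0:
        raise ParameterError("depth must be positive")
    if not 0 <= noise_fraction < 1:
        raise ParameterError("noise_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chrom_sizes = truth.params["chrom_sizes"]
    n_noise = int(round(depth * noise_fraction))
    n_signal = depth - n_noise

    expr = np.array([r.expression for r in truth.records])
    counts = rng.multinomial(n_signal, expr / expr.sum())
    chroms, strands, positions = [], [], []
    for rec, k in zip(truth.records, counts):
        if k == 0:
            continue
        if cluster_sd > 0:
            offs = np.rint(rng.normal(0.0, cluster_sd, size=k)).astype(np.int64)
        else:
            offs = np.zeros(k, dtype=np.int64)
        # dispersion measured along the genome; strand only sets tag strand
        pos = rec.tss + offs
        size = chrom_sizes[rec.chrom]
        pos = np.clip(pos, 0, size - 1)
        chroms.append(np.full(k, rec.chrom, dtype=object))
        strands.append(np.full(k, rec.strand, dtype=object))
        positions.append(pos)
    if n_noise:
        all_chroms = list(chrom_sizes)
        idx = rng.integers(0, len(all_chroms), size=n_noise)
        noise_chrom = np.array(all_chroms, dtype=object)[idx]
        noise_pos = np.array(
            [rng.integers(0, chrom_sizes[c]) for c in noise_chrom], dtype=np.int64
        )
        noise_strand = np.where(rng.random(n_noise) < 0.5, "+", "-").astype(object)
        chroms.append(noise_chrom)
        strands.append(noise_strand)
        positions.append(noise_pos)
    return pd.DataFrame(
        {
            "chrom": np.concatenate(chroms) if chroms else [],
            "strand": np.concatenate(strands) if strands else [],
            "pos": np.concatenate(positions) if positions else [],
        }
    )


def simulate_chipseq_pair(
    truth: TruthTable,
    ip_depth: int = 200_000,
    input_depth: int = 200_000,
    fragment_len: int = 200,
    enrichment_model: str = "proportional",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an IP/input ChIP-seq fragment pair.

    Input fragments start uniformly along the genome.  IP fragments are a
    mixture of the same uniform background and TSS-centered fragments
    (centers Normal(tss, fragment_len/2)) with per-promoter weight set by
    ``enrichment_model``: ``proportional`` uses the truth table's
    expression-proportional enrichment, ``constant`` gives every promoter
    the mean enrichment, and ``null`` plants no enrichment at all (IP is
    uniform, for scaling-factor null checks).
    """
    rng = np.random.default_rng(seed)
    chrom_sizes = truth.params["chrom_sizes"]
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    genome_len = sizes.sum()

    def uniform_fragments(k: int, r) -> pd.DataFrame:
        ci = r.choice(len(chroms), size=k, p=sizes / genome_len)
        starts = np.empty(k, dtype=np.int64)
        for j, c in enumerate(chroms):
            mask = ci == j
            starts[mask] = r.integers(
                0, chrom_sizes[c] - fragment_len, size=int(mask.sum())
            )
        return pd.DataFrame(
            {
                "chrom": np.array(chroms, dtype=object)[ci],
                "start": starts,
                "end": starts + fragment_len,
            }
        )

    input_frags = uniform_fragments(input_depth, rng)

    if enrichment_model == "null":
        ip_frags = uniform_fragments(ip_depth, rng)
    else:
        enr = np.array([r.enrichment for r in truth.records], dtype=float)
        if enrichment_model == "constant":
            enr = np.full_like(enr, enr.mean())
        elif enrichment_model != "proportional":
            raise ParameterError(
                f"unknown enrichment_model {enrichment_model!r}"
            )
        # promoter point mass in units of background bp-equivalents
        weights = enr * fragment_len
        p_promoter = weights.sum() / (genome_len + weights.sum())
        n_prom = rng.binomial(ip_depth, p_promoter)
        bg = uniform_fragments(ip_depth - n_prom, rng)
        which = rng.choice(len(truth.records), size=n_prom, p=weights / weights.sum())
        centers = np.array(
            [truth.records[i].tss for i in which], dtype=float
        ) + rng.normal(0.0, fragment_len / 2, size=n_prom)
        starts = np.rint(centers - fragment_len / 2).astype(np.int64)
        prom_chroms = np.array(
            [truth.records[i].chrom for i in which], dtype=object
        )
        maxstart = np.array(
            [chrom_sizes[c] - fragment_len for c in prom_chroms], dtype=np.int64
        )
        starts = np.clip(starts, 0, maxstart)
        prom = pd.DataFrame(
            {"chrom": prom_chroms, "start": starts, "end": starts + fragment_len}
        )
        ip_frags = pd.concat([bg, prom], ignore_index=True)
    return ip_frags, input_frags


def simulate_nexus_tracks(
    truth: TruthTable,
    depth: int = 200_000,
    peak_sd: float = 3.0,
    seed: int = 0,
    offsets: Mapping[str, tuple[int, int]] | None = None,
) -> StrandedStopTrack:
    """Simulate ChIP-nexus stop-base tracks (raw counts).

    Reads are split evenly across promoters (equal per-class depth), half
    on the sense strand at the class's sense offset and half antisense at
    its antisense offset, each normally dispersed with sd ``peak_sd``.
    ``depth = 0`` yields empty tracks.
    """
    rng = np.random.default_rng(seed)
    chrom_sizes = truth.params["chrom_sizes"]
    if offsets is None:
        offsets = NEXUS_OFFSETS
    reads_chrom, reads_strand, reads_pos = [], [], []
    if depth > 0 and len(truth.records) > 0:
        per_prom = rng.multinomial(
            depth, np.full(len(truth.records), 1.0 / len(truth.records))
        )
        for rec, k in zip(truth.records, per_prom):
            if k == 0:
                continue
            off_s, off_a = offsets[rec.label]
            k_sense = rng.binomial(k, 0.5)
            direction = 1 if rec.strand == "+" else -1
            for count, off, sense in (
                (k_sense, off_s, True),
                (k - k_sense, off_a, False),
            ):
                if count == 0:
                    continue
                jitter = np.rint(rng.normal(0, peak_sd, size=count)).astype(np.int64)
                pos = rec.tss + direction * (off + jitter)
                pos = np.clip(pos, 0, chrom_sizes[rec.chrom] - 1)
                if sense:
                    strand = rec.strand
                else:
                    strand = "-" if rec.strand == "+" else "+"
                reads_chrom.append(np.full(count, rec.chrom, dtype=object))
                reads_strand.append(np.full(count, strand, dtype=object))
                reads_pos.append(pos)
    frame = pd.DataFrame(
        {
            "chrom": np.concatenate(reads_chrom) if reads_chrom else [],
            "strand": np.concatenate(reads_strand) if reads_strand else [],
            "pos": np.concatenate(reads_pos) if reads_pos else [],
        }
    )
    return stop_base_track(frame, chrom_sizes)


def reverse_complement_dataset(
    genome: Mapping[str, str],
    truth: TruthTable,
    genes: Sequence[GeneModel],
):
    """Mirror an entire synthetic dataset onto the opposite strand.

    Reverse-complements every contig and flips all strands and
    coordinates (position p -> N-1-p).  Running the pipeline on the
    mirrored dataset must reproduce every count and score — the
    orientation-involution property used by the test suite.
    """
    sizes = {c: len(s) for c, s in genome.items()}
    rc_genome = {c: s.translate(_COMP)[::-1] for c, s in genome.items()}

    def flip_strand(s: str) -> str:
        return "-" if s == "+" else "+"

    rc_records = [
        TruthRecord(
            gene_id=r.gene_id,
            chrom=r.chrom,
            strand=flip_strand(r.strand),
            tss=sizes[r.chrom] - 1 - r.tss,
            label=r.label,
            expression=r.expression,
            enrichment=r.enrichment,
            nexus_sense_offset=r.nexus_sense_offset,
            nexus_antisense_offset=r.nexus_antisense_offset,
        )
        for r in truth.records
    ]
    rc_truth = TruthTable(records=rc_records, params=dict(truth.params))
    rc_genes = [
        GeneModel(
            g.gene_id,
            g.chrom,
            flip_strand(g.strand),
            sizes[g.chrom] - g.end,
            sizes[g.chrom] - g.start,
        )
        for g in genes
    ]
    return rc_genome, rc_truth, rc_genes


def reverse_complement_tags(
    tags: pd.DataFrame, chrom_sizes: Mapping[str, int]
) -> pd.DataFrame:
    """Mirror a tag/read table onto the opposite strand."""
    sizes = tags["chrom"].map(chrom_sizes).to_numpy()
    return pd.DataFrame(
        {
            "chrom": tags["chrom"],
            "strand": np.where(tags["strand"] == "+", "-", "+"),
            "pos": sizes - 1 - tags["pos"].to_numpy(),
        }
    )


def reverse_complement_fragments(
    fragments: pd.DataFrame, chrom_sizes: Mapping[str, int]
) -> pd.DataFrame:
    """Mirror a fragment interval table ([s, e) -> [N-e, N-s))."""
    sizes = fragments["chrom"].map(chrom_sizes).to_numpy()
    return pd.DataFrame(
        {
            "chrom": fragments["chrom"],
            "start": sizes - fragments["end"].to_numpy(),
            "end": sizes - fragments["start"].to_numpy(),
        }
    )
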