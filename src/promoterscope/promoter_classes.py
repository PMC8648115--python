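"""Core-promoter element scanning and promoter-type classification.

Drosophila promoters fall into architectural types defined by short
sequence elements in fixed windows around the TSS: the TATA box upstream,
downstream promoter region (DPR) elements (DPE, MTE, pause button) 3' of
the TSS, the polypyrimidine TCT initiator at the start site itself, and
housekeeping-associated motifs (DRE and the Ohler 1/6/7 motifs).  Each
element is modelled either as an IUPAC consensus or as a position weight
matrix, scanned on the oriented (sense) promoter sequence within a
TSS-relative window in which a match may start.

Classification rules: TATA and TCT promoters only require their defining
element and are not excluded for carrying others.  DPE-type promoters may
carry DPE/MTE/PB but no TATA, TCT, DRE or Ohler motif; housekeeping (HK)
promoters may carry DRE/Ohler1/6/7 but no TATA, TCT or DPR element.  A
promoter may therefore receive zero, one, or (TATA together with TCT) two
labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cage_tss import PromoterRecord
from .errors import BoundaryError, InputError, ParameterError
from .sequences import PromoterSequence, oriented_promoter_sequence

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: element names recognised by the classifier
ELEMENTS = ("TATA", "DPE", "MTE", "PB", "TCT", "DRE", "Ohler1", "Ohler6", "Ohler7")

#: motif name -> element it evidences (DPE_O and DPE_K are variants of DPE)
MOTIF_TO_ELEMENT = {"DPE_O": "DPE", "DPE_K": "DPE"}

LABELS = ("TATA", "DPE", "TCT", "HK")

BASES = "ACGT"

__all__ = [
    "MotifDefinition",
    "MotifHit",
    "PromoterClassResult",
    "load_motif_config",
    "scan_consensus",
    "scan_pwm",
    "scan_all",
    "classify_promoter",
    "classify_set",
    "scan_span",
    "ELEMENTS",
    "LABELS",
]


@dataclass
class MotifDefinition:
    """A named core-promoter element model with its scan window.

    ``window_start``/``window_end`` are TSS-relative offsets (0 = TSS
    base, negative = upstream) at which a match may *start*.  ``model`` is
    an IUPAC consensus string, or a 4 x L probability matrix (rows A,C,G,T)
    for PWM mode, in which case ``min_score_fraction`` sets the match
    threshold as a fraction of the attainable log-odds score range.
    """

    name: str
    mode: str  # "consensus" | "pwm"
    model: str | np.ndarray
    window_start: int
    window_end: int
    min_score_fraction: float = 0.8
    source: str = "user"

    def __post_init__(self) -> None:
        if self.window_start > self.window_end:
            raise InputError(
                f"motif {self.name}: window_start > window_end "
                f"({self.window_start} > {self.window_end})"
            )
        if self.mode == "consensus":
            if not isinstance(self.model, str) or not self.model:
                raise InputError(f"motif {self.name}: consensus model must be a string")
            self.model = self.model.upper()
            bad = set(self.model) - set(IUPAC)
            if bad:
                raise InputError(
                    f"motif {self.name}: unknown IUPAC letter(s) {sorted(bad)}"
                )
        elif self.mode == "pwm":
            self.model = np.asarray(self.model, dtype=float)
            if self.model.ndim != 2 or self.model.shape[0] != 4:
                raise InputError(f"motif {self.name}: PWM must be 4 x L")
            colsums = self.model.sum(axis=0)
            if not np.allclose(colsums, 1.0, atol=1e-6):
                raise InputError(f"motif {self.name}: PWM columns must sum to 1")
            if not 0 < self.min_score_fraction <= 1:
                raise InputError(
                    f"motif {self.name}: min_score_fraction must be in (0, 1]"
                )
        else:
            raise InputError(f"motif {self.name}: unknown mode {self.mode!r}")

    @property
    def length(self) -> int:
        return len(self.model) if self.mode == "consensus" else self.model.shape[1]

    @property
    def element(self) -> str:
        return MOTIF_TO_ELEMENT.get(self.name, self.name)


@dataclass(frozen=True)
class MotifHit:
    """A motif match starting at a TSS-relative offset."""

    motif: str
    offset: int
    matched_seq: str
    score: float


@dataclass
class PromoterClassResult:
    """Element presence flags, class labels and hits for one promoter."""

    gene_id: str
    element_flags: dict[str, bool]
    labels: frozenset[str]
    hits: list[MotifHit] = field(default_factory=list)


def load_motif_config(path) -> list[MotifDefinition]:
    """Load motif definitions from a YAML file.

    Each entry needs ``name``, ``mode``, ``model``, ``window_start`` and
    ``window_end``; PWM entries may set ``min_score_fraction``.  Entries
    whose ``source`` is ``placeholder`` refuse to load: they mark slots
    that must be filled with a concrete published model before any
    study-comparison run.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = raw["motifs"] if isinstance(raw, dict) and "motifs" in raw else raw
    if not isinstance(entries, list):
        raise InputError(f"{path}: motif config must be a list of motif entries")
    defs = []
    for entry in entries:
        name = entry.get("name")
        if not name:
            raise InputError(f"{path}: motif entry without a name")
        if entry.get("source") == "placeholder":
            raise InputError(
                f"motif {name}: placeholder model — supply a concrete motif "
                "model and window before running"
            )
        for key in ("model", "window_start", "window_end"):
            if key not in entry:
                raise InputError(f"motif {name}: missing required field {key!r}")
        defs.append(
            MotifDefinition(
                name=name,
                mode=entry.get("mode", "consensus"),
                model=entry["model"],
                window_start=int(entry["window_start"]),
                window_end=int(entry["window_end"]),
                min_score_fraction=float(entry.get("min_score_fraction", 0.8)),
                source=entry.get("source", "user"),
            )
        )
    return defs


def _check_window(seq: PromoterSequence, motif: MotifDefinition) -> None:
    if motif.window_start < -seq.upstream:
        raise BoundaryError(
            f"motif {motif.name}: window start {motif.window_start} upstream of "
            f"supplied sequence (-{seq.upstream})"
        )
    if motif.window_end + motif.length - 1 > seq.downstream:
        raise BoundaryError(
            f"motif {motif.name}: window end {motif.window_end} plus motif "
            f"length {motif.length} exceeds supplied sequence (+{seq.downstream})"
        )


def scan_consensus(seq: PromoterSequence, motif: MotifDefinition) -> list[MotifHit]:
    """Exact degenerate-consensus scan on the oriented sense sequence."""
    if motif.mode != "consensus":
        raise ParameterError(f"motif {motif.name} is not in consensus mode")
    _check_window(seq, motif)
    pattern = motif.model
    allowed = [IUPAC[ch] for ch in pattern]
    hits = []
    for offset in range(motif.window_start, motif.window_end + 1):
        window = seq.subseq(offset, len(pattern))
        if all(b in a for b, a in zip(window, allowed)):
            hits.append(MotifHit(motif.name, offset, window, float(len(pattern))))
    return hits


def scan_pwm(
    seq: PromoterSequence,
    motif: MotifDefinition,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> list[MotifHit]:
    """Log-odds PWM scan with a relative-score threshold.

    Scores use log2((p + 1e-3) / background) per column.  A hit requires
    score >= min + min_score_fraction * (max - min), where min/max are the
    minimal/maximal attainable scores — the relative-score convention used
    by standard PWM scanners, so a fraction of 1 keeps only perfect
    matches and a fraction of 0 keeps every offset.
    """
    if motif.mode != "pwm":
        raise ParameterError(f"motif {motif.name} is not in PWM mode")
    background = np.asarray(background, dtype=float)
    if (background <= 0).any():
        raise ParameterError("background frequencies must be strictly positive")
    _check_window(seq, motif)

    logodds = np.log2((motif.model + 1e-3) / background[:, None])
    max_score = logodds.max(axis=0).sum()
    min_score = logodds.min(axis=0).sum()
    threshold = min_score + motif.min_score_fraction * (max_score - min_score)
    base_index = {b: i for i, b in enumerate(BASES)}
    L = motif.length
    hits = []
    for offset in range(motif.window_start, motif.window_end + 1):
        window = seq.subseq(offset, L)
        try:
            idx = [base_index[b] for b in window]
        except KeyError:  # ambiguous base in genome: no score
            continue
        score = float(logodds[idx, np.arange(L)].sum())
        if score >= threshold - 1e-12:
            hits.append(MotifHit(motif.name, offset, window, score))
    return hits


def scan_all(
    seq: PromoterSequence,
    motifs: Sequence[MotifDefinition],
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[dict[str, bool], list[MotifHit]]:
    """Scan every motif; return element presence flags and all hits."""
    flags = {e: False for e in ELEMENTS}
    all_hits: list[MotifHit] = []
    for motif in motifs:
        if motif.mode == "consensus":
            hits = scan_consensus(seq, motif)
        else:
            hits = scan_pwm(seq, motif, background)
        if hits:
            flags[motif.element] = True
            all_hits.extend(hits)
    return flags, all_hits


def classify_promoter(element_flags: Mapping[str, bool]) -> frozenset[str]:
    """Assign promoter-type labels from element presence flags.

    See the module docstring for the inclusion/exclusion rules.  Returns a
    possibly empty subset of {TATA, DPE, TCT, HK}.
    """
    f = {e: bool(element_flags.get(e, False)) for e in ELEMENTS}
    labels = set()
    if f["TATA"]:
        labels.add("TATA")
    if f["TCT"]:
        labels.add("TCT")
    hk_motifs = f["DRE"] or f["Ohler1"] or f["Ohler6"] or f["Ohler7"]
    dpr_motifs = f["DPE"] or f["MTE"] or f["PB"]
    if dpr_motifs and not (f["TATA"] or f["TCT"] or hk_motifs):
        labels.add("DPE")
    if hk_motifs and not (f["TATA"] or f["TCT"] or dpr_motifs):
        labels.add("HK")
    return frozenset(labels)


def scan_span(motifs: Sequence[MotifDefinition]) -> tuple[int, int]:
    """Upstream/downstream reach (bp from TSS) needed to scan ``motifs``."""
    up = max(0, max(-m.window_start for m in motifs))
    down = max(0, max(m.window_end + m.length - 1 for m in motifs))
    return up, down


def classify_set(
    promoters: Sequence[PromoterRecord],
    genome: Mapping[str, str],
    motifs: Sequence[MotifDefinition],
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[list[PromoterClassResult], dict[str, int]]:
    """Classify a promoter set; return per-promoter results and label counts.

    Counts are per label (a promoter carrying both TATA and TCT increments
    both), plus ``unclassified`` for promoters with no label.  Promoters
    whose scan window runs off the contig are dropped and counted in the
    ``dropped`` entry.
    """
    up, down = scan_span(motifs)
    results = []
    counts = {label: 0 for label in LABELS}
    counts["unclassified"] = 0
    dropped = 0
    for rec in promoters:
        try:
            seq = oriented_promoter_sequence(
                genome, rec.chrom, rec.tss, rec.strand, up, down
            )
        except BoundaryError:
            dropped += 1
            continue
        flags, hits = scan_all(seq, motifs, background)
        labels = classify_promoter(flags)
        results.append(PromoterClassResult(rec.gene_id, flags, labels, hits))
        if labels:
            for label in labels:
                counts[label] += 1
        else:
            counts["unclassified"] += 1
    counts["dropped"] = dropped
    if dropped:
        logger.info("classify_set: dropped %d promoter(s) at contig edges", dropped)
    return results, counts
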