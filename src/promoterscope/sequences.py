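"""Oriented promoter sequence extraction with TSS-relative indexing."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio.Seq import reverse_complement

from .errors import BoundaryError

__all__ = ["PromoterSequence", "oriented_promoter_sequence"]


@dataclass(frozen=True)
class PromoterSequence:
    """A sense-strand promoter sequence indexed by TSS-relative offset.

    ``seq[upstream]`` is the TSS base (offset 0); offset ``k`` maps to
    string index ``k + upstream``.  Length is upstream + downstream + 1.
    """

    seq: str
    upstream: int
    downstream: int

    def __post_init__(self) -> None:
        assert len(self.seq) == self.upstream + self.downstream + 1

    def base_at(self, offset: int) -> str:
        return self.subseq(offset, 1)

    def subseq(self, offset: int, length: int) -> str:
        """Bases starting at TSS-relative ``offset`` (sense orientation)."""
        i = offset + self.upstream
        if i < 0 or i + length > len(self.seq):
            raise BoundaryError(
                f"offset {offset} (+{length} bp) outside supplied window "
                f"[-{self.upstream}, +{self.downstream}]"
            )
        return self.seq[i : i + length]

    def __len__(self) -> int:
        return len(self.seq)


def oriented_promoter_sequence(
    genome: Mapping[str, str],
    chrom: str,
    tss: int,
    strand: str,
    upstream: int,
    downstream: int,
) -> PromoterSequence:
    """Extract the sense-strand sequence around a TSS.

    For ``+`` promoters this is genomic ``[tss - upstream, tss + downstream]``
    (inclusive); for ``-`` promoters, the reverse complement of
    ``[tss - downstream, tss + upstream]``.  In both cases offset 0 of the
    result is the TSS base read in gene orientation.  Windows running off
    the contig raise :class:`BoundaryError` — there is no silent padding.
    """
    if chrom not in genome:
        raise BoundaryError(f"contig {chrom!r} not in genome")
    ref = str(genome[chrom])
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
    elif strand == "-":
        lo, hi = tss - downstream, tss + upstream
    else:
        raise BoundaryError(f"invalid strand {strand!r}")
    if lo < 0 or hi >= len(ref):
        raise BoundaryError(
            f"window [{lo}, {hi}] off contig {chrom} (length {len(ref)})"
        )
    raw = ref[lo : hi + 1].upper()
    if strand == "-":
        raw = reverse_complement(raw)
    return PromoterSequence(seq=raw, upstream=upstream, downstream=downstream)
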