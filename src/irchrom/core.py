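"""Core genomic value types shared by every stage of the pipeline.

All coordinates are 0-based, half-open (BED convention) everywhere inside
the package; conversion to and from 1-based inclusive conventions (GFF3/GTF)
happens only at file boundaries in :mod:`irchrom.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome / contig identifier.
    start : int
        0-based inclusive start, ``>= 0``.
    end : int
        Exclusive end, ``> start``.
    strand : str
        ``'+'``, ``'-'`` or ``'.'`` (unspecified).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """One canonical transcript of a gene: ordered exons and derived introns.

    Exons are stored in genomic coordinate order; ``introns`` are exactly the
    gaps between consecutive exons.  Transcript 5'→3' order is genomic order
    for '+' strand genes and reversed for '-' strand genes.
    """

    gene_id: str
    transcript_id: str
    strand: str
    exons: list[GenomicInterval]
    introns: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
            if b.start == a.end:
                raise ValueError(
                    f"zero-length intron between adjacent exons in {self.transcript_id}"
                )
        if not self.introns:
            self.introns = [
                GenomicInterval(a.chrom, a.end, b.start, self.strand)
                for a, b in zip(self.exons, self.exons[1:])
            ]

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> int:
        """Genomic span (TSS to TES), introns included."""
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def exons_transcript_order(self) -> list[GenomicInterval]:
        return self.exons if self.strand != "-" else list(reversed(self.exons))

    def introns_transcript_order(self) -> list[GenomicInterval]:
        return self.introns if self.strand != "-" else list(reversed(self.introns))


class CoverageTrack:
    """Per-base non-negative coverage over a set of chromosomes.

    ``assay`` tags the track as ``'rna'``, ``'dnase'`` or ``'methylation'``.
    Methylation tracks additionally carry a per-base integer ``counts`` array;
    positions with count 0 are missing (NaN in ``values``), not 0.0.
    """

    def __init__(
        self,
        values: dict[str, np.ndarray],
        assay: str = "dnase",
        counts: dict[str, np.ndarray] | None = None,
    ):
        if assay not in ("rna", "dnase", "methylation"):
            raise ValueError(f"unknown assay tag {assay!r}")
        self.assay = assay
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
        for c, v in self.values.items():
            finite = v[np.isfinite(v)]
            if (finite < 0).any():
                raise ValueError(f"negative coverage on {c}")
            if assay == "methylation" and (finite > 1).any():
                raise ValueError(f"methylation fraction > 1 on {c}")
        self.counts = None
        if counts is not None:
            self.counts = {c: np.asarray(v, dtype=int) for c, v in counts.items()}

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    def slice(self, iv: GenomicInterval) -> np.ndarray:
        """Values over ``iv`` in genomic orientation."""
        arr = self.values[iv.chrom]
        if iv.end > len(arr):
            raise IndexError(
                f"interval {iv} beyond chromosome end ({len(arr)})"
            )
        return arr[iv.start : iv.end]

    def slice_oriented(self, iv: GenomicInterval, strand: str) -> np.ndarray:
        """Values over ``iv``, reversed when ``strand`` is '-'."""
        out = self.slice(iv)
        return out[::-1] if strand == "-" else out


@dataclass
class Pwm:
    """Position weight matrix: columns of 4 base probabilities (A, C, G, T).

    ``matrix`` has shape (width, 4), each row summing to 1.  ``consensus`` is
    the per-column argmax base, ties broken alphabetically (A < C < G < T).
    """

    motif_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if (self.matrix < 0).any():
            raise ValueError(f"negative PWM entry in {self.motif_id}")
        sums = self.matrix.sum(axis=1)
        if np.abs(sums - 1).max() > 1e-6:
            raise ValueError(
                f"PWM {self.motif_id}: column sums deviate from 1 "
                f"(max dev {np.abs(sums - 1).max():.3g})"
            )

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        # argmax takes the first (alphabetically smallest) base on ties
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


def validate_hexamer(hexamer: str, k: int = 6) -> str:
    """Uppercase and validate a k-mer over the ACGT alphabet."""
    h = hexamer.upper()
    if len(h) != k or any(b not in BASE_INDEX for b in h):
        raise ValueError(f"not a valid {k}-mer over ACGT: {hexamer!r}")
    return h
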