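"""Calling intron retention (IR) and intron excision (IE) events.

An intron is called retained (IR) when RNA-seq coverage is >= 1 at every one
of its bases, and excised (IE) when coverage is 0 at every base; introns with
partial coverage are ambiguous and contribute no event.  Genes whose mean
exonic read depth is below a threshold (default 20) are dropped entirely.
First introns are flagged so they can be excluded downstream: the first
intron commonly overlaps the promoter DHS, which would confound any
accessibility comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenomicInterval, GeneModel, CoverageTrack
from .stats import fisher_exact

_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass
class IntronEvent:
    """One classified intron with its flanking exons.

    ``exon5``/``exon3`` are the annotated exons adjacent to the intron in
    transcript 5'→3' orientation (so for '-' strand genes exon5 is the
    genomically downstream exon).  ``relative_position`` is the intron
    midpoint's offset within the gene's genomic span, reflected for '-'
    strand genes so 0 is always TSS-proximal.
    """

    gene_id: str
    intron_index: int  # 1 = first intron in transcript orientation
    exon5: GenomicInterval
    intron: GenomicInterval
    exon3: GenomicInterval
    label: str  # "IR" | "IE"
    relative_position: float
    is_first_intron: bool
    strand: str

    def __post_init__(self) -> None:
        if self.label not in ("IR", "IE"):
            raise ValueError(f"bad label {self.label!r}")
        if not 0.0 <= self.relative_position <= 1.0:
            raise ValueError("relative_position outside [0, 1]")

    @property
    def chrom(self) -> str:
        return self.intron.chrom

    @property
    def span(self) -> GenomicInterval:
        """Full event span: exon5 start to exon3 end in genomic coordinates."""
        lo = min(self.exon5.start, self.exon3.start)
        hi = max(self.exon5.end, self.exon3.end)
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    def part(self, name: str) -> GenomicInterval:
        if name not in ("exon5", "intron", "exon3"):
            raise ValueError(f"unknown part {name!r}")
        return getattr(self, name)

    @property
    def uid(self) -> str:
        return f"{self.gene_id}.i{self.intron_index}"


PARTS = ("exon5", "intron", "exon3")


def part_sequence(event: IntronEvent, part: str, genome: dict[str, str]) -> str:
    """Sequence of an event part in transcript 5'→3' orientation."""
    iv = event.part(part)
    seq = genome[iv.chrom][iv.start : iv.end]
    if event.strand == "-":
        seq = seq.translate(_RC)[::-1]
    return seq


def call_intron_events(
    models: list[GeneModel],
    rna: CoverageTrack,
    min_gene_exon_depth: float = 20,
    per_exon: bool = False,
) -> list[IntronEvent]:
    """Classify every annotated intron of sufficiently expressed genes.

    Parameters
    ----------
    min_gene_exon_depth : float
        Minimum mean RNA-seq depth over the canonical transcript's exonic
        bases for the gene to be considered.
    per_exon : bool
        If True, additionally require each of the intron's two flanking
        exons to meet the depth threshold individually.
    """
    events = []
    for m in models:
        for intron in m.introns:
            if len(intron) == 0:
                raise ValueError(f"zero-length intron in {m.transcript_id}")
        exonic = np.concatenate([rna.slice(e) for e in m.exons])
        if exonic.mean() < min_gene_exon_depth:
            continue
        exons_t = m.exons_transcript_order()
        introns_t = m.introns_transcript_order()
        for idx, intron in enumerate(introns_t, start=1):
            cov = rna.slice(intron)
            if cov.min() >= 1:
                label = "IR"
            elif cov.max() == 0:
                label = "IE"
            else:
                continue  # partial coverage: ambiguous, no event
            exon5, exon3 = exons_t[idx - 1], exons_t[idx]
            if per_exon and (
                rna.slice(exon5).mean() < min_gene_exon_depth
                or rna.slice(exon3).mean() < min_gene_exon_depth
            ):
                continue
            mid = (intron.start + intron.end) / 2.0
            rel = (mid - m.start) / m.span
            if m.strand == "-":
                rel = 1.0 - rel
            events.append(
                IntronEvent(
                    gene_id=m.gene_id,
                    intron_index=idx,
                    exon5=exon5,
                    intron=intron,
                    exon3=exon3,
                    label=label,
                    relative_position=float(np.clip(rel, 0.0, 1.0)),
                    is_first_intron=(idx == 1),
                    strand=m.strand,
                )
            )
    return events


def exclude_first_introns(events: list[IntronEvent]) -> list[IntronEvent]:
    """Drop every event in a gene's first intron."""
    return [e for e in events if not e.is_first_intron]


def match_ie_by_relative_position(
    ir_events: list[IntronEvent],
    ie_events: list[IntronEvent],
    tolerance: float = 0.1,
) -> list[IntronEvent]:
    """IE events with a relative gene position similar to some IR event.

    An IE event is eligible if |rel(IE) - rel(IR)| <= tolerance for at least
    one IR event; the union is returned with each IE event appearing once.
    This controls for the systematic 5'→3' non-uniformity of DNase coverage
    along genes when comparing IR against IE.
    """
    ir_pos = np.array([e.relative_position for e in ir_events])
    matched = []
    for ie in ie_events:
        if ir_pos.size and np.abs(ir_pos - ie.relative_position).min() <= tolerance:
            matched.append(ie)
    if ir_events and ie_events and not matched:
        warnings.warn("no IE event within tolerance of any IR event")
    return matched


def first_intron_ir_rate_test(events_all: list[IntronEvent]):
    """Test whether first introns are retained more often than other introns.

    Returns ``(table, p)`` where table is the 2x2 array
    [[first-intron IR, first-intron IE], [other IR, other IE]] and p is the
    two-sided Fisher exact p-value.
    """
    table = np.zeros((2, 2), dtype=int)
    for e in events_all:
        row = 0 if e.is_first_intron else 1
        col = 0 if e.label == "IR" else 1
        table[row, col] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate margin in first-intron table; p = 1")
        return table, 1.0
    _, p = fisher_exact(table)
    return table, p


def events_to_frame(events: list[IntronEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in events],
            "intron_index": [e.intron_index for e in events],
            "chrom": [e.chrom for e in events],
            "intron_start": [e.intron.start for e in events],
            "intron_end": [e.intron.end for e in events],
            "strand": [e.strand for e in events],
            "label": [e.label for e in events],
            "relative_position": [e.relative_position for e in events],
            "is_first_intron": [e.is_first_intron for e in events],
        }
    )


def write_events(events: list[IntronEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)
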