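"""DHS-overlap statistics, coverage profiles and methylation profiles.

"DHS content" is the fraction of events (intron plus both flanking exons)
overlapping at least one DNase I hypersensitive-site peak by >= 1 bp; the
IR vs IE difference is quantified by the Fisher exact test.  Bin profiles
length-normalize each event part into a fixed number of bins so events of
different lengths can be averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, GeneModel, CoverageTrack
from .events import IntronEvent, PARTS
from .stats import fisher_exact, mann_whitney_u


@dataclass
class DhsContentTable:
    """DHS content (fraction of events with an overlapping peak) per class."""

    n_ir: int
    n_ie: int
    ir_overlap: int
    ie_overlap: int
    p_value: float

    @property
    def dhs_content_ir(self) -> float:
        return self.ir_overlap / self.n_ir

    @property
    def dhs_content_ie(self) -> float:
        return self.ie_overlap / self.n_ie

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": ["IR", "IE"],
                "n_events": [self.n_ir, self.n_ie],
                "n_overlap": [self.ir_overlap, self.ie_overlap],
                "dhs_content": [self.dhs_content_ir, self.dhs_content_ie],
                "p_value": [self.p_value, self.p_value],
            }
        )


@dataclass
class BinProfile:
    """Per-bin values across the three event parts, transcript-oriented.

    ``values`` and ``support`` have shape (3, bins_per_part), rows ordered
    (exon5, intron, exon3).  NaN marks bins with no supporting data.
    """

    label: str
    bins_per_part: int
    values: np.ndarray
    support: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pi, part in enumerate(PARTS):
            for b in range(self.bins_per_part):
                rows.append(
                    (self.label, part, b, self.values[pi, b],
                     self.support[pi, b] if self.support is not None else np.nan)
                )
        return pd.DataFrame(rows, columns=["class", "part", "bin", "value", "support"])


def _peak_trees(peaks: list[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def _overlaps(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> bool:
    t = trees.get(chrom)
    return bool(t is not None and t.overlap(start, end))


def dhs_content(
    events: list[IntronEvent], peaks: list[GenomicInterval]
) -> DhsContentTable:
    """Fraction of IR and IE events whose full span overlaps a DHS peak.

    The overlap window is the event span: exon5 start through exon3 end.
    Significance of the IR vs IE difference by two-sided Fisher exact test.
    """
    ir = [e for e in events if e.label == "IR"]
    ie = [e for e in events if e.label == "IE"]
    if not ir or not ie:
        raise ValueError("need at least one event of each class")
    trees = _peak_trees(peaks)
    ir_hit = sum(_overlaps(trees, e.chrom, e.span.start, e.span.end) for e in ir)
    ie_hit = sum(_overlaps(trees, e.chrom, e.span.start, e.span.end) for e in ie)
    table = np.array(
        [[ir_hit, len(ir) - ir_hit], [ie_hit, len(ie) - ie_hit]]
    )
    if (table.sum(axis=0) == 0).any():
        p = 1.0
    else:
        _, p = fisher_exact(table)
    return DhsContentTable(
        n_ir=len(ir), n_ie=len(ie), ir_overlap=ir_hit, ie_overlap=ie_hit, p_value=p
    )


def _part_bins(iv: GenomicInterval, strand: str, nbins: int):
    """Genomic (start, end) per bin, ordered 5'→3' of the transcript.

    Parts shorter than nbins are degenerate: every bin covers the whole part.
    """
    length = len(iv)
    if length < nbins:
        return [(iv.start, iv.end)] * nbins
    edges = np.linspace(iv.start, iv.end, nbins + 1)
    bins = [
        (int(np.floor(edges[i])), max(int(np.floor(edges[i])) + 1, int(np.floor(edges[i + 1]))))
        for i in range(nbins)
    ]
    if strand == "-":
        bins = bins[::-1]
    return bins


def dhs_bin_profile(
    events: list[IntronEvent],
    peaks: list[GenomicInterval],
    bins_per_part: int = 10,
) -> dict[str, BinProfile]:
    """Per-bin DHS overlap frequency for IR and IE events.

    Each part is length-normalized into ``bins_per_part`` bins; the bin value
    is the fraction of events whose bin interval intersects any peak.
    """
    trees = _peak_trees(peaks)
    out = {}
    for label in ("IR", "IE"):
        group = [e for e in events if e.label == label]
        hits = np.zeros((3, bins_per_part))
        for e in group:
            for pi, part in enumerate(PARTS):
                for b, (s, t) in enumerate(_part_bins(e.part(part), e.strand, bins_per_part)):
                    if _overlaps(trees, e.chrom, s, t):
                        hits[pi, b] += 1
        values = hits / len(group) if group else np.full((3, bins_per_part), np.nan)
        out[label] = BinProfile(
            label=label,
            bins_per_part=bins_per_part,
            values=values,
            support=np.full((3, bins_per_part), len(group)),
        )
    return out


def classify_genes_by_ir(
    models: list[GeneModel], events_all: list[IntronEvent]
) -> dict[str, str]:
    """Assign each gene to one group: ir_first_intron > ir_elsewhere > no_ir."""
    ir_first = {e.gene_id for e in events_all if e.label == "IR" and e.is_first_intron}
    ir_any = {e.gene_id for e in events_all if e.label == "IR"}
    groups = {}
    for m in models:
        if m.gene_id in ir_first:
            groups[m.gene_id] = "ir_first_intron"
        elif m.gene_id in ir_any:
            groups[m.gene_id] = "ir_elsewhere"
        else:
            groups[m.gene_id] = "no_ir"
    return groups


def gene_coverage_profile(
    models: list[GeneModel],
    events_all: list[IntronEvent],
    dnase: CoverageTrack,
    max_gene_len: int = 5000,
    upstream: int = 1000,
) -> dict[str, pd.DataFrame]:
    """Strand-aware mean DNase coverage profile per gene group.

    Genes longer than ``max_gene_len`` are dropped.  The profile runs from
    ``-upstream`` (promoter side of the TSS) to ``max_gene_len - 1``;
    positions past a gene's own end do not contribute to the mean.  Groups
    are ir_first_intron / ir_elsewhere / no_ir with the first-intron group
    taking priority.
    """
    groups = classify_genes_by_ir(models, events_all)
    length = upstream + max_gene_len
    sums = {g: np.zeros(length) for g in ("ir_first_intron", "ir_elsewhere", "no_ir")}
    supp = {g: np.zeros(length) for g in sums}
    for m in models:
        if m.span > max_gene_len:
            continue
        arr = dnase.values[m.chrom]
        prof = np.full(length, np.nan)
        if m.strand == "-":
            tss = m.end  # exclusive end = base just past the 5'-most base
            lo = max(tss - max_gene_len, tss - m.span)
            hi = min(tss + upstream, len(arr))
            window = arr[lo:hi][::-1]  # runs 5'→3' away from upstream side
            n_up = hi - tss
            if n_up < upstream:
                warnings.warn(f"{m.gene_id}: upstream window truncated at contig end")
            prof[upstream - n_up : upstream - n_up + len(window)] = window
        else:
            tss = m.start
            lo = max(tss - upstream, 0)
            hi = min(tss + m.span, tss + max_gene_len)
            if tss - lo < upstream:
                warnings.warn(f"{m.gene_id}: upstream window truncated at contig start")
            prof[upstream - (tss - lo) : upstream - (tss - lo) + (hi - lo)] = arr[lo:hi]
        g = groups[m.gene_id]
        ok = ~np.isnan(prof)
        sums[g][ok] += prof[ok]
        supp[g][ok] += 1
    out = {}
    positions = np.arange(-upstream, max_gene_len)
    for g in sums:
        with np.errstate(invalid="ignore"):
            mean = np.where(supp[g] > 0, sums[g] / np.maximum(supp[g], 1), np.nan)
        out[g] = pd.DataFrame({"position": positions, "mean_coverage": mean,
                               "n_genes": supp[g]})
    return out


def coverage_depth_comparison(
    ir_events: list[IntronEvent],
    ie_events: list[IntronEvent],
    dnase: CoverageTrack,
):
    """Per-event mean DNase coverage for IR vs IE plus Mann-Whitney U p.

    Events should already be first-intron-filtered and position-matched.
    Returns ``(ir_means, ie_means, U, p)``.
    """
    if not ir_events or not ie_events:
        raise ValueError("both event classes must be non-empty")
    ir_means = np.array([dnase.slice(e.span).mean() for e in ir_events])
    ie_means = np.array([dnase.slice(e.span).mean() for e in ie_events])
    u, p = mann_whitney_u(ir_means, ie_means)
    return ir_means, ie_means, u, p


def methylation_profile(
    events: list[IntronEvent],
    methylation: CoverageTrack,
    bins_per_part: int = 10,
) -> dict[str, BinProfile]:
    """Read-count-weighted mean methylation per bin for IR and IE events.

    Bin value = sum(fraction * count) / sum(count) over non-missing
    cytosines in the bin, pooled over events; bins with no covered cytosine
    are NaN.
    """
    out = {}
    for label in ("IR", "IE"):
        group = [e for e in events if e.label == label]
        wsum = np.zeros((3, bins_per_part))
        wtot = np.zeros((3, bins_per_part))
        for e in group:
            vals = methylation.values[e.chrom]
            cnts = (
                methylation.counts[e.chrom]
                if methylation.counts is not None
                else np.ones(len(vals))
            )
            for pi, part in enumerate(PARTS):
                for b, (s, t) in enumerate(_part_bins(e.part(part), e.strand, bins_per_part)):
                    v, c = vals[s:t], cnts[s:t]
                    ok = ~np.isnan(v)
                    wsum[pi, b] += (v[ok] * c[ok]).sum()
                    wtot[pi, b] += c[ok].sum()
        with np.errstate(invalid="ignore"):
            values = np.where(wtot > 0, wsum / np.maximum(wtot, 1e-300), np.nan)
        out[label] = BinProfile(
            label=label, bins_per_part=bins_per_part, values=values, support=wtot
        )
    return out
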