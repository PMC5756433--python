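"""Readers and writers for the standard formats the pipeline touches.

File conventions handled here, once:

* GFF3/GTF exon coordinates are 1-based inclusive → internal 0-based half-open.
* BED / bedGraph are already 0-based half-open and pass through unchanged.
* Methylation is a bedGraph-like TSV of per-cytosine methylated fraction plus
  supporting read count; count 0 means missing, not 0.0.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomicInterval, GeneModel, CoverageTrack, Pwm


class ParseError(ValueError):
    """Raised for malformed records; message names the offending line."""


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, fmt: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 or GTF, one canonical transcript per gene.

    The canonical transcript is the one with the longest exonic span; ties are
    broken by lexicographically smallest transcript_id.  Introns are derived
    as the gaps between consecutive exons.  Single-exon genes are kept with
    zero introns.
    """
    if fmt not in ("gff3", "gtf"):
        raise ValueError(f"unknown gene-model format {fmt!r}")
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises a zoo of exception types
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    # transcript -> gene mapping (GFF3: via Parent chain; GTF: gene_id attr)
    tx_gene: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype in ("mRNA", "transcript"):
            tid = feat.id
            parents = feat.attributes.get("Parent") or feat.attributes.get("gene_id")
            tx_gene[tid] = parents[0] if parents else tid

    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_strand: dict[str, str] = {}
    for exon in db.features_of_type("exon"):
        if exon.end < exon.start:
            raise ParseError(
                f"{path}: exon end < start at {exon.seqid}:{exon.start}-{exon.end}"
            )
        if "transcript_id" in exon.attributes:  # GTF
            tid = exon.attributes["transcript_id"][0]
            tx_gene.setdefault(tid, exon.attributes.get("gene_id", [tid])[0])
        elif "Parent" in exon.attributes:  # GFF3
            tid = exon.attributes["Parent"][0]
        else:
            raise ParseError(
                f"{path}: exon without transcript attribute at "
                f"{exon.seqid}:{exon.start}-{exon.end}"
            )
        strand = exon.strand if exon.strand in ("+", "-") else "."
        tx_strand[tid] = strand
        tx_exons.setdefault(tid, []).append(
            GenomicInterval(exon.seqid, exon.start - 1, exon.end, strand)
        )

    # canonical transcript per gene: longest exonic span, ties by transcript_id
    by_gene: dict[str, list[str]] = {}
    for tid in tx_exons:
        gid = tx_gene.get(tid, tid)
        by_gene.setdefault(gid, []).append(tid)

    models = []
    for gid in sorted(by_gene):
        tid = min(
            by_gene[gid],
            key=lambda t: (-sum(len(e) for e in tx_exons[t]), t),
        )
        models.append(
            GeneModel(
                gene_id=gid,
                transcript_id=tid,
                strand=tx_strand[tid],
                exons=tx_exons[tid],
            )
        )
    return models


def write_gene_models_gff3(models: list[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GFF3 (gene/mRNA/exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            row = [m.chrom, "irchrom", "gene", str(m.start + 1), str(m.end),
                   ".", m.strand, ".", f"ID={m.gene_id}"]
            fh.write("\t".join(row) + "\n")
            row[2] = "mRNA"
            row[8] = f"ID={m.transcript_id};Parent={m.gene_id}"
            fh.write("\t".join(row) + "\n")
            for i, e in enumerate(m.exons, 1):
                fh.write(
                    "\t".join([
                        m.chrom, "irchrom", "exon", str(e.start + 1), str(e.end),
                        ".", m.strand, ".",
                        f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}",
                    ]) + "\n"
                )


# ---------------------------------------------------------------------------
# intervals (BED)
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# coverage (bedGraph)
# ---------------------------------------------------------------------------

def read_coverage(
    path: str | Path,
    chrom_sizes: dict[str, int],
    assay: str = "dnase",
) -> CoverageTrack:
    """Expand a bedGraph into a per-base CoverageTrack; uncovered bases are 0.

    Overlapping bedGraph intervals are ambiguous and raise ParseError.
    """
    values = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: fewer than 4 bedGraph fields")
            chrom, start, end, val = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in values:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > len(values[chrom]) or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: interval [{start},{end}) beyond "
                    f"{chrom} bounds (size {len(values[chrom])})"
                )
            if covered[chrom][start:end].any():
                raise ParseError(f"{path}:{lineno}: overlapping bedGraph intervals")
            values[chrom][start:end] = val
            covered[chrom][start:end] = True
    return CoverageTrack(values, assay=assay)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write a CoverageTrack as run-length-encoded bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            if len(v) == 0:
                continue
            breaks = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(v)]])
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")


def read_methylation(path: str | Path, chrom_sizes: dict[str, int]) -> CoverageTrack:
    """Read per-cytosine methylation: chrom, start, end, fraction, read count.

    Positions absent from the file or with count 0 are missing (NaN).
    """
    values = {c: np.full(n, np.nan) for c, n in chrom_sizes.items()}
    counts = {c: np.zeros(n, dtype=int) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: need 5 methylation fields")
            chrom, start = fields[0], int(fields[1])
            frac, count = float(fields[3]), int(fields[4])
            if chrom not in values:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if count > 0:
                if not 0 <= frac <= 1:
                    raise ParseError(f"{path}:{lineno}: fraction outside [0,1]")
                values[chrom][start] = frac
                counts[chrom][start] = count
    return CoverageTrack(values, assay="methylation", counts=counts)


def write_methylation(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            n = track.counts[chrom] if track.counts else np.ones(len(v), dtype=int)
            for pos in np.flatnonzero(~np.isnan(v)):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{v[pos]:g}\t{n[pos]}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------

def _finish_pwm(motif_id: str, rows: list[list[float]], origin: str) -> Pwm:
    mat = np.asarray(rows, dtype=float)
    if (mat < 0).any():
        raise ParseError(f"{origin}: negative entry in motif {motif_id}")
    sums = mat.sum(axis=1)
    dev = np.abs(sums - 1)
    if (dev > 1e-3).any():
        raise ParseError(
            f"{origin}: motif {motif_id} column sums deviate from 1 "
            f"by up to {dev.max():.3g}"
        )
    if (dev > 1e-6).any():
        warnings.warn(f"renormalizing PWM columns of {motif_id}")
    mat = mat / sums[:, None]
    return Pwm(motif_id=motif_id, matrix=mat)


def read_pwms(path: str | Path, fmt: str = "meme_minimal") -> list[Pwm]:
    """Read PWMs from MEME-minimal text or a plain ``>id`` + rows format.

    Each matrix row holds the A, C, G, T probabilities of one motif column.
    Columns off by more than 1e-3 from summing to 1 are an error; smaller
    deviations are renormalized with a warning.
    """
    if fmt == "meme_minimal":
        return _read_meme(path)
    if fmt == "plain":
        return _read_plain_pwms(path)
    raise ValueError(f"unknown PWM format {fmt!r}")


def _read_meme(path: str | Path) -> list[Pwm]:
    pwms, motif_id, rows, expect = [], None, [], 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if motif_id is not None and rows:
                    pwms.append(_finish_pwm(motif_id, rows, str(path)))
                motif_id, rows, expect = line.split()[1], [], 0
            elif line.startswith("letter-probability matrix"):
                for token in line.replace(":", " ").split():
                    if token.startswith("w="):
                        pass
                expect = -1  # rows follow until blank/next MOTIF
            elif expect == -1 and line and motif_id is not None:
                parts = line.split()
                if len(parts) >= 4:
                    try:
                        rows.append([float(x) for x in parts[:4]])
                    except ValueError:
                        expect = 0
                else:
                    expect = 0
    if motif_id is not None and rows:
        pwms.append(_finish_pwm(motif_id, rows, str(path)))
    return pwms


def _read_plain_pwms(path: str | Path) -> list[Pwm]:
    pwms, motif_id, rows = [], None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if motif_id is not None:
                    pwms.append(_finish_pwm(motif_id, rows, str(path)))
                motif_id, rows = line[1:].split()[0], []
            elif line:
                rows.append([float(x) for x in line.split()[:4]])
    if motif_id is not None:
        pwms.append(_finish_pwm(motif_id, rows, str(path)))
    return pwms


def write_pwms_meme(pwms: list[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {p.width}\n")
            for row in p.matrix:
                fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")
            fh.write("\n")
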