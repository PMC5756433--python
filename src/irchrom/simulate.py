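"""Seeded generators for every input the pipeline consumes.

The generators emulate, at toy scale, the statistical structure of the
DNase I-seq / RNA-seq / bisulfite-seq inputs the analysis assumes: gene
models with introns on a single contig, Poisson RNA coverage with planted
retained (full-coverage) and excised (zero-coverage) introns, Poisson DNase
cut counts with a promoter peak, DHS peaks enriched on retained-intron
events, multiplicative footprint dips at planted hexamer sites,
beta-distributed methylation that is lower in the 3' exons of IR events,
and PWM collections whose consensus embeds chosen hexamers.

A dataset is fully determined by its :class:`SimulationConfig` (one RNG,
seeded once, sub-generators drawn in a fixed order), so every downstream
truth-recovery check is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import BASES, GenomicInterval, GeneModel, CoverageTrack, Pwm
from .footprints import (
    FootprintHmm, STATE_NAMES, STATE_INDEX, N_STATES, WINDOW_LEN,
)
from . import io as _io

_RC = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class FootprintSpec:
    """One hexamer to plant with a DNase footprint dip.

    ``dip_factor`` multiplies the expected DNase rate over the hexamer
    ± ``dip_halfwidth`` (0 = total protection, 1 = no footprint).
    ``prob_ir`` / ``prob_ie`` are per-event planting probabilities in the
    given region of IR resp. IE events.
    """

    hexamer: str
    region: str = "exon3"
    dip_factor: float = 0.3
    dip_halfwidth: int = 15
    prob_ir: float = 0.9
    prob_ie: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dip_factor <= 1.0:
            raise ValueError("dip_factor must be in [0, 1]")
        if self.region not in ("exon5", "intron", "exon3"):
            raise ValueError(f"bad region {self.region!r}")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic dataset; see the methods note for rationale.

    Defaults give genes deep enough for the depth-20 expression filter, a
    DNase background of 20 cuts/base with a 10x promoter peak over TSS±200,
    and DHS planting probabilities mirroring the IR >> IE enrichment the
    analysis is designed to detect.
    """

    seed: int = 0
    n_genes: int = 50
    exon_length_range: tuple[int, int] = (150, 300)
    intron_length_range: tuple[int, int] = (100, 250)
    introns_per_gene_range: tuple[int, int] = (2, 3)
    intergenic_spacer: int = 1500
    ir_fraction: float = 0.5
    first_intron_ir_fraction: float | None = None
    ambiguous_fraction: float = 0.0
    rna_depth_mean: float = 30.0
    min_gene_mean_depth: float = 20.0
    dnase_background_rate: float = 20.0
    promoter_peak_fold: float = 10.0
    promoter_halfwidth: int = 200
    dhs_fold: float = 5.0
    dhs_prob_ir: float = 0.30
    dhs_prob_ie: float = 0.05
    dhs_length_range: tuple[int, int] = (60, 140)
    footprint_hexamers: tuple[FootprintSpec, ...] = ()
    scrub_chance_occurrences: bool = True
    methylation_params: dict = field(
        default_factory=lambda: {
            ("IR", "exon3"): (2.0, 8.0),
            ("IE", "exon3"): (5.0, 5.0),
            "default": (3.0, 3.0),
        }
    )
    methylation_read_depth: float = 10.0

    def __post_init__(self) -> None:
        for p in (self.ir_fraction, self.ambiguous_fraction,
                  self.dhs_prob_ir, self.dhs_prob_ie):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for r in (self.rna_depth_mean, self.dnase_background_rate):
            if r <= 0:
                raise ValueError("rates must be positive")
        self.footprint_hexamers = tuple(
            fs if isinstance(fs, FootprintSpec) else FootprintSpec(*fs)
            for fs in self.footprint_hexamers
        )


@dataclass
class SyntheticDataset:
    """All generated inputs plus the truth tables behind them."""

    config: SimulationConfig
    genome: dict[str, str]
    models: list[GeneModel]
    rna: CoverageTrack
    dnase: CoverageTrack
    dhs_peaks: list[GenomicInterval]
    methylation: CoverageTrack
    intron_truth: dict[str, str]  # "gene.iN" -> IR | IE | ambiguous
    planted_footprints: list[dict]
    dhs_truth: dict[str, bool]  # event uid -> carries a planted DHS

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_fasta(self.genome, outdir / "genome.fa")
        _io.write_gene_models_gff3(self.models, outdir / "genes.gff3")
        _io.write_coverage(self.rna, outdir / "rna.bedgraph")
        _io.write_coverage(self.dnase, outdir / "dnase.bedgraph")
        _io.write_intervals(self.dhs_peaks, outdir / "dhs.bed")
        _io.write_methylation(self.methylation, outdir / "methylation.tsv")


# ---------------------------------------------------------------------------
# gene models and genome sequence
# ---------------------------------------------------------------------------

def simulate_genes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], dict[str, str]]:
    """Non-overlapping genes on one contig, separated by intergenic spacers.

    The spacer (default 1500 bp) leaves room for the 1000 bp upstream
    promoter window of the gene-profile analysis.  Sequence is uniform over
    ACGT; footprint hexamers are planted later, once intron classes exist.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.introns_per_gene_range
    if lo > hi or config.exon_length_range[0] > config.exon_length_range[1]:
        raise ValueError("empty length range")
    models = []
    pos = config.intergenic_spacer
    structures = []
    for g in range(config.n_genes):
        n_introns = int(rng.integers(lo, hi + 1))
        exon_lens = rng.integers(
            config.exon_length_range[0], config.exon_length_range[1] + 1,
            size=n_introns + 1,
        )
        intron_lens = rng.integers(
            config.intron_length_range[0], config.intron_length_range[1] + 1,
            size=max(n_introns, 0),
        )
        strand = "+" if rng.random() < 0.5 else "-"
        structures.append((exon_lens, intron_lens, strand))
    for g, (exon_lens, intron_lens, strand) in enumerate(structures):
        exons = []
        p = pos
        for i, el in enumerate(exon_lens):
            exons.append(GenomicInterval("chr1", p, p + int(el), strand))
            p += int(el)
            if i < len(intron_lens):
                p += int(intron_lens[i])
        models.append(
            GeneModel(
                gene_id=f"g{g:04d}", transcript_id=f"g{g:04d}.t1",
                strand=strand, exons=exons,
            )
        )
        pos = p + config.intergenic_spacer
    genome_len = pos if models else config.intergenic_spacer
    seq_codes = rng.integers(0, 4, size=genome_len)
    genome = {"chr1": "".join(BASES[c] for c in seq_codes)}
    return models, genome


# ---------------------------------------------------------------------------
# intron truth classes and RNA coverage
# ---------------------------------------------------------------------------

def assign_intron_truth(
    models: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, str]:
    """IR / IE / ambiguous truth label per intron (transcript order)."""
    truth = {}
    for m in models:
        for idx in range(1, len(m.introns) + 1):
            ir_frac = config.ir_fraction
            if idx == 1 and config.first_intron_ir_fraction is not None:
                ir_frac = config.first_intron_ir_fraction
            u = rng.random()
            if u < config.ambiguous_fraction:
                label = "ambiguous"
            elif u < config.ambiguous_fraction + (1 - config.ambiguous_fraction) * ir_frac:
                label = "IR"
            else:
                label = "IE"
            truth[f"{m.gene_id}.i{idx}"] = label
    return truth


def simulate_rna_coverage(
    models: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    genome_len: int | None = None,
    truth: dict[str, str] | None = None,
) -> tuple[CoverageTrack, dict[str, str]]:
    """Poisson exonic coverage and class-determined intron coverage.

    Exonic bases draw Poisson(rna_depth_mean), redrawn until the gene mean
    clears the expression filter; IR introns draw Poisson(depth/2) with
    zeros raised to 1 (full coverage by construction); IE introns are zero;
    ambiguous introns get coverage over a contiguous half only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = assign_intron_truth(models, config, rng)
    if genome_len is None:
        genome_len = (max(m.end for m in models) + config.intergenic_spacer
                      if models else config.intergenic_spacer)
    cov = np.zeros(genome_len)
    for m in models:
        for _ in range(100):
            draws = [rng.poisson(config.rna_depth_mean, size=len(e)) for e in m.exons]
            if np.concatenate(draws).mean() >= config.min_gene_mean_depth:
                break
        for e, d in zip(m.exons, draws):
            cov[e.start : e.end] = d
        introns_t = m.introns_transcript_order()
        for idx, intron in enumerate(introns_t, start=1):
            label = truth[f"{m.gene_id}.i{idx}"]
            L = len(intron)
            if label == "IR":
                d = rng.poisson(config.rna_depth_mean * 0.5, size=L)
                d[d == 0] = 1
                cov[intron.start : intron.end] = d
            elif label == "ambiguous":
                d = rng.poisson(config.rna_depth_mean * 0.5, size=L)
                d[d == 0] = 1
                half = L // 2
                d[half:] = 0  # partial coverage: neither IR nor IE
                cov[intron.start : intron.end] = d
            # IE: stays zero
    return CoverageTrack({"chr1": cov}, assay="rna"), truth


# ---------------------------------------------------------------------------
# hexamer planting
# ---------------------------------------------------------------------------

def _event_part_interval(m: GeneModel, idx: int, region: str) -> GenomicInterval:
    exons_t = m.exons_transcript_order()
    introns_t = m.introns_transcript_order()
    if region == "exon5":
        return exons_t[idx - 1]
    if region == "intron":
        return introns_t[idx - 1]
    return exons_t[idx]


def plant_footprint_sequences(
    models: list[GeneModel],
    truth: dict[str, str],
    genome: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[dict]]:
    """Write footprint hexamers into event-part sequences.

    Planting respects transcript orientation ('-' strand events receive the
    reverse complement on the genomic + strand).  Returns the mutated genome
    and the planted-site table (genomic coordinates of each hexamer, with
    its dip parameters, consumed by :func:`simulate_dnase_coverage`).

    When ``config.scrub_chance_occurrences`` is set (the default), accidental
    occurrences of planted hexamers inside event-part sequences are mutated
    away, so planted hexamers occur only where a footprint dip was written:
    the sequence is uniform except at planted sites, and each hexamer's
    occurrence set coincides with its truth table.
    """
    arr = {c: bytearray(s, "ascii") for c, s in genome.items()}
    occupied = {c: np.zeros(len(s), dtype=bool) for c, s in genome.items()}
    planted = []
    for m in models:
        for idx in range(1, len(m.introns) + 1):
            label = truth[f"{m.gene_id}.i{idx}"]
            if label not in ("IR", "IE"):
                continue
            for fs in config.footprint_hexamers:
                prob = fs.prob_ir if label == "IR" else fs.prob_ie
                if rng.random() >= prob:
                    continue
                iv = _event_part_interval(m, idx, fs.region)
                L = len(iv)
                if L < 6:
                    raise ValueError(
                        f"part {fs.region} of {m.gene_id}.i{idx} too short to plant"
                    )
                # avoid writing over an earlier planted site; skip if no room
                gstart = None
                for _ in range(20):
                    off = int(rng.integers(0, L - 5))
                    cand = iv.end - off - 6 if m.strand == "-" else iv.start + off
                    if not occupied[iv.chrom][cand : cand + 6].any():
                        gstart = cand
                        break
                if gstart is None:
                    continue
                written = (
                    fs.hexamer.translate(_RC)[::-1] if m.strand == "-" else fs.hexamer
                )
                arr[iv.chrom][gstart : gstart + 6] = written.encode()
                occupied[iv.chrom][gstart : gstart + 6] = True
                planted.append(
                    {
                        "hexamer": fs.hexamer, "gene_id": m.gene_id,
                        "intron_index": idx, "label": label,
                        "region": fs.region, "chrom": iv.chrom,
                        "start": gstart, "end": gstart + 6,
                        "dip_factor": fs.dip_factor,
                        "dip_halfwidth": fs.dip_halfwidth,
                    }
                )
    if config.scrub_chance_occurrences and config.footprint_hexamers:
        _scrub_chance_occurrences(models, arr, occupied, config, rng)
    return {c: b.decode() for c, b in arr.items()}, planted


def _scrub_chance_occurrences(models, arr, occupied, config, rng) -> None:
    """Mutate accidental event-part occurrences of planted hexamers.

    An occurrence is accidental when its 6 bp genomic range is disjoint from
    every planted site.  Its middle base is redrawn until the oriented part
    sequence no longer contains any planted hexamer at that offset; a few
    passes handle mutations that create new occurrences.
    """
    targets = {fs.hexamer for fs in config.footprint_hexamers}
    targets |= {h.translate(_RC)[::-1] for h in targets}  # '-' strand parts
    for _ in range(5):
        dirty = False
        for m in models:
            for idx in range(1, len(m.introns) + 1):
                for region in ("exon5", "intron", "exon3"):
                    iv = _event_part_interval(m, idx, region)
                    seq = arr[iv.chrom][iv.start : iv.end].decode()
                    for off in range(len(seq) - 5):
                        if seq[off : off + 6] not in targets:
                            continue
                        g0 = iv.start + off
                        if occupied[iv.chrom][g0 : g0 + 6].any():
                            continue
                        pos = g0 + 3
                        old = arr[iv.chrom][pos : pos + 1].decode()
                        choices = [b for b in BASES if b != old]
                        arr[iv.chrom][pos] = ord(choices[int(rng.integers(0, 3))])
                        dirty = True
        if not dirty:
            return


# ---------------------------------------------------------------------------
# DNase coverage, DHS peaks, footprint dips
# ---------------------------------------------------------------------------

def simulate_dnase_coverage(
    models: list[GeneModel],
    truth: dict[str, str],
    genome: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
    planted: list[dict] | None = None,
) -> tuple[CoverageTrack, list[GenomicInterval], dict[str, bool]]:
    """Poisson DNase cuts from a structured expected-rate landscape.

    Rate = background λ, raised to ``promoter_peak_fold``·λ over TSS±200 and
    to ``dhs_fold``·λ inside planted DHS intervals, then multiplied by the
    dip factor over each planted hexamer ± halfwidth.  Every gene gets a
    promoter DHS (so first-intron events always have a peak to exclude);
    non-first IR/IE events additionally carry a DHS in their 3' exon with
    probability ``dhs_prob_ir`` / ``dhs_prob_ie``.
    """
    planted = planted or []
    for site in planted:
        seq = genome[site["chrom"]][site["start"] : site["end"]]
        fwd = site["hexamer"]
        if seq not in (fwd, fwd.translate(_RC)[::-1]):
            raise ValueError(
                f"planted hexamer {fwd} not present at "
                f"{site['chrom']}:{site['start']} (found {seq}); "
                "plant sequences before simulating coverage"
            )
    sizes = {c: len(s) for c, s in genome.items()}
    rate = {c: np.full(n, config.dnase_background_rate) for c, n in sizes.items()}
    peaks: list[GenomicInterval] = []
    dhs_truth: dict[str, bool] = {}
    lam = config.dnase_background_rate
    for m in models:
        tss = m.start if m.strand != "-" else m.end
        lo = max(0, tss - config.promoter_halfwidth)
        hi = min(sizes[m.chrom], tss + config.promoter_halfwidth)
        rate[m.chrom][lo:hi] = config.promoter_peak_fold * lam
        peaks.append(GenomicInterval(m.chrom, lo, hi, "."))
        exons_t = m.exons_transcript_order()
        for idx in range(1, len(m.introns) + 1):
            uid = f"{m.gene_id}.i{idx}"
            label = truth[uid]
            if label not in ("IR", "IE") or idx == 1:
                dhs_truth[uid] = False
                continue
            prob = config.dhs_prob_ir if label == "IR" else config.dhs_prob_ie
            if rng.random() < prob:
                exon3 = exons_t[idx]
                length = int(rng.integers(*config.dhs_length_range))
                length = min(length, len(exon3))
                start = exon3.start + int(rng.integers(0, len(exon3) - length + 1))
                rate[m.chrom][start : start + length] = config.dhs_fold * lam
                peaks.append(GenomicInterval(m.chrom, start, start + length, "."))
                dhs_truth[uid] = True
            else:
                dhs_truth[uid] = False
    for site in planted:
        lo = max(0, site["start"] - site["dip_halfwidth"])
        hi = min(sizes[site["chrom"]], site["end"] + site["dip_halfwidth"])
        rate[site["chrom"]][lo:hi] *= site["dip_factor"]
    values = {c: rng.poisson(r).astype(float) for c, r in rate.items()}
    return CoverageTrack(values, assay="dnase"), peaks, dhs_truth


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    models: list[GeneModel],
    truth: dict[str, str],
    genome: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CoverageTrack:
    """Beta-distributed per-cytosine methylation with class/region shapes.

    Cytosines (genomic C bases) inside event parts draw Beta(a, b) with the
    (class, region) shape from ``methylation_params`` (3' exon assignments
    win when an exon flanks two introns); read counts are Poisson, and
    count-0 sites are missing.
    """
    sizes = {c: len(s) for c, s in genome.items()}
    values = {c: np.full(n, np.nan) for c, n in sizes.items()}
    counts = {c: np.zeros(n, dtype=int) for c, n in sizes.items()}
    params = config.methylation_params
    default = params.get("default", (3.0, 3.0))

    shape_a = {c: np.full(n, np.nan) for c, n in sizes.items()}
    shape_b = {c: np.full(n, np.nan) for c, n in sizes.items()}
    # two passes so exon3 assignments win when an exon flanks two introns
    for pass_regions in (("exon5", "intron"), ("exon3",)):
        for m in models:
            for idx in range(1, len(m.introns) + 1):
                label = truth[f"{m.gene_id}.i{idx}"]
                if label not in ("IR", "IE"):
                    continue
                for region in pass_regions:
                    iv = _event_part_interval(m, idx, region)
                    a, b = params.get((label, region), default)
                    shape_a[m.chrom][iv.start : iv.end] = a
                    shape_b[m.chrom][iv.start : iv.end] = b
    for chrom, seq in genome.items():
        is_c = np.frombuffer(seq.encode(), dtype="S1") == b"C"
        mask = is_c & np.isfinite(shape_a[chrom])
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        n_reads = rng.poisson(config.methylation_read_depth, size=idx.size)
        fracs = rng.beta(shape_a[chrom][idx], shape_b[chrom][idx])
        keep = n_reads > 0  # count-0 cytosines are missing, not 0.0
        values[chrom][idx[keep]] = fracs[keep]
        counts[chrom][idx[keep]] = n_reads[keep]
    return CoverageTrack(values, assay="methylation", counts=counts)


# ---------------------------------------------------------------------------
# PWM collection
# ---------------------------------------------------------------------------

def simulate_pwm_collection(
    hexamers_to_embed: list[str],
    n_decoys: int,
    rng: np.random.Generator | int = 0,
    width: int = 8,
    strength: float = 0.97,
) -> tuple[list[Pwm], dict[tuple[str, str], bool]]:
    """PWMs whose consensus embeds the given hexamers, plus decoys.

    Embedded motifs have near-deterministic hexamer columns flanked by
    low-information columns, so the hexamer's covered IC fraction is >= 0.5
    (truth positive).  Decoy consensus strings avoid every embedded hexamer
    (truth negative).  Returns (pwms, truth) with truth keyed by
    (hexamer, motif_id).
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if width < 6:
        raise ValueError("cannot embed a hexamer in fewer than 6 columns")
    hexamers_to_embed = [h.upper() for h in hexamers_to_embed]

    def strong_column(base: str) -> list[float]:
        col = [(1 - strength) / 3] * 4
        col["ACGT".index(base)] = strength
        return col

    def weak_column() -> list[float]:
        col = np.full(4, 0.2)
        col[rng.integers(0, 4)] = 0.4
        return list(col)

    pwms, truth = [], {}
    for i, h in enumerate(hexamers_to_embed):
        offset = int(rng.integers(0, width - 5))
        cols = []
        for j in range(width):
            if offset <= j < offset + 6:
                cols.append(strong_column(h[j - offset]))
            else:
                cols.append(weak_column())
        pwms.append(Pwm(motif_id=f"embed_{i:03d}_{h}", matrix=np.array(cols)))
    for i in range(n_decoys):
        for _ in range(1000):
            cols = [strong_column(BASES[int(b)])
                    for b in rng.integers(0, 4, size=width)]
            p = Pwm(motif_id=f"decoy_{i:03d}", matrix=np.array(cols))
            if not any(h in p.consensus for h in hexamers_to_embed):
                break
        else:
            raise RuntimeError("could not draw a decoy avoiding all hexamers")
        pwms.append(p)
    for h in hexamers_to_embed:
        for p in pwms:
            truth[(h, p.motif_id)] = p.motif_id.startswith("embed_") and h in p.consensus
    return pwms, truth


# ---------------------------------------------------------------------------
# labelled HMM training profiles
# ---------------------------------------------------------------------------

def make_reference_hmm(
    fp_mean: float = 0.35,
    edge_mean: float = 0.65,
    bg_mean: float = 1.0,
    secondary_fp_mean: float = 0.55,
    secondary_edge_mean: float = 0.80,
    fp_var: float = 0.01,
    edge_var: float = 0.02,
    bg_var: float = 0.02,
    background_coverage: float = 1.0,
) -> FootprintHmm:
    """The ground-truth 13-state HMM used to generate labelled profiles.

    Emission means are on the standardized-coverage scale (background 1.0;
    the primary footprint dip at ``fp_mean``).  Secondary footprints —
    tandem motifs up- or downstream of the primary one — are generated
    shallower than the primary dip, so decoding reserves the primary
    footprint state for the deep hexamer-centered dip.
    ``background_coverage`` sets ``c_train``, the raw coverage level of the
    data the model will decode: :func:`simulate_labeled_profiles` multiplies
    sampled values by it, so training profiles land on the same raw scale
    as the DNase track.
    """
    means = np.empty(N_STATES)
    variances = np.empty(N_STATES)
    for name, i in STATE_INDEX.items():
        secondary = name.endswith(("u", "d"))
        if name.startswith("BG"):
            means[i], variances[i] = bg_mean, bg_var
        elif name.startswith("FP"):
            means[i] = secondary_fp_mean if secondary else fp_mean
            variances[i] = fp_var
        else:  # DN / UP ramps
            means[i] = secondary_edge_mean if secondary else edge_mean
            variances[i] = edge_var
    t = np.zeros((N_STATES, N_STATES))

    def set_t(src, **dest):
        for d, p in dest.items():
            t[STATE_INDEX[src], STATE_INDEX[d]] = p

    set_t("BG1", BG1=0.96, DNu=0.01, DN=0.03)
    set_t("DNu", DNu=0.5, FPu=0.5)
    set_t("FPu", FPu=0.8, UPu=0.2)
    set_t("UPu", UPu=0.5, BGu=0.5)
    set_t("BGu", BGu=0.9, DN=0.1)
    set_t("DN", DN=0.6, FP=0.4)
    set_t("FP", FP=0.92, UP=0.08)
    set_t("UP", UP=0.6, BG2=0.35, BGd=0.05)
    set_t("BGd", BGd=0.95, DNd=0.05)
    set_t("DNd", DNd=0.5, FPd=0.5)
    set_t("FPd", FPd=0.8, UPd=0.2)
    set_t("UPd", UPd=0.5, BG2=0.5)
    set_t("BG2", BG2=1.0)
    return FootprintHmm(
        transitions=t, means=means, variances=variances,
        c_train=float(background_coverage),
    )


def simulate_labeled_profiles(
    hmm: FootprintHmm,
    n_profiles: int,
    length: int = WINDOW_LEN,
    rng: np.random.Generator | int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sample (values, state-label) pairs from a known footprint HMM."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    out = []
    for _ in range(n_profiles):
        states = np.empty(length, dtype=int)
        states[0] = rng.choice(N_STATES, p=hmm.start)
        for tpos in range(1, length):
            states[tpos] = rng.choice(N_STATES, p=hmm.transitions[states[tpos - 1]])
        values = rng.normal(
            hmm.means[states], np.sqrt(hmm.variances[states])
        )
        values = np.maximum(values, 0.0) * hmm.c_train
        out.append((values, states))
    return out


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete dataset from one seed, in a fixed draw order."""
    rng = np.random.default_rng(config.seed)
    models, genome = simulate_genes(config, rng)
    genome_len = len(genome["chr1"])
    truth = assign_intron_truth(models, config, rng)
    rna, _ = simulate_rna_coverage(models, config, rng, genome_len, truth)
    genome, planted = plant_footprint_sequences(models, truth, genome, config, rng)
    dnase, peaks, dhs_truth = simulate_dnase_coverage(
        models, truth, genome, config, rng, planted
    )
    methylation = simulate_methylation(models, truth, genome, config, rng)
    return SyntheticDataset(
        config=config, genome=genome, models=models, rna=rna, dnase=dnase,
        dhs_peaks=peaks, methylation=methylation, intron_truth=truth,
        planted_footprints=planted, dhs_truth=dhs_truth,
    )
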