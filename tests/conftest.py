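import itertools

import numpy as np
import pytest

from irchrom.core import GenomicInterval, GeneModel, CoverageTrack
from irchrom.simulate import (
    SimulationConfig, FootprintSpec, simulate_dataset,
    make_reference_hmm, simulate_labeled_profiles,
)
from irchrom.footprints import train_footprint_hmm


def random_hexamers(rng: np.random.Generator, n: int, avoid=(), unrelated_to=()):
    """n distinct random hexamers avoiding a set; with ``unrelated_to``,
    candidates sharing a 4-mer with any listed hexamer (distance-0 variants
    of the same element) are also rejected."""
    from irchrom.motifs import hexamer_distance

    avoid = set(avoid)
    out = []
    while len(out) < n:
        h = "".join(rng.choice(list("ACGT"), 6))
        if h in avoid or h in out:
            continue
        if any(hexamer_distance(h, p) == 0 for p in unrelated_to):
            continue
        out.append(h)
    return out


ALL_HEXAMERS = ["".join(t) for t in itertools.product("ACGT", repeat=6)]


@pytest.fixture
def two_intron_gene():
    """A 3-exon '+' gene: exons [0,100), [150,250), [300,400)."""
    exons = [
        GenomicInterval("chr1", 0, 100, "+"),
        GenomicInterval("chr1", 150, 250, "+"),
        GenomicInterval("chr1", 300, 400, "+"),
    ]
    return GeneModel(gene_id="gA", transcript_id="gA.t1", strand="+", exons=exons)


def make_rna_track(model, exon_depth, intron_depths, size=500):
    """Coverage with constant exonic depth and given per-intron fill values
    (scalar per intron, or an explicit array)."""
    cov = np.zeros(size)
    for e in model.exons:
        cov[e.start:e.end] = exon_depth
    for intron, d in zip(model.introns, intron_depths):
        cov[intron.start:intron.end] = d
    return CoverageTrack({"chr1": cov}, assay="rna")


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-gene dataset with DHS planting and no ambiguity."""
    cfg = SimulationConfig(seed=101, n_genes=60, dhs_prob_ir=0.5, dhs_prob_ie=0.05)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def trained_hmm():
    truth = make_reference_hmm(background_coverage=20.0)
    profiles = simulate_labeled_profiles(truth, 300, rng=7)
    return train_footprint_hmm(profiles)


@pytest.fixture(scope="session")
def reference_hmm():
    return make_reference_hmm(background_coverage=20.0)
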