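# irchrom

Intron retention meets chromatin accessibility: a tested, reusable pipeline
for asking whether retained introns sit in open chromatin, and for finding
the protein footprints that open chromatin leaves in DNase I-seq coverage.

## The problem

Intron retention (IR) is the most common form of alternative splicing in
plants. Because splicing happens co-transcriptionally, chromatin structure —
measured genome-wide by DNase I-seq as hypersensitive sites (DHSs) and, at
base resolution, as protein *footprints* — is a natural candidate regulator
of IR. This package implements the complete analysis chain connecting the
two:

1. **Event calling** (`irchrom.events`). From gene models and per-base
   RNA-seq coverage, an intron is *retained* (IR) when every base has
   coverage ≥ 1 and *excised* (IE) when every base has coverage 0; introns
   with partial coverage are ambiguous and dropped. Genes need a mean exonic
   read depth ≥ 20 to be considered. First introns are excluded downstream
   (they overlap the promoter DHS), and IE events are matched to IR events
   by relative position within the gene to control for 5'→3' coverage bias.
2. **DHS and methylation statistics** (`irchrom.chromatin`). DHS content
   (fraction of events — intron plus flanking exons — overlapping a peak),
   length-normalized bin profiles across event parts, gene-level coverage
   profiles around the TSS, per-event coverage comparison (Mann–Whitney U),
   and read-count-weighted methylation profiles.
3. **Footprint discovery** (`irchrom.footprints`). For every hexamer, the
   DNase coverage over its occurrences (±100 bp, clipped at part boundaries,
   lowest-coverage instance per part) is averaged into a 206-position
   profile, standardized by the training background C_train, and decoded by
   a 13-state continuous HMM (background → down → footprint → up →
   background, with optional secondary footprint blocks for tandem motifs).
   Each hexamer is scored by

   &nbsp;&nbsp;&nbsp;&nbsp;**S = −log(C_FP / C_BG)**

   where C_FP is the mean standardized coverage decoded as the primary
   footprint state and C_BG the mean over background states; S ≥ 0.30 calls
   a footprint (0.20 in cross-species work).
4. **Enrichment and conservation** (`irchrom.stats`). Per-hexamer IR vs IE
   presence/absence Fisher tests with Benjamini–Hochberg control, the
   hypergeometric test for the overlap of two species' hexamer sets over the
   4096-hexamer universe, and the exact multi-set intersection distribution
   (iterated hypergeometric mixing) for simultaneous overlap of many sets.
5. **Motifs** (`irchrom.motifs`). Hexamer clustering under a k-mer metric
   (distance 0 when two hexamers share a 4-mer, edit distance otherwise;
   complete linkage, cut at height 4), consensus strings with degenerate
   positions, positional-preference histograms, and PWM matching under the
   exact-consensus + ≥50%-information-content rule.
6. **Synthetic data** (`irchrom.simulate`). Seeded generators produce every
   input the pipeline consumes — genomes, gene models, RNA/DNase coverage,
   DHS peaks, methylation, labelled HMM training profiles and PWM libraries
   — together with the ground truth behind them, so the whole analysis is
   testable end to end without downloads.

## Worked example

```python
from irchrom import (
    SimulationConfig, FootprintSpec, simulate_dataset,
    call_intron_events, exclude_first_introns, dhs_content,
    make_reference_hmm, simulate_labeled_profiles, FootprintModel,
)

cfg = SimulationConfig(
    seed=7, n_genes=120,
    footprint_hexamers=(FootprintSpec("CCGCCG", "exon3", dip_factor=0.3,
                                      dip_halfwidth=10, prob_ir=0.4),),
)
ds = simulate_dataset(cfg)
events = exclude_first_introns(call_intron_events(ds.models, ds.rna))
table = dhs_content(events, ds.dhs_peaks)
print(f"DHS content: IR {100 * table.dhs_content_ir:.1f}% vs "
      f"IE {100 * table.dhs_content_ie:.1f}% (Fisher p = {table.p_value:.2g})")

truth = make_reference_hmm(background_coverage=cfg.dnase_background_rate)
result = FootprintModel(simulate_labeled_profiles(truth, 500, rng=8)).fit()
scored, _ = result.scan(events, ds.genome, ds.dnase,
                        parts=("exon3",), classes=("IR",),
                        hexamers=["CCGCCG", "ACGTAC"])
print(scored[["hexamer", "n_occ", "c_fp", "c_bg", "S", "is_footprint"]]
      .to_string(index=False))
```

prints

```
DHS content: IR 24.7% vs IE 4.1% (Fisher p = 9.4e-05)
hexamer  n_occ     c_fp     c_bg        S  is_footprint
 CCGCCG     27 0.358537 1.547884 1.462611          True
```

The planted hexamer CCGCCG was found in 27 retained-intron 3' exons; its
averaged profile dips to 0.36× the training background inside the decoded
footprint against a local background of 1.55× (elevated by DHS peaks), giving
S = 1.46, well above the 0.30 cutoff. The control hexamer ACGTAC occurred
fewer than 10 times at this scale and is reported in the unscored table
rather than being scored from thin evidence.

The same stages are scriptable from a shell:

```bash
irchrom simulate --seed 7 --out data/
irchrom events --gff data/genes.gff3 --rna data/rna.bedgraph --fasta data/genome.fa
irchrom chromatin --gff data/genes.gff3 --rna data/rna.bedgraph \
    --fasta data/genome.fa --dhs data/dhs.bed --dnase data/dnase.bedgraph
irchrom footprints train --profiles profiles.tsv --out hmm.json
irchrom footprints scan --gff data/genes.gff3 --rna data/rna.bedgraph \
    --fasta data/genome.fa --dnase data/dnase.bedgraph --hmm hmm.json
```

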