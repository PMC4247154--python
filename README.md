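# revscreen

Quantification toolkit for **reporter-reversion RNAi screens** — the
cell-based assay design in which a *gfp*-expressing insect reporter line
(e.g. *Spodoptera frugiperda* Sf21-*gfp*) is co-transfected with a
*gfp*-silencing siRNA and a test siRNA; if the test siRNA knocks down a gene
the RNA-interference machinery needs, *gfp* silencing fails and fluorescence
"reverts". The package covers the full computational path of such a screen,
for bench scientists and analysts who have flow-cytometry event data, qPCR
Ct tables, homology-search hit tables and protein alignments, and want the
numbers in between reproduced exactly:

1. **Synthetic data** (`revscreen.simulate`) — seeded generators for
   event-level flow cytometry (two-component log-normal mixture), qPCR Ct
   tables with known fold-change structure, and toy protein families evolved
   on a known tree.
2. **Gating** (`revscreen.gating`) — percent-*gfp*-positive per well, with a
   threshold set at an upper quantile (default 99.5%) of the non-fluorescent
   parental line.
3. **Reversion scoring** (`revscreen.reversion`) — with A, B, C the percent
   *gfp*-positive in the test co-transfection, the *gfp*-silenced control and
   the untouched reporter line,

   ```
   %reversion = 100 · (A − B) / (C − B)
   ```

   aggregated per gene as the maximum-reversion siRNA's triplicate
   mean ± SD, with threshold-plus-forced-include hit calling.
4. **Knockdown validation** (`revscreen.qpcr`) — the comparative-Ct method:
   ΔCT = target − reference Ct, ΔΔCT = sample − calibrator,
   fold change = 2^−ΔΔCT, knockdown % = 100 · (1 − 2^−ΔΔCT).
5. **Ortholog calling** (`revscreen.orthologs`) — candidate filter (best hit
   must cover > 70% of the query) and per-organism ortholog filter (lowest
   e-value hit with identity **or** coverage > 50%), assembled into a
   cross-species presence/absence matrix pairing in-silico identification
   with in-vivo validation.
6. **Phylogenetics** (`revscreen.phylo`) — complete deletion of gap/missing
   columns, p-distance (amino-acid differences per site), hand-written
   neighbour joining with deterministic tie-breaks, bootstrap supports
   (default 1500 replicates), Newick output.

A bundled, literature-transcribed 42-gene validated-factor table and the
matching cross-species matrix serve as reference fixtures.

## Worked example

Run the whole pipeline on the built-in synthetic dataset (10 genes with true
reversion effects r = 0.0, 0.1, …, 0.9; three siRNAs × three replicates per
gene; one six-taxon protein family):

```sh
revscreen all --seed 7 --outdir demo
```

```
INFO revscreen: simulate: 99 FACS samples, 6 qPCR genes, 6 taxa
INFO revscreen: gate: 99 samples gated at quantile 0.995
INFO revscreen: screen: 9/10 genes pass (threshold 5%, 0 forced)
INFO revscreen: qpcr: 6 genes quantified from 72 wells
INFO revscreen: ortho: 30 hits in, 6 putative candidates
INFO revscreen: phylo: 6 taxa, 294 retained sites, 1500 bootstrap replicates
```

`demo/screen_report.tsv` then holds the per-gene reversion estimates — e.g.
gene `G05` (true effect r = 0.4) is scored 40.33 ± 0.55 %reversion, and the
r = 0 gene is the one non-hit, so the effect ladder is recovered.
`demo/knockdown_report.tsv` inverts the simulated 0.25 fold change from noisy
Cts (e.g. `G01`: fold change 0.278, knockdown 72.2%), and `demo/tree.nwk`
recovers the generating topology with 100% bootstrap support on every
internal edge:

```
((Ce:0.145408,Nl:0.106293)100:0.085884,(Dm:0.085884,Tc:0.077381)100:0.057823,
 (Bm:0.057398,Sf:0.048044)100:0.054422);
```

Scoring the bundled reference table instead reproduces the published
accounting — 41 threshold-passing genes plus one literature-rescued forced
include = 42 validated factors:

```sh
revscreen screen --fixture --outdir demo
```

Every artifact gets a `.meta.json` sidecar with the seed and config hash;
re-running any stage with the same seed is byte-identical.

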