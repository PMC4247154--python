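# Methods

## The assay and its statistic

A reporter-reversion RNAi screen measures whether knocking down a candidate
gene disables the RNA-interference machinery itself. A stably
*gfp*-expressing reporter line is silenced with a *gfp* siRNA; co-transfecting
a test siRNA against a functional RNAi factor blocks that silencing, and the
reporter fluorescence "reverts". Three populations are quantified by flow
cytometry as percent *gfp*-positive cells: the test co-transfection (A), the
*gfp*-silenced control (B) and the untouched reporter line (C). The per-well
statistic is

    %reversion = 100 · (A − B) / (C − B),

0 for no effect on silencing and 100 for a complete rescue. Each gene is
assayed with several independently designed siRNAs; the siRNA with the
maximum mean reversion is selected and the gene is reported as that siRNA's
replicate mean ± sample (n−1) SD. A gene is a validated factor when this
mean clears a threshold, or when it appears on an explicit forced-include
list (genes retained on external literature evidence although their own
assay was uninformative).

### Numerical conventions

* **Denominator floor.** |C − B| < 0.5 percentage points means the *gfp*
  silencing itself failed, so the ratio is undefined; the package raises
  `UninformativeAssayError` rather than returning an unstable number.
* **No clamping.** Reversion values below 0 or above 100 are returned as
  computed and flagged `out_of_range`; clamping would hide over-reversion
  and paradoxical effects.
* **Hit threshold.** Default 5% mean reversion. The published class
  boundary is not stated explicitly; the smallest reversions reported as
  real in this assay family are ≈ 9–11%, while excluded genes show
  negligible or mild reversion, so 5% separates the two classes with margin
  on both sides. It is a configurable parameter, not a claim about the
  original analysis.
* **Ties** on the best siRNA break toward the lexicographically smallest
  siRNA id, for determinism.

## Gating model

Events are gated on a single fluorescence channel with a strictly-greater
threshold; the parent gate is all events (no scatter gating is modelled).
The threshold is the empirical 99.5th percentile (numpy's linear-interpolation
quantile) of the non-fluorescent parental line, so at most 0.5% of negative
events leak through. Because the same leakage enters A, B and C, it cancels
almost exactly in the reversion ratio. Percent positive is non-increasing in
the threshold and invariant under joint positive rescaling of events and
threshold; both are property-tested.

## Synthetic flow cytometry

Fluorescence is a two-component mixture in log space: events are *gfp*-negative
(log-normal, μ = ln 10, σ = 0.5) or *gfp*-positive (μ = ln 1000, σ = 0.5),
arbitrary linear units. The positive fraction is determined by the
population's role:

| role      | positive fraction                  | default |
|-----------|------------------------------------|---------|
| plain     | 0                                  | 0       |
| reporter  | π                                  | 0.90    |
| silenced  | π_B = π(1 − s)                     | 0.09    |
| test      | π_A = π_B + r_eff (π − π_B)        | —       |

with π the reporter-line positive fraction, s the silencing efficiency
(default 0.9) and r_eff = r · (per-siRNA efficacy). Transfection
heterogeneity is absorbed into s and r rather than modelled per cell, since
the assay quantifies only population fractions. Per-siRNA efficacy
multipliers default to (1.0, 0.6, 0.3) so max-over-siRNA aggregation is
genuinely exercised; real siRNAs against one gene routinely span such a
potency range. Each sample draws from an independent substream
(`SeedSequence(seed, spawn_key=(counter,))`, counter assigned in design
order), so a sample's events do not depend on generation order and a fixed
seed is bit-reproducible.

What this emulates — and does not: mixture locations and fractions with
binomial sampling noise, yes; instrument artifacts (spillover, doublets,
debris, autofluorescence drift, scatter structure), no. Passing recovery
tests therefore show the estimator chain is correct under the stated
mixture, not that a particular cytometer's gate geometry is reproduced.

## qPCR model and comparative Ct

Relative expression uses the classic comparative-Ct method with
amplification efficiency fixed at 2 and no efficiency correction: technical
replicate Cts are averaged per role on the Ct scale, ΔCT = mean target −
mean reference per role, ΔΔCT = ΔCT_sample − ΔCT_calibrator, fold change =
2^−ΔΔCT, knockdown % = 100(1 − fold). Biological replicates enter the same
pooled Ct average; well counts are reported so a reader can see the support.

The simulator places sample-well target Cts −log₂(fold) cycles above the
calibrator's target Cts (default calibrator target mean 24 cycles, exposed
as `ct_target_calibrator_mean`), adds Gaussian per-well noise (default sd
0.2 cycles) to the target channel, and gives every well the one fixed
reference-channel mean (default 16 cycles) — the endogenous-control channel
is treated as the stable anchor of the design. Under this model the ΔΔCT
estimator has sd ≈ 0.2·√(2/6) ≈ 0.115 cycles at the default 2 biological ×
3 technical replicates, which is what the recovery tests check (within 20%
of the true fold change in ≈ 98% of runs).

## Homology filters

Hit tables are the standard 12-column tab-separated pairwise-alignment
layout, optionally extended with `qlen` and `%query-coverage`; with 12
columns, coverage is computed from the single best-HSP span (merged-HSP
coverage is deliberately not implied). Best hits order by (e-value,
−bitscore, subject id). Both published thresholds are read as strict
inequalities — candidate calls require coverage **> 70%**, per-organism
ortholog calls require identity **or** coverage **> 50%** — so the boundary
values 70.0 and 50.0 are rejected; both thresholds are configurable and both
filters are monotone by construction. Alignment identity between two rows
counts identical columns among columns where both sequences are ungapped,
matching the complete-deletion logic of the phylogenetics stage.

The comparative matrix stores, per gene × organism, the pair (in-silico
identification, in-vivo validation) as `+`/`−` with free-text homolog notes
passed through verbatim; a validation flag without in-silico support (or a
note) is rejected as inconsistent.

## Phylogenetics

* **Complete deletion**: every column containing `-`, `.`, `?` or `X` in any
  row is removed; missing-data symbols are treated exactly like gaps.
* **p-distance**: fraction of differing residues over retained columns.
* **Neighbour joining**: Saitou–Nei agglomeration on the Q-criterion with
  the standard two-point branch-length formulas. Ties in the Q minimum break
  on the smallest (i, j) pair in the current join order; a negative
  estimated branch length is set to zero with the deficit moved to its
  sibling edge (the closing 3-taxon star clamps at zero). For additive
  inputs the generating topology and all path lengths are recovered exactly;
  tests verify this against an exhaustive least-squares topology oracle
  (4 taxa) and an independent NJ implementation (scikit-bio).
* **Bootstrap**: retained columns are resampled with replacement; each
  replicate is rebuilt with p-distance + NJ and an internal edge's support
  is the percent of replicates containing its bipartition. Default 1500
  replicates; the test suite and the demo family use 20–100 for desk-scale
  runs. Supports are deterministic under a fixed seed.
* **Newick**: branch lengths at 6 decimals, supports as integer internal
  labels; round trips preserve the bipartition set, lengths and supports.

## Synthetic protein families

A root sequence drawn uniformly over the 20 amino acids evolves along a
user-specified edge list; on a branch with substitution probability p each
site is independently redrawn uniformly from the alphabet (the redraw may
restore the original residue). This gives a clean closed form used as a test
oracle: two leaves joined by branches p₁, p₂ mismatch per site with
probability (1 − (1−p₁)(1−p₂)) · 19/20. Gap columns are punched into one
uniformly chosen taxon at rate `gap_rate`. No indel process or
rate-heterogeneity is modelled; the generator exists to provide ground-truth
topologies and identities, not realistic protein evolution.

The emitted all-vs-all hit tables set identity to 100·(1 − observed
p-distance) over both-ungapped columns, so they agree exactly with
`pairwise_identity` on the same rows.

## Bundled reference fixtures

`revscreen/data/` carries a transcription of the published 42-gene
validated-factor table (category, %reversion, per-organism identity
columns), the matching cross-species presence/absence matrix, and the two
control siRNA sequences. In the source text several identity integers and a
few trailing matrix cells are typographically ambiguous; those cells are
best-effort and marked as transcription in the module docstring. They are
display columns only — the quantity the package computes from this fixture,
the 41-threshold-hits-plus-one-forced-include = 42 accounting, depends only
on the reversion column and the forced-include flag, which are unambiguous.

## Problem sizes

Defaults were chosen so a full desk run stays interactive: recovery checks
use 10 genes × 3 siRNAs × 3 replicates at 10⁴ events per well; NJ exactness
uses hundreds of random additive matrices on 4–8 taxa; bootstrap calibration
uses a 4-taxon, 500-residue family at 100 replicates. These sizes already
pin the estimators' behaviour (binomial standard errors < 1 percentage
point); larger runs only shrink Monte-Carlo noise.

## Known limitations

* The gate is a one-channel threshold; published per-well percentages from
  any specific instrument/software gate cannot be regenerated without that
  gate's geometry.
* The hit threshold and the forced-include mechanism are explicit,
  configurable stand-ins for a published selection step that was partly
  curatorial; exact reproduction of a curated candidate list is not an
  algorithmic claim.
* Query coverage from 12-column hit tables uses the best single HSP; tools
  that merge HSPs will report higher coverage near the 70% boundary.
* NJ follows one deterministic tie/negative-branch policy; other programs'
  trees may differ on degenerate inputs even with identical distances.
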