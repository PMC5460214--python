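# Methods

This note documents the statistical procedures, the defaults and the design
choices behind `samirnet`, and what the synthetic benchmarks do and do not
establish about real data.

## Transcript differential expression

The transcriptome has a single RPKM value per gene per condition (SR,
SEN), so no per-gene variance is estimable and the statistics are
descriptive:

* `FC = log2(SEN / SR)` — when either value falls below the pseudocount
  (default 0.01 RPKM) it is added to both values before the ratio; genes
  with both values above it keep the exact ratio. The bundled published
  table contains no zeros, so its values are unaffected.
* `dRPKM = SEN − SR` — the plain difference in RPKM. The published table's
  arithmetic forces this reading (e.g. INHBA: 177.25 − 282.13 = −104.88,
  matching the printed column) even though such data are often displayed
  on a log-scaled difference axis.
* `D = sqrt(FC² + log2(|dRPKM|)²)` — a Euclidean combination of the ratio
  and the log-scaled absolute difference, used to rank genes that move
  strongly on both scales. The closed form is a reconstruction: it
  reproduces the printed `D` column for all 558 bundled rows at 2 dp
  (±0.01 slack on `dRPKM` for upstream rounding of the printed SR/SEN
  inputs), which is the sole evidence for it; its provenance is therefore
  empirical, and the formula is validated by a dedicated test rather than
  assumed. For `|dRPKM| < 1` (including 0) the log term is clamped to 0 so
  D stays real and degrades to `|FC|` near the origin.

Quadrant calls require sign-concordant exceedance of both thresholds:
*down* iff `FC ≤ −fc_min` and `dRPKM ≤ −drpkm_min` (symmetrically for
*up*). Defaults `fc_min = 0.58` (1.5-fold) and `drpkm_min = 5.0` RPKM are
chosen so that the selection boundary just admits the weakest entries in
the bundled table (smallest magnitudes |FC| = 0.59, |dRPKM| = 5.03); both
are configurable because no canonical values exist for these descriptive
cut-offs. Ranking ties on D break lexicographically by gene then
transcript so output order is reproducible.

Comparisons against printed 2-dp values use half-away-from-zero rounding,
matching table formatting conventions.

## Protein differential abundance

Each protein row is tested with a two-tailed unpaired Student's t-test,
pooled-variance by default (the classical form for triplicate designs);
Welch is available as a flag. The t statistic is oriented SEN − SR and
`direction` is the sign of the mean difference. Degenerate rows with zero
variance in both groups give (t = 0, p = 1) when the means agree and the
smallest positive double with a warning when they differ. Rows with
missing intensities are rejected rather than imputed, since no defensible
imputation model is available for arbitrary intensity units; the input
matrix is tested as provided, with no proteome-wide normalisation beyond
the per-row z-scores `(x − mean)/sd` (sample sd, n−1) used for display.

No multiple-testing correction is applied by default — the integration
stage consumes the raw p ranking — but Benjamini–Hochberg adjusted
p-values can be added with a flag. The `alpha = 0.05` default is the
conventional per-test level.

Calibration facts (verified by simulation in the test suite): the
empirical type-I error at α = 0.05 over 10,000 null rows (3 vs 3 Gaussian)
lies in [0.04, 0.06]; the power at a mean shift of exactly 3 within-group
sd is ≈ 0.78, in agreement with the noncentral-t closed form
(ncp = 3/√(2/3), df = 4, exact power 0.7826). A power of 0.8 is therefore
not reachable in this design at exactly 3 sd; it requires a shift of about
3.1 sd or a fourth replicate.

## Target integration

mirSVR scores are consumed, never computed. Predictions are retained when
`score < −0.2` strictly — the boundary value itself is excluded. Scores
printed at 2 dp can display as −0.20 while lying below the boundary; at
printed precision such rows are dropped, which only matters when feeding
the filter a rounded table. Transcript-level predictions collapse to gene
level by the most negative score across transcripts, because the
downstream intersections and the Venn summary are gene/protein-level;
transcript-level counts are also reported since the appropriate
granularity for published aggregate counts is ambiguous.

Regulation modes follow from set membership: *degradation* (mRNA-down
only), *translational_repression* (protein-down only — the pattern
reported for SMARCA5 and HOXA1 under mir-100-5p), *both*, or
*predicted_only*. The co-targeting matrix is a 0/1 gene × miRNA incidence;
`clusters_hit` maps targeting miRNAs to their host loci (MIR17HG:
mir-17-5p, mir-18a-5p, mir-19a-3p, mir-20a-5p, mir-92a-1-5p, mir-19b1-5p;
MIR100HG: mir-100-5p, mir-125b-5p, let-7a-2-3p); unknown miRNAs are
labelled `other` with a warning rather than rejected.

A published-table quirk handled on input: duplicate (miRNA, transcript)
rows occur (TSC22D3/NM_198057 appears twice in one block with two scores);
the reader collapses exact duplicate keys to the most negative score with
a warning instead of rejecting the file.

## Steiner sub-networks and enrichment

The objective is minimum node count (unit edge weights): category seeds
should be "transitively linked" through as few intermediates as possible.
The Takahashi–Matsuyama heuristic grows the tree from the
lexicographically first seed and repeatedly attaches the nearest
unconnected seed along a shortest path; every tie (nearest seed, path
choice) breaks lexicographically, so the tree is a deterministic function
of the graph and seed set, independent of seed input order. The heuristic
has the classical 2(1 − 1/ℓ) approximation guarantee and, on random
instances small enough to solve exactly by subset enumeration (the
`minimum_steiner_tree_exact` oracle), matches the optimum in ≥ 95% of
cases and never beats it. A weighted mode (edge cost 1 − confidence) is
available for confidence-scored networks. Seeds absent from the graph are
dropped with a warning; seeds spread over several components yield a
per-component forest with a flag, and the size statistic then counts all
retained components.

Edge classes for export: *tree* edges form the connecting trees; *intra*
edges are additional graph edges inside one category's sub-network; *inter*
edges join different categories' sub-networks. The classes are disjoint by
construction.

Enrichment: for a category with k retained seeds, `n_sim` (default 1000)
random k-subsets are drawn uniformly without replacement from the null
universe — by default all graph nodes; optionally the SEN-downregulated
genes (plus the observed seeds, which are always eligible) — and the
Steiner size of each is recorded. The add-one estimator
`p = (1 + #{null ≤ observed}) / (n_sim + 1)` bounds p away from 0 and
makes it valid (stochastically ≥ uniform under the null, verified by
simulation). Monte-Carlo p-values agree with exhaustive enumeration over
all C(n, k) seed sets within sampling error on fully enumerable graphs.
The choice of universe, n_sim and tie-breaking are free parameters of this
kind of analysis with no canonical values; the defaults above are the
package's documented choices.

## Synthetic data

The generators produce inputs with the marginal structure the analysis
assumes, each from an independent substream of one seed (bit-reproducible):

* Expression: SR ~ log-normal(μ = 3, σ = 1.2 on the natural-log scale;
  median ≈ 20 RPKM, heavy right tail spanning the published 0.56–529 RPKM
  range); SEN = SR · 2^e with e ~ N(−2, 0.5) for the planted 10% down
  genes, N(+2, 0.5) for 5% up, N(0, 0.15) for the rest. At the default
  thresholds this yields quadrant recall ≥ 0.8 for planted down genes and
  false-positive rate ≤ 5%.
* Proteins: 3 + 3 replicates, within-group sd 1, planted down shift of 3 sd
  for 10% of rows; a configurable fraction (default 0.3) of the planted
  down proteins is assigned to genes *not* down at the mRNA level,
  planting translational-repression cases.
* Targets: per-miRNA gene draws over-sample mRNA-down genes (weight 4);
  scores are uniform on (−1.35, −0.201] with probability
  `score_frac_below` (default 0.7) and on [−0.2, 0] otherwise, matching
  the published score range.
* Network: Barabási–Albert (m = 2) or duplication-divergence background
  over 300 of the simulated genes, with a randomly placed module of 15
  nodes rewired to pairwise density 0.6 — the functionally coherent
  category the enrichment should detect. Test and acceptance runs use
  scaled-down graphs (80–120 nodes, module size 8) so the full benchmark
  suite completes in seconds.

What passing on synthetic data does **not** show: real RPKM values are not
log-normal draws with independent effects; real protein intensities have
correlated, non-Gaussian noise and missingness; real mirSVR scores and
STRING edges have structured biases. The benchmarks establish algorithmic
correctness and statistical calibration under the stated model, not
biological validity of any particular gene call. Dataset-scale published
counts (hundreds of down-regulated genes/proteins, thousands of predicted
targets) depend on the original deposited data and prediction database and
are outside what the package can or does reproduce.

## Numerical and degenerate-input conventions

* Unicode minus (U+2212) is normalised to ASCII on all numeric input.
* Gene symbols are upper-cased everywhere (STRING/GMT inputs mix cases).
* p-values are clipped to the smallest positive double; −log10 p is then
  always finite and strictly decreasing in p.
* Empty expression tables and empty target tables are warnings, not
  errors; invalid values (negative RPKM, non-numeric fields, malformed GMT
  lines) are validation errors naming the offending row or line.
* Pipeline reruns with identical inputs and seed are byte-identical; all
  report JSON is written with sorted keys and no timestamps.

## Known limitations

* The distance statistic D is an empirical reconstruction (see above).
* Single-replicate transcriptome: no significance statement is attached to
  quadrant calls; thresholds are descriptive.
* The null universe for enrichment is a modelling choice; p-values can
  shift materially between the all-genes and downregulated-genes universes
  on real data.
* The exact Steiner solver is exponential and guarded to small instances;
  it exists as an oracle, not an analysis path.
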