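# Methods

This note documents the models, statistics and numerical choices behind
`thermoadapt`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## The analysis in one paragraph

The package analyzes bulk log-scale expression matrices from a serial
thermal-adaptation experiment: an ancestor strain (`Anc`) and a lineage of
evolved strains (`41B`, `43B`, `45L`), each assayed in exponential growth at
the regular temperature (`r`), at its evolution temperature (`e`), and minutes
after an abrupt temperature upshift (`hs`, the heat-shock responsive state).
After global normalization and replicate averaging, it asks four questions:
(i) do conditions cluster into responsive versus steady states; (ii) how do
genotype-mediated (ΔG), temperature-mediated (ΔT) and heat-shock-induced
(ΔHS_A) expression changes correlate; (iii) which principal components carry
the reorganization and which genes and gene sets load on them; and (iv) is
the simultaneous change Δ(G+HS_A) smaller than the additive prediction
ΔG + ΔHS_A — negative epistasis, quantified as 1 − slope of an ordinary
least-squares fit.

## Normalization and profiles

Each array (column) is shifted so its median log-expression is zero
("global normalization"). The median of an even-length column is the mean of
the two central order statistics. Missing values are not permitted: loaders
fail loudly rather than impute, because the upstream array pipeline produces
complete matrices. Replicates are combined by the arithmetic mean into
profiles labeled `<strain>_<condition>` (e.g. `41B_r`, `45L_hs`).

All internal arithmetic is base-agnostic; the package treats values as log2
by convention (microarray practice), and every operation — correlation,
clustering, PCA, regression — is invariant to the choice of log base up to
an overall scale that cancels in the reported statistics.

## Condition clustering

Profiles are clustered agglomeratively on the distance `1 − Pearson r`
between profile columns, with average linkage; both are configurable
(`spearman`/`euclidean` distances, any scipy linkage) and recorded in the
output metadata. The tree is exported as Newick with branch lengths derived
from merge heights. Profiles are clustered in the caller's column order;
scipy's linkage is deterministic for a fixed order, which keeps trees
reproducible.

## Contrasts

Standard contrasts are differences of replicate-averaged profiles:

| name | definition | meaning |
|---|---|---|
| ΔG(s) | `s_r − Anc_r` | genotype-mediated change |
| ΔHS_A | `Anc_hs − Anc_r` | heat-shock-induced change (ancestor) |
| ΔT(s) | `s_e − s_r` | growth-temperature-mediated change |
| Δ(G+HS_A)(s) | `s_hs − Anc_r` | simultaneous change |

Correlations between contrasts use Pearson r on log values (matching
log–log scatter comparisons); p-values are two-sided from the t-distribution
with n − 2 degrees of freedom.

## PCA and gene selection

Arrays (or profiles) are the observations and genes the variables, so
components capture expression-level variance between culturing conditions.
The decomposition is covariance PCA: gene-wise centering, no unit-variance
scaling — scaling would erase the magnitude structure that makes PC1 track
growth rate. The sign of each component is fixed so its largest-magnitude
loading is positive, making results reproducible across linear-algebra
backends.

`top_loaded_genes` selects the ⌈αN⌉ most positively and ⌊αN⌋ most negatively
loaded genes per component (α = 0.05 by default). The ceil/floor split is
deliberate: on a 4,383-gene matrix it yields exactly 439 genes per component,
the size used for the per-component enrichment analysis. Whether "top 5%
each tail" should instead mean 2⌈αN⌉ genes is genuinely ambiguous; the
439-gene anchor fixes the convention here, and `tail_fraction` is
configurable. Ties are broken by gene-id order.

## Enrichment

Two tests, for two kinds of input:

**Binomial over-representation** (selected gene lists, e.g. PC top genes):
for a set of size K inside a universe of N genes and a selection of n genes
overlapping it in k, p = P(X ≥ k) with X ~ Binomial(n, K/N), computed as an
exact tail. The alternative is one-sided (enrichment) by default, with a
two-sided option. Bonferroni's multiplier is the number of sets tested.
The default significance level is 0.001.

**Ranked running-sum** (per-gene contrasts): genes are ranked by the
contrast, descending. For each set, member increments are proportional to
|delta|^p (p = 1 by default; p = 0 gives the classic KS statistic, invariant
to monotone rescaling of the contrast) and non-member decrements are
constant; the enrichment score (ES) is the signed maximum excursion of the
running sum. Significance comes from gene-label permutations: with two to
three replicates per condition, sample-label permutation is degenerate, so
random same-size gene sets form the null. Because the null depends only on
set size, it is computed once per unique size (1,000 permutations by
default) and shared. For an observed ES the p-value is the fraction of
same-signed null scores at least as extreme (with a +1 continuity guard);
NES divides ES by the mean same-signed null magnitude, and FDR q-values use
the standard positive/negative NES-ratio method. The running-sum extrema are
evaluated only at member positions (the path is linear between hits), which
makes each permutation O(K) after an O(N) setup.

The set-size filter keeps sets whose intersection with the analyzed universe
contains at least 16 genes ("more than 15"), applied after intersection.

## Negative epistasis

For each evolved strain, Δ(G+HS_A) is regressed on ΔG + ΔHS_A by OLS with a
free intercept (a through-origin option is provided); the reported magnitude
is exactly 1 − slope. No errors-in-variables correction is applied, for
fidelity to the plain regression the statistic is defined by — but note the
consequence: the additive contrast is itself noisy (it contains three
replicate means, the shared `Anc_r` entering twice), so the slope is
attenuated toward zero by a factor Var(signal)/(Var(signal)+Var(noise)).
With triplicate/duplicate designs and per-array noise σ = 0.3 log2 units,
the additive contrast carries ≈ 0.195 log2² of noise variance; the
generator's default effect sizes put 3–4 log2² of signal variance on it, so
the residual bias in 1 − slope is 0.02–0.04. Users can quantify the
attenuation for any configuration with the generator.

Restricting the regression to the most-displaced genes (e.g. the union of
top-loaded PC genes) does *not* narrow the slope's confidence interval under
this noise model — the √n loss beats the gain in regressor spread — but it
does shrink the attenuation bias, because the subset's signal variance rises
while the noise variance is unchanged. The subset option therefore trades
variance for bias; both full and subset fits are reported.

## The synthetic-data generator

`simulate()` produces a dataset with known ground truth. Default design:
4 strains × (3 `r` + 3 `e` + 2 `hs`) = 32 arrays over 4,000 genes. The
ancestor's `e` arrays (at the reference high temperature 44.8 °C) are
included by default and can be disabled; the deposited design is ambiguous
on this point, so it is an option rather than an assumption.

Per-gene log2 effects (defaults in parentheses):

- **baseline** ~ Normal(0, 1.5) — shared by every array.
- **heat-shock response**: an up-regulon of 6% of genes ~ Normal(+5, 1.5)
  (strong chaperone-like induction, ~30-fold at the mean), a repressed
  component of 12% ~ Normal(−2.5, 1.0) (growth and translation genes), and
  Normal(0, 0.5) background elsewhere. Together ≈ 2.7 log2² of variance.
- **genotype effects**: each evolved strain adds an independent
  Normal(0, 0.6) increment to its predecessor's effect (cumulative along the
  lineage); the ancestor's effect is identically zero.
- **temperature effects** ~ correlated mixture with the strain's genotype
  effect targeting Pearson ρ = −0.6 (mutation-moved expression is moved back
  by the growth temperature), sd 0.45. An optional per-strain
  `hs_alignment` coefficient adds a multiple of the heat-shock response to
  plant an increasing alignment between ΔT and ΔHS_A along the lineage; it
  is off by default because it also drags the evolved `e` profiles toward
  the responsive cluster.
- **epistasis**: in evolved strains the `hs` deviation is
  (1 − e)·(genotype + heat-shock) with e = 0.25 by default, so the
  population regression slope of the simultaneous on the additive change is
  1 − e by construction. The damping is keyed on strain identity (the
  ancestor is never damped), keeping the σ_G = 0 edge case well defined.
- **replicate noise** ~ Normal(0, 0.2) per gene and array.
- **growth rates**: each array gets
  `0.7 − 0.35 · RMS(expected displacement from the strain's own r-state)`
  h⁻¹ plus Normal(0, 0.02) jitter. Heat shock and growth at high temperature
  cost fitness; adaptive mutations do not (evolved strains are not slower at
  the regular temperature). This plants the growth axis that PC1 tracks
  (|r| ≈ 0.93 on default data).

The relative effect scales were fixed by a closed-form design analysis, not
by matching any particular dataset: the heat-shock variance must exceed
(5/3)·V_G + V_G²/Var(baseline) for the dendrogram's first split to separate
responsive from steady states, while the total contrast signal must exceed
roughly 2.5 log2² for the OLS attenuation bias of the epistasis estimate to
stay within 0.05 under σ = 0.3 noise. The defaults (V_hs ≈ 2.7,
σ_G = 0.6) satisfy both with margin.

Gene sets are sampled uniformly without replacement (20 sets, sizes 16–50 by
default), plus one planted set of 50 genes drawn with 10:1 odds from the 100
genes with the strongest true heat-shock response — a known
over-representation signal for testing both enrichment methods.

**What the generator does not emulate**: probe-level hybridization,
intensity-dependent (loess-type) biases, gene–gene correlation beyond the
planted low-rank structure, heteroskedastic noise, compositional effects of
median normalization on strongly asymmetric responses, and any regulatory
network mechanism. Passing recovery tests therefore demonstrates that the
*statistics* behave as designed under the planted model, not that the model
captures every property of real arrays.

## Reference points computed by the acceptance script

`scripts/acceptance.py` regenerates everything from a seed and reports, among
others: the 32-array design count; the 439-gene selection on a 4,383-gene
ranking; per-strain epistasis magnitudes (≈ 26% under the default e = 0.25);
the maximal absolute error of the magnitude over the planted grid
e ∈ {0, 0.1, 0.25, 0.5} (20 seeds × 3 strains at n = 2,000 genes, noise
0.3 — typically ≤ 0.04); the realized genotype–temperature correlation
(≈ −0.6); the dendrogram bifurcation indicator; planted-set detection
p-values; the ranked-test type-I rate at nominal 0.05 over 200 null sets
(expected 0.02–0.10); |corr(PC1, growth)| (≈ 0.93); and the growth-rate
arithmetic ln(2×10⁴)/t for t = 14 and 23 h (0.7074 and 0.4306 h⁻¹). Problem
sizes were chosen so the whole script completes in seconds on one CPU while
keeping Monte-Carlo error well below the tolerances of interest.

## Known limitations

- The epistasis magnitude inherits OLS attenuation; with weak designs
  (few replicates, high noise, small effects) it is biased toward
  overestimating e at e = 0. The generator's recovery grid quantifies this.
- FDR q-values from the NES-ratio method are coarse when few sets are
  tested; p-values are the primary inferential quantity for small
  collections.
- The GEO series-matrix reader parses the expression table and sample titles
  only; strain/condition mapping from titles is left to the caller, and
  values are passed through untransformed because the deposited log base is
  not encoded in the format.
- Real-data reproduction of the deposited series requires downloading the
  archive and mapping its sample titles; the offline test suite exercises
  that path on a synthetic series-matrix file instead.
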