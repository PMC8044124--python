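# Methods

This note documents the models, conventions and numerical choices behind
`coresist`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite does not itself compute.

## 1. Waterfall discretization

For one drug, let v₍₁₎ ≥ v₍₂₎ ≥ … ≥ v₍ₙ₎ be the non-missing responses in
decreasing order (the "waterfall"), n ≥ 3 and not all equal.

* **Linearity.** `linearity_r` is the Pearson correlation of the sorted
  curve against its own least-squares line, which equals |r(index, value)|
  and lies in [0, 1].  If `linearity_r ≥ linearity_cutoff` the distribution
  has no natural break and the **median rule** applies: threshold = median
  of the values.
* **Inflection rule.** Otherwise both axes are rescaled to [0, 1]
  (index → (i−1)/(n−1), value → (v−v₍ₙ₎)/(v₍₁₎−v₍ₙ₎)) and the threshold is
  the sorted value whose point lies farthest, in perpendicular distance,
  from the chord joining the first and last points.  Ties break toward the
  smallest index.  Rescaling prevents the index axis from dominating when n
  is large, and makes the selected index — hence the calls — invariant
  under increasing affine transforms of the response scale (the threshold
  itself maps equivariantly, t → a·t + b).
* **Cutoff default 0.95.**  The screens this method originates from used a
  0.95 correlation criterion; the value is exposed as
  `linearity_cutoff`.
* **Polarity and boundary.**  Polarity is an explicit input because summary
  scales disagree (activity area: high = sensitive; log IC50: low =
  sensitive).  A value exactly at the threshold is always called
  *sensitive* — an arbitrary but fixed convention, asserted in tests.

Degenerate inputs (fewer than 3 finite values; zero spread) raise typed
errors rather than returning a fabricated threshold.

## 2. Co-resistance scoring

Two distinct frequency notions are computed and labelled, because they
answer different questions:

* **Joint (network) frequency.** Raw co-resistance counts over a pair set
  are min–max rescaled to [0, 1].  This is a *relative* measure: the
  top-count pair is always 1 regardless of cohort size, and a set of equal
  counts is rejected as degenerate (callers may fall back to raw
  fractions).  Degree bins are low = [0, 0.10), mid = [0.10, 0.60),
  high = [0.60, 1] — the high bin is closed on the left to honour the
  "≥ 60%" convention.
* **Conditional (panel) frequency.** Within the panel of lines resistant to
  a panel drug, each candidate drug d scores
  (panel lines resistant to d) / (panel lines evaluable for d).  Ranks sort
  by descending score with deterministic tie-breaking: larger evaluable
  count first, then lexicographic drug id.  Removing non-focal drugs can
  only improve (never worsen) the focal drug's rank number.

Lines missing either call of a pair are excluded from both numerator and
denominator.  Lineage profiles report per-lineage frequency relative to the
pan-cancer frequency; lineages with fewer than `min_evaluable` (default 3)
evaluable lines are flagged, and a zero pan-cancer frequency yields flagged
missing ratios, not an error.

## 3. Genomic association

A *case* is one co-resistant drug pair with its co-resistant cell-line set.

* **Alteration profiles.**  Per feature, the fraction of the case's
  co-resistant lines carrying the alteration, with per-feature denominators
  (lines with data).  Features with no data in any case line are omitted —
  missing is not absence.
* **Association matrices.**  Pairwise Pearson correlation of two cases'
  frequency vectors over their shared features (≥ 3 required), giving a
  symmetric, unit-diagonal case × case matrix; zero-variance vectors yield
  flagged missing entries.  "Association" is not uniquely defined in this
  setting, so Spearman and Jaccard (profiles binarized at frequency > 0)
  variants are selectable.  The default correlates over *feature space*;
  line-space association can be obtained by transposing the input.
* **Mutation types.**  Proportions over {missense, nonsense, essential
  splicing, frameshift} among the case's records; they sum to 1 by
  construction.  Gene–gene mutation correlations use pairwise deletion:
  a (gene, type) bin with no record anywhere in the table is treated as
  "no input data" (NaN) and dropped from the pair, mirroring public screens
  where some categories are simply unprofiled.
* **Expression stratification and RTK ranking.**  Lines split at a raw
  intensity cutoff (default gene EGFR, cutoff 4; boundary value goes to
  the *high* stratum — fixed convention).  For each (case, stratum) cell,
  mean RTK expression is z-scored across the RTK list *within the cell*, so
  cases on different intensity baselines contribute comparably; the overall
  ranking is the descending cross-case mean of z-scores.  Empty cells are
  flagged missing rather than imputed.

## 4. Gene-set matching

The per-gene upregulation statistic is the difference of means (case
co-resistant lines vs. the case's remaining evaluable lines) on the
log-intensity scale; a pooled-SD standardized variant is selectable.  The
"rest" group is all evaluable non-co-resistant lines — the most inclusive
baseline; restricting to lines sensitive to both drugs is possible by
filtering upstream.  Top-k (default k = 1000) is deterministic, ties broken
lexicographically.  The reported proportion divides by the annotated set
size; the ÷k variant is emitted alongside for transparency.  No enrichment
p-values are computed — the output is a descriptive overlap.

## 5. Dose–response analytics

The viability model is the four-parameter logistic
f(d) = bottom + (top − bottom)/(1 + (d/m)^h), fitted by least squares on
log-dose via `scipy.optimize.curve_fit` with a deterministic multi-start
grid (Hill slope h ∈ {0.5, 1, 2, 4} × four log-spaced midpoint starts across
the dose range; best SSE wins).  A constrained two-parameter variant
(top = 1, bottom = 0) serves control-normalized data.  Constant responses
are rejected as unidentifiable; total failure raises with per-start
diagnostics rather than returning a silent non-converged object.

**ICx semantics.**  x is inhibition relative to the zero-dose asymptote:
ICx solves f(d) = (1 − x)·top, closed form
d = m·((top − r)/(r − bottom))^(1/h) with r = (1 − x)·top, defined only
when r lies strictly between the asymptotes.  For a full-range curve
(top = 1, bottom = 0) IC50 = m; for partial-range curves it deliberately is
not.  Inversion round-trips through the forward curve to 1e−9.

**Combination index.**  The mutually exclusive Chou–Talalay form
CI = d_a/Dx_a + d_b/Dx_b at a user-chosen common effect level (the level is
a required input; it is not guessed).  CI = 1 within 1e−6 is called
additive; below, synergy; above, antagonism.  CI is invariant under a
consistent rescaling of concentration units.

## 6. Synthetic-data generator

The generator emulates a large pharmacogenomic screen; defaults state that
world once and are not tuned per test:

| parameter | default | reason |
|---|---|---|
| n_cell_lines × n_drugs | 1001 × 265 | screened-panel dimensions |
| n_lineages | 23 | cancer types in the lineage analysis |
| gene universe | 17 000, incl. a 22-gene RTK list | mutational/expression landscape scale |
| response mixture | sensitive −2, resistant +2, σ = 1 (log IC50) | ≥ 4σ mode separation, the regime waterfall splitting assumes; resistant = high IC50 by construction |
| resistant fraction | 0.3 per drug | mid-range minority class; unstated upstream, chosen once |
| missing rate | 0.05 uniform | plausible screen dropout; uniform because no mechanism is documented |
| planted pairs | one RTK-inhibitor anchor × first 3 CTDs, κ = 0.9 | the gefitinib ↔ CTD motif |
| mutation types | missense .47 / nonsense .25 / frameshift .25 / splicing .03 | missense > 45%, essential splicing rarest (> 2%) |
| alteration base rate / enrichment δ | 0.10 / 0.30 | clear but not saturating signal in co-resistant lines |
| AXL–EGFR coupling ρ | 0.8 | strong planted expression correlation |
| AXL shift / planted-set shift | +3σ / +2σ in co-resistant lines | recoverable-by-design effect sizes |
| expression scale | N(5, 1) log intensity | spans the stratification cutoff of 4 |

Coupling semantics: for a planted pair (a, b, κ), b's latent state copies
a's with probability κ per line and is redrawn independently otherwise; a
drug may depend on at most one pair.  Randomness is hierarchical — one
global seed, one substream per drug/gene/feature — so enlarging the panel
leaves existing columns byte-identical for a fixed pair specification.
Files round-trip exactly (floats written at 17 significant digits) and
regenerate byte-identically per seed.

**What a green test does not establish.**  The generator draws summary
responses from clean two-component Gaussians with uniform missingness and
lineage labels independent of everything else.  Real screens have
heavy-tailed responses, dose-range censoring, lineage-correlated
resistance, batch structure in expression, and co-occurring alterations —
none of which are modeled.  Green recovery tests certify the *algorithms*
under the stated world, not performance on any real screen.  Synthetic
EMT/CSC sets intentionally overlap planted upregulated genes (half of each
planted set plus random fill), so matching proportions on synthetic bundles
are high by design.

## 7. Pipeline and formats

Matrices are CSV (cell lines × columns, header row, ""/NA = missing),
mutations a long TSV, gene sets one-gene-per-line text, networks GraphML +
edge-list TSV, configuration a single YAML document (CLI flags override).
The driver fails fast — all referenced inputs are checked before any
computation — and each output table carries a header comment with tool
version and a config hash (the hash excludes the output directory, so
identical analyses landing in different places produce byte-identical
tables).  The run manifest records version, config echo, SHA-256 input
checksums, per-stage row counts and timestamps; timestamps make the
manifest itself the one deliberately non-reproducible file.

## 8. Known limitations

* The waterfall method is a two-class discretizer; multimodal response
  distributions (> 2 clusters) are out of scope.
* Min–max normalization is cohort-relative: normalized frequencies are not
  comparable across different pair sets.
* No significance testing accompanies co-resistance frequencies or set
  overlaps; outputs are descriptive, as in the analysis this package
  operationalizes.
* The 4PL noise study in the test suite uses triplicate measurements per
  dose (the replicate count of the underlying viability assay); single
  replicates at 2% noise leave midpoint estimates outside ±10% in roughly
  one fit in eight.
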