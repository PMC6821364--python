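# Methods

`selexpress` implements the computational side of engineering
ligand-inducible bacterial promoters: analysing in vitro selection
(SELEX-style) sequencing of randomized operator libraries, characterizing
the transcriptional response of individual promoter clones, and learning
which sequence features make an operator inducible.  This note documents
the models, their assumptions, the tunable parameters, and what the
synthetic-data studies do and do not establish.

## Gapped k-mer enrichment with a Markov background

Selected-round reads are scanned for *gapped k-mers*: an `l`-mer and an
`n`-mer (`l, n ∈ {4, 5}`) separated by `m` wildcard positions,
`m = 0 … N − l − n` for region length `N` (16–19 bp here).  A pattern is
counted **once per read** (first occurrence), and patterns seen in fewer
than `count_threshold = 50` reads are discarded.  Counts pool across the
equimolar length libraries by default.

Expected counts come from an order-5 Markov model trained on the
unselected starting library (pseudocount 1 per `(context, base)` cell;
initial 5-mer probabilities estimated from windows at *every* offset, a
stationary estimate appropriate for patterns occurring anywhere in the
read).  The probability of a gapped pattern is the chain factorization —
initial 5-mer probability times one conditional per subsequent position —
with every wildcard factor equal to 1.  Wildcards inside later contexts
are marginalized exactly by a forward pass over the 4^5 context states;
because the four conditionals at any step sum to 1, the wildcard still
contributes a unit factor, so the computation reproduces the literal
factor list while remaining exact for context-dependent chains.

Two expected-count conventions are provided:

* `single-position` (default): pattern probability × total reads — the
  method's literal description;
* `per-read-any-offset`: `Σ_L n_L · (1 − (1 − p)^{offsets(L)})`, which
  matches the per-read presence counting rule.  Offsets are treated as
  independent; this is accurate for patterns without strong self-overlap
  and is the convention used for null calibration, where the band is
  defined on the same scale as the counting rule.

Enrichment is observed/expected; the most enriched pattern seeds the PWM,
whose column `i` weights each base by the enrichment of the 1-mismatch
variant at `i` (variants failing the count filter contribute 0; a `log1p`
alternative is available).  Spacer positions are emitted as flagged
uniform columns.  Forward strand only by default — the selected motifs
are palindromic, so reverse-complement collapsing is nearly a no-op; a
flag exists.

## Clustering and rank-size analysis

Unique selected sequences with ≥ 10× coverage are clustered greedily at
90% identity: sequences are visited most-abundant/longest first, each
joining the first cluster whose representative it matches at or above the
threshold (identity = matches / longer length under best ungapped offset),
else founding a new cluster — the classic CD-HIT strategy without its
short-word heuristics, which small inputs do not need.  Clusters below 5
members are dropped, and `log(size)` is regressed on 1-based rank:
successful affinity selection shows an exponential rank-size decay.

## Induction summaries and Hill fits

Normalized fluorescence is `(GFP − blank) / (OD600 − blank)`.  Fold
induction is induced/uninduced normalized fluorescence; fold repression is
no-repressor/repressed.  For population (cytometry-style) data the median
is taken first.  Dose responses are fit to

    y(L) = y0 + Vmax · L^n / (Km^n + L^n)

by bounded nonlinear least squares with a multi-start grid (Km log-spaced
over the measured range × n ∈ {0.5, 1, 2, 4}); `n` is bounded in
(10⁻³, 10].  A free basal term `y0` is included because uninduced
baselines are nonzero; `fix_y0` constrains it when background has been
subtracted.  Manual curve inspection is replaced by a `converged` flag,
multi-start bookkeeping, and a `non_inducible` flag (fitted dynamic range
below 2% of the data scale).  Sequence-diversity "speedometer" coordinates
pair Levenshtein distance to a reference operator (default: highest fold
induction) with fold induction.

## Sequence model and feature importance

Gap-filled aligned operators are one-hot encoded over `{A, T, G, C, -}`
(alignment is ingested, not computed — an external aligner produced it;
equal-length synthetic sets are trivially aligned).  An RBF-kernel SVR
predicts fold induction; hyperparameters (`C`, `gamma`, `epsilon` over a
log-spaced 5×5×3 grid) are chosen by 3-fold inner CV, out-of-fold
predictions are produced under 5-fold CV, and a 10% holdout split off
before any fitting is scored once.  Spearman correlation is the headline
metric; Pearson is reported alongside.  Targets are used untransformed by
default (`log_target` available).

Feature importance contrasts inducible (fold induction ≥ 2 by default)
with uninducible operators.  For each of 100 bootstrap resamples,
simulated annealing searches binary feature masks — single-feature flips,
Metropolis acceptance, geometric cooling `T_t = t0 · α^t` with the
temperature scaled by the starting objective so acceptance is scale-free
(`t0 = 0.1`, `α = 0.95`, 500 iterations by default; the objective is the
2-fold-CV normalized MSE of an SVR with fixed mid-grid hyperparameters,
since re-tuning inside the search would be quadratic cost).  The initial
mask is all-on and the best-ever mask is returned.  The bagged frequency
of a feature is the fraction of bootstraps selecting it, and

    importance(i, j, k) = bagged_frequency(i, j) × observed_frequency(i, j, k)

for position `i`, character `j`, class `k`.  "Internal normalization" is
taken as per-(position, class) sum-to-one, giving class PWMs rendered as
logos (gap character included, spacers greyed).

## The synthetic-data generator

The generator emulates the study's data-generating processes, not any
particular instrument:

* **Library**: reads drawn from an order-5 chain.  Two presets exist.
  The default composition `(A, C, G, T) = (0.60, 0.04, 0.03, 0.33)` with
  a 10% same-base persistence models a severely skewed base delivery; it
  was designed, before any pipeline test was wired, so that the census of
  patterns passing the 50-count filter at 10⁵-read depth sits well above
  the filter — the regime in which the null-calibration band
  `[0.8, 1.25]` is meaningful, since Poisson noise alone at the filter
  boundary would otherwise dominate.  `SELECTION_BASE_FREQS =
  (0.32, 0.18, 0.12, 0.38)` is a milder composition used for selection
  scenarios: motif recovery requires the starting library to contain tens
  of perfect planted sites, and ultra-rare letters would hand more
  enrichment leverage to a single winner's private spacer letters than to
  the planted consensus.
* **Selection**: the planted operator is a palindromic dimer
  (`AACAA`-spacer-`TTGTT`, half sites at consensus probability 0.8; an
  optional weak spacer preference can be planted via `spacer_pwm`,
  default none); binding energy is the additive log-odds score, minimized
  over offsets.  Each round resamples reads with probability ∝
  `count · exp(−β·E)` and re-amplifies to the round size in one
  multinomial draw (no per-cycle PCR jackpot model).  β = 2 with this
  energy scale drives a 5-round selection to the minimum-energy class.
  The reference library depth (5×10⁶ reads) keeps that class diverse
  (~150–180 distinct perfect sites); with far fewer winners, a pair of
  winner reads sharing rare flank or spacer letters can spuriously
  out-enrich the planted consensus — a finite-diversity artifact worth
  remembering when interpreting shallow selections.
* **Expression**: single-operator occupancy,
  `θ = R_eff / (R_eff + Kd)` with
  `R_eff = atf·(1 + w·L/ligand_kd) / (1 + L/ligand_kd)`; expression is
  `v_const · (1 − θ)` with mean-corrected lognormal noise (positive
  fluorescence by construction).  `w` (`residual_activity`, default 0) is
  the DNA-binding activity retained by ligand-bound repressor; `w = 0`
  recovers full release (expression → `v_const` at saturating ligand),
  while small `w > 0` produces the finite induction plateaus required for
  a stable fitted Vmax, the regime used for the affinity-ordering study
  (atf = 10 µM, `w = 3·10⁻³`, Kd grid 3–300 nM).  Hill-shaped dose
  curves emerge from this mechanism without ever being fit in.
* **Labeled operator sets**: inducible operators carry the `TACA` core at
  positions 1–4 with planted flank bases (G at 7, C at 13, 1-based) and a
  fold induction around 20 modulated by the base at a tuning position;
  uninducible operators carry the core at 3–6 with contrasting flanks and
  fold induction ≈ 1.05.  Noise is lognormal (CV 10%).

What passing these studies shows: the estimators recover planted truth
under the stated noise at desk scale.  What they do not show: performance
on real selections (no sequencing-error model beyond barcode corruption,
no PCR jackpots, no cytometry bimodality — an optional mixture is left
out by default), and no claim that real operator libraries have these
compositions.

## Reference study conditions (selexpress.study)

| study | key sizes | what is measured |
|---|---|---|
| motif recovery | 5M-read library, 5 rounds × 50k reads, β=2 | seed equals planted core; PWM column correlation; core enrichment gain |
| null calibration | 2M-read library, one β=0 round of 100k | fraction of filtered patterns with enrichment in [0.8, 1.25] |
| Hill recovery | 8 concentrations × 3 replicates, 5% CV, 100 seeds | median Km/Vmax/n errors; noiseless recovery |
| affinity ordering | Kd ∈ {3…300} nM, atf 10 µM, w=3·10⁻³ | Spearman(Kd, Vmax), Spearman(Kd, fold repression) |
| sequence model | 200 labeled operators | out-of-fold and holdout Spearman |
| importance recovery | 10 outer seeds × 100 bootstraps, 60-iteration anneal, 60 operators | fraction of seeds whose top differential scores sit on planted positions |

Problem sizes were chosen so each study runs in seconds to a few minutes
on one CPU.

## Numerical choices and degenerate inputs

Pattern counting is vectorized by encoding reads as base-4 integers and
bin-counting per (l, m, n) template; it is exactly equivalent to per-read
enumeration (tested).  Zero-count Markov contexts (possible only at
pseudocount 0) fall back to uniform conditionals.  Seed ties break by
observed count, then pattern text.  All-zero PWM positions raise
(degenerate seed); all-zero importance columns fall back to uniform with
a warning.  Hill fits report non-convergence rather than silently
substituting; flat responses are flagged non-inducible.  Empty classes,
empty libraries, ragged alignments and duplicate barcodes raise
configuration errors.  Every stochastic component takes an explicit seed
and is reproducible bit-for-bit.

## Known limitations

* The two expected-count conventions bracket, but do not exactly model,
  per-read presence probabilities of strongly self-overlapping (repeat)
  patterns; such patterns can sit a few percent below unit enrichment in
  null data.
* Greedy clustering reproduces the documented CD-HIT strategy, not
  CD-HIT's exact outputs.
* The annealing objective uses fixed SVR hyperparameters; importance
  scores are a screening statistic, not causal effect sizes.
* Percent-of-constitutive activity requires a measured reference clone in
  the input table.
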