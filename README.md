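# selexpress

Analysis pipeline for engineering **ligand-inducible bacterial promoters**
from in vitro selection.  An allosteric transcription factor (aTF)
represses a promoter by occupying an operator sequence placed between the
−35 and −10 elements; adding ligand releases the repressor and induces
expression.  Starting from a randomized 16–19 bp operator library, the
workflow is:

1. **Demultiplex** selection-round reads by 8 bp sample barcode and
   extract the randomized region (`selexpress.io`).
2. **Quantify enrichment** of gapped k-mers — `l`-mer / `m`-spacer /
   `n`-mer patterns with `l, n ∈ {4, 5}` — counted once per read,
   filtered at 50 counts, and normalized by expected counts from an
   order-5 Markov model of the unselected library
   (`selexpress.kmers`, `selexpress.enrichment`).  Enrichment =
   observed / expected; the top-enriched pattern seeds a **PWM** whose
   columns are weighted by the enrichments of all 1-mismatch variants
   (`selexpress.pwm`).
3. **Cluster** selected operators (≥10× coverage, greedy 90% identity)
   and fit the descending cluster-size curve
   `size(rank) = a·e^(−b·rank)`, the signature of successful affinity
   enrichment (`selexpress.cluster`).
4. **Characterize induction**: normalized fluorescence (GFP/OD600), fold
   induction and repression, and Hill dose–response fits
   `y = y0 + Vmax·L^n / (Km^n + L^n)` by multi-start nonlinear least
   squares (`selexpress.induction`).
5. **Learn sequence determinants**: one-hot-encoded gap-filled operators
   → RBF-kernel support-vector regression of fold induction (5-fold CV +
   10% holdout), then bootstrap **simulated-annealing feature
   importance**, `score(i,j,k) = bagged_frequency(i,j) ×
   observed_frequency(i,j,k)`, contrasting inducible vs uninducible
   operators as class-specific PWMs (`selexpress.regression`,
   `selexpress.importance`).

A synthetic-data generator (`selexpress.simulate`) emulates the whole
experiment — biased starting libraries, Boltzmann affinity selection
against a planted palindromic dimeric motif, and occupancy-driven
reporter expression with Hill-shaped dose responses — so every stage is
testable end to end without any external data.  `selexpress.study`
packages the reference validation studies.

## Worked example

```python
import numpy as np
from selexpress import study, simulate as sim
from selexpress.induction import HillModel

# five selection rounds against the planted dimeric operator, then the
# full enrichment -> seed -> PWM analysis (about two minutes on one CPU)
out = study.motif_recovery_study(seed=1)
print(out["results"].summary())

# dose response of one operator clone (Kd = 10 nM) and its Hill fit
expr = sim.simulate_expression(
    {"op_A": 10.0}, np.r_[0.0, np.geomspace(0.1, 1000.0, 7)],
    sim.ExpressionSimConfig(noise_cv=0.05, seed=2), replicates=3,
)
fit = HillModel(expr["ligand_conc"], expr["gfp_raw"] / expr["od600"]).fit()
print(fit.summary())
```

prints

```
Gapped k-mer enrichment analysis
========================================
sample reads:        50000
count threshold:     50
expected convention: single-position
patterns retained:   16335
seed pattern:        AACAAxxxTTGTT
seed enrichment:     181917.22
PWM consensus:       AACAAxxxTTGTT
...

Hill dose-response fit
========================================
observations: 24   converged: True
   param     estimate    std err
      y0        8.924      0.344
    vmax        93.92       1.74
      km        115.1       5.87
  hill_n       0.9691      0.034
residual SSE: 23.35
```

The recovered seed `AACAAxxxTTGTT` is exactly the planted palindromic
core (two reverse-complement half sites around a 3 bp spacer), present in
all 50 000 final-round reads and enriched ~180 000-fold over its Markov
expectation.  The Hill fit recovers the occupancy-model dose response:
basal activity y0 ≈ 9 (residual repression at zero ligand), near-full
induction Vmax ≈ 94 (in units where constitutive expression is 100), and
half-maximal induction at Km ≈ 115 µM ligand with cooperativity n ≈ 1.

A `selexpress` command-line tool wraps each stage (`demux`, `enrich`,
`motif`, `cluster`, `hill`, `train`, `importance`, `simulate`); see
`selexpress --help`.

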