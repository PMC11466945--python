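# Methods

## Observational design being modeled

The pipeline targets a replicated-pen design: 12 pens of 8 pigs
(4 barrows, 4 gilts) assigned by litter origin to littermate (LM),
half-littermate (HLM), and non-littermate (NLM) treatments, 4 pens each.
Behavior is observed in three 6-h windows at 15, 19, and 23 weeks of
age.  Lying and lying-in-contact are scan-sampled every 10 min (36 scans
per window); tail-biting events (a bite or pull eliciting a visible
reaction) are recorded continuously as biter → recipient.  Tail injury
is scored twice weekly on the 0–4 scale across the 14-week
growing-finishing phase (weeks 10–24); the maximal tail score (MTS) is
each pig's worst score and MTS ≥ 2 defines a victim of tail biting.

Each pen is one independent network replicate.  Association networks
yield one data point per pen-period (n = 36); bite networks are
aggregated over the three periods because per-period bite matrices are
sparse (n = 12).

## Association index

For dyad (a, b): HWI = x / ((n_a + n_b)/2) with x the co-lying scan
count and n_a, n_b the individual lying counts, all from the same
aggregate.  The half-weight form corrects for time each pig is
observable in the scored state and lies in [0, 1].  Convention: if
n_a + n_b = 0 (a pig never observed lying) the index is defined as 0
rather than NaN, keeping downstream metrics total.  No strong-tie
threshold is applied by default (`min_hwi = 0`); a cutoff flag exists
for sensitivity analyses.

Scans with an incomplete pen roster (pig removed mid-study or not
identifiable) can be dropped from aggregation (`drop_incomplete=True`),
so index denominators only count scans where every pig was scored.

## Network metrics

All metrics are computed from first principles and are verified in the
test suite against exhaustive path-enumeration and matrix-power
oracles, plus a networkx cross-check.

* **Density** — realized dyads (weight > 0) over n(n−1)/2 undirected or
  n(n−1) directed dyads.
* **Strength** — row/column sums of the weight matrix (in = received,
  out = performed; for symmetric HWI matrices the total strength is the
  plain row sum).
* **Betweenness** — unnormalized Brandes accumulation; all shortest
  paths counted fractionally, never broken arbitrarily; disconnected
  pairs contribute zero (no harmonic fallback).  Weighted betweenness
  uses edge length 1/weight (the standard strength-to-length inversion).
  Defaults: 1/HWI lengths for association networks, hop counts for the
  sparse bite networks; both switchable.
* **Freeman centralization** — C = Σ_v (c_max − c(v)) / D_max with
  D_max the star-graph spread: degrees, (n−1)(n−2) undirected and
  (n−1)² directed in/out; betweenness, (n−1)²(n−2)/2 undirected and
  (n−1)²(n−2) directed.  Star = 1 and complete graph = 0 hold exactly.
  Degree centralization defaults to **binary** degrees (edge present iff
  weight > 0), the classical Freeman definition; a weighted
  (strength-based) variant normalized by a star carrying the observed
  maximum edge weight is available by flag.
* Degenerate conventions: an edgeless network has density 0 and all
  centralizations 0 (vacuous spread); centralization requires n ≥ 3.

## Injury scoring and class comparisons

MTS classes {0, 1, ≥2} are cross-tabulated against treatment and tested
with Pearson's chi-square (statistic Σ(O−E)²/E, margins-based expected
counts, df = (r−1)(c−1)).  Medians and IQRs use linear interpolation
between order statistics at positions 0.25(n−1)+1 and 0.75(n−1)+1
(numpy's "linear" rule); the convention is documented because published
per-pig quartiles are not always reconstructible from class counts, and
per-pig medians over a class distribution can differ from pen-level
summaries.

## Statistical layer

* **Correlation screen** — pairwise Pearson r among candidate metrics;
  for |r| > 0.8 one member is dropped, preferring to drop the unweighted
  twin of a weighted metric (unweighted and weighted degree are nearly
  collinear in sparse bite networks), otherwise the later-listed one.
  Constant columns are reported and retained.
* **Kruskal–Wallis** — scipy's tie-corrected H; the post hoc compares
  pooled mean ranks with the rank-LSD criterion (t reference, N−k df,
  variance S²(N−1−H)/(N−k)(1/n_i+1/n_j)), optional Bonferroni scaling.
  The exact post-hoc formula is a documented choice — only a package
  routine, not a formula, is named in the literature this follows.
* **Linear mixed models** — REML via statsmodels MixedLM with a pen
  random intercept (plus a pig-within-pen variance component for
  pig-level repeated measures).  Association-network pig-level
  betweenness is square-root transformed.  EMMs average predictions
  over the other factor levels with **equal weights**, so they equal
  cell means on balanced designs (tested).  All pairwise treatment
  contrasts use a Tukey studentized-range reference
  (q = |t|√2) with containment-style df = n_pens − n_levels.
* **Proportional-odds model** — statsmodels OrderedModel (logit link),
  maximum likelihood, no pen random effect.  The proportional-odds
  assumption is probed by a likelihood-ratio test against the
  unconstrained multinomial logit; when it rejects (p < 0.05) odds
  ratios are withheld, mirroring how an analysis should refuse to
  report ORs from a failed assumption.  MTS levels 3–4 are kept
  distinct by default; `collapse_sparse_levels` merges them into ≥2.
* **Victimization model** — binomial logit with a pen random intercept,
  fitted by marginal maximum likelihood with Gauss–Hermite quadrature
  (15 nodes) written in `tailnet.glmm`; statsmodels offers no
  frequentist binomial GLMM, and the ML fit is deterministic and showed
  negligible recovery bias (≈ −0.004 on a true coefficient of 0.7 at
  400 pigs / 50 pens) where a variational approximation did not.
* **AIC comparison** — candidate fits must share identical data rows
  (verified via a row hash); ranked ascending with ΔAIC.

## Synthetic generator

The generator's defaults are the study design constants above plus
generative parameters chosen to land in a realistic regime:

| parameter | default | meaning / rationale |
|---|---|---|
| `p_lie` | 0.8 | probability a pig is lying at a scan; finishing pigs rest most of the midday observation window, and no numeric budget is published to anchor it |
| `kappa` | 0 | preference concentration; 0 = exchangeable pigs |
| `bite_rate_base` | 0.06 | Poisson mean bites per directed dyad per period; chosen so aggregated bite-network density (~0.1–0.2) and mean bites received per pig (~1–2) match the sparse networks the analysis expects |
| `biter_heterogeneity` | 0.8 | SD of the sender log-rate effect (a few pigs do most biting) |
| `victim_heterogeneity` | 0.6 | SD of the receiver log-rate effect |
| `injury_gain` | 0.5 | per-bite probability that the next assessment escalates one level |
| `heal_prob` | 0.1 | per-assessment healing probability at scores 1–2 in bite-free windows |

Mechanisms:

* **Lying.**  Each pig lies independently with `p_lie`.  Among lying
  pigs, dyads race with exponential scores at rate w(a, b); winners are
  accepted greedily under a two-neighbor cap (mimicking row-lying: a
  pig touches at most two flank neighbors) up to a per-scan budget of
  ⌊n_lying/2⌋ pairs.  The budget makes contact a limited resource
  allocated by preference — without it the greedy race saturates every
  pig's capacity and preference weights stop shaping the aggregate.
  Preference structures: `uniform` (w ≡ 1), `hub` (one pig's dyads at
  1+κ), `block` (two half-pen blocks at 1+κ inside, emulating
  half-littermate pens).
* **Biting.**  Directed dyad counts are Poisson with mean
  `bite_rate_base · exp(s_out(i) + s_in(j))`; the log-additive
  sender/receiver form is the simplest that lets in- and out-degree
  heterogeneity be dialed independently.  Timestamps are uniform over
  the 6-h window.
* **Injury.**  Between assessments, a score escalates one level with
  probability 1 − (1 − `injury_gain`)^bites (capped at 4); scores 1–2
  heal one level with `heal_prob` in bite-free windows; scores never go
  negative.  These dynamics are deliberately simple plumbing — their
  parameters exist so recovery effect sizes are explicit.
* **Streams.**  One RNG stream per (pen, stage) is spawned from the
  global seed, so identical (config, seed) gives byte-identical CSVs
  and adding pens never perturbs existing pens.

What the generator does **not** emulate: pen geometry and
thermoregulatory clumping (lying preferences are purely dyadic weights);
two-staged tail biting with passive recipients (event streams model
reaction-eliciting bites only); scoring-observer error; litter
pedigree structure behind the treatment labels.  Passing recovery tests
therefore show the pipeline detects the structure it claims to detect,
not that real pens carry that structure.

A consequence of the design intensity worth knowing: at 36 scans per
window almost every dyad co-lies at least once, so simulated binary
association densities run ~0.95–1.0 (observed pens report ~0.8–0.9) and
structural heterogeneity expresses itself mostly through edge weights;
hub structure still raises binary degree centralization detectably
because the matching budget keeps some dyads unrealized.

## Problem sizes used in validation

The test suite validates the metric engine on the complete isomorph
sweep of connected graphs with n ≤ 6 (141 graphs) plus 1000 random
8-node graphs; parameter recovery uses 200 replicates of 400
observations; structure recovery uses 20 replicate pens per arm; the
law-of-large-numbers check on the bite generator uses 5000 dyad draws.
The acceptance script runs the same computations at 100 replicates and
1000 graphs.

## Known limitations

* Pen-level sample sizes this small (4 pens/treatment) give the mixed
  models little power; the pipeline reports convergence and singularity
  flags rather than pretending otherwise.
* The proportional-odds diagnostic is a large-sample LR test; with
  sparse top MTS levels it can be undefined (reported as NaN, ORs
  released).
* The Tukey df containment rule is an approximation; with 12 pens and
  3 treatments it uses 9 df, which is conservative relative to
  Kenward–Roger-style corrections.
* EMM equal weighting differs from observed-frequency weighting when
  designs are unbalanced (e.g. after removals).
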