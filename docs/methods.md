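# Methods

This note documents the models implemented in `trialnet`, the parameters
that matter, the numerical choices, and the limits of what the synthetic
study conditions can show.

## Synthetic trial cohorts

The analyses require a table of phase III cancer RCTs — cooperative
group, disease, treatment type, publication year, survival hazard ratio
(HR, > 1 favoring the new arm) and p-value — but no such registry is
publicly deposited at trial-level resolution. `trialnet.cohort` therefore
generates cohorts with the statistical structure the downstream analysis
assumes. Defaults are sized to the study scale: 280 trials over
1955–2006.

**Hazard ratios.** `log HR` is drawn from a Normal(0.05, 0.25) body —
new treatments slightly superior on average, the equipoise regime — and,
with probability 0.05, the HR is replaced by a draw from a Pareto tail
with survival exponent 2.8 above 1.5: occasional breakthrough results.
All five parameters are configurable (`HRModel`). The tail exponent
echoes the exponent scale reported for treatment-success distributions;
the body scale keeps ~56% of trials above parity ("slightly above 50%"
success). The mixture reproduces the qualitative shape of the observed
success histogram, not its exact data.

**p-values.** No registry links effect sizes to reported p-values, so a
standard asymptotic survival-trial model is used: the log-HR standard
error is `2/sqrt(events)` with the event count log-uniform on [50, 800]
(a realistic phase III range), the z-score is jittered by a log-normal
factor (sd 0.3), and `p = 2·Φ(−z)` clipped into (0, 1]. The result is a
monotone-with-noise link: larger |log HR| ⇒ stochastically smaller p.

**Attributes and time.** Group/disease/treatment labels are i.i.d.
categorical with configurable frequencies; ECOG receives the largest
group share, matching its standing as the largest cooperative group.
Years are uniform over the range and sorted; only the chronological
*order* matters to the growth model, so the marginal year distribution is
deliberately simple.

## Network models

**Shared characteristics.** An edge joins two trials sharing a label on
at least one attribute of the chosen subset (OR semantics). OR is the
only reading consistent with the observed density ordering: networks on
single attributes are disjoint unions of cliques (one per label) and
multi-attribute networks must be denser, not sparser. The four
multi-attribute subsets form the analysis set; the three single-attribute
networks are verified to be clique unions in tests and excluded, being
trivially clustered.

**Success-biased growth (preferential attachment by fitness).** Trials
enter in chronological order; the earliest `m0 = 19` form a complete seed
graph and each later trial ties to `m = 18` distinct existing trials,
drawn without replacement with probability proportional to the attachment
fitness, renormalizing after each draw. The defaults give average degree
≈ 2m ≈ 36, matching the published growth-network scale; `m0 = m + 1` is
the smallest seed supporting `m` ties. The fitness (score rule) is
configurable because the exact published combination of HR and p-value is
not recoverable from the source text:

* `hr_times_one_minus_p` (default): `s = HR · (1 − p)`;
* `hr_only`: `s = HR`;
* `hr_if_significant`: `s = HR · 1[p ≤ 0.05]`.

Degree does **not** enter the attachment probability by default — the
model's premise is that *success* plays the role degree plays in classic
preferential attachment; a `degree_weighted` variant
(`s · (degree + 1)`) is available behind a flag. If every existing score
is zero (possible only under the indicator rule), the step falls back to
uniform sampling and logs a warning. A complete seed was chosen over an
empty one so the seed generation is well-defined for all `m ≤ m0`;
under fitness-only attachment the choice only affects the `C(m0, 2)`
seed edges.

**Random null.** `G(n, p)` with `p = avg_degree/(n − 1)`, matched per
analysis network, five members per ensemble by default; member seeds are
derived from the ensemble seed.

## Topology and centrality conventions

* *Average shortest path*: mean geodesic over all reachable unordered
  pairs; unreachable pairs are excluded, not infinite.
* *Global clustering*: mean of local clustering coefficients
  (Watts–Strogatz convention), degree-<2 nodes contributing 0. For ER
  graphs both this and transitivity have expectation `p`, so the
  random-network comparisons are insensitive to the convention;
  transitivity is exposed separately.
* *Closeness*: Wasserman–Faust component-scaled form
  `((n_c−1)/Σd) · ((n_c−1)/(n−1))`, which stays in [0, 1] on
  disconnected graphs and reduces to the standard form on connected ones.
* *Betweenness*: Brandes accumulation, normalized by `(n−1)(n−2)/2`
  unordered pairs.
* *HITS authority/hub*: power iteration on `A + I` until successive
  max-normalized iterates differ by < 1e−8 in max norm; the `+I` shift
  leaves eigenvectors unchanged while making the Perron eigenvalue
  strictly dominant, so the iteration converges on bipartite structures
  where the bare recurrence oscillates. Scores are normalized to unit
  maximum; on undirected graphs authority = hub, and both are reported.
  Published central-trial tables use an unstated normalization, so score
  *magnitudes* are not comparable — rankings and profiles are.
* *Small world*: observed vs ensemble-mean clustering and path length;
  flagged when the clustering ratio exceeds 1.5 and the path ratio is
  below 1.5 (both thresholds configurable and reported).

Ensemble-scale summaries run on the adjacency matrix (scipy all-pairs
BFS; triangle counts via a matrix cube) for speed; per-node centralities
delegate to networkx under the conventions above. Both routes are checked
against exhaustive-enumeration oracles on all random graphs of ≤ 7 nodes.

## Discrete power-law fitting

`trialnet.powerlaw` implements the standard tail-fitting recipe for
integer data:

* For each candidate cutoff `x_min` (every distinct value leaving at
  least `tail_min = 10` tail points — the floor prevents degenerate fits
  on ~280-node graphs), the exponent is estimated by the
  continuous-approximation MLE
  `α = 1 + n_tail / Σ ln(x_i/(x_min − ½))`; an exact discrete MLE
  maximizing the Hurwitz-zeta likelihood is available (`method="zeta"`)
  and agrees within 0.02 for `x_min ≥ 6`.
* The KS distance between the empirical tail CDF and the fitted tail CDF
  is evaluated at both step edges of every observed value (equivalent to
  the integer-grid supremum); the `x_min` minimizing KS is selected, ties
  going to the smallest cutoff (largest tail). For near-continuous inputs
  the scan is capped at 250 evenly spaced candidate cutoffs; integer
  degree data has fewer distinct values and is scanned exhaustively.
* Goodness of fit: a semiparametric bootstrap (default 1000 replicates;
  heavier settings via `n_boot`). Each replicate draws the tail from the
  fitted model and the body from the empirical sub-cutoff data, then is
  refitted *with full cutoff re-selection*; the p-value is the fraction
  of replicate KS values at least the observed one, and p > 0.1 is the
  conventional plausibility threshold. Calibration is verified in tests:
  ~10% of null datasets are rejected at the 0.1 level.
* Sampling from the fitted tail uses the standard inversion
  `floor((x_min − ½) u^(−1/(α−1)) + ½)`.

**Classification.** A degree histogram is *scale-free* when the power law
is plausible with α ≤ 4; otherwise a shifted-geometric (discrete
exponential) alternative is fitted **on the same tail with its
KS-minimizing rate** — the symmetric treatment, since the power law's
cutoff is itself KS-selected — and the histogram is *single-scale* when
the geometric KS is at least as small, else *broad-scale*. With a
mean-matched (MLE) geometric rate instead, the power law wins even on
Poisson (ER) degree data, which is why the KS-optimal rate is used.

## Success vs network position

Node-level (measure, HR) pairs drive everything; binning is presentation.
Equal-width bins (default 20) carry per-bin mean HR (arithmetic by
default, geometric behind a flag, HRs being ratio-scale), and for degree
a per-distinct-value table is also emitted. The headline statistic is the
bin-free Spearman ρ with a permutation p-value (default 10,000
permutations, seeded). A constant measure makes the trend undefined and
is flagged rather than silently zeroed; a constant outcome yields ρ = 0,
p = 1 by convention. Central-trial profiles take the top k = 10 nodes per
measure (ties broken by trial id for determinism) and report modal
attributes with membership counts and the mean HR of the top set.

## Reproducibility

All randomness flows from one master seed through
`numpy.random.SeedSequence` keyed on (seed, CRC32(stage label), index);
the study manifest records the derived seeds, configuration and package
version, and re-running a study reproduces byte-identical CSV/JSON/
GraphML outputs. Derived seeds stay below 2^31.

## Problem sizes

Default analyses run at the study scale (cohorts of 280; graphs of ~280
nodes; ensembles of 5). Replicate experiments in the test suite use 50
replicates with 500–2000 bootstrap/permutation draws, and the reference
random-ensemble values are computed over 25 graphs per row so the
Monte-Carlo standard error (~5·10⁻⁴) is negligible against the published
two-decimal precision.

## Known limitations

* The synthetic cohort emulates marginal structure only: no temporal
  drift in success rates, no correlation between attributes and HR
  (except where tests plant one), no duplicate reporting, no missing
  data. Conclusions from passing tests are about the *mechanisms*
  (growth bias ⇒ degree–success coupling; shared attributes ⇒ clustered
  small worlds), not about the historical trial record.
* With the default HR mixture (5% Pareto tail mass), the growth network's
  degree distribution is a lognormal-body/power-tail composite: cutoff
  scans land near the published values (x_min ≈ 20–26, α ≈ 2.8–3.0), but
  a correctly calibrated bootstrap accepts the power law in only a
  minority-to-half of replicates, because only ~14 trials per cohort sit
  in the truly Pareto regime. The published high plausibility rate is a
  property of the real HR data, which the generator does not claim to
  reproduce; plausibility rates here are sensitive to `tail_mass` (a
  pure-Pareto fitness roughly doubles them).
* HITS magnitudes depend on normalization and are not comparable to
  published tables; use rankings.
* The citation structure between trials is out of scope; edge
  "direction" in time is recorded as provenance only and all analytics
  are undirected.
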