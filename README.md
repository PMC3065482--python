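# trialnet

Social-network models of treatment discovery in cancer randomized
controlled trials (RCTs).

## The scientific problem

Phase III cancer trials run by the NCI cooperative groups show a striking
pattern: new treatments are, on average, only slightly better than the
standards they challenge, yet a small number of trials produce outsized
survival gains — a heavy-tailed distribution of treatment success. One
proposed mechanism is social: researchers preferentially build on the work
of successful peers, so the *interaction structure between trials* shapes
which discoveries happen.

`trialnet` implements that analysis as a tested, reproducible pipeline for
researchers in clinical meta-research and network science. A trial is a
node carrying its cooperative group, disease, treatment type, publication
year, survival hazard ratio HR (coded so HR > 1 favors the new treatment)
and p-value. Networks over the trials are built three ways:

1. **Shared characteristics** — an edge joins trials sharing a label on at
   least one chosen attribute (group, disease, treatment type);
2. **Success-biased growth** — trials enter chronologically and each new
   trial ties to `m` existing trials with probability proportional to an
   attachment fitness
   `s_i = HR_i · (1 − p_i)` (preferential attachment by *success*, not
   degree): `P(i receives a tie) = s_i / Σ_j s_j`;
3. **Erdős–Rényi null** — `G(n, p)` ensembles matched on node count and
   average degree.

The pipeline then asks, for each network family:

* **Topology** — mean geodesic distance `L` over reachable pairs and
  global clustering `C` (mean of local clustering coefficients), compared
  with the matched random ensemble: a network is *small-world* when
  `C / C_rand` is large while `L / L_rand ≈ 1`.
* **Degree distribution** — a discrete power-law tail fit
  `p(k) ∝ k^(−α), k ≥ x_min`, with `α` by maximum likelihood, `x_min` by
  KS-distance minimization, and plausibility by a semiparametric bootstrap
  (p > 0.1 ⇒ power law plausible); degree histograms are classified
  scale-free / broad-scale / single-scale.
* **Success vs position** — Spearman rank correlation (with permutation
  p-values) between HR and degree, closeness, betweenness and local
  clustering, plus profiles of the most central trials.

Because the underlying 280-trial registry is not publicly deposited, the
package ships a synthetic-cohort generator with the statistical structure
the analysis assumes (log-normal HR body slightly above parity, Pareto
right tail of breakthroughs, p-values stochastically decreasing in effect
size, realistic attribute frequencies). See `docs/methods.md` for the
model details and what the synthetic conditions do and do not show.

## Worked example

```python
import trialnet as tn

cohort = tn.generate_cohort(tn.CohortConfig(seed=0))
g = tn.build_preferential_attachment_network(cohort, tn.PAConfig(seed=0))

fit = tn.fit_power_law([d for _, d in g.degree()])
fit.bootstrap_gof(n_boot=1000, seed=0)
print(fit.summary())

n = g.number_of_nodes()
ens = tn.build_er_ensemble(n, 2 * g.number_of_edges() / n, 5, seed=1)
sw = tn.small_world_assessment(g, ens)
trend = tn.hr_vs_measure_trend(cohort, g, "degree", seed=0)
```

prints

```
Discrete power-law tail fit
==========================================
n (samples)                            280
n_tail (x >= x_min)                    184
x_min                                   24
alpha                               3.0386
KS statistic                        0.0426
estimator                       continuous
bootstrap gof p                     0.3080
bootstrap replicates                  1000
power law (p > 0.1)              plausible
==========================================
```

with `sw` reporting clustering 0.26 vs 0.12 in the matched random ensemble
(ratio 2.11) at identical path length (ratio 1.00) — a small world — and
`trend.trend_rho = 0.30` with permutation p = 0.0001: in the
success-biased growth network, better-connected trials report larger
survival gains. The degree distribution is power-law plausible with
exponent ≈ 3 above a cutoff of ≈ 24 interactions.

The same stages are available from the shell:

```bash
trialnet synth --n 280 --seed 0 --out trials.csv
trialnet net pa --trials trials.csv --m 18 --m0 19 --out pa.graphml
trialnet metrics --graph pa.graphml --out metrics.csv --summary topo.json
trialnet plfit --graph pa.graphml --boot 1000 --seed 0
trialnet study run --config study.yaml --out results/
```

`trialnet study init-config --out study.yaml` writes the full default
configuration; `study run` executes cohort → networks → null ensembles →
topology table → degree fits → trend tables → central-trial profiles and
serializes everything (CSV/GraphML/JSON) with a manifest that makes the
run byte-for-byte reproducible from its master seed.

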