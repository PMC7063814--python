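# morbtraj

Population-scale modelling of **multimorbidity disease trajectories** from
hospital-registry data, for epidemiologists and health-systems researchers
who want interpretable, sex- and age-stratified models of how chronic
disease combinations accumulate over a lifetime.

## The model

The input is a table of hospital stays (pseudonymous patient id, sex,
5-year age band, admission/release dates, release type including
in-hospital death, level-3 ICD-10 diagnosis codes).  The analysis:

1. **Washout cohort.** Keep patients with no diagnosis in A00–N99 during
   an initial washout window (default 1997–2002), so everyone starts with
   the same empty disease history.
2. **Health states.** Each patient-year is a cumulative binary vector
   x ∈ {0,1}^D over the D = 131 WHO diagnosis blocks of chapters A00–N99
   (e.g. I10–I15 hypertensive diseases): x_b = 1 iff block *b* was ever
   diagnosed by 31 December of that year.  Diagnoses are never removed.
3. **Multimorbidity clusters.** The observed vectors are partitioned by
   monothetic divisive clustering: each binary split questions a single
   block and maximises the decrease of within-cluster inertia
   Σ_c Σ_{i∈c} ‖x_i − μ_c‖².  Every cluster is therefore described by
   *inclusion* criteria (blocks all members have) and *exclusion*
   criteria (blocks no member has), and cluster 0 — the healthy cluster —
   excludes everything.
4. **Multilayer transition network.** For each sex g and 10-year age band
   a, the yearly cluster transition rate
   q_{g,a,k,j} = P(cluster j next year | cluster k, sex g, band a)
   is estimated on patient-years, with in-hospital death as an absorbing
   pseudo-state and end-of-window years censored.  Because vectors only
   grow, inter-cluster steps are possible in one direction only and the
   transition graph is acyclic; clusters without outgoing links are sink
   states.
5. **Derived statistics.** Reduced trajectories (cluster sequences with
   consecutive repeats removed), mortality regions (clusters banded by
   yearly in-hospital mortality), region-entry rankings, relative risks
   of entering the high-mortality region within a horizon (Katz 95% CIs),
   progredient-vs-stable comorbidity comparisons (Fisher's exact test,
   Bonferroni), sex-bias screening of all transitions, and a generative
   Markov simulator with two single-disease benchmark labellings.

Because the registry this design targets is not public, the package
ships a **synthetic registry generator** with planted ground truth
(nested latent multimorbidity states, sex/age-dependent acquisition
rates, state-dependent in-hospital mortality, a terminal sink state
carrying a planted 2× entry hazard from one state, and diagnosis noise),
so every stage is testable against known dynamics.

## Worked example

```bash
cd analysis
python 01_generate_registry.py   # 20,000 synthetic patients, seed 1
python 02_build_cohort.py
python 03_cluster.py
python 04_network.py
python 06_risk.py
```

prints, among other things:

```
cohort M = 19221 of 20000 patients (96.1% pass the washout)
fitted K = 5 clusters (truncated=False)
  cluster 0: include [], 4 exclusions, size 178214, mortality 0.11%/yr, mean age 41
  cluster 1: include ['H90-H95'], 0 exclusions, size 7577, mortality 4.87%/yr, mean age 59
  ...
acyclic=True; sinks=[1]; robust collapsed edges (q>0.5%, n>=100): 11
planted-rate recovery: 95.2% of 522 cells in 95% CIs
planted hazard check (men 50-59, vs other intermediates): RR = 1.82 +/- 0.74 (true 2.0)
```

Reading: the washout retains 96% of patients; the divisive fit recovers
the five planted latent states as clusters (cluster 1, containing the
terminal state's defining blocks, has the high 4.9%/yr mortality and is
the network's only sink); 95.2% of the estimated stratified transition
rates fall inside exact binomial 95% CIs of the planted rates; and the
planted doubled region-entry hazard is recovered as RR ≈ 2 with its CI
covering the true value.

The same pipeline is available as a CLI (`morbtraj run --config cfg.yaml
--seed 1`, plus per-stage subcommands `gen-data`, `build-cohort`,
`cluster`, `network`, `trajectories`, `risk`, `simulate`, `compare`) and
as a library (`import morbtraj`).

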