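# Methods

This note documents the models, conventions and numerical choices behind
`morbtraj`, and what the synthetic-data experiments do and do not show.

## Cumulative health states

A patient's health state at the end of calendar year *t* is the binary
vector over the D = 131 WHO diagnosis blocks of ICD-10 chapters I–XIV
(codes A00–N99) accumulated over *all* stays up to *t*.  The encoding is
deliberately memoryful: hospital data do not reveal which diseases a
patient has been cured of, so past diagnoses are never removed and
vectors are componentwise non-decreasing in time.  Conventions:

- A stay contributes to the year containing its **admission** date (the
  year-end snapshot convention is otherwise ambiguous for stays spanning
  New Year).
- Codes with a 4th character are truncated to level 3 before block
  lookup; codes outside A00–N99 (chapters O–Z) map to no block and never
  set a bit.
- One state row exists per cohort patient and observation year, up to
  and including the year of an in-hospital death; death is handled as a
  terminal event, never as a state.

**Effective age.** Ages are observable only as 5-year bands at
admission.  Both the cohort builder and the synthetic generator use the
convention *age = years since the start of the 5-year band recorded at
the patient's first admission* ("effective birth year").  The true age
is underestimated by 0–4 years, but estimator and generator use the
identical quantity, so the sex × 10-year-band stratification is
self-consistent and rate recovery is well-posed.  Ten-year bands run
0–9 … 80–89 with an open 90+ top band.

## Washout cohort

Patients with any A00–N99 code on a stay admitted during the washout
years (default 1997–2002) are excluded; patients absent from the washout
window, or present with only O–Z codes, are retained.  This forces a
common all-zero initial state at the start of observation (2003–2014).

## Monothetic divisive clustering

The clustering is a divisive, monothetic procedure on binary vectors:
starting from one cluster, repeatedly split the cluster whose best
single-variable bipartition ("block *b* present?") maximally decreases
the total within-cluster inertia (squared Euclidean distance to the
centroid; for binary data the inertia of a cluster with weighted column
sums s and weight n is Σ_j s_j − s_j²/n).  The split search is exact
over all variables via the weighted co-occurrence matrix; duplicate
vectors are collapsed and weighted by multiplicity, which leaves all
inertia computations unchanged.

Numerical choices:

- **Stopping**: at K leaves, or earlier when no split has gain > 1e-12
  (the model is then flagged `truncated`).
- **Tie rule**: among (cluster, variable) pairs within 1e-12 of the
  maximal gain, lowest cluster label first, then lowest block index.
- **Labels**: the root cluster is 0; at each split the zero-branch keeps
  its parent's label and the one-branch takes the next fresh integer.
  The all-exclusion (healthy) path therefore always keeps label 0.
- **Distance**: raw 0/1 vectors, no scaling or weighting of blocks.
- K is a configuration parameter.  The `choose_k_diagnostic` compares
  the observed inertia curve with column-permuted null replicates
  (margins preserved, correlations destroyed); it informs but does not
  automate the choice.

Every fitted model satisfies, and the tests assert: each observed vector
matches exactly one leaf's criteria; no variable is both inclusion and
exclusion in a leaf; every leaf pair disagrees on at least one path
variable — which is what makes inter-cluster transitions one-directional
on cumulative vectors and the transition graph acyclic.

## Transition network

For each layer (sex, 10-year band), transitions are counted between a
patient's cluster in year *t* (the stratum is taken in the source year)
and year *t*+1.  A source patient-year is **at risk** when the patient is
observed, or dies in hospital, in the following year; the final observed
year is censored.  Rates are conditional frequencies over at-risk years,
so per (layer, source) the cluster rates plus the death rate sum to 1;
censored years are tracked separately and excluded from denominators
(folding them in would bias every rate downward by the censoring share).
Sources observed only as censored are reported as undefined, not zero.

Derived operations: collapsing layers sums counts exactly and recomputes
rates (recording mean transit age per edge); the robustness filter keeps
edges with rate > 0.5% and count ≥ 100 (both configurable — the count
threshold is this package's concrete rendering of "statistically
robust"); sink states have no outgoing inter-cluster links (self-loops
and death do not count); mortality regions label clusters with mean age
≥ 55 by yearly in-hospital mortality bands, default low 0.2–0.3%,
medium 0.3–1%, high 2–11%, leaving gaps unlabelled.

## Risks

Relative risks of entering a cluster region within a horizon (default 1
year) are computed on patient-years: every year a patient of the stratum
spends in the source cluster is one trial; rows already in the region
are not trials, and rows with fewer than `horizon` remaining observed
years and no event are excluded.  Baselines: all same-stratum
patient-years outside the region (the headline comparison), the healthy
cluster only, or an explicit cluster set (used to recover the planted
hazard, where the exact truth is known).  The 95% CI is the Katz normal
approximation on log RR with SE = √(1/e₁ − 1/n₁ + 1/e₀ − 1/n₀),
validated against a 10,000-resample bootstrap; the reported half-width
is the larger deviation of the CI from the point estimate.  Progredient
patients are those inside a cluster set at a reference year (their first
qualifying year) and outside it — or, in the narrowed variant, inside a
target region — three years later; comorbidity differences use two-sided
Fisher tests with Bonferroni correction over the tested blocks, and the
same machinery screens male-vs-female transition rates per (age band,
source, destination) triple with ≥ 100 at-risk years in both sexes.

## Simulation and benchmarks

The fitted network defines a Markov model: next year's cluster depends
only on sex, current age band and current cluster.  The simulator draws
a start population from the real cohort's first observation year
(sex, exact age, cluster), advances ages by one year per step (the
oldest band absorbs), samples transitions/death from the matching layer
after renormalising away the censor mass (censoring is an observation
artifact, not a biological event), and logs two diagnostics: undefined
rows (patient left in place) and logically impossible steps (entering a
cluster that excludes a block implied earlier on the path) — a known
limitation of the cluster-level Markov approximation.

Benchmarks label each patient-year by a single block instead of a
cluster: the most recently acquired block (ties within a year: lowest
block id) or the patient's population-least-frequent block; all-zero
years get a dedicated healthy label.  Model comparison simulates, per
model, a cohort matched to that model's own held-out start distribution
and measures total-variation divergence between simulated and held-out
real reduced-length and final-occupancy distributions; the summary score
is the mean of the two divergences (total variation was chosen as a
bounded, interpretable statistic), with the within-inertia of each
model's induced partition reported alongside.

## Synthetic registry

The generator emulates the registry the analysis targets: stays over
1997–2014, 5-year age bands at admission, ';'-separated level-3 codes,
normal/transfer/death releases.  Its latent structure is chosen so every
downstream estimate has a known truth:

- **States**: state 0 is empty; each intermediate state adds two
  dedicated blocks; the terminal state is the union of all intermediate
  sets plus two more blocks.  Block sets grow strictly along every
  allowed transition, so the latent graph is acyclic by construction and
  the terminal state is a sink.
- **Rates** (yearly, per sex and 10-year band): onset 0.06 split evenly
  over the intermediates, direct healthy→terminal entry 0.002,
  progression into the terminal state 0.025 — doubled to 0.05 for state
  1, the planted high-risk pattern; in-hospital death 0.001 / 0.004 /
  0.04 for healthy / intermediate / terminal.  All scale with age as
  0.4 + 0.2·band, making acquisition rise with age; sexes are symmetric
  unless a test plants a bias via elementwise multipliers.  Rows are
  capped at 0.95 total outgoing probability.
- **Population**: 25% of patients never acquire a somatic block
  ("healthy"; they receive only Z-coded stays), and 5% of the rest get
  one somatic stay during the washout (exercising cohort exclusion).
  Every patient receives one Z-coded registration stay during the
  washout window, which pins the first admission year before dynamics
  and makes the effective-age convention exact.  Background stays are
  Poisson (0.4/year, roughly the stays-per-person-year of the registry
  the generator emulates); acquisition and death years force a stay.
- **Diagnoses**: each stay draws 1 + Poisson(1.7) codes from the
  patient's cumulative blocks (matching a mean near 2.7 and median 3
  diagnoses per stay), with every newly acquired block guaranteed on the
  first stay of its year; with probability 0.05 an observation-period
  stay of a non-healthy patient carries one extra uniformly random
  block — a transient acute diagnosis that nevertheless enters the
  cumulative vector.  Noise is confined to the observation period so the
  designed cohort fractions stay interpretable.

**What recovery tests show — and don't.** Never-sick patients pool into
the healthy cluster without being latently at risk of moving, so
cluster-level rates out of cluster 0 dilute the planted dynamic rates by
a time- and age-varying factor.  The recovery evaluation therefore uses
the ground truth to remove the never-sick at-risk mass from healthy-
cluster move/stay cells (death cells need no correction: never-sick
patients share the healthy-state death rate).  Diagnosis noise
occasionally plants a defining block, creating rare cluster transitions
where the latent rate is zero; these cells are kept in the evaluation
and account for most of the ~5% of cells falling outside their exact
binomial intervals.  The generator realises the model class the
estimator assumes (Markov in the latent state, piecewise-constant rates
per band); passing tests show the pipeline recovers planted dynamics
under those conditions, not that real hospital data satisfy them — in
particular, real registries have outpatient gaps, coding incentives,
non-Markov histories and far richer block correlations.

## Problem sizes

Unit tests run on a 2,500-patient registry; the end-to-end checks use a
single 50,000-patient registry (about 565,000 patient-year states),
25 replicate 20,000-patient registries for CI-coverage of the planted
relative risk, and a 30,000-patient run in `scripts/acceptance.py` —
sizes at which every binomial check is well-powered while the whole
suite completes in a few minutes on one CPU.

## Known limitations

- Length-of-stay, outpatient events and realistic ICD-10 code
  frequencies are not modelled; the generator's codes are uniform within
  blocks.
- Cluster labels are fitting-order labels, not the age-ordered labels a
  publication figure would use.
- The "±" notation for relative risks is reported as the maximal CI
  deviation from the point estimate; the underlying interval is
  asymmetric on the RR scale.
- The simulator treats undefined (never-observed) rows as "stay", which
  slightly favours inertia in sparsely observed strata.
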