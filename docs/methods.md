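# Methods

This note documents the statistical model implemented in `panelped`,
the numerical and design choices made where several reasonable options
existed, and what the simulation-based tests do and do not establish.

## Model

### Genotype space and paring

A genotype is a vector of K binary carrier indicators, one per model
gene, each representing "carries any pathogenic variant" at that locus
(the database rows are labelled accordingly, e.g.
`BRCA1_hetero_anyPV`).  The engine restricts the space to genotypes
with at most `max_mut` simultaneous mutations — the paring parameter,
default 2, clamped to K — giving `Σ_{j≤max_mut} C(K, j)` states ordered
noncarrier, singles in gene order, then pairs lexicographically.
Paring at 2 keeps a 24-gene model at 301 states instead of 2²⁴.

Probability mass assigned by the untruncated model to pared-away
genotypes is **renormalized** over the retained states, both for
founder priors and for each (mother, father) transmission distribution.
This keeps every conditional a proper distribution, which the engine's
posterior-sums-to-1 invariant requires; with `max_mut = K` the
renormalization is a no-op and priors/transmissions are the exact
Hardy–Weinberg/Mendelian products.

### Carrier representation

Carriers are modelled as heterozygous: a carrier parent transmits the
variant allele with probability 1/2, a non-carrier with probability 0,
and a child carries iff it receives at least one variant allele.  With
allele frequencies in the 10⁻⁴–10⁻² range, homozygous carriers have
prior mass ≤ f² ≈ 10⁻⁴ of the carrier state and are absorbed into it.
The forward simulator, by contrast, tracks true allele counts (0/1/2),
so the tests quantify exactly what the heterozygous approximation
costs: at the default frequencies it is not detectable in 2000-family
calibration runs.

### Likelihood

Per member and cancer, the likelihood uses **net** penetrances: the
per-age probability at the observed diagnosis age for affected members,
or the survival term `1 − Σ_{s≤C} P(T=s)` for members unaffected at
censoring age C.  Members with no censoring age and no diagnoses
contribute a flat likelihood (they are either pseudo-parents or awaiting
imputation).  Additional factors:

* **Germline test results** — perfect-test default (a positive result
  zeroes all genotypes not carrying that gene; a negative result zeroes
  carriers); sensitivity/specificity are configurable in
  `ModelOptions`.
* **Tumour markers** (ER/PR/HER2/CK14/CK5.6/MSI) — pluggable per-variant
  conditional probability tables in the database; with no table
  configured a recorded marker result is ignored (uninformative
  default).
* **Risk modifiers** (mastectomy/oophorectomy/hysterectomy) — a
  per-(surgery, cancer) hazard factor in the database scales the
  per-age penetrance from the intervention age onward; the survival
  term is recomputed from the adjusted curve, so it remains a proper
  sub-distribution.  Shipped defaults are neutral (factor 1).

### Multi-carrier penetrance (dominant-gene rule)

The penetrance database is indexed by a *single* gene variant, so a
combination rule is needed for genotypes carrying several mutations.
`panelped` uses a dominant-gene rule: for each cancer and sex, the
carried variant with the largest lifetime (age-94) net cumulative
penetrance supplies the whole curve.  This is simple, keeps every
genotype's age distribution a proper sub-distribution, and reduces to
the ordinary carrier curve for single carriers.  Alternatives
(independent competing hazards across carried genes) would yield
slightly higher multi-carrier penetrance; at paring 2 and rare
frequencies the difference is confined to genotypes with ≤ 10⁻⁴ prior
mass.  The same rule is used by the forward simulator, the imputation
mixture, and the risk projection, so all components share one model.

### Peeling

`peel` runs sum-product message passing on the bipartite tree of
genotype variables and nuclear-family factors (the Elston–Stewart
anterior/posterior factorisation).  Identical-twin sets are collapsed
into one genotype variable whose local likelihood is the product over
twins.  Every message is normalized to sum 1, which makes the
computation immune to underflow without changing the posterior; local
likelihood products are accumulated in log space.  Marginals for *all*
members fall out of one sweep, so any number of counselees costs one
pass.  Loops are rejected (`LoopError`), not approximated.  The engine
is validated against `brute_force_posterior`, an independent exhaustive
enumeration (guarded at 10⁷ configurations), to 10⁻¹⁰ on hundreds of
random families.

### Future risk

Risk by age `a` for a counselee free of cancer r at age C is
`Σ_G P(G|H,U) · (F_G(a) − F_G(C)) / (1 − F_G(C))` with F the cumulative
crude (default) or net penetrance.  The division conditions each
genotype-specific term on being cancer-r-free at the current age; the
unconditional variant would understate risk for older counselees.  The
same conditioning is applied for both penetrance types.  Cancers the
counselee has already had are omitted.  The grid runs from
`C + age_by` to 94, the end of the database age axis.

### Missing ages: multiple imputation

Missing censoring ages are sampled as (mean age of same-generation
relatives with known ages) + Normal(0, 10), clamped to [1, 94] and to a
minimum 15-year parent–child gap; generations with no known ages borrow
the nearest informative generation's mean shifted 25 years per step.
Missing diagnosis ages are sampled from the founder-prior-averaged net
penetrance truncated at the censoring age (genotype is unknown at
imputation time).  Each of `iterations` (default 20) passes yields a
completed pedigree; per-pass results are aggregated elementwise as
estimate = mean, lower = min, upper = max.  Per-pass random substreams
are spawned deterministically from the master seed, so results are
identical however the passes are scheduled; the `parallel` option is
accepted for interface compatibility and the engine simply honours the
seed-stability contract with sequential execution.  A counselee whose
own censoring age had to be imputed gets no future-risk grid (grids
anchored at sampled ages would not be congruent across passes); their
posterior is still reported with imputation bounds.

## Pedigree checking choices

* **Heredity harmonization**: a child's recorded ancestry (or race)
  conflicting with both parents' recorded values is reset to the
  neutral category (`nonAJ` / `All_Races`) with a message; processing in
  generation order propagates resets downward.  Race and ancestry are
  harmonized by the same rule.
* **Sex–cancer compatibility** is derived from the database rather than
  hard-coded: a diagnosis is incompatible iff the penetrance slice for
  that sex is identically zero.
* **Disconnected members** are those with no parent–child path to any
  counselee; mating-only links with no shared children carry no
  genotype information and are treated as non-influential.
* **Pseudo-parents**: children recorded with a single parent get a
  shared synthetic founder of the opposite sex (one per known parent
  and missing role, so sibships stay intact) carrying the known
  parent's ancestry prior, a flat likelihood, and no censoring age.
* **Twins**: identical-twin sets must share parents, sex, race and
  ancestry — violations are errors, since the engine enforces a shared
  genotype downstream.
* Ages above 94 are clamped to the age axis with a warning; a diagnosis
  age exceeding the censoring age is an error.

## Synthetic data and what the tests show

`make_toy_database` builds the study conditions for all simulation
tests: discretized-Gaussian penetrance curves (carrier lifetime mass
0.25–0.55, onset modes 40–55; noncarrier mass 0.06, mode 68), crude =
net × a fixed Gompertz other-cause survival, allele frequencies uniform
on [10⁻⁴, 10⁻²], and female-only cancers with identically zero male
slices.  `simulate_family` draws founders from Hardy–Weinberg,
transmits alleles by coin flips, samples diagnosis ages from the net
penetrance and censors them at generation-dependent current ages
(means 75/50/25, sd 8).

The calibration experiment (2000 families, single-gene model) verifies
that predicted carrier probabilities match observed carrier fractions
per decile within 99% binomial intervals.  Because the simulator and
the engine share the penetrance model, this establishes *internal*
consistency — correct inversion of the generative model — not the
accuracy of any real-world penetrance estimates.  Real pedigrees also
differ in ways the simulator does not emulate: clinical ascertainment
(families present *because* of their cancer burden), genotype-dependent
censoring, reporting error in relatives' histories, and linked or
recessive loci.  Passing tests therefore validate the machinery, not
the epidemiology of any particular database.

## Numerical notes and limitations

* Posterior normalization is exact to 10⁻⁹ by construction; peeling
  matches enumeration to 10⁻¹⁰ on all tested instances.
* Aggregation sorts per-pass values before reducing, making it exactly
  permutation-invariant despite floating-point addition.
* Problem sizes in the test suite and acceptance script (families ≤ 9
  members, panels ≤ 7 genes, 120–2000 simulated families) were chosen
  so the exhaustive oracle stays within its enumeration guard while
  exercising every paring level; the engine itself handles hundreds of
  members and the 301-state 24-gene pared space.
* Looped pedigrees (intermarried sibling pairs, cousin matings) are
  detected and rejected, not approximated.
* No X-linked inheritance, de novo mutations, linked loci, or
  two-hit recessive models; no second-primary risks; no ascertainment
  correction.
* The `BRCAPRO5` preset is defined here as the BRCAPRO6 panel minus
  CDKN2A (BRCA1, BRCA2, MLH1, MSH2, MSH6) — a repository convention,
  since the classic model family does not pin down this gene list.
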