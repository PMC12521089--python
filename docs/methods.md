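# Methods

This note documents the statistical model behind `faersignal`, the
generative model of the bundled synthetic-data module, every numerical
choice that affects results, and the known limitations. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The disproportionality model

A spontaneous-report database is reduced, per analysis term (MedDRA
Preferred Term or System Organ Class), to a 2×2 table against one target
drug:

|            | term present | term absent |
|------------|--------------|-------------|
| target drug | a | b |
| other drugs | c | d |

with N = a + b + c + d.

**Counting unit.** By default the unit is the distinct (report, term) pair:
a is the number of distinct target-drug reports mentioning the term, the
margin a + b is the total number of (report, PT) pairs among target-drug
reports, and N is the total number of pairs at that MedDRA level. This is
the common convention for spontaneous-report disproportionality — PT-level
margins then equal total PT mentions. A report-level mode (b and d count
reports *without* the term) is available via `counting="report"`; it changes
b and d but not a and c, and matters only when multi-event reports are
frequent. A duplicated PT within one report always counts once. Tables with
a = 0 are never emitted (no signal can exist without a single co-report).

**ROR.** ror = ad/bc with Wald interval
exp(ln ror ± z·√(1/a + 1/b + 1/c + 1/d)), z = 1.96. When any of b, c, d is
zero, the Haldane–Anscombe correction adds 0.5 to all four cells before
computing the ROR and its CI; this keeps the statistic finite without
biasing ordinary tables (the correction is applied only to the tables that
need it).

**PRR and χ².** prr = [a/(a+b)] / [c/(c+d)]; χ² is the Pearson statistic
N(ad − bc)²/[(a+b)(c+d)(a+c)(b+d)] without continuity correction. The Yates
variant (subtracting N/2 from |ad − bc|) is a flag, off by default: the
fixed χ² ≥ 4 gate is conventionally quoted for the uncorrected statistic.

**BCPNN information component.** The IC is the posterior log2 ratio of the
joint reporting probability to the product of its margins. We use the
closed-form posterior-moment formulation with joint prior count γ11 = 1,
margin priors α1 = β1 = 1, joint pseudo-counts α = β = 2, and the adaptive
γ = γ11(N+α)(N+β)/[(a+b+α1)(a+c+β1)] that centres the prior on
independence:

    IC   = log2[ (a+γ11)(N+α)(N+β) / ((N+γ)(a+b+α1)(a+c+β1)) ]
    V    = (1/ln²2)·[ (N−a+γ−γ11)/((a+γ11)(1+N+γ))
                     + (N−a−b+α−α1)/((a+b+α1)(1+N+α))
                     + (N−a−c+β−β1)/((a+c+β1)(1+N+β)) ]
    IC025 = IC − z·√V

with z = 1.96 by default; the historical "IC − 2√V" variant is a config
switch (`CriteriaConfig.ic_z`). As N grows with proportions fixed, IC
converges to log2[aN/((a+b)(a+c))]; the suite checks agreement within 0.01
bits at N = 10⁶.

**MGPS / EBGM.** Under the multi-item gamma-Poisson shrinker, the observed
count of each table is a | λ ~ Poisson(λE), with baseline
E = (a+b)(a+c)/N (the independence expectation; no stratification is
applied) and relative reporting rate λ drawn from a two-component gamma
mixture

    λ ~ p·Gamma(α₁, rate β₁) + (1−p)·Gamma(α₂, rate β₂).

The five hyperparameters are fit by maximizing the marginal likelihood — a
mixture of negative-binomial terms — over all tables at one analysis level,
by Nelder–Mead from DuMouchel's canonical start (0.2, 0.1, 2.0, 4.0, 1/3)
on log/logit-transformed parameters. Components are reported with the
larger prior mean first (resolving label-swap); with fewer than 10 tables
the canonical start is returned unconverged and shrinkage follows it. The
posterior of λ is again a two-component gamma mixture with components
(αⱼ + a, βⱼ + E) and weight from the marginal likelihoods;
EBGM = exp(E[ln λ | a]) via digamma functions, and EBGM05 is the 5th
posterior percentile found by bracketed root-finding (Brent) on the mixture
CDF (xtol 1e−12). Both are validated against an independent
numerical-integration oracle to 1e−4 absolute.

**Consensus rule.** A term is a signal only when all four gates pass:
n ≥ 3 with ROR CI lower bound > 1; PRR ≥ 2 with χ² ≥ 4 and n ≥ 3;
IC025 > 0; EBGM ≥ 2. The EBGM gate tests the geometric mean by default —
the threshold is conventionally quoted against EBGM — with EBGM05 gating a
config switch, since signal tables customarily print "EBGM (EBGM05)".
Missing statistics fail their gate. No multiple-testing adjustment is
applied (fixed per-term thresholds are the norm for these screens); this is
a deliberate, documented limitation — the consensus requirement is the
false-positive control.

## Cleaning rules

* **Deduplication:** per CASEID keep the version with the maximum FDA_DT;
  among ties, the maximum PRIMARYID. Versions with missing FDA_DT sort
  below any dated version (a dated report is taken as more recent). The
  rule is idempotent and is verified to reproduce a ground-truth duplicate
  ledger with zero errors.
* **Drug cohort:** a report enters the cohort when a DRUG row matches a
  synonym (uppercased, trimmed, exact match on drugname or prod_ai;
  substring matching opt-in because FAERS free-text names make it
  high-recall/low-precision) *and* carries the required role code (primary
  suspect by default; concomitant-only reports are excluded).
* **Events:** PTs are trimmed and casefolded before lookup. The PT→SOC map
  is authoritative — no reclassification is performed even where the source
  hierarchy is debatable (e.g. cheilitis under gastrointestinal disorders).
  Unmapped PTs get the sentinel SOC `UNMAPPED` and are tallied in the
  manifest. IME and label flags are set by casefolded membership.
* **Ages:** converted to years via DEC×10, YR×1, MON÷12, WK÷52.1775,
  DY÷365.25, HR÷8766; a bare number with no unit is taken as years.
  Age bins are half-open at the lower bound, so exactly 18 falls in
  "18–65" and exactly 66 in "66–85" — the only reading under which the
  conventional bin labels (<18, 18–65, 66–85, >85) partition the line.
* **Dates:** FAERS integer dates; 8-digit values must be valid calendar
  dates, 6-digit (YYYYMM) and 4-digit (YYYY) values are retained for
  year-level summaries but treated as missing for any day-resolution
  arithmetic. Invalid dates become missing and are counted as warnings
  rather than dropping the record.

## Time to onset

Onset = event date (DEMO.event_dt, the FAERS field carrying event onset;
REAC has no date) minus the *earliest* full-precision start date among the
target drug's THER rows (first exposure bounds onset when multiple therapy
episodes exist). Reports lacking a full date on either side are excluded as
`missing_date`; negative differences as `negative`; the three counts always
sum to the case total. Default bins [0–30], [31–60], [61–90], [91–180],
[181–360], >360 days follow the customary early/mid/late treatment-phase
groupings and are fully configurable. Median and quartiles use linear
interpolation (numpy's default), the natural choice when no method is
mandated.

## The synthetic-data generator

The generator emulates the *structure* of a FAERS extract, not
pharmacology:

* **Drugs:** each case includes each catalog drug independently with its
  `use_prob` (a weighted fallback guarantees ≥ 1 drug); the role code (PS,
  SS, C, I) is drawn per drug from that drug's role distribution. The
  default catalog has one analyzed drug (20% of cases, 90% PS) and five
  background drugs.
* **Events:** each report carries Poisson(1)+1 distinct PTs — so multi-event
  reports exist, which is what distinguishes pair-level from report-level
  counting — drawn without replacement with weights (background probability
  × designed multiplier) via Gumbel top-k. A multiplier m for (drug, PT)
  therefore scales that PT's reporting odds by m in reports listing the
  drug; the realized cross-product ratio of the ground-truth counts
  recovers m (verified within 20% at 50,000 cases, and by 95% ROR-CI
  coverage of m ∈ {1, 2, 5, 10} across seeded replicates). A multiplier of
  0 removes the pair entirely; in the degenerate case where every PT weight
  of a case is 0 the case emits no event row.
* **Dates:** FDA receipt dates are uniform over 2004-01-01 … 2024-06-30;
  onset intervals are log-normal with median 81 days and σ = 1.1 (quartiles
  near 31/169 days, the shape reported for oral-retinoid cohorts); the
  event date precedes receipt by 0–90 days and therapy start = event −
  onset. Negative intervals are created by swapping start/event dates
  (probability 0.02 by default) — exercising the exclusion rule without a
  separate date model. Start/event dates are missing with probability 0.10
  each; 5% of event dates are truncated to month or year precision.
* **Demographics, outcomes, indications:** drawn from fixed margins chosen
  to mirror a published oral-retinoid reporting profile (56% female, 44.5%
  age missing, 81% US, physician-dominated reporters, outcome and
  indication frequencies of the same shape), so demographic summaries on
  synthetic data look like the real cohort's.
* **Duplicates:** each case emits a second version with probability
  `dup_rate` under a strictly larger PRIMARYID, with FDA_DT 1–180 days
  later or — with probability 0.1 — identical, to exercise the PRIMARYID
  tiebreak. The full ledger (every version, with the version the dedup rule
  must keep) is part of the ground truth.

What the generator does **not** model: dose, drug–drug interactions,
reporter/country covariance with events, secular reporting trends, term
misspellings, or LLT-level coding. Passing tests therefore demonstrate
correctness of the pipeline's rules and estimators under a clean generative
model, not robustness to real-world coding noise.

## Problem sizes and runtime choices

The test suite and acceptance script size their simulations to study scale
where the property demands it and small scale elsewhere: consensus
sensitivity/specificity use 20 replicates of 50,000 cases (the designed
multiplier-10 term must be consensus-flagged in ≥ 18/20 runs; null terms in
≤ 1% of term-runs); multiplier recovery uses 50,000 cases; CI-coverage of
designed multipliers uses 20 replicates of 20,000 cases; MGPS recovery uses
5,000 simulated cells (each hyperparameter within 25% relative error);
oracle-equivalence checks use 1,000-case datasets where brute-force
enumeration is exact and fast.

## Numerical choices, in one place

* Haldane 0.5 only when a zero cell would make the ROR infinite.
* χ² uncorrected by default; Yates by flag.
* IC multiplier z = 1.96 (2.0 by config); BCPNN priors as listed above.
* MGPS: Nelder–Mead, 4,000 iterations max, xatol 1e−6, fatol 1e−8, on
  (log α₁, log β₁, log α₂, log β₂, logit p); optimizer failure returns the
  canonical start flagged `converged=False`.
* EBGM05: Brent root-finding on [1e−12, mixture ppf(1 − 1e−6)], xtol 1e−12.
* Quantiles: linear interpolation; percentages rounded to one decimal with
  denominator = all cases.
* Sorting everywhere is stable with explicit keys, making repeat runs
  byte-identical.

## Limitations

* Disproportionality measures reporting association, not incidence or
  causation; the package inherits every bias of spontaneous reporting
  (under-reporting, stimulated reporting, confounding by indication).
* No stratification or regression adjustment of E, and no multiple-testing
  correction — by design, matching standard screening practice.
* The FAERS reader supports the ASCII dialect only (no XML), assumes
  PT-coded REAC terms, and performs no LLT→PT recoding or spelling
  correction.
* MedDRA and IME lists are licensed resources; the package consumes them as
  user-supplied CSVs and ships only synthetic stand-ins in its tests.
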