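# Methods

## Model overview

`invasim` simulates the progression of an in-situ carcinoma to invasive
disease as the interplay of three components:

1. **Tumor cells (discrete agents).** Each cell carries three boolean
   pathway-mutation flags — proliferation (δ_P), apoptosis (δ_A) and immune
   evasion (δ_IE) — a continuous EMT score in [0, 1] with a derived
   mesenchymal flag ζ, and a cell-autonomous mutation probability.
2. **Immune populations (continuous).** NK cells, CTLs and regulatory
   T cells (Tregs) evolve by ordinary differential equations; NK
   recruitment is constant (innate), CTL/Treg recruitment is driven by the
   number of mutant tumor cells cleared by the immune system in the current
   cycle (antigen stimulation), with Treg recruitment additionally
   modulated by TGF-β.
3. **TGF-β (algebraic).** τ = τ_MUT·N_MUT + τ_Treg·N_Treg: produced by
   mutant tumor cells and Tregs, it drives EMT and Treg recruitment.

Time advances in cell cycles of 18 h. Per cycle each cell takes exactly
one of five fates with probabilities

    ρ_P  = p (1 + δ_P Δ_P)(1 − ζ Δ_MGA) / (1 + N_C/K_0)
    ρ_A  = d_C (1 − δ_A Δ_A)
    ρ_NK = δ_MUT · N_NK/(N_C/K_1 + N_NK) · E_NK/(1 + N_Treg/K_2)
               · (1 − δ_IE Δ_IE)(1 − ζ Δ_MIE)
    ρ_CTL = analogous with N_CTL and E_CTL
    ρ_R  = 1 − ρ_P − ρ_A − ρ_NK − ρ_CTL

δ_MUT is 1 for cells with at least one mutation and
`delta_mut_baseline` (default 0) otherwise, so unmutated cells are
(by default) invisible to effectors while any mutation makes a cell
immunogenic. Mesenchymal growth arrest (Δ_MGA) and mesenchymal immune
evasion (Δ_MIE) are proportional reductions of proliferation and
clearance for mesenchymal cells; Δ_MIE = 1 means mesenchymal cells are
never immune-cleared.

Defining rest as the complement keeps the five probabilities a proper
distribution; the growth-arrest mass removed from ρ_P flows into rest,
which reproduces the intended "arrested cells rest in G0" semantics. In
the (parameter-pathological) case where the four active fates exceed
probability 1 they are rescaled proportionally and rest becomes 0.

The CTL clearance term mirrors the NK term with its own efficacy
E_CTL > E_NK (CTLs clear with greater efficiency than NK cells) and
shares K_1, K_2 by default. All constants are configurable.

## Mutation machinery

A proliferating cell acquires a mutation with its current cell-autonomous
probability; acquisition picks uniformly among its not-yet-mutated
pathways and resets the probability to 0, while a non-mutating
proliferation increases it by a fixed increment of 1e-4. Mutations never
revert and are inherited by daughters (including a mutation acquired in
the division that produced the daughter). Daughters start their own
mutation ladder at 0.

## EMT score

The EMT score follows a deliberately simple phenomenological recurrence —
state- and TGF-β-dependent, bounded, thresholded:

    s' = clamp_[0,1]( s + emt_gain · τ/(τ + K_τ) · (1 − s) − emt_decay · s )

a contracting recurrence with a Hill-type TGF-β activation. At constant τ
the score converges to g/(g + emt_decay) with g = emt_gain·τ/(τ + K_τ). A
cell is mesenchymal iff its score is strictly above T_MES.

**Daughters are born epithelial (score 0).** This is a deliberate design
choice where the design was genuinely open, and it is load-bearing. If
daughters inherited the parental score, every cell in the tumor would
carry the *same* score — the recurrence is deterministic, driven by the
shared TGF-β field, from a shared initial state — so the mesenchymal flag
would be a tumor-wide switch. A proportional Δ_MGA reduction applied to
every cell cancels exactly in the growth-rate *difference* between mutant
clones and the bulk, which makes the mutant-fraction dynamics (and hence
the time to invasion) nearly independent of Δ_MGA in the regime where the
whole tumor is mesenchymal, and it forbids the partial mesenchymal
fractions seen in the modeled biology. Resetting the score at birth —
interpretable as dilution of the EMT expression program through division —
creates an age-structured phenotype: fast-dividing clones stay enriched
for epithelial cells while the resting bulk converts, which is what gives
the mesenchymal parameters their population-level effects.

## Algorithmic order within one cycle

1. Fates are drawn for all cells against cycle-start populations
   (synchronous update) and applied; clearances are tallied.
2. Mutation machinery runs for proliferating parents; daughters are
   appended (not exposed to fates until the next cycle).
3. Effector exhaustion removes `deactivation_per_kill` NK/CTL cells per
   clearance, then the immune ODEs advance one cycle.
4. TGF-β is recomputed algebraically from the new mutant and Treg counts.
5. Every cell's EMT score and phenotype update against the new TGF-β.

Because the forcing terms (cleared-mutant count, τ, inflammation-resolved
recruitment rates) are frozen within a cycle, each immune ODE is linear,
N' = a − dN, and is advanced with its exact solution
N(1) = a/d + (N₀ − a/d)e^(−d). No numerical integrator — and therefore no
integrator tolerance — enters the simulation; the test suite checks the
update against adaptive integration to 1e-8 relative error.

The cleared-mutant forcing N*_MUT is the count for the *current* cycle
(a rate reading of antigen stimulation); a cumulative mode is available
via `cumulative_clearance`.

## Warmup and progression

Simulations start from `n_0 = 10` unmutated epithelial cells and run a
1000-cycle warmup with mutations off and only NK cells present (at their
recruitment/death equilibrium σ_NK/d_NK). During warmup all cells are
exchangeable, so fates are drawn as a single multinomial per cycle. With
immune pressure on unmutated cells off, the post-warmup size fluctuates
around the mean-field carrying capacity N* = K_0(p/d_C − 1) (= 300 cells
at the defaults; the scale stands in for a ~1e9-cell tumor).

After warmup, mutations and the adaptive response switch on. The tumor has
*progressed* at the first post-warmup cycle at which the mutant fraction
is ≥ 50%; the time to invasion is that cycle count. Runs are censored at
2000 cycles; tumor extinction produces a censored record with an
extinction flag. 841 cycles ≡ 631 days at 18 h/cycle.

Inflammation is an exogenous schedule of LOW/HIGH states (constant-low,
constant-high, or cycling with durations ILD/IHD, half-open blocks,
default 100 LOW / 50 HIGH starting LOW); only the CTL and Treg recruitment
coefficients are state-paired.

## Reproducibility

Each patient owns one PCG64 generator; the per-cycle draw order (fates,
mutation acceptances, pathway choices) is fixed. Per-patient seeds derive
from the cohort master seed as `SeedSequence([master_seed, index])`, so
cohorts are independent of execution order and two cohorts with the same
master seed share per-patient streams (common random numbers across
parameter settings, which is how the sweep and sensitivity workflows
reduce comparison noise). Identical config + seed reproduce output files
byte-for-byte.

## Default parameter set

The shipped defaults are the package's own calibration
(`scripts/calibrate.py` re-evaluates its conditions): carrying capacity of order 1e2; per-cycle
turnover high enough that the mutation ladder (fixed increment 1e-4)
produces recurrent mutant clones on a ~100-cycle scale; NK efficacy low
enough that proliferation/apoptosis mutants are mildly supercritical
against innate pressure alone (escape is a rare branching event, giving
the observed several-hundred-cycle waiting times) while CTL recruitment is
strong enough that escaping clones face an adaptive contention phase that
Tregs and EMT must erode. Censoring at the defaults is ~15–30% of a
cohort; the median time to invasion is several hundred cycles.

Key units: populations are scaled cell counts; τ is in arbitrary
concentration units (K_τ and K_4 set its scale); all rates are per
18-h cycle.

## Sensitivity analysis

Morris one-at-a-time elementary effects over the 31-parameter registry
(all biological constants; run-control settings excluded). Priors:
uniform [0, 1] for effect sizes, efficacies and the EMT threshold
(no literature anchor); truncated normal N(m_e, 2m_e) on the valid range
for anchored rates, with m_e the default value. Design points live in the
unit hypercube (r trajectories of k+1 points, default r = 30, 4 levels,
step Δ = ℓ/(2(ℓ−1))) and map to parameter space through prior quantile
functions, clipped to the 1–99 percentile band for unbounded priors so
"the range of variation" is finite. The analysed output is the restricted
mean invasion-free survival (area under the KM curve, horizon
`max_cycles`); the mean over uncensored patients is available as an
alternative. μ* is the mean absolute elementary effect, σ their standard
deviation. Integer-valued parameters (IHD, ILD) are rounded at
application.

## Survival statistics

Kaplan–Meier product-limit estimation with right censoring (events precede
censorings at ties), restricted mean survival time as the exact integral
of the step function, and the standard two-group log-rank test (1 df).
These are implemented from their defining sums; the test suite
cross-checks them against lifelines to 1e-10 on random datasets and
against brute-force enumeration oracles.

## What the simulator does and does not represent

The model is well-mixed (no spatial structure), binarizes EMT (no partial
states), treats inflammation as exogenous, and compresses immunity to
three populations with phenomenological saturation terms. Passing tests
show internal consistency with the stated equations and the qualitative
cohort-level behaviors under the calibrated defaults — not calibration to
any real tumor. In particular:

- The Δ_MIE monotonicity of cohort survival is robust across seeds at the
  shipped defaults.
- The interior Δ_MGA optimum is a delicate balance of a protective channel
  (growth arrest slows mesenchymal mutant clones, most strongly during the
  adaptive-contention phase when clones are old and heavily mesenchymal)
  and a harmful channel (an arrested mesenchymal bulk shrinks the
  denominator of the mutant fraction and releases crowding for
  fast-dividing, epithelially-born mutant daughters). With clearance
  independent of proliferation state — as the fate equations prescribe —
  these channels nearly cancel: at 200 patients per cohort the
  interior-optimum signal is comparable to Monte-Carlo noise (a few tens
  of RMST cycles), so with shared seeds the triple
  Δ_MGA ∈ {0, 0.2, 0.4} shows the interior maximum in some seed
  realizations and not in others. The Δ_MIE monotonicity, by contrast, is
  large relative to noise and reproduces across seeds.

## Scaled problem sizes

Cohort-level checks use 200 patients per cohort and the sensitivity
ranking check uses r = 4 trajectories with 50 patients per evaluation;
these sizes give stable qualitative conclusions for the properties they
test while keeping a full verification run to minutes.
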