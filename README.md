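# invasim

An agent-based simulator of carcinoma progression under immune
surveillance and epithelial–mesenchymal transition (EMT), for systems
biologists studying how mesenchymal phenotype properties and inflammatory
context shape the time from in-situ tumor to invasive disease.

Tumor cells are discrete agents that acquire mutations in three pathways
(proliferation, apoptosis, immune evasion) and switch between epithelial
and mesenchymal states under TGF-β; NK cells, cytotoxic T lymphocytes and
regulatory T cells are continuous populations coupled to the tumor through
clearance, antigen-driven recruitment and suppression; inflammation cycles
between low and high states that modulate adaptive recruitment. The
package simulates in-silico patient cohorts, summarizes them with
Kaplan–Meier invasion-free survival, and quantifies parameter influence
with Morris elementary-effects sensitivity analysis.

## Model core

Per 18-hour cell cycle, each tumor cell proliferates, apoptoses, is
cleared by an NK cell or CTL, or rests, with probabilities

```
ρ_P  = p (1 + δ_P Δ_P)(1 − ζ Δ_MGA) / (1 + N_C/K_0)
ρ_A  = d_C (1 − δ_A Δ_A)
ρ_NK = δ_MUT · N_NK/(N_C/K_1 + N_NK) · E_NK/(1 + N_Treg/K_2) · (1 − δ_IE Δ_IE)(1 − ζ Δ_MIE)
ρ_R  = 1 − ρ_P − ρ_A − ρ_NK − ρ_CTL
```

(CTL clearance mirrors the NK term with efficacy E_CTL). Immune
populations follow `N'_NK = σ_NK − d_NK N_NK`,
`N'_CTL = σ_CTL N*_MUT − d_CTL N_CTL`,
`N'_Treg = σ_Treg N*_MUT τ/(1+τ/K_4) − d_Treg N_Treg`, with
`τ = τ_MUT N_MUT + τ_Treg N_Treg`, where `N*_MUT` is the number of mutant
cells immune-cleared in the cycle. A tumor has progressed when ≥ 50% of
its cells carry a mutation; the tracked outcome is this time to invasion,
right-censored at 2000 cycles. See `docs/methods.md` for the full model
account and design choices.

## Worked example

Simulate a 50-patient cohort at the shipped defaults and print the
survival summary:

```
$ invasim simulate --n-patients 50 --seed 42 --out results/demo
cohort of 50 written to results/demo/cohort.csv; censoring fraction 0.200; restricted mean invasion-free survival 1074.0 cycles
```

Ten of the 50 simulated patients (20%) never progress within the
2000-cycle horizon; averaged over the cohort (area under the Kaplan–Meier
curve) a patient stays invasion-free for about 1074 cycles ≈ 806 days.
`results/demo/` now holds the per-patient table (`cohort.csv`, one row per
patient with time to invasion in cycles and days plus censoring and
extinction flags), the KM curve (`km.csv`) and a JSON manifest with every
effective parameter and the master seed, from which the run can be
reproduced byte-for-byte.

Sweeping mesenchymal immune evasion reproduces the qualitative clinical
prediction that more immune-evasive mesenchymal cells shorten
invasion-free survival:

```
$ invasim sweep --param delta_mie --values 0.2,0.5,0.8 --n-patients 200 --seed 42 --out results/mie
$ cat results/mie/sweep_summary.csv
value,rmst_cycles,censoring_fraction,logrank_p_vs_first
0.2,939.71,0.175,
0.5,852.145,0.13,0.1745909284
0.8,685.26,0.075,8.126222431e-05
```

Restricted mean survival falls monotonically (940 → 852 → 685 cycles) as
Δ_MIE rises from 0.2 to 0.8, and the log-rank test strongly separates the
extreme cohorts (p ≈ 8e-5).

Other subcommands: `invasim morris` (μ* sensitivity table over the
31-parameter registry), `invasim km` (KM curve from a cohort CSV),
`invasim fixtures` (deterministic test scenarios).

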