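# seedscreen

Quantitative analysis of chemically modified siRNAs: duplex melting
thermodynamics and seed-mediated off-target screening.

Sugar-modified nucleosides (for example 2′-formamido ribose) are introduced
into the seed region of an siRNA guide strand to destabilize the short
seed-only duplexes that drive miRNA-like off-target repression, while leaving
full-length on-target pairing intact. Evaluating such designs requires two
kinds of quantitative analysis, both provided by this package:

1. **Duplex melting thermodynamics.** UV melting curves (A260 vs temperature)
   of short RNA duplexes are reduced to melting temperatures and van't Hoff
   parameters. For a non-self-complementary duplex at total single-strand
   concentration *C*ₜ, the two-state association equilibrium gives

   1/*T*ₘ = (*R* ln(*C*ₜ/4) + Δ*S*°) / Δ*H*°,

   so regressing 1/*T*ₘ on log₁₀(*C*ₜ/4) over a concentration series yields
   Δ*H*° from the slope and Δ*S*° from the intercept, and
   Δ*G*°(T) = Δ*H*° − *T*Δ*S*°. Ribose pucker populations are estimated from
   the NMR coupling constant via C3′-endo(%) = 100 − 10·*J*₁′₋₂′.

2. **Seed-dependent off-target statistics.** The guide-strand seed (positions
   2–8 from the 5′ end) defines a 7-mer complement sought in transcript
   3′UTRs; transcripts carrying it are *seed-matched* (SM). After QC
   filtering (microarray feature flags, or a TPM ≥ 10 floor for RNA-seq) and
   quantile normalization, per-transcript log₂ fold changes (treated vs mock)
   are compared between SM and non-SM groups with a two-sided Wilcoxon
   rank-sum test, alongside MA coordinates and cumulative distributions.

A fully seeded synthetic-data module generates every input — melting curves,
UTR sets with planted seed complements, expression tables with known
knockdown effects, luciferase and qPCR assay tables — with truth labels, so
the whole pipeline is testable end to end without access to the original
instrument data.

## Worked example

```python
from seedscreen import (gibbs_free_energy, predict_tm, vant_hoff_fit,
                        c3_endo_percent)

# duplex association parameters of an unmodified 11-mer RNA duplex
dH, dS = -118.8, -350.9          # kcal/mol, cal/(mol*K)
print(round(gibbs_free_energy(dH, dS, 310.15), 1))   # -10.0 kcal/mol at 37 C

# analytic Tm over the measured concentration series, fitted back
conc = [6e-6, 12e-6, 18e-6, 24e-6]                    # total strand conc, M
fit = vant_hoff_fit([(c, predict_tm(dH, dS, c).tm_K) for c in conc])
print(round(fit.dH_kcal_per_mol, 1))                  # -118.8

# ribose pucker from the H1'-H2' coupling of 2'-formamidouridine
print(c3_endo_percent(8.8).c3_endo_percent)           # 12.0 %
```

The end-to-end synthetic pipeline runs from the command line:

```bash
seedscreen demo --seed 7 --out demo_out/
```

which simulates a 3000-transcript UTR set (450 seed-matched), a mock/treated
microarray table with a −0.5 log₂ shift on SM transcripts, and a noisy
melting-curve series, then analyzes all of it. With seed 7 it prints

```json
{
  "seed_scan": {"n_sm": 450, "n_non_sm": 2550},
  "offtarget": {
    "n_sm": 450, "n_other": 2549,
    "p_two_sided": 3.42e-145,
    "mean_log2fc_sm": -0.412,
    "mean_log2fc_other": 0.074
  },
  "vant_hoff": {
    "dH_kcal_per_mol": -120.41, "dS_cal_per_mol_K": -356.03,
    "dG37_kcal_per_mol": -9.98, "r_squared": 0.996
  }
}
```

The rank-sum p-value detects the planted seed-dependent repression (SM mean
log₂ fold change −0.41 vs +0.07 for the rest, after quantile normalization);
the van't Hoff fit recovers the generating Δ*H*° = −118.8 kcal/mol to within
the noise of the simulated curves. Other subcommands (`simulate`,
`fit-thermo`, `tm`, `pucker`, `seed-scan`, `design-reporter`, `offtarget`,
`luc`, `qpcr`) expose each stage separately; see `seedscreen --help`.

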