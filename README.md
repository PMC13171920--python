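# megsni

Tools for studying how serum biomarkers of dementia relate to a whole-brain
MEG functional-connectivity statistic — synchronous neural interactions
(SNI) — and how genes and viral exposure history moderate that relationship,
together with an exhaustive HLA class II epitope scan and a synthetic-data
generator that makes the whole chain testable without any private cohort
data.

## What it computes

**The SNI statistic** (`megsni.sni`). Each sensor series of a multichannel
recording is *prewhitened*: an ARIMA(p, d, q) model (default order
(50, 1, 3)) is fitted and its residuals — the innovations — replace the raw
series, removing temporal autocorrelation. All C(M, 2) pairwise zero-lag
Pearson correlations r between innovation series (30,628 pairs for a
248-channel array) are Fisher-transformed,

    r_z = arctanh(r) = ½ ln((1 + r)/(1 − r)),

and the per-pair statistic is SNI = |r_z|; the per-scan scalar is the mean
over pairs.

**Moderation analysis** (`megsni.cohort`). With repeated annual visits per
subject, inference uses linear mixed-effects models with a random intercept
per subject. The screen regresses SNI on age and seven serum biomarkers
(Aβ40, Aβ42, Aβ42/40, NFL, tTau, pTau181, pTau217) jointly. For a binary
factor F (ApoE group, HLA-DRB1*13 carriage, virus serostatus), the model
`SNI ~ age + pTau217 + F + F×pTau217` tests whether the SNI-vs-pTau217
slopes are parallel across F; if the interaction rejects, the two stratified
slopes b₁, b₂ (from separate mixed models per stratum) are compared with the
slope-difference normal deviate

    Z = (b₁ − b₂) / √(SE₁² + SE₂²)      (Paternoster test).

MoCA workflows mirror the same design with the cognitive score as outcome
and a pTau217×SNI interaction.

**Epitope scan** (`megsni.epitope`). Every linear 15-mer of a protein
(N − 15 + 1 windows for length N) is scored against an HLA-II allele by a
pluggable binding-affinity backend (predicted IC50, nM). The predicted best
binding affinity (PBBA) is the minimum IC50 over windows; windows under
50 nM are strong-binder "hits". Trained predictors are not re-implemented —
use the TSV adapter for an external tool's scores, or the deterministic mock
backend for offline work.

**Synthetic data** (`megsni.synthetic`). Scenario-driven generators for (a)
repeated-visits cohort tables — log-normal biomarkers matched to printed
mean/median pairs, ApoE/HLA genotypes and virus serostatus at template
frequencies, and an SNI column drawn from an explicit linear model whose
pTau217 slope depends on group membership — and (b) MEG-like recordings with
exact target zero-lag correlation (latent-factor construction) and optional
AR temporal coloring.

## Worked example

```python
from megsni import (default_cohort_scenario, generate_cohort,
                    screen_biomarkers, test_moderation)

sim = generate_cohort(default_cohort_scenario(), seed=1)   # 335 rows, 175 subjects
scr = screen_biomarkers(sim.table)
print(scr[["predictor", "p", "association"]].tail(1))
#    predictor             p association
# 7    ptau217  1.650766e-17    positive

res = test_moderation(sim.table, "drb1_1301")
print(f"interaction p = {res.interaction_p:.2e}")
print(f"slopes: absent {res.slope_absent[0]:.5f}, present {res.slope_present[0]:.5f}")
print(f"Paternoster Z = {res.paternoster_z:.2f} ({res.direction})")
# interaction p = 6.56e-11
# slopes: absent 0.00155, present -0.00177
# Paternoster Z = 6.69 (absent > present)
```

The screen flags only pTau217 (the only biomarker wired to SNI in the
default scenario) as a positive association. The moderation analysis
recovers the planted protective-allele effect: the SNI-vs-pTau217 slope is
positive in non-carriers of DRB1*13:01 and negative in carriers, and the
Paternoster Z is large and positive (absent > present).

The same workflows are available from the shell:

```
megsni simulate cohort --seed 1 --out cohort.csv
megsni analyze moderation --in cohort.csv --factor drb1_1301
megsni epitope-scan --fasta proteins.fasta --allele "DRB1*13:01" --backend mock
```

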