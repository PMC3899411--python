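# mcod

Tools for quantifying the mortality burden of Parkinson's disease (PD) — or
any chronic disease coded by a single ICD-10 category — in a country whose
vital statistics record only the *underlying* cause of death.

Standard mortality statistics assign each death a single underlying cause,
which for slowly progressive diseases such as PD captures only 30–50% of the
deaths in which the disease was actually involved. Two complementary analyses
recover the fuller picture:

1. **Death-certificate tabulation** — classify every condition mentioned on a
   certificate into one of three cause roles (immediate = Part I line 1,
   intermediate = later Part I lines, contributory = Part II) and rank
   conditions by frequency within each role. This profiles the comorbidity of
   decedents.
2. **Multiple-cause extrapolation** — estimate the number of deaths *with*
   the disease mentioned (the multiple-cause count) from the target country's
   underlying-cause table, borrowing conditional mention probabilities from a
   reference country that codes multiple causes, rescaled for differences in
   disease structure.

## The estimator

Index strata by *j* (sex × age band) and underlying-cause categories by *i*
(ischemic heart disease I20–I25, malignant neoplasm C00–C75, cerebrovascular
disease I60–I69, pneumonia J10–J18, PD G20, other). With
P<sub>ref,j</sub>(G20 | D<sub>i</sub>) the reference country's proportion of
certificates mentioning PD among deaths with underlying cause D<sub>i</sub>,
and R<sub>·,j</sub> the PD underlying-cause death rates,

    P_tgt,j(G20 | D_i) = P_ref,j(G20 | D_i) · R_tgt,j / R_ref,j        (P = 1 for D_i = G20)
    M_ij = N_tgt,ij · P_tgt,j(G20 | D_i)
    M_j  = Σ_i M_ij

Rates follow by dividing M<sub>j</sub> by the target population (per 100 000).
Adjusted proportions are capped at 1 and every cap, zero-cell imputation or
fallback is written to an audit log.

Because certificate microdata are confidential, the package ships
(a) a fixture builder that reconstructs a 477-certificate set exactly
reproducing the published Japanese PD comorbidity table, and (b) a synthetic
two-country cohort generator with known truth for validating the estimator.

## Worked example

```python
import mcod

# 1. comorbidity tabulation on the packaged 477-certificate fixture
certs = mcod.table2_fixture(seed=0)
tabs = mcod.tabulate_mentions(certs)            # excludes "Parkinson's disease"
print(tabs["contributory"].rows[:3])
print(mcod.mention_prevalence(certs, "Dementia"))

# 2. estimator validation on synthetic two-country cohorts
res = mcod.recovery_experiment(n_seeds=20, base_seed=0)
print(round(res.mean_abs_rel_error, 4))
```

prints

```
(('Cerebrovascular diseases', 19, 4.0), ('Dementia', 18, 3.8), ('Diabetes mellitus', 17, 3.6))
4.8
0.0124
```

— the top contributory comorbidities among the 477 PD decedents
(cerebrovascular disease on 19 certificates = 4.0%, dementia 3.8%, diabetes
3.6%), a 4.8% any-role dementia prevalence, and a 1.2% mean absolute relative
error when the estimator recovers the true multiple-cause total from
model-consistent 100 000-death cohorts.

A fitted model exposes the usual surface:

```python
model = mcod.MultipleCauseModel(target_uc, reference_uc, reference_mentions)
results = model.fit()
print(results.summary())      # totals, rates, audit-event count, stratum table
results.to_frame()            # sex, age_band, M, M_rounded, rate
```

The same operations are available from a shell via the `mcod` CLI
(`tabulate`, `extrapolate`, `simulate`, `recover`, `fixtures`).

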