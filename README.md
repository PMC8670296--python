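# methpanel

Selection and evaluation of methylated-DNA marker panels for colon cancer
detection.

Promoter CpG-island hypermethylation is an early, frequent event in
colorectal carcinogenesis, which makes small panels of methylated genes
attractive classifiers for tissue diagnosis and for liquid biopsy of
circulating cell-free DNA. `methpanel` implements the full analytic
pipeline around quantitative multiplex methylation-specific PCR (QM-MSP)
data: per-gene quantification, rank-based marker selection, locked-threshold
ROC evaluation, prevalence-adjusted diagnostic metrics, a
hierarchical-clustering prescreen for array data, microsatellite-instability
association tests, and a synthetic-cohort generator so the whole analysis is
runnable and testable without access to patient data.

It is written for computational biologists and biostatisticians building or
auditing methylation-based diagnostic panels.

## The model

For one gene in one sample, percent methylation is

```
%M = 100 · (# methylated copies) / (# methylated + unmethylated copies)
```

and a panel *P* of genes is scored per sample by the **cumulative
methylation index**, CMI = Σ_{g∈P} %M_g, with 0 ≤ CMI ≤ 100·|P|. A sample
is called carcinoma when CMI ≥ t.

**Marker selection** reduces a candidate list to a minimal panel in three
stages: (1) keep genes whose %M is significantly *higher* in carcinoma than
in normal tissue (two-sided Mann–Whitney, p < 0.05); (2) discard genes
whose normal-tissue 75th percentile is ≥ 10 %M (high background risks false
positives; the boundary is inclusive); (3) rank survivors by descending
carcinoma 75th percentile and keep the top six.

**Threshold locking** chooses t on training data only: among candidate
cutoffs (midpoints between consecutive distinct observed scores), take the
one maximizing sensitivity subject to specificity ≥ 90%, ties broken toward
the larger cutoff. The locked value is immutable and applied unchanged to
the test set — the package's file formats and CLI enforce this discipline
structurally.

**Diagnostic metrics** at population prevalence π (default 1%):

```
%PPV = 100 · se·π / (se·π + (1−sp)(1−π))
%NPV = 100 · sp·(1−π) / ((1−se)·π + sp·(1−π))
%Accuracy = 100 · (se·π + sp·(1−π))
```

with exact (Clopper–Pearson) CIs for sensitivity/specificity and DeLong CIs
for the AUC. The empirical AUC satisfies AUC = U/(n₁n₂), the Mann–Whitney
identity, which the test suite verifies on random instances.

**Synthetic cohorts** are drawn by inverse transform from piecewise-linear
quantile functions fitted to published per-gene five-number summaries
(packaged for 13 colon markers, 30 carcinomas vs 23 adjacent normals), so
simulated quartiles match the published ones by construction.

## Worked example

```python
import methpanel as mp

# 1. run the marker-selection procedure on the packaged reference summaries
summaries = [mp.marker_summary_from_reference(r)
             for r in mp.load_reference_markers().values()]
result = mp.select_from_summaries(summaries)
print("shortlist:", " > ".join(result.shortlist_ranked))
print("panel:    ", ", ".join(result.panel.genes))

# 2. simulate a cohort, split it, lock a threshold on training data,
#    evaluate the held-out test set
cohort = mp.generate_tissue_cohort(
    mp.default_tissue_spec(seed=1, n_carcinoma=60, n_normal=46))
train, test = mp.split_cohort(cohort, seed=1)

def scores(m, panel):
    cmi = mp.compute_cmi(m, panel)
    return (cmi[m.class_mask(mp.CARCINOMA)].to_numpy(),
            cmi[m.class_mask(mp.NORMAL)].to_numpy())

locked = mp.lock_threshold(*scores(train, mp.TISSUE_6), specificity_floor=0.90)
report = mp.evaluate_locked(*scores(test, mp.TISSUE_6), locked, prevalence=0.01)
```

Output:

```
shortlist: TMEFF2 > GPX7 > MAL > ARHGEF7 > TWIST1 > AKR1B1 > HIN1 > GAS7
panel:     TMEFF2, GPX7, MAL, ARHGEF7, TWIST1, AKR1B1
locked CMI threshold: 60 (training sens 1.00, spec 1.00)
test: sens 1.000, spec 1.000, AUC 1.000
at 1% prevalence: PPV 100.0%, NPV 100.0%, accuracy 100.00%
```

Reading the numbers: of 13 candidate genes, two fail the significance
filter, three are eliminated for high normal-tissue background, and the
eight survivors are ranked by carcinoma q75; the top six form the minimal
panel. On the simulated cohort the 6-gene CMI separates the classes
completely, so the locked cutoff (CMI = 60, a midpoint of observed training
scores) classifies every test sample correctly, and at 1% prevalence both
predictive values are 100%.

The same workflow is available from the shell:

```
methpanel simulate --kind tissue --seed 1 --split --out cohort.csv
methpanel lock     --input cohort.train.csv --panel tissue-6 --out thr.json
methpanel evaluate --input cohort.test.csv --threshold thr.json \
                   --panel tissue-6 --out report.json
```

`evaluate` exits with code 3 if the threshold file was not produced by
`lock`.

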