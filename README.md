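# ploidyscope

DNA image cytometry (DNA-ICM) ploidy analysis for brush-biopsy cytology, plus
the statistics used to evaluate it as a diagnostic test.

Oral lesions are easy to see and hard to triage: distinguishing benign
change, potentially malignant disorder and squamous cell carcinoma from a
non-invasive brush biopsy is the clinically useful problem. One established
adjunct is to measure the DNA content of individual nuclei by Feulgen
densitometry and look for **DNA aneuploidy** — the cytometric fingerprint of
chromosomal aneuploidy. `ploidyscope` implements that pipeline end to end
for cytopathology researchers and methodologists:

- **densitometry** — per-pixel optical density `OD(x, y) = log10(I0 / I(x, y))`
  and the integrated optical density (IOD) of a nucleus over its mask;
- **ploidy analysis** — normalization of IODs to c-units against internal
  reference cells (`c = 2 · IOD / mean(IOD_ref)`), DNA histograms, stemline
  detection by Gaussian-kernel density modes, and ESACP-style classification:
  a specimen is *DNA-aneuploid* if a stemline mode deviates more than 10%
  from the diploid and tetraploid regions (outside 2c ± 0.2c **and**
  4c ± 0.4c), or if at least one cell exceeds 9c (single-cell aneuploidy);
  cells above 5c are counted but never trigger on their own;
- **diagnostics** — confusion tables against follow-up outcome; sensitivity,
  specificity, PPV, NPV with exact (Clopper–Pearson) 95% CIs; the binary-test
  AUC `(Se + Sp)/2` with a Hanley–McNeil CI; a DeLong-type chi-square test
  for two correlated AUCs;
- **regression** — grouped-data logistic regression by an IRLS fitter that
  detects and reports complete/quasi-complete separation instead of printing
  stopping-rule artifacts, closed-form conditional odds ratios with Wald CIs,
  and a labelled Firth alternative;
- **synthetic data** — generators for reference-cell populations, stemline
  mixtures (G0/G1 peak, G2/M doubling peak, S-phase plateau, rare events
  above 9c), nucleus image patches, and labelled cohorts, so the whole
  pipeline is testable without a slide. A reconstructed 602-case study
  cohort ships as a packaged fixture.

## Worked example

```sh
python examples/evaluate_study_cohort.py
```

prints, among other lines:

```
cytology: counts {'tp': 308, 'fp': 90, 'fn': 0, 'tn': 204}
  sensitivity   100.0%  (95% CI 98.8-100.0%)
  specificity    69.4%  (95% CI 63.8-74.6%)
  auc          0.85  (95% CI 0.82-0.88)

icm: counts {'tp': 288, 'fp': 6, 'fn': 20, 'tn': 288}
  sensitivity    93.5%  (95% CI 90.1-96.0%)
  specificity    98.0%  (95% CI 95.6-99.2%)
  auc          0.96  (95% CI 0.94-0.97)
```

Dichotomized cytology (doubtful/suspicious/positive vs negative) catches
every outcome-positive case but at 69.4% specificity; ploidy analysis keeps
98.0% specificity at 93.5% sensitivity. The exact CI is what makes the
degenerate proportions honest: 308/308 still has a finite lower bound
(98.8%), where a Wald interval collapses. `examples/regression_separation.py`
shows the same cohort's logistic fit: the cytology coefficient is separated
(no finite MLE exists because there are no false-negative cytology cases),
while the ploidy odds ratio within cytology-positive cases is identifiable —
OR = 201.6 (95% CI 78.43–518.23) — and equals the closed-form cross-product
ratio. `examples/simulate_and_classify.py` and
`examples/densitometry_roundtrip.py` exercise the generator, the classifier
and the image-to-IOD path.

The same operations are scriptable from the shell:

```sh
ploidyscope simulate --preset aneuploid-3.52c --seed 7 --out out/
ploidyscope analyze --cells out/cells.csv --out out/results.json
ploidyscope evaluate --cohort cohort.csv --out metrics.json --roc roc.png
ploidyscope regress --cohort cohort.csv --out models.json
ploidyscope reproduce-study --out report/
```

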