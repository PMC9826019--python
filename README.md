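# her2refine

Refined HER2-low scoring for invasive breast cancer: a tested implementation
of the pipeline that sharpens the boundary between HER2 IHC score 0 and
score 1+, the line that decides eligibility for HER2-directed antibody–drug
conjugates in HER2-non-amplified disease.

## The problem

HER2 immunohistochemistry is reported on the ordinal 0 / 1+ / 2+ / 3+ scale,
but the guideline definition of 1+ ("incomplete, faint/barely perceptible
staining in > 10% of tumour cells") is coarse: many staining scenarios —
faint *complete* staining, weak complete staining in ≤ 10%, moderate
incomplete staining — are simply undefined, and interobserver agreement on
0 vs 1+ is poor. `her2refine` implements a refinement pipeline that uses
HER2 mRNA level (normalised RT-PCR units) as ground truth:

1. **Detailed staining profile** — per case, the percentage of invasive
   cells $p_{i,c}$ at each intensity $i \in \{\text{faint, weak, moderate,
   strong}\}$ × completeness $c \in \{\text{complete, incomplete}\}$, with
   cytoplasmic staining tracked separately, plus a modified H-score
   $H = \sum_{i,c} p_{i,c}\, w_i\, w_c$ with $w_\text{faint}=0.5,
   w_\text{weak}=1, w_\text{moderate}=2, w_\text{strong}=3$ and
   $w_\text{complete}=1, w_\text{incomplete}=0.5$ (range 0–300).
2. **mRNA dichotomization** — exact one-dimensional 2-means (an exhaustive
   split scan, deterministic and provably optimal) splits mRNA into
   low/high clusters; the boundary lands near 8.7 units.
3. **Cut-point derivation** — a population of small tanh networks trained
   by Levenberg–Marquardt under Monte Carlo cross-validation predicts the
   mRNA cluster from the staining percentages; per-parameter response
   curves and Youden-optimal thresholding yield percentage cut-points, and
   backward elimination marks which parameters actually participate.
4. **Refined scorer** — the resulting rule set for 1+: faint staining
   (complete + incomplete pooled) in ≥ 20%, weak complete in ≤ 10% (> 0),
   weak incomplete in > 10%, moderate incomplete in ≤ 10% (> 0); upper
   categories retain their existing boundaries.
5. **Validation analytics** — Cohen's kappa / exact agreement / discordance
   decomposition over 3×3 score cross-tabulations, and chi-square / Fisher
   association tests between score groups and covariates.

Because the underlying 363-case cohort is not public, the package ships a
**synthetic cohort generator** that emulates its published statistical
structure (pattern prevalences, score proportions near 37/39/24%, a bimodal
mRNA mixture with 2-means cut-off near 8.7) with planted, recoverable
ground truth — every stage of the pipeline is testable end to end.

## Worked example

```bash
her2refine simulate --seed 3 --n-cases 120 --out cohort.csv
her2refine score cohort.csv --out scored.csv
her2refine cluster scored.csv --out-dir clusters/
```

prints

```
wrote 120 cases to cohort.csv
scored 120 cases -> scored.csv
cutoff 8.77, sizes (61, 59)
```

`scored.csv` now carries `refined_score`, `guideline_score` and `h_score`
per case; the cluster step reports the exact 2-means mRNA cut-off (8.77
units here — the low/high boundary) and the cluster sizes. A case with,
say, 15% faint incomplete staining only is `1+` under the existing
guideline but `0` under the refined rules — the reclassification the
refinement exists for:

```python
>>> from her2refine import ExpressionProfile, refined_score, guideline_score
>>> p = ExpressionProfile(case_id="x", faint_incomplete=15.0)
>>> str(guideline_score(p)), str(refined_score(p))
('1+', '0')
```

The whole pipeline (simulate → cluster → train → cut-points → rescore →
concordance → associations) runs as:

```bash
her2refine pipeline --simulate --seed 5 --out-dir run/
```

writing `cutpoints.json` (parameter, direction, threshold, selected),
`ann_summary.json` (blind-test AUC, classification rate), a Table-style
concordance report and association tests, plus a JSON-lines run manifest
recording seeds and a config hash.

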