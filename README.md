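# glycoserum

Whole-serum *N*-glycan profiling for inflammatory-bowel-disease biomarker
analysis: composition-based MALDI-TOF glycan annotation, structural
classification, biosynthesis-pathway fold-change mapping, Bonferroni
differential screening with AUROC-based ratio-marker selection, bootstrap
group comparisons across clinical strata, and Kaplan–Meier / Cox
prognostic analysis. The pipeline targets glycoblotting-style serum
glycomics of ulcerative colitis (UC) versus healthy controls (HLT), and is
exercised end-to-end on synthetic cohorts because no patient-level data
are publicly deposited.

## Who this is for

Glycomics and clinical-biostatistics practitioners who have (a) a
samples × glycans abundance matrix (pmol/µL) keyed by four-digit
monosaccharide composition codes or integer *m/z* labels, and (b) sample
metadata with disease group, severity scores, and time-to-surgery
outcomes — and who want a tested, reproducible version of the standard
"screen → ratio marker → strata → survival" serum-glycomics workflow.

## The model in brief

**Mass model.** A glycan composition (Hex *h*, HexNAc *n*, Fuc *f*,
NeuAc *s*; written as the four-digit code *hnfs*, e.g. `5402`) prepared by
glycoblotting is sialic-acid methyl-esterified, benzyloxyamine (BOA)
tagged, and detected as the sodium adduct:

    m/z = h·162.052824 + n·203.079373 + f·146.057909 + s·(291.095417 + 14.015650)
          + 123.068414 (BOA oxime) + 22.989769 (Na⁺)

Integer peak names are the floor of this value: `5402` → *m/z* 2378,
`5410` → *m/z* 1914.

**Classification.** Composition-only heuristics partition glycans into
high-mannose / hybrid / complex / other; complex glycans get an
antennarity min(*n* − 2, 4), an agalactosyl-bi-antennary flag (*h* = 3,
2 antennae), and a highly-sialylated multi-branched flag (≥ 3 antennae,
≥ 3 NeuAc). The packaged 61-glycan reference panel reproduces the
published marginals (5/6/50 types, 25/10/15 antennarity, 43 sialylated,
33 fucosylated, 13 highly sialylated multi-branched, 4 agalactosyl
bi-antennary).

**Statistics.** Per-glycan Student's *t* with Bonferroni control at
α/61; discrimination by AUROC = P(case > control) (Mann–Whitney, ties
half); the ratio marker divides the best significant up-regulated glycan
by the best down-regulated one; bootstrap (10 000 resamples) point
estimates and p-values for group means; Kaplan–Meier + log-rank for
time-to-surgery by marker status; Cox proportional hazards
(Newton–Raphson, Breslow ties, Wald CIs) with a p < 0.1 univariate entry
rule and |r| > 0.7 collinearity exclusion before the multivariate fit.

## Worked example

```sh
glycoserum run-all --out-dir demo --seed 42
```

simulates a 75 UC + 75 HLT cohort and writes 17 report tables under
`demo/reports/`. With seed 42 the run log and reports show:

* `marker.csv` — the screen finds 24 Bonferroni-significant glycans and
  selects the planted ratio marker **m/z 2378/1914** (`5402`/`5410`) with
  AUROC **0.891**: the probability a random patient's ratio exceeds a
  random control's.
* `bootstrap.csv` — bootstrap point estimates of complex-type glycan
  totals: **412 pmol/µL in UC vs 331 in HLT** (p = 0.0002, the smallest
  value attainable at B = 10 000 with the add-one rule).
* `logrank.csv` — patients above the median ratio (cutoff 21.5) reach
  surgery faster: log-rank χ² = 21.0, p ≈ 5 × 10⁻⁶.
* `cox.csv` — univariate hazard ratio for marker-high **4.15
  [2.17–7.94]**; after the entry rule and collinearity check the
  multivariate model retains marker-high at HR **3.56 [1.83–6.92]**,
  i.e. the marker stays an independent prognostic factor alongside
  extent, CAI and the highly-sialylated aggregate.

Library use mirrors the CLI:

```python
import glycoserum as gs

panel = gs.reference_panel()
abundance, metadata = gs.simulate_cohort(gs.CohortConfig(seed=42))
groups = metadata["group"].astype(str)
res = gs.per_glycan_differential(abundance, groups, panel=panel)
marker = gs.select_ratio_marker(res, abundance, groups, panel)
print(marker.name, round(marker.auroc, 3))   # m/z 2378/1914 0.891
```

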