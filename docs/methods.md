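# Methods

This note documents the models, rules and numerical choices behind
`glycoserum`, in the order the pipeline runs, together with what the
synthetic cohort generator does and does not emulate.

## Mass model and annotation

Glycans are identified by monosaccharide composition only: counts of
hexose (Hex), *N*-acetylhexosamine (HexNAc), deoxyhexose (Fuc) and
*N*-acetylneuraminic acid (NeuAc), written most compactly as a four-digit
code in that order (`5402` = Hex₅HexNAc₄NeuAc₂). A valid *N*-glycan needs
HexNAc ≥ 2 and Hex ≥ 3 (the trimannosyl-chitobiose core).

The theoretical mass assumes glycoblotting-style derivatization:

| term | mass (Da) | why |
|---|---|---|
| Hex residue | 162.052824 | dehydrated monoisotopic residue |
| HexNAc residue | 203.079373 | 〃 |
| Fuc residue | 146.057909 | 〃 |
| NeuAc residue | 291.095417 + 14.015650 | every sialic acid is methyl-esterified (+CH₂) |
| reducing-end tag | 123.068414 | benzyloxyamine (BOA) oxime, C₇H₉NO net of water |
| adduct | 22.989769 | [M+Na]⁺, no electron-mass correction |

The sodium adduct (rather than [M+H]⁺) is fixed by the observed panel
endpoints: Hex₅HexNAc₂ computes to 1362.481 and Hex₇HexNAc₆Fuc₃NeuAc₄ to
4157.522, matching the published range to three decimals. Integer peak
names use **floor**, not rounding: floor(1914.698) = 1914; rounding would
misname that glycan 1915.

Peak annotation matches observed peaks to candidate compositions within
±0.2 Da (typical external-calibration MALDI-TOF accuracy; configurable),
greedily by smallest mass distance, at most one peak per candidate and
one candidate per peak. Exact ties break toward fewer total residues,
then lexicographic counts, so results do not depend on input order.

## Structural classification

Composition cannot resolve linkage, so classes are heuristic and are
documented as such:

* **high-mannose** — HexNAc 2, Hex 5–9, no Fuc/NeuAc;
* **hybrid** — HexNAc 3 with Hex ≥ 5;
* **complex** — HexNAc ≥ 4, or HexNAc 3 with Hex ≤ 4;
* **other** — anything else (e.g. paucimannose).

Antennarity of complex glycans is min(HexNAc − 2, 4), with one override:
Hex₃HexNAc₅ without sialic acid is scored as *bisected* bi-antennary,
because a bisecting GlcNAc is indistinguishable from a third antenna by
composition and an agalactosyl structure with three antennae but no
galactose acceptor sites is the less parsimonious reading. Galactose
count is Hex − 3 (three core mannoses). Derived flags:
agalactosyl bi-antennary (complex, 2 antennae, Hex = 3), highly
sialylated multi-branched (complex, ≥ 3 antennae, NeuAc ≥ 3), and
sialyl-Lewis-X potential (complex, NeuAc ≥ 1, Fuc ≥ 2 — a single fucose
is assumed core-linked).

### Reference panel

The packaged 61-composition panel is a fixture constrained by the
published marginals (5 high-mannose, 6 hybrid, 50 complex split
25/10/15 by antennarity, 43 sialylated, 33 fucosylated, 13 highly
sialylated multi-branched, 4 agalactosyl bi-antennary) and by six named
members (`5200`/1362, `5410`/1914, `5402`/2378, `6523`/3341,
`7624`/4011, `7634`/4157). The remaining membership is a package choice;
the exact published glycan list is not available. The loader re-validates
every constraint with the live classifier, so a rule change that breaks
the marginals fails loudly rather than silently reshaping downstream
counts.

## Biosynthesis network

Detected compositions form a DAG with an edge a → b when b = a plus
exactly one residue of one kind; edge mass deltas are therefore exactly
the four residue masses (NeuAc including its methyl-ester increment).
Edges are restricted to detected (panel) compositions — no inferred
intermediates. Node fold changes are log₂ of the ratio of *arithmetic*
group means (patients over controls), computed on abundances, not logs.
Exports: GraphML, and SIF (`source addition target`) plus a node
attribute table, both Cytoscape-ready.

## Cohort statistics

* **t-test**: classic equal-variance two-sample Student's *t*, two-sided;
  Welch available behind a flag but not the default, for fidelity to the
  workflow being operationalized.
* **Multiplicity**: Bonferroni at α/G over the G = 61 panel glycans.
* **AUROC**: rank (Mann–Whitney) formulation, P(case > control) with
  ties counted 0.5 — identical to the trapezoidal area under the
  empirical ROC, and invariant to monotone rescaling.
* **Ratio marker**: numerator = significant up-regulated glycan with
  maximal AUROC; denominator = significant down-regulated glycan with
  maximal 1 − AUROC (the direction-corrected orientation; reported
  down-glycan AUROCs in this literature are orientation-ambiguous).
  Ties break toward the smaller integer label for determinism. Samples
  with non-positive denominator abundance are excluded with a warning.
  With no significant glycan in either direction the procedure raises an
  explicit "no marker selectable" error rather than guessing.
* **Bootstrap**: within-group resampling with replacement; point
  estimate = mean of B bootstrap means; two-sided
  p = 2·min(#(diff ≤ 0)+1, #(diff ≥ 0)+1)/(B+1), capped at 1 — the
  add-one rule keeps p strictly positive. Default B = 10 000. All
  resampling flows from one seeded NumPy generator, so results are
  bit-for-bit reproducible.
* **Strata**: binary clinical contrasts — total vs left-sided colitis,
  CAI > 10, Mayo endoscopic score 3 vs 1–2 (score 0 excluded), steroid-
  refractory yes/no — each reported with means, Student's *t*, and the
  bootstrap summary.

## Survival analysis

Kaplan–Meier is the plain product-limit estimator; with no censoring it
reproduces the empirical survivor function exactly (up to float
rounding). The log-rank test is the standard 1-df chi-square.

The Cox model maximizes the log partial likelihood by Newton–Raphson
with step-halving, stopping at gradient max-norm < 1e-8 (or 100
iterations → error). Ties use **Breslow** by default — adequate for
continuous synthetic times — with Efron behind a flag; covariates are
mean-centered internally for stability. Inference is Wald: 95% CI =
exp(b ± 1.96·se). Monotone likelihoods (perfect separation) are detected
by runaway coefficients (|b| > 50) or exploded standard errors
(se > 100) and raised as errors, never reported silently.

Model building mirrors the clinical workflow: univariate screen with
entry rule p < 0.1; before the multivariate fit, any covariate pair with
|Pearson r| > 0.7 (computed on the covariates as entered) drops the
member with the larger univariate p. The 0.7 threshold operationalizes a
stated-but-unquantified collinearity exclusion.

Dichotomization uses linear-interpolation empirical quantiles (median by
default, 25th percentile as an alternative cut); "high" is strictly
greater than the cutoff. Sensitivity/specificity treat the event as
"surgery ever during follow-up", ignoring censoring — a deliberate
simplification, flagged in logs, that overstates certainty when
follow-up is short.

## Synthetic cohort generator

Defaults emulate the study conditions: 75 patients + 75 controls, 61
panel glycans, log-normal abundances (per-glycan log₁₀ SD 0.15).
Baseline log₁₀ abundances are set per structural class and scaled so
per-sample totals land at a few hundred pmol/µL with `5402` the most
abundant serum glycan (~100 pmol/µL) and `5410` around 10, giving a
healthy-control ratio near 10.

Planted patient effects (log₁₀ shifts): `5402` +0.22 and `5410` −0.18
(the marker pair, the largest effects by design), +0.12 for the 13
highly sialylated multi-branched glycans, +0.10 for the 4 agalactosyl
bi-antennary glycans, +0.06 for other sialylated complex glycans, −0.06
for a set of nine neutral/mono-sialylated bi-antennary glycans
(the IgG-dominated pool), zero for high-mannose and hybrid. These values
were chosen analytically so the default cohort reproduces the reported
qualitative structure: ~20–25 Bonferroni-significant glycans, marker
ratio medians ~25 (UC) vs ~11 (HLT), marker AUROC ~0.88.

A single standard-normal **severity latent** per patient drives CAI
(center 10, slope 4, rounded and clipped to 0–20), Mayo score (cut
points giving roughly the reported 15/20/40 split of scores 1/2/3),
disease extent (~75% total colitis), steroid-refractory status
(logistic, ~27% base rate), and — weakly — the marker glycans (`5402`
+0.06·z, `5410` −0.04·z, highly sialylated glycans +0.06·z). One shared
mechanism reproduces consistent stratum effects across all four clinical
contrasts.

Time to surgery is exponential with baseline hazard 0.008/month for
marker-low patients multiplied by exp(log 4.33) for marker-high (the
marker-high flag is the median split of the simulated ratio). Censoring
is uniform administrative censoring; the window is solved numerically so
the expected censored fraction equals the configured 40%. The real
study's follow-up scheme is unpublished; this choice is synthetic-only.

A `null_cohort` variant zeroes every effect, coupling and hazard ratio
and serves as the type-I-error harness.

**What passing tests do not show.** The generator draws independent
Gaussian noise per glycan: no instrument noise, peak overlap, isotope
interference, batch effects, heavy tails, or correlated measurement
error; clinical variables derive from one latent, so real multimorbidity
structure is absent. Tests on this generator validate the *procedures*
(calibration, recovery, invariances), not the clinical effect sizes,
which are not recoverable from published aggregates.

## Numerical and design choices

* Problem sizes in the heavier checks — 1000 null replicates for
  family-wise error, 200 cohorts for Cox CI coverage, 20 datasets for
  cross-package Cox agreement — balance Monte-Carlo error against a test
  suite that completes in a couple of minutes.
* Lifelines and statsmodels serve strictly as independent oracles in
  tests; the analysis code paths never call them.
* Reports avoid wall-clock timestamps so identical configurations
  produce byte-identical output.
* Seeds: every stochastic component takes one named seed; derived
  generators are spawned deterministically from it.

## Known limitations

* Classification is composition-only; isomers, linkage (α2,3 vs α2,6
  sialylation), bisecting GlcNAc vs antenna, and true sialyl-Lewis-X
  epitopes are not resolvable.
* The mass model covers BOA-tagged, methyl-esterified [M+Na]⁺ species
  only; other derivatizations need a custom `MassModel`.
* The panel beyond its six anchored members is synthetic in membership;
  per-glycan conclusions about specific non-anchor compositions carry no
  external meaning.
* Cox inference is Wald-based; profile-likelihood CIs and proportional-
  hazards diagnostics beyond the KM tables are out of scope, as are
  competing risks and time-dependent covariates.
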