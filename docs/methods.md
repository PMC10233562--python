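# Methods

## The feature catalog

The catalog (`src/bloodhof/data/registry.yaml`) holds 110 high-order
features: 76 proportional, 6 composite, 28 scoring. A *feature* is one
catalog entry; an entry may carry several **formula variants** when the
literature reports more than one formula or cutoff set under the same name
(APRI, FPR, NLPR, ALBI, PNI, GPS, LIPI, COP-LMR, COP-NLR, ALB-dNLR, SIS,
ACBS, CNG). Variant 1 is the default; a per-feature variant policy can
override it. Aliases record every reported synonym; an alias may be

* **plain** (SIRI → SIM, OPNI → PNI, PIV → AISI),
* **inverse** — the alias denotes the reciprocal ratio (MLR = 1/LMR,
  AFR = 1/FAR, PNR = 1/NPR); evaluating an inverse alias returns the
  reciprocal of the canonical value, or
* **variant-selecting** (mGPS → GPS cutoff set 2, LNI → LIPI cutoff set 2,
  GGLR → the GGT/Lymph variant of the `GLR` conflict entry).

Two reported abbreviations are genuinely ambiguous across unrelated
formulas: `GLR` (Gran/Lymph, GGT/Lymph, or Glc/Lymph) and `LLR` (WBC/Lymph
or LDH/Lymph). These strings are *reserved tokens*: looking them up raises
an ambiguity error listing the disambiguated names (GranLR, GGLR, GlcLR;
WLR, LDHLR). Internally each conflict row is a single multi-variant entry
(canonical GranLR and WLR, the first printed formula), mirroring how other
multi-formula rows are stored and keeping the category counts at exactly
76/6/28. The disambiguated names are variant-selecting aliases, so
`compute_feature(reg, "GlcLR", panel)` evaluates Glc/Lymph.

A handful of published values are plainly typographical and are stored in
the clinically coherent reading, each flagged with a note in the catalog:
CRP "mmol/L" → mg/L (CNG); PNI lymphocytes "/mL" → /µL (making variant 1
identical to variant 2); F-NLR fibrinogen "g/dL" → g/L; the LAR inverse
alias "ALR: ALP/Lymph" → Alb/Lymph (it sits in the inverse column). Two
published oddities are kept verbatim because the intent is unknowable: the
ANPG neutrophil condition "Neu > 2 or < 7" (satisfied by any count; the
rule still scores as printed) and the PIV-LDH rule that awards a point for
LDH *below* 1.5×ULN. The "WRPI" name that appears only in a correlation
table has no published formula anywhere and is not in the catalog.

## Units and reference intervals

Every analyte has one canonical unit (counts 10⁹/L, HGB/Alb/Glb/Fib g/L,
prealbumin and CRP mg/L, enzymes IU/L, bilirubin/creatinine µmol/L, lipids
and glucose mmol/L; percentage differentials are fractions in [0,1] with
`%` registered as 0.01). All conversions are multiplicative; formulas and
cutoffs state their working units explicitly and inputs are converted
before substitution or comparison, so supplying albumin as 4 g/dL or
40 g/L yields identical results. Hemoglobin mmol/L (used by the ACBS
cutoffs) converts at 1 mmol/L = 16.114 g/L (monomer convention).

Upper limits of normal (APRI, LIPI, PIV-LDH) come from a reference-interval
file. The packaged defaults are generic adult values — laboratories should
override them; a missing ULN yields a `missing-uln` cell, never a guess.

## Evaluation semantics

Formulas are parsed into expression trees (grammar: `+ − * / ^`,
parentheses, numeric constants, `log10`, `ln`, `sqrt`, `ULN(analyte)`).
Evaluation is vectorized over patients and never raises for data problems:
a cell is MISSING with reason `absent-analyte`, `zero-denominator`
(|denominator| < 1e-12 in working units, rather than ±inf),
`domain-error` (log/√ of a non-positive value), or `missing-uln`. Missing
values propagate — a scoring rule that reads dNLR is missing whenever WBC
is. Nothing is imputed, matching a cohort design that excludes incomplete
pre-treatment panels. Two derivations are applied when an input is absent
but derivable: BMI = Weight/Height², and GNRI's ideal body mass from the
Lorentz height/sex formula (men H−100−(H−150)/4, women H−100−(H−150)/2.5,
H in cm) — the GNRI literature does not fix a rule, so the choice is
configurable by simply supplying `IdealWeight`.

Scoring rules support threshold conditions (with sex-specific or
ULN-relative cutoffs), ordered bands with a mandatory else-band (CONUT,
ALBI-PLR), and ordered condition-cases (the three-level COP-NLR variant).
Comparisons use the printed strictness verbatim (`<` vs `≤`): GPS variant 1
gives 0 points at CRP = 10 mg/L while variant 3 gives 1. Printed CONUT
bands leave micro-gaps (3.49–3.5); bands are implemented as ordered
at-or-above thresholds so every input maps to a defined score.

## Nomenclature

Six conventions: (1) prefer the canonical (most-reported) abbreviation over
its reciprocal form; (2) prefer clinically meaningful names — honored by
the catalog's canonical choices (LIPI over LNI), not computable; (3)
products concatenate initial letters, ratios add `R` (LA vs LAR); (4)
orient a ratio so the cohort-median ratio is ≥ 1 (exact ties keep the
caller's order); (5) on a single-letter clash, expand the clashing analyte
to its short token (Glc → GlcLR, Gran → GranLR, GGT → GGLR — the token
table mirrors published usage); (6) abbreviations of 3–6 characters; since
the literature itself uses 2-letter names (LA, NP, MP), short names
produce warnings, not errors.

## Correlation screening

The screen reproduces a matched-subgroup design: hold every clinical
covariate except the target fixed (or quota-balanced), Spearman-correlate
each blood feature (LOFs pass through; HOFs are computed) against the
encoded target, and keep features with |ρ| at or above a fixed threshold —
0.305 for the n = 60 groups and 0.321 for the n = 52 smoking group. These
constants are carried as configuration, not re-derived: they do not equal
the two-sided t-approximation critical value (≈ 0.254 at n = 60,
α = 0.05), which `critical_rho(n, alpha)` provides separately for
auditing. Encodings (configurable): male = 1/female = 0, ever = 1/never = 0,
stage I–IV → 1–4, adenocarcinoma = 0/squamous = 1. Missing cells are
dropped pairwise; all-missing or constant columns are excluded and logged.
No multiplicity correction is applied — the design is a fixed threshold,
so with ~110 correlated features a null cohort still yields occasional
threshold crossings at the per-feature rate implied by the threshold
(≈ 1.8% at n = 60); the package's null calibration is therefore stated
per feature, not family-wise.

## Survival statistics

All estimators are self-contained; `lifelines` and `scikit-survival`
appear only as cross-check oracles in the test suite.

* **Kaplan–Meier**: standard product-limit estimator; S(0) = 1,
  right-continuous steps at event times.
* **C-index** (Harrell): pairs are comparable when the earlier time has the
  event; equal times are comparable only when exactly one has an event
  (both-event ties skipped); tied scores count ½.
* **Cox PH**: Newton–Raphson on the Breslow partial likelihood (Breslow
  rather than Efron ties, for oracle simplicity — the brute-force
  grid-search and reference cross-checks use the same convention), with
  step-halving so the recorded likelihood trace is non-decreasing;
  convergence when the largest step < 1e-8, at most 50 iterations;
  non-convergence or a singular information matrix raises with the
  iteration trace. Standard errors from the inverse observed information.
  The risk-model interface accepts any external score vector (e.g. a
  neural survival model's output); Cox is the shipped reference.
* **Decision curve**: at a fixed horizon, subjects censored before the
  horizon are excluded (complete case) and NB(p_t) = TP/N − (FP/N)·
  p_t/(1−p_t) is computed per threshold alongside treat-all
  (prevalence − (1−prevalence)·p_t/(1−p_t), the descending "backslash")
  and treat-none (identically zero). The complete-case handling is the
  simplest defensible treatment of censoring and is a documented
  limitation (inverse-probability-of-censoring weighting is out of scope).
* **Calibration**: quantile bins on predicted survival at a horizon;
  observed survival is the within-bin Kaplan–Meier at that horizon; empty
  quantile bins (tied predictions) merge with their neighbor.

## Synthetic cohort generator

The generator emulates the summary profile of a late-stage NSCLC registry
cohort; defaults: n = 1423; males 945/1423; stage III 482 and IV 595 with
the unspecified I/II remainder split 150/196 (chosen, together with a
sex-dependent adenocarcinoma probability of 0.90 for women and 0.545 for
men reproducing the overall 945/1423, so that the stage-II-heavy matched
subgroups of the screening design are feasible — under full marginal
independence they are not, though the real cohort evidently satisfied
them); age from a piecewise-linear quantile curve with median 62 and IQR
52–67; smoking prevalence 51/1423 ≈ 3.6% (the source text also says
"approximately 36%", an internal contradiction; the count is kept, which
makes the n = 52 smoking subgroup infeasible on default cohorts — its
quota error is designed behavior, and smoking-effect studies should raise
`smoking_fraction`).

Analytes are log-normal with 95% of their mass inside the adult reference
interval; covariate effects shift the log-mean by a stated number of
log-SDs per covariate level (stage centered at 2.5). Defaults carry a
stage gradient of GGT +0.35, Lymph −0.30, Neu +0.20 log-SD per stage —
the minimal analyte-level pattern consistent with the reported
stage-correlated indices (GGLR, ALRI, GPR positive; LMR, HII negative).
Correlation between analytes arises only through shared covariate effects
(no residual copula); differential counts stay coherent (WBC is the sum of
the five differentials, Gran = Neu+Eosin+Baso, percentages = count/WBC,
plateletcrit = Plt×MPV).

Survival is Weibull proportional hazards, shape 1.2, log-HR 0.5 per stage
level; censoring is Uniform(60, 1700) days, blending staggered
administrative entry with loss to follow-up. Scale 1470 days and the
window were tuned jointly (once, against the generator itself) so default
cohorts show ≈ 47.4% deaths and median observed follow-up ≈ 499 days;
these are tuning targets, not asserted equalities. Purely administrative
censoring cannot produce this pair — only ~47% deaths despite a ~500-day
median observed time requires substantial early loss to follow-up, which
the uniform window supplies.

What passing tests do **not** show: the generator reproduces marginal
summaries and injected effect signs, not the real cohort's joint analyte
distribution, its correlation magnitudes, or any reported model accuracy.
Results that depend on the unavailable patient data or on an external
deep-learning risk model (its C-index tables, SHAP rankings, decision
curves, the published nomogram's C-index of ~0.74) are out of scope and
are replaced by the property-based checks in the test suite.

## Problem sizes and verification

The test suite verifies: formula fidelity on ≥ 30 independently
hand-derived golden values (1e-6 relative); the reciprocal law on 1,000
random positive panels (1e-12); scoring ranges on 10,000 wide-drawn
panels; exact agreement of the C-index with an O(n²) pair enumerator on
200 random censored instances (n ≤ 100); the Cox optimum against a 1-D
grid search (1e-4) and Breslow coefficients against scikit-survival
(1e-5); Kaplan–Meier against lifelines (1e-10); stage log-HR recovery at
n = 2,000 over 20 seeds (pooled bias ≤ 3·SE/√20, ≥ 18/20 within 3 SE);
default event fraction within ±3% of 0.474 over 20 seeds; and screening
power/null over 100 seeds each — 0.5-log-SD stage shifts on GGT and Lymph
push GGLR past 0.305 in ≥ 90% of seeds, and with no effects GGLR crosses
in ≤ 5%. Power/null cohorts are drawn at n = 2,000 (group size, thresholds
and effect sizes unchanged) so quota sampling is reliably feasible across
all replicates. `scripts/acceptance.py` recomputes the same quantities at
reduced Monte-Carlo sizes (10–30 replicates) and reports whatever the run
produces.
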