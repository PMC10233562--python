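# bloodhof

A toolkit for **high-order features (HOFs) of routine blood tests** — the
derived indices (NLR, SII, GPS, CONUT, LIPI, …) that combine directly
measured analytes (low-order features, LOFs) and are widely reported as
prognostic markers in oncology, with non-small-cell lung cancer as the
motivating application.

The literature names these indices inconsistently (the same formula under
several abbreviations, the same abbreviation for several formulas, reciprocal
pairs like LMR/MLR treated as different markers). This package ships a
curated, machine-readable catalog of **110 features** — 76 proportional
(ratios/products, e.g. NLR = Neu/Lymph, SII = Neu×Plt/Lymph), 6 composite
(formulas with constants/transforms: ALBI, dNLR, GNRI, MELD, PALBI, PNI) and
28 scoring systems (cutoff-based point sums: GPS, CONUT, LIPI, SIS, …) — with
every reported formula/cutoff variant, reported aliases, inverse aliases, and
explicit units. Around the catalog it provides:

* **unit-aware evaluation** of any feature on a patient's lab panel, with
  principled missingness (no imputation; each undefined cell carries a
  machine-readable reason);
* **nomenclature rules** for canonicalizing reported names and generating
  compliant abbreviations (products by initial letters, ratios with an `R`
  suffix, ratio orientation by cohort median, conflict disambiguation:
  `GLR` → GranLR / GGLR / GlcLR);
* **correlation screening** of blood features against clinical covariates
  (sex, age, smoking, pathotype, stage) on matched subgroups, using Spearman
  rank correlation against fixed |ρ| thresholds (0.305 at n = 60, 0.321 at
  n = 52);
* **survival evaluation statistics implemented from first principles**:
  Kaplan–Meier, Harrell's C-index, a Cox proportional-hazards reference risk
  model (Newton–Raphson, Breslow ties), decision-curve net benefit
  NB(p_t) = TP/N − (FP/N)·p_t/(1−p_t), and calibration tables;
* a **synthetic NSCLC-like cohort generator** (n = 1423, stage-skewed, ~47%
  deaths, median follow-up ≈ 500 days) with controllable covariate-linked
  analyte effects and a Weibull proportional-hazards survival mechanism, so
  the whole pipeline is testable without patient data.

## Worked example

```python
import bloodhof as bh

reg = bh.default_registry()
panel = bh.LabPanel("pt-001", {
    "Neu":  (4.2, "10^9/L"), "Lymph": (1.4, "10^9/L"), "Mono": (0.52, "10^9/L"),
    "WBC":  (6.5, "10^9/L"), "Plt":   (301.0, "10^9/L"),
    "Alb":  (3.4, "g/dL"),   "CRP":   (12.0, "mg/L"),  "LDH": (310.0, "IU/L"),
    "TChol": (150.0, "mg/dL"),
}, {"age": 62, "sex": "male"})

for name in ["NLR", "SII", "LMR", "MLR", "dNLR", "PNI", "GPS", "CONUT", "LIPI"]:
    fv = bh.compute_feature(reg, name, panel)
    print(name, fv.value)
```

prints

```
NLR    3.0        # Neu/Lymph = 4.2/1.4
SII    903.0      # Neu*Plt/Lymph
LMR    2.6923     # Lymph/Mono
MLR    0.3714     # inverse alias: 1/LMR
dNLR   1.8261     # Neu/(WBC - Neu)
PNI    41.0       # 10*Alb[g/dL] + 0.005*Lymph[/uL]
GPS    2.0        # Alb < 3.5 g/dL and CRP > 10 mg/L both score
CONUT  4.0        # Alb band 2 + Lymph band 1 + TChol band 1
LIPI   1.0        # LDH > ULN only (dNLR <= 3)
```

Units are converted automatically (`Alb` given in g/dL, cutoffs applied in
the units each rule states). Name handling follows the nomenclature rules:

```python
bh.canonicalize(reg, "MLR")                              # ('LMR', True)
bh.propose_abbreviation("ratio", ["Glc"], ["Lymph"], reg).proposed  # 'GlcLR'
bh.canonicalize(reg, "GLR")   # raises AmbiguousNameError: GranLR, GGLR, GlcLR
```

A command-line interface mirrors the library:

```bash
bloodhof simulate --out cohort/ --seed 1          # synthetic cohort
bloodhof compute  --in cohort/lofs.csv --out hofs.csv
bloodhof screen   --in cohort/lofs.csv --covariate stage --out screen.csv
bloodhof name MLR                                  # -> "LMR (inverse)"
bloodhof evaluate --scores scores.csv --survival cohort/survival.csv
```

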