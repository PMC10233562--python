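# Analyte catalog: canonical unit per analyte plus registered conversions.
# factor maps a value in `unit` to the canonical unit: canonical = value * factor.
# All conversions are purely multiplicative (offset 0).
analytes:
  WBC:
    name: White blood cell count
    canonical: "10^9/L"
    units: {"10^9/L": 1.0, "G/L": 1.0, "10^6/L": 1.0e-3, "/uL": 1.0e-3, "10^4/uL": 10.0, "10^3/uL": 1.0}
  Neu:
    name: Neutrophil count
    canonical: "10^9/L"
    units: {"10^9/L": 1.0, "G/L": 1.0, "10^6/L": 1.0e-3, "/uL": 1.0e-3, "10^4/uL": 10.0, "10^3/uL": 1.0}
  Lymph:
    name: Lymphocyte count
    canonical: "10^9/L"
    units: {"10^9/L": 1.0, "G/L": 1.0, "10^6/L": 1.0e-3, "/uL": 1.0e-3, "10^4/uL": 10.0, "10^3/uL": 1.0}
  Mono:
    name: Monocyte count
    canonical: "10^9/L"
    units: {"10^9/L": 1.0, "G/L": 1.0, "10^6/L": 1.0e-3, "/uL": 1.0e-3, "10^4/uL": 10.0, "10^3/uL": 1.0}
  Eosin:
    name: Eosinophil count
    canonical: "10^9/L"
    units: {"10^9/L": 1.0, "G/L": 1.0, "10^6/L": 1.0e-3, "/uL": 1.0e-3, "10^4/uL": 10.0, "10^3/uL": 1.0}
  Baso:
    name: Basophil count
    canonical: "10^9/L"
    units: {"10^9/L": 1.0, "G/L": 1.0, "10^6/L": 1.0e-3, "/uL": 1.0e-3, "10^4/uL": 10.0, "10^3/uL": 1.0}
  Gran:
    name: Granulocyte count
    canonical: "10^9/L"
    units: {"10^9/L": 1.0, "G/L": 1.0, "10^6/L": 1.0e-3, "/uL": 1.0e-3, "10^4/uL": 10.0, "10^3/uL": 1.0}
  RBC:
    name: Red blood cell count
    canonical: "10^12/L"
    units: {"10^12/L": 1.0, "10^6/uL": 1.0}
  HGB:
    name: Hemoglobin
    canonical: "g/L"
    units: {"g/L": 1.0, "g/dL": 10.0, "mmol/L": 16.114}
  MCHC:
    name: Mean corpuscular hemoglobin concentration
    canonical: "g/L"
    units: {"g/L": 1.0, "g/dL": 10.0}
  Plt:
    name: Platelet count
    canonical: "10^9/L"
    units: {"10^9/L": 1.0, "G/L": 1.0, "10^6/L": 1.0e-3, "/uL": 1.0e-3, "10^4/uL": 10.0, "10^3/uL": 1.0}
  MPV:
    name: Mean platelet volume
    canonical: "fL"
    units: {"fL": 1.0}
  PDW:
    name: Platelet distribution width
    canonical: "fL"
    units: {"fL": 1.0}
  PCT:
    name: Plateletcrit
    canonical: "%"
    units: {"%": 1.0, "fraction": 100.0}
  RDW:
    name: Red cell distribution width
    canonical: "%"
    units: {"%": 1.0}
  Neu_ratio:
    name: Neutrophil fraction of WBC
    canonical: "fraction"
    units: {"fraction": 1.0, "%": 0.01}
  Lymph_ratio:
    name: Lymphocyte fraction of WBC
    canonical: "fraction"
    units: {"fraction": 1.0, "%": 0.01}
  Mono_ratio:
    name: Monocyte fraction of WBC
    canonical: "fraction"
    units: {"fraction": 1.0, "%": 0.01}
  Baso_ratio:
    name: Basophil fraction of WBC
    canonical: "fraction"
    units: {"fraction": 1.0, "%": 0.01}
  Alb:
    name: Albumin
    canonical: "g/L"
    units: {"g/L": 1.0, "g/dL": 10.0, "mg/dL": 0.01}
  Glb:
    name: Globulin
    canonical: "g/L"
    units: {"g/L": 1.0, "g/dL": 10.0}
  preAlb:
    name: Prealbumin (transthyretin)
    canonical: "mg/L"
    units: {"mg/L": 1.0, "g/L": 1000.0, "mg/dL": 10.0}
  CRP:
    name: C-reactive protein
    canonical: "mg/L"
    units: {"mg/L": 1.0, "mg/dL": 10.0}
  SAA:
    name: Serum amyloid A
    canonical: "mg/L"
    units: {"mg/L": 1.0}
  Fib:
    name: Fibrinogen
    canonical: "g/L"
    units: {"g/L": 1.0, "g/dL": 10.0, "mg/dL": 0.01}
  Ddim:
    name: D-dimer
    canonical: "mg/L"
    units: {"mg/L": 1.0, "ug/mL": 1.0, "ng/mL": 1.0e-3}
  AST:
    name: Aspartate aminotransferase
    canonical: "IU/L"
    units: {"IU/L": 1.0, "U/L": 1.0}
  ALT:
    name: Alanine aminotransferase
    canonical: "IU/L"
    units: {"IU/L": 1.0, "U/L": 1.0}
  ALP:
    name: Alkaline phosphatase
    canonical: "IU/L"
    units: {"IU/L": 1.0, "U/L": 1.0}
  GGT:
    name: Gamma-glutamyl transferase
    canonical: "IU/L"
    units: {"IU/L": 1.0, "U/L": 1.0}
  LDH:
    name: Lactate dehydrogenase
    canonical: "IU/L"
    units: {"IU/L": 1.0, "U/L": 1.0}
  TBil:
    name: Total bilirubin
    canonical: "umol/L"
    units: {"umol/L": 1.0, "mg/dL": 17.1}
  Crea:
    name: Creatinine
    canonical: "umol/L"
    units: {"umol/L": 1.0, "mg/dL": 88.4}
  UA:
    name: Uric acid
    canonical: "umol/L"
    units: {"umol/L": 1.0, "mg/dL": 59.48}
  Glc:
    name: Glucose
    canonical: "mmol/L"
    units: {"mmol/L": 1.0, "mg/dL": 0.0555}
  TChol:
    name: Total cholesterol
    canonical: "mmol/L"
    units: {"mmol/L": 1.0, "mg/dL": 0.02586}
  TG:
    name: Triglycerides
    canonical: "mmol/L"
    units: {"mmol/L": 1.0, "mg/dL": 0.01129}
  HDLC:
    name: HDL cholesterol
    canonical: "mmol/L"
    units: {"mmol/L": 1.0, "mg/dL": 0.02586}
  INR:
    name: International normalized ratio
    canonical: "ratio"
    units: {"ratio": 1.0}
  Age:
    name: Age
    canonical: "years"
    units: {"years": 1.0}
  Sex:
    name: Sex (male=1, female=0)
    canonical: "code"
    units: {"code": 1.0}
  Weight:
    name: Body weight
    canonical: "kg"
    units: {"kg": 1.0}
  Height:
    name: Body height
    canonical: "m"
    units: {"m": 1.0, "cm": 0.01}
  IdealWeight:
    name: Ideal body weight
    canonical: "kg"
    units: {"kg": 1.0}
  BMI:
    name: Body mass index
    canonical: "kg/m^2"
    units: {"kg/m^2": 1.0}
# Unicode spellings accepted everywhere an ASCII unit is registered.
unit_synonyms:
  "µmol/L": "umol/L"
  "µg/mL": "ug/mL"
  "/µL": "/uL"
  "10^4/µL": "10^4/uL"
  "10^3/µL": "10^3/uL"
  "10^6/µL": "10^6/uL"
  "/mm^3": "/uL"
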