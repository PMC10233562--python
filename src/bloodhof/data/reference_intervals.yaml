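# Default adult reference intervals, in each analyte's canonical unit.
# These are generic adult values for a mixed population; override with your
# laboratory's intervals for real analyses. The upper bound doubles as the
# ULN used by ULN-relative formulas (APRI, LIPI, PIV-LDH).
intervals:
  WBC: {lower: 3.5, upper: 9.5}
  Neu: {lower: 1.8, upper: 6.3}
  Lymph: {lower: 1.1, upper: 3.2}
  Mono: {lower: 0.1, upper: 0.6}
  Eosin: {lower: 0.02, upper: 0.52}
  Baso: {lower: 0.005, upper: 0.06}
  Gran: {lower: 2.0, upper: 7.0}
  RBC: {lower: 3.8, upper: 5.8}
  HGB: {lower: 115.0, upper: 160.0}
  MCHC: {lower: 316.0, upper: 354.0}
  Plt: {lower: 125.0, upper: 350.0}
  MPV: {lower: 7.0, upper: 11.0}
  PDW: {lower: 9.0, upper: 17.0}
  PCT: {lower: 0.1, upper: 0.28}
  RDW: {lower: 11.5, upper: 14.5}
  Neu_ratio: {lower: 0.4, upper: 0.75}
  Lymph_ratio: {lower: 0.2, upper: 0.5}
  Mono_ratio: {lower: 0.03, upper: 0.1}
  Baso_ratio: {lower: 0.001, upper: 0.01}
  Alb: {lower: 40.0, upper: 55.0}
  Glb: {lower: 20.0, upper: 40.0}
  preAlb: {lower: 200.0, upper: 400.0}
  CRP: {lower: 0.2, upper: 8.0}
  SAA: {lower: 0.5, upper: 10.0}
  Fib: {lower: 2.0, upper: 4.0}
  Ddim: {lower: 0.05, upper: 0.5}
  AST: {lower: 15.0, upper: 40.0}
  ALT: {lower: 9.0, upper: 50.0}
  ALP: {lower: 45.0, upper: 125.0}
  GGT: {lower: 10.0, upper: 60.0}
  LDH: {lower: 120.0, upper: 250.0}
  TBil: {lower: 3.4, upper: 17.1}
  Crea: {lower: 57.0, upper: 97.0}
  UA: {lower: 200.0, upper: 420.0}
  Glc: {lower: 3.9, upper: 6.1}
  TChol: {lower: 3.1, upper: 5.7}
  TG: {lower: 0.4, upper: 1.7}
  HDLC: {lower: 1.0, upper: 1.6}
  INR: {lower: 0.8, upper: 1.2}
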