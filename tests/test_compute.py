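import math

import numpy as np
import pandas as pd
import pytest

from bloodhof import compute_feature, compute_matrix
from bloodhof.compute import FeatureEngine
from bloodhof.expressions import OK


class TestGoldenValues:
    def test_golden_file_is_large_enough(self, golden_cases):
        assert len(golden_cases) >= 30

    def test_hand_derived_values(self, registry, golden_cases, make_panel):
        """Every frozen flat-arithmetic value reproduces to 1e-6 relative."""
        for case in golden_cases:
            panel = make_panel(clinical=case["clinical"], **case["panel"])
            policy = None
            if case["variant"]:
                canonical = registry.get_definition(case["feature"]).definition.canonical_abbr
                policy = {canonical: case["variant"]}
            fv = compute_feature(registry, case["feature"], panel, variant_policy=policy)
            assert fv.value is not None, f"{case['feature']}: missing ({fv.reason})"
            assert fv.value == pytest.approx(case["expected"], rel=1e-6), case["feature"]


# flat re-implementations, independent of the expression-tree evaluator
_FLAT_ORACLES = {
    "NLR": lambda t: t.Neu / t.Lymph,
    "SII": lambda t: t.Neu * t.Plt / t.Lymph,
    "AISI": lambda t: t.Neu * t.Plt * t.Mono / t.Lymph,
    "PLR": lambda t: t.Plt / t.Lymph,
    "LMR": lambda t: t.Lymph / t.Mono,
    "HALP": lambda t: t.HGB * t.Alb * t.Lymph / t.Plt,
    "HII": lambda t: t.Plt * t.Lymph / t.Neu * 100,
    "HLAN": lambda t: (t.HGB * t.Lymph * t.Alb / t.Neu) / 100,
    "ELR": lambda t: t.Eosin / t.Lymph,
    "BLR": lambda t: t.Baso / t.Lymph,
    "NPAR": lambda t: t.Neu_ratio / t.Alb,
    "MPR": lambda t: t.MPV / t.Plt,
    "WCR": lambda t: t.WBC / t.CRP,
    "TCHDR": lambda t: t.TChol / t.HDLC * 100,
    "TGHDR": lambda t: t.TG / t.HDLC * 100,
    "MGLR": lambda t: t.Mono * t.Lymph / t.Gran,
    "NLLR": lambda t: t.Neu / t.Lymph**2,
    "FIB-4": lambda t: (t.AST * t.Age) / (np.sqrt(t.ALT) * t.Plt),
    "APRI": lambda t: (t.AST / 40.0) / t.Plt * 100,
    "ALBI": lambda t: 0.66 * np.log10(t.TBil) - 0.085 * t.Alb,
    "PNI": lambda t: t.Alb + 5 * t.Lymph,
    "MELD": lambda t: 9.57 * np.log(t.Crea / 88.4)
    + 3.78 * np.log(t.TBil / 17.1)
    + 11.2 * np.log(t.INR)
    + 6.43,
    "GNRI": lambda t: 1.519 * t.Alb + 41.7 * t.Weight / t.IdealWeight,
    "ALI": lambda t: t.BMI * t.Alb * t.Lymph / t.Neu,
    "d-CWL": lambda t: t.CRP / (t.WBC * t.Lymph),
}


class TestOracleEquivalence:
    @pytest.mark.parametrize("feature", sorted(_FLAT_ORACLES))
    def test_expression_tree_matches_flat_arithmetic(
        self, engine, random_positive_table, feature
    ):
        values, reasons, _, _ = engine.evaluate(feature, random_positive_table)
        expected = _FLAT_ORACLES[feature](random_positive_table)
        ok = reasons == OK
        assert ok.mean() > 0.99
        np.testing.assert_allclose(values[ok], np.asarray(expected)[ok], rtol=1e-10)


class TestInvariants:
    def test_reciprocal_law_for_all_inverse_aliases(
        self, registry, engine, random_positive_table
    ):
        """alias x canonical = 1 on 1,000 strictly positive panels."""
        pairs = registry.inverse_aliases()
        assert len(pairs) >= 10
        for alias, canonical in pairs:
            va, ra, _, _ = engine.evaluate(alias, random_positive_table)
            vc, rc, _, _ = engine.evaluate(canonical, random_positive_table)
            ok = (ra == OK) & (rc == OK)
            assert ok.mean() > 0.99
            np.testing.assert_allclose(va[ok] * vc[ok], 1.0, rtol=1e-12, err_msg=alias)

    def test_positivity_of_subtraction_free_proportional_features(
        self, registry, engine, random_positive_table
    ):
        for name in registry.list_features("proportional"):
            variant = registry.features[name].variants[0]
            if variant.expression.has_subtraction:
                continue
            values, reasons, _, _ = engine.evaluate(name, random_positive_table)
            assert (values[reasons == OK] > 0).all(), name

    def test_scoring_outputs_stay_in_declared_range(self, registry, intervals):
        rng = np.random.default_rng(42)
        n = 10_000
        cols = {}
        for code in registry.units.analytes:
            ri = intervals.get(code)
            if ri is not None and ri.lower and ri.upper:
                # wide draw: half an order of magnitude beyond the interval
                lo, hi = np.log(ri.lower) - 0.5, np.log(ri.upper) + 0.5
                cols[code] = np.exp(rng.uniform(lo, hi, n))
            else:
                cols[code] = rng.uniform(0.1, 10.0, n)
        cols["Sex"] = rng.integers(0, 2, n).astype(float)
        table = pd.DataFrame(cols)
        engine = FeatureEngine(registry, intervals)
        for name in registry.list_features("scoring"):
            feat = registry.features[name]
            lo, hi = feat.score_range
            for variant in feat.variants:
                values, reasons = engine._eval_rules(variant.rules, table, frozenset())
                ok = reasons == OK
                assert ok.any()
                assert values[ok].min() >= lo and values[ok].max() <= hi, (
                    f"{name} variant {variant.variant_id}"
                )
                assert np.allclose(values[ok], np.round(values[ok]))

    @pytest.mark.parametrize("feature", ["PNI", "GPS", "CAR", "CONUT", "ALBI", "NPAR"])
    def test_unit_invariance_for_albumin(self, registry, make_panel, feature):
        base = dict(
            Lymph=1.2, Mono=0.4, Neu=5.0, WBC=7.2, Plt=250, CRP=12,
            TChol=(150, "mg/dL"), TBil=10, Neu_ratio=(65, "%"),
        )
        p_gl = make_panel(Alb=32.0, **base)
        p_gdl = make_panel(Alb=(3.2, "g/dL"), **base)
        v1 = compute_feature(registry, feature, p_gl)
        v2 = compute_feature(registry, feature, p_gdl)
        assert v1.value == pytest.approx(v2.value, rel=1e-12)


class TestMissingPropagation:
    def test_inverse_alias_of_zero_value(self, registry, make_panel):
        fv = compute_feature(registry, "LMR", make_panel(Lymph=3.0, Mono=0.0))
        assert fv.is_missing and fv.reason == "zero-denominator"

    def test_scoring_missing_analyte(self, registry, make_panel):
        fv = compute_feature(registry, "GPS", make_panel(Alb=30.0))
        assert fv.is_missing and fv.reason == "absent-analyte"

    def test_nested_feature_missing_propagates(self, registry, make_panel):
        # LIPI needs dNLR, which needs WBC
        fv = compute_feature(registry, "LIPI", make_panel(Neu=8.0, LDH=300.0))
        assert fv.is_missing and fv.reason == "absent-analyte"

    def test_uln_missing_reported(self, registry, make_panel):
        from bloodhof.units import ReferenceIntervals

        fv = compute_feature(
            registry, "APRI", make_panel(AST=80.0, Plt=100.0), intervals=ReferenceIntervals({})
        )
        assert fv.is_missing and fv.reason == "missing-uln"


class TestMatrix:
    def test_small_matrix_shape(self, registry, make_panel):
        panels = [
            make_panel(patient_id=f"p{i}", Neu=4 + i, Lymph=2.0, Plt=250.0) for i in range(3)
        ]
        m = compute_matrix(registry, panels, features=["NLR", "SII"])
        assert m.values.shape == (3, 2)
        assert (m.reasons.to_numpy() == OK).all()

    def test_full_catalog_gives_110_columns(self, registry, random_positive_table):
        engine = FeatureEngine(registry)
        table = random_positive_table.iloc[:5]
        names = registry.canonical_order()
        values = {n: engine.evaluate(n, table)[0] for n in names}
        assert len(values) == 110

    def test_missing_cell_has_reason(self, registry, make_panel):
        panels = [make_panel(Alb=30.0, Neu=4.0, Lymph=2.0)]
        m = compute_matrix(registry, panels, features=["GPS", "NLR"])
        assert math.isnan(m.values.iloc[0]["GPS"])
        assert m.reasons.iloc[0]["GPS"] != OK
        assert m.missingness_summary().loc["GPS", "absent-analyte"] == 1

    def test_empty_cohort_rejected(self, registry):
        with pytest.raises(ValueError, match="empty"):
            compute_matrix(registry, [])

    def test_duplicate_patient_ids_rejected(self, registry, make_panel):
        panels = [make_panel(patient_id="p1", Neu=4.0), make_panel(patient_id="p1", Neu=5.0)]
        with pytest.raises(ValueError, match="unique"):
            compute_matrix(registry, panels, features=["NLR"])
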