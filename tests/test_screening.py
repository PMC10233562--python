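import numpy as np
import pandas as pd
import pytest

from bloodhof.cohort import CohortSpec, generate_cohort, inject_effect
from bloodhof.compute import compute_matrix
from bloodhof.screening import (
    ScreeningConfig,
    ScreeningConfigError,
    ScreeningGroup,
    build_group,
    clinical_frame,
    critical_rho,
    default_screening_config,
    encode_covariate,
    screen_features,
    spearman_rho,
)


def rank_average(x):
    """Average ranks with ties — independent brute-force ranking."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def brute_spearman(x, y):
    rx, ry = rank_average(np.asarray(x, float)), rank_average(np.asarray(y, float))
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        assert spearman_rho(x, y) == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(5, 40)
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            assert spearman_rho(x, y) == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_invariant_under_monotone_transform_and_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(rho, abs=1e-12)
        assert spearman_rho(y, x) == pytest.approx(rho, abs=1e-12)
        assert spearman_rho(x, -y) == pytest.approx(-rho, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestCriticalRho:
    def test_n60_alpha05(self):
        assert critical_rho(60, 0.05) == pytest.approx(0.254, abs=2e-3)

    def test_limit_behavior_and_monotonicity(self):
        assert critical_rho(4, 0.999) < 1e-3
        assert critical_rho(30, 0.05) > critical_rho(60, 0.05)

    def test_printed_thresholds_are_not_the_t_approximation(self):
        # the packaged constants are reported values, deliberately carried
        # as configuration rather than re-derived
        assert abs(critical_rho(60, 0.05) - 0.305) > 0.02


class TestConfig:
    def test_packaged_thresholds(self):
        config = default_screening_config()
        assert config.rs_thresholds[60] == 0.305
        assert config.rs_thresholds[52] == 0.321
        assert config.confidence == 0.95

    def test_unknown_group_size_without_fallback_errors(self):
        config = ScreeningConfig(alpha_fallback=False)
        with pytest.raises(ScreeningConfigError, match="group size"):
            config.threshold_for(45)

    def test_alpha_fallback(self):
        config = ScreeningConfig(alpha_fallback=True)
        assert config.threshold_for(45) == pytest.approx(critical_rho(45, 0.05))

    def test_target_cannot_be_filtered_when_balanced(self):
        with pytest.raises(ScreeningConfigError):
            ScreeningGroup("sex", filters={"sex": "male"}, balance={"male": 30, "female": 30})


@pytest.fixture(scope="module")
def cohort():
    panels, _ = generate_cohort(CohortSpec(seed=5))
    return panels


class TestBuildGroup:
    def test_sex_group_quota(self, cohort):
        config = default_screening_config()
        ids = build_group(cohort, config.groups["sex"], seed=1)
        assert len(ids) == 60
        clin = clinical_frame(cohort).loc[ids]
        assert (clin["sex"] == "male").sum() == 30
        assert (clin["sex"] == "female").sum() == 30
        assert clin["stage"].eq("II").all()
        assert clin["age"].between(30, 65).all()

    def test_stage_group_quota(self, cohort):
        config = default_screening_config()
        ids = build_group(cohort, config.groups["stage"], seed=1)
        clin = clinical_frame(cohort).loc[ids]
        assert clin["stage"].value_counts().to_dict() == {"I": 15, "II": 15, "III": 15, "IV": 15}

    def test_reproducible_given_seed(self, cohort):
        config = default_screening_config()
        g = config.groups["stage"]
        assert build_group(cohort, g, seed=7) == build_group(cohort, g, seed=7)
        assert build_group(cohort, g, seed=7) != build_group(cohort, g, seed=8)

    def test_infeasible_quota_names_the_level(self, cohort):
        group = ScreeningGroup("stage", balance={"I": 10_000, "II": 1, "III": 1, "IV": 1})
        with pytest.raises(ValueError, match="stage=.?I"):
            build_group(cohort, group, seed=0)


class TestScreenFeatures:
    def test_injected_stage_effect_is_detected_with_positive_sign(self, registry):
        spec = CohortSpec(seed=9, effects=())
        spec = inject_effect(spec, "GGT", "stage", 0.6)
        spec = inject_effect(spec, "Lymph", "stage", -0.5)
        panels, _ = generate_cohort(spec)
        config = default_screening_config()
        ids = set(build_group(panels, config.groups["stage"], seed=2))
        sub = [p for p in panels if p.patient_id in ids]
        matrix = compute_matrix(registry, sub, features=["GGLR", "NLR", "MPR"])
        cov = encode_covariate(clinical_frame(sub), "stage")
        result = screen_features(matrix, cov, config)
        row = result.set_index("feature").loc["GGLR"]
        assert row["passed"] and row["rho"] > 0

    def test_output_invariant_under_column_permutation(self, registry, cohort):
        config = default_screening_config()
        ids = set(build_group(cohort, config.groups["stage"], seed=3))
        sub = [p for p in cohort if p.patient_id in ids]
        features = ["NLR", "PLR", "LMR", "GGLR", "SII"]
        cov = encode_covariate(clinical_frame(sub), "stage")
        a = screen_features(compute_matrix(registry, sub, features=features), cov, config)
        b = screen_features(
            compute_matrix(registry, sub, features=features[::-1]), cov, config
        )
        pd.testing.assert_frame_equal(a, b)

    def test_all_missing_column_excluded(self):
        values = pd.DataFrame(
            {"good": np.arange(10.0), "empty": np.full(10, np.nan)},
            index=[f"p{i}" for i in range(10)],
        )
        cov = pd.Series(np.arange(10.0), index=values.index)
        result = screen_features(values, cov, threshold=0.305)
        assert list(result["feature"]) == ["good"]

    def test_sorted_by_absolute_rho(self, registry, cohort):
        config = default_screening_config()
        ids = set(build_group(cohort, config.groups["sex"], seed=4))
        sub = [p for p in cohort if p.patient_id in ids]
        cov = encode_covariate(clinical_frame(sub), "sex")
        result = screen_features(
            compute_matrix(registry, sub, features=["NLR", "HGB", "PLR", "HALP"]), cov, config
        )
        rho_abs = result["rho"].abs().to_numpy()
        assert (np.diff(rho_abs) <= 1e-15).all()
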