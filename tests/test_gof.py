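"""GOF quantity, sampling-constant calibration, and phase-II selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gofsurv import (
    CohortConfig,
    GofDesignConfig,
    GofDesignError,
    assemble_cohort,
    calibrate_constant,
    fit_external,
    gof_quantity,
    median_age_strata,
    select_phase2,
    select_phase2_balanced,
)
from gofsurv.external import ExternalModel
from gofsurv.gof import compute_d


@pytest.fixture(scope="module")
def cohort():
    return assemble_cohort(CohortConfig(seed=33, censor_rate_param=0.087))


@pytest.fixture(scope="module")
def external(cohort):
    return fit_external(cohort, bootstrap_size=10_000, seed=2)


class TestGofQuantity:
    @pytest.mark.parametrize(
        "event,s_e,expected",
        [
            (1, 1.0, 1.0),   # event despite predicted certain survival: worst fit
            (0, 1.0, 0.0),   # perfectly predicted control
            (0, 0.3, 0.7),
            (1, 0.3, 0.3),
        ],
    )
    def test_formula(self, event, s_e, expected):
        assert gof_quantity(event, s_e) == pytest.approx(expected)

    def test_invalid_survival_rejected(self):
        with pytest.raises(GofDesignError):
            gof_quantity(1, 0.0)
        with pytest.raises(GofDesignError):
            gof_quantity(0, 1.5)


class TestCalibrateConstant:
    def test_linear_regime(self):
        assert calibrate_constant(np.array([0.1, 0.2, 0.3, 0.4]), 1.0) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_saturation(self):
        c = calibrate_constant(np.full(10, 0.5), 10.0)
        assert c >= 2.0
        assert np.minimum(1, c * np.full(10, 0.5)).sum() == pytest.approx(10.0)

    def test_infeasible_target_reports_ceiling(self):
        d = np.array([0.0, 0.0, 0.5, 0.5])
        with pytest.raises(GofDesignError, match="at most 2"):
            calibrate_constant(d, 3.0)

    @settings(max_examples=50, deadline=None)
    @given(
        st.integers(min_value=5, max_value=200),
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=0.1, max_value=0.95),
    )
    def test_root_residual_on_random_vectors(self, n, seed, frac):
        """sum min(1, c d_i) hits the target within 1e-5 for random d."""
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 1, n) * (rng.random(n) < 0.9)
        n_pos = (d > 0).sum()
        if n_pos == 0:
            return
        target = max(frac * n_pos, 1e-3)
        c = calibrate_constant(d, target)
        assert abs(np.minimum(1.0, c * d).sum() - target) < 1e-5


class TestSelectPhase2:
    def test_all_cases_kept_with_unit_weight(self, cohort, external):
        sample = select_phase2(cohort, external, GofDesignConfig(seed=4))
        event = cohort.data["event"].to_numpy()
        assert (sample.prob[event == 1] == 1.0).all()
        assert (sample.selected[event == 1] == 1).all()
        assert (sample.weight[event == 1] == 1.0).all()

    def test_weights_are_inverse_probabilities(self, cohort, external):
        sample = select_phase2(cohort, external, GofDesignConfig(seed=4))
        sel = sample.selected == 1
        np.testing.assert_allclose(sample.weight[sel], 1.0 / sample.prob[sel])

    def test_expected_control_count_matches_ratio(self, cohort, external):
        """Realized control counts concentrate around ratio * n_cases."""
        d = compute_d(cohort, external)
        event = cohort.data["event"].to_numpy()
        n_cases = int(event.sum())
        sample = select_phase2(cohort, external, GofDesignConfig(seed=0))
        p = sample.prob[event == 0]
        assert sample.expected_controls == pytest.approx(n_cases, abs=1e-4)
        sd = np.sqrt(np.sum(p * (1 - p)))
        counts = []
        rng = np.random.default_rng(12)
        for _ in range(50):
            s = select_phase2(cohort, external, GofDesignConfig(), rng=rng)
            counts.append(int(s.selected[event == 0].sum()))
        assert abs(np.mean(counts) - n_cases) < 3 * sd / np.sqrt(50)

    def test_selection_probability_nondecreasing_in_d(self, cohort, external):
        sample = select_phase2(cohort, external, GofDesignConfig(seed=4))
        event = cohort.data["event"].to_numpy()
        d = sample.d_values[event == 0]
        p = sample.prob[event == 0]
        order = np.argsort(d)
        assert np.all(np.diff(p[order]) >= -1e-12)

    def test_perfect_external_fit_is_infeasible(self, cohort):
        """S_e = 1 for everyone leaves no selectable controls."""
        model = ExternalModel(
            eta=np.zeros(6), jump_times=np.array([]), cumhaz=np.array([]),
        )
        with pytest.raises(GofDesignError):
            select_phase2(cohort, model, GofDesignConfig(seed=0))

    def test_case_target_required_without_all_cases(self, cohort, external):
        with pytest.raises(GofDesignError, match="case_target"):
            select_phase2(
                cohort, external, GofDesignConfig(include_all_cases=False, seed=0)
            )


class TestBalancedSelection:
    def test_single_stratum_reduces_to_unstratified(self, cohort, external):
        config_flat = GofDesignConfig(seed=6)
        config_one = GofDesignConfig(seed=6, strata=lambda c: np.zeros(c.n, dtype=int))
        a = select_phase2(cohort, external, config_flat)
        b = select_phase2_balanced(cohort, external, config_one)
        np.testing.assert_array_equal(a.selected, b.selected)
        np.testing.assert_allclose(a.prob, b.prob)

    def test_per_stratum_control_targets(self, cohort, external):
        config = GofDesignConfig(seed=6, strata=median_age_strata)
        sample = select_phase2_balanced(cohort, external, config)
        event = cohort.data["event"].to_numpy()
        labels = sample.strata_labels
        for lab in (0, 1):
            mask = labels == lab
            n_cases = int(event[mask].sum())
            assert sample.prob[mask & (event == 0)].sum() == pytest.approx(
                n_cases, abs=1e-4
            )

    def test_constants_differ_when_d_distributions_differ(self, cohort, external):
        """Older stratum has larger baseline risk, hence different c0."""
        config = GofDesignConfig(seed=6, strata=median_age_strata)
        sample = select_phase2_balanced(cohort, external, config)
        assert sample.constants[0]["c0"] != pytest.approx(
            sample.constants[1]["c0"], rel=1e-3
        )

    def test_stratum_without_cases_is_an_error(self, cohort, external):
        event = cohort.data["event"].to_numpy()

        def bad_strata(c):
            # put every case into stratum 0; stratum 1 has none
            return np.where(event == 1, 0, np.arange(c.n) % 2)

        with pytest.raises(GofDesignError, match="stratum"):
            select_phase2_balanced(
                cohort, external, GofDesignConfig(seed=0, strata=bad_strata)
            )


def test_horvitz_thompson_unbiasedness(cohort, external):
    """E[sum_selected w g] = sum_all g over repeated GOF draws (<2% rel err)."""
    rng = np.random.default_rng(99)
    d = compute_d(cohort, external)
    event = cohort.data["event"].to_numpy()
    from gofsurv.gof import _probabilities_one_stratum

    prob, _ = _probabilities_one_stratum(event, d, GofDesignConfig())
    g = cohort.data["z"].to_numpy() + 3.0  # bounded positive attribute
    total = g.sum()
    n_draws = 2000
    draws = rng.random((n_draws, cohort.n)) < prob
    with np.errstate(divide="ignore"):
        w = np.where(prob > 0, 1.0 / prob, 0.0)
    ht = (draws * (w * g)).sum(axis=1)
    assert abs(ht.mean() - total) / total < 0.02


def test_phase2_table_export(cohort, external):
    sample = select_phase2(cohort, external, GofDesignConfig(seed=4))
    frame = sample.to_frame(cohort)
    assert list(frame.columns) == [
        "subject_id", "selected", "prob", "weight", "stratum", "D",
    ]
    assert frame["selected"].sum() == sample.realized_m
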