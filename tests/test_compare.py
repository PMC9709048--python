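import numpy as np
import pytest

import mixedstock as ms
from mixedstock.compare import (
    EquivalenceConfig,
    equal_tailed_interval,
    equivalence_test,
    hdi,
    posterior_difference,
)


class TestPosteriorDifference:
    def test_identity_gives_zero(self, quick_fit):
        _, _, samples, _ = quick_fit
        diffs = posterior_difference(samples, samples, kind="theta")
        assert set(diffs) == set(samples.parameter_labels("theta"))
        for d in diffs.values():
            assert np.all(d == 0.0)

    def test_constant_shift(self):
        a = {"p": np.full(100, 0.7)}
        b = {"p": np.full(100, 0.2)}
        (d,) = posterior_difference(a, b).values()
        assert d == pytest.approx(np.full(100, 0.5))

    def test_truncates_to_shorter_with_warning(self):
        a = {"p": np.zeros(9000)}
        b = {"p": np.zeros(8000)}
        with pytest.warns(UserWarning, match="truncating"):
            (d,) = posterior_difference(a, b).values()
        assert d.size == 8000

    def test_unshared_parameters_skipped_with_warning(self):
        a = {"p": np.zeros(100), "only_a": np.zeros(100)}
        b = {"p": np.zeros(100)}
        with pytest.warns(UserWarning, match="only_a"):
            diffs = posterior_difference(a, b)
        assert list(diffs) == ["p"]

    def test_no_shared_parameters_errors(self):
        with pytest.raises(ms.ValidationError, match="share no parameters"):
            posterior_difference({"a": np.zeros(10)}, {"b": np.zeros(10)})


class TestHdi:
    def test_constant_draws(self):
        assert hdi(np.full(20, 3.5), 0.89) == (3.5, 3.5)

    def test_exhaustive_window_scan_oracle(self):
        # draws 1..100 at level 0.5: every 50-draw window has width 49;
        # ties break to the smallest left endpoint.
        assert hdi(np.arange(1, 101, dtype=float), 0.5) == (1.0, 50.0)

    def test_skewed_draws_match_brute_force(self):
        rng = np.random.default_rng(7)
        draws = rng.gamma(2.0, 1.0, size=2000)
        lo, hi = hdi(draws, 0.89)
        s = np.sort(draws)
        m = int(np.ceil(0.89 * 2000))
        widths = s[m - 1 :] - s[: 2000 - m + 1]
        k = int(np.argmin(widths))
        assert (lo, hi) == (s[k], s[k + m - 1])
        assert hi - lo <= (equal_tailed_interval(draws, 0.89)[1] - equal_tailed_interval(draws, 0.89)[0])

    def test_symmetric_unimodal_close_to_equal_tailed(self):
        draws = np.random.default_rng(0).standard_normal(100_000)
        h = np.array(hdi(draws, 0.89))
        e = np.array(equal_tailed_interval(draws, 0.89))
        assert np.max(np.abs(h - e)) < 0.05

    def test_too_few_draws_errors(self):
        with pytest.raises(ms.ValidationError):
            hdi(np.arange(5, dtype=float), 0.89)


class TestEquivalenceTest:
    def test_point_mass_inside_rope_accepted(self):
        res = equivalence_test(np.zeros(100))
        r = res.parameters["diff"]
        assert (r.proportion_in_rope, r.decision) == (1.0, "accepted")

    def test_point_mass_outside_rope_rejected(self):
        r = equivalence_test(np.full(100, 0.5)).parameters["diff"]
        assert (r.proportion_in_rope, r.decision) == (0.0, "rejected")

    def test_uniform_overlap_matches_analytic_value(self):
        # HDI of U(-0.1, 0.1) at 89% has width 0.178; ROPE overlap 0.10;
        # proportion = 0.10 / 0.178 = 0.562.
        draws = np.random.default_rng(42).uniform(-0.1, 0.1, 100_000)
        r = equivalence_test(draws).parameters["diff"]
        assert r.proportion_in_rope == pytest.approx(0.562, abs=0.02)
        assert r.decision == "undecided"

    def test_self_comparison_accepted_everywhere(self, quick_fit):
        _, _, samples, _ = quick_fit
        diffs = posterior_difference(samples, samples, kind="theta")
        res = equivalence_test(diffs)
        assert all(r.decision == "accepted" for r in res.parameters.values())

    def test_unit_shift_rejected_everywhere(self, quick_fit):
        _, _, samples, _ = quick_fit
        pooled = samples.pooled("theta")
        shifted = {k: v + 1.0 for k, v in pooled.items()}
        res = equivalence_test(posterior_difference(shifted, pooled))
        assert all(r.decision == "rejected" for r in res.parameters.values())

    def test_symmetric_rope_exchange_invariance(self):
        rng = np.random.default_rng(9)
        a = {"p": rng.normal(0.03, 0.02, 5000)}
        b = {"p": rng.normal(0.0, 0.02, 5000)}
        p_ab = equivalence_test(posterior_difference(a, b)).parameters["p"].proportion_in_rope
        p_ba = equivalence_test(posterior_difference(b, a)).parameters["p"].proportion_in_rope
        assert p_ab == pytest.approx(p_ba, abs=1e-9)

    def test_draw_counting_estimator_close_to_geometric(self):
        draws = np.random.default_rng(10).uniform(-0.1, 0.1, 100_000)
        geo = equivalence_test(draws).parameters["diff"].proportion_in_rope
        cnt = (
            equivalence_test(draws, EquivalenceConfig(method="draws"))
            .parameters["diff"]
            .proportion_in_rope
        )
        assert cnt == pytest.approx(geo, abs=0.02)

    def test_degenerate_config_errors(self):
        with pytest.raises(ms.ValidationError):
            EquivalenceConfig(rope_low=0.1, rope_high=-0.1)
        with pytest.raises(ms.ValidationError):
            EquivalenceConfig(ci_level=1.5)
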