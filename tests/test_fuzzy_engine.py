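"""Membership functions, rule-base construction, inference and defuzzification."""

import math

import numpy as np
import pytest

from cogfuse.fuzzy_engine import (
    FISConfig,
    FuzzyVariable,
    auto_sigma,
    build_monotone_rulebase,
    defuzz_centroid,
    evaluate_fis,
    evaluate_fis_batch,
    gaussmf,
    output_load_variable,
    pimf,
)
from _oracle import brute_force_mamdani, oracle_centroid

FWHM = 2 * math.sqrt(2 * math.log(2))


class TestMembershipFunctions:
    def test_gaussian_closed_form(self):
        mf = gaussmf("m", 0.5, 0.2)
        assert mf.degree(0.5) == pytest.approx(1.0)
        # one sigma from the peak
        assert mf.degree(0.7) == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_pi_plateau_and_shoulders(self):
        mf = pimf("low", 0.0, 0.2, 0.4, 0.6)
        assert mf.degree(0.3) == pytest.approx(1.0)
        assert mf.degree(0.1) == pytest.approx(0.5)  # rising shoulder midpoint
        assert mf.degree(0.5) == pytest.approx(0.5)  # falling shoulder midpoint
        assert mf.degree(-0.5) == 0.0 and mf.degree(1.0) == 0.0

    def test_degrees_bounded(self):
        x = np.linspace(-2, 3, 400)
        for mf in (gaussmf("g", 0.5, 0.1), pimf("p", 0, 0.1, 0.2, 0.9)):
            d = mf.degree(x)
            assert np.all((d >= 0) & (d <= 1))

    def test_invalid_construction(self):
        with pytest.raises(ValueError):
            gaussmf("g", 0.5, 0.0)
        with pytest.raises(ValueError):
            pimf("p", 0.5, 0.4, 0.6, 0.7)


class TestAutoSigma:
    def test_uniform_centers(self):
        sig = auto_sigma([0.1, 0.5, 0.9])
        assert np.allclose(sig, 0.4 / FWHM)

    def test_temperature_bank_nearest_gap(self):
        # centers 15/19/22/25/28 degC: first gap 4, remaining gaps 3
        sig = auto_sigma([15, 19, 22, 25, 28])
        assert sig[0] == pytest.approx(4 / FWHM, abs=1e-4)
        assert np.allclose(sig[1:], 3 / FWHM, atol=1e-4)
        assert sig[0] == pytest.approx(1.699, abs=1e-3)

    def test_neighbours_cross_at_half(self):
        centers = [0.2, 0.8]
        sig = auto_sigma(centers)
        a, b = (gaussmf("a", c, s) for c, s in zip(centers, sig))
        mid = 0.5
        assert a.degree(mid) == pytest.approx(0.5, abs=1e-12)
        assert b.degree(mid) == pytest.approx(0.5, abs=1e-12)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            auto_sigma([0.5, 0.5, 0.9])


class TestRuleBase:
    def test_single_input_identity(self):
        rb = build_monotone_rulebase([3])
        assert [rb.table[(i,)] for i in range(3)] == [0, 1, 2]

    def test_low_high_rounds_to_medium(self):
        rb = build_monotone_rulebase([3, 3])
        assert rb.table[(0, 2)] == 1
        assert rb.table[(2, 2)] == 2
        assert rb.table[(0, 0)] == 0

    def test_tie_resolves_upward(self):
        # mean score 0.25 is equidistant from anchors 0 and 0.5
        rb = build_monotone_rulebase([3, 3])
        assert rb.table[(0, 1)] == 1

    def test_totality_and_monotonicity(self):
        rb = build_monotone_rulebase([5, 3, 2])
        assert len(rb.table) == 30
        for combo, out in rb.table.items():
            for i in range(3):
                for up in range(combo[i] + 1, rb.n_levels_per_input[i]):
                    bumped = combo[:i] + (up,) + combo[i + 1 :]
                    assert rb.table[bumped] >= out

    def test_load_score_reinterpretation(self):
        # U-shaped scores: both extremes of the input map to high output
        rb = build_monotone_rulebase([(1.0, 0.5, 0.0, 0.5, 1.0)])
        assert rb.table[(0,)] == 2 and rb.table[(4,)] == 2 and rb.table[(2,)] == 0


def _symmetric_config(n_inputs=2, grid_n=1001):
    mk = lambda name: FuzzyVariable(
        name, (0.0, 1.0),
        tuple(gaussmf(l, c, s) for l, c, s in
              zip(("low", "medium", "high"), [0.1, 0.5, 0.9], auto_sigma([0.1, 0.5, 0.9]))),
    )
    return FISConfig(
        "sym", tuple(mk(f"x{i}") for i in range(n_inputs)),
        output_load_variable(), build_monotone_rulebase([3] * n_inputs), grid_n=grid_n,
    )


class TestInference:
    def test_all_medium_centers_give_half(self):
        cfg = _symmetric_config(3)
        assert evaluate_fis(cfg, [0.5, 0.5, 0.5]) == pytest.approx(0.5, abs=1e-6)

    def test_low_corner_matches_brute_force(self):
        cfg = _symmetric_config(3)
        out = evaluate_fis(cfg, [0.1, 0.1, 0.1])
        assert 0.1 < out < 0.35
        assert out == pytest.approx(brute_force_mamdani(cfg, [0.1] * 3), abs=1e-3)

    def test_output_always_bounded(self):
        cfg = _symmetric_config(2)
        rng = np.random.default_rng(7)
        out = evaluate_fis_batch(cfg, rng.uniform(-1, 2, (500, 2)))
        assert np.all((out >= 0) & (out <= 1))

    def test_mirror_symmetry(self):
        # three 3-level inputs: rule means land on sixths, so the upward
        # tie-break never fires and the rule table is mirror-symmetric
        cfg = _symmetric_config(3)
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, (200, 3))
        f = evaluate_fis_batch(cfg, x)
        g = evaluate_fis_batch(cfg, 1.0 - x)
        assert np.allclose(f + g, 1.0, atol=1e-6)

    def test_monotone_in_inputs(self):
        # centroid defuzzification is monotone up to a small numerical wrinkle
        # where rule dominance switches; dips stay rare and below 5e-3
        cfg = _symmetric_config(3)
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, (1000, 3))
        y = np.clip(x + rng.uniform(0, 0.5, (1000, 3)), 0, 1)
        d = evaluate_fis_batch(cfg, y) - evaluate_fis_batch(cfg, x)
        assert d.min() >= -5e-3
        assert np.mean(d < -1e-6) < 0.01

    def test_grid_convergence(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, (50, 2))
        coarse = evaluate_fis_batch(_symmetric_config(2, grid_n=2001), x)
        fine = evaluate_fis_batch(_symmetric_config(2, grid_n=4001), x)
        assert np.max(np.abs(coarse - fine)) < 1e-4

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            evaluate_fis(_symmetric_config(2), [0.5])


class TestDefuzz:
    def test_symmetric_profile_centers(self):
        grid = np.linspace(0, 1, 1001)
        mu = np.exp(-0.5 * ((grid - 0.5) / 0.1) ** 2)
        assert defuzz_centroid(mu) == pytest.approx(0.5, abs=1e-9)

    def test_uniform_profile(self):
        assert defuzz_centroid(np.ones(101)) == pytest.approx(0.5)

    def test_truncated_gaussian_pulls_inward(self):
        grid = np.linspace(0, 1, 100001)
        mu = np.exp(-0.5 * ((grid - 0.9) / 0.17) ** 2)
        got = defuzz_centroid(np.exp(-0.5 * ((np.linspace(0, 1, 1001) - 0.9) / 0.17) ** 2))
        assert got < 0.9
        assert got == pytest.approx(oracle_centroid(mu), abs=1e-3)

    def test_empty_aggregate(self):
        with pytest.raises(ValueError, match="empty aggregate"):
            defuzz_centroid(np.zeros(101))


class TestSerialization:
    def test_yaml_round_trip(self, tmp_path):
        cfg = _symmetric_config(2)
        path = tmp_path / "fis.yaml"
        cfg.save(path)
        loaded = FISConfig.load(path)
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, (20, 2))
        assert np.allclose(evaluate_fis_batch(cfg, x), evaluate_fis_batch(loaded, x))


# --- property tests -------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6, unique=True))
def test_auto_sigma_half_width_at_half_maximum(centers):
    centers = sorted(centers)
    gaps = [b - a for a, b in zip(centers, centers[1:])]
    if min(gaps) < 1e-3:
        return  # near-duplicate centers are rejected elsewhere
    sig = auto_sigma(centers)
    for k, c in enumerate(centers):
        nearest = min(g for i, g in enumerate(gaps) if i in (k - 1, k))
        # degree drops to exactly one half at half the nearest-neighbour gap
        assert gaussmf("g", c, sig[k]).degree(c + nearest / 2) == pytest.approx(
            0.5, abs=1e-9
        )


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.integers(2, 5), min_size=1, max_size=3))
def test_rulebase_always_total_and_monotone(levels):
    rb = build_monotone_rulebase(levels)
    size = int(np.prod(levels))
    assert len(rb.table) == size
    for combo, out in rb.table.items():
        for i, n in enumerate(levels):
            for up in range(combo[i] + 1, n):
                assert rb.table[combo[:i] + (up,) + combo[i + 1 :]] >= out
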