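"""Feature extractors: oracle equivalence, analytic values, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from szeeg import (
    DegenerateInputError,
    ParameterError,
    dfa,
    hjorth_params,
    hurst_rs,
    katz_fd,
    kolmogorov_complexity,
    lyapunov_rosenstein,
    lz_complexity,
    make_fixture,
    rqa_measures,
    sample_entropy,
)
from szeeg.features import (
    feature_matrix,
    lz76_phrase_count,
    default_variants,
)
from szeeg.synthetic import SegmentMatrix


def _noise(n, seed=0, sigma=1.0):
    return sigma * np.random.default_rng(seed).standard_normal(n)


# ---------------------------------------------------------------------------
# oracle equivalence on short random sequences
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_sample_entropy_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(60, 200))
        x = rng.standard_normal(n)
        r = 0.2 * x.std()
        expected = oracles.sampen_bruteforce(x, m=2, r=r)
        got = sample_entropy(x, m=2, r_frac=0.2)
        if math.isinf(expected):
            assert math.isinf(got)
        else:
            assert abs(got - expected) < 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_recurrence_rate_matches_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(50, 150))
        x = rng.standard_normal(n)
        m, tau, theiler = 2, 2, 2
        eps = 0.5 * x.std()
        got = rqa_measures(x, m=m, tau=tau, eps=eps, theiler=theiler)["recurrence_rate"]
        expected = oracles.recurrence_rate_bruteforce(x, m, tau, eps, theiler)
        assert abs(got - expected) < 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_lz76_matches_bruteforce(self, seed):
        rng = np.random.default_rng(200 + seed)
        bits = rng.integers(0, 2, size=int(rng.integers(20, 200)))
        assert lz76_phrase_count(bits) == oracles.lz76_bruteforce(bits)

    def test_lz76_known_small_cases(self):
        assert lz76_phrase_count([0] * 100) == 1
        assert lz76_phrase_count([0, 1] * 50) == 2


# ---------------------------------------------------------------------------
# DFA and Hurst
# ---------------------------------------------------------------------------

class TestScalingExponents:
    def test_dfa_white_noise_near_half(self):
        vals = [dfa(_noise(4096, s)) for s in range(10)]
        assert 0.4 <= np.mean(vals) <= 0.6

    @pytest.mark.parametrize("hurst,lo,hi", [(0.3, 0.2, 0.4), (0.8, 0.7, 0.9)])
    def test_dfa_tracks_fgn_hurst(self, hurst, lo, hi):
        vals = [dfa(make_fixture("fgn", 4096, seed=s, hurst=hurst)) for s in range(5)]
        assert lo <= np.mean(vals) <= hi

    def test_dfa_constant_errors(self):
        with pytest.raises(DegenerateInputError):
            dfa(np.ones(1024))

    def test_dfa_rejects_oversized_scale(self):
        with pytest.raises(ParameterError):
            dfa(_noise(256), scales=[8, 128])

    def test_hurst_white_noise(self):
        vals = [hurst_rs(_noise(4096, 50 + s)) for s in range(10)]
        assert 0.4 <= np.mean(vals) <= 0.65

    def test_hurst_fgn_low(self):
        vals = [hurst_rs(make_fixture("fgn", 4096, seed=s, hurst=0.3)) for s in range(5)]
        assert 0.2 <= np.mean(vals) <= 0.45

    def test_hurst_ramp_near_one(self):
        assert hurst_rs(np.arange(2048, dtype=float)) > 0.9

    def test_hurst_constant_errors(self):
        with pytest.raises(DegenerateInputError):
            hurst_rs(np.zeros(512))


# ---------------------------------------------------------------------------
# RQA specifics
# ---------------------------------------------------------------------------

class TestRQA:
    def test_constant_signal_full_recurrence(self):
        out = rqa_measures(np.full(60, 2.5), m=1, tau=1, eps=0.1, theiler=0)
        assert out["recurrence_rate"] == 1.0

    def test_points_beyond_radius_never_recur(self):
        x = np.repeat([0.0, 10.0], 10)
        out = rqa_measures(x, m=1, tau=1, eps=0.5, theiler=9)
        assert out["recurrence_rate"] < 1.0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ParameterError):
            rqa_measures(_noise(100), m=2, tau=1, eps=0.0)

    def test_sine_is_highly_deterministic(self):
        x = make_fixture("sine", 400, omega=0.2)
        out = rqa_measures(x, m=2, tau=8)
        assert out["determinism"] > 0.9


# ---------------------------------------------------------------------------
# entropy / complexity / Hjorth analytic cases
# ---------------------------------------------------------------------------

class TestSampleEntropy:
    def test_constant_is_zero(self):
        assert sample_entropy(np.full(100, 4.2)) == 0.0

    def test_strict_alternation_is_zero(self):
        x = np.tile([0.0, 1.0], 50)
        assert sample_entropy(x, m=2, r_frac=0.1) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            sample_entropy(np.array([1.0, 2.0, 3.0]), m=2)

    @settings(max_examples=20, deadline=None)
    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
    )
    def test_affine_invariance(self, a, b):
        x = _noise(150, seed=3)
        assert sample_entropy(a * x + b) == pytest.approx(sample_entropy(x), abs=1e-10)


class TestKatz:
    @pytest.mark.parametrize("slope", [0.5, -2.0, 10.0])
    def test_ramp_dimension_is_one(self, slope):
        assert katz_fd(slope * np.arange(200)) == pytest.approx(1.0, abs=1e-9)

    def test_triangle_hand_value(self):
        # [0, 1, 0]: L = 2 sqrt(2), d = max(sqrt(1+1), sqrt(4+0)) = 2
        expected = math.log10(2 * math.sqrt(2)) / math.log10(2.0)
        assert katz_fd([0.0, 1.0, 0.0]) == pytest.approx(expected, abs=1e-12)
        assert katz_fd([0.0, 1.0, 0.0]) == pytest.approx(
            oracles.katz_bruteforce([0.0, 1.0, 0.0]), abs=1e-12
        )

    def test_noise_rougher_than_sine(self):
        sine = make_fixture("sine", 500, omega=0.1)
        vals = [katz_fd(_noise(500, s)) - katz_fd(sine) for s in range(10)]
        assert np.mean(vals) > 0

    def test_identical_points_error(self):
        with pytest.raises(DegenerateInputError):
            katz_fd(np.ones(10))


class TestLZAndKolmogorov:
    def test_constant_minimal(self):
        n = 100
        assert kolmogorov_complexity(np.zeros(n)) == pytest.approx(
            math.log2(n) / n, abs=1e-12
        )
        assert lz_complexity(np.zeros(n)) == pytest.approx(
            1.0 / (n / math.log2(n)), abs=1e-12
        )

    def test_periodic_is_compressible(self):
        x = np.tile([0.0, 1.0], 500)
        assert lz_complexity(x) < 0.1

    def test_random_near_one(self):
        x = _noise(1000, seed=4)
        assert 0.8 <= lz_complexity(x) <= 1.2
        assert abs(kolmogorov_complexity(x) - 1.0) < 0.15

    @settings(max_examples=20, deadline=None)
    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
    )
    def test_lzc_affine_invariance(self, a, b):
        x = _noise(200, seed=9)
        assert lz_complexity(a * x + b) == pytest.approx(lz_complexity(x), abs=1e-12)

    def test_complexity_ordering_constant_periodic_random(self):
        """constant <= periodic <= random for LZC, Kolmogorov K, and SampEn
        (10-seed average for the random case)."""
        n = 400
        const = np.zeros(n)
        periodic = np.tile([0.0, 1.0, 2.0, 1.0], n // 4)
        rand_lzc = np.mean([lz_complexity(_noise(n, s)) for s in range(10)])
        rand_k = np.mean([kolmogorov_complexity(_noise(n, s)) for s in range(10)])
        rand_se = np.mean([sample_entropy(_noise(n, s)) for s in range(10)])
        assert lz_complexity(const) <= lz_complexity(periodic) <= rand_lzc
        assert kolmogorov_complexity(const) <= kolmogorov_complexity(periodic) <= rand_k
        assert sample_entropy(const) <= sample_entropy(periodic) <= rand_se


class TestHjorth:
    def test_dense_sine_parameters(self):
        omega, amp = 0.05, 2.0
        out = hjorth_params(make_fixture("sine", 20000, omega=omega, amplitude=amp))
        assert out["activity"] == pytest.approx(amp**2 / 2, rel=0.01)
        assert out["mobility"] == pytest.approx(omega, rel=0.02)
        assert out["complexity"] == pytest.approx(1.0, abs=0.05)

    def test_constant_errors(self):
        with pytest.raises(DegenerateInputError):
            hjorth_params(np.full(100, 1.0))

    def test_noise_more_mobile_than_slow_sine(self):
        sine = hjorth_params(make_fixture("sine", 2000, omega=0.05))["mobility"]
        noise = np.mean([hjorth_params(_noise(2000, s))["mobility"] for s in range(5)])
        assert noise > sine


class TestLyapunov:
    def test_logistic_r4_near_ln2(self):
        orbit = make_fixture("logistic_map", 2000, r=4.0, x0=0.2, burn=0)
        lam = lyapunov_rosenstein(orbit, m=1, tau=1)
        assert abs(lam - math.log(2)) < 0.1
        # the orbit-derivative oracle agrees with the known value
        assert abs(oracles.logistic_lyapunov_oracle(orbit, 4.0) - math.log(2)) < 0.05

    def test_sine_is_nonchaotic(self):
        lam = lyapunov_rosenstein(make_fixture("sine", 3000, omega=0.3), m=5, tau=1)
        assert lam <= 0.05

    def test_period_two_orbit_contracts(self):
        orbit = make_fixture("logistic_map", 2000, r=3.2, x0=0.3, burn=0)
        assert lyapunov_rosenstein(orbit, m=1, tau=1) < 0
        assert oracles.logistic_lyapunov_oracle(orbit, 3.2) < 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            lyapunov_rosenstein(_noise(80), m=5, tau=5)


# ---------------------------------------------------------------------------
# feature-matrix assembly
# ---------------------------------------------------------------------------

def _segment_matrix(data_2d: np.ndarray) -> SegmentMatrix:
    length, nseg = data_2d.shape
    return SegmentMatrix(channel=0, segment_length=length, n_segments=nseg, values=data_2d)


class TestFeatureMatrix:
    def test_subwindow_shape_counting(self, rng):
        sm = _segment_matrix(rng.standard_normal((1000, 3)))
        fm = feature_matrix(sm, "hjorth", n_subwindows=10)
        assert fm.values.shape == (30, 10)
        assert fm.segment_index.tolist() == sum([[k] * 10 for k in range(3)], [])

    def test_dense_mode_row_per_sample(self, rng):
        sm = _segment_matrix(rng.standard_normal((200, 1)))
        fm = feature_matrix(sm, "hjorth", mode="dense", dense_window=50)
        assert fm.values.shape == (200, 10)

    def test_identical_segments_give_constant_columns(self):
        seg = np.sin(0.1 * np.arange(500)) + 0.01 * np.random.default_rng(0).standard_normal(500)
        sm = _segment_matrix(np.tile(seg[:, None], (1, 4)))
        fm = feature_matrix(sm, "lzc", n_subwindows=5)
        for col in fm.values.T:
            assert np.ptp(col.reshape(4, 5), axis=0).max() == 0.0

    def test_degenerate_cells_are_imputed_and_counted(self, rng):
        data = rng.standard_normal((400, 2))
        data[:200, 0] = 7.0  # first two sub-windows of segment 0 are constant
        fm = feature_matrix(_segment_matrix(data), "sampen", n_subwindows=4)
        assert np.isfinite(fm.values).all()
        assert fm.values[0, 0] == 0.0  # constant sub-window: SampEn 0 by convention
        fm2 = feature_matrix(_segment_matrix(data), "katz", n_subwindows=4)
        assert np.isfinite(fm2.values).all()
        assert fm2.n_imputed > 0  # katz flags constant sub-windows

    def test_variant_count_enforced(self, rng):
        sm = _segment_matrix(rng.standard_normal((100, 1)))
        with pytest.raises(ParameterError):
            feature_matrix(sm, "lzc", variant_params=[{}] * 3)

    @pytest.mark.parametrize("method", ["dfa", "hurst", "rqa", "sampen", "katz",
                                        "kolmogorov", "hjorth", "lzc", "lle"])
    def test_default_grids_have_ten_documented_variants(self, method):
        grid = default_variants(method)
        assert len(grid) == 10
        assert all(isinstance(v, dict) and v for v in grid)
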