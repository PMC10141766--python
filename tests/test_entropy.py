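"""Tsallis and dispersion entropy against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import micompen as mc
from micompen.entropy import DispersionConfig, _map_to_classes
from micompen.preprocess import DegenerateSignalError


# --- independent oracles ---------------------------------------------------

def sneddon_oracle(x):
    """Brute-force: enumerate sign changes/zeros of successive differences,
    split into bins at those indices, average within-bin variance ratios."""
    x = np.asarray(x, dtype=float)
    d = np.diff(x)
    crit = []
    last_nonzero = 0.0
    for i in range(len(d)):
        if i > 0 and (d[i] == 0 or (last_nonzero != 0 and np.sign(d[i]) != np.sign(last_nonzero))):
            crit.append(i)
        if d[i] != 0:
            last_nonzero = d[i]
    edges = sorted(set([0] + crit + [len(x)]))
    ratios = []
    for a, b in zip(edges[:-1], edges[1:]):
        seg = x[a:b]
        ratios.append(np.var(seg) / np.var(x))
    return 1.0 - sum(ratios) / len(ratios)


def dispen_oracle_classified(u, m, c, d=1):
    """Exhaustive pattern counting over a pre-classified integer series."""
    n_pat = len(u) - (m - 1) * d
    counts = {}
    for i in range(n_pat):
        pat = tuple(u[i + j * d] for j in range(m))
        counts[pat] = counts.get(pat, 0) + 1
    return -sum((k / n_pat) * math.log(k / n_pat) for k in counts.values())


# --- tsallis_q -------------------------------------------------------------

class TestTsallisQ:
    @pytest.mark.parametrize("p, q, expected", [
        ([0.25] * 4, 2.0, 0.75),                 # 1 - 4/16
        ([1.0, 0.0, 0.0], 2.0, 0.0),
        ([1.0, 0.0, 0.0], 0.5, 0.0),
        ([0.5, 0.25, 0.25], 2.0, 0.625),         # 1 - (0.25+0.0625+0.0625)
    ])
    def test_closed_forms(self, p, q, expected):
        assert mc.tsallis_q(p, q) == pytest.approx(expected, abs=1e-12)

    def test_q_one_is_shannon(self):
        p = [0.5, 0.3, 0.2]
        shannon = -sum(pi * math.log(pi) for pi in p)
        assert mc.tsallis_q(p, 1.0) == pytest.approx(shannon, abs=1e-12)

    @pytest.mark.parametrize("q", [1 - 1e-4, 1 + 1e-4])
    def test_continuity_at_q_one(self, q):
        p = [0.5, 0.3, 0.2]
        assert mc.tsallis_q(p, q) == pytest.approx(
            mc.tsallis_q(p, 1.0), abs=1e-4)

    def test_rejects_non_probability(self):
        with pytest.raises(ValueError):
            mc.tsallis_q([0.5, 0.6], 2.0)


# --- tsallis_sneddon -------------------------------------------------------

class TestSneddon:
    def test_piecewise_constant_bins_give_one(self):
        # all within-bin variances zero
        x = np.array([1.0, 1.0, 2.0, 2.0, 1.0, 1.0, 3.0, 3.0])
        assert mc.tsallis_sneddon(x) == pytest.approx(1.0, abs=1e-12)
        assert sneddon_oracle(x) == pytest.approx(1.0, abs=1e-12)

    def test_single_bin_equals_global_variance_gives_zero(self):
        # strictly monotone signal: no critical points, one bin = whole window
        x = np.array([0.0, 1.0, 3.0, 6.0, 10.0])
        with pytest.warns(RuntimeWarning, match="critical"):
            val = mc.tsallis_sneddon(x)
        assert val == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("x", [
        [0.0, 2.0, 1.0, 3.0, 0.0, 2.0],
        [5.0, 1.0, 4.0, 4.0, 2.0, 6.0, 3.0],
        [0.0, 1.0, 2.0, 1.0, 0.0, 1.0, 2.0, 1.0],
    ])
    def test_matches_bruteforce_oracle(self, x):
        assert mc.tsallis_sneddon(np.array(x)) == pytest.approx(
            sneddon_oracle(x), abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(DegenerateSignalError):
            mc.tsallis_sneddon(np.ones(10))

    def test_bounded_above_by_one(self):
        for s in range(10):
            x = np.random.default_rng(s).standard_normal(500)
            assert mc.tsallis_sneddon(x) <= 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(-5, 5), min_size=4, max_size=30))
    def test_oracle_agreement_property(self, vals):
        x = np.array(vals, dtype=float)
        if np.var(x) == 0:
            return
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert mc.tsallis_sneddon(x) == pytest.approx(
                sneddon_oracle(x), abs=1e-12)


# --- tsallis histogram mode ------------------------------------------------

def test_histogram_mode_unbounded_by_one():
    # near-uniform amplitudes over 16 bins: entropy approaches 15/16, and the
    # Eq-15 form on finer partitions can exceed the Sneddon bound of 1
    x = np.linspace(0.0, 1.0, 1024)
    val = mc.tsallis_histogram(x)
    assert val == pytest.approx(1.0 - 16 * (1 / 16) ** 2, abs=1e-3)


# --- dispersion entropy ----------------------------------------------------

class TestDispersion:
    def test_single_repeating_pattern_is_zero(self):
        u = np.tile([1, 1], 50).astype(float)
        cfg = DispersionConfig(mapping="identity")
        assert mc.dispersion_entropy(u, cfg) == 0.0

    def test_alternating_classified_series(self):
        # u = (1,2,1,2,1): patterns (1,2) x2 and (2,1) x2 -> entropy ln 2
        cfg = DispersionConfig(m=2, c=2, d=1, mapping="identity")
        u = np.array([1, 2, 1, 2, 1], dtype=float)
        assert mc.dispersion_entropy(u, cfg) == pytest.approx(
            math.log(2), abs=1e-12)

    def test_iid_uniform_approaches_upper_bound(self):
        x = np.random.default_rng(0).uniform(size=100_000)
        val = mc.dispersion_entropy(x, DispersionConfig(m=2, c=2))
        assert abs(val - math.log(4)) < 0.01

    def test_exhaustive_oracle_all_short_windows(self):
        # every classified window of length <= 12 over the (m=2, c=2) alphabet
        cfg = DispersionConfig(m=2, c=2, d=1, mapping="identity")
        for n in range(3, 13):
            for u in itertools.product((1, 2), repeat=n):
                got = mc.dispersion_entropy(np.array(u, dtype=float), cfg)
                want = dispen_oracle_classified(u, m=2, c=2)
                assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("m, c", [(2, 2), (2, 3), (3, 2)])
    def test_bounds(self, m, c):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.standard_normal(400)
            val = mc.dispersion_entropy(x, DispersionConfig(m=m, c=c))
            assert 0.0 <= val <= m * math.log(c) + 1e-12

    def test_affine_invariance_of_ncdf_mapping(self):
        x = np.random.default_rng(2).standard_normal(1000)
        cfg = DispersionConfig(m=2, c=3)
        base = mc.dispersion_entropy(x, cfg)
        assert mc.dispersion_entropy(2.5 * x + 40.0, cfg) == pytest.approx(
            base, abs=1e-12)

    def test_noise_above_sinusoid(self):
        n = 3000
        t = np.arange(n) / 250.0
        noise = np.random.default_rng(3).standard_normal(n)
        sine = np.sin(2 * np.pi * 10.0 * t)
        cfg = DispersionConfig()
        assert mc.dispersion_entropy(noise, cfg) > \
            mc.dispersion_entropy(sine, cfg)

    def test_constant_signal_is_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            assert mc.dispersion_entropy(np.ones(100)) == 0.0

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            mc.dispersion_entropy(np.array([1.0, 2.0]),
                                  DispersionConfig(m=3, c=2))

    def test_ncdf_mapping_covers_all_classes(self):
        x = np.random.default_rng(4).standard_normal(10_000)
        u = _map_to_classes(x, 4)
        assert set(np.unique(u)) == {1, 2, 3, 4}
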