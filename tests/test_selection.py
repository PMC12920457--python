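"""Correlation profiling, critical r, summaries, and scale selection."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from tanninspec import (
    CorrelationBandSelector,
    critical_r_threshold,
    pearson_profile,
    select_optimal_scale,
    summarize_profile,
)
from tanninspec.cwt import cwt_spectrum
from tanninspec.selection import CorrelationProfile


def test_perfect_correlation_selected(rng):
    y = rng.normal(size=30)
    F = np.c_[y, rng.normal(size=30)]
    prof = pearson_profile(F, y)
    assert prof.r[0] == pytest.approx(1.0)
    assert prof.selected[0]


def test_negation_antisymmetry(rng):
    y = rng.normal(size=25)
    F = rng.normal(size=(25, 6))
    a = pearson_profile(F, y)
    b = pearson_profile(-F, y)
    np.testing.assert_allclose(b.r, -a.r, atol=1e-14)
    np.testing.assert_allclose(b.p, a.p, atol=1e-14)
    np.testing.assert_array_equal(b.selected, a.selected)


def test_matches_direct_formula_on_hand_data():
    """r and p agree with an explicit evaluation of the defining formulas."""
    x = np.array([1.0, 2.0, 4.0, 4.5, 6.0, 7.0, 8.5, 9.0, 10.5, 12.0])
    y = np.array([2.1, 2.0, 3.9, 4.4, 5.2, 6.9, 7.4, 9.5, 9.9, 12.5])
    prof = pearson_profile(x[:, None], y)
    n = 10
    r_direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    t_direct = r_direct * np.sqrt((n - 2) / (1 - r_direct**2))
    p_direct = 2 * (1 - stats.t.cdf(abs(t_direct), n - 2))
    assert prof.r[0] == pytest.approx(r_direct, abs=1e-10)
    assert prof.p[0] == pytest.approx(p_direct, abs=1e-10)


class TestCriticalR:
    def test_known_values(self):
        # n=440 is the sample count consistent with a printed 0.123 gate
        assert critical_r_threshold(440, 0.01) == pytest.approx(0.1227, abs=5e-4)
        assert critical_r_threshold(171, 0.01) == pytest.approx(0.1965, abs=5e-4)

    def test_inversion_against_p_value(self):
        """The threshold is the |r| whose two-sided p equals alpha (independent
        root-finding oracle)."""
        for n, alpha in ((50, 0.01), (171, 0.05), (440, 0.01)):
            def p_of_r(r):
                t = r * np.sqrt((n - 2) / (1 - r**2))
                return 2 * stats.t.sf(t, n - 2) - alpha

            r_root = brentq(p_of_r, 1e-9, 1 - 1e-9)
            assert critical_r_threshold(n, alpha) == pytest.approx(r_root, abs=1e-10)

    def test_strictly_decreasing_in_n(self):
        vals = [critical_r_threshold(n, 0.01) for n in (10, 30, 100, 300, 1000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            critical_r_threshold(2)


def test_summary_mirror_identity(small_samples):
    """Negating the feature block mirrors extrema and preserves NFB/|r|."""
    from tanninspec import apply_transform

    samples, tannins = small_samples
    y = tannins.values_for(samples.sample_ids)
    t = apply_transform(samples, "lg'R")
    a = summarize_profile(pearson_profile(t.values, y))
    b = summarize_profile(pearson_profile(-t.values, y))
    assert a.nfb == b.nfb
    assert a.mean_abs_r == pytest.approx(b.mean_abs_r, abs=1e-14) or (a.mean_abs_r is None)
    if a.pos_extremum is not None:
        assert b.neg_extremum == pytest.approx(-a.pos_extremum)
    if a.neg_extremum is not None:
        assert b.pos_extremum == pytest.approx(-a.neg_extremum)


def test_empty_selection_summary(rng):
    y = rng.normal(size=20)
    F = rng.normal(size=(20, 5))
    prof = pearson_profile(F, y, critical_r=0.9999)
    prof.selected[:] = False
    s = summarize_profile(prof)
    assert s.nfb == 0
    assert s.pos_extremum is None and s.neg_extremum is None and s.mean_abs_r is None


def test_alpha_nesting(rng):
    y = rng.normal(size=40)
    F = y[:, None] * rng.uniform(0.1, 1, 30)[None, :] + rng.normal(0, 1.0, (40, 30))
    strict = pearson_profile(F, y, alpha=0.01)
    loose = pearson_profile(F, y, alpha=0.05)
    assert set(np.flatnonzero(strict.selected)) <= set(np.flatnonzero(loose.selected))


def test_affine_invariance_of_mask(rng):
    y = rng.normal(size=30)
    F = rng.normal(size=(30, 8))
    base = pearson_profile(F, y)
    scaled = pearson_profile(3.0 * F + 7.0, 0.5 * y - 2.0)
    np.testing.assert_array_equal(base.selected, scaled.selected)


def test_constant_feature_and_constant_y(rng):
    y = rng.normal(size=15)
    F = np.c_[np.ones(15), y]
    prof = pearson_profile(F, y)
    assert prof.r[0] == 0.0 and prof.p[0] == 1.0 and not prof.selected[0]
    with pytest.raises(ValueError, match="constant"):
        pearson_profile(F, np.ones(15))


def _profile_with(mean_abs_r, scale_n=4):
    r = np.full(scale_n, mean_abs_r)
    return CorrelationProfile(
        axis=np.arange(scale_n, dtype=float), r=r, p=np.zeros(scale_n),
        selected=np.ones(scale_n, dtype=bool), critical_r=0.1, alpha=0.01, n=50,
    )


class TestOptimalScale:
    def test_argmax(self):
        profiles = {2: _profile_with(0.2), 32: _profile_with(0.5), 1024: _profile_with(0.3)}
        best, table = select_optimal_scale(profiles)
        assert best == 32
        assert len(table) == 3

    def test_tie_breaks_to_smaller_scale(self):
        profiles = {4: _profile_with(0.4), 64: _profile_with(0.4)}
        best, _ = select_optimal_scale(profiles)
        assert best == 4

    def test_all_empty_rejected(self):
        p = _profile_with(0.4)
        p.selected[:] = False
        with pytest.raises(ValueError, match="no scale"):
            select_optimal_scale({2: p})

    def test_interior_scale_on_noisy_bump(self):
        """A mid-width tannin-coupled bump in white noise is best resolved at
        an interior scale (neither end of the dyadic range) in >=8/10 seeds."""
        scales = [2, 4, 8, 16, 32, 64, 128, 256]
        interior = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, p = 60, 600
            y = rng.uniform(5, 20, n)
            bump = np.exp(-0.5 * ((np.arange(p) - 300) / 10.0) ** 2)
            X = 0.01 * y[:, None] * bump[None, :] + rng.normal(0, 0.08, (n, p))
            co = cwt_spectrum(X, scales)
            profs = {a: pearson_profile(co[k], y) for k, a in enumerate(scales)}
            best, _ = select_optimal_scale(profs)
            interior += best not in (scales[0], scales[-1])
        assert interior >= 8


def test_selector_transforms_and_is_clonable(rng):
    from sklearn.base import clone

    y = rng.normal(size=50)
    F = np.c_[y + rng.normal(0, 0.1, 50), rng.normal(size=(50, 9))]
    sel = CorrelationBandSelector(alpha=0.01).fit(F, y)
    assert sel.support_[0]
    reduced = sel.transform(F)
    assert reduced.shape[1] == sel.support_.sum()
    clone(sel)


def test_fdr_gate_never_looser_than_raw_alpha(rng):
    """Benjamini-Hochberg passes only p-values <= alpha*i/m <= alpha, so the
    FDR-gated mask is a subset of the raw-alpha mask."""
    y = rng.normal(size=60)
    F = y[:, None] * rng.uniform(0, 0.6, 40)[None, :] + rng.normal(0, 1, (60, 40))
    plain = CorrelationBandSelector(alpha=0.05).fit(F, y)
    fdr = CorrelationBandSelector(alpha=0.05, fdr=True).fit(F, y)
    assert set(np.flatnonzero(fdr.support_)) <= set(np.flatnonzero(plain.support_))
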