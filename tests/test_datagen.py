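"""Synthetic spectra generator: structure, determinism, coupling, fixtures."""

import dataclasses

import numpy as np
import pytest

from tanninspec import (
    GeneratorConfig,
    critical_r_threshold,
    generate_dataset,
    inject_outliers,
    pearson_profile,
    tannin_from_assay,
)
from tanninspec.io import average_replicates


def test_campaign_design_counts():
    """180 samples scanned in triplicate give 540 spectra rows."""
    scans, tannins = generate_dataset(GeneratorConfig(seed=0))
    assert scans.n_scans == 540
    assert len(np.unique(scans.sample_ids)) == 180
    assert len(tannins.table) == 180
    assert scans.n_bands == 1557


def test_determinism_and_seed_sensitivity(small_config):
    a1, t1 = generate_dataset(small_config)
    a2, t2 = generate_dataset(small_config)
    assert np.array_equal(a1.reflectance, a2.reflectance)
    assert t1.table.equals(t2.table)
    b, tb = generate_dataset(dataclasses.replace(small_config, seed=small_config.seed + 1))
    assert not np.array_equal(a1.reflectance, b.reflectance)


def test_zero_noise_replicates_identical():
    cfg = GeneratorConfig(n_samples=10, n_bands=80, scan_noise_sd=0.0, seed=3)
    scans, _ = generate_dataset(cfg)
    for sid in np.unique(scans.sample_ids):
        rows = scans.reflectance[scans.sample_ids == sid]
        assert np.array_equal(rows[0], rows[1]) and np.array_equal(rows[0], rows[2])


def test_tannin_within_clip_and_positive():
    for seed in range(5):
        _, tannins = generate_dataset(GeneratorConfig(n_samples=40, n_bands=60, seed=seed))
        v = tannins.table.to_numpy()
        assert np.all(v >= 4.73) and np.all(v <= 20.17)


def test_monotone_coupling_noise_free():
    """Tannin-coupled absorption depth grows linearly with tannin."""
    cfg = GeneratorConfig(
        n_samples=30, n_bands=400, scan_noise_sd=0.0,
        sample_intercept_sd=0.0, sample_slope_sd=0.0,
        uncoupled_depth_jitter_sd=0.0, seed=5,
    )
    scans, tannins = generate_dataset(cfg)
    samples = average_replicates(scans)
    y = tannins.values_for(samples.sample_ids)
    # depth at the 7050 cm^-1 coupled band relative to a flat reference point
    band = int(np.argmin(np.abs(samples.wavenumbers - 7050)))
    ref = int(np.argmin(np.abs(samples.wavenumbers - 6300)))
    depth = samples.reflectance[:, ref] - samples.reflectance[:, band]
    # strip the mode baseline offset by regressing within modes: global corr
    # is already ~1 because offsets are small relative to depth range
    r = np.corrcoef(depth, y)[0, 1]
    assert r > 0.99
    slope = np.polyfit(y, depth, 1)[0]
    assert slope > 0


def test_management_modes_ordered_and_near_parallel():
    cfg = GeneratorConfig(
        n_samples=30, n_bands=200, scan_noise_sd=0.0,
        sample_intercept_sd=0.0, sample_slope_sd=0.0,
        uncoupled_depth_jitter_sd=0.0, coupling_strength=0.0, seed=2,
    )
    scans, _ = generate_dataset(cfg)
    curves = {}
    for mode in np.unique(scans.management_mode):
        curves[mode] = scans.reflectance[scans.management_mode == mode].mean(axis=0)
    means = {m: c.mean() for m, c in curves.items()}
    assert means["low-yield"] < means["medium-yield"] < means["high-yield"]
    labels = list(curves)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            diff = curves[a] - curves[b]
            assert np.std(diff) < 1e-8  # parallel up to the constant offset


def test_null_coupling_gives_null_correlations():
    """With coupling off, per-band |r| stays below the p<0.01 critical value
    for at least 95% of bands."""
    from tanninspec import ManagementMode

    # a single stratum isolates the coupling mechanism from mode offsets
    cfg = GeneratorConfig(n_samples=500, n_bands=300, replicates_per_sample=1,
                          coupling_strength=0.0, seed=11,
                          management_modes=(ManagementMode("single", 13.2, 3.0, 0.0),))
    scans, tannins = generate_dataset(cfg)
    samples = average_replicates(scans)
    y = tannins.values_for(samples.sample_ids)
    prof = pearson_profile(samples.reflectance, y, alpha=0.01)
    crit = critical_r_threshold(500, 0.01)
    frac_below = np.mean(np.abs(prof.r) < crit)
    assert frac_below >= 0.95


class TestInjectOutliers:
    def test_exactly_listed_samples_differ(self, small_dataset):
        scans, tannins = small_dataset
        ids = [1, 3, 5, 7, 9, 11, 13, 15, 17]  # nine samples, as in a screening
        s2, t2 = inject_outliers(scans, tannins, ids, y_shift=5.0, spectral_shift=0.05)
        changed_spec = {
            int(sid)
            for sid in np.unique(scans.sample_ids)
            if not np.array_equal(
                scans.reflectance[scans.sample_ids == sid],
                s2.reflectance[s2.sample_ids == sid],
            )
        }
        changed_y = set(tannins.table.index[tannins.table != t2.table])
        assert changed_spec == set(ids)
        assert changed_y == set(ids)

    def test_zero_shift_is_identity(self, small_dataset):
        scans, tannins = small_dataset
        s2, t2 = inject_outliers(scans, tannins, [2, 4], y_shift=0.0, spectral_shift=0.0)
        assert np.array_equal(scans.reflectance, s2.reflectance)
        assert tannins.table.equals(t2.table)

    def test_unknown_id_raises(self, small_dataset):
        scans, tannins = small_dataset
        with pytest.raises(KeyError):
            inject_outliers(scans, tannins, [9999], y_shift=1.0)


class TestAssayFormula:
    @pytest.mark.parametrize(
        "C,V1,N,M,expected",
        [(0.0, 100.0, 25.0, 1.0, 0.0), (1.0, 100.0, 25.0, 1.0, 2.5), (2.0, 50.0, 10.0, 4.0, 0.25)],
    )
    def test_values(self, C, V1, N, M, expected):
        assert tannin_from_assay(C, V1, N, M) == pytest.approx(expected)

    def test_mass_homogeneity(self):
        assert tannin_from_assay(3.0, 80.0, 5.0, 2.0) == pytest.approx(
            tannin_from_assay(3.0, 80.0, 5.0, 1.0) / 2.0
        )

    def test_nonpositive_mass_raises(self):
        with pytest.raises(ValueError):
            tannin_from_assay(1.0, 1.0, 1.0, 0.0)


@pytest.mark.parametrize(
    "kwargs",
    [dict(n_samples=0), dict(n_bands=1), dict(wavenumber_min=9000, wavenumber_max=4000),
     dict(tannin_clip=(5.0, 4.0)), dict(coupling_strength=-0.1)],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        generate_dataset(GeneratorConfig(**kwargs))
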