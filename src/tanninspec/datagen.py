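"""Synthetic NIR reflectance generator for tannin calibration studies.

The generator emulates diffuse-reflectance spectra of ground walnut kernel
powder over 4000-10000 cm^-1: a smooth baseline that rises with wavenumber,
near-parallel offsets between orchard-management modes, Gaussian absorption
features in the O-H combination (4000-5000 cm^-1) and first-overtone
(~7000 cm^-1) regions whose depths scale linearly with tannin content, plus
per-sample baseline variability (packing/scatter) and i.i.d. scan noise.
Three replicate scans per sample mimic the measurement protocol; injected
outliers provide fixtures for the Monte-Carlo screening stage.

The model is deliberately phenomenological: no radiative-transfer or
Beer-Lambert physics, just the statistical structure the downstream analysis
assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import SampleSpectrumSet, SpectrumSet, TanninTable

__all__ = [
    "ManagementMode",
    "AbsorptionBand",
    "GeneratorConfig",
    "generate_dataset",
    "inject_outliers",
    "tannin_from_assay",
]


@dataclass(frozen=True)
class ManagementMode:
    """One orchard-management stratum: tannin distribution + spectral offset."""

    label: str
    tannin_mean: float  # mg/g
    tannin_sd: float  # mg/g
    baseline_offset: float  # reflectance units, added to the whole curve


@dataclass(frozen=True)
class AbsorptionBand:
    """Gaussian absorption feature.

    ``tannin_coupled`` bands have depth = coupling_strength * tannin (mg/g);
    uncoupled bands have a fixed ``base_depth`` with mild per-sample jitter.
    """

    center: float  # cm^-1
    width: float  # cm^-1 (Gaussian sigma)
    tannin_coupled: bool
    base_depth: float = 0.0  # reflectance units, uncoupled bands only


# Defaults: high-tannin orchards reflect slightly more (near-parallel curves),
# pooled tannin mean (10.5+13.2+15.8)/3 = 13.17 mg/g.
_DEFAULT_MODES = (
    ManagementMode("low-yield", 10.5, 2.4, -0.012),
    ManagementMode("medium-yield", 13.2, 2.4, 0.0),
    ManagementMode("high-yield", 15.8, 2.4, 0.012),
)

# O-H combination bands (4000-5000) and first overtone (~7000) carry the
# tannin signal; the 5600 / 8600 bands are tannin-blind matrix features.
_DEFAULT_BANDS = (
    AbsorptionBand(4400.0, 160.0, True),
    AbsorptionBand(4850.0, 130.0, True),
    AbsorptionBand(7050.0, 210.0, True),
    AbsorptionBand(5600.0, 180.0, False, 0.025),
    AbsorptionBand(8600.0, 250.0, False, 0.020),
)


@dataclass
class GeneratorConfig:
    """Conditions of the simulated acquisition campaign.

    Defaults mirror the study design the pipeline is built for: 180 samples
    from three management modes, 3 replicate scans each, 1557 bands over
    4000-10000 cm^-1, tannin clipped to the observed 4.73-20.17 mg/g range.
    """

    n_samples: int = 180
    replicates_per_sample: int = 3
    wavenumber_min: float = 4000.0
    wavenumber_max: float = 10000.0
    n_bands: int = 1557
    management_modes: tuple = _DEFAULT_MODES
    tannin_clip: tuple = (4.73, 20.17)
    coupling_strength: float = 0.004  # reflectance depth per mg/g tannin
    absorption_bands: tuple = _DEFAULT_BANDS
    scan_noise_sd: float = 0.004  # reflectance units per scan
    noise_ar1_phi: float = 0.0  # 0 => white noise; >0 => AR(1) along bands
    baseline_coeffs: tuple = (0.35, 0.40, -0.10)  # c0 + c1*u + c2*u^2
    sample_intercept_sd: float = 0.015  # packing-density scatter
    sample_slope_sd: float = 0.008
    uncoupled_depth_jitter_sd: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_bands < 2:
            raise ValueError("n_samples must be positive and n_bands >= 2")
        if self.replicates_per_sample <= 0:
            raise ValueError("replicates_per_sample must be positive")
        if not self.wavenumber_min < self.wavenumber_max:
            raise ValueError("wavenumber_min must be < wavenumber_max")
        low, high = self.tannin_clip
        if not low < high:
            raise ValueError("tannin_clip low must be < high")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")
        if not self.management_modes:
            raise ValueError("at least one management mode is required")

    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.wavenumber_min, self.wavenumber_max, self.n_bands)

    def coupled_windows(self, half_widths: float = 2.5) -> list:
        """Wavenumber intervals carrying tannin signal (center +/- k*sigma)."""
        return [
            (b.center - half_widths * b.width, b.center + half_widths * b.width)
            for b in self.absorption_bands
            if b.tannin_coupled
        ]


def generate_dataset(config: GeneratorConfig) -> tuple:
    """Draw a (SpectrumSet, TanninTable) pair under ``config``.

    Deterministic for a fixed config (including seed).  Samples are assigned
    to management modes round-robin; each sample gets a smooth spectrum
    (baseline + mode offset + per-sample intercept/slope scatter - Gaussian
    absorptions) measured ``replicates_per_sample`` times with additive scan
    noise, clipped into (0, 1].
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w = config.wavenumbers()
    u = (w - config.wavenumber_min) / (config.wavenumber_max - config.wavenumber_min)
    c0, c1, c2 = config.baseline_coeffs
    baseline = c0 + c1 * u + c2 * u**2

    modes = config.management_modes
    mode_of = [modes[i % len(modes)] for i in range(config.n_samples)]
    sample_ids = np.arange(1, config.n_samples + 1)

    low, high = config.tannin_clip
    tannin = np.array(
        [np.clip(rng.normal(m.tannin_mean, m.tannin_sd), low, high) for m in mode_of]
    )

    intercepts = rng.normal(0.0, config.sample_intercept_sd, config.n_samples)
    slopes = rng.normal(0.0, config.sample_slope_sd, config.n_samples)

    # Gaussian absorption profiles, one per configured band.
    profiles = np.stack(
        [np.exp(-0.5 * ((w - b.center) / b.width) ** 2) for b in config.absorption_bands]
    )

    clean = np.empty((config.n_samples, config.n_bands))
    for i in range(config.n_samples):
        depths = []
        for b in config.absorption_bands:
            if b.tannin_coupled:
                depths.append(config.coupling_strength * tannin[i])
            else:
                depths.append(b.base_depth + rng.normal(0.0, config.uncoupled_depth_jitter_sd))
        absorption = np.asarray(depths) @ profiles
        clean[i] = baseline + mode_of[i].baseline_offset + intercepts[i] + slopes[i] * u - absorption

    n_rep = config.replicates_per_sample
    n_scans = config.n_samples * n_rep
    reflectance = np.repeat(clean, n_rep, axis=0)
    if config.scan_noise_sd > 0:
        noise = rng.normal(0.0, config.scan_noise_sd, (n_scans, config.n_bands))
        if config.noise_ar1_phi > 0:
            phi = config.noise_ar1_phi
            for j in range(1, config.n_bands):
                noise[:, j] = phi * noise[:, j - 1] + np.sqrt(1 - phi**2) * noise[:, j]
        reflectance = reflectance + noise
    reflectance = np.clip(reflectance, 1e-6, 1.0)

    sset = SpectrumSet(
        wavenumbers=w,
        reflectance=reflectance,
        sample_ids=np.repeat(sample_ids, n_rep),
        replicate_index=np.tile(np.arange(n_rep), config.n_samples),
        management_mode=np.repeat(np.array([m.label for m in mode_of], dtype=object), n_rep),
    )
    tt = TanninTable(dict(zip(sample_ids.tolist(), tannin.tolist())))
    return sset, tt


def inject_outliers(
    spectra: SpectrumSet,
    tannins: TanninTable,
    sample_ids,
    y_shift: float = 0.0,
    spectral_shift: float = 0.0,
) -> tuple:
    """Perturb the listed samples; every other row is returned bit-identical.

    ``y_shift`` adds to the reference tannin (mg/g); ``spectral_shift`` adds a
    constant reflectance offset to the sample's scans.  Fixture for the
    Monte-Carlo outlier screen.
    """
    ids = list(sample_ids)
    known = set(spectra.unique_sample_ids().tolist())
    unknown = [s for s in ids if s not in known]
    if unknown:
        raise KeyError(f"unknown sample ids: {unknown}")
    out_spec = spectra.copy()
    mask = np.isin(out_spec.sample_ids, np.asarray(ids))
    if spectral_shift != 0.0:
        out_spec.reflectance[mask] += spectral_shift
    out_t = tannins.copy()
    if y_shift != 0.0:
        out_t.table.loc[ids] = out_t.table.loc[ids] + y_shift
    return out_spec, out_t


def tannin_from_assay(C: float, V1: float, N: float, M: float) -> float:
    """Colorimetric assay bookkeeping: tannin mg/g from a gallic-acid curve.

    ``C``: gallic acid from the standard curve (mg); ``V1``: determination
    volume (mL); ``N``: dilution factor; ``M``: sample mass (g); 1000 is the
    unit-conversion coefficient.
    """
    if M <= 0:
        raise ValueError("sample mass M must be positive")
    if min(C, V1, N) < 0:
        raise ValueError("C, V1 and N must be non-negative")
    return C * V1 * N / (M * 1000.0)
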