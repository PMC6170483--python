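"""Synthetic oil-blend spectra with known ground truth.

The generator emulates a four-component edible-oil mixing design measured
on three portable instrument profiles (a 125-channel NIR filter
spectrometer, a 3108-channel FT-NIR and a 3122-channel Raman unit).  Each
pure component is a sum of Gaussian bands at literature positions for oil
C-H / C=C / C=O vibrations, with per-component amplitudes so that the
component fractions are spectrally identifiable.  A blend spectrum is the
fraction-weighted sum of the pure spectra plus a fixed smooth baseline
(shared by all samples, emulating scatter/fluorescence offsets) and seeded
Gaussian channel noise; the iodine value is the fraction-weighted sum of
the component iodine values plus seeded response noise.  With all noise at
zero the data are exactly bilinear, so a full-rank PLS model reproduces the
response to numerical precision.

The module also provides ``planted_dataset``, a sparse-signal fixture in
which exactly ``n_informative`` channels carry independent latent signals
that the response depends on linearly, every other channel being pure
noise.  The accompanying :class:`TruthMask` makes the recall and precision
of every wavelength selector directly computable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SpectralDataset

__all__ = [
    "ComponentModel",
    "SimulationConfig",
    "TruthMask",
    "INSTRUMENT_PROFILES",
    "default_components",
    "sample_fractions",
    "generate_dataset",
    "plant_uninformative_region",
    "planted_dataset",
]

# channel count and axis range per instrument profile
INSTRUMENT_PROFILES: dict[str, tuple[int, float, float, str]] = {
    "micronir": (125, 900.0, 1700.0, "nm"),
    "mems": (3108, 1100.0, 2100.0, "nm"),
    "raman": (3122, 175.0, 3200.0, "cm-1"),
}

# Mixing-design bounds for (soybean, olive, peanut, blend) fractions.
DEFAULT_FRACTION_RANGES: tuple[tuple[float, float], ...] = (
    (0.0, 0.8546),
    (0.0, 0.6934),
    (0.0, 0.8835),
    (0.0, 0.8546),
)

# NIR band positions (nm): C-H second overtones (1168, 1210), C-H
# combination bands (1392, 1414) and first overtones (1726, 1761).
_NIR_BANDS = (1168.0, 1210.0, 1392.0, 1414.0, 1726.0, 1761.0)
# Raman band positions (cm^-1) of the common oil bands: C=O and C=C
# stretches, CH2 scissor/twist, =C-H rocks/bends, C-C stretches.
_RAMAN_BANDS = (1745.0, 1655.0, 1438.0, 1301.0, 1266.0, 1125.0, 1080.0, 1068.0, 970.0, 868.0)

# Per-component band amplitude patterns (one multiplier per band), chosen so
# the 4 x p pure-spectrum matrix has full rank.
_AMPLITUDES = {
    "soybean": (1.00, 0.55, 0.90, 0.45, 0.80, 0.60, 0.70, 0.50, 0.95, 0.40),
    "olive": (0.50, 1.00, 0.40, 0.85, 0.55, 0.90, 0.35, 0.75, 0.45, 0.80),
    "peanut": (0.80, 0.45, 1.00, 0.60, 0.95, 0.40, 0.85, 0.55, 0.50, 0.90),
    "blend": (0.65, 0.80, 0.55, 1.00, 0.45, 0.70, 0.60, 0.90, 0.75, 0.50),
}

# Iodine values (g I2 / 100 g) assigned to the pure components so that
# blends under the default mixing ranges realize responses spanning about
# 86-126.
DEFAULT_IODINE_VALUES = {"soybean": 130.0, "olive": 84.0, "peanut": 96.0, "blend": 108.0}


@dataclass
class ComponentModel:
    """A pure oil component: its iodine value and Gaussian band list."""

    name: str
    iodine_value: float
    bands: list[tuple[float, float, float]]  # (center, width, amplitude)

    def spectrum(self, axis: np.ndarray) -> np.ndarray:
        s = np.zeros_like(axis, dtype=float)
        for center, width, amp in self.bands:
            if width <= 0 or amp <= 0:
                raise ValueError("band widths and amplitudes must be positive")
            s += amp * np.exp(-0.5 * ((axis - center) / width) ** 2)
        return s


@dataclass
class SimulationConfig:
    n_samples: int = 59
    instrument_profile: str = "micronir"
    components: list[ComponentModel] | None = None
    fraction_ranges: tuple[tuple[float, float], ...] = DEFAULT_FRACTION_RANGES
    noise_sd_spectral: float = 0.002
    noise_sd_response: float = 0.5
    baseline_amplitude: float = 0.05
    informative_floor: float = 0.05  # fraction of the peak pure intensity
    seed: int = 0


@dataclass
class TruthMask:
    informative_channels: np.ndarray

    def __post_init__(self) -> None:
        self.informative_channels = np.unique(
            np.asarray(self.informative_channels, dtype=int)
        )
        if self.informative_channels.size == 0:
            raise ValueError("truth mask must contain at least one channel")

    def recall(self, selected: np.ndarray) -> float:
        hit = np.intersect1d(self.informative_channels, np.asarray(selected, dtype=int))
        return hit.size / self.informative_channels.size

    def precision(self, selected: np.ndarray) -> float:
        selected = np.unique(np.asarray(selected, dtype=int))
        hit = np.intersect1d(self.informative_channels, selected)
        return hit.size / selected.size if selected.size else 0.0


def _axis(profile: str) -> np.ndarray:
    try:
        p, lo, hi, _unit = INSTRUMENT_PROFILES[profile]
    except KeyError:
        raise ValueError(f"unknown instrument profile {profile!r}") from None
    return np.linspace(lo, hi, p)


def default_components(profile: str) -> list[ComponentModel]:
    """Four-component oil set with bands inside the profile's axis."""
    p, lo, hi, unit = INSTRUMENT_PROFILES[profile]
    centers = _RAMAN_BANDS if unit == "cm-1" else _NIR_BANDS
    width = 18.0 if unit == "cm-1" else 22.0
    comps = []
    for name, amps in _AMPLITUDES.items():
        bands = [
            (c, width, a)
            for c, a in zip(centers, amps)
            if lo <= c <= hi
        ]
        comps.append(ComponentModel(name, DEFAULT_IODINE_VALUES[name], bands))
    return comps


def sample_fractions(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Component fractions on the simplex within the per-component ranges.

    Rejection sampling of flat Dirichlet draws; raises if the ranges are
    infeasible or the rejection budget is exhausted.
    """
    ranges = np.asarray(config.fraction_ranges, dtype=float)
    if np.any(ranges[:, 0] > ranges[:, 1]) or np.any(ranges < 0) or np.any(ranges > 1):
        raise ValueError("fraction ranges must be nested in [0, 1]")
    if ranges[:, 1].sum() < 1.0 or ranges[:, 0].sum() > 1.0:
        raise ValueError("fraction ranges admit no simplex point")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = ranges.shape[0]
    out = np.empty((config.n_samples, k))
    got = 0
    budget = 2000 * config.n_samples
    while got < config.n_samples and budget > 0:
        draw = rng.dirichlet(np.ones(k), size=min(4 * (config.n_samples - got), 1024))
        ok = np.all((draw >= ranges[:, 0]) & (draw <= ranges[:, 1]), axis=1)
        take = draw[ok][: config.n_samples - got]
        out[got : got + take.shape[0]] = take
        got += take.shape[0]
        budget -= draw.shape[0]
    if got < config.n_samples:
        raise ValueError("rejection budget exhausted; fraction ranges too tight")
    return out


def _baseline(axis: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Fixed low-order polynomial offset shared by every sample."""
    t = (axis - axis.min()) / (axis.max() - axis.min())
    coefs = rng.normal(0.0, amplitude, size=3)
    return coefs[0] + coefs[1] * t + coefs[2] * t ** 2


def generate_dataset(config: SimulationConfig):
    """Generate an oil-blend dataset.

    Returns ``(SpectralDataset, TruthMask, fractions)``.  The truth mask
    holds every channel where some pure component's band intensity exceeds
    ``informative_floor`` times the overall peak pure intensity.
    """
    axis = _axis(config.instrument_profile)
    comps = config.components or default_components(config.instrument_profile)
    ranges = np.asarray(config.fraction_ranges, dtype=float)
    if len(comps) != ranges.shape[0]:
        raise ValueError("one fraction range per component required")
    ss = np.random.SeedSequence(config.seed)
    rng_frac, rng_base, rng_noise, rng_resp = (np.random.default_rng(c) for c in ss.spawn(4))

    F = sample_fractions(config, rng_frac)
    S = np.vstack([c.spectrum(axis) for c in comps])  # n_components x p
    baseline = _baseline(axis, config.baseline_amplitude, rng_base)
    X = F @ S + baseline
    if config.noise_sd_spectral > 0:
        X = X + rng_noise.normal(0.0, config.noise_sd_spectral, size=X.shape)
    iv = np.array([c.iodine_value for c in comps])
    y = F @ iv
    if config.noise_sd_response > 0:
        y = y + rng_resp.normal(0.0, config.noise_sd_response, size=y.shape)

    floor = config.informative_floor * S.max()
    informative = np.flatnonzero(S.max(axis=0) >= floor)
    ds = SpectralDataset(
        X, axis, y,
        instrument_label=config.instrument_profile,
    )
    return ds, TruthMask(informative), F


def plant_uninformative_region(
    ds: SpectralDataset,
    truth: TruthMask,
    region: tuple[float, float],
    noise_sd: float,
    seed: int = 0,
):
    """Replace an axis interval with pure seeded noise.

    Returns a new ``(SpectralDataset, TruthMask)`` pair with the region's
    channels overwritten by Gaussian noise and removed from the informative
    set.  Refuses to wipe out every informative channel.
    """
    lo, hi = min(region), max(region)
    in_region = np.flatnonzero((ds.axis >= lo) & (ds.axis <= hi))
    if in_region.size == 0:
        raise ValueError("region contains no channels")
    remaining = np.setdiff1d(truth.informative_channels, in_region)
    if remaining.size == 0:
        raise ValueError("region would cover every informative channel")
    rng = np.random.default_rng(seed)
    X = ds.X.copy()
    X[:, in_region] = rng.normal(0.0, noise_sd, size=(ds.n_samples, in_region.size))
    new_ds = SpectralDataset(
        X, ds.axis.copy(), ds.y.copy(),
        instrument_label=ds.instrument_label,
        sample_ids=list(ds.sample_ids),
    )
    return new_ds, TruthMask(remaining)


def planted_dataset(
    n_samples: int = 59,
    n_channels: int = 125,
    n_informative: int = 5,
    signal_noise_sd: float = 0.02,
    noise_channel_sd: float = 0.1,
    response_noise_sd: float = 0.3,
    seed: int = 0,
):
    """Sparse-signal fixture: exactly ``n_informative`` channels carry signal.

    Latent factors C ~ U(0, 1) drive one informative channel each; the
    response is an affine combination of the factors scaled to the iodine
    range of the oil blends (about 86-126 g I2/100 g).  Every other channel
    fluctuates around a constant baseline level with standard deviation
    ``noise_channel_sd`` — smaller than the chemical-band variation (a
    U(0, 1) factor has SD 0.29), as in real spectra where uninformative
    regions carry only detector/baseline noise.  Returns
    ``(SpectralDataset, TruthMask)``.
    """
    if n_informative < 1 or n_informative >= n_channels:
        raise ValueError("need 1 <= n_informative < n_channels")
    ss = np.random.SeedSequence(seed)
    rng_pos, rng_lat, rng_noise, rng_resp = (np.random.default_rng(c) for c in ss.spawn(4))
    informative = np.sort(rng_pos.choice(n_channels, size=n_informative, replace=False))
    C = rng_lat.uniform(0.0, 1.0, size=(n_samples, n_informative))
    X = 0.5 + rng_noise.normal(0.0, noise_channel_sd, size=(n_samples, n_channels))
    X[:, informative] = C + rng_noise.normal(0.0, signal_noise_sd, size=C.shape)
    weights = rng_resp.uniform(0.5, 1.5, size=n_informative)
    coefs = 40.0 * weights / weights.sum()
    y = 86.0 + C @ coefs
    if response_noise_sd > 0:
        y = y + rng_resp.normal(0.0, response_noise_sd, size=n_samples)
    ds = SpectralDataset(
        X, np.arange(n_channels, dtype=float), y, instrument_label="planted"
    )
    return ds, TruthMask(informative)
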