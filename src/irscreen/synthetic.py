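"""Synthetic plasma-like ATR-FTIR spectra with known ground truth.

Real cohort spectra for case/control screening studies are rarely deposited,
so every downstream stage (preprocessing, splitting, feature selection,
classification, figures of merit) is exercised against generated data whose
class structure is known exactly.

Each sample spectrum is a sum of Gaussian absorption bands at biologically
plausible wavenumbers (phosphodiesters, polysaccharides, Amide III/I,
lipid C=O, ...), with the Amide I band near 1650 cm^-1 dominant, plus a
smooth polynomial baseline with a per-sample random scale.  Samples of the
positive class receive an additive intensity shift at a planted subset of
marker bands.  Replicate measurements add iid Gaussian noise to the
noiseless per-sample template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .spectra import SpectralDataset


@dataclass
class BandSpec:
    """One Gaussian absorption band.

    ``class_effect`` is a signed absorbance shift added to the band amplitude
    for positive-class samples (an intensity difference, not a peak shift,
    so marker recovery by wavenumber is unambiguous).
    """

    centre: float  # cm^-1
    width: float  # Gaussian sd, cm^-1
    base_amplitude: float  # absorbance units
    class_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be non-negative")


# Band positions follow the plasma biofingerprint assignments commonly used
# for case/control discrimination; amplitudes are set so Amide I (1643/1661
# region) dominates, as in measured plasma absorbance spectra.
def default_bands() -> list[BandSpec]:
    amplitudes = {
        901: (10.0, 0.20),
        959: (8.0, 0.15),
        980: (8.0, 0.15),
        999: (6.0, 0.20),
        1018: (10.0, 0.22),
        1277: (6.0, 0.20),
        1311: (12.0, 0.28),
        1364: (10.0, 0.22),
        1402: (6.0, 0.20),
        1464: (10.0, 0.32),
        1489: (10.0, 0.25),
        1582: (6.0, 0.20),
        1626: (14.0, 0.50),
        1643: (16.0, 1.00),  # Amide I: dominant by construction
        1661: (14.0, 0.60),
        1742: (10.0, 0.15),
    }
    return [BandSpec(c, w, a) for c, (w, a) in amplitudes.items()]


#: default planted markers: four well-separated bands (cm^-1)
DEFAULT_MARKER_CENTRES = (999.0, 1277.0, 1402.0, 1582.0)


@dataclass
class GeneratorConfig:
    """Study-design parameters of the generator.

    Defaults emulate the screening-cohort conditions the pipeline targets:
    476 samples, balanced classes, triplicate acquisition on a 600-4000 cm^-1
    grid at 2 cm^-1 spacing, additive noise sd 0.01 absorbance, and an
    additive class effect of 0.05 absorbance on four marker bands.
    ``band_scale_sd`` is the between-sample relative variability of band
    intensities (biological variation), which makes the two classes overlap
    the way measured cohort spectra do.
    """

    n_samples: int = 476
    positive_fraction: float = 0.5
    grid_lo: float = 600.0
    grid_hi: float = 4000.0
    grid_spacing: float = 2.0
    bands: list[BandSpec] = field(default_factory=default_bands)
    marker_subset: Optional[Sequence[int]] = None  # indices into bands
    class_effect: float = 0.05
    baseline_coeffs: tuple[float, ...] = (0.05, 0.08, -0.04)
    baseline_scale_range: tuple[float, float] = (0.5, 1.5)
    band_scale_sd: float = 0.10  # per-sample, per-band relative amplitude variability
    noise_sd: float = 0.01
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.marker_subset is None:
            self.marker_subset = tuple(
                i
                for i, b in enumerate(self.bands)
                if b.centre in DEFAULT_MARKER_CENTRES
            )
        bad = [i for i in self.marker_subset if not 0 <= i < len(self.bands)]
        if bad:
            raise ValueError(f"marker_subset indices out of range: {bad}")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    labels: np.ndarray  # per sample, 1 = positive
    marker_wavenumbers: np.ndarray  # band centres carrying the class effect
    marker_band_indices: np.ndarray
    templates: np.ndarray  # noiseless per-sample spectra (n_samples x grid)
    wavenumbers: np.ndarray


def _gaussian(grid: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - centre) / width) ** 2)


def generate(cfg: GeneratorConfig) -> tuple[SpectralDataset, GroundTruth]:
    """Generate a replicate-level dataset plus its ground truth.

    Deterministic for a given ``cfg.seed``.  Per sample the noiseless
    template is the band sum (with the class effect added on marker bands for
    positives) plus the random-scaled polynomial baseline; each replicate row
    is the template plus iid Gaussian noise.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = np.arange(cfg.grid_lo, cfg.grid_hi + 0.5 * cfg.grid_spacing, cfg.grid_spacing)
    n = cfg.n_samples
    n_pos = int(round(cfg.positive_fraction * n))
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1

    band_shapes = np.stack([_gaussian(grid, b.centre, b.width) for b in cfg.bands])
    base_amps = np.array([b.base_amplitude for b in cfg.bands])
    effects = np.array(
        [
            b.class_effect if b.class_effect != 0.0 else
            (cfg.class_effect if i in set(cfg.marker_subset) else 0.0)
            for i, b in enumerate(cfg.bands)
        ]
    )

    # baseline shape: polynomial in the scaled coordinate t in [0, 1]
    t = (grid - grid[0]) / (grid[-1] - grid[0]) if grid.size > 1 else np.zeros_like(grid)
    baseline_shape = sum(c * t**k for k, c in enumerate(cfg.baseline_coeffs))
    lo, hi = cfg.baseline_scale_range
    scales = rng.uniform(lo, hi, size=n)

    amps = base_amps[None, :] + np.outer(labels, effects)  # (n, n_bands)
    if cfg.band_scale_sd > 0:
        # between-sample biological variability of band intensities, which
        # makes the classes overlap as measured cohort spectra do
        amps = amps * (1.0 + rng.normal(0.0, cfg.band_scale_sd, size=amps.shape))
    templates = amps @ band_shapes + np.outer(scales, baseline_shape)

    rows = np.repeat(templates, cfg.replicates, axis=0)
    if cfg.noise_sd > 0:
        rows = rows + rng.normal(0.0, cfg.noise_sd, size=rows.shape)
    sample_ids = np.repeat([f"S{i:04d}" for i in range(n)], cfg.replicates)
    replicate_ids = np.tile(np.arange(1, cfg.replicates + 1), n)
    row_labels = np.repeat(labels, cfg.replicates)

    ds = SpectralDataset(
        wavenumbers=grid,
        absorbance=rows,
        sample_ids=np.asarray(sample_ids, dtype=object),
        replicate_ids=replicate_ids,
        labels=row_labels,
    )
    marker_idx = np.asarray(sorted(cfg.marker_subset), dtype=int)
    truth = GroundTruth(
        labels=labels,
        marker_wavenumbers=np.array([cfg.bands[i].centre for i in marker_idx]),
        marker_band_indices=marker_idx,
        templates=templates,
        wavenumbers=grid,
    )
    return ds, truth
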