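"""Preprocessing chain for ATR-FTIR spectra.

The chain, applied in fixed order, is the standard recipe for biofluid
fingerprint spectra:

1. truncation to the biofingerprint region (default 900-1800 cm^-1),
2. Savitzky-Golay smoothing (default 7-point window, 2nd-order polynomial),
3. automatic weighted least-squares (AWLS) baseline correction, and
4. normalization to the Amide I peak (the protein C=O stretch near
   1650 cm^-1, the dominant band in plasma spectra).

AWLS is an asymmetric iteratively-reweighted polynomial fit: points above
the current baseline estimate (absorption peaks) are strongly down-weighted,
points at or below it keep full weight, so the fit settles onto the
peak-free background which is then subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectralDataset, truncate

logger = logging.getLogger(__name__)

#: weight given to points sitting above the current baseline estimate
AWLS_PEAK_WEIGHT = 0.01


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``sg_window`` must be odd and larger than ``sg_polyorder``.  The Amide I
    normalization searches for the window maximum within
    ``amide_i_target ± amide_i_search_halfwidth`` so that a peak shifted by a
    few cm^-1 is still used as the reference.
    """

    truncate_lo: float = 900.0
    truncate_hi: float = 1800.0
    sg_window: int = 7
    sg_polyorder: int = 2
    awls_polyorder: int = 2
    awls_max_iter: int = 50
    awls_tol: float = 1e-6
    amide_i_target: float = 1650.0
    amide_i_search_halfwidth: float = 10.0

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError(f"sg_window must be odd, got {self.sg_window}")
        if self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must exceed sg_polyorder")
        if self.awls_max_iter < 1:
            raise ValueError("awls_max_iter must be >= 1")
        if self.awls_tol < 0:
            raise ValueError("awls_tol must be non-negative")


class DegenerateSpectrumError(ValueError):
    """A spectrum cannot be normalized (non-positive window maximum)."""


def savitzky_golay(ds: SpectralDataset, window: int, polyorder: int) -> SpectralDataset:
    """Savitzky-Golay smoothing of every row.

    Each point is replaced by the value of a local least-squares polynomial
    fit of the given order over a sliding window.  Edges use one-sided
    polynomial fits so that any polynomial of degree <= ``polyorder`` is
    reproduced exactly everywhere.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > ds.n_wavenumbers:
        raise ValueError("window exceeds number of wavenumber points")
    smoothed = savgol_filter(ds.absorbance, window, polyorder, axis=1, mode="interp")
    return ds.with_absorbance(smoothed)


def _weighted_polyfit(t: np.ndarray, y: np.ndarray, w: np.ndarray, order: int) -> np.ndarray:
    """Weighted LSQ polynomial fit, evaluated on the grid t (scaled to [-1,1])."""
    V = np.polynomial.polynomial.polyvander(t, order)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(V * sw[:, None], y * sw, rcond=None)
    return V @ coef


def awls_baseline(
    ds: SpectralDataset,
    polyorder: int = 2,
    max_iter: int = 50,
    tol: float = 1e-6,
    return_baselines: bool = False,
):
    """Automatic weighted least-squares baseline correction.

    For each row, a polynomial baseline of order ``polyorder`` is fitted by
    iteratively reweighted least squares: points above the current fit get
    weight ``AWLS_PEAK_WEIGHT``, points at or below keep weight 1.  Iteration
    stops when the maximum absolute change of the fitted baseline drops below
    ``tol`` or after ``max_iter`` iterations (non-convergence is logged, not
    raised).  Returns the dataset with the baseline subtracted.
    """
    if polyorder >= ds.n_wavenumbers:
        raise ValueError("awls polyorder must be < number of wavenumbers")
    w = ds.wavenumbers
    # scale the abscissa to [-1, 1] for a well-conditioned Vandermonde matrix
    t = 2 * (w - w[0]) / (w[-1] - w[0]) - 1 if w.size > 1 else np.zeros_like(w)
    corrected = np.empty_like(ds.absorbance)
    baselines = np.empty_like(ds.absorbance)
    for i, y in enumerate(ds.absorbance):
        weights = np.ones_like(y)
        baseline = _weighted_polyfit(t, y, weights, polyorder)
        converged = max_iter == 1
        for _ in range(max_iter - 1):
            weights = np.where(y > baseline, AWLS_PEAK_WEIGHT, 1.0)
            new_baseline = _weighted_polyfit(t, y, weights, polyorder)
            if np.max(np.abs(new_baseline - baseline)) < tol:
                baseline = new_baseline
                converged = True
                break
            baseline = new_baseline
        if not converged:
            logger.warning(
                "AWLS baseline did not converge for row %d within %d iterations; "
                "using last iterate",
                i,
                max_iter,
            )
        corrected[i] = y - baseline
        baselines[i] = baseline
    out = ds.with_absorbance(corrected)
    if return_baselines:
        return out, baselines
    return out


def awls_iteration_sse(
    y: np.ndarray, t: np.ndarray, polyorder: int, max_iter: int
) -> list[float]:
    """Weighted SSE of each AWLS iteration (diagnostic; used by tests)."""
    sses = []
    weights = np.ones_like(y)
    baseline = _weighted_polyfit(t, y, weights, polyorder)
    sses.append(float(np.sum(weights * (y - baseline) ** 2)))
    for _ in range(max_iter - 1):
        weights = np.where(y > baseline, AWLS_PEAK_WEIGHT, 1.0)
        baseline = _weighted_polyfit(t, y, weights, polyorder)
        sses.append(float(np.sum(weights * (y - baseline) ** 2)))
    return sses


def normalize_amide_i(
    ds: SpectralDataset, target: float = 1650.0, halfwidth: float = 10.0
) -> SpectralDataset:
    """Normalize each row to its maximum within the Amide I window.

    "The Amide I peak" denotes the band, not a single coordinate: each row is
    divided by its maximum absorbance within ``[target - halfwidth,
    target + halfwidth]``, so a peak shifted by a few cm^-1 still normalizes
    to exactly 1 at its own apex.
    """
    mask = (ds.wavenumbers >= target - halfwidth) & (ds.wavenumbers <= target + halfwidth)
    if not mask.any():
        raise ValueError(
            f"no grid point within {halfwidth} cm^-1 of {target} cm^-1"
        )
    peak = ds.absorbance[:, mask].max(axis=1)
    bad = np.nonzero(peak <= 0)[0]
    if bad.size:
        raise DegenerateSpectrumError(
            f"non-positive Amide I window maximum for sample(s) "
            f"{[str(s) for s in ds.sample_ids[bad]]}"
        )
    return ds.with_absorbance(ds.absorbance / peak[:, None])


def preprocess(ds: SpectralDataset, cfg: PreprocessConfig | None = None):
    """Full chain: truncate -> Savitzky-Golay -> AWLS -> Amide I normalize.

    Returns ``(dataset, provenance)`` where ``provenance`` records the
    applied parameters.
    """
    cfg = cfg or PreprocessConfig()
    out = truncate(ds, cfg.truncate_lo, cfg.truncate_hi)
    out = savitzky_golay(out, cfg.sg_window, cfg.sg_polyorder)
    out = awls_baseline(out, cfg.awls_polyorder, cfg.awls_max_iter, cfg.awls_tol)
    out = normalize_amide_i(out, cfg.amide_i_target, cfg.amide_i_search_halfwidth)
    provenance = {"steps": ["truncate", "savitzky_golay", "awls_baseline", "normalize_amide_i"],
                  "config": asdict(cfg)}
    return out, provenance
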