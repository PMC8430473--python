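"""Spectral quality control and preprocessing.

The preprocessing chain applied to every pixel spectrum is

    quality test -> Savitzky-Golay smoothing -> second-order polynomial
    baseline correction -> (optional) min-max normalization -> cropping
    to the fingerprint region

Second-derivative spectra (Savitzky-Golay, nine smoothing points) are
available for band-position work.  Chemical maps are computed on
baseline-corrected but *unnormalized* spectra, since min-max scaling
would flatten the content differences the maps quantify; spectra that
enter the multivariate data matrix are globally min-max normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectralCube, Spectrum, window_mask

QUALITY_WINDOW = (1800.0, 1600.0)  # amide I neighbourhood used by the QC test
NOISE_WINDOW = (1800.0, 1750.0)  # band-free region used to estimate noise
AMIDE_I_WINDOW = (1700.0, 1600.0)
FINGERPRINT = (1730.0, 900.0)


# --------------------------------------------------------------------------
# quality control


@dataclass
class QualityReport:
    max_abs_1800_1600: float
    snr: float
    passed: bool
    reasons: list[str] = field(default_factory=list)


def quality_test(
    s: Spectrum,
    amax_bounds: tuple[float, float] = (0.1, 2.0),
    snr_min: float = 10.0,
) -> QualityReport:
    """Section-thickness / signal-to-noise screen on the 1800-1600 cm^-1 window.

    SNR is the maximum absorbance in 1800-1600 divided by the standard
    deviation of the linearly detrended absorbance in the band-free
    1800-1750 cm^-1 stretch.
    """
    w = s.wavenumbers
    if w.max() < NOISE_WINDOW[1] or w.min() > QUALITY_WINDOW[1]:
        raise ValueError("spectrum does not cover the 1800-1600 cm^-1 quality window")
    peak = s.max_in(*QUALITY_WINDOW)
    noise_win = s.window(*NOISE_WINDOW)
    resid = noise_win.absorbance - np.polyval(
        np.polyfit(noise_win.wavenumbers, noise_win.absorbance, 1), noise_win.wavenumbers
    )
    noise_sd = float(resid.std())
    snr = float(peak / noise_sd) if noise_sd > 0 else np.inf

    reasons = []
    lo, hi = amax_bounds
    if peak < lo:
        reasons.append(f"thickness too low (max absorbance {peak:.3g} < {lo})")
    if peak > hi:
        reasons.append(f"absorbance too high (max absorbance {peak:.3g} > {hi})")
    if snr < snr_min:
        reasons.append(f"low SNR ({snr:.3g} < {snr_min})")
    return QualityReport(max_abs_1800_1600=peak, snr=snr, passed=not reasons, reasons=reasons)


# --------------------------------------------------------------------------
# smoothing and differentiation (array cores + Spectrum wrappers)


def _check_sg(window: int, polyorder: int, n: int) -> None:
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if window <= polyorder:
        raise ValueError("Savitzky-Golay window must exceed the polynomial order")
    if window > n:
        raise ValueError("Savitzky-Golay window longer than the spectrum")


def smooth_array(values: np.ndarray, step: float, window: int = 9, polyorder: int = 2) -> np.ndarray:
    _check_sg(window, polyorder, values.shape[-1])
    return savgol_filter(values, window, polyorder, axis=-1)


def smooth(s: Spectrum, window: int = 9, polyorder: int = 2) -> Spectrum:
    step = abs(float(s.wavenumbers[0] - s.wavenumbers[1]))
    return Spectrum(s.wavenumbers, smooth_array(s.absorbance, step, window, polyorder))


def second_derivative_array(
    values: np.ndarray, step: float, window: int = 9, polyorder: int = 2
) -> np.ndarray:
    _check_sg(window, polyorder, values.shape[-1])
    # even-order derivative: invariant to the descending grid direction
    return savgol_filter(values, window, polyorder, deriv=2, delta=step, axis=-1)


def second_derivative(s: Spectrum, window: int = 9, polyorder: int = 2) -> Spectrum:
    step = abs(float(s.wavenumbers[0] - s.wavenumbers[1]))
    return Spectrum(s.wavenumbers, second_derivative_array(s.absorbance, step, window, polyorder))


# --------------------------------------------------------------------------
# baseline correction


def baseline_array(
    values: np.ndarray,
    grid: np.ndarray,
    order: int = 2,
    n_iter: int = 10,
    keep_sigma: float = 2.0,
) -> np.ndarray:
    """Iteratively fitted polynomial baseline for each row of ``values``.

    Fit a polynomial of ``order`` by least squares, keep the support points
    that lie below the fit plus ``keep_sigma`` noise standard deviations
    (absorption bands poke above and are dropped), refit; ``n_iter`` rounds.
    The noise level is estimated from the *negative* residuals only, so
    absorption-band amplitude cannot inflate the threshold and bias the
    baseline toward band flanks.  Returns the baseline, same shape as
    ``values``.
    """
    if order < 0:
        raise ValueError("baseline order must be non-negative")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[-1]
    if n < order + 1:
        raise ValueError("not enough points to fit the baseline polynomial")
    u = (grid - grid.mean()) / (abs(grid[0] - grid[-1]) or 1.0)
    V = np.vander(u, order + 1, increasing=True)  # (n, order+1)
    w = np.ones_like(values)
    baseline = np.zeros_like(values)
    for _ in range(n_iter):
        # per-row weighted least squares via batched normal equations
        A = np.einsum("pn,ni,nj->pij", w, V, V)
        b = np.einsum("pn,ni->pi", w * values, V)
        coef = np.linalg.solve(A + 1e-12 * np.eye(order + 1), b[..., None])[..., 0]
        baseline = coef @ V.T
        resid = values - baseline
        neg = resid < 0
        n_neg = neg.sum(axis=-1)
        sig = np.sqrt((resid**2 * neg).sum(axis=-1) / np.maximum(n_neg, 1))
        sig = np.where(n_neg > 0, sig, 0.0)
        new_w = (resid <= keep_sigma * sig[:, None]).astype(float)
        # never let the support collapse below the fit's degrees of freedom
        ok = new_w.sum(axis=-1) >= order + 2
        w = np.where(ok[:, None], new_w, w)
    return baseline


#: Band-free wavenumber stretches of the cartilage fingerprint spectrum,
#: used as baseline support anchors: above the amide I band, the gap between
#: the CH2 side-chain and amide III bands, and below the carbohydrate region.
BASELINE_ANCHORS: tuple[tuple[float, float], ...] = (
    (1800.0, 1745.0),
    (1310.0, 1268.0),
    (945.0, 900.0),
)


def baseline_anchor_array(
    values: np.ndarray,
    grid: np.ndarray,
    order: int = 2,
    anchors: tuple[tuple[float, float], ...] = BASELINE_ANCHORS,
) -> np.ndarray:
    """Polynomial baseline fitted by least squares to band-free anchor windows.

    Anchor windows outside the grid are ignored; if too few anchor points
    remain the iterative estimator is used instead.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    mask = np.zeros(grid.size, dtype=bool)
    n_windows = 0
    for hi, lo in anchors:
        m = window_mask(grid, hi, lo)
        n_windows += int(m.any())
        mask |= m
    if mask.sum() < order + 2 or n_windows == 0:
        return baseline_array(values, grid, order=order)
    # a polynomial needs at least order+1 separated anchor windows to be
    # well-posed; cap the order when cropping removed some of them
    order = min(order, n_windows - 1)
    u = (grid - grid.mean()) / (abs(grid[0] - grid[-1]) or 1.0)
    V = np.vander(u, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V[mask], values[:, mask].T, rcond=None)
    return (V @ coef).T


def baseline_correct(
    s: Spectrum,
    order: int = 2,
    n_iter: int = 10,
    keep_sigma: float = 2.0,
    support: str = "iterative",
) -> Spectrum:
    """Subtract a polynomial baseline; support is ``iterative`` or ``anchors``."""
    if support == "anchors":
        base = baseline_anchor_array(s.absorbance[None, :], s.wavenumbers, order)[0]
    elif support == "iterative":
        base = baseline_array(s.absorbance[None, :], s.wavenumbers, order, n_iter, keep_sigma)[0]
    else:
        raise ValueError(f"unknown baseline support {support!r}")
    return Spectrum(s.wavenumbers, s.absorbance - base)


# --------------------------------------------------------------------------
# normalization and cropping


def minmax_normalize_array(values: np.ndarray, grid: np.ndarray, mode: str = "global") -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if mode == "global":
        lo = values.min(axis=-1, keepdims=True)
        hi = values.max(axis=-1, keepdims=True)
        rng = hi - lo
        if np.any(rng <= 0):
            raise ValueError("cannot min-max normalize a constant spectrum")
        return (values - lo) / rng
    if mode == "amideI":
        m = window_mask(grid, *AMIDE_I_WINDOW)
        if not m.any():
            raise ValueError("grid does not cover the amide I window")
        peak = values[..., m].max(axis=-1, keepdims=True)
        if np.any(peak <= 0):
            raise ValueError("non-positive amide I maximum; cannot normalize")
        return values / peak
    raise ValueError(f"unknown normalization mode {mode!r}")


def minmax_normalize(s: Spectrum, mode: str = "global") -> Spectrum:
    return Spectrum(s.wavenumbers, minmax_normalize_array(s.absorbance[None, :], s.wavenumbers, mode)[0])


def crop(s: Spectrum, hi: float, lo: float) -> Spectrum:
    """Restrict to grid points within [lo, hi]; swapped bounds auto-normalize."""
    m = window_mask(s.wavenumbers, hi, lo)
    if not m.any():
        raise ValueError(f"crop window [{lo}, {hi}] does not overlap the grid")
    return Spectrum(s.wavenumbers[m], s.absorbance[m])


# --------------------------------------------------------------------------
# regions of interest


@dataclass
class ROISet:
    """Axis-aligned pixel rectangles (x0, y0, width, height) in one zone."""

    rois: list[tuple[int, int, int, int]]
    zone: str | None = None

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def pixel_indices(self) -> list[tuple[int, int]]:
        """(iy, ix) pairs covered by any ROI, in deterministic order."""
        seen = []
        for x0, y0, w, h in self.rois:
            for iy in range(y0, y0 + h):
                for ix in range(x0, x0 + w):
                    seen.append((iy, ix))
        return seen


def _overlaps(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    return ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah


def extract_rois(
    cube: SpectralCube,
    n: int = 5,
    size: tuple[int, int] = (10, 10),
    seed: int = 0,
    max_tries: int = 20000,
) -> ROISet:
    """Place ``n`` disjoint ``size`` rectangles uniformly at random (seeded)."""
    w, h = size
    if cube.nx < w or cube.ny < h:
        raise ValueError(f"cube {cube.nx}x{cube.ny} too small for a {w}x{h} ROI")
    if n * w * h > cube.nx * cube.ny:
        raise ValueError(f"cannot host {n} disjoint {w}x{h} ROIs in a {cube.nx}x{cube.ny} cube")
    rng = np.random.default_rng(seed)
    rois: list[tuple[int, int, int, int]] = []
    tries = 0
    while len(rois) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(f"failed to place {n} disjoint {w}x{h} ROIs after {max_tries} tries")
        x0 = int(rng.integers(0, cube.nx - w + 1))
        y0 = int(rng.integers(0, cube.ny - h + 1))
        cand = (x0, y0, w, h)
        if all(not _overlaps(cand, r) for r in rois):
            rois.append(cand)
    return ROISet(rois=rois, zone=cube.zone)


def average_roi(cube: SpectralCube, roi: tuple[int, int, int, int]) -> Spectrum:
    """Arithmetic mean spectrum over one ROI rectangle."""
    x0, y0, w, h = roi
    if x0 < 0 or y0 < 0 or x0 + w > cube.nx or y0 + h > cube.ny:
        raise ValueError(f"ROI {roi} exceeds cube bounds {cube.nx}x{cube.ny}")
    block = cube.data[y0 : y0 + h, x0 : x0 + w, :]
    return Spectrum(cube.grid, block.reshape(-1, cube.grid.size).mean(axis=0))


# --------------------------------------------------------------------------
# whole-cube pipeline


def preprocess_cube(
    cube: SpectralCube,
    smooth_window: int = 9,
    smooth_polyorder: int = 2,
    baseline_order: int = 2,
    baseline_support: str = "anchors",
    normalize: str | None = None,
    crop_bounds: tuple[float, float] | None = FINGERPRINT,
) -> SpectralCube:
    """Smoothing -> baseline -> (normalize) -> crop, vectorized over pixels."""
    grid = cube.grid
    step = abs(float(grid[0] - grid[1]))
    flat = cube.flat()
    flat = smooth_array(flat, step, smooth_window, smooth_polyorder)
    if baseline_support == "anchors":
        flat = flat - baseline_anchor_array(flat, grid, order=baseline_order)
    elif baseline_support == "iterative":
        flat = flat - baseline_array(flat, grid, order=baseline_order)
    else:
        raise ValueError(f"unknown baseline support {baseline_support!r}")
    if normalize is not None:
        flat = minmax_normalize_array(flat, grid, mode=normalize)
    if crop_bounds is not None:
        m = window_mask(grid, *crop_bounds)
        if not m.any():
            raise ValueError("crop window does not overlap the cube grid")
        grid = grid[m]
        flat = flat[:, m]
    data = flat.reshape(cube.ny, cube.nx, grid.size)
    return cube.with_data(
        grid,
        data,
        preprocess={
            "smooth_window": smooth_window,
            "smooth_polyorder": smooth_polyorder,
            "baseline_order": baseline_order,
            "baseline_support": baseline_support,
            "normalize": normalize,
            "crop": list(crop_bounds) if crop_bounds else None,
        },
    )


def cube_quality(
    cube: SpectralCube,
    amax_bounds: tuple[float, float] = (0.1, 2.0),
    snr_min: float = 10.0,
) -> tuple[np.ndarray, dict]:
    """Vectorized per-pixel quality mask plus a summary dict for the QC report.

    Applies the same criteria as :func:`quality_test` to every pixel.
    """
    grid = cube.grid
    if grid.max() < NOISE_WINDOW[1] or grid.min() > QUALITY_WINDOW[1]:
        raise ValueError("cube grid does not cover the 1800-1600 cm^-1 quality window")
    flat = cube.flat()
    qmask = window_mask(grid, *QUALITY_WINDOW)
    nmask = window_mask(grid, *NOISE_WINDOW)
    peak = flat[:, qmask].max(axis=-1)
    # linear detrend of the band-free stretch via a fixed projection matrix
    kn = grid[nmask]
    V = np.vander((kn - kn.mean()) / (np.ptp(kn) or 1.0), 2, increasing=True)
    P = V @ np.linalg.solve(V.T @ V, V.T)
    resid = flat[:, nmask] - flat[:, nmask] @ P.T
    noise_sd = resid.std(axis=-1)
    with np.errstate(divide="ignore"):
        snr = np.where(noise_sd > 0, peak / np.maximum(noise_sd, 1e-300), np.inf)
    lo, hi = amax_bounds
    mask = (peak >= lo) & (peak <= hi) & (snr >= snr_min)
    summary = {
        "n_pixels": int(mask.size),
        "n_passed": int(mask.sum()),
        "fraction_passed": float(mask.mean()),
        "median_snr": float(np.median(snr[np.isfinite(snr)])) if np.isfinite(snr).any() else np.inf,
    }
    return mask.reshape(cube.ny, cube.nx), summary
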