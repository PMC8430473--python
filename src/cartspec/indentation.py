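"""Hertz-model nanoindentation fitting and modulus-histogram peak analysis.

For a four-sided pyramidal AFM tip the contact law is

    F = 2 tan(alpha) E / (pi (1 - nu^2)) * delta^2

so the least-squares modulus over depths up to ``max_fit_depth`` has the
closed form E = k * pi (1 - nu^2) / (2 tan alpha) with
k = sum(F delta^2) / sum(delta^4).  Stiffness distributions are
summarized as count histograms; per-zone peak moduli come from fitting a
single Gaussian or, for the bimodal deep zone, a sum of two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .synth import hertz_prefactor


@dataclass
class ForceCurve:
    """One indentation curve: depth (nm, non-decreasing) vs force (nN)."""

    depth: np.ndarray
    force: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.depth, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.shape != f.shape or d.ndim != 1 or d.size < 3:
            raise ValueError("depth and force must be equal-length vectors of >= 3 points")
        if np.any(d < 0) or np.any(np.diff(d) < 0):
            raise ValueError("depth must be non-negative and non-decreasing")
        self.depth = d
        self.force = f


@dataclass
class IndenterParams:
    alpha: float = 17.5  # tip half-opening angle, degrees
    nu: float = 0.5  # Poisson ratio
    max_fit_depth: float = 500.0  # nm; excludes substrate-affected depths

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 90.0:
            raise ValueError("alpha must lie in (0, 90) degrees")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("nu must lie in [0, 0.5]")


@dataclass
class HertzFit:
    E: float  # kPa
    contact_offset: float  # nm
    rss: float  # nN^2
    n_used: int


def _quadratic_modulus(depth: np.ndarray, force: np.ndarray, params: IndenterParams) -> tuple[float, float]:
    """Closed-form LS fit of F = k d^2 through the origin; returns (E_kPa, rss)."""
    d2 = depth**2
    denom = float(d2 @ d2)
    if denom == 0:
        raise ValueError("all usable depths are zero")
    k = float(force @ d2) / denom  # nN / nm^2
    rss = float(np.sum((force - k * d2) ** 2))
    E = k * 1e6 / hertz_prefactor(params.alpha, params.nu)  # back to kPa
    return E, rss


def fit_hertz(curve: ForceCurve, params: IndenterParams | None = None, estimate_contact: bool = False) -> HertzFit:
    """Fit the pyramidal contact law to one curve, honouring the depth cap.

    With ``estimate_contact`` the contact point is grid-searched (0 to half
    the capped depth range, 1 nm steps) and the closed-form fit is applied
    to the shifted depths; otherwise contact is taken at zero depth.
    """
    params = params or IndenterParams()
    mask = curve.depth <= params.max_fit_depth
    depth = curve.depth[mask]
    force = curve.force[mask]
    if depth.size < 3:
        raise ValueError("fewer than 3 points within the fit depth")
    if np.all(force <= 0):
        raise ValueError("no positive forces within the fit depth")

    if not estimate_contact:
        E, rss = _quadratic_modulus(depth, force, params)
        if E <= 0:
            raise ValueError("fitted modulus is non-positive")
        return HertzFit(E=E, contact_offset=0.0, rss=rss, n_used=int(depth.size))

    best: HertzFit | None = None
    span = float(depth.max() - depth.min())
    for offset in np.arange(0.0, span / 2.0 + 1.0, 1.0):
        shifted = np.clip(depth - offset, 0.0, None)
        if np.count_nonzero(shifted) < 3:
            break
        try:
            E, rss = _quadratic_modulus(shifted, force, params)
        except ValueError:
            continue
        if E > 0 and (best is None or rss < best.rss):
            best = HertzFit(E=E, contact_offset=float(offset), rss=rss, n_used=int(depth.size))
    if best is None:
        raise ValueError("contact-point search found no valid fit")
    return best


# --------------------------------------------------------------------------
# histograms and peak fitting


@dataclass
class Histogram:
    centers: np.ndarray
    counts: np.ndarray
    bin_width: float

    def __iter__(self):  # allows tuple-unpacking (centers, counts)
        return iter((self.centers, self.counts))


def freedman_diaconis_width(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    width = 2.0 * iqr / values.size ** (1.0 / 3.0)
    if width <= 0:
        width = max(float(np.ptp(values)) / 10.0, 1.0)
    return width


def build_histogram(moduli, bin_width: float | None = None) -> Histogram:
    """Count histogram of moduli; default bin width is Freedman-Diaconis."""
    values = np.asarray(moduli, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 moduli for a histogram")
    if bin_width is None:
        bin_width = freedman_diaconis_width(values)
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], values.max())  # closed last bin
    counts, _ = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return Histogram(centers=centers, counts=counts.astype(float), bin_width=float(bin_width))


@dataclass
class PeakFit:
    n_components: int
    centers: np.ndarray  # kPa, ascending
    widths: np.ndarray  # Gaussian sigmas, kPa
    amplitudes: np.ndarray
    goodness: float  # R^2 of the count fit


def _gauss_sum(x, *params):
    y = np.zeros_like(x, dtype=float)
    for a, c, w in zip(params[0::3], params[1::3], params[2::3]):
        y = y + a * np.exp(-0.5 * ((x - c) / w) ** 2)
    return y


def fit_gaussian_peaks(hist: Histogram, n_components: int = 1, seed: int = 0, n_starts: int = 8) -> PeakFit:
    """Multi-start nonlinear LS of a sum of Gaussians to histogram counts."""
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    x = np.asarray(hist.centers, dtype=float)
    y = np.asarray(hist.counts, dtype=float)
    occupied = int(np.count_nonzero(y))
    need = 5 if n_components == 1 else 8
    if occupied < need:
        raise ValueError(f"need >= {need} occupied bins for {n_components} component(s)")

    rng = np.random.default_rng(seed)
    span = float(x.max() - x.min())
    amp0 = float(y.max())
    sigma0 = max(span / (4.0 * n_components), hist.bin_width)

    # deterministic starts at the histogram modes, then jittered restarts
    order = np.argsort(y)[::-1]
    if n_components == 1:
        starts = [[amp0, float(x[order[0]]), sigma0]]
    else:
        c1 = float(x[order[0]])
        far = order[np.abs(x[order] - c1) > span / 4.0]
        c2 = float(x[far[0]]) if far.size else c1 + span / 3.0
        starts = [[amp0, min(c1, c2), sigma0, amp0, max(c1, c2), sigma0]]
    while len(starts) < n_starts:
        p = list(starts[0])
        for j in range(1, len(p), 3):
            p[j] = float(rng.uniform(x.min(), x.max()))
        for j in range(2, len(p), 3):
            p[j] = float(rng.uniform(hist.bin_width, span / 2.0))
        starts.append(p)

    lower = [0.0, x.min() - span, hist.bin_width / 4.0] * n_components
    upper = [np.inf, x.max() + span, 2.0 * span] * n_components
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(_gauss_sum, x, y, p0=p0, bounds=(lower, upper), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - _gauss_sum(x, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise ValueError("Gaussian peak fit did not converge from any start")
    rss, popt = best
    amps = np.array(popt[0::3])
    centers = np.array(popt[1::3])
    widths = np.abs(np.array(popt[2::3]))
    order = np.argsort(centers)
    amps, centers, widths = amps[order], centers[order], widths[order]
    if n_components == 2:
        overlapping = abs(centers[1] - centers[0]) < 0.5 * (widths[0] + widths[1])
        areas = amps * widths
        negligible = areas.min() < 0.1 * areas.max()
        if overlapping or negligible:
            raise ValueError("components collapsed onto one peak; refit with n_components=1")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    return PeakFit(
        n_components=n_components, centers=centers, widths=widths, amplitudes=amps, goodness=r2
    )


def compare_moduli(group_a, group_b, alpha: float = 0.05) -> tuple[float, bool]:
    """Two-tailed Student's t-test between two modulus samples."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return p, bool(p < alpha)


def fit_moduli(curves, params: IndenterParams | None = None, estimate_contact: bool = False) -> np.ndarray:
    """Vector of fitted moduli (kPa) for a list of curves."""
    return np.array([fit_hertz(c, params, estimate_contact).E for c in curves])
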