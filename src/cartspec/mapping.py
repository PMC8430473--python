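"""Band-integration chemical mapping and group-comparison statistics.

Per-pixel indices computed from baseline-corrected absorbance:

* **CC** (collagen content): trapezoidal area under the amide I band,
  1750-1590 cm^-1 (window clipped to the available grid).
* **PG** (proteoglycan content): area of the sugar-ring region,
  1140-965 cm^-1.
* **CI** (collagen integrity): ratio of the CH2 side-chain area
  (1360-1325 cm^-1) to the amide II area (1590-1490 cm^-1).

Group comparisons follow the cascade: Shapiro-Wilk normality on each
group; if both normal, Levene's variance test selects Student's t
(equal variances) or Welch's t; any non-normal group falls back to the
Mann-Whitney U test.  Treatment effects with pig as a random effect use
a two-level random-intercept linear model (REML).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ROISet
from .spectra import SpectralCube, Spectrum, window_mask

CC_WINDOW = (1750.0, 1590.0)
PG_WINDOW = (1140.0, 965.0)
CH_WINDOW = (1360.0, 1325.0)
AMIDE_II_WINDOW = (1590.0, 1490.0)

# amide I window as printed in the map-figure caption (configurable variant)
CC_WINDOW_CAPTION = (1700.0, 1600.0)


@dataclass(frozen=True)
class BandWindow:
    hi: float
    lo: float

    def __post_init__(self) -> None:
        if self.hi <= self.lo:
            raise ValueError(f"window needs hi > lo, got ({self.hi}, {self.lo})")


def _as_window(w) -> BandWindow:
    if isinstance(w, BandWindow):
        return w
    hi, lo = w
    if hi < lo:
        hi, lo = lo, hi
    return BandWindow(hi, lo)


def _trap_weights(grid_desc: np.ndarray, window: BandWindow) -> tuple[np.ndarray, np.ndarray]:
    """Mask and trapezoid weights (over ascending wavenumber) for a window."""
    m = window_mask(grid_desc, window.hi, window.lo)
    if m.sum() < 2:
        raise ValueError(f"window [{window.lo}, {window.hi}] cm^-1 does not overlap the grid")
    k = grid_desc[m][::-1]  # ascending
    w = np.zeros_like(k)
    dk = np.diff(k)
    w[:-1] += dk / 2.0
    w[1:] += dk / 2.0
    return m, w[::-1]  # weights back in descending order


def integrate_band(s: Spectrum, window) -> float:
    """Trapezoidal integral of absorbance over wavenumber inside the window."""
    window = _as_window(window)
    m, w = _trap_weights(s.wavenumbers, window)
    return float(s.absorbance[m] @ w)


def integrate_cube(cube: SpectralCube, window) -> np.ndarray:
    """Per-pixel band integral, shape (ny, nx)."""
    window = _as_window(window)
    m, w = _trap_weights(cube.grid, window)
    return cube.data[..., m] @ w


@dataclass
class ChemicalMap:
    """Per-pixel CC / CI / PG index maps of one cube."""

    cc: np.ndarray
    ci: np.ndarray
    pg: np.ndarray
    zone: str | None = None
    group: str | None = None
    animal_id: str | None = None

    def parameter(self, name: str) -> np.ndarray:
        return {"CC": self.cc, "CI": self.ci, "PG": self.pg}[name]


def compute_maps(
    cube: SpectralCube,
    cc_window=CC_WINDOW,
    pg_window=PG_WINDOW,
    ch_window=CH_WINDOW,
    amide_ii_window=AMIDE_II_WINDOW,
) -> ChemicalMap:
    """CC / PG by band integration, CI as a CH / amide II area ratio.

    Pixels whose amide II integral is non-positive get CI = NaN.
    """
    cc = integrate_cube(cube, cc_window)
    pg = integrate_cube(cube, pg_window)
    ch = integrate_cube(cube, ch_window)
    aii = integrate_cube(cube, amide_ii_window)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(aii > 0, ch / np.where(aii > 0, aii, 1.0), np.nan)
    return ChemicalMap(cc=cc, ci=ci, pg=pg, zone=cube.zone, group=cube.group, animal_id=cube.animal_id)


def zone_statistics(cmap: ChemicalMap, rois: ROISet) -> pd.DataFrame:
    """Per-ROI means and SDs of the three indices (rows = ROIs)."""
    rows = []
    for i, (x0, y0, w, h) in enumerate(rois):
        if w * h == 0:
            raise ValueError("empty ROI")
        for arr_name in ("CC", "CI", "PG"):
            arr = cmap.parameter(arr_name)
            if y0 + h > arr.shape[0] or x0 + w > arr.shape[1] or x0 < 0 or y0 < 0:
                raise ValueError(f"ROI {(x0, y0, w, h)} exceeds map bounds")
        block = {n: cmap.parameter(n)[y0 : y0 + h, x0 : x0 + w] for n in ("CC", "CI", "PG")}
        rows.append(
            {
                "roi": i,
                "zone": cmap.zone,
                "group": cmap.group,
                "animal_id": cmap.animal_id,
                "cc_mean": float(np.nanmean(block["CC"])),
                "cc_sd": float(np.nanstd(block["CC"], ddof=1)),
                "ci_mean": float(np.nanmean(block["CI"])),
                "ci_sd": float(np.nanstd(block["CI"], ddof=1)),
                "pg_mean": float(np.nanmean(block["PG"])),
                "pg_sd": float(np.nanstd(block["PG"], ddof=1)),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# group statistics


@dataclass
class GroupComparison:
    parameter: str
    zone: str | None
    mean_C: float
    mean_HMB: float
    percent_difference: float
    test_used: str
    p_value: float
    significant: bool


def compare_groups(
    values_C,
    values_HMB,
    alpha: float = 0.05,
    parameter: str = "",
    zone: str | None = None,
) -> GroupComparison:
    """Normality/variance test cascade, then the appropriate two-sample test."""
    a = np.asarray(values_C, dtype=float)
    b = np.asarray(values_HMB, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    mean_c, mean_h = float(a.mean()), float(b.mean())
    pct = 100.0 * (mean_h - mean_c) / mean_c

    degenerate = a.std() == 0 and b.std() == 0
    if degenerate:
        test, p = "student_t", 1.0 if mean_c == mean_h else 0.0
    else:
        normal_a = a.std() == 0 or stats.shapiro(a).pvalue > alpha
        normal_b = b.std() == 0 or stats.shapiro(b).pvalue > alpha
        if normal_a and normal_b:
            equal_var = stats.levene(a, b, center="mean").pvalue > alpha
            if equal_var:
                test, p = "student_t", float(stats.ttest_ind(a, b, equal_var=True).pvalue)
            else:
                test, p = "welch_t", float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            test, p = "mann_whitney", float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return GroupComparison(
        parameter=parameter,
        zone=zone,
        mean_C=mean_c,
        mean_HMB=mean_h,
        percent_difference=pct,
        test_used=test,
        p_value=p,
        significant=bool(p < alpha),
    )


@dataclass
class RandomInterceptFit:
    effect: float
    se: float
    p_value: float
    n_animals: int


def fit_random_intercept(values, animal_ids, treatment) -> RandomInterceptFit:
    """Treatment effect with animal as a random intercept (REML).

    ``treatment`` holds the per-observation group labels; the returned
    effect is the fitted fixed-effect difference (second level minus first,
    in sorted label order).
    """
    import statsmodels.api as sm

    frame = pd.DataFrame({"y": np.asarray(values, float), "animal": animal_ids, "trt": treatment})
    levels = sorted(frame["trt"].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 treatment levels, got {levels}")
    per_group = frame.groupby("trt")["animal"].nunique()
    if (per_group < 2).any():
        raise ValueError("each treatment group needs at least 2 animals for a random intercept")
    frame["x"] = (frame["trt"] == levels[1]).astype(float)
    exog = sm.add_constant(frame["x"])
    model = sm.MixedLM(frame["y"], exog, groups=frame["animal"])
    fit = model.fit(reml=True)
    return RandomInterceptFit(
        effect=float(fit.params["x"]),
        se=float(fit.bse["x"]),
        p_value=float(fit.pvalues["x"]),
        n_animals=int(frame["animal"].nunique()),
    )


def per_animal_means(roi_stats: pd.DataFrame) -> pd.DataFrame:
    """Collapse ROI rows to one row per (group, animal, zone): mean of ROI means."""
    return (
        roi_stats.groupby(["group", "animal_id", "zone"], as_index=False)[
            ["cc_mean", "ci_mean", "pg_mean"]
        ]
        .mean()
        .rename(columns={"cc_mean": "CC", "ci_mean": "CI", "pg_mean": "PG"})
    )


def group_comparison_table(per_animal: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """The 3 zones x 3 parameters comparison table (animals as units)."""
    rows = []
    for zone in ("SZ", "MZ", "DZ"):
        sub = per_animal[per_animal["zone"] == zone]
        for param in ("CC", "CI", "PG"):
            comp = compare_groups(
                sub.loc[sub["group"] == "C", param],
                sub.loc[sub["group"] == "HMB", param],
                alpha=alpha,
                parameter=param,
                zone=zone,
            )
            rows.append(
                {
                    "zone": zone,
                    "parameter": param,
                    "mean_C": comp.mean_C,
                    "mean_HMB": comp.mean_HMB,
                    "pct_diff": comp.percent_difference,
                    "test": comp.test_used,
                    "p": comp.p_value,
                    "significant": comp.significant,
                }
            )
    return pd.DataFrame(rows)
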