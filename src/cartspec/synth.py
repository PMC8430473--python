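"""Synthetic-study generator: hyperspectral cubes and force-indentation curves.

Emulates a two-group (control vs HMB-supplemented), three-zone (SZ/MZ/DZ),
five-animals-per-group cartilage imaging study.  Every pixel spectrum is a
sum of Gaussian bands (see :mod:`cartspec.bands`) scaled by the zone/group
profile and a per-pixel, per-family log-normal heterogeneity jitter, plus a
random quadratic baseline and iid Gaussian noise.  Force-indentation curves
follow the pyramidal-indenter contact law

    F = 2 tan(alpha) E / (pi (1 - nu^2)) * delta^2

with zone-dependent ground-truth Young's moduli; the deep zone is a
two-component mixture (proteoglycan and collagen phases).

All randomness flows through explicit integer seeds; fixed seeds give
bitwise-reproducible output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import FAMILIES, BandModel, ZoneGroupProfile, default_bands, default_profiles
from .spectra import GROUPS, ZONES, SpectralCube, build_grid


def derive_seed(seed: int, label: str) -> int:
    """Stable sub-seed for a named stage/object (below 2**31)."""
    digest = hashlib.sha256(f"{label}:{int(seed)}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# --------------------------------------------------------------------------
# hyperspectral cubes


@dataclass
class GeneratorConfig:
    """Geometry and noise terms of one synthetic hyperspectral cube."""

    grid_hi: float = 1800.0  # cm^-1; wider than the analysed range so the
    grid_lo: float = 900.0  # 1800-1600 quality window exists
    grid_step: float = 3.93  # cm^-1, the instrument sampling rate
    pixels_x: int = 64
    pixels_y: int = 64
    pixel_pitch_um: float = 1.1
    noise_sd: float = 0.008  # a.u., iid per channel
    baseline_coeffs_sd: float = 0.02  # a.u., random per-pixel quadratic baseline
    heterogeneity_sd: float = 0.10  # log-sd of per-pixel per-family jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.grid_hi <= self.grid_lo:
            raise ValueError("grid_hi must exceed grid_lo")
        if min(self.noise_sd, self.baseline_coeffs_sd, self.heterogeneity_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.pixels_x < 1 or self.pixels_y < 1:
            raise ValueError("cube must have at least one pixel")

    def grid(self) -> np.ndarray:
        return build_grid(self.grid_hi, self.grid_lo, self.grid_step)


def generate_cube(
    config: GeneratorConfig,
    profile: ZoneGroupProfile,
    bands: list[BandModel],
) -> SpectralCube:
    """One synthetic cube for the (zone, group) cell described by ``profile``."""
    if not bands:
        raise ValueError("band list must not be empty")
    grid = config.grid()
    ny, nx, m = config.pixels_y, config.pixels_x, grid.size
    rng = np.random.default_rng(config.seed)

    # family signatures: sum of member bands on the grid
    signatures = np.zeros((len(FAMILIES), m))
    for band in bands:
        signatures[FAMILIES.index(band.family)] += band.profile(grid)
    multipliers = np.array([profile.multiplier(f) for f in FAMILIES])

    # per-pixel per-family log-normal jitter with unit mean
    s = config.heterogeneity_sd
    if s > 0:
        jitter = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=(ny, nx, len(FAMILIES)))
    else:
        jitter = np.ones((ny, nx, len(FAMILIES)))

    data = np.einsum("yxf,f,fm->yxm", jitter, multipliers, signatures)

    # random quadratic baseline per pixel on a centred, scaled axis
    u = (grid - grid.mean()) / (grid[0] - grid[-1])
    coeffs = rng.normal(0.0, config.baseline_coeffs_sd, size=(ny, nx, 3))
    data += coeffs[..., 0:1] + coeffs[..., 1:2] * u + coeffs[..., 2:3] * u**2

    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)

    return SpectralCube(
        grid=grid,
        data=data,
        pixel_pitch_um=config.pixel_pitch_um,
        zone=profile.zone,
        group=profile.group,
        meta={"seed": config.seed},
    )


# --------------------------------------------------------------------------
# force-indentation curves


#: Ground-truth Young's moduli per (group, zone), kPa.  The deep zone is a
#: two-component equal-weight mixture (proteoglycan phase, collagen phase).
ZONE_MODULI: dict[tuple[str, str], list[tuple[float, float]]] = {
    ("C", "SZ"): [(33.88, 1.0)],
    ("HMB", "SZ"): [(88.82, 1.0)],
    ("C", "MZ"): [(29.16, 1.0)],
    ("HMB", "MZ"): [(80.02, 1.0)],
    ("C", "DZ"): [(40.02, 0.5), (77.58, 0.5)],
    ("HMB", "DZ"): [(42.72, 0.5), (81.38, 0.5)],
}


def hertz_prefactor(alpha_deg: float, nu: float) -> float:
    """Geometry factor 2 tan(alpha) / (pi (1 - nu^2)) of the contact law."""
    if not 0.0 < alpha_deg < 90.0:
        raise ValueError("tip half-opening angle must lie in (0, 90) degrees")
    if not 0.0 <= nu < 1.0:
        raise ValueError("Poisson ratio must lie in [0, 1)")
    return 2.0 * np.tan(np.deg2rad(alpha_deg)) / (np.pi * (1.0 - nu**2))


def hertz_force(depth_nm: np.ndarray, E_kpa: float, alpha_deg: float = 17.5, nu: float = 0.5) -> np.ndarray:
    """Force in nN at indentation depth in nm for modulus E in kPa."""
    d = np.asarray(depth_nm, dtype=float)
    # E[Pa] * delta^2[m^2] -> N; kPa and nm fold into a 1e-6 factor to nN
    return hertz_prefactor(alpha_deg, nu) * E_kpa * d**2 * 1e-6


@dataclass
class ForceCurveConfig:
    """Ground truth and noise terms of one synthetic force-indentation curve."""

    E_true: float | list[tuple[float, float]] = 33.88  # kPa, or [(kPa, weight), ...]
    alpha: float = 17.5  # tip half-opening angle, degrees
    nu: float = 0.5  # Poisson ratio of soft biological tissue
    max_depth: float = 500.0  # nm
    n_points: int = 100
    force_noise_sd: float = 0.0  # nN
    contact_offset: float = 0.0  # nm
    modulus_sd: float = 0.0  # kPa spread around each mixture component
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("need at least 3 points per curve")
        if not 0.0 < self.alpha < 90.0:
            raise ValueError("alpha must lie in (0, 90) degrees")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("nu must lie in [0, 0.5]")
        comps = self.components()
        if any(e <= 0 for e, _ in comps):
            raise ValueError("ground-truth moduli must be positive")
        if abs(sum(w for _, w in comps) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def components(self) -> list[tuple[float, float]]:
        if isinstance(self.E_true, (int, float)):
            return [(float(self.E_true), 1.0)]
        return [(float(e), float(w)) for e, w in self.E_true]


def sample_moduli(
    components: list[tuple[float, float]],
    n: int,
    sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` moduli (kPa) from a Gaussian mixture around the components."""
    rng = np.random.default_rng(seed)
    centers = np.array([c for c, _ in components])
    weights = np.array([w for _, w in components])
    idx = rng.choice(len(centers), size=n, p=weights / weights.sum())
    draws = centers[idx]
    if sd > 0:
        draws = draws + rng.normal(0.0, sd, size=n)
    return np.abs(draws)


def generate_force_curve(config: ForceCurveConfig):
    """One synthetic indentation curve; modulus drawn from the mixture."""
    from .indentation import ForceCurve  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed)
    E = float(sample_moduli(config.components(), 1, config.modulus_sd, seed=rng.integers(2**31))[0])
    depth = np.linspace(0.0, config.max_depth, config.n_points)
    contact = np.clip(depth - config.contact_offset, 0.0, None)
    force = hertz_force(contact, E, config.alpha, config.nu)
    if config.force_noise_sd > 0:
        force = force + rng.normal(0.0, config.force_noise_sd, size=force.shape)
    return ForceCurve(depth=depth, force=force, meta={"E_true_kpa": E, "alpha_deg": config.alpha, "nu": config.nu})


# --------------------------------------------------------------------------
# whole-study simulation


@dataclass
class StudyConfig:
    """The full two-group, five-animal, three-zone study design."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_animals: int = 5
    groups: tuple[str, ...] = GROUPS
    zones: tuple[str, ...] = ZONES
    # biological between-animal variation (log-normal CVs)
    animal_family_sd: float = 0.01  # per-family composition jitter
    animal_scale_sd: float = 0.01  # global section-thickness/intensity scale
    pg_sz_ratio: float = 1.20
    # AFM side of the study: one 25 x 25 indentation map per (group, zone)
    n_curves: int = 625
    curve_points: int = 100
    force_noise_sd: float = 0.02  # nN
    modulus_sd: float = 4.0  # kPa within-zone spread of the modulus

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be at least 1")


def _animal_profile(
    base: ZoneGroupProfile, cfg: StudyConfig, seed: int, group: str, animal: int
) -> ZoneGroupProfile:
    rng = np.random.default_rng(derive_seed(seed, f"animal:{group}:{animal}"))
    sf, ss = cfg.animal_family_sd, cfg.animal_scale_sd
    fam = rng.lognormal(-0.5 * sf * sf, sf, size=len(FAMILIES)) if sf > 0 else np.ones(len(FAMILIES))
    scale = rng.lognormal(-0.5 * ss * ss, ss) if ss > 0 else 1.0
    return base.scaled({f: scale * fam[i] for i, f in enumerate(FAMILIES)})


def iter_cubes(cfg: StudyConfig, seed: int):
    """Yield every cube of the study (group-major, then animal, then zone)."""
    profiles = default_profiles(pg_sz_ratio=cfg.pg_sz_ratio)
    for group in cfg.groups:
        for animal in range(1, cfg.n_animals + 1):
            animal_id = f"{group}{animal:02d}"
            for zone in cfg.zones:
                profile = _animal_profile(profiles[(zone, group)], cfg, seed, group, animal)
                gen = GeneratorConfig(
                    **{**asdict(cfg.generator), "seed": derive_seed(seed, f"cube:{animal_id}:{zone}")}
                )
                cube = generate_cube(gen, profile, default_bands(zone))
                cube.animal_id = animal_id
                yield cube


def study_force_curves(cfg: StudyConfig, seed: int, group: str, zone: str):
    """The 25 x 25 indentation-map curves for one (group, zone) cell."""
    curves = []
    for i in range(cfg.n_curves):
        fc = ForceCurveConfig(
            E_true=ZONE_MODULI[(group, zone)],
            n_points=cfg.curve_points,
            force_noise_sd=cfg.force_noise_sd,
            modulus_sd=cfg.modulus_sd,
            seed=derive_seed(seed, f"curve:{group}:{zone}:{i}"),
        )
        curve = generate_force_curve(fc)
        curve.meta.update(curve_id=f"{group}-{zone}-{i:04d}", group=group, zone=zone)
        curves.append(curve)
    return curves


def write_study(cfg: StudyConfig, out_dir: str | Path, seed: int) -> dict:
    """Write the full study (cubes + curves + manifest) under ``out_dir``.

    Layout: ``<group>/<animal>/<zone>/cube.{csv,json}`` plus
    ``curves/<group>_<zone>/curves.csv`` and a top-level ``manifest.json``.
    Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for cube in iter_cubes(cfg, seed):
        sub = out_dir / cube.group / cube.animal_id / cube.zone
        files = cube.to_dir(sub)
        entries.append(
            {
                "kind": "cube",
                "group": cube.group,
                "animal_id": cube.animal_id,
                "zone": cube.zone,
                "seed": cube.meta["seed"],
                "files": [str(f.relative_to(out_dir)) for f in files],
            }
        )
    for group in cfg.groups:
        for zone in cfg.zones:
            curves = study_force_curves(cfg, seed, group, zone)
            sub = out_dir / "curves" / f"{group}_{zone}"
            sub.mkdir(parents=True, exist_ok=True)
            rows = []
            for curve in curves:
                for d, f in zip(curve.depth, curve.force):
                    rows.append((curve.meta["curve_id"], d, f))
            frame = pd.DataFrame(rows, columns=["curve_id", "depth_nm", "force_nN"])
            frame.to_csv(sub / "curves.csv", index=False, float_format="%.9g")
            sidecar = {
                "alpha_deg": 17.5,
                "nu": 0.5,
                "spring_constant_N_per_m": 0.1,
                "group": group,
                "zone": zone,
                "n_curves": cfg.n_curves,
                "seed": derive_seed(seed, f"curve:{group}:{zone}:0"),
            }
            (sub / "curves.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
            entries.append(
                {
                    "kind": "curves",
                    "group": group,
                    "zone": zone,
                    "seed": sidecar["seed"],
                    "files": [
                        str((sub / "curves.csv").relative_to(out_dir)),
                        str((sub / "curves.json").relative_to(out_dir)),
                    ],
                }
            )
    manifest = {
        "design": {
            "groups": list(cfg.groups),
            "zones": list(cfg.zones),
            "n_animals": cfg.n_animals,
        },
        "seed": int(seed),
        "entries": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
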