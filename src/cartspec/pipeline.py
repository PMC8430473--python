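"""End-to-end pipeline orchestration with a validated config and manifest.

Stages mirror the analysis flow: ``simulate`` writes the synthetic study,
``preprocess`` applies QC + spectral preprocessing, ``map`` produces
chemical maps and the zone-wise group-comparison table, ``indent`` fits
the indentation curves and the modulus-histogram peaks, ``multivariate``
assembles the 450 x 196 matrix and runs correlation-mode PCA, ``nets``
trains the MLP and SOM and runs the sensitivity analysis.  ``full`` runs
everything in order and writes a run manifest.

Every stage derives its own seed from the global seed and the stage name,
so any stage is re-runnable in isolation with identical output.
"""

from __future__ import annotations

import hashlib
import json
import time

from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import indentation as ind
from . import mapping, multivariate, neural, preprocess, synth
from .spectra import GROUPS, ZONES, SpectralCube

FLOAT_FMT = "%.12g"


# --------------------------------------------------------------------------
# configuration schema (unknown keys rejected)


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneratorBlock(_Block):
    grid_hi: float = 1800.0
    grid_lo: float = 900.0
    grid_step: float = 3.93
    pixels_x: int = 64
    pixels_y: int = 64
    pixel_pitch_um: float = 1.1
    noise_sd: float = 0.008
    baseline_coeffs_sd: float = 0.02
    heterogeneity_sd: float = 0.10


class StudyBlock(_Block):
    generator: GeneratorBlock = GeneratorBlock()
    n_animals: int = 5
    animal_family_sd: float = 0.01
    animal_scale_sd: float = 0.01
    pg_sz_ratio: float = 1.20
    n_curves: int = 625
    curve_points: int = 100
    force_noise_sd: float = 0.02
    modulus_sd: float = 4.0


class PreprocessBlock(_Block):
    smooth_window: int = 9
    smooth_polyorder: int = 2
    baseline_order: int = 2
    crop_hi: float = 1730.0
    crop_lo: float = 900.0
    amax_lo: float = 0.1
    amax_hi: float = 2.0
    snr_min: float = 10.0


class MappingBlock(_Block):
    cc_window: tuple[float, float] = mapping.CC_WINDOW
    pg_window: tuple[float, float] = mapping.PG_WINDOW
    ch_window: tuple[float, float] = mapping.CH_WINDOW
    amide_ii_window: tuple[float, float] = mapping.AMIDE_II_WINDOW
    n_rois: int = 5
    roi_size: tuple[int, int] = (10, 10)
    alpha: float = 0.05


class IndentBlock(_Block):
    alpha_deg: float = 17.5
    nu: float = 0.5
    max_fit_depth: float = 500.0
    estimate_contact: bool = False
    bin_width: float | None = None


class MatrixBlock(_Block):
    spectra_per_sample: int = 15
    region_hi: float = 1730.0
    region_lo: float = 960.0


class SplitBlock(_Block):
    ratios: tuple[float, float, float] = (75.0, 15.0, 15.0)
    stratified: bool = True


class MLPBlock(_Block):
    n_hidden: int = 18
    optimizer: str = "bfgs"
    epochs: int = 100
    learning_rate: float = 0.01
    momentum: float = 0.80
    accept_threshold: float = 0.95
    reject_threshold: float = 0.05


class SOMBlock(_Block):
    grid: tuple[int, int] = (5, 5)
    epochs: int = 1000
    alpha_start: float = 0.9
    alpha_end: float = 0.01
    radius_start: float = 5.0
    radius_end: float = 0.0


class PipelineConfig(_Block):
    seed: int = 0
    study: StudyBlock = StudyBlock()
    preprocessing: PreprocessBlock = PreprocessBlock()
    mapping: MappingBlock = MappingBlock()
    indentation: IndentBlock = IndentBlock()
    matrix: MatrixBlock = MatrixBlock()
    split: SplitBlock = SplitBlock()
    mlp: MLPBlock = MLPBlock()
    som: SOMBlock = SOMBlock()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        return cls.model_validate(data)

    def study_config(self) -> synth.StudyConfig:
        g = self.study.generator
        return synth.StudyConfig(
            generator=synth.GeneratorConfig(**g.model_dump()),
            n_animals=self.study.n_animals,
            animal_family_sd=self.study.animal_family_sd,
            animal_scale_sd=self.study.animal_scale_sd,
            pg_sz_ratio=self.study.pg_sz_ratio,
            n_curves=self.study.n_curves,
            curve_points=self.study.curve_points,
            force_noise_sd=self.study.force_noise_sd,
            modulus_sd=self.study.modulus_sd,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(config: PipelineConfig, stage: str) -> int:
    return synth.derive_seed(config.seed, f"stage:{stage}")


# --------------------------------------------------------------------------
# manifest helpers


def _load_manifest(out: Path) -> dict:
    path = out / "run_manifest.json"
    if path.exists():
        return json.loads(path.read_text())
    return {"stages": {}}


def _record_stage(out: Path, config: PipelineConfig, stage: str, files: list[Path], t0: float) -> None:
    manifest = _load_manifest(out)
    manifest["config_hash"] = config.config_hash()
    manifest["stages"][stage] = {
        "seed": stage_seed(config, stage),
        "outputs": sorted(str(f.relative_to(out)) for f in files),
        "wall_time_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def manifest_fingerprint(manifest: dict) -> str:
    """Hash of the manifest with volatile keys (timestamps, wall time) removed."""
    clean = {
        "config_hash": manifest.get("config_hash"),
        "stages": {
            name: {k: v for k, v in stage.items() if k not in ("timestamp", "wall_time_s")}
            for name, stage in manifest.get("stages", {}).items()
        },
    }
    return hashlib.sha256(json.dumps(clean, sort_keys=True).encode()).hexdigest()


def _require(path: Path, stage: str, needed_by: str) -> None:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' requires outputs of stage '{stage}' at {path}; run it first"
        )


# --------------------------------------------------------------------------
# in-memory core used by both the CLI stages and the acceptance analysis


def analyze_chemistry(
    config: PipelineConfig, seed: int | None = None, keep_matrix_entries: bool = True
) -> dict:
    """Generate + preprocess + map the whole study in memory.

    Returns a dict with the per-ROI table, per-animal means, the group
    comparison table, QC summaries and (optionally) the (cube, ROI) pairs
    of normalized spectra for matrix assembly.  Cubes are processed one at
    a time to bound memory.
    """
    seed = config.seed if seed is None else seed
    study_cfg = config.study_config()
    pp, mp = config.preprocessing, config.mapping
    roi_rows, qc_rows, entries = [], [], []
    region = (config.matrix.region_hi, config.matrix.region_lo)
    for cube in synth.iter_cubes(study_cfg, synth.derive_seed(seed, "stage:simulate")):
        _, qc = preprocess.cube_quality(cube, amax_bounds=(pp.amax_lo, pp.amax_hi), snr_min=pp.snr_min)
        qc_rows.append({"animal_id": cube.animal_id, "zone": cube.zone, **qc})
        roi_seed = synth.derive_seed(seed, f"roi:{cube.animal_id}:{cube.zone}")
        rois = preprocess.extract_rois(cube, n=mp.n_rois, size=tuple(mp.roi_size), seed=roi_seed)

        corrected = preprocess.preprocess_cube(
            cube,
            smooth_window=pp.smooth_window,
            smooth_polyorder=pp.smooth_polyorder,
            baseline_order=pp.baseline_order,
            normalize=None,
            crop_bounds=(pp.crop_hi, pp.crop_lo),
        )
        cmap = mapping.compute_maps(
            corrected,
            cc_window=tuple(mp.cc_window),
            pg_window=tuple(mp.pg_window),
            ch_window=tuple(mp.ch_window),
            amide_ii_window=tuple(mp.amide_ii_window),
        )
        roi_rows.append(mapping.zone_statistics(cmap, rois))

        if keep_matrix_entries:
            normalized = preprocess.preprocess_cube(
                cube,
                smooth_window=pp.smooth_window,
                smooth_polyorder=pp.smooth_polyorder,
                baseline_order=pp.baseline_order,
                normalize="global",
                crop_bounds=region,
            )
            # keep only ROI pixels to bound memory across the 30 cubes
            keep = np.zeros((normalized.ny, normalized.nx), dtype=bool)
            for x0, y0, w, h in rois:
                keep[y0 : y0 + h, x0 : x0 + w] = True
            slim = SpectralCube(
                grid=normalized.grid,
                data=np.where(keep[..., None], normalized.data, 0.0),
                pixel_pitch_um=normalized.pixel_pitch_um,
                zone=normalized.zone,
                group=normalized.group,
                animal_id=normalized.animal_id,
                meta=normalized.meta,
            )
            entries.append((slim, rois))

    roi_stats = pd.concat(roi_rows, ignore_index=True)
    per_animal = mapping.per_animal_means(roi_stats)
    comparisons = mapping.group_comparison_table(per_animal, alpha=mp.alpha)
    return {
        "roi_stats": roi_stats,
        "per_animal": per_animal,
        "comparisons": comparisons,
        "qc": pd.DataFrame(qc_rows),
        "matrix_entries": entries if keep_matrix_entries else None,
    }


def build_data_matrix(config: PipelineConfig, entries, seed: int | None = None):
    seed = config.seed if seed is None else seed
    dm = multivariate.assemble_matrix(
        entries,
        spectra_per_sample=config.matrix.spectra_per_sample,
        seed=synth.derive_seed(seed, "stage:multivariate"),
    )
    return dm


def run_networks(config: PipelineConfig, dm, seed: int | None = None) -> dict:
    """Split, standardize, train MLP + SOM, sensitivity — all in memory."""
    seed = config.seed if seed is None else seed
    std = multivariate.standardize(dm)
    class_names = sorted(np.unique(std.class_labels()).tolist())
    y = np.array([class_names.index(c) for c in std.class_labels()])
    split = neural.split_data(
        std.class_labels(),
        neural.SplitConfig(
            ratios=tuple(config.split.ratios),
            stratified=config.split.stratified,
            seed=synth.derive_seed(seed, "stage:split"),
        ),
    )
    mlp_cfg = neural.MLPConfig(
        n_inputs=std.m,
        n_hidden=config.mlp.n_hidden,
        n_outputs=len(class_names),
        optimizer=config.mlp.optimizer,
        epochs=config.mlp.epochs,
        learning_rate=config.mlp.learning_rate,
        momentum=config.mlp.momentum,
        accept_threshold=config.mlp.accept_threshold,
        reject_threshold=config.mlp.reject_threshold,
        seed=synth.derive_seed(seed, "stage:mlp"),
    )
    model, report = neural.train_mlp(std.X, y, split, class_names, mlp_cfg)
    sens = neural.sensitivity(model, std.X[split.train], y[split.train], wavenumbers=std.wavenumbers)

    som_cfg = neural.SOMConfig(
        grid_shape=tuple(config.som.grid),
        epochs=config.som.epochs,
        alpha_start=config.som.alpha_start,
        alpha_end=config.som.alpha_end,
        radius_start=config.som.radius_start,
        radius_end=config.som.radius_end,
        seed=synth.derive_seed(seed, "stage:som"),
    )
    som = neural.SOM(som_cfg).fit(std.X[split.train])
    qe = {
        name: neural.quantization_error(som, std.X[idx])
        for name, idx in (("teaching", split.train), ("test", split.test), ("validation", split.validation))
        if idx.size
    }
    clusters = neural.map_clusters(som, std.X, std.class_labels())
    return {
        "standardized": std,
        "class_names": class_names,
        "y": y,
        "split": split,
        "mlp": model,
        "mlp_report": report,
        "sensitivity": sens,
        "som": som,
        "qe": qe,
        "clusters": clusters,
    }


# --------------------------------------------------------------------------
# disk-backed stages (CLI surface)


def cmd_simulate(config: PipelineConfig, out: str | Path) -> dict:
    out = Path(out)
    t0 = time.time()
    study_dir = out / "study"
    manifest = synth.write_study(config.study_config(), study_dir, stage_seed(config, "simulate"))
    files = [study_dir / f for e in manifest["entries"] for f in e["files"]]
    files.append(study_dir / "manifest.json")
    _record_stage(out, config, "simulate", files, t0)
    return manifest


def _iter_study_cubes(study_dir: Path):
    manifest = json.loads((study_dir / "manifest.json").read_text())
    for entry in manifest["entries"]:
        if entry["kind"] != "cube":
            continue
        yield SpectralCube.from_dir(study_dir / Path(entry["files"][0]).parent)


def cmd_preprocess(config: PipelineConfig, out: str | Path) -> pd.DataFrame:
    out = Path(out)
    _require(out / "study" / "manifest.json", "simulate", "preprocess")
    t0 = time.time()
    pp = config.preprocessing
    dest = out / "preprocessed"
    qc_rows, files = [], []
    for cube in _iter_study_cubes(out / "study"):
        _, qc = preprocess.cube_quality(cube, amax_bounds=(pp.amax_lo, pp.amax_hi), snr_min=pp.snr_min)
        qc_rows.append({"animal_id": cube.animal_id, "zone": cube.zone, **qc})
        corrected = preprocess.preprocess_cube(
            cube,
            smooth_window=pp.smooth_window,
            smooth_polyorder=pp.smooth_polyorder,
            baseline_order=pp.baseline_order,
            normalize=None,
            crop_bounds=(pp.crop_hi, pp.crop_lo),
        )
        files += corrected.to_dir(dest / cube.group / cube.animal_id / cube.zone)
    qc_frame = pd.DataFrame(qc_rows)
    qc_path = dest / "qc_report.csv"
    qc_frame.to_csv(qc_path, index=False, float_format=FLOAT_FMT)
    files.append(qc_path)
    _record_stage(out, config, "preprocess", files, t0)
    return qc_frame


def cmd_map(config: PipelineConfig, out: str | Path) -> pd.DataFrame:
    out = Path(out)
    _require(out / "preprocessed", "preprocess", "map")
    t0 = time.time()
    mp = config.mapping
    dest = out / "maps"
    dest.mkdir(parents=True, exist_ok=True)
    roi_rows, files = [], []
    for cube in _iter_preprocessed(out / "preprocessed"):
        roi_seed = synth.derive_seed(config.seed, f"roi:{cube.animal_id}:{cube.zone}")
        rois = preprocess.extract_rois(cube, n=mp.n_rois, size=tuple(mp.roi_size), seed=roi_seed)
        cmap = mapping.compute_maps(
            cube,
            cc_window=tuple(mp.cc_window),
            pg_window=tuple(mp.pg_window),
            ch_window=tuple(mp.ch_window),
            amide_ii_window=tuple(mp.amide_ii_window),
        )
        sub = dest / cube.group / f"{cube.animal_id}_{cube.zone}"
        sub.mkdir(parents=True, exist_ok=True)
        for name in ("cc", "ci", "pg"):
            path = sub / f"{name}.csv"
            np.savetxt(path, getattr(cmap, name), delimiter=",", fmt=FLOAT_FMT)
            files.append(path)
        sidecar = sub / "map.json"
        sidecar.write_text(
            json.dumps(
                {
                    "zone": cube.zone,
                    "group": cube.group,
                    "animal_id": cube.animal_id,
                    "rois": [list(r) for r in rois],
                    "windows": {
                        "cc": list(mp.cc_window),
                        "pg": list(mp.pg_window),
                        "ch": list(mp.ch_window),
                        "amide_ii": list(mp.amide_ii_window),
                    },
                },
                indent=1,
                sort_keys=True,
            )
        )
        files.append(sidecar)
        roi_rows.append(mapping.zone_statistics(cmap, rois))
    roi_stats = pd.concat(roi_rows, ignore_index=True)
    per_animal = mapping.per_animal_means(roi_stats)
    comparisons = mapping.group_comparison_table(per_animal, alpha=mp.alpha)
    for name, frame in (("roi_stats", roi_stats), ("per_animal", per_animal), ("group_comparisons", comparisons)):
        path = dest / f"{name}.csv"
        frame.to_csv(path, index=False, float_format=FLOAT_FMT)
        files.append(path)
    _record_stage(out, config, "map", files, t0)
    return comparisons


def _iter_preprocessed(root: Path):
    for sidecar in sorted(root.glob("*/*/*/cube.json")):
        yield SpectralCube.from_dir(sidecar.parent)


def cmd_indent(config: PipelineConfig, out: str | Path) -> pd.DataFrame:
    out = Path(out)
    _require(out / "study", "simulate", "indent")
    t0 = time.time()
    ib = config.indentation
    params = ind.IndenterParams(alpha=ib.alpha_deg, nu=ib.nu, max_fit_depth=ib.max_fit_depth)
    dest = out / "indentation"
    dest.mkdir(parents=True, exist_ok=True)
    files, rows, peaks = [], [], {}
    moduli_by_cell: dict[tuple[str, str], np.ndarray] = {}
    for group in GROUPS:
        for zone in ZONES:
            curve_dir = out / "study" / "curves" / f"{group}_{zone}"
            _require(curve_dir / "curves.csv", "simulate", "indent")
            frame = pd.read_csv(curve_dir / "curves.csv")
            cell_rows = []
            for curve_id, sub in frame.groupby("curve_id", sort=True):
                curve = ind.ForceCurve(sub["depth_nm"].to_numpy(), sub["force_nN"].to_numpy())
                fit = ind.fit_hertz(curve, params, estimate_contact=ib.estimate_contact)
                cell_rows.append({"curve_id": curve_id, "E_kPa": fit.E, "rss": fit.rss})
            cell = pd.DataFrame(cell_rows)
            moduli = cell["E_kPa"].to_numpy()
            moduli_by_cell[(group, zone)] = moduli
            path = dest / f"moduli_{group}_{zone}.csv"
            cell.to_csv(path, index=False, float_format=FLOAT_FMT)
            files.append(path)
            hist = ind.build_histogram(moduli, bin_width=ib.bin_width)
            n_comp = 2 if zone == "DZ" else 1
            fitres = ind.fit_gaussian_peaks(hist, n_components=n_comp, seed=stage_seed(config, "indent"))
            peaks[f"{group}_{zone}"] = {
                "centers_kPa": fitres.centers.tolist(),
                "widths_kPa": fitres.widths.tolist(),
                "r2": fitres.goodness,
                "n_curves": int(moduli.size),
            }
            rows.append({"group": group, "zone": zone, "mean_E_kPa": float(moduli.mean())})
    comparisons = []
    for zone in ZONES:
        p, sig = ind.compare_moduli(moduli_by_cell[("C", zone)], moduli_by_cell[("HMB", zone)])
        comparisons.append({"zone": zone, "p": p, "significant": sig})
    peaks_path = dest / "peaks.json"
    peaks_path.write_text(json.dumps(peaks, indent=1, sort_keys=True))
    comp_path = dest / "modulus_comparisons.csv"
    pd.DataFrame(comparisons).to_csv(comp_path, index=False, float_format=FLOAT_FMT)
    files += [peaks_path, comp_path]
    _record_stage(out, config, "indent", files, t0)
    return pd.DataFrame(rows)


def cmd_multivariate(config: PipelineConfig, out: str | Path) -> multivariate.PCAResult:
    out = Path(out)
    _require(out / "study", "simulate", "multivariate")
    t0 = time.time()
    pp, mp = config.preprocessing, config.matrix
    entries = []
    for cube in _iter_study_cubes(out / "study"):
        roi_seed = synth.derive_seed(config.seed, f"roi:{cube.animal_id}:{cube.zone}")
        rois = preprocess.extract_rois(
            cube, n=config.mapping.n_rois, size=tuple(config.mapping.roi_size), seed=roi_seed
        )
        normalized = preprocess.preprocess_cube(
            cube,
            smooth_window=pp.smooth_window,
            smooth_polyorder=pp.smooth_polyorder,
            baseline_order=pp.baseline_order,
            normalize="global",
            crop_bounds=(mp.region_hi, mp.region_lo),
        )
        entries.append((normalized, rois))
    dm = build_data_matrix(config, entries)
    std = multivariate.standardize(dm)
    res = multivariate.pca(std)
    dest = out / "multivariate"
    dest.mkdir(parents=True, exist_ok=True)
    k = max(multivariate.select_components(res.eigenvalues, "kaiser"), 2)
    files = []
    matrix_path = dest / "data_matrix.csv"
    matrix_frame = pd.DataFrame(dm.X, columns=[f"{w:.4f}" for w in dm.wavenumbers])
    pd.concat([dm.labels.reset_index(drop=True), matrix_frame], axis=1).to_csv(
        matrix_path, index=False, float_format=FLOAT_FMT
    )
    scores_path = dest / "pca_scores.csv"
    scores = pd.DataFrame(res.scores[:, :k], columns=[f"PC{i+1}" for i in range(k)])
    pd.concat([dm.labels.reset_index(drop=True), scores], axis=1).to_csv(
        scores_path, index=False, float_format=FLOAT_FMT
    )
    loadings_path = dest / "pca_loadings.csv"
    loadings = pd.DataFrame(res.loadings[:, :k], columns=[f"PC{i+1}" for i in range(k)])
    loadings.insert(0, "wavenumber", dm.wavenumbers)
    loadings.to_csv(loadings_path, index=False, float_format=FLOAT_FMT)
    summary_path = dest / "pca_summary.json"
    summary_path.write_text(
        json.dumps(
            {
                "eigenvalues": res.eigenvalues[: max(k, 10)].tolist(),
                "explained_pct": res.explained_pct[: max(k, 10)].tolist(),
                "kaiser_k": multivariate.select_components(res.eigenvalues, "kaiser"),
                "scree_k": multivariate.select_components(res.eigenvalues, "scree"),
                "d": dm.d,
                "m": dm.m,
            },
            indent=1,
        )
    )
    files += [matrix_path, scores_path, loadings_path, summary_path]
    _record_stage(out, config, "multivariate", files, t0)
    return res


def cmd_nets(config: PipelineConfig, out: str | Path) -> dict:
    out = Path(out)
    matrix_path = out / "multivariate" / "data_matrix.csv"
    _require(matrix_path, "multivariate", "nets")
    t0 = time.time()
    frame = pd.read_csv(matrix_path)
    label_cols = ["zone", "group", "animal_id"]
    wn = np.array([float(c) for c in frame.columns if c not in label_cols])
    dm = multivariate.DataMatrix(
        X=frame.drop(columns=label_cols).to_numpy(float),
        labels=frame[label_cols],
        wavenumbers=wn,
    )
    result = run_networks(config, dm)
    dest = out / "nets"
    dest.mkdir(parents=True, exist_ok=True)
    files = []
    conf_path = dest / "confusion.csv"
    result["mlp_report"].confusion.to_csv(conf_path, float_format=FLOAT_FMT)
    files.append(conf_path)
    proba = result["mlp"].predict_proba(result["standardized"].X)
    for i, name in enumerate(result["class_names"]):
        path = dest / f"gain_{name}.csv"
        neural.gain_curve(proba, result["y"], i).to_csv(path, index=False, float_format=FLOAT_FMT)
        files.append(path)
    sens_path = dest / "sensitivity.csv"
    pd.DataFrame(
        {
            "wavenumber": result["standardized"].wavenumbers,
            "ratio": result["sensitivity"].ratios,
            "important": result["sensitivity"].important,
        }
    ).to_csv(sens_path, index=False, float_format=FLOAT_FMT)
    files.append(sens_path)
    som_path = dest / "som_map.csv"
    clusters = result["clusters"]
    som = result["som"]
    pd.DataFrame(
        {
            "neuron": np.arange(som.n_neurons),
            "grid_y": som.grid_coords[:, 0].astype(int),
            "grid_x": som.grid_coords[:, 1].astype(int),
            "majority_class": [str(c) for c in clusters.neuron_class],
            "hits": clusters.hit_counts,
        }
    ).to_csv(som_path, index=False, float_format=FLOAT_FMT)
    files.append(som_path)
    report_path = dest / "nets_report.json"
    report_path.write_text(
        json.dumps(
            {
                "recognition": result["mlp_report"].recognition,
                "final_loss": result["mlp_report"].loss_history[-1],
                "qe": result["qe"],
                "n_clusters": clusters.n_clusters,
                "count_important": result["sensitivity"].count_important,
            },
            indent=1,
            sort_keys=True,
        )
    )
    files.append(report_path)
    _record_stage(out, config, "nets", files, t0)
    return result


def cmd_full(config: PipelineConfig, out: str | Path) -> dict:
    out = Path(out)
    cmd_simulate(config, out)
    cmd_preprocess(config, out)
    comparisons = cmd_map(config, out)
    moduli = cmd_indent(config, out)
    pca_res = cmd_multivariate(config, out)
    nets = cmd_nets(config, out)
    return {"comparisons": comparisons, "moduli": moduli, "pca": pca_res, "nets": nets}
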