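"""End-to-end orchestration: phantom -> quantify -> labels -> study.

The pipeline works on a simple directory layout, one sub-directory per
patient holding co-registered NIfTI volumes:

    <cohort>/<patient_id>/dce.nii.gz          4D dynamic series
                          adc.nii.gz, t2w.nii.gz
                          prostate_mask.nii.gz, tumour_mask.nii.gz
                          grade_map.nii.gz

``run_quantify`` writes the seven semi-quantitative maps, iAUGC60 and
(Ktrans, Ve) under each configured AIF; ``run_labels`` builds the
tumour / excluded-ring / benign label grid; ``run_study`` pools analysed
voxels across patients into the feature table (dropping Tonset, Twashout and
IRW, which are unstable at this sampling), computes the effect-size report
and correlation matrices, prunes correlated features and runs the classifier
grid.  Every stage writes a manifest (config hash, seed, constants version)
sufficient to reproduce its outputs bit-wise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aif import AIF_CONSTANTS, AifSpec, evaluate_aif
from .cad import grid_report, run_model_grid
from .conversion import acquisition_preset, convert_volume
from .io import load_dce, load_volume, save_volume, write_sidecar
from .masks import DEFAULT_MARGIN_MM, LABEL_CODES, build_labels, stratify_by_grade
from .phantom import PhantomSpec, generate_cohort
from .semiquant import fit_semiquant_volume
from .stats import correlation_prune, effect_size_report
from .tofts import fit_tofts_volume, iaugc60_volume

__all__ = [
    "RunConfig",
    "write_phantom_cohort",
    "run_quantify",
    "run_labels",
    "build_feature_table",
    "run_study",
]

log = logging.getLogger("dceprost")

#: semi-quantitative maps written by run_quantify, in export order
SEMIQUANT_MAPS = ("t_onset", "ire", "ttp", "me", "t_washout", "irw", "auc")

#: feature columns entering the study (Tonset/Twashout/IRW are computed and
#: exported but excluded from statistics and classification)
STUDY_FEATURES = (
    "t2w",
    "adc",
    "ttp",
    "ire",
    "me",
    "auc",
    "ktrans_parker",
    "ve_parker",
    "ktrans_weinmann",
    "ve_weinmann",
    "iaugc60",
)


@dataclass
class RunConfig:
    """Configuration of a pipeline run; defaults mirror the study constants."""

    input_dir: str = "."
    output_dir: str = "out"
    acquisition: str = "60x7.2"
    aif_models: tuple[str, ...] = ("parker", "weinmann")
    dose: float = 0.1
    hematocrit: float = 0.42
    onset_time: float | None = None  # None -> end of the baseline frames
    margin_mm: float = DEFAULT_MARGIN_MM
    corr_threshold: float = 0.65
    downsample_ratio: float = 1.0
    test_fraction: float = 0.20
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.corr_threshold < 1:
            raise ValueError("corr_threshold must lie in (0, 1)")
        if self.margin_mm < 0:
            raise ValueError("margin_mm must be >= 0")
        acquisition_preset(self.acquisition)  # raises on unknown preset

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "aif_models" in payload:
            payload["aif_models"] = tuple(payload["aif_models"])
        return cls(**payload)

    @property
    def acq(self):
        return acquisition_preset(self.acquisition)

    def resolved_onset(self) -> float:
        if self.onset_time is not None:
            return float(self.onset_time)
        acq = self.acq
        return acq.n_baseline * acq.dt

    def aif_spec(self, model: str) -> AifSpec:
        return AifSpec(
            model_name=model,
            dose=self.dose,
            hematocrit=self.hematocrit,
            onset_time=self.resolved_onset(),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _manifest(config: RunConfig, stage: str, extra: dict | None = None) -> dict:
    payload = {
        "stage": stage,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "aif_constants_version": AIF_CONSTANTS["version"],
        "software_version": __version__,
    }
    if extra:
        payload.update(extra)
    return payload


def _patient_dirs(root) -> list[Path]:
    root = Path(root)
    dirs = sorted(p for p in root.iterdir() if p.is_dir() and (p / "dce.nii.gz").exists())
    if not dirs:
        raise FileNotFoundError(f"no patient directories with dce.nii.gz under {root}")
    return dirs


def write_phantom_cohort(spec: PhantomSpec, out_dir) -> list[Path]:
    """Generate a phantom cohort and write it in the pipeline's NIfTI layout."""
    out = Path(out_dir)
    patients = generate_cohort(spec)
    affine = np.diag(list(spec.voxel_size) + [1.0])
    written = []
    for pat in patients:
        pdir = out / pat.patient_id
        save_volume(pdir / "dce.nii.gz", pat.signal, affine, dt=pat.acq.dt)
        save_volume(pdir / "adc.nii.gz", pat.adc, affine)
        save_volume(pdir / "t2w.nii.gz", pat.t2w, affine)
        save_volume(pdir / "prostate_mask.nii.gz", pat.prostate_mask, affine)
        save_volume(pdir / "tumour_mask.nii.gz", pat.tumour_mask, affine)
        save_volume(pdir / "grade_map.nii.gz", pat.grade_map.astype(np.int16), affine)
        save_volume(pdir / "truth_ktrans.nii.gz", pat.truth_ktrans, affine)
        save_volume(pdir / "truth_ve.nii.gz", pat.truth_ve, affine)
        written.append(pdir)
    write_sidecar(out / "phantom_spec.json", dataclasses.asdict(spec))
    log.info("phantom cohort written: %d patients under %s", len(written), out)
    return written


def _quantify_patient(pdir: Path, out_pdir: Path, config: RunConfig) -> dict:
    acq = config.acq
    series = load_dce(pdir / "dce.nii.gz", acq)
    mask_path = pdir / "prostate_mask.nii.gz"
    mask = load_volume(mask_path)[0].astype(bool) if mask_path.exists() else None
    spatial = series.signal.shape[:3]
    flat_mask = (
        mask.reshape(-1) if mask is not None else np.ones(int(np.prod(spatial)), bool)
    )
    flat_sig = series.signal.reshape(-1, series.signal.shape[3])
    onset = config.resolved_onset()
    log.info("%s: %d voxels enter quantification", pdir.name, int(flat_mask.sum()))

    conc, conv_report = convert_volume(series.signal, acq, acq.t1_tissue, mask=mask)
    flat_conc = conc.reshape(-1, conc.shape[3])
    sq, sq_report = fit_semiquant_volume(
        flat_sig[flat_mask], series.times, n_baseline=acq.n_baseline
    )

    def to_map(values: np.ndarray) -> np.ndarray:
        out = np.full(flat_mask.shape, np.nan)
        out[flat_mask] = values
        return out.reshape(spatial)

    for name in SEMIQUANT_MAPS:
        save_volume(out_pdir / f"{name}.nii.gz", to_map(sq[name]), series.affine)

    from .tofts import GRID_DT, KTRANS_BOUNDS, VE_BOUNDS

    fine = np.arange(0.0, series.times.max() + 1.0, 0.5)
    fit_reports = {}
    for model in config.aif_models:
        spec = config.aif_spec(model)
        aif = evaluate_aif(spec, fine)
        fit = fit_tofts_volume(flat_conc[flat_mask], series.times, aif)
        save_volume(out_pdir / f"ktrans_{model}.nii.gz", to_map(fit["ktrans"]), series.affine)
        save_volume(out_pdir / f"ve_{model}.nii.gz", to_map(fit["ve"]), series.affine)
        fit_reports[model] = {
            "aif_spec": dataclasses.asdict(spec),
            "ktrans_bounds_per_min": list(KTRANS_BOUNDS),
            "ve_bounds": list(VE_BOUNDS),
            "conv_grid_dt_s": GRID_DT,
            "n_not_converged": int((~fit["converged"]).sum()),
        }
    iaugc = iaugc60_volume(flat_conc[flat_mask], series.times, onset)
    save_volume(out_pdir / "iaugc60.nii.gz", to_map(iaugc), series.affine)

    report = {
        "patient": pdir.name,
        "conversion": conv_report,
        "semiquant": sq_report,
        "tofts": fit_reports,
    }
    write_sidecar(out_pdir / "quality_report.json", report)
    return report


def run_quantify(config: RunConfig) -> list[dict]:
    """Compute all parameter maps for every patient under ``input_dir``.

    Idempotent for a fixed configuration; header/temporal mismatches abort
    before any computation.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    pdirs = _patient_dirs(config.input_dir)
    # validate every header before computing anything
    for pdir in pdirs:
        load_dce(pdir / "dce.nii.gz", config.acq)
    reports = [
        _quantify_patient(pdir, out / pdir.name / "maps", config) for pdir in pdirs
    ]
    write_sidecar(out / "manifest_quantify.json", _manifest(config, "quantify"))
    return reports


def run_labels(config: RunConfig) -> list[dict]:
    """Build label grids (tumour / excluded / benign / outside) per patient."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    results = []
    for pdir in _patient_dirs(config.input_dir):
        tumour, affine = load_volume(pdir / "tumour_mask.nii.gz")
        prostate, _ = load_volume(pdir / "prostate_mask.nii.gz")
        grade, _ = load_volume(pdir / "grade_map.nii.gz")
        voxel_size = tuple(float(v) for v in np.abs(np.diag(affine)[:3]))
        grid = build_labels(
            tumour.astype(bool),
            prostate.astype(bool),
            grade.astype(int),
            config.margin_mm,
            voxel_size,
            affine,
        )
        save_volume(out / pdir.name / "labels.nii.gz", grid.labels, affine)
        save_volume(out / pdir.name / "grade.nii.gz", grid.grade, affine)
        counts = grid.counts()
        log.info("%s: label counts %s", pdir.name, counts)
        results.append({"patient": pdir.name, "counts": counts})
    write_sidecar(out / "manifest_labels.json", _manifest(config, "labels"))
    return results


def build_feature_table(config: RunConfig, maps_root=None, labels_root=None) -> pd.DataFrame:
    """Pool analysed voxels of every patient into the study feature table.

    Rows carry the MRI features, the benign/tumour label, the grade stratum
    and the patient id; excluded-ring and outside voxels never enter.
    """
    maps_root = Path(maps_root if maps_root is not None else config.output_dir)
    labels_root = Path(labels_root if labels_root is not None else config.output_dir)
    frames = []
    for pdir in _patient_dirs(config.input_dir):
        mdir = maps_root / pdir.name / "maps"
        labels, _ = load_volume(labels_root / pdir.name / "labels.nii.gz")
        grade, _ = load_volume(labels_root / pdir.name / "grade.nii.gz")
        from .masks import LabelGrid

        grid = LabelGrid(labels=labels.astype(int), grade=grade.astype(int))
        strata = stratify_by_grade(grid)
        keep = (labels == LABEL_CODES["benign"]) | (labels == LABEL_CODES["tumour"])
        cols = {}
        for feat in STUDY_FEATURES:
            if feat == "t2w":
                data, _a = load_volume(pdir / "t2w.nii.gz")
            elif feat == "adc":
                data, _a = load_volume(pdir / "adc.nii.gz")
            else:
                data, _a = load_volume(mdir / f"{feat}.nii.gz")
            cols[feat] = data[keep]
        frame = pd.DataFrame(cols)
        frame["label"] = np.where(
            labels[keep] == LABEL_CODES["tumour"], "tumour", "benign"
        )
        frame["stratum"] = strata[keep]
        frame["patient_id"] = pdir.name
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    n_before = len(table)
    table = table.dropna(subset=[f for f in STUDY_FEATURES])
    log.info("feature table: %d voxels (%d dropped as NaN)", len(table), n_before - len(table))
    return table


def run_study(config: RunConfig, table: pd.DataFrame | None = None) -> dict:
    """Effect sizes, correlation pruning and the classifier grid.

    Returns a dict with the effect-size report, correlation matrices, the
    retained feature list and the classifier report; the same tables are
    written as delimited text under ``output_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    if table is None:
        table = build_feature_table(config)
    if table["patient_id"].nunique() < 2:
        raise ValueError("study requires maps and labels from at least 2 patients")

    report = effect_size_report(table)
    corr_panels = {}
    for stratum in ("low_grade", "high_grade", "all", "benign"):
        if stratum == "all":
            sub = table[table["label"] == "tumour"]
        elif stratum == "benign":
            sub = table[table["label"] == "benign"]
        else:
            sub = table[table["stratum"] == stratum]
        if len(sub) >= 3:
            corr_panels[stratum] = sub[list(STUDY_FEATURES)].corr()

    # prune among the DCE parameters; T2w and ADC always stay
    dce_feats = [f for f in STUDY_FEATURES if f not in ("t2w", "adc")
                 and f not in ("ktrans_weinmann", "ve_weinmann")]
    retained_dce, corr_all = correlation_prune(table, dce_feats, config.corr_threshold)
    retained = ["t2w", "adc"] + retained_dce

    cad_results = run_model_grid(
        table,
        seed=config.seed,
        downsample_ratio=config.downsample_ratio,
        test_fraction=config.test_fraction,
    )
    cad_table = grid_report(cad_results)

    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "effect_sizes.csv", index=False)
    for stratum, panel in corr_panels.items():
        panel.to_csv(out / f"correlation_{stratum}.csv")
    cad_table.to_csv(out / "cad_report.csv", index=False)
    importance_rows = []
    for (stratum, fset, clf), res in cad_results.items():
        if getattr(res, "feature_importance", None):
            for feat, frac in res.feature_importance.items():
                importance_rows.append(
                    {"stratum": stratum, "feature_set": fset, "feature": feat,
                     "importance": frac}
                )
    pd.DataFrame(importance_rows).to_csv(out / "feature_importance.csv", index=False)
    write_sidecar(
        out / "manifest_study.json",
        _manifest(config, "study", {"retained_features": retained}),
    )
    return {
        "effect_sizes": report,
        "correlations": corr_panels,
        "retained_features": retained,
        "cad_results": cad_results,
        "cad_report": cad_table,
    }
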