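"""Digital prostate DCE-MRI phantom with known voxel-wise ground truth.

The phantom stands in for a prostatectomy-validated patient cohort: each
synthetic patient carries an ellipsoidal prostate containing spherical tumour
foci with Gleason grade groups drawn from a realistic cohort mix, voxel-wise
Tofts kinetics with grade-dependent (Ktrans, Ve) distributions, and
grade-dependent ADC and T2w distributions with configurable standardised
effect sizes.  Dynamic signal is synthesised by the SPGR forward model from
Parker-AIF Tofts concentration curves plus additive Gaussian noise, and the
benign:tumour analysed-voxel imbalance is structured to a configurable ratio
(default ~4.6:1, the imbalance of the study it emulates, at reduced scale).

Two entry points matter downstream:

* :func:`generate_cohort` — full image-domain patients (4D DCE series, ADC,
  T2w, masks, grade map, ground-truth parameter maps) for pipeline runs;
* :func:`sample_feature_table` — a geometry-free voxel sampler that pushes
  class draws through the full signal pipeline (forward model, noise, SPGR
  conversion, Tofts and piecewise-linear fitting) and returns the voxel
  feature table; this is the workhorse for effect-size calibration and the
  classifier study at large n.

:func:`calibrate_effect_sizes` tunes the class distributions so that the
population Cohen's d of each feature matches a target: exactly (analytically)
for the directly drawn features (ADC, T2w), and iteratively through the
kinetic forward model for Ktrans (tumour Ktrans location) and TTP (tumour Ve
location, which moves kep and hence time-to-peak).  With only two kinetic
knobs per tumour class the remaining derived features (IRE, iAUGC60, ME, Ve)
land where the kinetics put them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aif import AifSpec, evaluate_aif
from .conversion import AcquisitionParams, acquisition_preset, convert_volume, spgr_signal
from .masks import DEFAULT_MARGIN_MM, build_labels
from .semiquant import fit_semiquant_volume
from .tofts import fit_tofts_volume, iaugc60_volume, tofts_forward_many

__all__ = [
    "ClassDists",
    "PhantomSpec",
    "PhantomPatient",
    "DEFAULT_EFFECT_TARGETS",
    "generate_cohort",
    "sample_feature_table",
    "calibrate_effect_sizes",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """A requested effect-size target cannot be reached under the bounds."""


@dataclass
class ClassDists:
    """Per-tissue-class parameter distributions (normal, truncated to range).

    Ktrans in min^-1, Ve as a fraction, ADC in 1e-3 mm^2/s, T2w in arbitrary
    units.
    """

    ktrans_mean: float
    ktrans_sd: float
    ve_mean: float
    ve_sd: float
    adc_mean: float
    adc_sd: float
    t2w_mean: float
    t2w_sd: float


def _default_classes() -> dict[str, ClassDists]:
    # Benign prostate kinetics and signal parameters are physiological
    # starting values; tumour classes shift in the directions the study
    # reports (higher Ktrans, higher kep hence lower TTP, lower ADC, lower
    # T2w) and are refined by calibrate_effect_sizes.
    # Tumour classes are markedly more heterogeneous than benign gland —
    # wide Ktrans/Ve spreads keep the standardised differences of derived
    # curve features (ME, AUC, Ve) moderate while the class means carry the
    # kep (= Ktrans/Ve) shift that lowers tumour time-to-peak.
    return {
        "benign": ClassDists(0.15, 0.06, 0.30, 0.18, 1.50, 0.35, 100.0, 20.0),
        "low_grade": ClassDists(0.16, 0.06, 0.20, 0.16, 1.39, 0.35, 95.6, 20.0),
        "high_grade": ClassDists(0.21, 0.10, 0.24, 0.16, 1.16, 0.35, 99.1, 20.0),
    }


#: default effect-size targets: |Cohen's d| of tumour-vs-benign voxel values
#: per stratum, with the sign giving the tumour-minus-benign direction
DEFAULT_EFFECT_TARGETS: dict[str, dict[str, float]] = {
    "low_grade": {
        "adc": -0.323,
        "ttp": -0.478,
        "ktrans_parker": 0.264,
        "t2w": -0.221,
    },
    "high_grade": {
        "adc": -0.959,
        "ttp": -0.548,
        "ktrans_parker": 0.759,
        "t2w": -0.045,
    },
}

#: Gleason grade-group mix of tumour foci (grade groups 1..5)
GRADE_GROUP_PROBS = (0.066, 0.508, 0.328, 0.0, 0.098)


@dataclass
class PhantomSpec:
    """Configuration of the synthetic cohort."""

    n_patients: int = 8
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    voxel_size: tuple[float, float, float] = (0.8, 0.8, 0.8)
    n_foci_per_patient: int = 2
    benign_tumour_ratio: float = 4.63
    margin_mm: float = DEFAULT_MARGIN_MM
    classes: dict[str, ClassDists] = field(default_factory=_default_classes)
    acquisition: str = "60x7.2"
    aif: AifSpec | None = None
    s0: float = 5000.0
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.benign_tumour_ratio <= 0:
            raise ValueError("benign_tumour_ratio must be > 0")
        for name, d in self.classes.items():
            if not (0 < d.ktrans_mean < 5 and 0 < d.ve_mean <= 1):
                raise ValueError(f"class {name}: kinetics outside Tofts fit bounds")

    @property
    def acq(self) -> AcquisitionParams:
        return acquisition_preset(self.acquisition)

    def aif_spec(self) -> AifSpec:
        if self.aif is not None:
            return self.aif
        return AifSpec(
            model_name="parker", onset_time=self.acq.n_baseline * self.acq.dt
        )


@dataclass
class PhantomPatient:
    """One synthetic patient: images, masks and stored ground truth."""

    patient_id: str
    signal: np.ndarray  # (x, y, z, t)
    times: np.ndarray
    acq: AcquisitionParams
    aif_spec: AifSpec
    adc: np.ndarray
    t2w: np.ndarray
    prostate_mask: np.ndarray
    tumour_mask: np.ndarray
    grade_map: np.ndarray
    truth_ktrans: np.ndarray
    truth_ve: np.ndarray
    voxel_size: tuple[float, float, float]


def _draw_kinetics(d: ClassDists, n: int, rng: np.random.Generator):
    ktrans = np.clip(rng.normal(d.ktrans_mean, d.ktrans_sd, n), 0.01, 4.9)
    ve = np.clip(rng.normal(d.ve_mean, d.ve_sd, n), 0.05, 0.95)
    return ktrans, ve


def _draw_maps(d: ClassDists, n: int, rng: np.random.Generator):
    adc = np.clip(rng.normal(d.adc_mean, d.adc_sd, n), 0.05, None)
    t2w = np.clip(rng.normal(d.t2w_mean, d.t2w_sd, n), 1.0, None)
    return adc, t2w


def _grade_to_class(grade: np.ndarray) -> np.ndarray:
    """Map grade-group integers to class names ('' where grade 0)."""
    out = np.full(grade.shape, "benign", dtype="U10")
    out[(grade >= 1) & (grade <= 2)] = "low_grade"
    out[grade >= 3] = "high_grade"
    return out


def _ellipsoid_mask(shape, semi_axes, centre) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi_axes))
    return acc <= 1.0


def _foci_masks(shape, voxel_size, centres, radius_mm):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    masks = []
    for c in centres:
        acc = sum(
            ((g - ci) * vs) ** 2 for g, ci, vs in zip(grids, c, voxel_size)
        )
        masks.append(acc <= radius_mm**2)
    return masks


def _solve_focus_radius(prostate, centres, voxel_size, margin_mm, target_ratio):
    """Bisect the focus radius so benign:tumour matches the target ratio.

    The ratio counts analysed voxels only (the excluded ring is removed),
    so it falls monotonically as the foci grow.
    """
    shape = prostate.shape
    r_lo, r_hi = 1.2, float(min(s * v for s, v in zip(shape, voxel_size))) / 2

    def ratio_at(r):
        tumour = np.zeros(shape, dtype=bool)
        for m in _foci_masks(shape, voxel_size, centres, r):
            tumour |= m
        tumour &= prostate
        if not tumour.any():
            return np.inf, tumour
        grade = np.where(tumour, 1, 0)
        lg = build_labels(tumour, prostate, grade, margin_mm, voxel_size)
        counts = lg.counts()
        if counts["tumour"] == 0:
            return np.inf, tumour
        return counts["benign"] / counts["tumour"], tumour

    for _ in range(22):
        r_mid = 0.5 * (r_lo + r_hi)
        ratio, _t = ratio_at(r_mid)
        if abs(ratio - target_ratio) / target_ratio < 0.03:
            return r_mid
        if ratio > target_ratio:
            r_lo = r_mid
        else:
            r_hi = r_mid
    return 0.5 * (r_lo + r_hi)


def generate_cohort(spec: PhantomSpec) -> list[PhantomPatient]:
    """Generate the synthetic cohort; bit-identical for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    acq = spec.acq
    times = acq.times
    aif_spec = spec.aif_spec()
    aif = evaluate_aif(aif_spec, np.arange(0.0, times.max() + 1.0, 0.5))
    patients = []
    shape = spec.grid_shape
    for p in range(spec.n_patients):
        semi = np.array([0.38 * shape[0], 0.38 * shape[1], 0.42 * shape[2]])
        semi *= rng.uniform(0.92, 1.08, size=3)
        centre = np.array(shape) / 2.0
        prostate = _ellipsoid_mask(shape, semi, centre)
        # foci centres at a modest offset from the prostate centre
        centres = []
        for _ in range(spec.n_foci_per_patient):
            u = rng.uniform(0.15, 0.5)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            centres.append(centre + u * semi * direction)
        radius_mm = _solve_focus_radius(
            prostate, centres, spec.voxel_size, spec.margin_mm, spec.benign_tumour_ratio
        )
        grades = rng.choice(
            np.arange(1, 6), size=spec.n_foci_per_patient, p=GRADE_GROUP_PROBS
        )
        tumour = np.zeros(shape, dtype=bool)
        grade_map = np.zeros(shape, dtype=np.int16)
        for m, g in zip(_foci_masks(shape, spec.voxel_size, centres, radius_mm), grades):
            m = m & prostate
            tumour |= m
            grade_map[m] = g  # later foci overwrite overlaps
        grade_map[~tumour] = 0

        cls = _grade_to_class(grade_map)
        truth_ktrans = np.full(shape, np.nan)
        truth_ve = np.full(shape, np.nan)
        adc = np.zeros(shape)
        t2w = np.zeros(shape)
        n_t = times.size
        signal = np.empty(shape + (n_t,))
        # voxels outside the prostate carry baseline signal + noise only
        base = spgr_signal(0.0, acq, spec.s0, acq.t1_tissue)
        signal[...] = base
        for name in ("benign", "low_grade", "high_grade"):
            if name == "benign":
                sel = prostate & ~tumour
            else:
                sel = tumour & (cls == name)
            n_sel = int(sel.sum())
            if n_sel == 0:
                continue
            d = spec.classes[name]
            kt, ve = _draw_kinetics(d, n_sel, rng)
            a, t2 = _draw_maps(d, n_sel, rng)
            truth_ktrans[sel] = kt
            truth_ve[sel] = ve
            adc[sel] = a
            t2w[sel] = t2
            conc = tofts_forward_many(kt, ve, aif, times)
            signal[sel] = spgr_signal(conc, acq, spec.s0, acq.t1_tissue)
        out_d = spec.classes["benign"]
        n_out = int((~prostate).sum())
        adc[~prostate], t2w[~prostate] = _draw_maps(out_d, n_out, rng)
        if spec.noise_sd > 0:
            signal += rng.normal(0.0, spec.noise_sd, size=signal.shape)
        patients.append(
            PhantomPatient(
                patient_id=f"phantom_{p:02d}",
                signal=signal,
                times=times,
                acq=acq,
                aif_spec=aif_spec,
                adc=adc,
                t2w=t2w,
                prostate_mask=prostate,
                tumour_mask=tumour,
                grade_map=grade_map,
                truth_ktrans=truth_ktrans,
                truth_ve=truth_ve,
                voxel_size=spec.voxel_size,
            )
        )
    return patients


def _features_from_curves(
    kt_true,
    ve_true,
    spec: PhantomSpec,
    rng: np.random.Generator,
    quick: bool = False,
):
    """Push voxel kinetics through signal synthesis, conversion and fitting."""
    acq = spec.acq
    times = acq.times
    aif_spec = spec.aif_spec()
    fine = np.arange(0.0, times.max() + 1.0, 0.5)
    aif_parker = evaluate_aif(aif_spec, fine)
    conc_true = tofts_forward_many(kt_true, ve_true, aif_parker, times)
    signal = spgr_signal(conc_true, acq, spec.s0, acq.t1_tissue)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
    conc_meas, _report = convert_volume(
        signal[:, None, None, :], acq, acq.t1_tissue
    )
    conc_meas = conc_meas[:, 0, 0, :]
    out: dict[str, np.ndarray] = {}
    fit_p = fit_tofts_volume(conc_meas, times, aif_parker)
    out["ktrans_parker"] = fit_p["ktrans"]
    out["ve_parker"] = fit_p["ve"]
    sq, _rep = fit_semiquant_volume(signal, times, n_baseline=acq.n_baseline)
    for name in ("ttp", "ire", "me", "auc"):
        out[name] = sq[name]
    if not quick:
        aif_w = evaluate_aif(replace(aif_spec, model_name="weinmann"), fine)
        fit_w = fit_tofts_volume(conc_meas, times, aif_w)
        out["ktrans_weinmann"] = fit_w["ktrans"]
        out["ve_weinmann"] = fit_w["ve"]
        out["iaugc60"] = iaugc60_volume(conc_meas, times, aif_spec.onset_time)
    return out


def sample_feature_table(
    spec: PhantomSpec,
    n_benign: int,
    n_low: int,
    n_high: int,
    seed: int | None = None,
    quick: bool = False,
) -> pd.DataFrame:
    """Sample a voxel feature table straight from the class distributions.

    Draws voxels per class (no geometry), runs the full measurement pipeline
    and returns the feature table with label/stratum/patient_id columns.
    ``quick`` skips the Weinmann fits and iAUGC60 (used inside calibration).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for stratum, n in (("benign", n_benign), ("low_grade", n_low), ("high_grade", n_high)):
        if n == 0:
            continue
        d = spec.classes[stratum]
        kt, ve = _draw_kinetics(d, n, rng)
        adc, t2w = _draw_maps(d, n, rng)
        feats = _features_from_curves(kt, ve, spec, rng, quick=quick)
        frame = pd.DataFrame(feats)
        frame["adc"] = adc
        frame["t2w"] = t2w
        frame["label"] = "benign" if stratum == "benign" else "tumour"
        frame["stratum"] = stratum
        frame["truth_ktrans"] = kt
        frame["truth_ve"] = ve
        rows.append(frame)
    table = pd.concat(rows, ignore_index=True)
    table["patient_id"] = [
        f"phantom_{i % max(spec.n_patients, 1):02d}" for i in range(len(table))
    ]
    return table


def _analytic_direct_calibration(classes, targets):
    """Set tumour ADC/T2w means so the population d matches exactly."""
    benign = classes["benign"]
    for stratum in ("low_grade", "high_grade"):
        t = targets.get(stratum, {})
        d = classes[stratum]
        if "adc" in t:
            d.adc_sd = benign.adc_sd
            d.adc_mean = benign.adc_mean + t["adc"] * benign.adc_sd
        if "t2w" in t:
            d.t2w_sd = benign.t2w_sd
            d.t2w_mean = benign.t2w_mean + t["t2w"] * benign.t2w_sd
    return classes


def _pooled_d(a: np.ndarray, b: np.ndarray) -> float:
    from .stats import cohens_d

    return cohens_d(a, b)


#: feasible bounds for the kinetic calibration knobs
_KT_MEAN_BOUNDS = (0.03, 2.0)
_VE_MEAN_BOUNDS = (0.08, 0.90)


def calibrate_effect_sizes(
    spec: PhantomSpec,
    targets: dict[str, dict[str, float]] | None = None,
    n_cal: int = 1000,
    tol: float = 0.05,
    max_iter: int = 8,
) -> PhantomSpec:
    """Tune class distributions toward per-stratum effect-size targets.

    ADC and T2w are adjusted analytically (exact population d).  For the
    kinetic chain, the tumour Ktrans location is tuned against the fitted
    Ktrans effect size and the tumour Ve location against the TTP effect
    size, by damped Newton iterations on a common-random-number estimate of
    both d's (so the objective is smooth in the knobs).  Raises
    :class:`CalibrationError`, naming the parameter, if a target is
    unreachable inside the knob bounds.
    """
    targets = copy.deepcopy(targets if targets is not None else DEFAULT_EFFECT_TARGETS)
    classes = copy.deepcopy(spec.classes)
    for stratum, t in targets.items():
        for feat, val in t.items():
            if val < 0 and feat not in ("adc", "t2w", "ttp"):
                raise ValueError("targets are signed tumour-minus-benign d values")
    classes = _analytic_direct_calibration(classes, targets)

    # common-random-number benign reference sample
    base_seed = (spec.seed * 9973 + 17) % (2**31)
    rng_b = np.random.default_rng(base_seed)
    bd = classes["benign"]
    kt_b, ve_b = _draw_kinetics(bd, n_cal, rng_b)
    feats_b = _features_from_curves(kt_b, ve_b, spec, np.random.default_rng(base_seed + 1), quick=True)

    for si, stratum in enumerate(("low_grade", "high_grade")):
        t = targets.get(stratum, {})
        want = np.array([t.get("ktrans_parker", np.nan), t.get("ttp", np.nan)])
        if np.all(np.isnan(want)):
            continue
        d_cls = classes[stratum]

        def estimate(kt_mean, ve_mean):
            trial = replace(
                ClassDists(**vars(d_cls)), ktrans_mean=kt_mean, ve_mean=ve_mean
            )
            rng_t = np.random.default_rng(base_seed + 100 + si)
            kt, ve = _draw_kinetics(trial, n_cal, rng_t)
            feats = _features_from_curves(
                kt, ve, spec, np.random.default_rng(base_seed + 200 + si), quick=True
            )
            d_kt = _pooled_d(feats["ktrans_parker"], feats_b["ktrans_parker"])
            d_ttp = _pooled_d(feats["ttp"], feats_b["ttp"])
            return np.array([d_kt, d_ttp])

        x = np.array([d_cls.ktrans_mean, d_cls.ve_mean])
        f0 = estimate(*x)
        # one-sided probes for a full 2x2 Jacobian
        h = np.array([0.05, 0.05])
        j = np.empty((2, 2))
        j[:, 0] = (estimate(x[0] + h[0], x[1]) - f0) / h[0]
        j[:, 1] = (estimate(x[0], x[1] + h[1]) - f0) / h[1]
        err = f0 - want
        for _ in range(max_iter):
            if np.all(np.abs(err) < tol):
                break
            try:
                step = np.linalg.solve(j, err)
            except np.linalg.LinAlgError:
                raise CalibrationError(
                    f"{stratum}: singular response of (ktrans, ttp) to the knobs"
                ) from None
            x_new = x - np.clip(step, -0.25, 0.25)
            x_new[0] = np.clip(x_new[0], *_KT_MEAN_BOUNDS)
            x_new[1] = np.clip(x_new[1], *_VE_MEAN_BOUNDS)
            f_new = estimate(*x_new)
            x, f0 = x_new, f_new
            err = f0 - want
        if not np.all(np.abs(err) < tol):
            which = "ktrans_parker" if abs(err[0]) >= abs(err[1]) else "ttp"
            raise CalibrationError(
                f"{stratum}: target for {which} unreachable within bounds "
                f"(residual {err}, knobs {x})"
            )
        d_cls.ktrans_mean = float(x[0])
        d_cls.ve_mean = float(x[1])

    return replace(spec, classes=classes)
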