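"""Spoiled-gradient-echo (SPGR) signal <-> gadolinium concentration conversion.

The dynamic series is acquired with a 3D spoiled gradient echo.  In steady
state the signal is

    S(C) = S0 * sin(a) * (1 - E) / (1 - cos(a) * E),   E = exp(-TR * R1),

with R1 = 1/T10 + r1 * C, relaxivity r1 and pre-contrast longitudinal
relaxation time T10.  The inverse uses only the signal-to-baseline ratio, so
the unknown scanner scale S0 cancels.  Fixed relaxation constants are used
throughout: r1 = 3.5 L mmol^-1 s^-1, T10 = 1.597 s in prostate tissue and
1.664 s in arterial blood.

Conversion is the exact closed-form inversion of the SPGR equation; samples
whose enhancement ratio drives the inverted exponential out of (0, 1]
(non-physical) are flagged and clamped, and negative concentrations (noise
below baseline) are clamped to zero with the pre-clamp values retained for
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AcquisitionParams",
    "SignalCurve",
    "ConcentrationCurve",
    "ACQUISITION_PRESETS",
    "spgr_signal",
    "signal_to_concentration",
    "convert_volume",
]

#: contrast-agent relaxivity, L mmol^-1 s^-1
DEFAULT_R1 = 3.5
#: fixed pre-contrast T1 of prostate tissue, seconds
T1_TISSUE = 1.597
#: fixed pre-contrast T1 of arterial blood, seconds
T1_BLOOD = 1.664


@dataclass(frozen=True)
class AcquisitionParams:
    """Dynamic acquisition metadata and fixed relaxation constants.

    ``tr`` is the SPGR repetition time (s), ``flip_angle`` the excitation
    angle in degrees, ``dt`` the frame spacing (s), ``n_baseline`` the number
    of pre-contrast frames averaged into the baseline.
    """

    tr: float = 0.004
    flip_angle: float = 20.0
    dt: float = 3.6
    n_timepoints: int = 120
    n_baseline: int = 5
    r1: float = DEFAULT_R1
    t1_tissue: float = T1_TISSUE
    t1_blood: float = T1_BLOOD

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise ValueError("tr must be > 0")
        if not (0 < self.flip_angle < 90):
            raise ValueError("flip_angle must lie in (0, 90) degrees")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be >= 1")
        if not self.r1 > 0:
            raise ValueError("r1 must be > 0")
        if not (self.t1_tissue > 0 and self.t1_blood > 0):
            raise ValueError("T1 values must be > 0")

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_timepoints) * self.dt


#: the three dynamic protocols used across the cohort
ACQUISITION_PRESETS: dict[str, AcquisitionParams] = {
    "60x7.2": AcquisitionParams(dt=7.2, n_timepoints=60),
    "90x5.3": AcquisitionParams(dt=5.3, n_timepoints=90),
    "120x3.6": AcquisitionParams(dt=3.6, n_timepoints=120),
}


def acquisition_preset(name: str, **overrides) -> AcquisitionParams:
    """Return a named acquisition preset, optionally overriding fields."""
    try:
        preset = ACQUISITION_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(ACQUISITION_PRESETS)}"
        ) from None
    return replace(preset, **overrides) if overrides else preset


@dataclass(frozen=True)
class SignalCurve:
    """A voxel's dynamic signal in arbitrary scanner units."""

    times: np.ndarray
    signal: np.ndarray
    n_baseline: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must share a shape")
        if self.n_baseline < 1 or self.n_baseline > self.signal.size:
            raise ValueError("n_baseline out of range")

    @property
    def baseline(self) -> float:
        """Mean of the first ``n_baseline`` (pre-contrast) signal values."""
        return float(np.mean(self.signal[: self.n_baseline]))


@dataclass(frozen=True)
class ConcentrationCurve:
    """Contrast-agent concentration (mM) versus time (s) for one voxel.

    ``raw_conc`` keeps the pre-clamp values for diagnostics; ``flagged`` marks
    samples whose enhancement ratio was non-physical for the SPGR model.
    """

    times: np.ndarray
    conc: np.ndarray
    raw_conc: np.ndarray | None = None
    flagged: np.ndarray | None = None
    convertible: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "conc", np.asarray(self.conc, dtype=float))
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must share a shape")

    @property
    def n_flagged(self) -> int:
        return 0 if self.flagged is None else int(np.sum(self.flagged))


def spgr_signal(conc, acq: AcquisitionParams, s0: float, t10: float):
    """Forward SPGR signal for concentration ``conc`` (mM).

    Strictly increasing in concentration over the physiological range for
    flip angles below 90 degrees, and linear in the scanner scale ``s0``.
    """
    if not t10 > 0:
        raise ValueError("t10 must be > 0")
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    a = np.deg2rad(acq.flip_angle)
    r1_eff = 1.0 / t10 + acq.r1 * conc
    e = np.exp(-acq.tr * r1_eff)
    out = s0 * np.sin(a) * (1.0 - e) / (1.0 - np.cos(a) * e)
    return out if out.ndim else float(out)


#: clamp ceiling for non-physical (saturated) enhancement, mM
CONC_CLAMP_MAX = 50.0


def _ratio_to_conc(ratio, acq: AcquisitionParams, t10: float):
    """Closed-form inverse of the SPGR equation from the baseline ratio.

    Returns ``(conc, flagged)``.  Concentration may be slightly negative for
    sub-baseline noise (caller clamps to zero); ``flagged`` marks ratios
    outside the invertible branch E in (0, 1] — signal above the SPGR
    saturation ceiling (E <= 0, clamped to ``CONC_CLAMP_MAX``) or negative
    signal (E > 1).
    """
    a = np.deg2rad(acq.flip_angle)
    cos_a = np.cos(a)
    e0 = np.exp(-acq.tr / t10)
    ratio = np.asarray(ratio, dtype=float)
    # rho = S/S0 relative to sin(a); at conc 0 this equals (1-E0)/(1-cos(a)E0)
    rho = ratio * (1.0 - e0) / (1.0 - cos_a * e0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (1.0 - rho) / (1.0 - rho * cos_a)
    flagged = ~np.isfinite(e) | (e <= 0) | (e > 1)
    e_min = np.exp(-acq.tr * (1.0 / t10 + acq.r1 * CONC_CLAMP_MAX))
    e_cl = np.clip(np.nan_to_num(e, nan=1.0), e_min, 1.0)
    r1_eff = -np.log(e_cl) / acq.tr
    conc = (r1_eff - 1.0 / t10) / acq.r1
    return conc, flagged


def signal_to_concentration(
    curve: SignalCurve, acq: AcquisitionParams, t10: float = T1_TISSUE
) -> ConcentrationCurve:
    """Convert a dynamic signal curve to gadolinium concentration.

    Only the signal-to-baseline ratio enters, so the scanner scale cancels.
    A zero (or negative) baseline marks the voxel unconvertible; flagged
    samples are clamped into range and counted.
    """
    baseline = curve.baseline
    if not baseline > 0:
        return ConcentrationCurve(
            times=curve.times,
            conc=np.zeros_like(curve.signal),
            raw_conc=np.full_like(curve.signal, np.nan),
            flagged=np.ones(curve.signal.shape, dtype=bool),
            convertible=False,
        )
    raw, flagged = _ratio_to_conc(curve.signal / baseline, acq, t10)
    conc = np.clip(raw, 0.0, None)
    return ConcentrationCurve(
        times=curve.times, conc=conc, raw_conc=raw, flagged=flagged, convertible=True
    )


def convert_volume(
    signal: np.ndarray,
    acq: AcquisitionParams,
    t10: float = T1_TISSUE,
    mask: np.ndarray | None = None,
):
    """Convert a 4D (x, y, z, t) signal array to concentration.

    Returns ``(conc, report)`` where ``report`` counts unconvertible voxels
    (non-positive baseline) and flagged samples.  Voxels outside ``mask`` are
    left as NaN.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 4:
        raise ValueError("signal must be 4-D (x, y, z, t)")
    spatial = signal.shape[:3]
    flat = signal.reshape(-1, signal.shape[3])
    if mask is not None:
        sel = np.asarray(mask, dtype=bool).reshape(-1)
    else:
        sel = np.ones(flat.shape[0], dtype=bool)
    conc = np.full_like(flat, np.nan)
    baseline = flat[sel, : acq.n_baseline].mean(axis=1)
    ok = baseline > 0
    idx = np.flatnonzero(sel)
    raw, flagged = _ratio_to_conc(
        flat[idx[ok]] / baseline[ok, None], acq, t10
    )
    conc[idx[ok]] = np.clip(raw, 0.0, None)
    conc[idx[~ok]] = 0.0
    report = {
        "n_voxels": int(sel.sum()),
        "n_unconvertible": int((~ok).sum()),
        "n_flagged_samples": int(flagged.sum()),
    }
    return conc.reshape(*spatial, signal.shape[3]), report
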