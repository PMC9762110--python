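"""Population arterial input functions (AIFs) for DCE-MRI kinetic modelling.

Two population models are provided:

* ``parker`` — a high-temporal-resolution population average with a first-pass
  bolus peak, a recirculation peak and a slow sigmoid-modulated exponential
  washout (sum of two Gaussians plus a modulated exponential).  The published
  constants describe whole-blood concentration.
* ``weinmann`` — a low-temporal-resolution biexponential plasma clearance
  derived from direct contrast-agent measurements in healthy volunteers.

Both are normalised to a common plasma-concentration domain through the
haematocrit, since the Tofts model consumes plasma concentration Cp(t).
All public functions work in seconds; the published per-minute constants are
converted once at load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "AifSpec",
    "AifCurve",
    "parker_aif",
    "weinmann_aif",
    "evaluate_aif",
    "load_aif_constants",
    "AIF_CONSTANTS",
]

_VALID_MODELS = ("parker", "weinmann")


def load_aif_constants() -> dict:
    """Load the versioned published AIF constants shipped with the package."""
    with resources.files("dceprost").joinpath("aif_constants.json").open() as fh:
        return json.load(fh)


AIF_CONSTANTS = load_aif_constants()

#: dose (mmol per kg body weight) at which the published constants apply
REFERENCE_DOSE = AIF_CONSTANTS["reference_dose_mmol_per_kg"]


@dataclass(frozen=True)
class AifSpec:
    """Configuration of a population AIF.

    Parameters
    ----------
    model_name:
        ``"parker"`` or ``"weinmann"``.
    dose:
        Administered dose in mmol per kg body weight.  The published constants
        are defined at 0.1 mmol/kg; concentrations scale linearly with dose.
    hematocrit:
        Unitless haematocrit fraction in [0, 1), used to convert between
        whole-blood and plasma concentration.
    onset_time:
        Bolus-arrival offset in seconds; concentration is identically zero
        before this time.
    """

    model_name: str = "parker"
    dose: float = REFERENCE_DOSE
    hematocrit: float = 0.42
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        if self.model_name not in _VALID_MODELS:
            raise ValueError(f"unknown AIF model {self.model_name!r}; expected one of {_VALID_MODELS}")
        if not self.dose > 0:
            raise ValueError("dose must be > 0")
        if not (0 <= self.hematocrit < 1):
            raise ValueError("hematocrit must lie in [0, 1)")
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")


@dataclass(frozen=True)
class AifCurve:
    """An evaluated AIF: blood and plasma concentration (mM) versus time (s)."""

    times: np.ndarray
    blood_conc: np.ndarray
    plasma_conc: np.ndarray
    spec: AifSpec = field(default_factory=AifSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "blood_conc", np.asarray(self.blood_conc, dtype=float))
        object.__setattr__(self, "plasma_conc", np.asarray(self.plasma_conc, dtype=float))
        if not (self.times.shape == self.blood_conc.shape == self.plasma_conc.shape):
            raise ValueError("times, blood_conc and plasma_conc must share a shape")

    def to_text(self, path, domain: str = "plasma") -> None:
        """Write a two-column delimited table (time_s, conc_mM)."""
        conc = self.plasma_conc if domain == "plasma" else self.blood_conc
        np.savetxt(
            path,
            np.column_stack([self.times, conc]),
            header="time_s\tconc_mM",
            delimiter="\t",
            comments="",
        )


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be a 1-D vector")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


def parker_blood_conc(t_min: np.ndarray, constants: dict | None = None) -> np.ndarray:
    """Evaluate the Parker population form at times ``t_min`` (minutes post-bolus).

    Returns whole-blood concentration in mM at the reference dose.  Negative
    times evaluate to the (vanishingly small) analytic tails; callers zero the
    pre-bolus portion.
    """
    c = constants or AIF_CONSTANTS["parker"]
    v = lambda k: c[k]["value"]  # noqa: E731
    t = np.asarray(t_min, dtype=float)
    gauss1 = v("A1") / (v("sigma1") * np.sqrt(2 * np.pi)) * np.exp(
        -((t - v("T1")) ** 2) / (2 * v("sigma1") ** 2)
    )
    gauss2 = v("A2") / (v("sigma2") * np.sqrt(2 * np.pi)) * np.exp(
        -((t - v("T2")) ** 2) / (2 * v("sigma2") ** 2)
    )
    washout = v("alpha") * np.exp(-v("beta") * t) / (1 + np.exp(-v("s") * (t - v("tau"))))
    return gauss1 + gauss2 + washout


def parker_aif(spec: AifSpec, times: np.ndarray) -> AifCurve:
    """Evaluate the Parker population AIF on ``times`` (seconds).

    The published constants give whole-blood concentration at 0.1 mmol/kg;
    amplitudes are scaled linearly with ``spec.dose`` and plasma concentration
    is obtained as blood / (1 - haematocrit).
    """
    if spec.model_name != "parker":
        raise ValueError("spec.model_name must be 'parker'")
    times = _check_times(times)
    t_min = (times - spec.onset_time) / 60.0
    blood = parker_blood_conc(t_min) * (spec.dose / REFERENCE_DOSE)
    blood = np.where(times < spec.onset_time, 0.0, blood)
    plasma = blood / (1.0 - spec.hematocrit)
    return AifCurve(times=times, blood_conc=blood, plasma_conc=plasma, spec=spec)


def weinmann_plasma_conc(t_min: np.ndarray, dose: float, constants: dict | None = None) -> np.ndarray:
    """Biexponential plasma concentration D*(a1*e^(-m1 t) + a2*e^(-m2 t)), mM."""
    c = constants or AIF_CONSTANTS["weinmann"]
    v = lambda k: c[k]["value"]  # noqa: E731
    t = np.asarray(t_min, dtype=float)
    return dose * (v("a1") * np.exp(-v("m1") * t) + v("a2") * np.exp(-v("m2") * t))


def weinmann_aif(spec: AifSpec, times: np.ndarray) -> AifCurve:
    """Evaluate the Weinmann biexponential AIF on ``times`` (seconds).

    The constants are plasma-domain; whole-blood concentration is derived as
    plasma * (1 - haematocrit).  At the onset instant the plasma value equals
    D * (a1 + a2).
    """
    if spec.model_name != "weinmann":
        raise ValueError("spec.model_name must be 'weinmann'")
    times = _check_times(times)
    t_min = (times - spec.onset_time) / 60.0
    plasma = weinmann_plasma_conc(t_min, spec.dose)
    plasma = np.where(times < spec.onset_time, 0.0, plasma)
    blood = plasma * (1.0 - spec.hematocrit)
    return AifCurve(times=times, blood_conc=blood, plasma_conc=plasma, spec=spec)


def evaluate_aif(spec: AifSpec, times: np.ndarray) -> AifCurve:
    """Dispatch to the AIF named in ``spec``."""
    if spec.model_name == "parker":
        return parker_aif(spec, times)
    return weinmann_aif(spec, times)
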