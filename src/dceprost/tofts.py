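"""Standard Tofts model: forward simulation, per-voxel fitting and iAUGC60.

The standard (two-parameter) Tofts model describes the tissue concentration
as the causal convolution of the plasma input with an exponential impulse
response,

    Ct(t) = Ktrans * int_0^t Cp(tau) exp(-(Ktrans/Ve) (t - tau)) dtau,

with the volume transfer constant Ktrans (min^-1) and the extravascular
extracellular volume fraction Ve; kep = Ktrans/Ve is always derived, never
stored independently.  The convolution is evaluated on a uniform internal
grid (default 1 s) with linear interpolation of the AIF; on each grid
interval the integral of a linear Cp against the exponential kernel is exact,
so discretisation error is well below measurement noise at 3.6-7.2 s frame
spacing.

Two fitters are provided:

* :func:`fit_tofts` — per-curve bounded nonlinear least squares on
  (Ktrans, Ve) with a small deterministic multi-start, the reference fitter.
* :func:`fit_tofts_volume` — a vectorised variable-projection fitter for
  whole volumes: for fixed kep the model is linear in Ktrans, so the search
  reduces to a dense 1-D scan over kep with parabolic refinement.  A test
  asserts agreement with the reference fitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .aif import AifCurve, AifSpec
from .conversion import ConcentrationCurve

__all__ = [
    "ToftsParams",
    "QuantMaps",
    "tofts_forward",
    "fit_tofts",
    "fit_tofts_volume",
    "iaugc60",
    "iaugc60_volume",
]

#: fitting bounds, Ktrans in min^-1 and Ve as a fraction
KTRANS_BOUNDS = (0.0, 5.0)
VE_BOUNDS = (1e-3, 1.0)
#: deterministic multi-start initial points (ktrans, ve)
MULTISTART = ((0.1, 0.2), (0.5, 0.3), (1.5, 0.5))
#: internal convolution grid spacing, seconds; fine enough that the
#: piecewise-linear AIF representation stays well below measurement noise
#: across the whole Ktrans/Ve fitting box
GRID_DT = 0.5


@dataclass(frozen=True)
class ToftsParams:
    """Fitted Tofts parameters for one voxel."""

    ktrans: float  # min^-1
    ve: float  # fraction; NaN when not estimable
    rmse: float = np.nan  # mM
    converged: bool = False
    n_iter: int = 0

    @property
    def kep(self) -> float:
        """Efflux rate constant Ktrans/Ve, min^-1 (always derived)."""
        return self.ktrans / self.ve


@dataclass
class QuantMaps:
    """Quantitative parameter maps sharing one grid and affine."""

    ktrans_map: np.ndarray
    ve_map: np.ndarray
    iaugc60_map: np.ndarray
    affine: np.ndarray
    aif_used: AifSpec

    def __post_init__(self) -> None:
        if not (self.ktrans_map.shape == self.ve_map.shape == self.iaugc60_map.shape):
            raise ValueError("map shapes must match")


def _exp_conv_coeffs(kep_per_s: float, h: float) -> tuple[float, float, float]:
    """Exact per-interval coefficients for conv of linear Cp with exp kernel.

    Over one grid step of length h the increment is Cp_end*P - dCp/h' * Q with
    P = (1-E)/k, Q = (1 - E(1+kh))/k^2, E = exp(-kh); series for small kh.
    """
    k = kep_per_s
    kh = k * h
    if kh < 1e-6:
        # trapezoid limit with first-order correction
        e = np.exp(-kh)
        p = h * (1.0 - kh / 2.0 + kh * kh / 6.0)
        q = h * h * (0.5 - kh / 3.0)
        return e, p, q
    e = np.exp(-kh)
    p = (1.0 - e) / k
    q = (1.0 - e * (1.0 + kh)) / (k * k)
    return e, p, q


def _unit_response(cp_grid: np.ndarray, kep: float, h: float) -> np.ndarray:
    """Ct on the internal grid for Ktrans = 1 min^-1 and given kep (min^-1)."""
    e, p, q = _exp_conv_coeffs(kep / 60.0, h)
    c0 = cp_grid[:-1]
    c1 = cp_grid[1:]
    b = c1 * p - (c1 - c0) / h * q
    y = np.empty_like(cp_grid)
    y[0] = 0.0
    # y[i] = e*y[i-1] + b[i-1]  — first-order IIR
    y[1:] = lfilter([1.0], [1.0, -e], b)
    return y / 60.0  # Ktrans is per minute, integration in seconds


def _sample_response(
    y_grid: np.ndarray,
    cp_grid: np.ndarray,
    grid: np.ndarray,
    kep: float,
    times: np.ndarray,
    h: float,
) -> np.ndarray:
    """Evaluate the unit response at arbitrary ``times``.

    Off-grid times are reached by one exact partial convolution step from the
    preceding grid node (not by interpolating the result, whose curvature
    near bolus arrival would dominate the error budget).
    """
    k = kep / 60.0
    j = np.clip(np.searchsorted(grid, times, side="right") - 1, 0, grid.size - 1)
    delta = times - grid[j]
    on_node = delta <= 1e-12
    j_next = np.minimum(j + 1, grid.size - 1)
    cp_t = np.where(
        on_node, cp_grid[j], cp_grid[j] + (cp_grid[j_next] - cp_grid[j]) * delta / h
    )
    kd = k * delta
    e = np.exp(-kd)
    small = kd < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(small, delta * (1 - kd / 2), (1 - e) / max(k, 1e-300))
        q = np.where(
            small, delta**2 * (0.5 - kd / 3), (1 - e * (1 + kd)) / max(k, 1e-300) ** 2
        )
    slope = np.where(on_node, 0.0, (cp_t - cp_grid[j]) / np.where(on_node, 1.0, delta))
    b = cp_t * p - slope * q
    return y_grid[j] * e + np.where(on_node, 0.0, b) / 60.0


def _prepare_grid(aif: AifCurve, t_max: float, grid_dt: float = GRID_DT):
    """Interpolate the AIF plasma curve onto the uniform internal grid."""
    if aif.times[0] > 0 or aif.times[-1] < t_max - 1e-9:
        raise ValueError("AIF must cover [0, max(times)]")
    n = int(np.ceil(t_max / grid_dt)) + 1
    grid = np.arange(n) * grid_dt
    cp = np.interp(grid, aif.times, aif.plasma_conc)
    return grid, cp


def tofts_forward(
    ktrans: float,
    ve: float,
    aif: AifCurve,
    times: np.ndarray,
    grid_dt: float = GRID_DT,
) -> ConcentrationCurve:
    """Simulate the tissue concentration curve for (Ktrans, Ve).

    Ktrans is in min^-1 and Ve a fraction; ``times`` in seconds.  Ktrans = 0
    yields the zero curve for any AIF; Ve = 0 with Ktrans > 0 is a domain
    error.
    """
    times = np.asarray(times, dtype=float)
    if ktrans < 0:
        raise ValueError("ktrans must be >= 0")
    if ktrans == 0:
        return ConcentrationCurve(times=times, conc=np.zeros_like(times))
    if ve <= 0:
        raise ValueError("ve must be > 0 when ktrans > 0")
    grid, cp = _prepare_grid(aif, float(times.max()), grid_dt)
    kep = ktrans / ve
    unit = _unit_response(cp, kep, grid_dt)
    conc = ktrans * _sample_response(unit, cp, grid, kep, times, grid_dt)
    return ConcentrationCurve(times=times, conc=conc)


def tofts_forward_many(
    ktrans: np.ndarray,
    ve: np.ndarray,
    aif: AifCurve,
    times: np.ndarray,
    grid_dt: float = GRID_DT,
) -> np.ndarray:
    """Vectorised forward model: one concentration curve per (Ktrans, Ve) pair.

    Runs the same exact per-interval recursion as :func:`tofts_forward` for
    all voxels simultaneously (time-stepped across the internal grid).
    Returns an (n_voxels, n_times) array in mM.
    """
    times = np.asarray(times, dtype=float)
    ktrans = np.asarray(ktrans, dtype=float)
    ve = np.asarray(ve, dtype=float)
    if ktrans.shape != ve.shape:
        raise ValueError("ktrans and ve must share a shape")
    if np.any(ktrans < 0):
        raise ValueError("ktrans must be >= 0")
    if np.any((ktrans > 0) & (ve <= 0)):
        raise ValueError("ve must be > 0 wherever ktrans > 0")
    grid, cp = _prepare_grid(aif, float(times.max()), grid_dt)
    kep = np.where(ktrans > 0, ktrans / np.where(ve > 0, ve, 1.0), 1.0)
    h_meas = _unit_response_many(cp, grid, kep, times, grid_dt)
    return np.where(ktrans[:, None] > 0, ktrans[:, None] * h_meas, 0.0)


def _unit_response_many(
    cp: np.ndarray,
    grid: np.ndarray,
    kep: np.ndarray,
    times: np.ndarray,
    grid_dt: float,
) -> np.ndarray:
    """Unit-Ktrans responses at ``times`` for a vector of kep values (min^-1)."""
    kep_s = kep / 60.0
    kh = kep_s * grid_dt
    e = np.exp(-kh)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(kh < 1e-6, grid_dt * (1 - kh / 2), (1 - e) / np.where(kep_s > 0, kep_s, 1.0))
        q = np.where(
            kh < 1e-6,
            grid_dt**2 * (0.5 - kh / 3),
            (1 - e * (1 + kh)) / np.where(kep_s > 0, kep_s, 1.0) ** 2,
        )
    n_grid = grid.size
    n_vox = kep.size
    state = np.zeros((n_vox, n_grid))
    yk = np.zeros(n_vox)
    for j in range(1, n_grid):
        b = cp[j] * p - (cp[j] - cp[j - 1]) / grid_dt * q
        yk = yk * e + b
        state[:, j] = yk
    state /= 60.0  # Ktrans is per minute, integration in seconds

    # exact partial convolution step from the preceding grid node to each
    # (possibly off-grid) measurement time, vectorised across voxels
    jt = np.clip(np.searchsorted(grid, times, side="right") - 1, 0, n_grid - 1)
    delta = times - grid[jt]
    on_node = delta <= 1e-12
    jt_next = np.minimum(jt + 1, n_grid - 1)
    cp_t = np.where(on_node, cp[jt], cp[jt] + (cp[jt_next] - cp[jt]) * delta / grid_dt)
    slope = np.where(on_node, 0.0, (cp_t - cp[jt]) / np.where(on_node, 1.0, delta))
    kd = kep_s[:, None] * delta[None, :]
    et = np.exp(-kd)
    k_safe = np.where(kep_s > 0, kep_s, 1.0)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        pt = np.where(kd < 1e-6, delta[None, :] * (1 - kd / 2), (1 - et) / k_safe)
        qt = np.where(
            kd < 1e-6,
            delta[None, :] ** 2 * (0.5 - kd / 3),
            (1 - et * (1 + kd)) / k_safe**2,
        )
    bt = cp_t[None, :] * pt - slope[None, :] * qt
    return state[:, jt] * et + np.where(on_node[None, :], 0.0, bt) / 60.0


def _usable_curve(conc: ConcentrationCurve) -> np.ndarray | None:
    """Return the finite data vector, or None if the curve is degenerate."""
    y = np.asarray(conc.conc, dtype=float)
    if not np.any(np.isfinite(y)):
        return None
    if conc.flagged is not None and bool(np.all(conc.flagged)):
        return None
    if np.nanmax(np.abs(y)) == 0.0:
        return None
    return y


def fit_tofts(
    conc: ConcentrationCurve,
    aif: AifCurve,
    init: tuple[float, float] | None = None,
    grid_dt: float = GRID_DT,
) -> ToftsParams:
    """Fit (Ktrans, Ve) to one concentration curve by bounded least squares.

    Deterministic multi-start from three fixed initial points (or a single
    caller-supplied ``init``); the start with the lowest final SSE wins, ties
    broken toward the lower Ktrans.  Degenerate curves (all zero or all
    flagged) return Ktrans = 0 with Ve not estimable rather than raising, so
    whole-volume maps survive bad voxels.
    """
    times = np.asarray(conc.times, dtype=float)
    n_post = int(np.sum(times > aif.spec.onset_time))
    if n_post < 10:
        raise ValueError("need at least 10 post-onset samples to fit")
    y = _usable_curve(conc)
    if y is None:
        return ToftsParams(ktrans=0.0, ve=np.nan, rmse=np.nan, converged=False)
    grid, cp = _prepare_grid(aif, float(times.max()), grid_dt)

    def residuals(theta):
        ktrans, ve = theta
        kep = ktrans / ve
        unit = _unit_response(cp, kep, grid_dt)
        return ktrans * _sample_response(unit, cp, grid, kep, times, grid_dt) - y

    lower = np.array([KTRANS_BOUNDS[0], VE_BOUNDS[0]])
    upper = np.array([KTRANS_BOUNDS[1], VE_BOUNDS[1]])
    starts = [init] if init is not None else list(MULTISTART)
    best = None
    total_nfev = 0
    for x0 in starts:
        sol = least_squares(
            residuals,
            x0=np.clip(x0, lower, upper),
            bounds=(lower, upper),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        total_nfev += sol.nfev
        sse = float(np.sum(sol.fun**2))
        if (
            best is None
            or sse < best[0] * (1.0 - 1e-12)
            or (abs(sse - best[0]) <= 1e-12 * max(best[0], 1e-300) and sol.x[0] < best[1].x[0])
        ):
            best = (sse, sol)
    sse, sol = best
    ktrans, ve = float(sol.x[0]), float(sol.x[1])
    return ToftsParams(
        ktrans=ktrans,
        ve=ve,
        rmse=float(np.sqrt(sse / y.size)),
        converged=bool(sol.success),
        n_iter=total_nfev,
    )


def _kep_grid(n: int = 400, lo: float = 0.005, hi: float = 30.0) -> np.ndarray:
    return np.geomspace(lo, hi, n)


def fit_tofts_volume(
    conc: np.ndarray,
    times: np.ndarray,
    aif: AifCurve,
    grid_dt: float = GRID_DT,
    kep_grid: np.ndarray | None = None,
):
    """Vectorised Tofts fit for many voxels at once.

    ``conc`` is (n_voxels, n_times).  For fixed kep the model is
    Ktrans * h(kep, t), linear in Ktrans, so the fit reduces to projecting
    each curve onto a dense log-spaced dictionary of unit responses, followed
    by parabolic refinement of kep in log space and an exact re-projection.

    Returns a dict of per-voxel arrays: ``ktrans``, ``ve``, ``rmse``,
    ``converged`` (False where the curve was degenerate or the solution sits
    outside the parameter bounds).
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(conc, dtype=float)
    if y.ndim != 2 or y.shape[1] != times.size:
        raise ValueError("conc must be (n_voxels, n_times)")
    n_vox = y.shape[0]
    grid, cp = _prepare_grid(aif, float(times.max()), grid_dt)
    keps = kep_grid if kep_grid is not None else _kep_grid()
    # dictionary of unit responses sampled at the measurement times
    H = np.empty((keps.size, times.size))
    for i, kep in enumerate(keps):
        unit = _unit_response(cp, kep, grid_dt)
        H[i] = _sample_response(unit, cp, grid, kep, times, grid_dt)
    hh = np.einsum("kt,kt->k", H, H)  # (n_kep,)
    yh = y @ H.T  # (n_vox, n_kep)
    yy = np.einsum("vt,vt->v", y, y)
    # SSE(v, k) = yy - (yh)^2 / hh at the optimal non-negative ktrans
    gain = np.clip(yh, 0.0, None) ** 2 / hh[None, :]
    sse = yy[:, None] - gain
    best = np.argmin(sse, axis=1)

    # parabolic refinement of log(kep) on the three bracketing grid points
    logk = np.log(keps)
    i0 = np.clip(best, 1, keps.size - 2)
    s_m, s_0, s_p = (sse[np.arange(n_vox), i0 + d] for d in (-1, 0, 1))
    denom = s_m - 2 * s_0 + s_p
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = 0.5 * (s_m - s_p) / denom
    shift = np.where(np.isfinite(shift), np.clip(shift, -1.0, 1.0), 0.0)
    step = logk[1] - logk[0]
    kep_hat = np.exp(logk[i0] + shift * step)

    # exact unit response at each voxel's refined kep, vectorised across voxels
    h_meas = _unit_response_many(cp, grid, kep_hat, times, grid_dt)

    hh_v = np.einsum("vt,vt->v", h_meas, h_meas)
    yh_v = np.einsum("vt,vt->v", y, h_meas)
    with np.errstate(divide="ignore", invalid="ignore"):
        ktrans = np.clip(yh_v / hh_v, 0.0, None)
    ktrans = np.where(np.isfinite(ktrans), ktrans, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ve = ktrans / kep_hat
    resid = y - ktrans[:, None] * h_meas
    rmse = np.sqrt(np.mean(resid**2, axis=1))

    degenerate = ~np.any(np.abs(np.nan_to_num(y)) > 0, axis=1)
    in_bounds = (
        (ktrans <= KTRANS_BOUNDS[1])
        & (ve >= VE_BOUNDS[0])
        & (ve <= VE_BOUNDS[1])
    )
    converged = in_bounds & ~degenerate
    # out-of-bounds solutions are flagged, then clamped for map display
    ktrans = np.where(degenerate, 0.0, np.minimum(ktrans, KTRANS_BOUNDS[1]))
    ve = np.where(degenerate, np.nan, np.clip(ve, VE_BOUNDS[0], VE_BOUNDS[1]))
    return {"ktrans": ktrans, "ve": ve, "rmse": rmse, "converged": converged}


def iaugc60(conc: ConcentrationCurve, t_start: float, window: float = 60.0) -> float:
    """Initial area under the concentration curve, reported in mM*min.

    Trapezoidal integral of ``conc`` over [t_start, t_start + window] with
    linearly interpolated window endpoints.  If the curve ends inside the
    window the integral is truncated at the last sample (with a warning);
    a start time beyond the curve end is an error.
    """
    times = np.asarray(conc.times, dtype=float)
    y = np.asarray(conc.conc, dtype=float)
    if t_start > times[-1]:
        raise ValueError("t_start lies beyond the end of the curve")
    t_end = t_start + window
    if t_end > times[-1]:
        warnings.warn("iAUGC window truncated at the last sample", stacklevel=2)
        t_end = float(times[-1])
    sel = (times > t_start) & (times < t_end)
    ts = np.concatenate([[t_start], times[sel], [t_end]])
    ys = np.concatenate([
        [np.interp(t_start, times, y)],
        y[sel],
        [np.interp(t_end, times, y)],
    ])
    return float(np.trapezoid(ys, ts) / 60.0)


def iaugc60_volume(
    conc: np.ndarray, times: np.ndarray, t_start: float, window: float = 60.0
) -> np.ndarray:
    """Vectorised iAUGC60 for (n_voxels, n_times) concentration arrays."""
    times = np.asarray(times, dtype=float)
    y = np.asarray(conc, dtype=float)
    out = np.empty(y.shape[0])
    for i in range(y.shape[0]):
        out[i] = iaugc60(ConcentrationCurve(times=times, conc=y[i]), t_start, window)
    return out
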