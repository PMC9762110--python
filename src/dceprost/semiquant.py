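"""Semi-quantitative DCE curve parameterisation.

Each voxel's dynamic signal is normalised to its pre-contrast baseline,
(S - S_base)/S_base, and a continuous piecewise-linear model is fitted:

* flat baseline at 0 until the contrast onset time ``Tonset``;
* a linear enhancement phase with slope ``IRE`` rising to the maximum
  enhancement ``ME`` over the time-to-peak ``TTP``;
* a flat plateau at ``ME`` until the washout time ``Twashout``;
* a linear washout phase with (non-positive) slope ``IRW``.

A three-segment variant without a washout phase is also scored, and the
lower-SSE model wins; curves that never wash out within the acquisition get
the sentinel pair (Twashout = 0, IRW = 0).  ``AUC`` is the signed trapezoidal
area under the normalised data curve (a data functional, not a model one).

Breakpoints are searched exhaustively on the sampling grid with a minimum
segment length of two samples.  Given breakpoints the model is linear in
(ME, IRW), so each candidate triple is scored by a closed-form 2x2 least
squares built from prefix sums — globally optimal at grid resolution and
fully deterministic.  Sign constraints (ME >= 0, IRW <= 0) define the model
class: a triple whose unconstrained solution has IRW > 0 is covered exactly
by the no-washout candidate of the same breakpoint pair (the IRW = 0
boundary re-solve), and a solution with ME < 0 describes a curve with no
positive enhancement, which is represented by the flat (non-enhancing)
outcome rather than fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conversion import SignalCurve

__all__ = [
    "SemiQuantParams",
    "normalise_signal",
    "auc_normalised",
    "fit_piecewise_linear",
    "fit_semiquant_volume",
]

#: minimum samples per segment (shared breakpoints counted in both segments)
MIN_SEG = 2

#: semi-quantitative parameter names in canonical export order
PARAM_NAMES = ("t_onset", "ire", "ttp", "me", "t_washout", "irw", "auc")


@dataclass(frozen=True)
class SemiQuantParams:
    """Semi-quantitative parameters of one voxel's normalised curve."""

    t_onset: float  # s
    ire: float  # normalised units / s
    ttp: float  # s
    me: float  # normalised units
    t_washout: float  # s; 0 sentinel when no washout
    irw: float  # normalised units / s, <= 0; 0 sentinel when no washout
    auc: float  # normalised units * s
    sse: float = 0.0
    non_enhancing: bool = False
    analysable: bool = True


def normalise_signal(curve: SignalCurve) -> np.ndarray:
    """Return the baseline-normalised enhancement curve (S - S0)/S0.

    Invariant under any positive scaling of the raw signal.  A non-positive
    baseline makes the voxel unanalysable.
    """
    baseline = curve.baseline
    if not baseline > 0:
        raise ValueError("non-positive baseline: voxel unanalysable")
    return (curve.signal - baseline) / baseline


def auc_normalised(norm_curve: np.ndarray, times: np.ndarray) -> float:
    """Signed trapezoidal area between the baseline and the normalised curve."""
    return float(np.trapezoid(np.asarray(norm_curve, float), np.asarray(times, float)))


class _SearchTables:
    """Breakpoint-candidate tables for one sampling grid (y-independent)."""

    def __init__(self, times: np.ndarray, min_seg: int = MIN_SEG):
        t = np.asarray(times, dtype=float)
        n = t.size
        if n < 8:
            raise ValueError("need at least 8 time points")
        self.times = t
        self.n = n
        m = min_seg - 1  # index gap implied by the segment-length rule
        # candidate (onset, peak) pairs: i >= m keeps >= min_seg baseline
        # samples; j - i >= m keeps the rise segment legal; j <= n-1-m leaves
        # room for the plateau
        i_list, j_list = [], []
        for i in range(m, n - 1 - m):
            for j in range(i + m, n - m):
                i_list.append(i)
                j_list.append(j)
        self.i = np.asarray(i_list)
        self.j = np.asarray(j_list)
        # candidate washout indices for the 4-segment model
        self.k = np.arange(2 * m, n - m)
        # prefix sums over t and t^2 (length n+1)
        ct = np.concatenate([[0.0], np.cumsum(t)])
        ct2 = np.concatenate([[0.0], np.cumsum(t * t)])
        ti, tj = t[self.i], t[self.j]
        span = tj - ti
        cnt_rise = self.j - self.i - 1  # interior samples of the rise
        s_t = ct[self.j] - ct[self.i + 1]
        s_t2 = ct2[self.j] - ct2[self.i + 1]
        rise_sq = (s_t2 - 2 * ti * s_t + ti * ti * cnt_rise) / span**2
        self.a11 = rise_sq + (n - self.j)  # phi1 . phi1
        tk = t[self.k]
        cnt_tail = n - 1 - self.k
        s_t_tail = ct[n] - ct[self.k + 1]
        s_t2_tail = ct2[n] - ct2[self.k + 1]
        self.a22 = s_t2_tail - 2 * tk * s_t_tail + tk * tk * cnt_tail  # phi2.phi2
        self.a12 = s_t_tail - tk * cnt_tail  # phi1.phi2 (phi1 == 1 past the plateau)
        # triple validity: washout must start after the plateau (k >= j + m)
        valid = self.k[None, :] >= (self.j[:, None] + m)
        self.pv, self.kv = np.nonzero(valid)  # flat list of legal triples
        self.a11v = self.a11[self.pv]
        self.a22v = self.a22[self.kv]
        self.a12v = self.a12[self.kv]
        det = self.a11v * self.a22v - self.a12v**2
        self.detv = np.where(np.abs(det) < 1e-300, np.inf, det)
        self.ti, self.tj, self.tk, self.span = ti, tj, tk, span

    def curve_terms(self, y: np.ndarray):
        """Per-curve projections b1 = phi1.y (pairs) and b2 = phi2.y (k)."""
        y = np.atleast_2d(y)
        t = self.times
        n = self.n
        cy = np.concatenate([np.zeros((y.shape[0], 1)), np.cumsum(y, axis=1)], axis=1)
        cty = np.concatenate(
            [np.zeros((y.shape[0], 1)), np.cumsum(y * t, axis=1)], axis=1
        )
        s_y = cy[:, self.j] - cy[:, self.i + 1]
        s_ty = cty[:, self.j] - cty[:, self.i + 1]
        tail_y = cy[:, [n]] - cy[:, self.j]
        b1 = (s_ty - self.ti * s_y) / self.span + tail_y
        tail_y_k = cy[:, [n]] - cy[:, self.k + 1]
        tail_ty_k = cty[:, [n]] - cty[:, self.k + 1]
        b2 = tail_ty_k - self.tk * tail_y_k
        return b1, b2


_TABLE_CACHE: dict[tuple, _SearchTables] = {}


def _tables_for(times: np.ndarray, min_seg: int = MIN_SEG) -> _SearchTables:
    key = (times.tobytes(), min_seg)
    if key not in _TABLE_CACHE:
        if len(_TABLE_CACHE) > 8:
            _TABLE_CACHE.clear()
        _TABLE_CACHE[key] = _SearchTables(times, min_seg)
    return _TABLE_CACHE[key]


def _fit_batch(tab: _SearchTables, y: np.ndarray):
    """Exhaustive-search fit of a batch of normalised curves.

    Returns an (n_curves, 8) array of [t_onset, ire, ttp, me, t_washout, irw,
    sse, non_enhancing].
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    nc = y.shape[0]
    yy = np.einsum("ct,ct->c", y, y)
    b1, b2 = tab.curve_terms(y)

    # --- 3-segment (no washout): model = ME * phi1, ME >= 0
    me3 = np.clip(b1 / tab.a11, 0.0, None)
    sse3 = yy[:, None] - 2 * me3 * b1 + me3**2 * tab.a11
    best3 = np.argmin(sse3, axis=1)
    sse3_best = sse3[np.arange(nc), best3]

    # --- 4-segment: model = ME * phi1 + IRW * phi2, ME >= 0, IRW <= 0
    # det > 0, so the constraint signs can be read off the solve numerators;
    # SSE = yy - gain with gain = (b1*num_me + b2*num_irw)/det
    b1v = b1[:, tab.pv]
    b2v = b2[:, tab.kv]
    num_me = b1v * tab.a22v - b2v * tab.a12v
    num_irw = tab.a11v * b2v - tab.a12v * b1v
    gain = (b1v * num_me + b2v * num_irw) / tab.detv
    gain = np.where((num_me >= 0) & (num_irw <= 0), gain, -np.inf)
    best4 = np.argmax(gain, axis=1)
    sse4_best = yy - gain[np.arange(nc), best4]

    out = np.zeros((nc, 8))
    tiny = 1e-12
    # numerical floor: tiny negative SSE from cancellation is clipped
    sse3_best = np.clip(sse3_best, 0.0, None)
    sse4_best = np.clip(sse4_best, 0.0, None)
    use4 = sse4_best < sse3_best - tiny * np.maximum(yy, 1.0)
    model_sse = np.where(use4, sse4_best, sse3_best)
    # non-enhancing: the flat zero model is at least as good as the best fit
    non_enh = yy <= model_sse + tiny * np.maximum(yy, 1.0)

    for c in range(nc):
        if non_enh[c]:
            out[c] = [0, 0, 0, 0, 0, 0, 0, 1]
            out[c, 6] = yy[c]
            continue
        if use4[c]:
            t = best4[c]
            p, kidx = tab.pv[t], tab.kv[t]
            me = (b1[c, p] * tab.a22v[t] - b2[c, kidx] * tab.a12v[t]) / tab.detv[t]
            irw = (tab.a11v[t] * b2[c, kidx] - tab.a12v[t] * b1[c, p]) / tab.detv[t]
            t_on, t_pk, t_wo = tab.ti[p], tab.tj[p], tab.tk[kidx]
            ttp = t_pk - t_on
            out[c] = [t_on, me / ttp, ttp, me, t_wo, irw, model_sse[c], 0]
        else:
            p = best3[c]
            me = me3[c, p]
            t_on, t_pk = tab.ti[p], tab.tj[p]
            ttp = t_pk - t_on
            out[c] = [t_on, me / ttp, ttp, me, 0.0, 0.0, model_sse[c], 0]
    return out


def fit_piecewise_linear(
    norm_curve: np.ndarray, times: np.ndarray, min_seg: int = MIN_SEG
) -> SemiQuantParams:
    """Fit the continuous piecewise-linear enhancement model to one curve.

    Exhaustive search over breakpoint triples on the sampling grid; the
    three-segment no-washout model competes on SSE and sets the sentinel pair
    (Twashout = 0, IRW = 0) when it wins.  A curve for which the flat model
    is optimal is returned all-zero and flagged non-enhancing.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(norm_curve, dtype=float)
    if y.shape != times.shape:
        raise ValueError("curve and times must share a shape")
    tab = _tables_for(times, min_seg)
    row = _fit_batch(tab, y[None, :])[0]
    return SemiQuantParams(
        t_onset=row[0],
        ire=row[1],
        ttp=row[2],
        me=row[3],
        t_washout=row[4],
        irw=row[5],
        auc=auc_normalised(y, times),
        sse=row[6],
        non_enhancing=bool(row[7]),
    )


def fit_semiquant_volume(
    signals: np.ndarray,
    times: np.ndarray,
    n_baseline: int = 5,
    batch: int = 8,
    min_seg: int = MIN_SEG,
):
    """Normalise and fit every row of ``signals`` (n_voxels, n_times).

    Returns ``(params, report)``: a dict of per-voxel arrays for the seven
    parameters plus ``sse``, ``non_enhancing``, ``analysable``, and a quality
    report counting unanalysable, non-enhancing and no-washout voxels.
    """
    times = np.asarray(times, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if sig.ndim != 2 or sig.shape[1] != times.size:
        raise ValueError("signals must be (n_voxels, n_times)")
    nv = sig.shape[0]
    tab = _tables_for(times, min_seg)
    baseline = sig[:, :n_baseline].mean(axis=1)
    analysable = baseline > 0
    res = np.zeros((nv, 8))
    auc = np.zeros(nv)
    idx = np.flatnonzero(analysable)
    norm_all = np.zeros_like(sig)
    norm_all[idx] = sig[idx] / baseline[idx, None] - 1.0
    auc[idx] = np.trapezoid(norm_all[idx], times, axis=1)
    for lo in range(0, idx.size, batch):
        sel = idx[lo : lo + batch]
        res[sel] = _fit_batch(tab, norm_all[sel])
    params = {name: res[:, i] for i, name in enumerate(
        ("t_onset", "ire", "ttp", "me", "t_washout", "irw")
    )}
    params["auc"] = auc
    params["sse"] = res[:, 6]
    params["non_enhancing"] = res[:, 7].astype(bool) & analysable
    params["analysable"] = analysable
    for key in params:
        if params[key].dtype != bool:
            params[key] = np.where(analysable, params[key], np.nan)
    report = {
        "n_voxels": int(nv),
        "n_unanalysable": int((~analysable).sum()),
        "n_non_enhancing": int(params["non_enhancing"].sum()),
        "n_no_washout": int(
            np.sum(
                analysable
                & ~params["non_enhancing"]
                & (np.nan_to_num(params["t_washout"]) == 0.0)
            )
        ),
    }
    return params, report
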