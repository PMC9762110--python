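"""Fit the standard Tofts model to a noisy voxel curve and report iAUGC60.

Simulates a tumour-like voxel (Ktrans = 0.35 /min, Ve = 0.30) under the
Parker AIF at 3.6 s sampling, adds concentration noise, and fits (Ktrans,
Ve) by bounded multi-start least squares.  Also computes the initial area
under the concentration curve over the first 60 s post-injection.
"""

import numpy as np

from dceprost import AifSpec, fit_tofts, iaugc60, parker_aif, tofts_forward
from dceprost.conversion import ConcentrationCurve

rng = np.random.default_rng(42)
times = np.arange(120) * 3.6
aif = parker_aif(AifSpec(onset_time=18.0), np.arange(0.0, times.max() + 1.0, 0.5))

kt_true, ve_true = 0.35, 0.30
clean = tofts_forward(kt_true, ve_true, aif, times)
noisy = ConcentrationCurve(times=times, conc=clean.conc + rng.normal(0, 0.02, times.size))

fit = fit_tofts(noisy, aif)
area = iaugc60(noisy, t_start=18.0)

print(f"truth : Ktrans {kt_true:.3f} /min, Ve {ve_true:.3f}, kep {kt_true/ve_true:.2f} /min")
print(
    f"fitted: Ktrans {fit.ktrans:.3f} /min, Ve {fit.ve:.3f}, kep {fit.kep:.2f} /min "
    f"(rmse {fit.rmse*1000:.1f} uM, converged={fit.converged})"
)
print(f"iAUGC60: {area:.3f} mM*min")
# With 0.02 mM noise the fit typically lands within a few percent of truth;
# iAUGC60 integrates the measured curve directly, so it needs no model at all.
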