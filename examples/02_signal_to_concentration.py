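"""Convert a dynamic SPGR signal curve to gadolinium concentration and back.

Synthesises a voxel's spoiled-gradient-echo signal for a known concentration
time course (fixed prostate T1 of 1597 ms, relaxivity 3.5 L/mmol/s), inverts
it with the closed-form baseline-ratio inversion, and prints the round-trip
error — which should sit at numerical precision, since the inversion is
exact, not linearised.
"""

import numpy as np

from dceprost import SignalCurve, acquisition_preset, signal_to_concentration, spgr_signal

acq = acquisition_preset("120x3.6")
times = acq.times

# a plausible tissue concentration curve: fast uptake, slow washout
conc_true = np.where(times > 18.0, 1.8 * (1 - np.exp(-(times - 18.0) / 40.0)), 0.0)
conc_true *= np.exp(-np.clip(times - 18.0, 0, None) / 600.0)

signal = spgr_signal(conc_true, acq, s0=2500.0, t10=acq.t1_tissue)
curve = SignalCurve(times=times, signal=signal, n_baseline=acq.n_baseline)
recovered = signal_to_concentration(curve, acq, acq.t1_tissue)

err = np.abs(recovered.conc - conc_true).max()
print(f"baseline signal : {curve.baseline:8.2f} (scanner units)")
print(f"peak enhancement: {signal.max() / curve.baseline:8.2f} x baseline")
print(f"peak conc       : {recovered.conc.max():8.3f} mM (true {conc_true.max():.3f})")
print(f"round-trip error: {err:.2e} mM, flagged samples: {recovered.n_flagged}")
# The error is ~1e-15 mM: the scanner scale cancels in the ratio and the
# SPGR equation is inverted algebraically.
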