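"""Extract the seven semi-quantitative parameters from a signal curve.

Builds a normalised enhancement curve with a known trapezoid shape (onset,
linear wash-in, plateau, washout), fits the continuous piecewise-linear
model by exhaustive breakpoint search, and prints the recovered parameters
next to the ground truth.
"""

import numpy as np

from dceprost import SignalCurve, fit_piecewise_linear, normalise_signal

times = np.arange(120) * 3.6
t_onset, ttp, me, t_washout, irw = 28.8, 36.0, 0.8, 302.4, -0.001

norm_true = np.zeros_like(times)
rise = (times > t_onset) & (times <= t_onset + ttp)
norm_true[rise] = me * (times[rise] - t_onset) / ttp
norm_true[(times > t_onset + ttp) & (times <= t_washout)] = me
wash = times > t_washout
norm_true[wash] = me + irw * (times[wash] - t_washout)

rng = np.random.default_rng(0)
signal = 400.0 * (1.0 + norm_true) + rng.normal(0, 2.0, times.size)
norm = normalise_signal(SignalCurve(times=times, signal=signal, n_baseline=5))
p = fit_piecewise_linear(norm, times)

print(f"{'parameter':10s} {'truth':>10s} {'fitted':>10s}")
print(f"{'Tonset':10s} {t_onset:10.1f} {p.t_onset:10.1f}   s")
print(f"{'IRE':10s} {me/ttp:10.4f} {p.ire:10.4f}   /s")
print(f"{'TTP':10s} {ttp:10.1f} {p.ttp:10.1f}   s")
print(f"{'ME':10s} {me:10.3f} {p.me:10.3f}")
print(f"{'Twashout':10s} {t_washout:10.1f} {p.t_washout:10.1f}   s")
print(f"{'IRW':10s} {irw:10.4f} {p.irw:10.4f}   /s")
print(f"{'AUC':10s} {'':>10s} {p.auc:10.1f}   (signed area)")
# Breakpoints land on the 3.6 s sampling grid, so the noiseless parameters
# are recovered exactly; with noise they move by at most a grid step or two.
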