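"""TCSPC histogram corrections and mono-exponential lifetime fitting.

Simulates raw detector histograms for three bead populations
(1.5 / 3.4 / 4.0 ns) with per-pixel delay skew, a constant background and
Poisson counting noise; applies the standard correction chain; fits each
pixel and prints the recovered population lifetimes.
"""

import numpy as np

import lifttomo as lt

rng = np.random.default_rng(0)
n_bins, bw = 200, 0.05  # 50 ps bins over a 10 ns window
t = (np.arange(n_bins) + 0.5) * bw

taus = np.repeat([1.5, 3.4, 4.0], 40)
delays = rng.integers(0, 15, size=taus.size)
raw = np.empty((taus.size, n_bins))
for p, (tau, delay) in enumerate(zip(taus, delays)):
    clean = lt.synthesize_decay(tau, 2e4, t)
    raw[p] = rng.poisson(np.roll(clean, delay) + 3.0)  # skew + background

corr = lt.CorrectionTables(background=np.full((1, n_bins), 3.0),
                           zero_ref_bins=delays)
hset = lt.preprocess_histograms(lt.TCSPCHistogramSet(raw, bin_width_ns=bw),
                                corr)

lmap = lt.fit_lifetime_map(hset.counts, t, refine=True)
print(f"fitted {int(lmap.mask.sum())}/{taus.size} pixels")
for tau in (1.5, 3.4, 4.0):
    est = lmap.tau_ns[lmap.mask & (np.abs(taus - tau) < 1e-9)]
    print(f"population {tau} ns -> mean fit {est.mean():.3f} ns "
          f"(sd {est.std():.3f})")
counts, centers = lt.lifetime_histogram(lmap, bins=np.arange(0.5, 5.0, 0.1))
print("histogram peaks (ns):", np.round(lt.histogram_peaks(counts, centers), 2))
print("Three distinct peaks = the three bead populations are resolved.")
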