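"""The three connectivity measures on one scan.

Static FC is the Pearson correlation of two nodes' timeseries (analyzed as
Fisher z). Dynamic FC is the variance of the edge's DCC conditional-
correlation series; entropic FC is that series' histogram differential
entropy (60 bins, nats). A scan whose true coupling switches regimes gets
high dFC; a steady scan does not.
"""

import numpy as np

from sdefc import (
    GroundTruth,
    alternating_regimes,
    dcc_edge,
    entropy_hist,
    scan_connectivity,
    simulate_scan,
    split_halves,
)

# steady coupling at r = 0.5
steady = GroundTruth(static_corr=np.array([[1.0, 0.5], [0.5, 1.0]]))
scan = simulate_scan(steady, 400, seed=2, node_ids=["A", "B"])
first, second = split_halves(scan)
print(f"split: {scan.n_timepoints} -> {first.n_timepoints} + {second.n_timepoints}")

mats = scan_connectivity(scan)
for name, cm in mats.items():
    print(f"{name:8s} edge value: {cm.values[0, 1]: .4f}")

# regime-switching coupling: r alternates 0.8 / 0.0 every 50 volumes
hi = np.array([[1.0, 0.8], [0.8, 1.0]])
lo = np.eye(2)
switching = GroundTruth(static_corr=lo, regimes=alternating_regimes(400, 50, hi, lo))
scan2 = simulate_scan(switching, 400, seed=3, node_ids=["A", "B"])

s_steady = dcc_edge(scan.data[:, 0], scan.data[:, 1])
s_switch = dcc_edge(scan2.data[:, 0], scan2.data[:, 1])
for label, s in (("steady", s_steady), ("switching", s_switch)):
    print(f"{label:10s} dFC (var R_t) = {np.var(s.series, ddof=1):.4f}   "
          f"eFC (H, nats) = {entropy_hist(s.series):.3f}   "
          f"DCC a={s.params['a']:.3f} b={s.params['b']:.3f}")

# The switching edge shows an order of magnitude more conditional-correlation
# variance: exactly the time-varying structure dFC is designed to detect.
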