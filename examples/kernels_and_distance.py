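"""Kernels, online traces and the van Rossum spike-train distance.

Shows the double-exponential kernel machinery every other component builds
on: evaluating the normalized kernel, realizing it online by filtering
twice, and measuring spike-train dissimilarity.
"""

import numpy as np

from superspike import KernelParams, frozen_poisson, kernel_eval, van_rossum_distance
from superspike.kernels import filter_spike_train

k = KernelParams()  # PSP shape: tau_rise 5 ms, tau_decay 10 ms, unit peak
print(f"kernel peak at t* = {k.peak_time_ms:.2f} ms, value {kernel_eval(k.peak_time_ms, k):.3f}")

# online two-stage filter vs the kernel itself
dense = np.zeros((400, 1))
dense[0, 0] = 1.0
trace = filter_spike_train(dense, k, 0.1)
t = (np.arange(400) + 1) * 0.1
print(f"max |online trace - kernel| over 40 ms: {np.abs(trace[:, 0] - kernel_eval(t, k)).max():.2e}")

a = frozen_poisson(5, 1000.0, 8.0, seed=1)
b = frozen_poisson(5, 1000.0, 8.0, seed=2)
_, d_ab = van_rossum_distance(a, b, k)
_, d_aa = van_rossum_distance(a, a, k)
print(f"van Rossum distance: d(a, b) = {d_ab:.4f},  d(a, a) = {d_aa:.4f}")
# d(a, a) = 0 exactly; d(a, b) grows with the number of non-coincident spikes.
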