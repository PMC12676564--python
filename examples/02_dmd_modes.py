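"""Hankel-DMD of a single 2-s EEG segment.

A noise-free two-tone segment (6 Hz anterior + 22 Hz posterior) is
shift-stacked (S=48), the DMD operator is fitted at rank R=100, and the
band-filtered mode map is printed: each retained mode has an eigenfrequency
(Hz) and a per-channel magnitude profile.
"""

import numpy as np

from dmdeeg import build_hankel, fit_dmd, mode_map

dt = 1 / 500.0
t = np.arange(1000) * dt
anterior = np.r_[np.linspace(2, 1, 10), np.zeros(9)]
posterior = np.r_[np.zeros(9), np.linspace(1, 2, 10)]
segment = (np.outer(anterior, np.sin(2 * np.pi * 6 * t))
           + np.outer(posterior, np.sin(2 * np.pi * 22 * t + 0.4)))

hankel = build_hankel(segment, S=48, dt=dt)
print(f"Hankel matrix: {hankel.values.shape}  (M*S x N-S+1)")

result = fit_dmd(hankel, R=100)
print(f"numerical rank kept: {result.rank}")

mm = mode_map(result, band=(4.0, 40.0))
print(f"retained modes in 4-40 Hz: K={mm.K}")
for j in range(mm.K):
    profile = mm.magnitudes[:, j]
    side = "anterior" if profile[:9].sum() > profile[10:].sum() else "posterior"
    print(f"  mode {j}: {mm.frequencies[j]:6.2f} Hz, {side}-weighted")

# The two planted tones come back within a fraction of a Hz, each with the
# scalp weighting it was planted with -- the information the 50x50 feature
# images rasterize.
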