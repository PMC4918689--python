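"""Build the tapered window and a correlation plot for one synthetic subject.

The taper is a 15-TR rectangle convolved with a 4-tap Gaussian (18 taps in
total), so 120 usable volumes leave 103 fully contained window positions.
The correlation plot CC_n stacks the windowed correlations of one reference
network against the six others.
"""

import numpy as np

from phmmdfc import SyntheticSpec, build_correlation_plot, build_taper, \
    generate_timecourses, n_windows

taper = build_taper(rect_len=15, gauss_len=4, gauss_sigma=1.0)
print(f"taper support: {len(taper)} TRs, weight sum {taper.weights.sum():.3f}")
print(f"window positions on 120 volumes: {n_windows(120, taper)}")

spec = SyntheticSpec(seed=7)  # 7 networks x 120 volumes at TR = 3 s
tc = generate_timecourses(spec, subject_index=0)
cp = build_correlation_plot(tc, reference_index=5, window=taper)  # MON vs rest

print(f"\nreference network: {cp.reference_label}")
print(f"correlation plot: {cp.n_channels} channels x {cp.n_windows} windows")
print(f"channels: {cp.channel_labels}")
print(f"correlation range: [{cp.values.min():+.2f}, {cp.values.max():+.2f}]")
# Each row tracks how one network's coupling with MON drifts across the
# session; values near +/-1 mean strong (anti-)correlation in that window.
print("first 5 windows of MON-DMN coupling:",
      np.round(cp.values[0, :5], 3))
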