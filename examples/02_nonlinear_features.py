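"""Non-linear parameters: complexity, irregularity, variability.

Compares a regular oscillation against broadband noise: the noise has
higher Lempel-Ziv complexity and sample entropy (more irregular) and a
lower central tendency measure (more variable second-order differences).
"""

import numpy as np

import nptnet
from nptnet.nonlinear import NonlinearConfig

rng = np.random.default_rng(1)
t = np.arange(5000) / 1000.0
regular = np.sin(2 * np.pi * 8.0 * t)
noisy = rng.standard_normal(t.size)

cfg = NonlinearConfig()  # m=1, r=0.25*std, CTM radius 0.025, median threshold
for name, x in [("8 Hz oscillation", regular), ("white noise", noisy)]:
    lzc = nptnet.lempel_ziv_complexity(x, cfg)
    sampen = nptnet.sample_entropy(x, cfg)
    ctm = nptnet.central_tendency_measure(x, NonlinearConfig(ctm_radius=0.1))
    print(f"{name:<17s} LZC={lzc:.3f}  SampEn={sampen:.3f}  CTM={ctm:.3f}")

# LZC near 0 marks a compressible (regular) signal, near 1 a random one;
# SampEn grows with irregularity; CTM counts the fraction of second-order
# difference points inside a small circle, so smooth signals score high.
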