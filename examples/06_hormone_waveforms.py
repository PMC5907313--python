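"""Sex-specific hormone source waveforms.

The male growth-hormone source oscillates daily (~24 h period); the female
estrogen source follows the ~monthly (720 h) estrous cycle with a single
peak.  Oscillations are mean-preserving, so sexes differ in waveform and in
source ratios (androgen:estrogen = 10 in males, estrogen:androgen = 3 in
females), not in period-averaged growth-hormone exposure.
"""

import numpy as np

from liversim import configure_sex, dominant_period, hormone_level, load_reference

male = configure_sex(load_reference(), "male")
gh = next(p for p in male.hormone_profiles if p.hormone == "growth_hormone")
t = np.arange(0.0, 7 * 24.0, 0.1)
print(f"male GH source dominant period: {dominant_period(hormone_level(gh, t), 0.1):.1f} h")

female = configure_sex(load_reference(), "female")
es = next(p for p in female.hormone_profiles if p.hormone == "estrogen")
tc = np.arange(0.0, 720.0, 0.1)
y = hormone_level(es, tc)
peaks = np.flatnonzero((y > np.roll(y, 1)) & (y >= np.roll(y, -1)))
print(f"female estrogen source: {len(peaks)} peak per 720 h cycle "
      f"(level range {y.min():.3f}..{y.max():.3f}, mean {y.mean():.3f})")

src_m = male.sources_by_id()
src_f = female.sources_by_id()
print(f"male androgen:estrogen source ratio: "
      f"{src_m['androgen_source'].effective_rate / src_m['estrogen_source'].effective_rate:.1f}")
print(f"female estrogen:androgen source ratio: "
      f"{src_f['estrogen_source'].effective_rate / src_f['androgen_source'].effective_rate:.1f}")
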