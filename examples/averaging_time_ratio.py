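"""The 4-orders-of-magnitude averaging-time law for a 100x weaker sample.

For two scenes that differ only by a 100x photoacoustic source amplitude,
coherently average shots against the same detector-noise stream until each
reaches time-domain SNR 20 and compare the required times (a few seeds
here; scripts/acceptance.py runs 20).
"""

import numpy as np

from dcpas.config import averaging_time_study_scenes
from dcpas.snr import averaging_time_ratio_log10, shots_to_reach_snr

weak, strong = averaging_time_study_scenes(amplitude_ratio=100.0)
kw = dict(centerburst_halfwidth=0.5e-6, exclusion_halfwidth=1.5e-6)

m_strong = shots_to_reach_snr(strong, 20.0, seed=0, **kw)
m_weak = shots_to_reach_snr(weak, 20.0, seed=0, **kw)
period = weak.record_length / 30e6
print(f"strong scene: {m_strong:7d} shots ({m_strong * period * 1e3:9.2f} ms)")
print(f"weak scene:   {m_weak:7d} shots ({m_weak * period * 1e3:9.2f} ms)")

logs = averaging_time_ratio_log10(weak, strong, threshold=20.0,
                                  seeds=[0, 1, 2], **kw)
print(f"log10(time ratio) per seed: {np.round(logs, 3)}")
print(f"mean: {logs.mean():.3f}  (expected ~4: SNR grows as sqrt(time), so a "
      f"100x weaker signal needs 100^2 = 10^4 x the averaging)")
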