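"""Recover a polymer absorption spectrum end-to-end (noiseless).

Simulates the full-scale PDMS scene (~449k-sample record, ~94k beat
notes), runs the apodize / FFT / map / normalize chain and reports the
recovered C-H overtone peak positions against the generator's.
"""

import numpy as np
from scipy.signal import find_peaks

from dcpas.config import build_scene, make_fixture
from dcpas.processing import optical_resolution, recover_absorption

cfg = make_fixture("pdms", scale="paper")
cfg.chain.noise_density_V = 0.0  # noiseless: a single shot suffices
scene = build_scene(cfg)

rec = recover_absorption(scene, m_shots=1)
v = np.where(rec.mask, rec.pa_normalized.magnitude, 0.0)
peaks, _ = find_peaks(v, prominence=0.05 * np.nanmax(v))
res = optical_resolution(rec.config, scene.pair)

print(f"record length: {scene.record_length} samples, "
      f"{scene.pair.n_teeth} beat notes")
print(f"apodization-limited resolution: {res / 1e9:.0f} GHz")
print("recovered peak positions (THz):",
      np.round(rec.nu_optical[peaks] / 1e12, 2))
print("generator peak positions (THz): [171.6 176.0 177.4]")

mu = scene.sample.mu_at(rec.nu_optical[rec.mask])
r = np.corrcoef(rec.pa_normalized.magnitude[rec.mask], mu)[0, 1]
print(f"correlation of normalized response with mu_a: r = {r:.5f}")

# The normalized response Vhat = V_pa / (I0 * H) is proportional to the
# absorption coefficient, so its maxima land on the sample's absorption
# peaks to within the ~500 GHz apodization-limited resolution.
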