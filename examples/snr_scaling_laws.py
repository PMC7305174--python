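"""Verify the square-root averaging law and the acquisition-time calculator.

Averages 1..256 noisy shots of the demo-scale strong-absorber scene,
fits SNR = A * sqrt(tau), then prints the projected acquisition-time
gains for a 500 GHz-repetition-rate comb with 10x stronger absorbance.
"""

import numpy as np

from dcpas.config import build_scene, make_fixture
from dcpas.interferogram import coherent_average, remove_acoustic_delay, simulate_shot
from dcpas.snr import (
    ScalingScenario,
    acquisition_time_scale,
    fit_sqrt_tau,
    time_domain_snr,
)

cfg = make_fixture("vacnt", scale="demo")
cfg.chain.noise_density_V = 6e-3
scene = build_scene(cfg)

points, shot = [], 0
for m in (1, 4, 16, 64, 256):
    pas = []
    for _ in range(m):
        pas.append(simulate_shot(scene, shot)[1])
        shot += 1
    avg = remove_acoustic_delay(coherent_average(pas), scene.chain.t_acoustic)
    r = time_domain_snr(avg, centerburst_halfwidth=0.5e-6)
    points.append(r)
    print(f"M = {m:4d} shots  tau = {r.averaging_time * 1e3:8.2f} ms  "
          f"SNR = {r.value:7.2f}")

fit = fit_sqrt_tau(points)
print(f"\nfit SNR = A sqrt(tau): A = {fit.amplitude:.1f}, "
      f"free exponent = {fit.exponent:.3f} (0.5 = white-noise averaging)")

t, s, proj = acquisition_time_scale(
    ScalingScenario(f_rep_factor=3000, absorbance_factor=10, baseline_time=7200)
)
print(f"\n500 GHz comb (3000x f_rep), 10x absorbance:")
print(f"  averaging-time factor 1/{1 / t:,.0f}; 2 h -> {proj * 1e3:.0f} ms")
_, s_only, _ = acquisition_time_scale(ScalingScenario(f_rep_factor=3000))
print(f"  at fixed time, 3000x f_rep alone gives sqrt(3000) = {s_only:.1f}x SNR")
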