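"""Map a 15 THz optical band into a ~6.3 MHz ultrasound band.

Builds the canonical comb pair (160 MHz repetition rates offset by
66.81 Hz, anchored so 7.5 MHz acoustic corresponds to 171.2 THz optical)
and prints the mapping constants and the non-aliasing diagnostic.
"""

import numpy as np

from dcpas import beat_notes, build_comb_pair, check_alias_free, ultrasound_from_optical

pair = build_comb_pair(160e6, 66.81, nu_center=171.2e12, bandwidth=15e12)
beats = beat_notes(pair)

print(f"compression factor (scale): {pair.scale:.4e}")
print(f"zero-beat optical offset nu0: {pair.nu0 / 1e12:.3f} THz")
print(f"comb teeth in the band: {pair.n_teeth}")
print(f"acoustic band: {beats.f_acoustic[0] / 1e6:.2f} to "
      f"{beats.f_acoustic[-1] / 1e6:.2f} MHz")
print(f"15 THz optical / scale = {15e12 / pair.scale / 1e6:.2f} MHz acoustic")
print(check_alias_free(pair))

# round-trip sanity: every tooth maps back onto itself
f_us = ultrasound_from_optical(pair, beats.nu_optical)
print(f"max round-trip error: {np.max(np.abs(pair.nu0 + pair.scale * f_us - beats.nu_optical)):.2e} Hz")

# The scale factor (~2.39 million) is the bandwidth compression: every
# 2.39 MHz of optical spectrum collapses onto 1 Hz of acoustic spectrum,
# which is what lets a 7.5 MHz ultrasound transducer "see" 15 THz of light.
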