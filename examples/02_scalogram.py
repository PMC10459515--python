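"""Morse-wavelet scalogram of a two-tone test signal.

A 6 Hz + 20 Hz mixture should produce two ridges; the row frequencies of
the strongest time-averaged magnitudes locate them.
"""

import numpy as np

from ulameeg import cwt_morse, render_tf_image

fs = 128
t = np.arange(512) / fs
x = np.sin(2 * np.pi * 6 * t) + np.sin(2 * np.pi * 20 * t)

s = cwt_morse(x, fs)
print(f"scale ladder: {len(s.scale_list)} scales, "
      f"{s.freqs[-1]:.2f}-{s.freqs[0]:.2f} Hz, ratio 2^(1/10)")

profile = s.magnitude.mean(axis=1)
top = np.argsort(profile)[-6:]
print("strongest rows (Hz):", np.sort(np.round(s.freqs[top], 2)))
print("-> clusters near the 6 and 20 Hz tones")

img = render_tf_image(s, size=225)
print(f"gray image: {img.pixels.shape}, dtype {img.pixels.dtype}, "
      f"range {img.pixels.min()}-{img.pixels.max()}")
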