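"""From a synthetic recording to one gray-tone feature vector.

Generates a single labeled recording, filters and segments it, renders a
scalogram image per channel, and samples the prime-mask gray tones.
"""

from ulameeg import (
    SynthSpec,
    clean_recording,
    generate_dataset,
    scalogram_image,
    segment_features,
    segment_recording,
)

rec = generate_dataset(SynthSpec(n_subjects=1, duration_s=8.0, seed=0))[0]
print(f"recording {rec.subject_id}: {rec.n_channels} channels x "
      f"{rec.n_samples} samples at {rec.fs:.0f} Hz, label={rec.label}")

seg = segment_recording(clean_recording(rec), window_len=512)[0]
images = [scalogram_image(seg.data[c], rec.fs, size=225)
          for c in range(rec.n_channels)]
fv = segment_features(images, n=15, label=seg.label)
print(f"feature vector: {len(fv.values)} gray tones "
      f"(= {rec.n_channels} channels x 225 patches x 15 primes)")
print("first 10 tones:", fv.values[:10].tolist())
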