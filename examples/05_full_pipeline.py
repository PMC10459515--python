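"""Full pipeline on the separable synthetic fixture (reduced rendering).

Generates 40 labeled recordings, runs filtering -> scalograms -> prime-mask
features -> fold-internal ReliefF -> SVM 10-fold CV, and prints the report.
Uses 45 x 45 images to keep the run under a minute; swap image_size=225,
relieff_m=7000 for the full-scale reference configuration.
"""

import tempfile
from pathlib import Path

from ulameeg import PipelineConfig, make_fixture, run_pipeline

with tempfile.TemporaryDirectory() as td:
    data = Path(td) / "data"
    make_fixture("separable", data, seed=1)
    cfg = PipelineConfig(
        data_dir=data, out_dir=Path(td) / "out",
        image_size=45, patch_n=15, relieff_m=500,
        cv_seed=1, relieff_seed=1,
    )
    res = run_pipeline(cfg)
    print(f"{res.n_segments} segments, {res.n_features} gray tones, "
          f"{res.n_selected} selected per training fold")
    print(res.report.to_markdown())
    print(f"pooled confusion: {res.report.confusion_total}")
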