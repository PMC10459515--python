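"""End-to-end orchestration: load -> filter -> segment -> CWT images ->
prime-mask features -> ReliefF -> SVM cross-validation.

A :class:`PipelineConfig` collects every stage parameter and validates them
all at once before any compute.  Each stage writes a versioned artifact
under ``out_dir`` keyed by a hash of the configuration fields that affect
it (plus the input file listing), so re-running with an unchanged config
reuses cached stages and editing, say, only the SVM grid recomputes only
the classification stage.

The global ReliefF stage scores every gray tone on the full dataset and
exports the weights; the evaluated classifier, however, refits ReliefF
inside each training fold, because selection fitted on all instances leaks
label information into the held-out folds and inflates cross-validated
accuracy even on label-free data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .classify import CVReport, SVMConfig, run_cv
from .features import feature_length, segment_features
from .preprocess import clean_recording, load_recording, segment_recording
from .relieff import FeatureMatrix, run_relieff
from .timefreq import MorseParams, scalogram_image

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "sweep_patch_sizes"]

log = logging.getLogger("ulameeg")

STAGES = ("segments", "features", "select", "report")


@dataclass
class PipelineConfig:
    """All stage parameters for one pipeline run."""

    data_dir: str | Path = "data"
    out_dir: str | Path = "out"
    window_len: int = 512
    notch_hz: float = 50.0
    notch_q: float = 30.0
    lowpass_hz: float = 60.0
    lowpass_order: int = 6
    morse_gamma: float = 3.0
    morse_time_bandwidth: float = 60.0
    voices_per_octave: int = 10
    image_size: int = 225
    patch_n: int | str = 15  # odd divisor of image_size, or "whole"
    relieff_k: int = 5
    relieff_m: int = 7000
    relieff_iterations: int | str = "all"
    relieff_seed: int = 0
    svm: SVMConfig = field(default_factory=SVMConfig)
    cv_folds: int = 10
    cv_seed: int = 0
    grouping: str = "segment"  # "segment" (study protocol) or "subject"
    use_cache: bool = True

    def patch_size(self) -> int:
        return self.image_size if self.patch_n == "whole" else int(self.patch_n)

    def validate(self) -> None:
        """Check every cross-stage invariant; raise one aggregated error."""
        errors = []
        if self.window_len < 32:
            errors.append(f"window_len={self.window_len} must be >= 32")
        n = self.patch_size()
        if n % 2 == 0:
            errors.append(f"patch_n={self.patch_n} must be odd (or 'whole')")
        elif self.image_size % n != 0:
            errors.append(
                f"patch_n={self.patch_n} does not divide image_size={self.image_size}"
            )
        if self.morse_time_bandwidth <= self.morse_gamma:
            errors.append(
                f"morse_time_bandwidth={self.morse_time_bandwidth} must exceed "
                f"morse_gamma={self.morse_gamma}"
            )
        if self.voices_per_octave < 1:
            errors.append("voices_per_octave must be >= 1")
        if self.relieff_k < 1:
            errors.append("relieff_k must be >= 1")
        if self.relieff_m < 1:
            errors.append("relieff_m must be >= 1")
        if self.cv_folds < 2:
            errors.append("cv_folds must be >= 2")
        if self.grouping not in ("segment", "subject"):
            errors.append(f"grouping={self.grouping!r} must be 'segment' or 'subject'")
        if errors:
            raise ValueError("invalid pipeline config: " + "; ".join(errors))

    def morse_params(self) -> MorseParams:
        return MorseParams(
            gamma=self.morse_gamma,
            time_bandwidth=self.morse_time_bandwidth,
            voices_per_octave=self.voices_per_octave,
        )


@dataclass
class PipelineResult:
    report: CVReport
    out_dir: Path
    n_segments: int
    n_features: int
    n_selected: int
    selected_idx: np.ndarray
    weights: np.ndarray
    cache_hits: list[str]


def _cfg_subset(cfg: PipelineConfig, keys: tuple[str, ...]) -> dict:
    d = asdict(cfg)
    return {k: d[k] for k in keys}


def _listing(data_dir: Path) -> list[tuple[str, int]]:
    return sorted(
        (p.name, p.stat().st_size)
        for p in data_dir.iterdir()
        if p.suffix.lower() in (".csv", ".npy", ".edf")
    )


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


_STAGE_KEYS = {
    "segments": ("window_len", "notch_hz", "notch_q", "lowpass_hz", "lowpass_order"),
    "features": (
        "morse_gamma", "morse_time_bandwidth", "voices_per_octave",
        "image_size", "patch_n",
    ),
    "select": ("relieff_k", "relieff_m", "relieff_iterations", "relieff_seed"),
    "report": ("svm", "cv_folds", "cv_seed", "grouping"),
}


def _stage_hash(cfg: PipelineConfig, stage: str, data_dir: Path) -> str:
    payload = {"listing": _listing(data_dir)}
    for s in STAGES[: STAGES.index(stage) + 1]:
        payload[s] = _cfg_subset(cfg, _STAGE_KEYS[s])
    return _hash(payload)


def _compute_segments(cfg: PipelineConfig, data_dir: Path):
    recordings = []
    for path in sorted(data_dir.iterdir()):
        if path.suffix.lower() in (".csv", ".npy", ".edf"):
            recordings.append(load_recording(path))
    if not recordings:
        raise ValueError(f"no recordings found in {data_dir}")
    segments = []
    for rec in recordings:
        cleaned = clean_recording(
            rec,
            notch_hz=cfg.notch_hz,
            notch_q=cfg.notch_q,
            lowpass_hz=cfg.lowpass_hz,
            lowpass_order=cfg.lowpass_order,
        )
        segs = segment_recording(cleaned, window_len=cfg.window_len)
        if not segs:
            log.warning("recording %s shorter than one window; skipped", rec.subject_id)
        segments.extend(segs)
    counts = {}
    for s in segments:
        counts[s.label] = counts.get(s.label, 0) + 1
    log.info(
        "segments: %d recordings -> %d segments (%s)",
        len(recordings), len(segments),
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
    )
    if not segments:
        raise ValueError("no segments produced; recordings too short")
    fs = recordings[0].fs
    return segments, fs


def _compute_features(cfg: PipelineConfig, segments, fs: float):
    n = cfg.patch_size()
    params = cfg.morse_params()
    X_rows, y, groups, seg_ids = [], [], [], []
    for seg in segments:
        images = [
            scalogram_image(
                seg.data[c], fs, params, size=cfg.image_size,
                source=(f"{seg.parent_id}#{seg.index}", c),
            )
            for c in range(seg.data.shape[0])
        ]
        seg_id = f"{seg.parent_id}#{seg.index}"
        fv = segment_features(images, n, label=seg.label, segment_id=seg_id)
        X_rows.append(fv.values)
        y.append(seg.label)
        groups.append(seg.parent_id)
        seg_ids.append(seg_id)
    X = np.vstack(X_rows).astype(np.float64)
    expected = feature_length(segments[0].data.shape[0], cfg.image_size, n)
    assert X.shape[1] == expected, (X.shape, expected)
    log.info("features: %d segments x %d gray tones", X.shape[0], X.shape[1])
    return X, np.array(y), np.array(groups), np.array(seg_ids)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage (with caching) and return the CV report + artifacts."""
    cfg.validate()
    data_dir = Path(cfg.data_dir)
    if not data_dir.is_dir():
        raise ValueError(f"data_dir {data_dir} does not exist")
    out_dir = Path(cfg.out_dir)
    cache_dir = out_dir / "cache"
    cache_dir.mkdir(parents=True, exist_ok=True)
    cache_hits: list[str] = []

    # stage 1+2: segments -> feature matrix (persisted together; segments
    # are cheap relative to the CWT so they share the features artifact)
    feat_hash = _stage_hash(cfg, "features", data_dir)
    feat_file = cache_dir / f"features-{feat_hash}.npz"
    if cfg.use_cache and feat_file.exists():
        with np.load(feat_file, allow_pickle=False) as z:
            X, y, groups = z["X"], z["y"], z["groups"]
        cache_hits.append("features")
        log.info("features: cache hit (%s)", feat_file.name)
    else:
        segments, fs = _compute_segments(cfg, data_dir)
        X, y, groups, seg_ids = _compute_features(cfg, segments, fs)
        np.savez_compressed(feat_file, X=X, y=y, groups=groups, seg_ids=seg_ids)

    # stage 3: ReliefF selection
    sel_hash = _stage_hash(cfg, "select", data_dir)
    sel_file = cache_dir / f"select-{sel_hash}.npz"
    m_eff = min(cfg.relieff_m, X.shape[1])
    if cfg.use_cache and sel_file.exists():
        with np.load(sel_file, allow_pickle=False) as z:
            weights, selected = z["weights"], z["selected"]
        cache_hits.append("select")
        log.info("select: cache hit (%s)", sel_file.name)
    else:
        fm = FeatureMatrix(X=X, y=y)
        res = run_relieff(
            fm, k=cfg.relieff_k, m=m_eff,
            iterations=cfg.relieff_iterations, seed=cfg.relieff_seed,
        )
        weights, selected = res.weights, res.selected_idx
        np.savez_compressed(sel_file, weights=weights, selected=selected)
        flags = np.zeros(len(weights), dtype=int)
        flags[selected] = 1
        import pandas as pd

        pd.DataFrame(
            {"feature_index": np.arange(len(weights)), "weight": weights,
             "selected_flag": flags}
        ).to_csv(out_dir / "weights.csv", index=False)
        log.info("select: kept %d / %d features", len(selected), X.shape[1])

    # stage 4: SVM cross-validation
    rep_hash = _stage_hash(cfg, "report", data_dir)
    rep_file = cache_dir / f"report-{rep_hash}.json"
    if cfg.use_cache and rep_file.exists():
        with open(rep_file) as fh:
            d = json.load(fh)
        report = CVReport(
            per_fold=d["per_fold"],
            mean_sd={k: tuple(v) for k, v in d["mean_sd"].items()},
            confusion_total=d["confusion_total"],
            positive_class=d["positive_class"],
            folds=d["folds"],
        )
        cache_hits.append("report")
        log.info("report: cache hit (%s)", rep_file.name)
    else:
        # ReliefF refit inside each training fold: selecting once on the
        # full matrix before CV leaks labels into the held-out folds and
        # inflates accuracy (the global weights above are an exported
        # artifact, not part of the evaluated model)
        def _fold_selector(X_tr: np.ndarray, y_tr: np.ndarray) -> np.ndarray:
            res = run_relieff(
                FeatureMatrix(X=X_tr, y=y_tr),
                k=cfg.relieff_k, m=m_eff,
                iterations=cfg.relieff_iterations, seed=cfg.relieff_seed,
            )
            return res.selected_idx

        report = run_cv(
            X, y, cfg.svm, folds=cfg.cv_folds, seed=cfg.cv_seed,
            groups=groups if cfg.grouping == "subject" else None,
            feature_selector=_fold_selector,
        )
        with open(rep_file, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        (out_dir / "report.md").write_text(report.to_markdown() + "\n")

    manifest = {
        "config": {k: str(v) if isinstance(v, (Path, SVMConfig)) else v
                   for k, v in asdict(cfg).items()},
        "n_segments": int(X.shape[0]),
        "n_features": int(X.shape[1]),
        "n_selected": int(len(selected)),
        "stage_hashes": {"features": feat_hash, "select": sel_hash, "report": rep_hash},
        "cache_hits": cache_hits,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return PipelineResult(
        report=report,
        out_dir=out_dir,
        n_segments=int(X.shape[0]),
        n_features=int(X.shape[1]),
        n_selected=int(len(selected)),
        selected_idx=np.asarray(selected),
        weights=np.asarray(weights),
        cache_hits=cache_hits,
    )


def sweep_patch_sizes(
    cfg: PipelineConfig, sizes: list[int | str]
) -> dict[str, CVReport | None]:
    """Run the full pipeline once per patch size; failures do not stop the sweep.

    Returns {size: CVReport or None-on-failure}; also writes a Markdown
    table of mean +/- SD metrics per size under out_dir.
    """
    if not sizes:
        raise ValueError("sweep needs at least one patch size")
    results: dict[str, CVReport | None] = {}
    rows = []
    for size in sizes:
        sub = PipelineConfig(**{**asdict(cfg), "patch_n": size,
                                "svm": cfg.svm,
                                "out_dir": Path(cfg.out_dir) / f"patch_{size}"})
        try:
            res = run_pipeline(sub)
            results[str(size)] = res.report
            cells = [
                f"{100 * res.report.mean_sd[m][0]:.2f} ± {res.report.mean_sd[m][1]:.4f}"
                for m in ("accuracy", "sensitivity", "precision", "f1")
            ]
            rows.append(f"| {size} | " + " | ".join(cells) + " |")
        except Exception as exc:  # per-size failure, sweep continues
            log.error("patch size %s failed: %s", size, exc)
            results[str(size)] = None
            rows.append(f"| {size} | failed: {exc} | | | |")
    table = "\n".join(
        ["| Patch | Accuracy | Sensitivity | Precision | F1 score |",
         "|---|---|---|---|---|"] + rows
    )
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "sweep.md").write_text(table + "\n")
    return results
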