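"""End-to-end orchestration: manifest in, tables + summaries + log out.

A run is described by one YAML config (seed, per-stage parameter blocks)
plus a manifest CSV listing the input micrographs (columns: path,
condition, modality, optional pixel_size_a). Every output row is traceable
to its source_id, and the config hash, seed, and package version are stored
in a JSON sidecar; deterministic stages are bit-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .detect import DetectionParams, segment_vesicles
from .io import (
    MeasurementTable,
    config_hash,
    load_config,
    read_micrograph,
    write_table,
)
from .morphometry import (
    measure_detection,
    metrics_to_frame,
    summarize_condition,
)
from .stats import bonferroni_threshold, format_threshold, mann_whitney_u, t_test_unpaired

MANIFEST_COLUMNS = ("path", "condition", "modality")


@dataclass
class RunConfig:
    manifest: str
    output_dir: str
    seed: int = 0
    detection: dict = field(default_factory=dict)
    morphometry: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = load_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class RunLogger:
    """Line-oriented log with ISO timestamps and stage tags."""

    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def log(self, stage: str, message: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.lines.append(f"{stamp} [{stage}] {message}")

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def load_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    base = path.parent
    for p in manifest["path"]:
        if not (base / p).exists() and not Path(p).exists():
            raise FileNotFoundError(f"manifest references missing input file: {p}")
    return manifest


def run_pipeline(config: RunConfig, config_path: Path | None = None) -> Path:
    """Detect -> measure -> summarize (-> compare) over an EM manifest.

    Returns the run directory containing vesicles.csv, summary.csv,
    comparison.json (when exactly two conditions are present), run.json
    metadata, and run.log.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger = RunLogger(out_dir / "run.log")
    cfg_hash = config_hash(config.to_dict())
    logger.log("setup", f"run config hash {cfg_hash} seed {config.seed}")

    manifest = load_manifest(config.manifest)
    base = Path(config.manifest).parent
    det_params = DetectionParams(**config.detection)
    morpho_kwargs = dict(config.morphometry)
    threshold = morpho_kwargs.pop("roundness_threshold", 0.6)
    formula = morpho_kwargs.pop("roundness_formula", "area_major")
    if morpho_kwargs:
        raise ValueError(f"unknown morphometry config keys: {sorted(morpho_kwargs)}")

    all_metrics = []
    failure = None
    for row in manifest.itertuples(index=False):
        path = base / row.path if (base / row.path).exists() else Path(row.path)
        override = getattr(row, "pixel_size_a", None)
        override = None if override is None or pd.isna(override) else float(override)
        try:
            m = read_micrograph(path, pixel_size_override_a=override, modality=row.modality)
            detections = segment_vesicles(m, det_params)
            metrics = [
                measure_detection(
                    d, roundness_threshold=threshold, roundness_formula=formula,
                    condition=str(row.condition),
                )
                for d in detections
            ]
            all_metrics.extend(metrics)
            logger.log("detect", f"{row.path}: {len(detections)} vesicles")
        except Exception as exc:
            failure = f"{row.path}: {exc}"
            logger.log("detect", f"FAILED {failure}")
            break

    frame = metrics_to_frame(all_metrics)
    write_table(
        MeasurementTable(frame, required_columns=("vesicle_id", "source_id")),
        out_dir / "vesicles.csv",
    )

    summaries = []
    if failure is None and len(frame):
        for label, group in frame.groupby("condition"):
            subset = [m for m in all_metrics if m.condition == label]
            s = summarize_condition(subset, str(label))
            summaries.append(
                {
                    "condition": s.condition,
                    "n": s.n,
                    "n_complete": s.n_complete,
                    "mean_diameter_nm": s.mean_diameter_nm,
                    "sd_diameter_nm": s.sd_diameter_nm,
                    "tubular_fraction": s.tubular_fraction,
                    "tubular_count": s.tubular_count,
                    "mode_positions_nm": ";".join(f"{p:.1f}" for p in s.mode_positions_nm),
                }
            )
            logger.log("summarize", f"{label}: n={s.n} mean={s.mean_diameter_nm:.1f} nm")
    pd.DataFrame(summaries).to_csv(out_dir / "summary.csv", index=False)

    if failure is None and config.stats and len(summaries) == 2:
        labels = [s["condition"] for s in summaries]
        x = frame.loc[frame["condition"] == labels[0], "diameter_nm"].to_numpy()
        y = frame.loc[frame["condition"] == labels[1], "diameter_nm"].to_numpy()
        test_name = config.stats.get("test", "mann_whitney_u")
        m_comparisons = int(config.stats.get("m", 1))
        alpha = bonferroni_threshold(float(config.stats.get("alpha", 0.05)), m_comparisons)
        test = (
            t_test_unpaired(x, y, alpha_adjusted=alpha)
            if test_name == "t_unpaired_two_tailed"
            else mann_whitney_u(x, y, alpha_adjusted=alpha)
        )
        comparison = {
            "conditions": labels,
            "test": test.test,
            "statistic": test.statistic,
            "p_value": test.p_value,
            "alpha_adjusted": alpha,
            "alpha_adjusted_display": format_threshold(alpha),
            "significant": test.significant,
            "bonferroni_m": m_comparisons,
        }
        (out_dir / "comparison.json").write_text(json.dumps(comparison, indent=2))
        logger.log("compare", f"{labels[0]} vs {labels[1]}: p={test.p_value:.4g}")

    meta = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "version": __version__,
        "config": config.to_dict(),
        "status": "failed" if failure else "ok",
    }
    if failure:
        meta["failure"] = failure
    (out_dir / "run.json").write_text(json.dumps(meta, indent=2, default=str))
    logger.flush()
    if failure:
        raise RuntimeError(f"pipeline stage failed (partial outputs preserved): {failure}")
    return out_dir
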