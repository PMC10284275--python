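"""End-to-end orchestration: simulate -> score -> features -> decode.

Stages communicate through files in a run directory so each stage can be
re-run and inspected independently; a manifest records the configuration,
the master seed and a SHA-256 checksum of every output, making reruns under
a fixed seed verifiable byte for byte.

The run configuration is a YAML mapping with the keys

``seed``
    master seed for every stage (int).
``out_dir``
    run directory, created if missing.
``simulate``
    optional mapping of :class:`~elevdec.synthetic.SimulationConfig`
    overrides; when present the pipeline generates its own inputs.
``inputs``
    used when ``simulate`` is absent: paths to the dictionary TSV, the
    per-video comment CSVs (with video_id and duration_s), the EEG
    data/metadata file pairs and optionally a self-report CSV.
``decode``
    optional :class:`~elevdec.decoding.CVConfig` overrides.
``options``
    ``log_power`` (bool) and ``smoothing_s`` (int) switches.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import decoding, eeg, scoring, synthetic
from .dictionary import read_dictionary, write_dictionary

__all__ = ["PipelineConfig", "run_pipeline", "stage_simulate", "stage_score",
           "stage_features", "stage_decode"]

log = logging.getLogger("elevdec")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineConfig:
    """Validated run configuration (see module docstring for the schema)."""

    def __init__(self, raw: Mapping[str, Any]):
        self.raw = dict(raw)
        self.seed = int(self.raw.get("seed", 0))
        if "out_dir" not in self.raw:
            raise PipelineError("config: 'out_dir' is required")
        self.out_dir = Path(self.raw["out_dir"])
        self.options = dict(self.raw.get("options", {}))
        self.log_power = bool(self.options.get("log_power", False))
        self.smoothing_s = int(self.options.get("smoothing_s", 0))
        sim = self.raw.get("simulate")
        self.sim_config = None
        if sim is not None:
            sim = dict(sim)
            self.eeg_format = sim.pop("eeg_format", "npy")
            if "video_durations_s" in sim:
                sim["video_durations_s"] = tuple(sim["video_durations_s"])
            sim.setdefault("seed", self.seed)
            self.sim_config = synthetic.SimulationConfig(**sim)
        self.inputs = dict(self.raw.get("inputs", {}))
        cv = dict(self.raw.get("decode", {}))
        cv.setdefault("rng_seed", self.seed)
        self.cv_config = decoding.CVConfig(**cv)
        if self.sim_config is None:
            self._validate_inputs()

    def _validate_inputs(self) -> None:
        if not self.inputs:
            raise PipelineError(
                "config: either a 'simulate' section or an 'inputs' section "
                "is required")
        for key in ("dictionary", "comments", "eeg"):
            if key not in self.inputs:
                raise PipelineError(f"config inputs: {key!r} is required")
        paths = [self.inputs["dictionary"]]
        for spec in self.inputs["comments"]:
            paths.append(spec["path"])
        for spec in self.inputs["eeg"]:
            paths.extend([spec["data"], spec["meta"]])
        if "selfreport" in self.inputs:
            paths.append(self.inputs["selfreport"])
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise PipelineError(f"config inputs: missing files {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def stage_simulate(cfg: PipelineConfig) -> dict[str, Any]:
    """Generate a full fixture set and write it into the run directory."""
    if cfg.sim_config is None:
        raise PipelineError("simulate stage: no 'simulate' section in config")
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    ds = synthetic.simulate_dataset(cfg.sim_config)
    dict_path = out / "dictionary.tsv"
    write_dictionary(ds.dictionary, dict_path)
    comment_specs = []
    for stream in ds.streams:
        p = out / f"comments_{stream.video_id}.csv"
        scoring.write_comments_csv(stream, p)
        comment_specs.append({"video_id": stream.video_id,
                              "duration_s": stream.duration_s, "path": str(p)})
    eeg_specs = []
    suffix = ".npy" if cfg.eeg_format == "npy" else ".csv"
    for rec in ds.recordings:
        stem = f"eeg_{rec.participant_id}_{rec.video_id}"
        dp, mp = out / f"{stem}{suffix}", out / f"{stem}_meta.csv"
        eeg.write_matrix(rec, dp, mp)
        eeg_specs.append({"data": str(dp), "meta": str(mp)})
    sr_path = out / "selfreport.csv"
    pd.DataFrame({"second": np.arange(len(ds.selfreport.mean_trace)),
                  "value": ds.selfreport.mean_trace}).to_csv(sr_path, index=False)
    lat_path = out / "latent.csv"
    pd.DataFrame({"second": np.arange(len(ds.latent)),
                  "latent": ds.latent.values}).to_csv(lat_path, index=False)
    log.info("simulate: %d comment streams, %d recordings -> %s",
             len(ds.streams), len(ds.recordings), out)
    return {
        "dictionary": str(dict_path),
        "comments": comment_specs,
        "eeg": eeg_specs,
        "selfreport": str(sr_path),
        "latent": str(lat_path),
    }


def stage_score(cfg: PipelineConfig, inputs: Mapping[str, Any]) -> Path:
    """Score comment streams and write the raw + z-scored series."""
    try:
        d = read_dictionary(inputs["dictionary"])
        raw_list = []
        for spec in inputs["comments"]:
            stream = scoring.read_comments_csv(
                spec["path"], spec["video_id"], int(spec["duration_s"]))
            raw_list.append(scoring.score_seconds(stream, d))
    except Exception as exc:
        raise PipelineError(f"score stage failed: {exc}") from exc
    raw = scoring.concatenate_series(raw_list)
    if cfg.smoothing_s > 1:
        raw = scoring.moving_average(raw, cfg.smoothing_s)
    z = scoring.zscore_across_videos([raw])
    out = cfg.out_dir / "scores.csv"
    scoring.write_scores_csv(raw, z, out)
    log.info("score: %d seconds over %d videos -> %s",
             len(z), len(z.video_boundaries), out)
    return out


def stage_features(cfg: PipelineConfig, inputs: Mapping[str, Any]) -> Path:
    """Extract per-participant band powers, group-average, write features."""
    video_order = [spec["video_id"] for spec in inputs["comments"]]
    per_participant: dict[str, dict[str, eeg.FeatureMatrix]] = {}
    try:
        for spec in inputs["eeg"]:
            rec = eeg.read_matrix(spec["data"], spec["meta"])
            fm = eeg.extract_features(rec, log10=cfg.log_power)
            per_participant.setdefault(rec.participant_id, {})[rec.video_id] = fm
    except Exception as exc:
        raise PipelineError(f"features stage failed: {exc}") from exc
    matrices = []
    for pid, by_video in sorted(per_participant.items()):
        missing = [v for v in video_order if v not in by_video]
        if missing:
            raise PipelineError(
                f"features stage: participant {pid} lacks videos {missing}")
        cat = eeg.FeatureMatrix(
            np.vstack([by_video[v].values for v in video_order]),
            by_video[video_order[0]].feature_labels)
        cat.to_csv(cfg.out_dir / f"features_{pid}.csv")
        matrices.append(cat)
    group = eeg.group_average(matrices)
    out = cfg.out_dir / "features_group.csv"
    group.to_csv(out)
    log.info("features: %d participants, %d s x %d features -> %s",
             len(matrices), group.n_seconds, group.n_features, out)
    return out


def stage_decode(cfg: PipelineConfig, features_csv: Path, scores_csv: Path
                 ) -> dict[str, Path]:
    """Cross-validated LASSO decoding plus the univariate correlation map."""
    try:
        fm = eeg.FeatureMatrix.from_csv(features_csv)
        scores = pd.read_csv(scores_csv)
        y = scores["z_score"].to_numpy(dtype=float)
    except Exception as exc:
        raise PipelineError(f"decode stage failed reading inputs: {exc}") from exc
    if fm.n_seconds != len(y):
        raise PipelineError(
            f"decode stage: {fm.n_seconds} feature rows vs {len(y)} score rows")
    labels = [f"{c}_{b}" for c, b in fm.feature_labels]
    result = decoding.cross_validated_decode(fm.values, y, cfg.cv_config,
                                             feature_labels=labels)
    out = cfg.out_dir
    paths = {
        "fold_metrics": out / "fold_metrics.csv",
        "summary": out / "decode_summary.json",
        "coefficients": out / "coefficients.csv",
        "correlation_map": out / "correlation_map.csv",
    }
    result.fold_metrics.to_csv(paths["fold_metrics"], index=False)
    with open(paths["summary"], "w") as fh:
        json.dump(result.summary(), fh, indent=2)
    coef = result.coefficient_table()
    coef[["channel", "band"]] = coef["feature"].str.rpartition("_")[[0, 2]]
    coef[["channel", "band", "coefficient"]].to_csv(
        paths["coefficients"], index=False)
    cmap = decoding.correlation_map(fm.values, y, feature_labels=labels)
    cmap.to_csv(paths["correlation_map"], index=False)
    s = result.summary()
    log.info("decode: r = %.3f +/- %.3f, NMSE = %.3f +/- %.3f",
             s["r_mean"], s["r_sd"], s["nmse_mean"], s["nmse_sd"])
    return paths


def run_pipeline(cfg: PipelineConfig | Mapping[str, Any] | str | Path) -> Path:
    """Execute all stages and write a checksummed manifest; returns out_dir."""
    if isinstance(cfg, (str, Path)):
        cfg = PipelineConfig.from_yaml(cfg)
    elif not isinstance(cfg, PipelineConfig):
        cfg = PipelineConfig(cfg)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(cfg.out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        inputs = stage_simulate(cfg) if cfg.sim_config is not None else cfg.inputs
        scores_csv = stage_score(cfg, inputs)
        features_csv = stage_features(cfg, inputs)
        stage_decode(cfg, features_csv, scores_csv)
        manifest = {
            "seed": cfg.seed,
            "config": _jsonable(cfg.raw),
            "outputs": {
                p.name: _sha256(p)
                for p in sorted(cfg.out_dir.iterdir())
                if p.is_file() and p.name not in ("manifest.json", "run.log")
            },
        }
        with open(cfg.out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    finally:
        log.removeHandler(handler)
        handler.close()
    return cfg.out_dir


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
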