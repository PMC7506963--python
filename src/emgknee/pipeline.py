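"""End-to-end orchestration: simulate -> preprocess -> featurize -> train ->
predict -> evaluate.

Every stage writes its artifact to the working directory and re-reads its
inputs from the previous stage's files, so a run can resume from any stage.
The evaluation always happens on the held-out tail of the stream: the
split is contiguous in time (default first 80% train, last 20% test) to
avoid leakage between temporally neighbouring feature windows, and the
min-max normalization is fit on the training portion only.  Predictions
are inverse-transformed back to degrees before scoring.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import models as mdl
from .evaluation import cross_corr_rho, rmse
from .preprocess import FilterSpec, preprocess_emg
from .signals import (AngleSeries, EmgRecording, read_angle_csv, read_emg_csv,
                      read_sidecar, write_angle_csv, write_emg_csv,
                      write_sidecar)
from .synthetic import GaitSimConfig, simulate_recording

log = logging.getLogger("emgknee")


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    Model hyper-parameter defaults mirror the full training recipe; for
    quick desk runs pass smaller ``lstm_epochs`` / ``lstm_hidden`` /
    ``bpnn_max_epochs``.
    """

    workdir: str = "emgknee_run"
    seed: int = 0
    # simulation
    duration_s: float = 60.0
    delay_s: float = 0.2
    interference_amp: float = 0.1
    noise_sd: float = 0.05
    # alignment / features
    delta_t: float = 0.2
    window_n: int = 20
    feature_mode: str = "rrtaf"  # "rrtaf" (16 cols) or "rms" (8 cols)
    # model
    model: str = "lstm"  # or "bpnn"
    split_frac: float = 0.8
    lstm_hidden: int = 200
    lstm_epochs: int = 200
    lstm_seq_len: int = 100
    lstm_batch: int = 50
    lstm_lr: float = 5e-4
    lstm_dropout: float = 0.5
    bpnn_hidden: int = 18
    bpnn_max_epochs: int = 50_000
    bpnn_lr: float = 0.1
    bpnn_goal_mse: float = 0.01
    bpnn_momentum: float = 0.9
    filter: FilterSpec = field(default_factory=FilterSpec)

    def validate(self) -> None:
        if not (0.0 < self.split_frac < 1.0):
            raise ValueError("split_frac must be in (0, 1)")
        if self.model not in ("lstm", "bpnn"):
            raise ValueError("model must be 'lstm' or 'bpnn'")
        if self.feature_mode not in ("rrtaf", "rms"):
            raise ValueError("feature_mode must be 'rrtaf' or 'rms'")

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = FilterSpec(**d["filter"])
        return cls(**d)

    @property
    def paths(self) -> dict:
        w = Path(self.workdir)
        return {
            "workdir": w,
            "meta": w / "recording_meta.json",
            "emg_raw": w / "emg_raw.csv",
            "angle": w / "angle.csv",
            "emg_clean": w / "emg_clean.csv",
            "features": w / "features.csv",
            "checkpoint": w / "model_checkpoint.npz",
            "predictions": w / "predictions.csv",
            "report_csv": w / "report.csv",
            "report_txt": w / "report.txt",
        }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> None:
    cfg.validate()
    p = cfg.paths
    p["workdir"].mkdir(parents=True, exist_ok=True)
    sim = GaitSimConfig(duration_s=cfg.duration_s, delay_s=cfg.delay_s,
                        interference_amp=cfg.interference_amp,
                        noise_sd=cfg.noise_sd, seed=cfg.seed)
    log.info("simulate: duration=%ss delay=%ss seed=%s",
             cfg.duration_s, cfg.delay_s, cfg.seed)
    rec = simulate_recording(sim)
    write_emg_csv(rec.emg, p["emg_raw"])
    write_angle_csv(rec.angle, p["angle"])
    write_sidecar(p["meta"], fs_emg=sim.fs_emg, fs_angle=sim.fs_angle,
                  delay_s=rec.truth_delay_s, seed=sim.seed,
                  duration_s=sim.duration_s)


def stage_preprocess(cfg: PipelineConfig) -> None:
    p = cfg.paths
    meta = read_sidecar(p["meta"])
    rec = read_emg_csv(p["emg_raw"], fs=meta["fs_emg"])
    log.info("preprocess: notch %s Hz Q=%s, band-pass %s-%s Hz order %s",
             cfg.filter.notch_freq, cfg.filter.notch_q,
             cfg.filter.bp_low, cfg.filter.bp_high, cfg.filter.bp_order)
    clean = preprocess_emg(rec, cfg.filter)
    write_emg_csv(clean, p["emg_clean"])


def stage_featurize(cfg: PipelineConfig) -> None:
    p = cfg.paths
    meta = read_sidecar(p["meta"])
    emg = read_emg_csv(p["emg_clean"], fs=meta["fs_emg"])
    angle = read_angle_csv(p["angle"], fs=meta["fs_angle"])
    ap = feat.compute_shift_points(cfg.delta_t, angle.fs, emg.fs)
    log.info("featurize: delta_t=%s -> l=%d angle samples, k=%d emg samples",
             cfg.delta_t, ap.l, ap.k)
    fs = feat.build_aligned_features(emg, angle,
                                     feat.WindowConfig(cfg.window_n, cfg.window_n),
                                     ap)
    df = pd.DataFrame(fs.X, columns=list(fs.feature_names))
    df["angle_deg"] = fs.y
    df.to_csv(p["features"], index=False)
    meta.update(delta_t=cfg.delta_t, lag_l=ap.l, shift_k=ap.k,
                fs_feature=fs.fs_feature)
    write_sidecar(p["meta"], **meta)


def _load_features(cfg: PipelineConfig):
    p = cfg.paths
    df = pd.read_csv(p["features"])
    y = df.pop("angle_deg").to_numpy()
    if cfg.feature_mode == "rms":
        df = df[[c for c in df.columns if c.endswith("_rms")]]
    return df.to_numpy(), y, tuple(df.columns)


def _split(n: int, frac: float) -> int:
    return int(round(n * frac))


def stage_train(cfg: PipelineConfig) -> None:
    p = cfg.paths
    X, y, names = _load_features(cfg)
    n_train = _split(len(y), cfg.split_frac)
    norm_X = feat.fit_normalization(X[:n_train])
    norm_y = feat.fit_normalization(y[:n_train])
    Xn = feat.apply_normalization(X[:n_train], norm_X)
    yn = feat.apply_normalization(y[:n_train], norm_y)

    if cfg.model == "lstm":
        mcfg = mdl.LSTMConfig(input_size=X.shape[1], hidden_size=cfg.lstm_hidden,
                              seq_len=cfg.lstm_seq_len, learning_rate=cfg.lstm_lr,
                              epochs=cfg.lstm_epochs, batch_size=cfg.lstm_batch,
                              dropout_p=cfg.lstm_dropout, seed=cfg.seed)
        log.info("train lstm: %s", mcfg)
        model = mdl.train_lstm(Xn, yn, mcfg, feature_names=names)
        weights = model.weights.arrays()
        mconf = dataclasses.asdict(model.config)
    else:
        mcfg = mdl.BPNNConfig(n_input=X.shape[1], n_hidden=cfg.bpnn_hidden,
                              learning_rate=cfg.bpnn_lr,
                              goal_mse=cfg.bpnn_goal_mse,
                              max_epochs=cfg.bpnn_max_epochs,
                              momentum=cfg.bpnn_momentum, seed=cfg.seed)
        log.info("train bpnn: %s", mcfg)
        model = mdl.train_bpnn(Xn, yn, mcfg, feature_names=names)
        weights = {"W_in": model.W_in, "b_in": model.b_in,
                   "W_out": model.W_out, "b_out": np.asarray(model.b_out)}
        mconf = dataclasses.asdict(model.config)

    meta = {"model": cfg.model, "config": mconf,
            "feature_names": list(names),
            "norm_x_min": norm_X.x_min.tolist(),
            "norm_x_max": norm_X.x_max.tolist(),
            "norm_y_min": norm_y.x_min.tolist(),
            "norm_y_max": norm_y.x_max.tolist(),
            "loss_history": model.loss_history,
            "n_train": n_train}
    np.savez(p["checkpoint"], _meta=json.dumps(meta), **weights)


def load_checkpoint(path):
    """Rebuild (model, norm_X, norm_y, meta) from a checkpoint file."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["_meta"]))
        arrays = {k: z[k] for k in z.files if k != "_meta"}
    names = tuple(meta["feature_names"])
    norm_X = feat.NormalizationParams(np.array(meta["norm_x_min"]),
                                      np.array(meta["norm_x_max"]))
    norm_y = feat.NormalizationParams(np.array(meta["norm_y_min"]),
                                      np.array(meta["norm_y_max"]))
    if meta["model"] == "lstm":
        w = mdl.LSTMWeights(**{k: arrays[k] for k in arrays if k != "b_out"},
                            b_out=float(arrays["b_out"]))
        model = mdl.LSTMModel(weights=w, config=mdl.LSTMConfig(**meta["config"]),
                              feature_names=names,
                              loss_history=list(meta["loss_history"]))
    else:
        model = mdl.BPNNModel(W_in=arrays["W_in"], b_in=arrays["b_in"],
                              W_out=arrays["W_out"], b_out=float(arrays["b_out"]),
                              config=mdl.BPNNConfig(**meta["config"]),
                              feature_names=names,
                              loss_history=list(meta["loss_history"]))
    return model, norm_X, norm_y, meta


def stage_predict(cfg: PipelineConfig) -> None:
    p = cfg.paths
    X, y, names = _load_features(cfg)
    model, norm_X, norm_y, meta = load_checkpoint(p["checkpoint"])
    n_train = meta["n_train"]
    Xn = feat.apply_normalization(X[n_train:], norm_X)
    if meta["model"] == "lstm":
        pred_n = mdl.predict_lstm(model, Xn, feature_names=names)
    else:
        pred_n = mdl.predict_bpnn(model, Xn, feature_names=names)
    pred_deg = feat.invert_normalization(pred_n, norm_y)
    pd.DataFrame({"estimated_deg": pred_deg,
                  "actual_deg": y[n_train:]}).to_csv(p["predictions"], index=False)


def stage_evaluate(cfg: PipelineConfig) -> dict:
    p = cfg.paths
    df = pd.read_csv(p["predictions"])
    report = {
        "model": cfg.model,
        "feature_mode": cfg.feature_mode,
        "rmse_deg": rmse(df["estimated_deg"], df["actual_deg"]),
        "rho": cross_corr_rho(df["estimated_deg"], df["actual_deg"]),
        "n_test": int(len(df)),
        "seed": cfg.seed,
    }
    pd.DataFrame([report]).to_csv(p["report_csv"], index=False)
    lines = ["knee angle estimation report",
             "----------------------------"]
    lines += [f"{k:>14}: {v}" for k, v in report.items()]
    p["report_txt"].write_text("\n".join(lines) + "\n")
    log.info("evaluate: rmse=%.4f deg rho=%.4f", report["rmse_deg"], report["rho"])
    return report


STAGES = ("simulate", "preprocess", "featurize", "train", "predict", "evaluate")


def run_pipeline(cfg: PipelineConfig, from_stage: str = "simulate") -> dict:
    """Run all stages from ``from_stage`` on; returns the evaluation report.

    Deterministic given cfg.seed; every stage's artifact is re-loadable so
    the pipeline can resume mid-way.
    """
    cfg.validate()
    if from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}")
    funcs = {"simulate": stage_simulate, "preprocess": stage_preprocess,
             "featurize": stage_featurize, "train": stage_train,
             "predict": stage_predict, "evaluate": stage_evaluate}
    report = None
    for name in STAGES[STAGES.index(from_stage):]:
        try:
            out = funcs[name](cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        if name == "evaluate":
            report = out
    return report
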