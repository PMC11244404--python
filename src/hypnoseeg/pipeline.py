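"""Configured, resumable end-to-end pipeline.

Stages run in the canonical order of the processing chain — simulate (or
load), electrode/montage validation + mastoid re-reference, FIR filtering,
ICA artifact removal, event-locked epoching, PSD feature extraction, model
training, evaluation — writing every intermediate into a run directory and
recording a manifest with a content hash per artifact. Re-running with
``resume=True`` recomputes only stages whose outputs are missing or whose
configuration changed.

The single global ``seed`` fans out to per-stage seeds by fixed offsets so
stages stay individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import io as _io
from .errors import ConfigError, ValidationError
from .evaluate import metrics_from_labels
from .features import EpochSet, compute_psd, extract_epochs
from .ica import clean_recording
from .models import Hyperparams, predict, split_dataset, train_model
from .preprocess import (
    FilterSpec,
    HIGH_PASS,
    LOW_PASS,
    NOTCH,
    apply_filter,
    design_fir,
    rereference,
)
from .synthdata import SyntheticConfig, simulate

STAGE_ORDER = (
    "simulate",
    "rereference",
    "filter",
    "ica",
    "epoch",
    "features",
    "train",
    "evaluate",
)

_SEED_OFFSETS = {"simulate": 0, "ica": 11, "split": 23, "train": 23}


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateBlock(_Block):
    duration: float = 120.0
    fs: float = 500.0
    event_spacing: float = 2.0
    state_block_s: float = 20.0
    artifact_rate: float = 12.0
    noise_sd: float = 2.0
    theta_alpha_multiplier: float = 1.5


class PreprocessBlock(_Block):
    lowpass: float | None = 30.0
    highpass: float | None = 0.1
    notch: float | None = 40.0
    notch_half_width: float = 2.0
    ref: tuple[str, str] = ("M1", "M2")


class ICABlock(_Block):
    n_components: int = 8
    exclude: str | list[int] = "auto"
    threshold: float = 0.55


class EpochBlock(_Block):
    window: tuple[float, float] = (0.2, 1.0)

    @field_validator("window")
    @classmethod
    def _ordered(cls, v):
        if not v[1] > v[0]:
            raise ValueError(f"epoch window {v} is reversed or empty")
        return v


class FeaturesBlock(_Block):
    psd: str = "periodogram"


class ModelBlock(_Block):
    kind: str = "eegnet"
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 25
    patience: int = 5
    representation: str = "time"


class PipelineConfig(_Block):
    seed: int = 0
    run_id: str = "run"
    log_level: str = "info"
    input_recording: str | None = None  # skip simulate, load this HDF5
    input_events: str | None = None
    simulate: SimulateBlock = SimulateBlock()
    preprocess: PreprocessBlock = PreprocessBlock()
    ica: ICABlock = ICABlock()
    epoch: EpochBlock = EpochBlock()
    features: FeaturesBlock = FeaturesBlock()
    model: ModelBlock = ModelBlock()

    @model_validator(mode="after")
    def _cross_checks(self):
        nyq = self.simulate.fs / 2.0
        for name, fc in (
            ("lowpass", self.preprocess.lowpass),
            ("highpass", self.preprocess.highpass),
            ("notch", self.preprocess.notch),
        ):
            if fc is not None and not 0 < fc < nyq:
                raise ValueError(
                    f"preprocess.{name} = {fc} Hz outside (0, Nyquist={nyq}) "
                    f"at fs={self.simulate.fs}"
                )
        win = self.epoch.window
        if (win[1] - win[0]) * self.simulate.fs < 8:
            raise ValueError(f"epoch window {win} too short at fs={self.simulate.fs}")
        return self


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load + schema-validate a YAML config; empty/missing content = defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw = loaded
    if overrides:
        raw = {**raw, **overrides}
    try:
        return PipelineConfig(**raw)
    except Exception as exc:  # pydantic error -> package error with detail
        raise ConfigError(f"invalid pipeline config: {exc}") from exc


# ---------------------------------------------------------------------------
# hashing and manifest


def _content_hash(path: Path) -> str:
    """Hash file *content* (HDF5 arrays+attrs, else raw bytes).

    HDF5 files embed modification timestamps, so byte hashes are not
    reproducible; hashing the stored arrays and attributes is.
    """
    h = hashlib.sha256()
    if path.suffix == ".h5":
        with h5py.File(path, "r") as f:
            def visit(name, obj):
                h.update(name.encode())
                if isinstance(obj, h5py.Dataset):
                    h.update(np.ascontiguousarray(obj[()]).tobytes())
                for k in sorted(obj.attrs):
                    h.update(k.encode())
                    h.update(str(obj.attrs[k]).encode())
            f.visititems(visit)
            for k in sorted(f.attrs):
                h.update(k.encode())
                h.update(str(f.attrs[k]).encode())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(block) -> str:
    return hashlib.sha256(
        json.dumps(block, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class PipelineError(ValidationError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, resume: bool = False
) -> dict:
    """Execute all stages; returns the manifest (also written as JSON).

    On a stage failure the partial manifest is persisted and a
    :class:`PipelineError` naming the stage is raised.
    """
    out = Path(out_dir) / config.run_id
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    old = {}
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text()).get("stages", {})
    manifest: dict = {"run_id": config.run_id, "seed": config.seed, "stages": {}}

    def record(stage: str, files: dict[str, Path], params: dict, t0: float):
        manifest["stages"][stage] = {
            "order": len(manifest["stages"]),
            "params": params,
            "config_hash": _config_hash(params),
            "files": {k: str(p.relative_to(out)) for k, p in files.items()},
            "hashes": {k: _content_hash(p) for k, p in files.items()},
            "seconds": round(time.time() - t0, 3),
        }

    def reusable(stage: str, params: dict, files: dict[str, Path]) -> bool:
        entry = old.get(stage)
        if not entry or entry.get("config_hash") != _config_hash(params):
            return False
        return all(p.exists() for p in files.values())

    def save_manifest():
        manifest_path.write_text(json.dumps(manifest, indent=2))

    state: dict = {}
    try:
        # --- simulate / load -------------------------------------------------
        t0 = time.time()
        sim = config.simulate
        params = sim.model_dump() | {"seed": config.seed}
        rec_path, ev_path = out / "raw.h5", out / "events.tsv"
        files = {"recording": rec_path, "events": ev_path}
        if config.input_recording:
            rec = _io.load_recording(config.input_recording)
            events = _io.load_events(config.input_events)
            _io.save_recording(rec, rec_path)
            _io.save_events(events, ev_path)
        elif reusable("simulate", params, files):
            rec = _io.load_recording(rec_path)
            events = _io.load_events(ev_path)
        else:
            mult = sim.theta_alpha_multiplier
            scfg = SyntheticConfig(
                fs=sim.fs,
                duration=sim.duration,
                event_spacing=sim.event_spacing,
                state_block_s=sim.state_block_s,
                artifact_rate=sim.artifact_rate,
                noise_sd=sim.noise_sd,
                class_band_power={"RH": {"theta": mult, "alpha": mult}, "ND": {}},
                seed=config.seed + _SEED_OFFSETS["simulate"],
            )
            rec, events, _, _ = simulate(scfg)
            _io.save_recording(rec, rec_path)
            _io.save_events(events, ev_path)
        record("simulate", files, params, t0)

        # --- re-reference ----------------------------------------------------
        t0 = time.time()
        params = {"ref": list(config.preprocess.ref)}
        path = out / "reref.h5"
        if reusable("rereference", params, {"recording": path}):
            rec = _io.load_recording(path)
        else:
            rec = rereference(rec, tuple(config.preprocess.ref))
            _io.save_recording(rec, path)
        record("rereference", {"recording": path}, params, t0)

        # --- filtering -------------------------------------------------------
        t0 = time.time()
        pp = config.preprocess
        params = pp.model_dump()
        path = out / "filtered.h5"
        if reusable("filter", params, {"recording": path}):
            rec = _io.load_recording(path)
        else:
            specs = []
            if pp.lowpass is not None:
                specs.append(FilterSpec(LOW_PASS, pp.lowpass))
            if pp.highpass is not None:
                specs.append(FilterSpec(HIGH_PASS, pp.highpass))
            if pp.notch is not None:
                specs.append(FilterSpec(NOTCH, pp.notch, half_width=pp.notch_half_width))
            for spec in specs:
                rec = apply_filter(rec, design_fir(spec, rec.fs))
            _io.save_recording(rec, path)
        record("filter", {"recording": path}, params, t0)

        # --- ICA -------------------------------------------------------------
        t0 = time.time()
        ic = config.ica
        params = ic.model_dump() | {"seed": config.seed + _SEED_OFFSETS["ica"]}
        path = out / "clean.h5"
        if reusable("ica", params, {"recording": path}):
            rec = _io.load_recording(path)
        else:
            rec, model, scores = clean_recording(
                rec,
                n_components=ic.n_components,
                exclude=ic.exclude,
                threshold=ic.threshold,
                seed=config.seed + _SEED_OFFSETS["ica"],
            )
            _io.save_recording(rec, path)
            (out / "ica_scores.json").write_text(
                json.dumps(
                    [
                        {
                            "component": s.index,
                            "score": round(s.score, 4),
                            "flagged": s.flagged,
                        }
                        for s in scores
                    ],
                    indent=2,
                )
            )
        record("ica", {"recording": path}, params, t0)

        # --- epoching --------------------------------------------------------
        t0 = time.time()
        params = {"window": list(config.epoch.window)}
        path = out / "epochs.h5"
        if reusable("epoch", params, {"epochs": path}):
            arrays, attrs = _io.load_array_group(path)
            epochs = EpochSet(
                data=arrays["data"],
                labels=arrays["labels"].astype("U2"),
                window=tuple(attrs["window"]),
                fs=attrs["fs"],
                channel_names=tuple(attrs["channel_names"]),
            )
        else:
            epochs = extract_epochs(rec, events, tuple(config.epoch.window))
            _io.save_array_group(
                path,
                {"data": epochs.data, "labels": epochs.labels.astype("S2")},
                {
                    "window": list(epochs.window),
                    "fs": epochs.fs,
                    "channel_names": list(epochs.channel_names),
                    "n_dropped": epochs.n_dropped,
                },
            )
        record("epoch", {"epochs": path}, params, t0)

        # --- PSD features ----------------------------------------------------
        t0 = time.time()
        params = config.features.model_dump()
        path = out / "features.h5"
        if not reusable("features", params, {"features": path}):
            psd = compute_psd(epochs, method=config.features.psd)
            _io.save_array_group(
                path,
                {
                    "psd": psd.values,
                    "freqs": psd.freqs,
                    "band_powers": psd.band_powers,
                    "labels": psd.labels.astype("S2"),
                },
                {"bands": list(psd.band_names)},
            )
        record("features", {"features": path}, params, t0)

        # --- train -----------------------------------------------------------
        t0 = time.time()
        mb = config.model
        params = mb.model_dump() | {"seed": config.seed + _SEED_OFFSETS["train"]}
        split_seed = config.seed + _SEED_OFFSETS["split"]
        tr, va, te = split_dataset(epochs.labels, mb.split, seed=split_seed)
        hyper = Hyperparams(
            lr=mb.lr,
            batch_size=mb.batch_size,
            max_epochs=mb.max_epochs,
            patience=mb.patience,
        )
        trained = train_model(
            mb.kind,
            epochs.data[tr],
            epochs.labels[tr],
            epochs.data[va],
            epochs.labels[va],
            hyper=hyper,
            seed=config.seed + _SEED_OFFSETS["train"],
            representation=mb.representation,
        )
        hist_path = out / "history.json"
        hist_path.write_text(json.dumps(trained.history, indent=2))
        record("train", {"history": hist_path}, params, t0)

        # --- evaluate --------------------------------------------------------
        t0 = time.time()
        pred, _ = predict(trained, epochs.data[te])
        report = metrics_from_labels(
            epochs.labels[te], pred, model=mb.kind, dataset=config.run_id
        )
        report_path = out / "report.json"
        report_path.write_text(
            json.dumps(
                {"model": mb.kind, "n_test": int(te.size), **report.as_dict()},
                indent=2,
            )
        )
        record("evaluate", {"report": report_path}, {"split": list(mb.split)}, t0)
    except Exception as exc:
        save_manifest()
        if isinstance(exc, PipelineError):
            raise
        stage = STAGE_ORDER[min(len(manifest["stages"]), len(STAGE_ORDER) - 1)]
        raise PipelineError(stage, exc) from exc

    manifest["stage_order"] = list(manifest["stages"])
    save_manifest()
    return manifest
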