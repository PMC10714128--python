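"""Session files: trial logs, phase-window sidecars, configs, fit results.

The trial log is a TSV with a small JSON metadata header in ``#``-prefixed
comment lines (schema version, config snapshot, seeds), one row per
delivered pulse.  The phase windows that decided each condition pulse go to
a compressed ``.npz`` sidecar, keyed by row index.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .edf import read_edf
from .loop import LoopParams, StimEvent
from .recording import MultichannelRecording
from .phase import PhaseEstimatorConfig
from .synth import MepModel, SynthConfig

TRIAL_LOG_SCHEMA = "plvloop-trial-log/1"

TRIAL_LOG_COLUMNS = ["trial", "time", "kind", "deciding_stplv", "isi",
                     "decision_time", "phase_key"]


@dataclass
class SessionBundle:
    """Paths of the files that make up one recorded/simulated session."""

    recording: Path | None
    trial_log: Path
    phase_windows: Path | None
    ground_truth: Path | None = None

    def __post_init__(self) -> None:
        self.trial_log = Path(self.trial_log)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_trial_log(events: list[StimEvent], path,
                    config_snapshot: dict | None = None,
                    seeds: dict | None = None,
                    phase_sidecar=None) -> None:
    """Write one TSV row per pulse; condition phase windows go to a sidecar."""
    path = Path(path)
    rows = []
    windows = {}
    for j, ev in enumerate(events):
        key = ""
        if ev.phase_window is not None and phase_sidecar is not None:
            key = f"w{j}"
            windows[f"{key}_phi1"] = ev.phase_window.phi1
            windows[f"{key}_phi2"] = ev.phase_window.phi2
        rows.append({
            "trial": j, "time": ev.time, "kind": ev.kind,
            "deciding_stplv": "" if ev.deciding_stplv is None
            else ev.deciding_stplv,
            "isi": ev.isi,
            "decision_time": "" if ev.decision_time is None
            else ev.decision_time,
            "phase_key": key,
        })
    meta = {"schema": TRIAL_LOG_SCHEMA,
            "config": _jsonable(config_snapshot or {}),
            "seeds": _jsonable(seeds or {})}
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS).to_csv(
            fh, sep="\t", index=False)
    if phase_sidecar is not None and windows:
        np.savez_compressed(phase_sidecar, **windows)


def read_trial_log(path) -> tuple[pd.DataFrame, dict]:
    """Read a trial-log TSV; returns ``(table, metadata)``."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path} is not a trial log (missing header)")
        meta = json.loads(first[2:])
        if meta.get("schema") != TRIAL_LOG_SCHEMA:
            raise ValueError(
                f"unsupported trial-log schema {meta.get('schema')!r}")
        table = pd.read_csv(fh, sep="\t")
    return table, meta


def save_json(obj, path) -> None:
    """Serialize fit results / diagnostics (dataclasses, arrays) to JSON."""
    payload = _jsonable(obj)
    if hasattr(obj, "params"):  # FitResult and friends
        payload = {
            "formula": obj.formula_id,
            "params": obj.params.to_dict(),
            "bse": obj.bse.to_dict(),
            "wald": obj.wald.to_dict(orient="index"),
            "aic": obj.aic,
            "llf_ml": obj.llf_ml,
            "n_obs": obj.n_obs,
            "n_groups": obj.n_groups,
            "converged": obj.converged,
            "singular": obj.singular,
            "warnings": obj.warnings,
        }
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2)


def read_recording(path) -> MultichannelRecording:
    """Load a session recording (EDF, μV); EEG and EMG channels are
    distinguished downstream by label prefix (``EMG_*``)."""
    return read_edf(path)


def write_raw_float(path, recording: MultichannelRecording) -> None:
    """Lossless float64 fallback: flat binary + JSON header sidecar.

    EDF quantizes to 16 bits; this format stores the exact samples for
    round-trip-critical intermediates.  ``path`` gets the raw float64
    little-endian channel-major data, ``path + '.json'`` the header.
    """
    path = Path(path)
    recording.data.astype("<f8").tofile(path)
    header = {"sample_rate": recording.sample_rate,
              "labels": list(recording.labels), "units": recording.units,
              "shape": list(recording.data.shape), "dtype": "<f8",
              "order": "channel-major"}
    Path(str(path) + ".json").write_text(json.dumps(header, indent=2))


def read_raw_float(path) -> MultichannelRecording:
    """Read the float64 binary + JSON-header fallback format."""
    path = Path(path)
    header = json.loads(Path(str(path) + ".json").read_text())
    data = np.fromfile(path, dtype=header["dtype"]).reshape(header["shape"])
    return MultichannelRecording(data=data,
                                 sample_rate=header["sample_rate"],
                                 labels=header["labels"],
                                 units=header["units"])


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML config with optional sections synth / phase / loop / mep."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping at top level")
    return cfg


def synth_config(cfg: dict) -> SynthConfig:
    section = dict(cfg.get("synth", {}))
    if "mixing" in section:
        section["mixing"] = np.asarray(section["mixing"], dtype=float)
    if "channels" in section:
        section["channels"] = tuple(section["channels"])
    return SynthConfig(**section)


def phase_config(cfg: dict) -> PhaseEstimatorConfig:
    section = dict(cfg.get("phase", {}))
    if "band" in section:
        section["band"] = tuple(section["band"])
    return PhaseEstimatorConfig(**section)


def loop_params(cfg: dict) -> LoopParams:
    return LoopParams(**cfg.get("loop", {}))


def mep_model(cfg: dict) -> MepModel:
    return MepModel(**cfg.get("mep", {}))
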