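"""On-disk record formats: flat float32 signal arrays with JSON sidecars,
uint8 label arrays, JSON-lines manifests, PNG masks and layout sidecars.

One record = three files sharing a stem::

    <id>.sig.f32   little-endian float32, (12, N) row-major, mV
    <id>.lab.u8    uint8, (12, N) row-major, wave-class codes 0-7
    <id>.json      config + labels/rhythm/phenotype + file references
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
from PIL import Image

from .synthesis import (
    LEAD_NAMES,
    LabelledSignal,
    Phenotype,
    RhythmType,
    SimulationConfig,
    WaveParams,
)

__all__ = [
    "write_record",
    "read_record",
    "write_manifest",
    "read_manifest",
    "config_to_dict",
    "config_from_dict",
    "save_mask_png",
    "load_mask_png",
    "save_image_png",
    "load_image_png",
]


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["rhythm"] = config.rhythm.value
    d["phenotype"] = config.phenotype.value
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["rhythm"] = RhythmType(d["rhythm"])
    d["phenotype"] = Phenotype(d["phenotype"])
    d["wave_params"] = WaveParams(**d["wave_params"])
    return SimulationConfig(**d)


def write_record(out_dir: str | Path, record_id: str,
                 signal: LabelledSignal) -> dict:
    """Write one record; returns its manifest entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig_path = out_dir / f"{record_id}.sig.f32"
    lab_path = out_dir / f"{record_id}.lab.u8"
    meta_path = out_dir / f"{record_id}.json"

    sig = np.ascontiguousarray(signal.samples, dtype="<f4")
    lab = np.ascontiguousarray(signal.labels, dtype=np.uint8)
    sig.tofile(sig_path)
    lab.tofile(lab_path)

    meta = {
        "id": record_id,
        "leads": list(LEAD_NAMES),
        "shape": list(sig.shape),
        "dtype": "<f4",
        "rhythm": signal.rhythm_label.value,
        "phenotype": signal.phenotype_label.value,
        "signal_file": sig_path.name,
        "labels_file": lab_path.name,
        "config": config_to_dict(signal.config),
    }
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return {
        "id": record_id,
        "seed": signal.config.seed,
        "rhythm": signal.rhythm_label.value,
        "phenotype": signal.phenotype_label.value,
        "paths": {
            "signal": sig_path.name,
            "labels": lab_path.name,
            "meta": meta_path.name,
        },
    }


def read_record(out_dir: str | Path, record_id: str) -> LabelledSignal:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{record_id}.json").read_text())
    shape = tuple(meta["shape"])
    sig = np.fromfile(out_dir / meta["signal_file"], dtype="<f4")
    lab = np.fromfile(out_dir / meta["labels_file"], dtype=np.uint8)
    config = config_from_dict(meta["config"])
    return LabelledSignal(
        samples=sig.reshape(shape).astype(np.float64),
        labels=lab.reshape(shape),
        config=config,
        rhythm_label=RhythmType(meta["rhythm"]),
        phenotype_label=Phenotype(meta["phenotype"]),
    )


def write_manifest(path: str | Path, entries: Iterable[dict]) -> None:
    """JSON lines, one record per line, keys sorted for byte-stability."""
    path = Path(path)
    with path.open("w") as fh:
        for entry in entries:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> list[dict]:
    with Path(path).open() as fh:
        return [json.loads(line) for line in fh if line.strip()]


# ---------------------------------------------------------------- PNG IO


def save_image_png(path: str | Path, pixels: np.ndarray) -> None:
    Image.fromarray(pixels, mode="RGB").save(path)


def load_image_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Single-channel PNG whose pixel values are the class codes."""
    Image.fromarray(mask.astype(np.uint8), mode="L").save(path)


def load_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))
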