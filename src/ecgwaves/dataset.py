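"""Reproducible batch generation of labelled synthetic ECG records.

A dataset is defined entirely by (n, seed, class_spec): record ``i`` gets
an independent seed derived from ``SeedSequence([seed, i])``, so any
record can be regenerated without generating the rest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .records import write_manifest, write_record
from .synthesis import (
    Phenotype,
    RhythmType,
    add_noise_and_wander,
    sample_config,
    synthesize_ecg,
)

__all__ = ["DatasetManifest", "generate_dataset", "record_seed", "parse_class_spec"]

ClassKey = tuple[RhythmType, Phenotype]


@dataclass
class DatasetManifest:
    path: Path
    entries: list[dict]

    def __len__(self) -> int:
        return len(self.entries)


def record_seed(dataset_seed: int, index: int) -> int:
    """Per-record seed: first word of SeedSequence([dataset_seed, index]),
    reduced below 2**31 so it remains a portable non-negative int."""
    ss = np.random.SeedSequence([int(dataset_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def parse_class_spec(spec: Mapping) -> dict[ClassKey, float]:
    """Normalise a class spec; keys may be (rhythm, phenotype) tuples or
    'SR/NORMAL'-style strings."""
    out: dict[ClassKey, float] = {}
    for key, prop in spec.items():
        if isinstance(key, str):
            rhythm_s, _, pheno_s = key.partition("/")
            key = (RhythmType(rhythm_s), Phenotype(pheno_s or "NORMAL"))
        else:
            key = (RhythmType(key[0]), Phenotype(key[1]))
        out[key] = out.get(key, 0.0) + float(prop)
    total = sum(out.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"class proportions sum to {total}, expected 1")
    return out


def _class_counts(n: int, spec: dict[ClassKey, float]) -> dict[ClassKey, int]:
    """Largest-remainder apportionment; deterministic tie-break by key."""
    keys = sorted(spec, key=lambda k: (k[0].value, k[1].value))
    exact = {k: n * spec[k] for k in keys}
    counts = {k: int(np.floor(exact[k])) for k in keys}
    short = n - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (-(exact[k] - counts[k]),
                                               k[0].value, k[1].value))
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def generate_dataset(
    n: int,
    seed: int,
    class_spec: Mapping,
    out_dir: str | Path,
    clean: bool = False,
) -> DatasetManifest:
    """Synthesise ``n`` records with the requested rhythm/phenotype mix.

    Class counts follow the proportions to within rounding
    (largest-remainder method); record ``i`` is assigned its class by
    cycling through the count table in sorted key order, and is generated
    from ``record_seed(seed, i)``.  With ``clean=True`` noise, wander and
    voltage scaling are skipped (ground-truth-only experiments).

    Re-running with the same (n, seed, class_spec) yields byte-identical
    files.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    spec = parse_class_spec(class_spec)
    counts = _class_counts(n, spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    assignment: list[ClassKey] = []
    for key in sorted(counts, key=lambda k: (k[0].value, k[1].value)):
        assignment.extend([key] * counts[key])

    entries = []
    width = max(len(str(n - 1)), 4)
    for i, (rhythm, phenotype) in enumerate(assignment):
        rid = f"rec{i:0{width}d}"
        cfg = sample_config(
            record_seed(seed, i), {"rhythm": rhythm, "phenotype": phenotype}
        )
        sig = synthesize_ecg(cfg)
        if not clean:
            sig = add_noise_and_wander(sig, cfg)
        entries.append(write_record(out_dir, rid, sig))

    manifest_path = out_dir / "manifest.jsonl"
    write_manifest(manifest_path, entries)
    run_config = {
        "n": n, "seed": seed, "clean": clean,
        "class_spec": {f"{k[0].value}/{k[1].value}": v for k, v in spec.items()},
    }
    (out_dir / "dataset_config.json").write_text(
        json.dumps(run_config, indent=2, sort_keys=True)
    )
    return DatasetManifest(path=manifest_path, entries=entries)
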