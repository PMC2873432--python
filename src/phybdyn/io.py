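"""Dataset and configuration I/O.

Datasets are plain CSV with a ``#``-prefixed metadata header block::

    # kind: dark_reversion
    # genotype_z: 1.0
    time_min,value,se
    0.0,1.0,0.05

Configuration files are YAML (or JSON, a YAML subset) with the sections
``rate_constants``, ``growth_parameters``, ``light_program`` and ``seed``;
unknown keys are rejected so typos fail loudly.  Units are fixed: minutes,
mm, umol m-2 s-1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import ExperimentDataset
from .growth import GrowthParameters
from .model import LightProgram, ModelVariant, RateConstants, Segment

logger = logging.getLogger("phybdyn")

_META_NUMERIC = {
    "genotype_z", "fluence_umol", "bleach_fraction", "noise_sd",
    "duration_min", "t_syn", "seed", "n_replicates",
}


class DatasetParseError(ValueError):
    """A dataset file violates the schema (message carries the location)."""


def write_dataset(path, dataset: ExperimentDataset) -> None:
    """Write an ExperimentDataset as metadata-headed CSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind: {dataset.kind}\n")
        for key, value in sorted(dataset.metadata.items()):
            fh.write(f"# {key}: {value}\n")
        pd.DataFrame(
            {"time_min": dataset.times, "value": dataset.values,
             "se": dataset.se}
        ).to_csv(fh, index=False)


def read_dataset(path) -> ExperimentDataset:
    """Parse a metadata-headed CSV dataset, validating all invariants."""
    path = Path(path)
    meta: dict = {}
    header_lines = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if ":" not in body:
                raise DatasetParseError(
                    f"{path}:{header_lines}: malformed metadata line {body!r}"
                )
            key, _, value = body.partition(":")
            key, value = key.strip(), value.strip()
            if key in _META_NUMERIC:
                meta[key] = float(value)
            elif value in ("True", "False"):
                meta[key] = value == "True"
            else:
                meta[key] = value
    kind = meta.pop("kind", None)
    if kind is None:
        raise DatasetParseError(f"{path}: missing 'kind' metadata line")
    table = pd.read_csv(path, comment="#")
    for col in ("time_min", "value", "se"):
        if col not in table.columns:
            raise DatasetParseError(f"{path}: missing column {col!r}")
    se = table["se"].to_numpy(dtype=float)
    bad = np.nonzero(se <= 0)[0]
    if bad.size:
        raise DatasetParseError(
            f"{path}: non-positive standard error in data row {bad[0]}"
        )
    times = table["time_min"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise DatasetParseError(f"{path}: time_min must be strictly increasing")
    if "genotype_z" not in meta:
        logger.warning("%s: metadata genotype_z absent, defaulting to 1", path)
        meta["genotype_z"] = 1.0
    return ExperimentDataset(
        kind=kind, times=times, values=table["value"].to_numpy(dtype=float),
        se=se, metadata=meta,
    )


_CONFIG_SECTIONS = {
    "rate_constants", "growth_parameters", "light_program", "variant",
    "seed", "datasets", "fit", "output_dir", "verbosity",
}


def load_config(path) -> dict:
    """Load and schema-check a YAML/JSON run configuration."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise DatasetParseError(f"{path}: configuration must be a mapping")
    unknown = set(cfg) - _CONFIG_SECTIONS
    if unknown:
        raise DatasetParseError(
            f"{path}: unknown configuration keys {sorted(unknown)}"
        )
    return cfg


def _from_mapping(cls, mapping: dict, what: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise DatasetParseError(f"unknown {what} keys {sorted(unknown)}")
    return cls(**mapping)


def rate_constants_from_config(cfg: dict) -> RateConstants:
    return _from_mapping(RateConstants, cfg.get("rate_constants", {}) or {},
                         "rate constant")


def growth_parameters_from_config(cfg: dict) -> GrowthParameters:
    return _from_mapping(GrowthParameters, cfg.get("growth_parameters", {}) or {},
                         "growth parameter")


def variant_from_config(cfg: dict) -> ModelVariant:
    return _from_mapping(ModelVariant, cfg.get("variant", {}) or {}, "variant")


def light_program_from_config(cfg: dict) -> LightProgram:
    """Light program from a list of {class, fluence, minutes} mappings."""
    entries = cfg.get("light_program")
    if not entries:
        return LightProgram.darkness()
    segments = []
    for i, entry in enumerate(entries):
        unknown = set(entry) - {"class", "fluence", "minutes"}
        if unknown:
            raise DatasetParseError(
                f"light_program[{i}]: unknown keys {sorted(unknown)}"
            )
        minutes = entry.get("minutes")
        segments.append(
            Segment(entry["class"], float(entry.get("fluence", 0.0)),
                    None if minutes is None else float(minutes))
        )
    return LightProgram(segments)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a resolved configuration, for provenance."""
    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_json(path, payload: dict) -> None:
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
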