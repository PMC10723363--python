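"""Plain-text readers and writers for cohort data.

Timeseries are TSV with one row per TR and a header row of region IDs;
atrophy/metadata/behavior are CSV with subjects as rows; planted truths are
JSON; configuration is YAML.  No imaging formats are required anywhere on the
core analysis path.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_cohort",
    "read_config_yaml",
    "write_config_yaml",
    "write_json",
]


def write_timeseries_tsv(path, values: np.ndarray, region_ids=None) -> None:
    """(T, R) timeseries as TSV, regions as columns with a header row."""
    values = np.asarray(values)
    if region_ids is None:
        region_ids = [f"region_{r:03d}" for r in range(values.shape[1])]
    pd.DataFrame(values, columns=region_ids).to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, complex):
            return [o.real, o.imag]
        return super().default(o)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, cls=_NumpyEncoder, indent=1))


def write_config_yaml(path, config) -> None:
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config)
        }
    clean = {}
    for k, v in config.items():
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, (np.floating, np.integer)):
            v = v.item()
        clean[k] = v
    Path(path).write_text(yaml.safe_dump(clean, sort_keys=False))


def read_config_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_cohort(cohort, out_dir) -> Path:
    """Write a synthetic cohort: per-subject timeseries TSVs plus cohort tables."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    regions = list(cohort.atrophy.columns)
    for sid, subj in zip(cohort.atrophy.index, cohort.subjects):
        write_timeseries_tsv(out / "timeseries" / f"{sid}.tsv",
                             subj.timeseries, regions)
    cohort.atrophy.to_csv(out / "atrophy.csv")
    cohort.behavior.to_csv(out / "behavior.csv")
    cohort.metadata.to_csv(out / "metadata.csv")
    np.savetxt(out / "basis.csv", cohort.basis, delimiter=",")
    write_json(out / "truths.json", {
        "severity": cohort.truths["severity"],
        "focal2": cohort.truths["focal2"],
        "focal3": cohort.truths["focal3"],
        "patterns": {k: v for k, v in cohort.truths["patterns"].items()},
        "true_amplitudes": [s.true_amplitudes for s in cohort.subjects],
    })
    write_config_yaml(out / "config.yaml", cohort.config)
    return out
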