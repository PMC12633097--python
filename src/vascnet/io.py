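"""Standard-format I/O: abundance/manifest TSV, module-label TSV, GMT, JSON.

Matrix files are TSV with the protein identifier in the first column, sample
ids as the header row and empty cells for missing values.  GMT is the usual
tab-delimited gene-set format (name, description, members...).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, SampleManifest


def write_abundance(X: AbundanceMatrix, path) -> None:
    df = X.values.copy()
    df.index.name = "protein"
    df.to_csv(path, sep="\t", na_rep="")


def read_abundance(path, scale_tag: str = "raw") -> AbundanceMatrix:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return AbundanceMatrix(values=df, scale_tag=scale_tag)


def write_manifest(manifest: SampleManifest, path) -> None:
    t = manifest.table.copy()
    t.index.name = "sample_id"
    t.to_csv(path, sep="\t", na_rep="")


def read_manifest(path) -> SampleManifest:
    sep = "," if str(path).endswith(".csv") else "\t"
    t = pd.read_csv(path, sep=sep, index_col=0)
    return SampleManifest(t)


def write_labels(labels: pd.Series, path) -> None:
    """Two-column TSV (protein, module); module 0 = unassigned/grey."""
    df = pd.DataFrame({"protein": labels.index, "module": labels.values})
    df.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["module"].to_numpy(), index=df["protein"], name="module")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, _desc, *members = parts
        sets[name] = [m for m in members if m]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
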