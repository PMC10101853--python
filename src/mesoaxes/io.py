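"""Plain-text readers and writers for the pipeline's interchange formats.

Matrices are feature-major TSV (first column feature ids, header row of
sample ids) with floats at 6 significant digits so a write/read/write
round trip is byte-identical.  Island maps are BED (0-based half-open),
gene sets are GMT, configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import OmicsView


def _fmt(x) -> str:
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, float) and float(x).is_integer() and abs(x) < 1e15:
        return f"{x:.1f}"
    return f"{x:.6g}"


def write_matrix(path, values: pd.DataFrame, feature_meta: pd.DataFrame | None = None) -> None:
    """Write a samples x features DataFrame as a feature-major TSV; the
    optional feature metadata goes to ``<path>.meta.tsv``."""
    path = Path(path)
    mat = values.T  # features as rows
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, mat.columns)) + "\n")
        arr = mat.to_numpy()
        for fid, row in zip(mat.index, arr):
            fh.write(str(fid) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    if feature_meta is not None:
        feature_meta.to_csv(str(path) + ".meta.tsv", sep="\t", index_label="feature_id")


def read_matrix(path) -> pd.DataFrame:
    """Read a feature-major TSV into a samples x features DataFrame.

    Raises on duplicate ids and on ragged rows (with the line number).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            seen, dup = set(), None
            for s in sample_ids:
                if s in seen:
                    dup = s
                    break
                seen.add(s)
            raise ValueError(f"duplicate sample id: {dup!r}")
        feats, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path.name}:{lineno}: ragged row ({len(parts)} fields, expected {len(header)})"
                )
            feats.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if len(set(feats)) != len(feats):
        dup = next(f for i, f in enumerate(feats) if f in feats[:i])
        raise ValueError(f"duplicate feature id: {dup!r}")
    return pd.DataFrame(np.array(rows).T if rows else np.empty((len(sample_ids), 0)),
                        index=sample_ids, columns=feats)


def write_view(path, view: OmicsView) -> None:
    write_matrix(path, view.values, view.feature_meta)


def read_view(path, name: str = "view") -> OmicsView:
    values = read_matrix(path)
    meta_path = Path(str(path) + ".meta.tsv")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col="feature_id")
    else:
        meta = pd.DataFrame({"chromosome": "chr1", "kind": "expression_norm"},
                            index=values.columns)
    return OmicsView(values=values, feature_meta=meta, name=name)


def write_island_bed(path, island_bed_df: pd.DataFrame) -> None:
    """BED4: chrom, start, end, island_id (0-based half-open)."""
    island_bed_df[["chrom", "start", "end", "island_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_island_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"line {lineno}: BED needs 4 columns")
            chrom, start, end, island_id = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(f"line {lineno}: start {start} >= end {end}")
            rows.append((chrom, start, end, island_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "island_id"])


def write_island_map(path, island_map: dict) -> None:
    """Island -> CpG membership as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("island_id\tcpg_id\n")
        for isl, cpgs in island_map.items():
            for c in cpgs:
                fh.write(f"{isl}\t{c}\n")


def read_island_map(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for isl, grp in df.groupby("island_id", sort=False):
        out[isl] = list(grp["cpg_id"])
    return out


def write_gmt(path, sets: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for set_id, genes in sets.items():
            fh.write("\t".join([set_id, "na"] + list(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets


def write_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default, sort_keys=True)
        fh.write("\n")
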