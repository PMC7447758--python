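"""Reading and writing datasets, networks and result tables.

Matrices travel as TSV with genes as rows (first column = gene ID) and a
header row of sample IDs; networks as edge-list TSV (source, target,
weight, sign, support), JSON with metadata, or SIF for graph viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import GeneNetwork, PerturbationDataset

_FLOAT_FMT = "%.12g"


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene IDs {dups}")
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        raise ValueError(f"{path}: non-numeric cells in columns {list(bad)}")
    return df.astype(float)


def read_dataset(y_path, p_path, groups_path=None) -> PerturbationDataset:
    """Load paired Y and P TSVs (plus an optional JSON replicate-group map).

    Gene and sample ordering follow the Y file; P must contain exactly
    the same genes and samples.  When no groups file is given, replicate
    groups are inferred from the nonzero pattern of each P column.
    """
    ydf = _read_matrix(y_path)
    pdf = _read_matrix(p_path)
    missing = set(ydf.index).symmetric_difference(pdf.index)
    if missing:
        raise ValueError(f"gene mismatch between Y and P: {sorted(missing)}")
    miss_s = set(ydf.columns).symmetric_difference(pdf.columns)
    if miss_s:
        raise ValueError(f"sample mismatch between Y and P: {sorted(miss_s)}")
    pdf = pdf.loc[ydf.index, ydf.columns]
    genes = list(ydf.index)
    samples = list(ydf.columns)
    groups = {}
    if groups_path is not None:
        raw = json.loads(Path(groups_path).read_text())
        name_to_idx = {g: i for i, g in enumerate(genes)}
        groups = {s: frozenset(name_to_idx[g] for g in targets)
                  for s, targets in raw.items()}
    return PerturbationDataset(ydf.to_numpy(), pdf.to_numpy(), genes, samples, groups)


def write_dataset(ds: PerturbationDataset, y_path, p_path, groups_path=None) -> None:
    for M, path in ((ds.Y, y_path), (ds.P, p_path)):
        pd.DataFrame(M, index=ds.genes, columns=ds.samples).to_csv(
            path, sep="\t", float_format=_FLOAT_FMT, index_label="gene")
    if groups_path is not None:
        out = {s: sorted(ds.genes[g] for g in ds.groups[s]) for s in ds.samples}
        Path(groups_path).write_text(json.dumps(out, indent=1))


def network_to_frame(net: GeneNetwork,
                     support: np.ndarray | None = None) -> pd.DataFrame:
    rows = []
    for i, j in zip(*np.nonzero(net.support)):
        rows.append({
            "source": net.genes[j], "target": net.genes[i],
            "weight": net.A[i, j], "sign": int(np.sign(net.A[i, j])),
            "support": float(support[i, j]) if support is not None else np.nan,
        })
    return pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "support"])


def write_network(net: GeneNetwork, path, fmt: str = "tsv",
                  support: np.ndarray | None = None) -> None:
    """Write a network as edge-list TSV, JSON (with metadata) or SIF."""
    path = Path(path)
    if fmt == "tsv":
        network_to_frame(net, support).to_csv(path, sep="\t", index=False,
                                              float_format=_FLOAT_FMT)
    elif fmt == "json":
        obj = {
            "genes": net.genes,
            "metadata": net.metadata,
            "links": network_to_frame(net, support).to_dict(orient="records"),
        }
        path.write_text(json.dumps(obj, indent=1, default=str))
    elif fmt == "sif":
        with open(path, "w") as fh:
            for i, j in zip(*np.nonzero(net.support)):
                rel = "activates" if net.A[i, j] > 0 else "represses"
                fh.write(f"{net.genes[j]}\t{rel}\t{net.genes[i]}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, genes: list[str] | None = None) -> GeneNetwork:
    """Read an edge-list TSV or JSON network back into a GeneNetwork."""
    path = Path(path)
    if path.suffix == ".json":
        obj = json.loads(path.read_text())
        genes = obj["genes"]
        df = pd.DataFrame(obj["links"], columns=["source", "target", "weight",
                                                 "sign", "support"])
        meta = obj.get("metadata", {})
    else:
        df = pd.read_csv(path, sep="\t")
        meta = {}
        if genes is None:
            genes = sorted(set(df["source"]) | set(df["target"]))
    idx = {g: k for k, g in enumerate(genes)}
    A = np.zeros((len(genes), len(genes)))
    for _, row in df.iterrows():
        A[idx[row["target"]], idx[row["source"]]] = row["weight"]
    return GeneNetwork(A, list(genes), meta)
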