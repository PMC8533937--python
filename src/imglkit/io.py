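"""Readers and writers for the on-disk exchange formats.

Counts travel as genes x samples TSV (optionally MatrixMarket with sidecar
identifier lists), sample metadata as TSV, regulatory edges as a
three-column TSV (``source  target  sign``) or Cytoscape SIF
(``source  activates|represses  target``), and planted ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

METADATA_COLUMNS = ("sample_id", "protocol", "cell_type", "replicate", "reference_ipsc")

_POSITIVE_SIGNS = {"1", "+1", "+", "activates", "activation", "activate"}
_NEGATIVE_SIGNS = {"-1", "-", "represses", "repression", "repress"}


def _check_unique(values, what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise ValueError(f"duplicate {what} identifier: {v!r}")
        seen.add(v)


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples count table from TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    return df


def write_counts(counts: pd.DataFrame, path) -> Path:
    path = Path(path)
    counts.to_csv(path, sep="\t", index_label="gene_id")
    return path


def write_counts_mtx(counts: pd.DataFrame, out_dir) -> dict:
    """Write counts as MatrixMarket plus gene/sample id sidecars."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out_dir / "counts.mtx",
        "genes": out_dir / "genes.txt",
        "samples": out_dir / "samples.txt",
    }
    mmwrite(paths["mtx"], csr_matrix(counts.to_numpy()))
    paths["genes"].write_text("\n".join(map(str, counts.index)) + "\n")
    paths["samples"].write_text("\n".join(map(str, counts.columns)) + "\n")
    return paths


def read_counts_mtx(mtx_dir) -> pd.DataFrame:
    from scipy.io import mmread

    mtx_dir = Path(mtx_dir)
    mat = mmread(mtx_dir / "counts.mtx").toarray()
    genes = (mtx_dir / "genes.txt").read_text().split()
    samples = (mtx_dir / "samples.txt").read_text().split()
    return pd.DataFrame(mat, index=genes, columns=samples)


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    _check_unique(md["sample_id"], "sample")
    return md.set_index("sample_id", drop=False)


def write_metadata(metadata: pd.DataFrame, path) -> Path:
    path = Path(path)
    metadata.to_csv(path, sep="\t", index=False)
    return path


def parse_sign(token, assume_activation: bool = False) -> int:
    tok = str(token).strip().lower()
    if tok in _POSITIVE_SIGNS:
        return 1
    if tok in _NEGATIVE_SIGNS:
        return -1
    if assume_activation:
        return 1
    raise ValueError(f"unrecognized edge sign {token!r}")


def read_network(path, assume_activation: bool = False) -> pd.DataFrame:
    """Read a signed TF->target edge list (TSV or SIF).

    Duplicate (source, target) pairs with conflicting signs are rejected;
    exact duplicates are collapsed. With ``assume_activation`` an unsigned
    two-column list is accepted and every edge is taken as activating.
    """
    path = Path(path)
    rows = []
    if path.suffix.lower() == ".sif":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            src, interaction, tgt = parts
            rows.append((src, tgt, parse_sign(interaction, assume_activation)))
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "source" not in df.columns or "target" not in df.columns:
            raise ValueError("edge list must have 'source' and 'target' columns")
        has_sign = "sign" in df.columns
        if not has_sign and not assume_activation:
            raise ValueError("unsigned edge list; pass assume_activation=True")
        for _, r in df.iterrows():
            sign = parse_sign(r["sign"], assume_activation) if has_sign else 1
            rows.append((r["source"], r["target"], sign))
    edges = pd.DataFrame(rows, columns=["source", "target", "sign"])
    signs_per_pair = edges.groupby(["source", "target"])["sign"].nunique()
    conflicts = signs_per_pair[signs_per_pair > 1]
    if len(conflicts):
        pair = conflicts.index[0]
        raise ValueError(f"conflicting signs for edge {pair[0]}->{pair[1]}")
    return edges.drop_duplicates(ignore_index=True)


def write_network(edges: pd.DataFrame, path) -> Path:
    path = Path(path)
    edges.to_csv(path, sep="\t", index=False)
    return path


def write_json(obj: Mapping, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
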