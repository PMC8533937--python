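"""Cross-protocol consensus of master TFs and regulome extraction.

Per-protocol MRI tables are compiled into a TF x protocol presence/MRI
matrix; TFs qualifying (significant MRI, upregulated by default) in at
least ``min_protocols`` protocols are retained and classified relative to
a focal protocol:

  a — present in every protocol;
  b — present in the focal protocol and at least two others, but not all;
  c — present in at least three non-focal protocols and absent in the
      focal one.

The first-neighbor regulome of chosen seed TFs is the union, over
protocols, of edges from a seed to any consensus TF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .grn import significant_mask


@dataclass
class ConsensusTable:
    mri: pd.DataFrame        # TF x protocol, NaN where absent/not qualifying
    presence: pd.DataFrame   # TF x protocol, bool
    groups: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    @property
    def tfs(self) -> list:
        return list(self.mri.index)

    @property
    def protocols(self) -> list:
        return list(self.mri.columns)


def compile_consensus(
    mri_tables: Mapping[str, pd.DataFrame],
    min_protocols: int = 3,
    min_mri_pct: float = 1.0,
    min_coherent: int = 5,
    include_down: bool = False,
) -> ConsensusTable:
    """Retain TFs with significant MRI in >= min_protocols protocols.

    "Present" means significant MRI and (by default) upregulated status;
    ``include_down`` admits downregulated master TFs as well.
    """
    if len(mri_tables) < 2:
        raise ValueError("need MRI tables for at least two protocols")
    protocols = list(mri_tables)
    per_protocol: dict = {}
    for prot, table in mri_tables.items():
        if not len(table):
            per_protocol[prot] = {}
            continue
        ok = significant_mask(table, min_mri_pct, min_coherent)
        if not include_down:
            ok &= table["status"] == "up"
        sub = table[ok]
        per_protocol[prot] = dict(zip(sub["tf"], sub["mri_pct"]))
    counts: dict = {}
    for prot in protocols:
        for tf in per_protocol[prot]:
            counts[tf] = counts.get(tf, 0) + 1
    retained = sorted(tf for tf, c in counts.items() if c >= min_protocols)
    if not retained:
        warnings.warn("consensus is empty: no TF qualifies in enough protocols")
    mri = pd.DataFrame(np.nan, index=retained, columns=protocols, dtype=float)
    for prot in protocols:
        for tf, v in per_protocol[prot].items():
            if tf in counts and counts[tf] >= min_protocols:
                mri.loc[tf, prot] = v
    presence = mri.notna()
    return ConsensusTable(mri=mri, presence=presence)


def classify_groups(ct: ConsensusTable, focal_protocol: str) -> pd.Series:
    """Assign each retained TF to group a/b/c (or none) relative to the focal protocol."""
    if focal_protocol not in ct.protocols:
        raise ValueError(f"unknown focal protocol {focal_protocol!r}")
    n_protocols = len(ct.protocols)
    labels = {}
    for tf in ct.tfs:
        pres = ct.presence.loc[tf]
        n_present = int(pres.sum())
        in_focal = bool(pres[focal_protocol])
        n_nonfocal = n_present - int(in_focal)
        if n_present == n_protocols:
            labels[tf] = "a"
        elif in_focal and n_nonfocal >= 2:
            labels[tf] = "b"
        elif not in_focal and n_nonfocal >= 3:
            labels[tf] = "c"
        else:
            labels[tf] = "none"
    groups = pd.Series(labels, name="group")
    ct.groups = groups
    return groups


def extract_regulome(
    networks: Mapping[str, nx.DiGraph],
    seed_tfs: Iterable,
    consensus_tfs: Iterable,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """First-neighbor edges from seed TFs to consensus TFs, pooled over protocols."""
    consensus = set(consensus_tfs)
    seeds = list(seed_tfs)
    bad = [s for s in seeds if s not in consensus]
    if bad:
        raise ValueError(f"seed TFs not in consensus: {bad}")
    rows: dict = {}
    seen_anywhere = set()
    for prot in sorted(networks):
        net = networks[prot]
        for s in seeds:
            if s not in net:
                continue
            seen_anywhere.add(s)
            for t in net.successors(s):
                if t not in consensus or t == s:
                    continue
                key = (s, t)
                sign = net.edges[s, t]["sign"]
                if key in rows:
                    rows[key]["protocols"].append(prot)
                else:
                    rows[key] = {"sign": sign, "protocols": [prot]}
    for s in seeds:
        if s not in seen_anywhere:
            warnings.warn(f"seed TF {s!r} absent from every network; omitted")
    records = []
    for (s, t), info in sorted(rows.items()):
        records.append(
            {
                "source": s,
                "target": t,
                "sign": info["sign"],
                "group_source": groups.get(s, "none") if groups is not None else "",
                "group_target": groups.get(t, "none") if groups is not None else "",
                "protocols": ",".join(info["protocols"]),
            }
        )
    return pd.DataFrame(
        records,
        columns=["source", "target", "sign", "group_source", "group_target", "protocols"],
    )
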