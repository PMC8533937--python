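"""Gene-regulatory-network reconstruction and Master Regulatory Index (MRI).

A protocol's network is the subgraph of a signed TF→target edge resource
restricted to strongly differential genes (|log2FC| above a threshold; the
sign gives the node an up/down status). From every TF a transcription
regulation cascade is propagated: an edge transmits the seed's status
composed with the product of edge signs along the path (activation
preserves the sign, repression flips it), and a reached gene is *coherent*
when its observed status matches the prediction. Propagation continues only
through coherent nodes — an incoherent node absorbs the signal.

Because a node's observed status is fixed, the sign product any admissible
path must carry is determined per node; the coherent set is therefore the
reachability closure in the parity-filtered edge set, and a single
visited-once traversal computes the same set as the fixpoint over all
coherent paths (cycles terminate trivially). MRI(tf) is the fraction of
network nodes the TF coherently controls, directly or indirectly.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .diffexp import STATUS_DOWN, STATUS_UP

_SIGN = {STATUS_UP: 1, STATUS_DOWN: -1}


@dataclass(frozen=True)
class MRIRecord:
    tf: str
    status: str
    n_coherent: int
    total_nodes: int
    mri_pct: float


def build_grn(
    edges: pd.DataFrame, de_result: pd.DataFrame, log2fc_threshold: float = 2.0
) -> nx.DiGraph:
    """Signed network over genes with |log2FC| > threshold for one contrast.

    Node status comes from the fold-change sign; an edge survives only when
    both endpoints do. Genes absent from the DE table are treated as not
    differential.
    """
    lfc = de_result["log2fc"]
    strong = lfc[lfc.abs() > log2fc_threshold]
    status = {g: (STATUS_UP if v > 0 else STATUS_DOWN) for g, v in strong.items()}
    net = nx.DiGraph()
    in_resource = set(edges["source"]) | set(edges["target"])
    for g in in_resource:
        if g in status:
            net.add_node(g, status=status[g])
    for src, tgt, sign in edges[["source", "target", "sign"]].itertuples(index=False):
        if src in net and tgt in net and src != tgt:
            net.add_edge(src, tgt, sign=int(sign))
    return net


def tf_set(net: nx.DiGraph) -> list:
    """Nodes with out-degree > 0, sorted."""
    return sorted(n for n in net.nodes if net.out_degree(n) > 0)


def propagate_cascade(net: nx.DiGraph, seed_tf) -> set:
    """Coherent genes reachable from ``seed_tf`` through coherent intermediates.

    The seed itself is excluded. A seed that is absent or not differential
    yields the empty set.
    """
    if seed_tf not in net:
        return set()
    seed_status = net.nodes[seed_tf].get("status")
    if seed_status not in _SIGN:
        return set()
    s0 = _SIGN[seed_status]
    # parity a path must carry to predict node's observed status
    parity = {v: _SIGN[net.nodes[v]["status"]] * s0 for v in net.nodes}
    reached = {seed_tf}
    queue = deque([seed_tf])
    while queue:
        u = queue.popleft()
        for v in net.successors(u):
            if v in reached:
                continue
            if parity[u] * net.edges[u, v]["sign"] == parity[v]:
                reached.add(v)
                queue.append(v)
    reached.discard(seed_tf)
    return reached


def compute_mri(net: nx.DiGraph, tf) -> MRIRecord:
    """MRI = coherent direct+indirect targets / total network nodes, in percent."""
    total = net.number_of_nodes()
    coherent = propagate_cascade(net, tf)
    status = net.nodes[tf].get("status", "absent") if tf in net else "absent"
    mri = 100.0 * len(coherent) / total if total else 0.0
    return MRIRecord(
        tf=tf, status=status, n_coherent=len(coherent), total_nodes=total, mri_pct=mri
    )


def rank_tfs(net: nx.DiGraph) -> pd.DataFrame:
    """MRI table for all TFs, ranked by mri_pct desc, n_coherent desc, id asc."""
    records = [compute_mri(net, tf) for tf in tf_set(net)]
    table = pd.DataFrame(
        [r.__dict__ for r in records],
        columns=["tf", "status", "n_coherent", "total_nodes", "mri_pct"],
    )
    if len(table):
        table = table.sort_values(
            by=["mri_pct", "n_coherent", "tf"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return table


def significant_mask(
    mri_table: pd.DataFrame, min_mri_pct: float = 1.0, min_coherent: int = 5
) -> pd.Series:
    """The "significant MRI" rule: mri_pct >= min_mri_pct AND n_coherent >= min_coherent.

    No published cutoff exists for a "significant" master-regulator score;
    the defaults are deliberately permissive and configurable.
    """
    return (mri_table["mri_pct"] >= min_mri_pct) & (
        mri_table["n_coherent"] >= min_coherent
    )
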