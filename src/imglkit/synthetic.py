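"""Synthetic multi-protocol microglia-differentiation fixtures.

Emulates the study design the pipeline targets: six differentiation
protocols with iMGL/iPSC/HPC sample groups, in vivo microglia positive
controls (fetal and adult), five negative-control cell types (CD14M, CD16M,
blood dendritic cells, neural precursors, neurons), negative-binomial
counts, and a signed TF→target network with planted ground truth:

* a marker program upregulated in microglia-like cell types only,
* a two-layer master-TF cascade (wide "SPI1-like" and narrow "CEBPA-like"
  seed TFs → intermediate TFs → targets) with 80% activating / 20%
  repressing edges plus a sprinkle of random extra edges (cycles allowed)
  and decoy edges among non-differential background genes,
* one focal protocol in which a designated subset of intermediate TFs is
  never activated (emulating differentiation driven by a partially
  inactive factor), and "partial" intermediate TFs that skip a couple of
  non-focal protocols so the consensus groups a/b/c are all populated.

Counts are drawn per gene and sample as NB(mean, dispersion) with
variance = mean + dispersion * mean^2; a sample's expected column total is
its library size under the program-free gene composition, and planted
genes have their mean multiplied by ``fold_change_up`` (divided, for
planted-down genes). Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io

CANONICAL_PROTOCOLS = ("Abud", "Muffat", "Douvaras", "McQuade", "Trudler", "Chen")
NEGATIVE_CONTROLS = ("CD14M", "CD16M", "bloodDC", "NPC", "neuron")
CONTROL_CELL_TYPES = ("fetalMG", "adultMG") + NEGATIVE_CONTROLS

ACTIVATION_PROB = 0.8
EXTRA_EDGE_FRACTION = 0.10
N_DECOY_EDGES = 40
N_ADULT_EXTRA = 10
FAITHFUL_MARKER_FRAC = 0.75
FOCAL_MARKER_FRAC = 0.25
PARTIAL_SKIP_PROTOCOLS = 2


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic fixture.

    The planted sets are explicit gene-id collections; everything else the
    fixture needs (shared immune programs, intermediate TFs, cascade
    targets, protocol-private up-programs) is derived deterministically
    from ``rng_seed``.
    """

    n_genes: int
    planted_marker_genes: frozenset = frozenset()
    planted_master_tfs: frozenset = frozenset()
    focal_deficient_tfs: frozenset = frozenset()
    n_protocols: int = 6
    focal_protocol: str = "Chen"
    n_reps_per_group: int = 6
    base_mean_range: tuple = (20.0, 2000.0)
    nb_dispersion: float = 0.05
    fold_change_up: float = 8.0
    # the planted TF layer emulates over-expressed factors (the focal
    # protocol literally drives differentiation by TF overexpression), so
    # master and intermediate TFs carry a stronger fold than program genes
    tf_fold_boost: float = 2.0
    library_size_range: tuple = (800_000, 1_200_000)
    rng_seed: int = 0
    protocol_labels: tuple | None = None
    # structural knobs of the planted architecture (defaults are the study
    # conditions; shrink only for toy fixtures)
    n_shared_immune: int = 150
    n_negative_own: int = 40
    n_partial_tfs: int = 4
    targets_per_intermediate: int = 8
    wide_direct_targets: int = 20
    narrow_direct_targets: int = 40
    extra_master_direct_targets: int = 10
    faithful_extra_up: int = 15
    focal_extra_up: int = 60

    @property
    def protocols(self) -> tuple:
        if self.protocol_labels is not None:
            return tuple(self.protocol_labels)
        if self.n_protocols == 6:
            return CANONICAL_PROTOCOLS
        return tuple(f"P{i + 1}" for i in range(self.n_protocols))

    @property
    def fallback_protocol(self) -> str:
        return self.protocols[0]

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_protocols <= 0 or self.n_reps_per_group <= 0:
            raise ValueError("n_genes, n_protocols, n_reps_per_group must be positive")
        if self.fold_change_up <= 1:
            raise ValueError("fold_change_up must exceed 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.tf_fold_boost < 1:
            raise ValueError("tf_fold_boost must be >= 1")
        lo, hi = self.base_mean_range
        if lo <= 0 or hi < lo:
            raise ValueError("base_mean_range must be a positive (lo, hi) pair")
        llo, lhi = self.library_size_range
        if llo <= 0 or lhi < llo:
            raise ValueError("library_size_range must be a positive (lo, hi) pair")
        if len(self.protocols) != self.n_protocols:
            raise ValueError("protocol_labels length must match n_protocols")
        if self.focal_protocol not in self.protocols:
            raise ValueError(f"focal protocol {self.focal_protocol!r} not among labels")
        if self.focal_deficient_tfs & self.planted_master_tfs:
            raise ValueError("focal_deficient_tfs must be downstream of, not among, masters")
        planted = (
            self.planted_marker_genes | self.planted_master_tfs | self.focal_deficient_tfs
        )
        if len(planted) + self._pool_demand() > self.n_genes:
            raise ValueError(
                "configuration error: n_genes smaller than the number of planted "
                "and derived entities"
            )

    def _pool_demand(self) -> int:
        n_masters = len(self.planted_master_tfs)
        n_intermediates = len(self.focal_deficient_tfs) + (
            self.n_partial_tfs if n_masters else 0
        )
        demand = (
            self.n_shared_immune
            + len(NEGATIVE_CONTROLS) * self.n_negative_own
            + N_ADULT_EXTRA
            + (self.n_partial_tfs if n_masters else 0)
            + n_intermediates * self.targets_per_intermediate
            + self.focal_extra_up
            + self.faithful_extra_up * max(self.n_protocols - 1, 0)
        )
        if n_masters >= 1:
            demand += self.wide_direct_targets
        if n_masters >= 2:
            demand += self.narrow_direct_targets
        if n_masters > 2:
            demand += (n_masters - 2) * self.extra_master_direct_targets
        return demand


def default_config(
    seed: int = 0,
    n_genes: int = 2000,
    n_markers: int = 120,
    n_masters: int = 2,
    n_deficient: int = 4,
    **overrides,
) -> GeneratorConfig:
    """The default study conditions with planted ids drawn from one namespace."""
    ids = [f"g{i:05d}" for i in range(n_markers + n_masters + n_deficient)]
    markers = frozenset(ids[:n_markers])
    masters = frozenset(ids[n_markers : n_markers + n_masters])
    deficient = frozenset(ids[n_markers + n_masters :])
    cfg = GeneratorConfig(
        n_genes=n_genes,
        planted_marker_genes=markers,
        planted_master_tfs=masters,
        focal_deficient_tfs=deficient,
        rng_seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


@dataclass
class PlantedTruth:
    """Ground truth written alongside each fixture."""

    genes: tuple
    marker_genes: frozenset
    up_programs: dict            # "{protocol}.{cell_type}" -> frozenset
    down_programs: dict
    expected_masters: dict       # protocol -> frozenset
    network: pd.DataFrame        # source, target, sign
    protocols: tuple
    focal_protocol: str
    fallback_protocol: str
    cell_types_by_protocol: dict
    seed_tf_wide: str | None = None
    seed_tf_narrow: str | None = None
    deficient_tfs: frozenset = frozenset()
    partial_tfs: frozenset = frozenset()
    partial_absence: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "marker_genes": sorted(self.marker_genes),
            "up_programs": {k: sorted(v) for k, v in self.up_programs.items()},
            "down_programs": {k: sorted(v) for k, v in self.down_programs.items()},
            "expected_masters": {k: sorted(v) for k, v in self.expected_masters.items()},
            "network": self.network.values.tolist(),
            "protocols": list(self.protocols),
            "focal_protocol": self.focal_protocol,
            "fallback_protocol": self.fallback_protocol,
            "cell_types_by_protocol": {
                k: list(v) for k, v in self.cell_types_by_protocol.items()
            },
            "seed_tf_wide": self.seed_tf_wide,
            "seed_tf_narrow": self.seed_tf_narrow,
            "deficient_tfs": sorted(self.deficient_tfs),
            "partial_tfs": sorted(self.partial_tfs),
            "partial_absence": {k: sorted(v) for k, v in self.partial_absence.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlantedTruth":
        return cls(
            genes=tuple(d["genes"]),
            marker_genes=frozenset(d["marker_genes"]),
            up_programs={k: frozenset(v) for k, v in d["up_programs"].items()},
            down_programs={k: frozenset(v) for k, v in d["down_programs"].items()},
            expected_masters={
                k: frozenset(v) for k, v in d["expected_masters"].items()
            },
            network=pd.DataFrame(
                d["network"], columns=["source", "target", "sign"]
            ).astype({"sign": int}),
            protocols=tuple(d["protocols"]),
            focal_protocol=d["focal_protocol"],
            fallback_protocol=d["fallback_protocol"],
            cell_types_by_protocol={
                k: tuple(v) for k, v in d["cell_types_by_protocol"].items()
            },
            seed_tf_wide=d["seed_tf_wide"],
            seed_tf_narrow=d["seed_tf_narrow"],
            deficient_tfs=frozenset(d["deficient_tfs"]),
            partial_tfs=frozenset(d["partial_tfs"]),
            partial_absence={k: tuple(v) for k, v in d["partial_absence"].items()},
        )


def _universe(config: GeneratorConfig) -> tuple:
    planted = sorted(
        config.planted_marker_genes
        | config.planted_master_tfs
        | config.focal_deficient_tfs
    )
    genes = list(planted)
    taken = set(planted)
    i = 0
    while len(genes) < config.n_genes:
        gid = f"g{i:05d}"
        i += 1
        if gid not in taken:
            genes.append(gid)
            taken.add(gid)
    return tuple(genes)


def _cell_types(config: GeneratorConfig) -> dict:
    labels = config.protocols
    n = len(labels)
    own_ipsc = {labels[0], labels[-1]}
    if n >= 3:
        own_ipsc.add(labels[-2])
    hpc = {labels[0]}
    if n > 3:
        hpc.add(labels[3])
    out = {}
    for prot in labels:
        cts = []
        if prot in own_ipsc:
            cts.append("iPSC")
        if prot in hpc:
            cts.append("HPC")
        cts.append("iMGL")
        if prot == labels[0]:
            cts.extend(CONTROL_CELL_TYPES)
        out[prot] = tuple(cts)
    return out


def generate_truth(config: GeneratorConfig) -> PlantedTruth:
    """Build the planted network, per-group expression programs, and bookkeeping."""
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 11])
    genes = _universe(config)
    protocols = config.protocols
    focal = config.focal_protocol
    fallback = config.fallback_protocol
    nonfocal = [p for p in protocols if p != focal]

    planted = (
        config.planted_marker_genes
        | config.planted_master_tfs
        | config.focal_deficient_tfs
    )
    pool = [g for g in genes if g not in planted]
    pool = [pool[i] for i in rng.permutation(len(pool))]

    def take(k: int) -> list:
        if k > len(pool):
            raise ValueError("configuration error: gene pool exhausted")
        out = pool[:k]
        del pool[:k]
        return out

    shared = take(config.n_shared_immune)
    neg_own = {ct: take(config.n_negative_own) for ct in NEGATIVE_CONTROLS}
    adult_extra = take(N_ADULT_EXTRA)

    masters = sorted(config.planted_master_tfs)
    wide = masters[0] if masters else None
    narrow = masters[1] if len(masters) > 1 else None
    extra_masters = masters[2:]
    deficient = sorted(config.focal_deficient_tfs)
    partial = take(config.n_partial_tfs) if masters else []
    intermediates = deficient + partial

    def sign() -> int:
        return 1 if rng.random() < ACTIVATION_PROB else -1

    tree_edges: list = []  # (source, target, sign)
    int_targets: dict = {}
    direct_targets: dict = {}
    if masters:
        # master -> intermediate edges are activating: the emulated factors
        # are over-expressed downstream TFs; repression is exercised on the
        # target layer and the random extra edges
        for inter in intermediates:
            tree_edges.append((wide, inter, 1))
        direct_targets[wide] = take(config.wide_direct_targets)
        for t in direct_targets[wide]:
            tree_edges.append((wide, t, sign()))
        if narrow is not None:
            direct_targets[narrow] = take(config.narrow_direct_targets)
            for t in direct_targets[narrow]:
                tree_edges.append((narrow, t, sign()))
        for m in extra_masters:
            direct_targets[m] = take(config.extra_master_direct_targets)
            for t in direct_targets[m]:
                tree_edges.append((m, t, sign()))
        for inter in intermediates:
            int_targets[inter] = take(config.targets_per_intermediate)
            for t in int_targets[inter]:
                tree_edges.append((inter, t, sign()))

    # statuses implied by the tree (masters up; signs compose downward)
    status = {m: 1 for m in masters}
    for src, tgt, sgn in tree_edges:
        status[tgt] = status[src] * sgn

    cascade_nodes = sorted(status)
    non_master_nodes = [n for n in cascade_nodes if n not in config.planted_master_tfs]
    edges = list(tree_edges)
    seen_pairs = {(s, t) for s, t, _ in edges}
    n_extra = int(round(EXTRA_EDGE_FRACTION * len(tree_edges)))
    attempts = 0
    while masters and len(edges) < len(tree_edges) + n_extra and attempts < 10000:
        attempts += 1
        src = cascade_nodes[rng.integers(len(cascade_nodes))]
        tgt = non_master_nodes[rng.integers(len(non_master_nodes))]
        if src == tgt or (src, tgt) in seen_pairs:
            continue
        edges.append((src, tgt, sign()))
        seen_pairs.add((src, tgt))

    # decoy edges among background genes that never enter any program; the
    # front of the pool still feeds protocol-private up-programs below, so
    # background ids are reserved from the end
    still_needed = config.focal_extra_up + config.faithful_extra_up * max(
        len(protocols) - 1, 0
    )
    n_decoy = min(N_DECOY_EDGES, max(len(pool) - still_needed - 1, 0))
    background = pool[len(pool) - (n_decoy + 1) :] if n_decoy else []
    for i in range(n_decoy):
        s, t = background[i], background[(i + 1) % len(background)]
        if (s, t) not in seen_pairs:
            edges.append((s, t, sign()))
            seen_pairs.add((s, t))

    network = pd.DataFrame(edges, columns=["source", "target", "sign"])

    # which partial intermediates skip which non-focal protocols
    partial_absence = {}
    for tf in partial:
        k = min(PARTIAL_SKIP_PROTOCOLS, len(nonfocal))
        absent = rng.choice(nonfocal, size=k, replace=False) if k else []
        partial_absence[tf] = tuple(sorted(absent))

    markers_sorted = sorted(config.planted_marker_genes)
    up_programs: dict = {}
    down_programs: dict = {}

    # in vivo controls and negatives (attributed to the fallback protocol)
    up_programs[f"{fallback}.fetalMG"] = frozenset(markers_sorted) | frozenset(shared)
    up_programs[f"{fallback}.adultMG"] = (
        frozenset(markers_sorted) | frozenset(shared) | frozenset(adult_extra)
    )
    for ct in NEGATIVE_CONTROLS:
        up_programs[f"{fallback}.{ct}"] = frozenset(shared) | frozenset(neg_own[ct])
    hpc_program = frozenset(shared[: config.n_shared_immune // 2])

    def marker_subset(frac: float) -> set:
        k = int(round(frac * len(markers_sorted)))
        if k == 0:
            return set()
        return set(rng.choice(markers_sorted, size=k, replace=False))

    cell_types = _cell_types(config)
    for prot in protocols:
        if "HPC" in cell_types[prot]:
            up_programs[f"{prot}.HPC"] = hpc_program
        active_inter = [
            i
            for i in intermediates
            if not (prot == focal and i in config.focal_deficient_tfs)
            and prot not in partial_absence.get(i, ())
        ]
        active = set(masters)
        for i in active_inter:
            active.add(i)
            active.update(int_targets.get(i, ()))
        for m in masters:
            active.update(direct_targets.get(m, ()))
        up = {n for n in active if status[n] == 1} if masters else set()
        down = {n for n in active if status[n] == -1} if masters else set()
        if prot == focal:
            up |= marker_subset(FOCAL_MARKER_FRAC)
            up.update(take(config.focal_extra_up))
            up -= config.focal_deficient_tfs
        else:
            up |= marker_subset(FAITHFUL_MARKER_FRAC)
            up.update(take(config.faithful_extra_up))
        up_programs[f"{prot}.iMGL"] = frozenset(up)
        down_programs[f"{prot}.iMGL"] = frozenset(down)

    expected_masters = {
        prot: (
            config.planted_master_tfs
            if prot == focal
            else config.planted_master_tfs | config.focal_deficient_tfs
        )
        for prot in protocols
    }

    return PlantedTruth(
        genes=genes,
        marker_genes=config.planted_marker_genes,
        up_programs=up_programs,
        down_programs=down_programs,
        expected_masters=expected_masters,
        network=network,
        protocols=protocols,
        focal_protocol=focal,
        fallback_protocol=fallback,
        cell_types_by_protocol=cell_types,
        seed_tf_wide=wide,
        seed_tf_narrow=narrow,
        deficient_tfs=config.focal_deficient_tfs,
        partial_tfs=frozenset(partial),
        partial_absence=partial_absence,
    )


def simulate_counts(truth: PlantedTruth, config: GeneratorConfig):
    """Negative-binomial counts plus a sample-metadata table for one fixture.

    Expected column totals equal the drawn library sizes under the
    program-free composition; planted genes keep their exact fold change in
    group-mean ratios relative to the matched iPSC baseline.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 23])
    genes = list(truth.genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    rows = []
    for prot in truth.protocols:
        ref = prot if "iPSC" in truth.cell_types_by_protocol[prot] else truth.fallback_protocol
        for ct in truth.cell_types_by_protocol[prot]:
            for rep in range(1, config.n_reps_per_group + 1):
                rows.append(
                    {
                        "sample_id": f"{prot}.{ct}.{rep}",
                        "protocol": prot,
                        "cell_type": ct,
                        "replicate": rep,
                        "reference_ipsc": ref,
                    }
                )
    metadata = pd.DataFrame(rows, columns=list(io.METADATA_COLUMNS))

    lo, hi = config.base_mean_range
    # Planted genes get baseline headroom for one full fold change inside the
    # dynamic range: a gene already at the ceiling (floor) of the range cannot
    # express a detectable up (down) fold on a rank-preserving scale, so the
    # planted-by-construction contract requires bounding their baselines.
    up_any: set = set().union(*truth.up_programs.values()) if truth.up_programs else set()
    down_any: set = (
        set().union(*truth.down_programs.values()) if truth.down_programs else set()
    )
    tf_layer = (
        truth.expected_masters.get(truth.focal_protocol, frozenset())
        | truth.deficient_tfs
        | truth.partial_tfs
    )
    lo_g = np.full(len(genes), lo)
    hi_g = np.full(len(genes), hi)
    fc = config.fold_change_up
    for i, g in enumerate(genes):
        eff = fc * config.tf_fold_boost if g in tf_layer else fc
        if g in up_any:
            hi_g[i] = max(hi / eff, lo * 2.0)
        if g in down_any:
            lo_g[i] = min(lo * eff, hi / 2.0)
        if lo_g[i] >= hi_g[i]:
            lo_g[i], hi_g[i] = lo, hi
    u = rng.uniform(0.0, 1.0, len(genes))
    base = 10 ** (np.log10(lo_g) + u * (np.log10(hi_g) - np.log10(lo_g)))
    composition = base / base.sum()
    libs = rng.integers(
        config.library_size_range[0], config.library_size_range[1] + 1, len(metadata)
    )

    fold = np.ones((len(genes), len(metadata)))
    for j, (_, row) in enumerate(metadata.iterrows()):
        key = f"{row['protocol']}.{row['cell_type']}"
        for g in truth.up_programs.get(key, ()):
            boost = config.tf_fold_boost if g in tf_layer else 1.0
            fold[gene_idx[g], j] = config.fold_change_up * boost
        for g in truth.down_programs.get(key, ()):
            boost = config.tf_fold_boost if g in tf_layer else 1.0
            fold[gene_idx[g], j] = 1.0 / (config.fold_change_up * boost)
    mu = composition[:, None] * fold * libs[None, :]

    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    return (
        pd.DataFrame(counts.astype(np.int64), index=genes, columns=metadata["sample_id"]),
        metadata,
    )


def simulate_two_group(
    n_genes: int,
    n_per_group: int = 6,
    dispersion: float = 0.05,
    fold_changes=None,
    base_mean_range: tuple = (20.0, 2000.0),
    library_size: int = 1_000_000,
    seed: int = 0,
):
    """Minimal two-group NB simulator for calibration and power studies.

    ``fold_changes`` (length ``n_genes``, default all ones) multiplies the
    test group's means. Returns (counts, test sample ids, reference ids).
    """
    rng = np.random.default_rng([seed, 31])
    genes = [f"g{i:05d}" for i in range(n_genes)]
    lo, hi = base_mean_range
    fc = np.ones(n_genes) if fold_changes is None else np.asarray(fold_changes, float)
    # same baseline-headroom rule as simulate_counts
    hi_g = np.where(fc > 1, np.maximum(hi / fc, lo * 2.0), hi)
    lo_g = np.where(fc < 1, np.minimum(lo / fc, hi / 2.0), lo)
    u = rng.uniform(0.0, 1.0, n_genes)
    base = 10 ** (np.log10(lo_g) + u * (np.log10(hi_g) - np.log10(lo_g)))
    composition = base / base.sum()
    mu_ref = composition * library_size
    mu = np.concatenate(
        [np.tile((mu_ref * fc)[:, None], n_per_group), np.tile(mu_ref[:, None], n_per_group)],
        axis=1,
    )
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    test = [f"test.{i + 1}" for i in range(n_per_group)]
    ref = [f"ref.{i + 1}" for i in range(n_per_group)]
    return (
        pd.DataFrame(counts.astype(np.int64), index=genes, columns=test + ref),
        test,
        ref,
    )


def write_fixture(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    network: pd.DataFrame,
    truth: PlantedTruth,
    out_dir,
    write_mtx: bool = False,
) -> dict:
    """Write counts/metadata/network/truth so the readers round-trip them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": io.write_counts(counts, out_dir / "counts.tsv"),
        "metadata": io.write_metadata(metadata, out_dir / "metadata.tsv"),
        "network": io.write_network(network, out_dir / "network.tsv"),
        "truth": io.write_json(truth.to_dict(), out_dir / "truth.json"),
    }
    if write_mtx:
        paths.update(io.write_counts_mtx(counts, out_dir / "mtx"))
    return paths


def make_fixture(config: GeneratorConfig, out_dir=None):
    """generate_truth + simulate_counts (+ optional write). Returns the objects."""
    truth = generate_truth(config)
    counts, metadata = simulate_counts(truth, config)
    if out_dir is not None:
        write_fixture(counts, metadata, truth.network, truth, out_dir)
    return truth, counts, metadata
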