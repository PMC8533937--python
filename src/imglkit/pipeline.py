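"""End-to-end orchestration: preprocess → diffexp → score → grn → consensus.

:func:`analyze` runs the whole chain in memory on already-loaded objects;
:func:`run_pipeline` wraps it with file reading/writing plus a manifest
(config echo, package version, SHA-256 of every output) so a rerun with
the same inputs is byte-identical. Any stage failure aborts with the stage
name and cause.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import pandas as pd
import yaml

from . import __version__, consensus as consensus_mod, diffexp, grn, identity, io, preprocess

STAGES = ("preprocess", "diffexp", "score", "grn", "consensus")

CONTROL_NEGATIVES = ("CD14M", "CD16M", "bloodDC", "NPC", "neuron")


@dataclass
class PipelineConfig:
    counts: str
    metadata: str
    network: str
    out_dir: str
    fc_threshold: float = 2.0
    padj_threshold: float = 0.01
    grn_log2fc_threshold: float = 2.0
    min_protocols: int = 3
    min_mri_pct: float = 1.0
    min_coherent: int = 5
    focal_protocol: str = "Chen"
    fallback_ipsc: str = "Abud"
    marker_positive: str = "fetalMG"
    marker_negatives: tuple = CONTROL_NEGATIVES
    similarity_controls: tuple = ("fetalMG", "adultMG")
    include_down: bool = False
    assume_activation: bool = False
    regulome_seeds: tuple | None = None
    qn_ties: str = "stable"
    rng_seed: int = 0
    stop_after: str | None = None

    def validate(self) -> None:
        for name in (
            "fc_threshold",
            "padj_threshold",
            "grn_log2fc_threshold",
            "min_protocols",
            "min_mri_pct",
            "min_coherent",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.stop_after is not None and self.stop_after not in STAGES:
            raise ValueError(f"unknown stage {self.stop_after!r}; stages: {STAGES}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.marker_negatives = tuple(cfg.marker_negatives)
        cfg.similarity_controls = tuple(cfg.similarity_controls)
        if cfg.regulome_seeds is not None:
            cfg.regulome_seeds = tuple(cfg.regulome_seeds)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline aborted at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisResults:
    norm: pd.DataFrame | None = None
    de_by_label: dict = field(default_factory=dict)
    marker_set: identity.MarkerSet | None = None
    similarity: pd.DataFrame | None = None
    pca_coords: pd.DataFrame | None = None
    pca_variance: object = None
    heatmap: identity.HeatmapResult | None = None
    networks: dict = field(default_factory=dict)
    mri_tables: dict = field(default_factory=dict)
    consensus_table: consensus_mod.ConsensusTable | None = None
    groups: pd.Series | None = None
    regulome: pd.DataFrame | None = None
    regulome_seeds: list = field(default_factory=list)


def _default_regulome_seeds(ct, groups) -> list:
    """Two group-a TFs with the highest mean MRI (the focal-overexpression pair)."""
    in_a = groups[groups == "a"].index
    if not len(in_a):
        return []
    mean_mri = ct.mri.loc[in_a].mean(axis=1).sort_values(ascending=False)
    return list(mean_mri.index[:2])


def analyze(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    edges,
    fc_threshold: float = 2.0,
    padj_threshold: float = 0.01,
    grn_log2fc_threshold: float = 2.0,
    min_protocols: int = 3,
    min_mri_pct: float = 1.0,
    min_coherent: int = 5,
    focal_protocol: str = "Chen",
    fallback_ipsc: str = "Abud",
    marker_positive: str = "fetalMG",
    marker_negatives: tuple = CONTROL_NEGATIVES,
    similarity_controls: tuple = ("fetalMG", "adultMG"),
    include_down: bool = False,
    regulome_seeds: tuple | None = None,
    qn_ties: str = "stable",
    stop_after: str | None = None,
) -> AnalysisResults:
    """Run the analysis chain in memory.

    ``edges`` is the signed edge list DataFrame, or a zero-argument callable
    producing it (evaluated only when the grn stage runs, so a missing
    network resource aborts there, not earlier).
    """
    res = AnalysisResults()
    stop_idx = STAGES.index(stop_after) if stop_after else len(STAGES) - 1

    try:
        res.norm = preprocess.preprocess_counts(counts, ties=qn_ties)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise StageError("preprocess", e) from e
    if stop_idx < 1:
        return res

    try:
        for contrast in diffexp.contrasts_from_metadata(metadata, fallback_ipsc):
            res.de_by_label[contrast.label] = diffexp.differential_test(
                res.norm, contrast, fc_threshold, padj_threshold
            )
    except Exception as e:
        raise StageError("diffexp", e) from e
    if stop_idx < 2:
        return res

    try:
        up_by_celltype = {
            ct: diffexp.classify_de(res.de_by_label[f"{fallback_ipsc}.{ct}"])["up"]
            for ct in (marker_positive, *marker_negatives)
            if f"{fallback_ipsc}.{ct}" in res.de_by_label
        }
        res.marker_set = identity.select_markers(
            up_by_celltype, marker_positive, marker_negatives
        )

        imgl_labels = sorted(l for l in res.de_by_label if l.endswith(".iMGL"))
        sim_rows = []
        for lab in imgl_labels:
            up_imgl = diffexp.classify_de(res.de_by_label[lab])["up"]
            for ctrl in similarity_controls:
                ctrl_lab = f"{fallback_ipsc}.{ctrl}"
                if ctrl_lab not in res.de_by_label:
                    continue
                up_ctrl = diffexp.classify_de(res.de_by_label[ctrl_lab])["up"]
                sim_rows.append(asdict(identity.similarity(up_imgl, up_ctrl, lab, ctrl)))
        res.similarity = pd.DataFrame(sim_rows)

        pca_genes = sorted(
            diffexp.classify_de(res.de_by_label[f"{fallback_ipsc}.{marker_positive}"])["up"]
        )
        res.pca_coords, res.pca_variance = identity.pca_embed(res.norm, pca_genes)

        heat_groups = {
            lab: res.de_by_label[lab]
            for lab in (*imgl_labels, *(f"{fallback_ipsc}.{c}" for c in similarity_controls))
            if lab in res.de_by_label
        }
        res.heatmap = identity.marker_heatmap_matrix(heat_groups, res.marker_set.genes)
    except Exception as e:
        raise StageError("score", e) from e
    if stop_idx < 3:
        return res

    try:
        edge_df = edges() if callable(edges) else edges
        for prot in sorted(metadata["protocol"].unique()):
            lab = f"{prot}.iMGL"
            if lab not in res.de_by_label:
                continue
            net = grn.build_grn(edge_df, res.de_by_label[lab], grn_log2fc_threshold)
            res.networks[prot] = net
            res.mri_tables[prot] = grn.rank_tfs(net)
    except Exception as e:
        raise StageError("grn", e) from e
    if stop_idx < 4:
        return res

    try:
        ct = consensus_mod.compile_consensus(
            res.mri_tables,
            min_protocols=min_protocols,
            min_mri_pct=min_mri_pct,
            min_coherent=min_coherent,
            include_down=include_down,
        )
        res.consensus_table = ct
        res.groups = consensus_mod.classify_groups(ct, focal_protocol)
        seeds = (
            list(regulome_seeds)
            if regulome_seeds
            else _default_regulome_seeds(ct, res.groups)
        )
        res.regulome_seeds = [s for s in seeds if s in set(ct.tfs)]
        res.regulome = consensus_mod.extract_regulome(
            res.networks, res.regulome_seeds, ct.tfs, res.groups
        )
    except Exception as e:
        raise StageError("consensus", e) from e
    return res


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages from files, write all outputs, return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        counts = io.read_counts(config.counts)
        metadata = io.read_metadata(config.metadata)
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocess", e) from e

    res = analyze(
        counts,
        metadata,
        lambda: io.read_network(config.network, config.assume_activation),
        fc_threshold=config.fc_threshold,
        padj_threshold=config.padj_threshold,
        grn_log2fc_threshold=config.grn_log2fc_threshold,
        min_protocols=config.min_protocols,
        min_mri_pct=config.min_mri_pct,
        min_coherent=config.min_coherent,
        focal_protocol=config.focal_protocol,
        fallback_ipsc=config.fallback_ipsc,
        marker_positive=config.marker_positive,
        marker_negatives=config.marker_negatives,
        similarity_controls=config.similarity_controls,
        include_down=config.include_down,
        regulome_seeds=config.regulome_seeds,
        qn_ties=config.qn_ties,
        stop_after=config.stop_after,
    )

    written: list = []

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    io.write_counts(res.norm, emit(out / "normalized.tsv"))
    for lab, de in res.de_by_label.items():
        de.to_csv(emit(out / f"de_{lab}.tsv"), sep="\t")
    if res.marker_set is not None:
        emit(out / "markers.txt").write_text(
            "\n".join(sorted(res.marker_set.genes)) + "\n"
        )
        res.similarity.to_csv(emit(out / "similarity.tsv"), sep="\t", index=False)
        coords = res.pca_coords.copy()
        coords.index.name = "sample_id"
        with open(emit(out / "pca.tsv"), "w") as fh:
            fh.write(
                "# variance_fractions: "
                + ",".join(f"{v:.6f}" for v in res.pca_variance)
                + "\n"
            )
            coords.to_csv(fh, sep="\t")
        res.heatmap.matrix.to_csv(emit(out / "heatmap_matrix.tsv"), sep="\t")
    for prot, table in res.mri_tables.items():
        table.to_csv(emit(out / f"mri_{prot}.tsv"), sep="\t", index=False)
    if res.consensus_table is not None:
        table = res.consensus_table.mri.copy()
        table.insert(0, "group", res.groups)
        table.index.name = "tf"
        table.to_csv(emit(out / "consensus.tsv"), sep="\t")
        res.regulome.to_csv(emit(out / "regulome.tsv"), sep="\t", index=False)
        io.write_json(
            {
                "n_consensus_tfs": len(res.consensus_table.tfs),
                "groups": {
                    g: sorted(res.groups[res.groups == g].index)
                    for g in ("a", "b", "c", "none")
                },
                "regulome_seeds": res.regulome_seeds,
                "significance_rule": {
                    "min_mri_pct": config.min_mri_pct,
                    "min_coherent": config.min_coherent,
                    "note": "no published cutoff for a significant MRI; rule is configurable",
                },
            },
            emit(out / "consensus.json"),
        )

    manifest = {
        "tool": "imglkit",
        "version": __version__,
        "seed": config.rng_seed,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
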