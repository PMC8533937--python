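import numpy as np
import networkx as nx
import pandas as pd
import pytest

from imglkit import io
from imglkit.synthetic import (
    GeneratorConfig,
    PlantedTruth,
    default_config,
    generate_truth,
    make_fixture,
    simulate_counts,
    simulate_two_group,
    write_fixture,
)

from conftest import small_config


class TestConfig:
    def test_too_small_universe_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="configuration error"):
            default_config(n_genes=100)

    def test_master_among_deficient_rejected(self):
        cfg = GeneratorConfig(
            n_genes=2000,
            planted_master_tfs=frozenset({"gX"}),
            focal_deficient_tfs=frozenset({"gX"}),
        )
        with pytest.raises(ValueError):
            cfg.validate()

    def test_focal_label_must_exist(self):
        with pytest.raises(ValueError, match="focal"):
            small_config(n_protocols=3, focal_protocol="Chen").validate()


class TestGenerateTruth:
    def test_no_planted_markers_gives_empty_marker_set(self):
        cfg = small_config(n_markers=0)
        truth = generate_truth(cfg)
        assert truth.marker_genes == frozenset()

    def test_deterministic_under_fixed_seed(self):
        cfg = small_config(seed=9)
        t1, t2 = generate_truth(cfg), generate_truth(cfg)
        assert t1.to_dict() == t2.to_dict()

    def test_each_master_wired_to_at_least_ten_targets(self):
        cfg = small_config(n_masters=3)
        truth = generate_truth(cfg)
        out_deg = truth.network.groupby("source").size()
        for m in sorted(cfg.planted_master_tfs):
            assert out_deg.get(m, 0) >= 10

    def test_masters_reach_five_targets_within_two_hops(self):
        truth = generate_truth(small_config())
        g = nx.from_pandas_edgelist(
            truth.network, "source", "target", create_using=nx.DiGraph
        )
        for m in (truth.seed_tf_wide, truth.seed_tf_narrow):
            within2 = set(nx.single_source_shortest_path_length(g, m, cutoff=2)) - {m}
            assert len(within2) >= 5

    def test_focal_excludes_deficient_from_expected_masters(self):
        truth = generate_truth(small_config())
        focal, fallback = truth.focal_protocol, truth.fallback_protocol
        assert truth.expected_masters[fallback] == (
            truth.expected_masters[focal] | truth.deficient_tfs
        )
        assert not (truth.expected_masters[focal] & truth.deficient_tfs)
        # the deficient TFs are never planted up in the focal iMGL group
        assert not (truth.up_programs[f"{focal}.iMGL"] & truth.deficient_tfs)

    def test_markers_planted_up_only_in_microglia_like_groups(self):
        truth = generate_truth(small_config())
        for key, up in truth.up_programs.items():
            celltype = key.split(".", 1)[1]
            if celltype in ("fetalMG", "adultMG", "iMGL"):
                continue
            assert not (up & truth.marker_genes)

    def test_network_signs_are_plus_minus_one(self):
        truth = generate_truth(small_config())
        assert set(truth.network["sign"]) <= {1, -1}
        assert not truth.network.duplicated(["source", "target"]).any()


class TestSimulateCounts:
    def test_deterministic_counts(self):
        cfg = small_config(seed=4)
        truth = generate_truth(cfg)
        c1, m1 = simulate_counts(truth, cfg)
        c2, m2 = simulate_counts(truth, cfg)
        assert c1.equals(c2) and m1.equals(m2)

    def test_planted_fold_change_reproduces_in_group_means(self):
        cfg = small_config(seed=1, fold_change_up=4.0, n_reps_per_group=10)
        truth = generate_truth(cfg)
        counts, metadata = simulate_counts(truth, cfg)
        prot = [p for p in truth.protocols if p != truth.focal_protocol][1]
        up = sorted(
            (truth.up_programs[f"{prot}.iMGL"] - truth.expected_masters[prot])
            - truth.partial_tfs
        )
        imgl = metadata[(metadata.protocol == prot) & (metadata.cell_type == "iMGL")]
        ipsc = metadata[
            (metadata.protocol == truth.fallback_protocol)
            & (metadata.cell_type == "iPSC")
        ]
        ratios = (
            counts.loc[up, imgl.sample_id].mean(axis=1)
            / counts.loc[up, ipsc.sample_id].mean(axis=1)
        )
        assert 3.0 <= ratios.mean() <= 5.0

    def test_equal_library_sizes_give_equal_column_sums_under_null(self):
        cfg = small_config(
            seed=2,
            n_markers=0,
            n_masters=0,
            n_deficient=0,
            focal_extra_up=0,
            faithful_extra_up=0,
            n_shared_immune=10,
            n_negative_own=2,
            library_size_range=(1_000_000, 1_000_000),
        )
        truth = generate_truth(cfg)
        # null construction: strip every planted program
        truth.up_programs = {k: frozenset() for k in truth.up_programs}
        truth.down_programs = {k: frozenset() for k in truth.down_programs}
        counts, _ = simulate_counts(truth, cfg)
        sums = counts.sum(axis=0).to_numpy(dtype=float)
        # column-total CV under the NB model is sqrt(sum(mu + disp*mu^2))/L
        # ~= sqrt(disp * sum(p^2)) ~ 1.2% for this log-uniform composition;
        # allow ~4 sigma for the max over all columns
        assert np.abs(sums / 1_000_000 - 1).max() < 0.05

    def test_metadata_carries_reference_links(self):
        cfg = small_config()
        truth = generate_truth(cfg)
        _, metadata = simulate_counts(truth, cfg)
        assert set(io.METADATA_COLUMNS) <= set(metadata.columns)
        own_ipsc = set(
            metadata[metadata.cell_type == "iPSC"]["protocol"].unique()
        )
        for _, row in metadata.iterrows():
            expect = row.protocol if row.protocol in own_ipsc else truth.fallback_protocol
            assert row.reference_ipsc == expect


class TestNullTwoGroup:
    def test_no_systematic_group_ratio_under_null(self):
        counts, test, ref = simulate_two_group(1000, seed=6)
        ratio = (counts[test].mean(axis=1) + 1) / (counts[ref].mean(axis=1) + 1)
        assert abs(np.log2(ratio).mean()) < 0.05


class TestFixtureIO:
    def test_counts_round_trip(self, tmp_path, small_fixture):
        _, truth, counts, metadata = small_fixture
        paths = write_fixture(counts, metadata, truth.network, truth, tmp_path)
        assert io.read_counts(paths["counts"]).equals(counts)

    def test_mtx_round_trip(self, tmp_path, small_fixture):
        _, truth, counts, metadata = small_fixture
        write_fixture(counts, metadata, truth.network, truth, tmp_path, write_mtx=True)
        back = io.read_counts_mtx(tmp_path / "mtx")
        np.testing.assert_array_equal(back.to_numpy(), counts.to_numpy())

    def test_network_file_has_one_row_per_edge(self, tmp_path, small_fixture):
        _, truth, counts, metadata = small_fixture
        paths = write_fixture(counts, metadata, truth.network, truth, tmp_path)
        lines = paths["network"].read_text().strip().splitlines()
        assert len(lines) - 1 == len(truth.network)

    def test_truth_json_round_trip(self, tmp_path, small_fixture):
        _, truth, counts, metadata = small_fixture
        paths = write_fixture(counts, metadata, truth.network, truth, tmp_path)
        back = PlantedTruth.from_dict(io.read_json(paths["truth"]))
        assert back.marker_genes == truth.marker_genes
        assert back.up_programs == truth.up_programs
        assert back.expected_masters == truth.expected_masters
        assert back.network.equals(truth.network.astype({"sign": int}))

    def test_byte_identical_fixtures_under_same_config(self, tmp_path):
        cfg = small_config(seed=12)
        for d in ("one", "two"):
            truth, counts, metadata = make_fixture(cfg)
            write_fixture(counts, metadata, truth.network, truth, tmp_path / d)
        for name in ("counts.tsv", "metadata.tsv", "network.tsv", "truth.json"):
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes()
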