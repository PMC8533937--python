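import pytest

from imglkit import pipeline, synthetic


@pytest.fixture(scope="session")
def default_fixture():
    """The default six-protocol study at seed 1."""
    cfg = synthetic.default_config(seed=1)
    truth, counts, metadata = synthetic.make_fixture(cfg)
    return cfg, truth, counts, metadata


@pytest.fixture(scope="session")
def default_analysis(default_fixture):
    """Full in-memory pipeline run on the seed-1 fixture."""
    _, truth, counts, metadata = default_fixture
    res = pipeline.analyze(
        counts,
        metadata,
        truth.network,
        regulome_seeds=(truth.seed_tf_wide, truth.seed_tf_narrow),
    )
    return truth, res


def small_config(seed: int = 3, **overrides) -> synthetic.GeneratorConfig:
    """A shrunken study for fast unit tests (same architecture)."""
    kw = dict(
        n_genes=700,
        n_markers=40,
        n_shared_immune=60,
        n_negative_own=20,
        n_reps_per_group=4,
    )
    kw.update(overrides)
    return synthetic.default_config(seed=seed, **kw)


@pytest.fixture()
def small_fixture():
    cfg = small_config()
    truth, counts, metadata = synthetic.make_fixture(cfg)
    return cfg, truth, counts, metadata
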