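import dataclasses

import pytest

import polyspec as ps


SMALL_SPEC = dict(
    seed=3,
    n_columns=24,
    n_states=4,
    n_flex=6,
    n_spec=9,
    n_shared=1,
    n_neutral=3,
    mutations_min=3,
    mutations_max=10,
)


@pytest.fixture(scope="session")
def default_bundle() -> ps.SyntheticBundle:
    """The default study conditions, seed 1."""
    return ps.generate(ps.GeneratorSpec(seed=1))


@pytest.fixture(scope="session")
def small_bundle() -> ps.SyntheticBundle:
    return ps.generate(ps.GeneratorSpec(**SMALL_SPEC))


@pytest.fixture(scope="session")
def default_run() -> ps.PipelineResult:
    """Full pipeline on the default synthetic bundle (no file outputs)."""
    cfg = ps.RunConfig(out_dir="unused", write_outputs=False,
                       synthetic={"seed": 1}, base_seed=100)
    return ps.run(cfg)


@pytest.fixture()
def small_config(tmp_path):
    return ps.RunConfig(out_dir=str(tmp_path / "out"),
                        synthetic=dict(SMALL_SPEC), base_seed=5)


def make_ensemble(columns, sequences):
    """Hand-built ensemble for recovery/reversion unit tests."""
    return ps.DesignEnsemble(
        columns=tuple(columns),
        sequences=tuple(sequences),
        fitnesses=tuple(0.0 for _ in sequences),
        mode="multi",
        state_ids=("s1",),
        base_seed=0,
    )


@pytest.fixture()
def ensemble_factory():
    return make_ensemble
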