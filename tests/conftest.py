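import numpy as np
import pytest

from ifacewcn.structure_io import ManifestEntry


@pytest.fixture
def rng():
    return np.random.default_rng(20150121)


@pytest.fixture(scope="session")
def slab_dimer():
    from ifacewcn.synthetic_data import SlabDimerSpec, make_slab_dimer

    return make_slab_dimer(SlabDimerSpec(seed=3))


@pytest.fixture(scope="session")
def slab_entry():
    return ManifestEntry("SYNT", [frozenset("A"), frozenset("B")], "homodimer")


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """A 10-dimer synthetic dataset with its manifest, analyzed once."""
    from ifacewcn import pipeline
    from ifacewcn.synthetic_data import make_fixture_set

    root = tmp_path_factory.mktemp("fixture_ds")
    manifest = make_fixture_set(10, seed=7, out_dir=root / "pdb")
    cfg = pipeline.RunConfig(
        manifest=manifest,
        pdb_dir=root / "pdb",
        out_dir=root / "out",
        dataset_name="synthetic-10",
    )
    summary = pipeline.run_dataset(cfg)
    return cfg, summary
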