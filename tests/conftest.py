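import pytest

from duplexindel.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """A small artifact-free simulation shared across read-only tests."""
    cfg = SimConfig(seed=42, n_molecules=300, n_somatic=60, n_germline=20)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def dirty_dataset():
    """A simulation with every artifact class switched on."""
    cfg = SimConfig(
        seed=1234, n_molecules=500, n_somatic=80, n_germline=25,
        single_strand_artifact_rate=0.05, collision_rate=0.02,
        n_mismerge=4, n_common=8,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def bam_dataset(tmp_path_factory):
    """A simulation written to disk (FASTA/BAM/FASTQ/tables)."""
    cfg = SimConfig(seed=7, n_molecules=150, n_somatic=30, n_germline=10)
    ds = simulate_dataset(cfg)
    outdir = tmp_path_factory.mktemp("simdata")
    paths = ds.write(str(outdir))
    return ds, paths
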