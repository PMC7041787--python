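import pytest

from crossomics.simulate import SimConfig, simulate_corpus


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """Scaled-down study design used by unit tests (fast, same structure)."""
    base = dict(
        seed=seed,
        n_genes=400,
        n_chroms=8,
        n_pathways=60,
        pathway_size_range=(10, 30),
        n_shared_causal_pathways=4,
        n_height_causal_pathways=4,
        n_cases=100,
        n_controls=100,
        n_smoking_meth_genes=60,
        n_dmp_genes=50,
        cpgs_per_gene=4,
        n_qtl_pairs=25,
        n_null_geno_snps=50,
        module_spec=((40, 0.8),) * 3,
        n_brain_noise_genes=120,
        reps_per_cell=2,
        n_cc_background_genes=100,
        n_dose_background_genes=150,
        ppi_n_nodes=300,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def corpus():
    """One shared small corpus; tests must not mutate it."""
    return simulate_corpus(small_config())


@pytest.fixture(scope="session")
def config():
    return small_config()
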