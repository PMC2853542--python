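import numpy as np
import pytest

import epicminer as em


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def noise_free_run(tmp_path_factory):
    """The noise-free 5-species simulation plus a full pipeline run on it.

    Shared across tests: the pipeline run is the expensive step, and every
    consumer reads the same deterministic seed-1 realization.
    """
    sim = em.simulate_genome_set(em.noise_free_config(1))
    out = tmp_path_factory.mktemp("noise_free")
    paths = em.write_simulation(sim, out)
    refs = [paths[f"ref{i}_fasta"] for i in range(1, sim.config.n_species)]
    markers, report = em.run_pipeline(paths["query_fasta"], paths["query_gff3"], refs)
    return {"sim": sim, "paths": paths, "refs": refs, "markers": markers, "report": report}


@pytest.fixture(scope="session")
def micro_sim_dir(tmp_path_factory):
    """A tiny 2-species noise-free simulation for fast CLI runs."""
    cfg = em.SimulationConfig(
        seed=7,
        n_species=2,
        n_genes=4,
        exons_per_gene=(2, 2),
        exon_substitution_rate=0.0,
        intron_substitution_rate=0.0,
        intron_indel_rate=0.0,
        n_duplicated_genes=1,
        n_long_intron_genes=1,
        n_low_identity_genes=0,
    )
    sim = em.simulate_genome_set(cfg)
    out = tmp_path_factory.mktemp("micro_sim")
    paths = em.write_simulation(sim, out)
    return {"sim": sim, "paths": paths}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
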