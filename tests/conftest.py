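import copy

import pytest

from silico16s.pipeline import RunConfig, run_pipeline
from silico16s.simulate import generate_community, table1_like_spec


@pytest.fixture(scope="session")
def community():
    spec, links = table1_like_spec()
    return generate_community(spec, ma_links=links)


@pytest.fixture(scope="session")
def sim_paths(community, tmp_path_factory):
    return community.write(tmp_path_factory.mktemp("sim"))


@pytest.fixture(scope="session")
def pipeline_result(community, sim_paths, tmp_path_factory):
    cfg = RunConfig(
        genomes_fasta=sim_paths["genomes"],
        taxonomy_tsv=sim_paths["taxonomy"],
        out_dir=tmp_path_factory.mktemp("run"),
        seed=community.spec.seed,
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def zero_divergence_community():
    spec, links = table1_like_spec()
    spec = copy.deepcopy(spec)
    for sp in spec.species:
        sp.divergence = 0.0
    return generate_community(spec, ma_links=links)
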