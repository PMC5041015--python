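import dataclasses

import pytest

from parasign import pipeline
from parasign.synth import SynthConfig, generate_pangenome


@pytest.fixture(scope="session")
def default_scenario():
    """The default synthetic study: 20 genomes, 3 subgroups with the
    CxxxHGH / CxxxxxHGH / ExxHGH patterns, context size 3, default noise."""
    return generate_pangenome(SynthConfig())


@pytest.fixture(scope="session")
def default_result(default_scenario):
    sp = default_scenario
    return pipeline.run_workflow(sp.genomes, sp.family_table, family_id=sp.config.family_id)


@pytest.fixture(scope="session")
def noiseless_scenario():
    cfg = dataclasses.replace(SynthConfig(), motif_mutation=0.0, gene_loss=0.0)
    return generate_pangenome(cfg)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_scenario):
    sp = noiseless_scenario
    return pipeline.run_workflow(sp.genomes, sp.family_table, family_id=sp.config.family_id)
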