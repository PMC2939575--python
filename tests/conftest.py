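import logging

import pytest

from intronevo import IntronEvolutionModel, build_paper_fixture

logging.getLogger("intronevo").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def paper_fixture():
    return build_paper_fixture(seed=7)


@pytest.fixture(scope="session")
def fitted(paper_fixture):
    """Full inference run on the packaged study fixture."""
    return IntronEvolutionModel.from_fixture(paper_fixture).fit()


@pytest.fixture(scope="session")
def lineage_ids(paper_fixture, fitted):
    """Resolve symbolic clade labels to inferred lineage ids."""
    rec = fitted.reconciliation
    return {label: rec.gene_lineage[rep]
            for label, rep in paper_fixture.clade_representatives.items()}
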