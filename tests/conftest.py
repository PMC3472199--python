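import numpy as np
import pytest

from ppofam.io_formats import splice_cds, translate
from ppofam.synthetic_family import (ArchetypeParams, SimulationConfig,
                                     build_archetype_protein, simulate_family)


@pytest.fixture(scope="session")
def default_family():
    """Quartet family with one decoy of every class (fixed seed)."""
    cfg = SimulationConfig(
        seed=7, duplication_rate=0.5, loss_rate=0.1,
        decoy_spec={"TOO_SHORT": 1, "PREMATURE_STOP": 1,
                    "MISSING_HIS": 1, "INCOMPLETE_DOMAIN": 1})
    return simulate_family(cfg)


@pytest.fixture(scope="session")
def family_proteins(default_family):
    """gene_id -> (CodingSequence, ProteinSequence) for every model."""
    out = {}
    for m in default_family.models:
        cds = splice_cds(m, default_family.genomes)
        out[m.gene_id] = (cds, translate(cds, tolerate_trailing=True))
    return out


@pytest.fixture(scope="session")
def archetype():
    """(residues, true boundaries, invariant mask) at a fixed seed."""
    rng = np.random.default_rng(0)
    return build_archetype_protein(ArchetypeParams(), rng)
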