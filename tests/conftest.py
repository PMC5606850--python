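import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hfqtail.ensemble_io import Conformation, ModelEnsemble, SelectionSets

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_bead_conformation(model_id, energy, beads):
    """Build a CA-bead conformation from (chain, res_id, res_name, xyz)."""
    return Conformation(
        model_id=model_id,
        total_energy=energy,
        chain_ids=np.array([b[0] for b in beads]),
        res_ids=np.array([b[1] for b in beads], dtype=int),
        res_names=np.array([b[2] for b in beads]),
        atom_names=np.array(["CA"] * len(beads)),
        coord=np.array([b[3] for b in beads], dtype=float),
    )


@pytest.fixture
def two_chain_selections():
    return SelectionSets(
        core=frozenset({1, 2}),
        tail=frozenset({10}),
        basic_core=frozenset({1}),
        numbering_scheme="test",
    )


@pytest.fixture
def two_model_bead_ensemble():
    """Two models, two chains: an ARG/ALA core pair plus a GLU tail bead.

    Model 1 places the tail bead 5 Å from the chain-A arginine (strong
    contact); model 2 pulls both tails far away.
    """
    def build(tail_a, tail_b, model_id, energy):
        beads = [
            ("A", 1, "ARG", (0.0, 0.0, 0.0)),
            ("A", 2, "ALA", (0.0, 6.0, 0.0)),
            ("A", 10, "GLU", tail_a),
            ("B", 1, "ARG", (30.0, 0.0, 0.0)),
            ("B", 2, "ALA", (30.0, 6.0, 0.0)),
            ("B", 10, "GLU", tail_b),
        ]
        return make_bead_conformation(model_id, energy, beads)

    m1 = build((5.0, 0.0, 0.0), (25.0, 0.0, 0.0), 1, -10.0)
    m2 = build((0.0, 0.0, 80.0), (30.0, 0.0, 80.0), 2, -2.0)
    return ModelEnsemble(models=[m1, m2], n_subunits=2, species_label="test")
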