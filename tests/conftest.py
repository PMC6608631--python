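import numpy as np
import pytest

from tetrare.metal_sites import RadiiTable
from tetrare.synthetic import MotifSpec, SyntheticSpec, generate_structure


@pytest.fixture(scope="session")
def radii():
    return RadiiTable()


@pytest.fixture()
def cubane_model():
    """Noise-free ideal cubane cluster as a parsed-equivalent model."""
    spec = SyntheticSpec(seed=0, motifs=[MotifSpec(kind="cubane")])
    model, truth = generate_structure(spec)
    return model, truth


@pytest.fixture()
def two_year_like_model():
    """His adduct plus one cubane, the motif content of the fully reacted
    two-year structure, with its DPI-scale coordinate precision."""
    spec = SyntheticSpec(
        seed=0,
        dpi=0.018,
        motifs=[
            MotifSpec(kind="his_site", center=(0.0, 0.0, 0.0)),
            MotifSpec(kind="cubane", center=(15.0, 0.0, 0.0)),
        ],
    )
    return generate_structure(spec)


def random_metal_model(rng: np.random.Generator, n_max: int = 30):
    """Random cloud of Re atoms in a 15 Å box (for cluster-oracle tests)."""
    from tetrare.pdbio import AtomRecord, StructureModel

    n = int(rng.integers(1, n_max + 1))
    coords = rng.uniform(0.0, 15.0, size=(n, 3))
    atoms = [
        AtomRecord(
            serial=i + 1, name="RE", element="Re", residue_name="RE1",
            chain="A", residue_number=i + 1, xyz=c, occupancy=1.0,
            b_factor=10.0, is_het=True,
        )
        for i, c in enumerate(coords)
    ]
    return StructureModel(atoms=atoms)
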