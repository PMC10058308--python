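import numpy as np
import pytest

from rpflex.pocket_detect import GridPocket
from rpflex.synthetic_fixtures import (
    make_cavity_shell,
    make_perturbed_ensemble,
    make_rna_template,
)


@pytest.fixture(scope="session")
def cavity_shell():
    """Atom shell sealing a spherical cavity of free radius 4 Å."""
    return make_cavity_shell(inner_radius=4.0, shell_thickness=6.0,
                             atom_spacing=1.0)


@pytest.fixture(scope="session")
def ring_template():
    """Ring-shaped synthetic RNA (20 nt) with a guaranteed axial pocket."""
    return make_rna_template(20)


@pytest.fixture(scope="session")
def small_ensemble(ring_template):
    """8-model ensemble with moderate per-nucleotide displacement."""
    return make_perturbed_ensemble(ring_template, n_models=8, s=0.4, seed=11)


def random_grid_pocket(rng: np.random.Generator, n_cells: int,
                       span: int = 8, **kwargs) -> GridPocket:
    """Random connected-ish voxel set for similarity fixtures."""
    cells = {(0, 0, 0)}
    while len(cells) < n_cells:
        base = list(cells)[rng.integers(len(cells))]
        step = rng.integers(-1, 2, size=3)
        cand = tuple(int(np.clip(base[d] + step[d], -span, span))
                     for d in range(3))
        cells.add(cand)
    defaults = dict(model_index=1, pocket_index_in_model=1,
                    origin=(0.0, 0.0, 0.0), spacing=1.0)
    defaults.update(kwargs)
    return GridPocket(cells=frozenset(cells), **defaults)
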