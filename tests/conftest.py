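import numpy as np
import pytest

from crystafm.core import Lattice2D
from crystafm import synthetic as syn

PAPER_CELL = dict(a_len=10.8, b_len=6.6, gamma=100.0)


@pytest.fixture(scope="session")
def paper_lattice() -> Lattice2D:
    return Lattice2D(**PAPER_CELL, origin=(2.0, 2.0))


def full_crystal(lattice, scan, template=None, layers=None):
    """Crystal covering every admissible site of the field of view."""
    template = template or syn.RepeatUnitTemplate()
    layers = layers or syn.LayerModel()
    sites = syn.allowed_sites(layers, lattice, template, scan)
    stripes = [
        syn.Stripe(i, row, lo, hi)
        for i, (row, (lo, hi)) in enumerate(sorted(sites.items()))
    ]
    topo = syn.render_topograph(stripes, template, layers, lattice, scan)
    return topo, stripes


@pytest.fixture(scope="session")
def clean_crystal(paper_lattice):
    """Noise-free, blur-free full crystal at the default scan geometry."""
    scan = syn.ScanParams(tip_blur_sigma=0.0, noise_sigma=0.0)
    topo, _ = full_crystal(paper_lattice, scan)
    return topo


@pytest.fixture(scope="session")
def blurred_crystal(paper_lattice):
    """Full crystal with the default tip blur, no noise."""
    scan = syn.ScanParams(tip_blur_sigma=0.5, noise_sigma=0.0)
    topo, _ = full_crystal(paper_lattice, scan)
    return topo


def toy_structure(coords, atom_names=None, res_ids=None, elements=None,
                  chain="A"):
    """Small synthetic AtomicStructure from raw coordinates (angstrom)."""
    from crystafm.structure import AtomicStructure

    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return AtomicStructure(
        element=np.asarray(elements if elements is not None else ["C"] * n),
        atom_name=np.asarray(atom_names if atom_names is not None else ["CA"] * n),
        res_name=np.asarray(["ALA"] * n),
        res_id=np.asarray(res_ids if res_ids is not None else np.arange(1, n + 1)),
        chain_id=np.asarray([chain] * n),
        coord=coords,
    )
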