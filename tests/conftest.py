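import numpy as np
import pytest

from dockmd.structure import Structure


def _peptide_atoms(n_res: int, ligand: bool, lig_offset: float):
    """Minimal peptide: N, CA, C, O, CB, H per residue along x, optionally
    followed by a 3-atom ligand (O1, C1, H1) displaced by lig_offset in z."""
    names, elements, resnames, resids, chains, coords = [], [], [], [], [], []
    templ = [
        ("N", "N", (0.0, 0.0, 0.0)),
        ("CA", "C", (1.4, 0.3, 0.0)),
        ("C", "C", (2.4, -0.6, 0.6)),
        ("O", "O", (2.4, -1.8, 0.5)),
        ("CB", "C", (1.5, 1.2, 1.2)),
        ("H", "H", (-0.5, 0.8, 0.3)),
    ]
    for r in range(n_res):
        for nm, el, xyz in templ:
            names.append(nm)
            elements.append(el)
            resnames.append("ALA")
            resids.append(r + 1)
            chains.append("A")
            coords.append((xyz[0] + 3.5 * r, xyz[1], xyz[2]))
    if ligand:
        for nm, el, xyz in [
            ("O1", "O", (1.5, 0.0, lig_offset)),
            ("C1", "C", (2.8, 0.2, lig_offset)),
            ("H1", "H", (3.3, 0.9, lig_offset)),
        ]:
            names.append(nm)
            elements.append(el)
            resnames.append("LIG")
            resids.append(n_res + 1)
            chains.append("B")
            coords.append(xyz)
    return names, elements, resnames, resids, chains, np.array(coords)


@pytest.fixture
def make_peptide():
    def factory(n_res=3, ligand=True, lig_offset=3.0):
        names, elements, resnames, resids, chains, coords = _peptide_atoms(
            n_res, ligand, lig_offset
        )
        return Structure(
            names=names,
            elements=elements,
            resnames=resnames,
            resids=resids,
            chains=chains,
            coords=coords,
        )

    return factory


@pytest.fixture
def peptide(make_peptide):
    return make_peptide()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
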