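import textwrap

import numpy as np
import pytest

from fodm.structure_io import HydroScale, ResidueCloud, ResidueRecord


def pdb_atom_line(serial, name, resname, chain, resnum, x, y, z,
                  occ=1.0, altloc=" ", element=None):
    element = element or name[0]
    return (f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}{resnum:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


@pytest.fixture
def glycine_pdb(tmp_path):
    """One glycine with heavy atoms at x = 0, 2, 4, 6 (mean 3)."""
    lines = [
        pdb_atom_line(1, "N", "GLY", "A", 1, 0, 0, 0),
        pdb_atom_line(2, "CA", "GLY", "A", 1, 2, 0, 0, element="C"),
        pdb_atom_line(3, "C", "GLY", "A", 1, 4, 0, 0),
        pdb_atom_line(4, "O", "GLY", "A", 1, 6, 0, 0),
        pdb_atom_line(5, "N", "ALA", "A", 2, 10, 0, 0),
        pdb_atom_line(6, "CA", "ALA", "A", 2, 12, 0, 0, element="C"),
        "END",
    ]
    path = tmp_path / "gly.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def two_chain_pdb(tmp_path):
    lines = []
    serial = 1
    for chain, n_res in (("A", 3), ("B", 2)):
        for i in range(n_res):
            x = 10 * i + (0 if chain == "A" else 100)
            lines.append(pdb_atom_line(serial, "CA", "ALA", chain, i + 1,
                                       x, 0, 0, element="C"))
            serial += 1
    lines.append("END")
    path = tmp_path / "two_chain.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_cloud(positions, hydrophobicities=None, names=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    h = hydrophobicities if hydrophobicities is not None else [float("nan")] * n
    names = names or ["ALA"] * n
    records = [
        ResidueRecord("A", i + 1, "", names[i], positions[i], float(h[i]))
        for i in range(n)
    ]
    return ResidueCloud(records, source_id="test", selection="synthetic")


@pytest.fixture
def flat_scale():
    """A scale mapping every residue to distinct, easily tracked values."""
    from fodm.structure_io import STANDARD_AA
    values = {aa: (i + 1) / 20 for i, aa in enumerate(sorted(STANDARD_AA))}
    return HydroScale(name="test-scale", values=values)


def random_rotation(seed):
    """A deterministic proper rotation matrix from a seeded QR decomposition."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
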