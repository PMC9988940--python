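"""Shared geometry helpers for structure/SASA tests: ideal-geometry amino
acid fixtures built with internal-coordinate (NeRF) placement."""

from __future__ import annotations

import numpy as np

from afmissense.structure import Atom, Provenance, ResidueModel, StructureModel


def place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """Position of atom d from internal coordinates relative to a-b-c."""
    angle = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dih),
            bond * np.sin(angle) * np.sin(dih),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def isolated_residue(aa: str = "A") -> StructureModel:
    """A single free amino-acid residue (heavy atoms, ideal geometry).

    Supports alanine (N, CA, C, O, CB) and glycine (no CB).
    """
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([1.458, 0.0, 0.0])
    C = place_atom(N + np.array([0.0, 1.0, 0.0]), N, CA, 1.525, 111.2, 60.0)
    O = place_atom(N, CA, C, 1.231, 120.8, 0.0)
    atoms = [Atom("N", "N", N), Atom("CA", "C", CA), Atom("C", "C", C), Atom("O", "O", O)]
    if aa == "A":
        CB = place_atom(N, C, CA, 1.53, 110.5, 122.5)
        atoms.append(Atom("CB", "C", CB))
    elif aa != "G":
        raise ValueError("only A and G fixtures are provided")
    return StructureModel(
        uniprot_id="FREE",
        residues=[ResidueModel(index=1, aa=aa, atoms=atoms, plddt=90.0)],
        provenance=Provenance.SYNTHETIC,
    )
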