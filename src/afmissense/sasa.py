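"""Solvent accessible surface area (Shrake-Rupley) and relative accessibility.

SASA is computed with the Shrake-Rupley test-point method on a deterministic
golden-spiral (Fibonacci) sphere: for each heavy atom, points are placed on a
sphere of radius (van der Waals + probe) and counted as accessible when they
fall inside no neighbouring expanded sphere. Relative accessibility (rASA)
divides a residue's SASA by a per-amino-acid reference maximum (Tien et al.
2013 theoretical values by default); positions with rASA below 0.7 are
treated as "less accessible" in the burial subset filter.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "SasaResult",
    "MaxAsaTable",
    "BurialClass",
    "UnknownElementError",
    "golden_spiral_points",
    "shrake_rupley",
    "relative_asa",
    "classify_burial",
    "load_max_asa",
    "load_vdw_radii",
    "annotate_model",
]

DEFAULT_PROBE_RADIUS = 1.4  # Å, water probe
DEFAULT_N_POINTS = 960


class UnknownElementError(ValueError):
    """An atom's element has no van der Waals radius in the bundled table."""


class BurialClass(str, enum.Enum):
    LESS_ACCESSIBLE = "less_accessible"
    ACCESSIBLE = "accessible"


@dataclass(frozen=True)
class MaxAsaTable:
    """Per-amino-acid maximum reference ASA (Å²), keyed by one-letter code."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.values) != 20 or any(v <= 0 for v in self.values.values()):
            raise ValueError("max-ASA table must have 20 positive entries")

    def __getitem__(self, aa: str) -> float:
        if aa not in self.values:
            raise KeyError(f"no max-ASA entry for amino acid {aa!r}")
        return self.values[aa]


def _read_data_tsv(filename: str) -> pd.DataFrame:
    with resources.files("afmissense.data").joinpath(filename).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_max_asa(scale: str = "tien2013_theoretical") -> MaxAsaTable:
    """Load a bundled max-ASA scale (default: Tien et al. 2013 theoretical)."""
    if scale != "tien2013_theoretical":
        raise ValueError(f"unknown max-ASA scale {scale!r}")
    df = _read_data_tsv("max_asa_tien2013.tsv")
    return MaxAsaTable(name=scale, values=dict(zip(df["aa"], df["max_asa"].astype(float))))


def load_vdw_radii() -> dict[str, float]:
    """Bundled element van der Waals radii (Å)."""
    df = _read_data_tsv("vdw_radii.tsv")
    return dict(zip(df["element"].astype(str), df["radius"].astype(float)))


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` deterministic, nearly uniform unit vectors (Fibonacci sphere)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass(frozen=True)
class SasaResult:
    """Per-atom and per-residue SASA for one model."""

    atom_sasa: np.ndarray  # (n_atoms,), Å²
    residue_sasa: dict[int, float]  # residue index -> Å²
    probe_radius: float
    n_sphere_points: int

    def total(self) -> float:
        return float(self.atom_sasa.sum())


def shrake_rupley(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
    vdw_radii: Optional[Mapping[str, float]] = None,
) -> SasaResult:
    """Shrake-Rupley SASA over all atoms of the model.

    Deterministic for a fixed point count (golden-spiral placement). A test
    point is blocked when strictly inside a neighbour's expanded sphere, so
    exactly tangent spheres do not occlude each other. Exactly coincident
    atoms of equal radius are collapsed to a single sphere whose area is
    assigned to the first of them (the duplicates contribute zero).
    """
    if vdw_radii is None:
        vdw_radii = load_vdw_radii()
    coords, radii, owners = [], [], []
    for res in model.residues:
        for atom in res.atoms:
            el = atom.element.upper()
            if el not in vdw_radii:
                raise UnknownElementError(
                    f"residue {res.index} atom {atom.name!r}: element {el!r} "
                    "has no van der Waals radius"
                )
            coords.append(atom.coord)
            radii.append(vdw_radii[el])
            owners.append(res.index)
    if not coords:
        raise ValueError("model has no atoms")
    coords_arr = np.asarray(coords)
    radii_arr = np.asarray(radii)
    n_atoms = len(coords_arr)

    # collapse exactly coincident atoms with the same radius onto the first
    seen: dict[tuple, int] = {}
    rep = np.arange(n_atoms)
    for i in range(n_atoms):
        key = (round(coords_arr[i, 0], 9), round(coords_arr[i, 1], 9),
               round(coords_arr[i, 2], 9), radii_arr[i])
        rep[i] = seen.setdefault(key, i)
    unique_idx = np.flatnonzero(rep == np.arange(n_atoms))

    unit = golden_spiral_points(n_sphere_points)
    tree = cKDTree(coords_arr[unique_idx])
    max_r = radii_arr.max()
    atom_sasa = np.zeros(n_atoms)
    for ui, i in enumerate(unique_idx):
        R = radii_arr[i] + probe_radius
        pts = coords_arr[i] + R * unit
        nb_local = tree.query_ball_point(coords_arr[i], R + max_r + probe_radius)
        nb = [unique_idx[k] for k in nb_local if unique_idx[k] != i]
        if nb:
            nb_arr = np.array(nb)
            d = np.linalg.norm(
                pts[:, None, :] - coords_arr[nb_arr][None, :, :], axis=2
            )
            blocked = (d < (radii_arr[nb_arr] + probe_radius)[None, :]).any(axis=1)
            accessible = int((~blocked).sum())
        else:
            accessible = n_sphere_points
        atom_sasa[i] = 4.0 * np.pi * R * R * accessible / n_sphere_points

    residue_sasa: dict[int, float] = {}
    for idx, s in zip(owners, atom_sasa):
        residue_sasa[idx] = residue_sasa.get(idx, 0.0) + float(s)
    return SasaResult(
        atom_sasa=atom_sasa,
        residue_sasa=residue_sasa,
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
    )


def relative_asa(
    res_sasa: float, aa: str, table: Optional[MaxAsaTable] = None
) -> float:
    """rASA = residue SASA / reference maximum for its amino acid.

    Values may exceed 1 for terminal or unusually exposed residues and are
    not clamped; values above 1.2 are flagged with a warning.
    """
    if table is None:
        table = load_max_asa()
    rasa = res_sasa / table[aa]
    if rasa > 1.2:
        warnings.warn(f"rASA {rasa:.2f} > 1.2 for {aa} (SASA {res_sasa:.1f} Å²)")
    return rasa


def classify_burial(rasa: float, threshold: float = 0.7) -> BurialClass:
    """Strictly-below-threshold positions are "less accessible"."""
    if rasa < 0:
        raise ValueError(f"rASA must be >= 0, got {rasa}")
    return BurialClass.LESS_ACCESSIBLE if rasa < threshold else BurialClass.ACCESSIBLE


def annotate_model(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
    max_asa: Optional[MaxAsaTable] = None,
    burial_threshold: float = 0.7,
) -> pd.DataFrame:
    """Per-residue descriptor table: index, aa, plddt, sasa, rasa, burial.

    Residues with non-standard amino acids get NaN rASA (no reference
    maximum); residues without a Cα have NaN pLDDT.
    """
    if max_asa is None:
        max_asa = load_max_asa()
    sasa = shrake_rupley(model, probe_radius, n_sphere_points)
    rows = []
    for res in model.residues:
        s = sasa.residue_sasa.get(res.index, 0.0)
        try:
            rasa = relative_asa(s, res.aa, max_asa)
        except KeyError:
            rasa = np.nan
        rows.append(
            {
                "index": res.index,
                "aa": res.aa,
                "plddt": res.plddt if res.plddt is not None else np.nan,
                "sasa": s,
                "rasa": rasa,
                "burial": (
                    classify_burial(rasa, burial_threshold).value
                    if np.isfinite(rasa)
                    else ""
                ),
            }
        )
    return pd.DataFrame(rows)
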