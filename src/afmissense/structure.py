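"""AlphaFold model structures: pLDDT-aware PDB I/O, the sliding-window
fragment tiling used for proteins too large for a single prediction window,
Kabsch rigid superposition, and stitching of overlapping fragment models into
a full-length chain.

AlphaFold stores the per-residue confidence score (pLDDT, 0-100) in the
B-factor column of its PDB files; every atom of a residue carries the same
value, so the Cα B-factor is read as the residue's pLDDT. Proteome-scale
predictions of chains longer than one window are shipped as overlapping
fragments F1..Fn (window 1400 residues, stride 200); consecutive fragments
are joined by least-squares superposition on the overlap Cα atoms, dropping
the duplicated overlap residues from the later fragment.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .aa import ONE_TO_THREE, THREE_TO_ONE

__all__ = [
    "Atom",
    "ResidueModel",
    "StructureModel",
    "Provenance",
    "FragmentPlan",
    "Fragment",
    "SuperpositionResult",
    "JoinRecord",
    "StitchError",
    "DegenerateGeometryError",
    "PlddtRangeError",
    "read_pdb_with_plddt",
    "write_pdb",
    "plan_fragments",
    "fragment_overlap",
    "kabsch_superpose",
    "apply_transform",
    "stitch_fragments",
    "global_plddt",
]


class Provenance(str, enum.Enum):
    AF2_DB = "af2_db"
    PROTEOME_FRAGMENT = "proteome_fragment"
    STITCHED = "stitched"
    SYNTHETIC = "synthetic"


class PlddtRangeError(ValueError):
    """A pLDDT value outside [0, 100]."""


class DegenerateGeometryError(ValueError):
    """Too few or collinear points for a unique superposition."""


class StitchError(ValueError):
    """Fragment set cannot be stitched (ordering/overlap violation)."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError("atom coordinate must be a 3-vector")


@dataclass
class ResidueModel:
    """One residue: 1-based sequence index, amino acid (one-letter), atoms,
    and the per-residue pLDDT (None when the residue has no Cα)."""

    index: int
    aa: str
    atoms: list[Atom]
    plddt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.plddt is not None and not 0.0 <= self.plddt <= 100.0:
            raise PlddtRangeError(
                f"residue {self.index}: pLDDT {self.plddt} outside [0, 100]"
            )

    @property
    def ca(self) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == "CA":
                return a
        return None


@dataclass
class StructureModel:
    uniprot_id: str
    residues: list[ResidueModel]
    provenance: Provenance = Provenance.AF2_DB

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) Cα coordinates of residues that have a Cα."""
        return np.array([r.ca.coord for r in self.residues if r.ca is not None])

    def plddt_values(self) -> np.ndarray:
        return np.array([r.plddt for r in self.residues if r.plddt is not None])

    def residue_by_index(self, index: int) -> Optional[ResidueModel]:
        for r in self.residues:
            if r.index == index:
                return r
        return None


def _element_from_atom(atom: gemmi.Atom) -> str:
    el = atom.element.name.strip()
    if el and el != "X":
        return el.upper()
    # fall back to the first alphabetic character of the atom name
    for ch in atom.name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_pdb_with_plddt(
    path: str | Path,
    uniprot_id: Optional[str] = None,
    provenance: Provenance = Provenance.AF2_DB,
) -> StructureModel:
    """Read an AlphaFold-style PDB model, taking each residue's pLDDT from
    its Cα B-factor.

    HETATM records and waters are ignored. A residue without a Cα is kept
    with ``plddt=None`` and a warning (it is excluded from descriptor joins
    downstream). A B-factor outside [0, 100] raises
    :class:`PlddtRangeError`.
    """
    st = gemmi.read_structure(str(path))
    residues: list[ResidueModel] = []
    if len(st) == 0:
        warnings.warn(f"{path}: no polymer residues found")
        return StructureModel(
            uniprot_id=uniprot_id or st.name or "unknown",
            residues=[],
            provenance=provenance,
        )
    model = st[0]
    for chain in model:
        for res in chain:
            if res.het_flag == "H" or res.is_water():
                continue
            atoms = [
                Atom(
                    name=a.name,
                    element=_element_from_atom(a),
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                )
                for a in res
            ]
            if not atoms:
                continue
            ca = next((a for a in res if a.name == "CA"), None)
            if ca is None:
                warnings.warn(
                    f"{path}: residue {res.seqid.num} ({res.name}) has no CA; "
                    "kept without pLDDT"
                )
                plddt = None
            else:
                plddt = float(ca.b_iso)
                if not 0.0 <= plddt <= 100.0:
                    raise PlddtRangeError(
                        f"{path}: residue {res.seqid.num} B-factor {plddt} "
                        "outside the pLDDT range [0, 100]"
                    )
            residues.append(
                ResidueModel(
                    index=res.seqid.num,
                    aa=THREE_TO_ONE.get(res.name.upper(), "X") if res.name else "X",
                    atoms=atoms,
                    plddt=plddt,
                )
            )
    if not residues:
        warnings.warn(f"{path}: only non-polymer records; empty model")
    return StructureModel(
        uniprot_id=uniprot_id or st.name or "unknown",
        residues=residues,
        provenance=provenance,
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a single-chain PDB; pLDDT goes to the B-factor of
    every atom of its residue (the AlphaFold convention)."""
    st = gemmi.Structure()
    st.name = model.uniprot_id
    gm = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for res in model.residues:
        gr = gemmi.Residue()
        gr.name = ONE_TO_THREE.get(res.aa, "UNK")
        gr.seqid = gemmi.SeqId(res.index, " ")
        gr.het_flag = "A"
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element.capitalize())
            ga.pos = gemmi.Position(*atom.coord)
            ga.occ = 1.0
            ga.b_iso = res.plddt if res.plddt is not None else 0.0
            gr.add_atom(ga)
        chain.add_residue(gr)
    gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass(frozen=True)
class FragmentPlan:
    """Sliding-window tiling F1..Fn of a chain of ``protein_length`` residues
    (inclusive 1-based ranges)."""

    protein_length: int
    window: int
    stride: int
    fragments: tuple[tuple[int, int], ...]

    @property
    def labels(self) -> list[str]:
        return [f"F{k + 1}" for k in range(len(self.fragments))]

    def range_of(self, label: str | int) -> tuple[int, int]:
        if isinstance(label, str):
            if not label.upper().startswith("F"):
                raise KeyError(f"unknown fragment label {label!r}")
            try:
                k = int(label[1:])
            except ValueError as exc:
                raise KeyError(f"unknown fragment label {label!r}") from exc
        else:
            k = int(label)
        if not 1 <= k <= len(self.fragments):
            raise KeyError(f"fragment F{k} not in plan of {len(self.fragments)}")
        return self.fragments[k - 1]

    def __len__(self) -> int:
        return len(self.fragments)


def plan_fragments(
    protein_length: int, window: int = 1400, stride: int = 200
) -> FragmentPlan:
    """Tile a chain with overlapping windows.

    F1 starts at residue 1; each subsequent fragment starts one stride
    later; every fragment ends at min(start + window - 1, length); the last
    fragment always reaches the chain end. A chain not longer than one
    window yields a single fragment.
    """
    if protein_length < 1:
        raise ValueError(f"protein_length must be >= 1, got {protein_length}")
    if stride < 1 or window < stride:
        raise ValueError(f"need window >= stride >= 1, got {window=}, {stride=}")
    if protein_length <= window:
        n = 1
    else:
        n = math.ceil((protein_length - window) / stride) + 1
    frags = []
    for k in range(n):
        start = 1 + k * stride
        end = min(start + window - 1, protein_length)
        frags.append((start, end))
    return FragmentPlan(
        protein_length=protein_length,
        window=window,
        stride=stride,
        fragments=tuple(frags),
    )


def fragment_overlap(plan: FragmentPlan, i: str | int, j: str | int) -> int:
    """Number of residues shared by two fragments (0 if disjoint)."""
    si, ei = plan.range_of(i)
    sj, ej = plan.range_of(j)
    return max(0, min(ei, ej) - max(si, sj) + 1)


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform: transformed = rotation @ x + translation."""

    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float
    n_paired: int


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> SuperpositionResult:
    """Least-squares optimal proper rigid superposition (Kabsch, via SVD).

    Returns the rotation/translation minimizing the RMSD of the transformed
    mobile points to the reference, with reflections excluded. Requires at
    least 3 non-collinear point pairs.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 paired points, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    scale = max(np.abs(P0).max(), np.abs(Q0).max(), 1e-12)
    for X in (P0, Q0):
        s = np.linalg.svd(X / scale, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1e-12):
            raise DegenerateGeometryError("points are (near-)collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_paired=n)


def apply_transform(model: StructureModel, result: SuperpositionResult) -> StructureModel:
    """Return a copy of the model with the rigid transform applied to all atoms."""
    R, t = result.rotation, result.translation
    residues = [
        ResidueModel(
            index=r.index,
            aa=r.aa,
            atoms=[
                Atom(name=a.name, element=a.element, coord=R @ a.coord + t)
                for a in r.atoms
            ],
            plddt=r.plddt,
        )
        for r in model.residues
    ]
    return StructureModel(
        uniprot_id=model.uniprot_id, residues=residues, provenance=model.provenance
    )


@dataclass(frozen=True)
class Fragment:
    """One fragment model: its tiling label, the global inclusive residue
    range it covers, and the model with local 1-based numbering."""

    label: str
    start: int
    end: int
    model: StructureModel

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.model):
            raise ValueError(
                f"{self.label}: range {self.start}-{self.end} does not match "
                f"model length {len(self.model)}"
            )


@dataclass(frozen=True)
class JoinRecord:
    """QC record for one stitching join."""

    earlier: str
    later: str
    overlap: int
    n_paired: int
    rmsd: float
    warned: bool


def stitch_fragments(
    fragments: Sequence[Fragment],
    selection: Optional[Sequence[str]] = None,
    min_overlap: int = 200,
    qc_rmsd_threshold: float = 5.0,
) -> tuple[StructureModel, list[JoinRecord]]:
    """Stitch overlapping fragment models into one full-length chain.

    For each consecutive pair (in sequence order), the later fragment is
    rigidly superposed onto the already-assembled chain via the overlap Cα
    atoms; the duplicated overlap residues are then dropped from the later
    fragment, keeping the earlier fragment's coordinates. pLDDT values are
    carried through unchanged. An overlap shorter than ``min_overlap``
    raises :class:`StitchError`; a join RMSD above ``qc_rmsd_threshold``
    warns but proceeds (the join is recorded either way).
    """
    by_label = {f.label: f for f in fragments}
    if selection is not None:
        try:
            chosen = [by_label[lbl] for lbl in selection]
        except KeyError as exc:
            raise StitchError(f"unknown fragment label {exc.args[0]!r}") from exc
    else:
        chosen = list(fragments)
    if not chosen:
        raise StitchError("no fragments to stitch")
    chosen = sorted(chosen, key=lambda f: f.start)

    first = chosen[0]
    assembled: dict[int, ResidueModel] = {}
    for r in first.model.residues:
        g = first.start + r.index - 1
        assembled[g] = ResidueModel(index=g, aa=r.aa, atoms=r.atoms, plddt=r.plddt)
    joins: list[JoinRecord] = []
    prev = first
    for frag in chosen[1:]:
        overlap = prev.end - frag.start + 1
        if overlap < min_overlap:
            raise StitchError(
                f"{prev.label}->{frag.label}: overlap {overlap} below "
                f"min_overlap {min_overlap}"
            )
        mobile_pts, ref_pts = [], []
        for g in range(frag.start, prev.end + 1):
            local = frag.model.residue_by_index(g - frag.start + 1)
            ref = assembled.get(g)
            if local is None or ref is None:
                continue
            if local.ca is None or ref.ca is None:
                continue
            mobile_pts.append(local.ca.coord)
            ref_pts.append(ref.ca.coord)
        sup = kabsch_superpose(np.array(mobile_pts), np.array(ref_pts))
        warned = sup.rmsd > qc_rmsd_threshold
        if warned:
            warnings.warn(
                f"{prev.label}->{frag.label}: overlap RMSD {sup.rmsd:.2f} Å "
                f"exceeds QC threshold {qc_rmsd_threshold} Å; stitching proceeds"
            )
        moved = apply_transform(frag.model, sup)
        for r in moved.residues:
            g = frag.start + r.index - 1
            if g <= prev.end:
                continue  # duplicated overlap residue: keep the earlier fragment
            assembled[g] = ResidueModel(index=g, aa=r.aa, atoms=r.atoms, plddt=r.plddt)
        joins.append(
            JoinRecord(
                earlier=prev.label,
                later=frag.label,
                overlap=overlap,
                n_paired=sup.n_paired,
                rmsd=sup.rmsd,
                warned=warned,
            )
        )
        prev = frag
    residues = [assembled[g] for g in sorted(assembled)]
    stitched = StructureModel(
        uniprot_id=first.model.uniprot_id,
        residues=residues,
        provenance=Provenance.STITCHED,
    )
    return stitched, joins


def global_plddt(model: StructureModel) -> float:
    """Median per-residue pLDDT; even counts use the midpoint of the two
    central values (so half-step medians like 92.625 are representable)."""
    vals = model.plddt_values()
    if vals.size == 0:
        raise ValueError("model has no pLDDT values")
    return float(np.median(vals))
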