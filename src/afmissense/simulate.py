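"""Synthetic labeled variant tables and synthetic structures.

The variant generator emulates the statistical structure the discrimination
analysis assumes: pathogenic variants concentrate at high-confidence
positions (truncated normal pLDDT around 88), benign variants follow a
bimodal pLDDT mixture (a low-confidence disordered mode around 38 and a
high-confidence mode around 88), relative accessibility decreases with
pLDDT (confident regions are ordered cores), and each stability predictor's
harmonized ΔΔG column is drawn from the binormal construction whose designed
AUROC is a config parameter -- pathogenic scores are shifted by
sqrt(2)·Φ⁻¹(AUC) standard deviations toward destabilizing values, so the
expected Mann-Whitney AUC equals the design value exactly.

The structure generator builds gently helical Cα-plus-backbone chains with
exact 3.8 Å consecutive Cα spacing (a valid, non-collinear PDB-writable
fixture), and can split them into overlapping fragments with independent
random rigid-body perturbations, mirroring the proteome fragment inputs of
the stitching pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.transform import Rotation

from .structure import (
    Atom,
    Fragment,
    FragmentPlan,
    Provenance,
    ResidueModel,
    StructureModel,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_variant_scores",
    "simulate_structure",
    "fragment_and_perturb",
    "designed_shift",
]

#: designed AUROCs default to the published total-set discrimination of the
#: five predictors (the study conditions the generator emulates)
DEFAULT_DDG_EFFECT = {
    "mcsm": 0.719,
    "saafec": 0.711,
    "maestro": 0.650,
    "cupsat": 0.614,
    "mupro": 0.534,
}


def designed_shift(auc: float, sd: float = 1.0) -> float:
    """Binormal location shift giving expected AUC = Φ(shift / (sd·√2))."""
    if not 0.5 <= auc < 1.0:
        raise ValueError(f"designed AUROC must be in [0.5, 1), got {auc}")
    return float(np.sqrt(2.0) * sd * stats.norm.ppf(auc))


@dataclass(frozen=True)
class SimulationConfig:
    """Distributions and seed for one synthetic dataset.

    Class sizes default to the 445 pathogenic / 647 benign of the evaluated
    catalog. ``plddt_design_auc``, when set, replaces the qualitative
    mixture/truncated-normal pLDDT model with a binormal design of that AUC
    mapped monotonically into [0, 100] (rank-preserving, so the empirical
    AUC targets the design value exactly in expectation).
    """

    n_pathogenic: int = 445
    n_benign: int = 647
    pathogenic_plddt: tuple[float, float] = (88.0, 6.0)
    benign_plddt_weight_low: float = 0.45
    benign_plddt_low: tuple[float, float] = (38.0, 8.0)
    benign_plddt_high: tuple[float, float] = (88.0, 6.0)
    ddg_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DDG_EFFECT)
    )
    rasa_midpoint_plddt: float = 70.0
    rasa_steepness: float = 0.08
    rasa_noise_sd: float = 0.15
    plddt_design_auc: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathogenic < 1 or self.n_benign < 1:
            raise ValueError("class counts must be >= 1")
        for name, auc in self.ddg_effect.items():
            if not 0.5 <= auc < 1.0:
                raise ValueError(f"{name}: designed AUROC {auc} outside [0.5, 1)")
        if self.plddt_design_auc is not None and not 0.5 <= self.plddt_design_auc < 1.0:
            raise ValueError("plddt_design_auc outside [0.5, 1)")
        for sd in (
            self.pathogenic_plddt[1],
            self.benign_plddt_low[1],
            self.benign_plddt_high[1],
            self.rasa_noise_sd,
        ):
            if sd <= 0:
                raise ValueError("all standard deviations must be > 0")
        if not 0.0 <= self.benign_plddt_weight_low <= 1.0:
            raise ValueError("benign mixture weight must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticDataset:
    table: pd.DataFrame
    config: SimulationConfig


def _truncnorm(rng, mean, sd, size, low=0.0, high=100.0):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def simulate_variant_scores(cfg: SimulationConfig) -> SyntheticDataset:
    """Draw one labeled scored-variant table per the config.

    Class counts are exact. The table has the same column layout as the
    scored-variant table produced by the real pipeline (variant key, binary
    label, plddt, rasa, five harmonized ΔΔG columns) and is bit-for-bit
    reproducible from (config, seed).
    """
    rng = np.random.default_rng(cfg.seed)
    n_p, n_b = cfg.n_pathogenic, cfg.n_benign
    n = n_p + n_b
    labels = np.r_[np.ones(n_p, dtype=int), np.zeros(n_b, dtype=int)]

    if cfg.plddt_design_auc is not None:
        shift = designed_shift(cfg.plddt_design_auc)
        z = np.r_[rng.normal(shift, 1.0, n_p), rng.normal(0.0, 1.0, n_b)]
        # monotone squash into [0, 100]: preserves ranks, hence the AUC
        plddt = 100.0 * stats.norm.cdf(z / 2.5)
    else:
        p_mean, p_sd = cfg.pathogenic_plddt
        plddt_p = _truncnorm(rng, p_mean, p_sd, n_p)
        low_mask = rng.random(n_b) < cfg.benign_plddt_weight_low
        plddt_b = np.where(
            low_mask,
            _truncnorm(rng, *cfg.benign_plddt_low, n_b),
            _truncnorm(rng, *cfg.benign_plddt_high, n_b),
        )
        plddt = np.r_[plddt_p, plddt_b]

    # relative accessibility decays with confidence (ordered cores are buried)
    rasa_mean = 1.0 / (
        1.0 + np.exp(cfg.rasa_steepness * (plddt - cfg.rasa_midpoint_plddt))
    )
    rasa = np.clip(rasa_mean + rng.normal(0.0, cfg.rasa_noise_sd, n), 0.0, None)

    table = pd.DataFrame(
        {
            "uniprot_id": [f"SYN{i // 9000:02d}" for i in range(n)],
            "position": (np.arange(n) % 9000) + 1,
            "label": labels,
            "plddt": plddt,
            "rasa": rasa,
        }
    )
    wt_idx = rng.integers(0, 20, n)
    mut_idx = (wt_idx + rng.integers(1, 20, n)) % 20
    table.insert(2, "wt", _AA[wt_idx])
    table.insert(3, "mut", _AA[mut_idx])

    for name, auc in cfg.ddg_effect.items():
        shift = designed_shift(auc)
        # harmonized convention: negative = destabilizing = pathogenic-like
        ddg = np.r_[rng.normal(-shift, 1.0, n_p), rng.normal(0.0, 1.0, n_b)]
        table[f"ddg_{name}"] = ddg
    return SyntheticDataset(table=table, config=cfg)


def simulate_structure(
    length: int,
    plddt_profile: Optional[Sequence[float]] = None,
    uniprot_id: str = "SYNTH",
    sequence: Optional[str] = None,
) -> StructureModel:
    """Helically twisted backbone chain with exact 3.8 Å Cα spacing.

    Each residue gets N, CA and C atoms; the twist avoids collinearity so
    the chain is usable for superposition and SASA fixtures. The pLDDT
    profile (default: constant 90) must lie in [0, 100].
    """
    if length < 2:
        raise ValueError(f"length must be >= 2, got {length}")
    if plddt_profile is None:
        plddt_profile = [90.0] * length
    plddt_profile = list(plddt_profile)
    if len(plddt_profile) != length:
        raise ValueError("pLDDT profile length must match chain length")
    for v in plddt_profile:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"pLDDT {v} outside [0, 100]")
    if sequence is None:
        sequence = "A" * length
    if len(sequence) != length:
        raise ValueError("sequence length must match chain length")

    radius = 2.3
    dtheta = np.deg2rad(100.0)
    chord = 2.0 * radius * np.sin(dtheta / 2.0)
    rise = float(np.sqrt(3.8**2 - chord**2))
    residues = []
    for i in range(length):
        theta = i * dtheta
        ca = np.array([radius * np.cos(theta), radius * np.sin(theta), rise * i])
        # approximate backbone neighbours along the local tangent
        tangent = np.array([-np.sin(theta), np.cos(theta), rise / 3.8])
        tangent /= np.linalg.norm(tangent)
        outward = np.array([np.cos(theta), np.sin(theta), 0.0])
        n_coord = ca - 1.46 * tangent + 0.3 * outward
        c_coord = ca + 1.52 * tangent + 0.3 * outward
        residues.append(
            ResidueModel(
                index=i + 1,
                aa=sequence[i],
                atoms=[
                    Atom("N", "N", n_coord),
                    Atom("CA", "C", ca),
                    Atom("C", "C", c_coord),
                ],
                plddt=float(plddt_profile[i]),
            )
        )
    return StructureModel(
        uniprot_id=uniprot_id, residues=residues, provenance=Provenance.SYNTHETIC
    )


def fragment_and_perturb(
    model: StructureModel,
    plan: FragmentPlan,
    seed: int = 0,
    zero_rotation: bool = False,
) -> list[Fragment]:
    """Split a model per the tiling plan into independently rigid-perturbed
    fragments (local 1-based numbering; the global offset lives in the
    Fragment range). ``zero_rotation`` keeps every fragment in place."""
    if plan.protein_length != len(model):
        raise ValueError(
            f"plan length {plan.protein_length} does not match model length {len(model)}"
        )
    rng = np.random.default_rng(seed)
    by_index = {r.index: r for r in model.residues}
    fragments = []
    for k, (start, end) in enumerate(plan.fragments):
        if zero_rotation:
            R = np.eye(3)
            t = np.zeros(3)
        else:
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(0.0, 20.0, 3)
        residues = []
        for g in range(start, end + 1):
            src = by_index[g]
            residues.append(
                ResidueModel(
                    index=g - start + 1,
                    aa=src.aa,
                    atoms=[
                        Atom(a.name, a.element, R @ a.coord + t) for a in src.atoms
                    ],
                    plddt=src.plddt,
                )
            )
        fragments.append(
            Fragment(
                label=f"F{k + 1}",
                start=start,
                end=end,
                model=StructureModel(
                    uniprot_id=model.uniprot_id,
                    residues=residues,
                    provenance=Provenance.PROTEOME_FRAGMENT,
                ),
            )
        )
    return fragments
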