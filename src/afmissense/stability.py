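"""Ingestion and sign harmonization of protein-stability (ΔΔG) predictions.

Five predictors are supported: mCSM, MAESTRO and CUPSAT (structure-based),
SAAFEC-SEQ and MUpro (sequence-based). All except MAESTRO natively report
negative ΔΔG as destabilizing; MAESTRO uses the opposite sign. Scores are
harmonized to a single convention -- by default positive = stabilizing,
negative = destabilizing -- by negating MAESTRO values and leaving the rest
unchanged. Downstream discrimination is rank-based, so no cross-predictor
rescaling is applied.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .variants import (
    ProteinChangeError,
    Significance,
    VariantRecord,
    parse_protein_change,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InputKind",
    "SignConvention",
    "PredictorSpec",
    "PREDICTORS",
    "DEFAULT_CONVENTION",
    "DdgPrediction",
    "SkippedRow",
    "DuplicatePredictionError",
    "load_ddg_table",
    "harmonize_sign",
    "join_scores_to_variants",
]


class InputKind(str, enum.Enum):
    STRUCTURE = "structure"
    SEQUENCE = "sequence"


class SignConvention(str, enum.Enum):
    """What a negative raw score means for the predictor."""

    NEGATIVE_DESTABILIZING = "negative_destabilizing"
    NEGATIVE_STABILIZING = "negative_stabilizing"


@dataclass(frozen=True)
class PredictorSpec:
    name: str
    input_kind: InputKind
    native_convention: SignConvention


PREDICTORS: dict[str, PredictorSpec] = {
    "mcsm": PredictorSpec("mcsm", InputKind.STRUCTURE, SignConvention.NEGATIVE_DESTABILIZING),
    "maestro": PredictorSpec("maestro", InputKind.STRUCTURE, SignConvention.NEGATIVE_STABILIZING),
    "cupsat": PredictorSpec("cupsat", InputKind.STRUCTURE, SignConvention.NEGATIVE_DESTABILIZING),
    "saafec": PredictorSpec("saafec", InputKind.SEQUENCE, SignConvention.NEGATIVE_DESTABILIZING),
    "mupro": PredictorSpec("mupro", InputKind.SEQUENCE, SignConvention.NEGATIVE_DESTABILIZING),
}

#: unified convention: positive scores are stabilizing, negative destabilizing
DEFAULT_CONVENTION = SignConvention.NEGATIVE_DESTABILIZING


def harmonize_sign(
    raw_value: float,
    predictor: str,
    unified: SignConvention = DEFAULT_CONVENTION,
) -> float:
    """Map a predictor's raw score onto the unified sign convention.

    Under the default (positive = stabilizing) convention MAESTRO values are
    negated and all other predictors' values pass through unchanged. The
    mapping is an involution for MAESTRO and the identity otherwise.
    """
    if predictor not in PREDICTORS:
        raise KeyError(f"unknown predictor {predictor!r}")
    native = PREDICTORS[predictor].native_convention
    return raw_value if native is unified else -raw_value


@dataclass(frozen=True)
class DdgPrediction:
    """One predictor's ΔΔG for one variant (kcal/mol-scale, predictor-native units)."""

    uniprot_id: str
    position: int
    wildtype_aa: str
    mutant_aa: str
    predictor: str
    raw_value: float
    harmonized_value: float

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.uniprot_id, self.position, self.wildtype_aa, self.mutant_aa)


@dataclass(frozen=True)
class SkippedRow:
    row: int
    reason: str


# Per-tool column aliases; predictor exports differ in naming only, so a
# single alias map per role suffices and can be overridden per call.
_VARIANT_COLUMNS = ("variant", "mutation", "substitution", "protein_change")
_VALUE_COLUMNS = ("ddg", "ddg_pred", "prediction", "score", "value")
_UNIPROT_COLUMNS = ("uniprot", "uniprot_id", "protein", "accession")


def _pick_column(df: pd.DataFrame, candidates: Sequence[str], role: str) -> str:
    lower = {c.lower(): c for c in df.columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    raise ValueError(f"no {role} column found; expected one of {candidates}")


def load_ddg_table(
    path: str | Path,
    predictor: str,
    column_map: Optional[Mapping[str, str]] = None,
    unified: SignConvention = DEFAULT_CONVENTION,
) -> tuple[list[DdgPrediction], list[SkippedRow]]:
    """Load one predictor's CSV/TSV export into harmonized predictions.

    Rows whose variant fails to parse or whose value is not numeric are
    returned in the skipped-row report, never silently dropped. Duplicate
    (variant, predictor) rows are both loaded and flagged for downstream
    deduplication.
    """
    if predictor not in PREDICTORS:
        raise KeyError(f"unknown predictor {predictor!r}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        var_col = column_map["variant"]
        val_col = column_map["ddg"]
        uni_col = column_map.get("uniprot")
    else:
        var_col = _pick_column(df, _VARIANT_COLUMNS, "variant")
        val_col = _pick_column(df, _VALUE_COLUMNS, "ddg value")
        try:
            uni_col = _pick_column(df, _UNIPROT_COLUMNS, "uniprot")
        except ValueError:
            uni_col = None

    predictions: list[DdgPrediction] = []
    skipped: list[SkippedRow] = []
    for i, row in df.iterrows():
        try:
            change = parse_protein_change(row[var_col])
        except ProteinChangeError as exc:
            skipped.append(SkippedRow(row=int(i), reason=f"variant: {exc}"))
            continue
        try:
            raw = float(row[val_col])
        except ValueError:
            skipped.append(
                SkippedRow(row=int(i), reason=f"non-numeric value {row[val_col]!r}")
            )
            continue
        predictions.append(
            DdgPrediction(
                uniprot_id=row[uni_col].strip() if uni_col else "",
                position=change.position,
                wildtype_aa=change.wildtype_aa,
                mutant_aa=change.mutant_aa,
                predictor=predictor,
                raw_value=raw,
                harmonized_value=harmonize_sign(raw, predictor, unified),
            )
        )
    dup_keys = pd.Series([p.key for p in predictions])
    n_dup = int(dup_keys.duplicated().sum())
    if n_dup:
        logger.warning("%s: %d duplicate variant rows flagged", path, n_dup)
    return predictions, skipped


class DuplicatePredictionError(ValueError):
    """Same (variant, predictor) with conflicting values."""


def join_scores_to_variants(
    catalog: Sequence[VariantRecord],
    scores: Mapping[str, Iterable[DdgPrediction]],
    structure_descriptors: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """One row per catalog variant with up to five harmonized ΔΔG columns.

    ``structure_descriptors``, when given, is a frame with columns
    (uniprot_id, position, plddt, rasa) joined on position. Missing scores
    stay missing (NaN); they are never imputed. Duplicate predictions for
    the same (variant, predictor) with different harmonized values raise
    :class:`DuplicatePredictionError`.
    """
    rows = []
    for rec in catalog:
        if rec.change is None:
            continue
        label = rec.clinical_significance.folded
        rows.append(
            {
                "uniprot_id": rec.uniprot_id,
                "position": rec.change.position,
                "wt": rec.change.wildtype_aa,
                "mut": rec.change.mutant_aa,
                "gene": rec.gene_symbol,
                "significance": rec.clinical_significance.value,
                "label": {"benign": 0, "pathogenic": 1}.get(label, np.nan),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("catalog contains no missense variants")

    for name in PREDICTORS:
        col = f"ddg_{name}"
        table[col] = np.nan
        for pred in scores.get(name, []):
            mask = (
                (table["uniprot_id"] == pred.uniprot_id)
                & (table["position"] == pred.position)
                & (table["wt"] == pred.wildtype_aa)
                & (table["mut"] == pred.mutant_aa)
            )
            if not mask.any():
                continue
            existing = table.loc[mask, col]
            clash = existing.notna() & ~np.isclose(
                existing.fillna(pred.harmonized_value), pred.harmonized_value
            )
            if clash.any():
                raise DuplicatePredictionError(
                    f"conflicting duplicate for {pred.key} / {name}: "
                    f"{existing[clash].tolist()} vs {pred.harmonized_value}"
                )
            table.loc[mask, col] = pred.harmonized_value

    if structure_descriptors is not None:
        desc = structure_descriptors.rename(columns={"index": "position"})
        keep = [c for c in ("uniprot_id", "position", "plddt", "rasa") if c in desc.columns]
        table = table.merge(desc[keep], on=[c for c in ("uniprot_id", "position") if c in keep], how="left")
    else:
        table["plddt"] = np.nan
        table["rasa"] = np.nan
    return table
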