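"""Curation of missense variant catalogs.

Parses protein-level variant notation, applies the curation filters used when
compiling clinically labeled missense variants from a ClinVar-style export and
an in-house cohort (review-star threshold, condition keywords, variant class,
label and allele-frequency filters), merges the two sources under a canonical
variant key, validates wild-type residues against UniProt sequences, and
summarizes the catalog.
"""

from __future__ import annotations

import enum
import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .aa import STANDARD_AA, to_one_letter

logger = logging.getLogger(__name__)

__all__ = [
    "Significance",
    "VariantClass",
    "Source",
    "ProteinChange",
    "VariantRecord",
    "FilterConfig",
    "CatalogSummary",
    "LabelConflict",
    "ProteinChangeError",
    "ProteinChangeFormatError",
    "SynonymousChangeError",
    "TruncatingChangeError",
    "CatalogIntegrityError",
    "parse_protein_change",
    "classify_change",
    "filter_records",
    "merge_catalogs",
    "validate_wildtype",
    "summarize_catalog",
    "map_review_status_to_stars",
    "read_variant_table",
    "write_variant_table",
    "read_fasta_sequences",
    "pct_int",
    "pct_1dp",
]


class Significance(str, enum.Enum):
    """Five-level clinical significance label plus the conflicting bucket."""

    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    CONFLICTING = "conflicting"

    @property
    def folded(self) -> Optional[str]:
        """Binary evaluation label: likely_* folds into its parent class."""
        if self in (Significance.BENIGN, Significance.LIKELY_BENIGN):
            return "benign"
        if self in (Significance.PATHOGENIC, Significance.LIKELY_PATHOGENIC):
            return "pathogenic"
        return None


class VariantClass(str, enum.Enum):
    MISSENSE = "missense"
    TRUNCATING = "truncating"
    OTHER = "other"


class Source(str, enum.Enum):
    CLINVAR = "clinvar"
    COHORT = "cohort"


class ProteinChangeError(ValueError):
    """Base error for unusable protein-change notation."""


class ProteinChangeFormatError(ProteinChangeError):
    """Text does not match any accepted missense notation."""


class SynonymousChangeError(ProteinChangeError):
    """Wild-type and mutant residue are identical."""


class TruncatingChangeError(ProteinChangeError):
    """Stop-gain or frameshift notation: a truncating change, not missense."""


@dataclass(frozen=True)
class ProteinChange:
    """A single amino-acid substitution in UniProt coordinates (1-based)."""

    wildtype_aa: str
    position: int
    mutant_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ProteinChangeError(f"position must be >= 1, got {self.position}")
        for aa in (self.wildtype_aa, self.mutant_aa):
            if aa not in STANDARD_AA:
                raise ProteinChangeError(f"non-standard amino acid {aa!r}")
        if self.wildtype_aa == self.mutant_aa:
            raise SynonymousChangeError(
                f"synonymous change {self.wildtype_aa}{self.position}{self.mutant_aa}"
            )

    def __str__(self) -> str:
        return f"{self.wildtype_aa}{self.position}{self.mutant_aa}"


_CHANGE_RE = re.compile(
    r"^(?:p\.)?\(?([A-Za-z]{1,3})(\d+)([A-Za-z*]{1,3}|\*)\)?$"
)
_TRUNCATING_RE = re.compile(
    r"^(?:p\.)?\(?([A-Za-z]{1,3})(\d+)(\*|Ter|X|ter|(?:[A-Za-z]{0,3})?fs.*)\)?$"
)


def parse_protein_change(text: str) -> ProteinChange:
    """Parse compact (``H101Q``) or HGVS-protein (``p.His101Gln``) notation.

    One- and three-letter residue codes yield identical results. Synonymous
    changes raise :class:`SynonymousChangeError`; stop-gain / frameshift
    notation raises :class:`TruncatingChangeError` (it is a truncating
    variant, not a substitution); anything else raises
    :class:`ProteinChangeFormatError`.
    """
    text = text.strip()
    if not text:
        raise ProteinChangeFormatError("empty protein change")
    if _TRUNCATING_RE.match(text):
        raise TruncatingChangeError(f"truncating notation: {text!r}")
    m = _CHANGE_RE.match(text)
    if m is None:
        raise ProteinChangeFormatError(f"unparseable protein change: {text!r}")
    wt_raw, pos_raw, mut_raw = m.groups()
    try:
        wt = to_one_letter(wt_raw)
        mut = to_one_letter(mut_raw)
    except KeyError as exc:
        raise ProteinChangeFormatError(f"{text!r}: {exc}") from exc
    return ProteinChange(wildtype_aa=wt, position=int(pos_raw), mutant_aa=mut)


def classify_change(text: str) -> VariantClass:
    """Classify raw protein-change text into missense / truncating / other."""
    try:
        parse_protein_change(text)
    except TruncatingChangeError:
        return VariantClass.TRUNCATING
    except ProteinChangeError:
        return VariantClass.OTHER
    return VariantClass.MISSENSE


@dataclass(frozen=True)
class VariantRecord:
    """One curated variant with its clinical label and provenance."""

    gene_symbol: str
    uniprot_id: str
    change: Optional[ProteinChange]
    clinical_significance: Significance
    review_stars: Optional[int]
    condition_text: str
    source: Source
    variant_class: VariantClass
    change_text: str = ""
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.review_stars is not None and not 0 <= self.review_stars <= 4:
            raise ValueError(f"review_stars must be in [0, 4], got {self.review_stars}")
        if self.variant_class is VariantClass.MISSENSE and self.change is None:
            raise ValueError("missense record requires a ProteinChange")

    @property
    def key(self) -> Optional[tuple[str, int, str, str]]:
        """Deduplication key (uniprot, position, wildtype, mutant); None for non-missense."""
        if self.change is None:
            return None
        c = self.change
        return (self.uniprot_id, c.position, c.wildtype_aa, c.mutant_aa)


@dataclass(frozen=True)
class FilterConfig:
    """Curation filter settings.

    Defaults mirror the compilation rules of the hereditary-cancer screen:
    at least two ClinVar review stars, a cancer/tumor condition keyword,
    missense class only, unknown/conflicting labels dropped, and a gnomAD
    minor-allele-frequency ceiling of 1%.
    """

    min_stars: int = 2
    condition_keywords: tuple[str, ...] = ("cancer", "tumor", "tumour")
    keep_classes: frozenset[VariantClass] = frozenset({VariantClass.MISSENSE})
    drop_labels: frozenset[Significance] = frozenset(
        {Significance.VUS, Significance.CONFLICTING}
    )
    max_maf: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.max_maf <= 1:
            raise ValueError(f"max_maf must be in (0, 1], got {self.max_maf}")
        if not self.condition_keywords:
            raise ValueError("condition_keywords must be non-empty")
        object.__setattr__(
            self,
            "condition_keywords",
            tuple(k.lower() for k in self.condition_keywords),
        )


def filter_records(
    records: Sequence[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> list[VariantRecord]:
    """Apply all curation filters; order is preserved, input is untouched.

    The review-star threshold applies only to ClinVar records (cohort
    variants have no ClinVar review status); a ClinVar record with unknown
    stars counts as 0 stars. A record with no allele frequency is treated as
    rare and kept.
    """
    kept: list[VariantRecord] = []
    for rec in records:
        if rec.source is Source.CLINVAR:
            stars = rec.review_stars if rec.review_stars is not None else 0
            if stars < cfg.min_stars:
                continue
        cond = rec.condition_text.lower()
        if not any(kw in cond for kw in cfg.condition_keywords):
            continue
        if rec.variant_class not in cfg.keep_classes:
            continue
        if rec.clinical_significance in cfg.drop_labels:
            continue
        if rec.maf is not None and rec.maf >= cfg.max_maf:
            continue
        if rec.maf is None:
            logger.debug("no MAF for %s %s: treated as rare", rec.gene_symbol, rec.change_text)
        kept.append(rec)
    return kept


class CatalogIntegrityError(ValueError):
    """Two records claim different wild-type residues at the same position."""


@dataclass(frozen=True)
class LabelConflict:
    key: tuple[str, int, str, str]
    clinvar_label: Significance
    cohort_label: Significance


def merge_catalogs(
    clinvar: Sequence[VariantRecord], cohort: Sequence[VariantRecord]
) -> tuple[list[VariantRecord], list[LabelConflict]]:
    """Merge ClinVar and cohort variants under the canonical key.

    Duplicates collapse to a single record keeping the ClinVar label; a label
    disagreement between the two sources is reported in the conflicts list,
    never silently resolved. Two records asserting different wild-type
    residues at the same (uniprot, position) raise
    :class:`CatalogIntegrityError`.
    """
    wt_seen: dict[tuple[str, int], str] = {}
    for rec in list(clinvar) + list(cohort):
        if rec.change is None:
            continue
        pos_key = (rec.uniprot_id, rec.change.position)
        prev = wt_seen.setdefault(pos_key, rec.change.wildtype_aa)
        if prev != rec.change.wildtype_aa:
            raise CatalogIntegrityError(
                f"wild-type disagreement at {pos_key}: {prev} vs {rec.change.wildtype_aa}"
            )

    merged: dict[tuple, VariantRecord] = {}
    order: list[tuple] = []
    conflicts: list[LabelConflict] = []
    for rec in clinvar:
        k = rec.key if rec.key is not None else ("__nonmissense__", id(rec))
        if k not in merged:
            merged[k] = rec
            order.append(k)
    for rec in cohort:
        k = rec.key if rec.key is not None else ("__nonmissense__", id(rec))
        if k not in merged:
            merged[k] = rec
            order.append(k)
        else:
            existing = merged[k]
            if (
                existing.source is Source.CLINVAR
                and existing.clinical_significance != rec.clinical_significance
            ):
                conflicts.append(
                    LabelConflict(
                        key=k,  # type: ignore[arg-type]
                        clinvar_label=existing.clinical_significance,
                        cohort_label=rec.clinical_significance,
                    )
                )
    return [merged[k] for k in order], conflicts


def validate_wildtype(record: VariantRecord, sequence: str) -> bool:
    """Check the recorded wild-type residue against the UniProt sequence.

    True iff the 1-based position is inside the sequence and the residue at
    that position matches the recorded wild type. Mismatches are logged so
    the exclusion reason is auditable.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if record.change is None:
        raise ValueError("cannot validate a record without a ProteinChange")
    pos = record.change.position
    if pos > len(sequence):
        logger.info(
            "%s %s: position %d beyond sequence length %d",
            record.uniprot_id, record.change, pos, len(sequence),
        )
        return False
    ok = sequence[pos - 1].upper() == record.change.wildtype_aa
    if not ok:
        logger.info(
            "%s %s: sequence has %s at position %d",
            record.uniprot_id, record.change, sequence[pos - 1], pos,
        )
    return ok


def pct_int(part: int, whole: int) -> int:
    """Integer percentage, rounding half away from zero; 0 when whole == 0."""
    if whole == 0:
        return 0
    x = 100.0 * part / whole
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def pct_1dp(part: int, whole: int) -> float:
    """One-decimal percentage, rounding half away from zero; 0.0 when whole == 0."""
    if whole == 0:
        return 0.0
    x = 1000.0 * part / whole
    scaled = int(x + 0.5) if x >= 0 else -int(-x + 0.5)
    return scaled / 10.0


@dataclass(frozen=True)
class CatalogSummary:
    """Counts over the unique-key variant set with derived percentages."""

    n_total: int
    n_unique: int
    n_missense: int
    n_truncating: int
    n_other: int
    n_benign: int
    n_pathogenic: int
    n_vus: int
    whole_zero: bool = False

    @property
    def n_known_label(self) -> int:
        return self.n_benign + self.n_pathogenic

    @property
    def missense_pct(self) -> int:
        return pct_int(self.n_missense, self.n_unique)

    @property
    def missense_pct_1dp(self) -> float:
        return pct_1dp(self.n_missense, self.n_unique)

    @property
    def truncating_pct(self) -> int:
        return pct_int(self.n_truncating, self.n_unique)

    @property
    def known_label_pct(self) -> int:
        """Share of missense variants carrying a benign or pathogenic label."""
        return pct_int(self.n_known_label, self.n_missense)

    @property
    def known_label_pct_1dp(self) -> float:
        return pct_1dp(self.n_known_label, self.n_missense)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_unique": self.n_unique,
            "n_missense": self.n_missense,
            "n_truncating": self.n_truncating,
            "n_other": self.n_other,
            "n_benign": self.n_benign,
            "n_pathogenic": self.n_pathogenic,
            "n_vus": self.n_vus,
            "whole_zero": self.whole_zero,
            "missense_pct": self.missense_pct,
            "missense_pct_1dp": self.missense_pct_1dp,
            "truncating_pct": self.truncating_pct,
            "known_label_pct": self.known_label_pct,
            "known_label_pct_1dp": self.known_label_pct_1dp,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def summarize_catalog(records: Sequence[VariantRecord]) -> CatalogSummary:
    """Count classes and labels over the unique-key set.

    Non-missense records (no canonical key) are deduplicated on
    (uniprot, change_text). Benign/pathogenic counts fold likely_* labels
    into their parent class.
    """
    unique: dict[tuple, VariantRecord] = {}
    for rec in records:
        k = rec.key if rec.key is not None else (rec.uniprot_id, rec.change_text, rec.variant_class)
        unique.setdefault(k, rec)
    uniq = list(unique.values())
    n_missense = sum(r.variant_class is VariantClass.MISSENSE for r in uniq)
    n_truncating = sum(r.variant_class is VariantClass.TRUNCATING for r in uniq)
    n_other = sum(r.variant_class is VariantClass.OTHER for r in uniq)
    n_benign = sum(r.clinical_significance.folded == "benign" for r in uniq)
    n_pathogenic = sum(r.clinical_significance.folded == "pathogenic" for r in uniq)
    n_vus = sum(r.clinical_significance is Significance.VUS for r in uniq)
    return CatalogSummary(
        n_total=len(records),
        n_unique=len(uniq),
        n_missense=n_missense,
        n_truncating=n_truncating,
        n_other=n_other,
        n_benign=n_benign,
        n_pathogenic=n_pathogenic,
        n_vus=n_vus,
        whole_zero=len(uniq) == 0,
    )


# ClinVar review-status strings -> gold stars (documented ClinVar scheme);
# unknown strings conservatively map to 0 stars.
_REVIEW_STATUS_STARS = {
    "practice guideline": 4,
    "reviewed by expert panel": 3,
    "criteria provided, multiple submitters, no conflicts": 2,
    "criteria provided, conflicting interpretations": 1,
    "criteria provided, conflicting classifications": 1,
    "criteria provided, single submitter": 1,
    "no assertion criteria provided": 0,
    "no classification provided": 0,
    "no assertion provided": 0,
}


def map_review_status_to_stars(status: str) -> int:
    return _REVIEW_STATUS_STARS.get(status.strip().lower(), 0)


_SIGNIFICANCE_ALIASES = {
    "benign": Significance.BENIGN,
    "likely benign": Significance.LIKELY_BENIGN,
    "likely_benign": Significance.LIKELY_BENIGN,
    "pathogenic": Significance.PATHOGENIC,
    "likely pathogenic": Significance.LIKELY_PATHOGENIC,
    "likely_pathogenic": Significance.LIKELY_PATHOGENIC,
    "uncertain significance": Significance.VUS,
    "vus": Significance.VUS,
    "conflicting": Significance.CONFLICTING,
    "conflicting interpretations of pathogenicity": Significance.CONFLICTING,
}


def parse_significance(text: str) -> Significance:
    key = text.strip().lower()
    if key not in _SIGNIFICANCE_ALIASES:
        raise ValueError(f"unknown clinical significance {text!r}")
    return _SIGNIFICANCE_ALIASES[key]


_TABLE_COLUMNS = [
    "gene", "uniprot", "protein_change", "significance", "stars",
    "condition", "source", "maf",
]


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a tab-separated variant table (header: gene, uniprot,
    protein_change, significance, stars, condition, source, maf)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    records: list[VariantRecord] = []
    for _, row in df.iterrows():
        change_text = row["protein_change"].strip()
        vclass = classify_change(change_text)
        change = (
            parse_protein_change(change_text)
            if vclass is VariantClass.MISSENSE
            else None
        )
        stars_raw = str(row.get("stars", "")).strip()
        if stars_raw == "":
            stars: Optional[int] = None
        elif stars_raw.isdigit():
            stars = int(stars_raw)
        else:
            stars = map_review_status_to_stars(stars_raw)
        maf_raw = str(row.get("maf", "")).strip()
        maf = float(maf_raw) if maf_raw else None
        records.append(
            VariantRecord(
                gene_symbol=row["gene"].strip(),
                uniprot_id=row["uniprot"].strip(),
                change=change,
                clinical_significance=parse_significance(row["significance"]),
                review_stars=stars,
                condition_text=row["condition"],
                source=Source(row["source"].strip().lower()),
                variant_class=vclass,
                change_text=change_text,
                maf=maf,
            )
        )
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as the tab-separated dialect read by read_variant_table."""
    rows = []
    for rec in records:
        rows.append(
            {
                "gene": rec.gene_symbol,
                "uniprot": rec.uniprot_id,
                "protein_change": rec.change_text or str(rec.change),
                "significance": rec.clinical_significance.value,
                "stars": "" if rec.review_stars is None else rec.review_stars,
                "condition": rec.condition_text,
                "source": rec.source.value,
                "maf": "" if rec.maf is None else repr(rec.maf),
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read FASTA into {accession: sequence}; UniProt-style ``sp|ACC|NAME``
    headers are reduced to the accession."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        if "|" in ident:
            parts = ident.split("|")
            if len(parts) >= 2 and parts[1]:
                ident = parts[1]
        seqs[ident] = str(rec.seq).upper()
    return seqs
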