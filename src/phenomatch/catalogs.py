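"""Tabular study inputs: mouse models, diseases, orthologs, external models.

All catalogues are plain TSV with a header row; ontology-term lists are
semicolon-delimited within a single column.  Readers validate enum labels,
term-id shape (``HP:NNNNNNN`` / ``MP:NNNNNNN``) and counts, and report the
offending 1-based file row on failure.  Records with empty term sets are
legal — they are simply ineligible for scoring downstream.

The ortholog table mirrors the shape of orthology-service exports
(``human_gene_symbol``, ``mouse_gene_symbol``, ``support_count`` = number of
agreeing prediction services, 0-12).  :func:`one_to_one_orthologs` applies
the support threshold (default >= 5 of 12) *before* the bijectivity
constraint, then keeps only pairs that are one-to-one in both directions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ModelRecord",
    "DiseaseRecord",
    "OrthologRecord",
    "ExternalModelRecord",
    "ValidationError",
    "read_models",
    "read_diseases",
    "read_orthologs",
    "read_external",
    "one_to_one_orthologs",
    "models_to_frame",
    "diseases_to_frame",
    "orthologs_to_frame",
    "external_to_frame",
]

TERM_ID_RE = re.compile(r"^(HP|MP):\d{7}$")

ZYGOSITIES = ("homozygous", "heterozygous", "hemizygous")
LIFE_STAGES = ("embryo", "early_adult")
VIABILITIES = ("lethal", "subviable", "viable", "unknown")
MOIS = ("AD", "AR", "AD&AR", "other")
EARLY_DEATH = ("none", "pre_infant", "childhood")
EVIDENCE = ("green", "amber", "red")

MODEL_COLUMNS = [
    "model_id", "mouse_gene", "zygosity", "life_stage", "viability",
    "mp_terms", "n_procedures", "preweaning_lethal",
]
DISEASE_COLUMNS = [
    "disease_id", "human_gene", "hpo_terms", "moi", "category",
    "early_death", "evidence",
]
ORTHOLOG_COLUMNS = ["human_gene_symbol", "mouse_gene_symbol", "support_count"]
EXTERNAL_COLUMNS = ["model_id", "mouse_gene", "mp_terms"]


class ValidationError(ValueError):
    """A catalogue row violates the documented schema."""


@dataclass(frozen=True)
class ModelRecord:
    """One mouse mutant line with its significant MP annotations."""

    model_id: str
    mouse_gene: str
    zygosity: str
    life_stage: str
    viability: str
    mp_terms: frozenset[str]
    n_procedures: int
    preweaning_lethal: bool

    @property
    def eligible(self) -> bool:
        return bool(self.mp_terms)


@dataclass(frozen=True)
class DiseaseRecord:
    """One Mendelian disorder with its HPO annotations and metadata."""

    disease_id: str
    human_gene: str
    hpo_terms: frozenset[str]
    moi: str
    category: str
    early_death: str
    evidence: str

    @property
    def eligible(self) -> bool:
        return bool(self.hpo_terms)


@dataclass(frozen=True)
class OrthologRecord:
    human_gene: str
    mouse_gene: str
    support: int


@dataclass(frozen=True)
class ExternalModelRecord:
    """A model from an external (MGI-style) catalogue: gene -> MP term set."""

    model_id: str
    mouse_gene: str
    mp_terms: frozenset[str]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _read_table(source, columns: Sequence[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table is missing column(s) {missing}")
    return df


def _parse_terms(cell: str, row: int, what: str) -> frozenset[str]:
    terms = [t.strip() for t in cell.split(";") if t.strip()]
    for t in terms:
        if not TERM_ID_RE.match(t):
            raise ValidationError(f"{what} row {row}: malformed term id {t!r}")
    return frozenset(terms)


def _check_enum(value: str, allowed: Sequence[str], row: int, col: str, what: str) -> str:
    if value not in allowed:
        raise ValidationError(
            f"{what} row {row}: {col} {value!r} is not one of {tuple(allowed)}"
        )
    return value


def _parse_bool(value: str, row: int, col: str, what: str) -> bool:
    low = value.strip().lower()
    if low in ("true", "1"):
        return True
    if low in ("false", "0"):
        return False
    raise ValidationError(f"{what} row {row}: {col} {value!r} is not a boolean")


def read_models(source: str | Path) -> list[ModelRecord]:
    """Read the mouse-model catalogue (see :data:`MODEL_COLUMNS`)."""
    df = _read_table(source, MODEL_COLUMNS, "models")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            n_proc = int(row.n_procedures)
        except ValueError:
            raise ValidationError(
                f"models row {i}: n_procedures {row.n_procedures!r} is not an integer"
            ) from None
        if n_proc < 0:
            raise ValidationError(f"models row {i}: n_procedures is negative")
        rec = ModelRecord(
            model_id=row.model_id,
            mouse_gene=row.mouse_gene,
            zygosity=_check_enum(row.zygosity, ZYGOSITIES, i, "zygosity", "models"),
            life_stage=_check_enum(row.life_stage, LIFE_STAGES, i, "life_stage", "models"),
            viability=_check_enum(row.viability, VIABILITIES, i, "viability", "models"),
            mp_terms=_parse_terms(row.mp_terms, i, "models"),
            n_procedures=n_proc,
            preweaning_lethal=_parse_bool(
                row.preweaning_lethal, i, "preweaning_lethal", "models"
            ),
        )
        if rec.viability == "lethal" and not rec.preweaning_lethal:
            raise ValidationError(
                f"models row {i}: viability 'lethal' requires preweaning_lethal true"
            )
        records.append(rec)
    return records


def read_diseases(source: str | Path) -> list[DiseaseRecord]:
    """Read the disease catalogue (see :data:`DISEASE_COLUMNS`)."""
    df = _read_table(source, DISEASE_COLUMNS, "diseases")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        records.append(
            DiseaseRecord(
                disease_id=row.disease_id,
                human_gene=row.human_gene,
                hpo_terms=_parse_terms(row.hpo_terms, i, "diseases"),
                moi=_check_enum(row.moi, MOIS, i, "moi", "diseases"),
                category=row.category,
                early_death=_check_enum(
                    row.early_death, EARLY_DEATH, i, "early_death", "diseases"
                ),
                evidence=_check_enum(row.evidence, EVIDENCE, i, "evidence", "diseases"),
            )
        )
    return records


def read_orthologs(source: str | Path) -> list[OrthologRecord]:
    """Read the ortholog-prediction table (see :data:`ORTHOLOG_COLUMNS`)."""
    df = _read_table(source, ORTHOLOG_COLUMNS, "orthologs")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            support = int(row.support_count)
        except ValueError:
            raise ValidationError(
                f"orthologs row {i}: support_count {row.support_count!r} "
                "is not an integer"
            ) from None
        if not 0 <= support <= 12:
            raise ValidationError(
                f"orthologs row {i}: support_count {support} outside 0..12"
            )
        records.append(
            OrthologRecord(
                human_gene=row.human_gene_symbol,
                mouse_gene=row.mouse_gene_symbol,
                support=support,
            )
        )
    return records


def read_external(source: str | Path) -> list[ExternalModelRecord]:
    """Read the external (MGI-style) model catalogue."""
    df = _read_table(source, EXTERNAL_COLUMNS, "external")
    return [
        ExternalModelRecord(
            model_id=row.model_id,
            mouse_gene=row.mouse_gene,
            mp_terms=_parse_terms(row.mp_terms, i, "external"),
        )
        for i, row in enumerate(df.itertuples(index=False), start=2)
    ]


# ---------------------------------------------------------------------------
# ortholog filter
# ---------------------------------------------------------------------------

def one_to_one_orthologs(
    records: Iterable[OrthologRecord], min_support: int = 5
) -> dict[str, str]:
    """One-to-one human-mouse ortholog map.

    Records below ``min_support`` agreeing prediction services are dropped
    first; among the survivors only pairs where the human gene maps to
    exactly one mouse gene *and* that mouse gene maps back to exactly one
    human gene are kept.  The result is a bijection (human -> mouse) on its
    domain; duplicated identical pairs do not veto themselves.
    """
    pairs = {(r.human_gene, r.mouse_gene) for r in records if r.support >= min_support}
    human_to: dict[str, set[str]] = {}
    mouse_to: dict[str, set[str]] = {}
    for h, m in pairs:
        human_to.setdefault(h, set()).add(m)
        mouse_to.setdefault(m, set()).add(h)
    return {
        h: next(iter(ms))
        for h, ms in human_to.items()
        if len(ms) == 1 and len(mouse_to[next(iter(ms))]) == 1
    }


# ---------------------------------------------------------------------------
# writing (used by the synthetic generator and pipeline outputs)
# ---------------------------------------------------------------------------

def _terms_cell(terms: Iterable[str]) -> str:
    return ";".join(sorted(terms))


def models_to_frame(records: Iterable[ModelRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model_id": r.model_id,
                "mouse_gene": r.mouse_gene,
                "zygosity": r.zygosity,
                "life_stage": r.life_stage,
                "viability": r.viability,
                "mp_terms": _terms_cell(r.mp_terms),
                "n_procedures": r.n_procedures,
                "preweaning_lethal": str(r.preweaning_lethal).lower(),
            }
            for r in records
        ],
        columns=MODEL_COLUMNS,
    )


def diseases_to_frame(records: Iterable[DiseaseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "disease_id": r.disease_id,
                "human_gene": r.human_gene,
                "hpo_terms": _terms_cell(r.hpo_terms),
                "moi": r.moi,
                "category": r.category,
                "early_death": r.early_death,
                "evidence": r.evidence,
            }
            for r in records
        ],
        columns=DISEASE_COLUMNS,
    )


def orthologs_to_frame(records: Iterable[OrthologRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "human_gene_symbol": r.human_gene,
                "mouse_gene_symbol": r.mouse_gene,
                "support_count": r.support,
            }
            for r in records
        ],
        columns=ORTHOLOG_COLUMNS,
    )


def external_to_frame(records: Iterable[ExternalModelRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model_id": r.model_id,
                "mouse_gene": r.mouse_gene,
                "mp_terms": _terms_cell(r.mp_terms),
            }
            for r in records
        ],
        columns=EXTERNAL_COLUMNS,
    )
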