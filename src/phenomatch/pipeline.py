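"""End-to-end disease-model identification pipeline.

Joins the catalogues through the one-to-one ortholog map, scores every
eligible (mouse model, disease) pair with the PhenoDigm percentage score,
calls matches (strictly > 0), aggregates to gene level, flags genes that are
novel relative to an external model catalogue, and applies the
lethality-based rescue rule (mouse preweaning lethality paired with curated
early-death reports in the human disorder can rescue a gene that obtained no
phenotype match).

Eligibility: a pair is scored when the model's mouse gene maps one-to-one to
the disease's human gene *and* both the model's MP set and the disease's HPO
set are non-empty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalogs import (
    DiseaseRecord,
    ExternalModelRecord,
    ModelRecord,
    OrthologRecord,
    one_to_one_orthologs,
)
from .ontology import ICTable, Ontology, information_content
from .similarity import PhenodigmScorer, ScoreResult

__all__ = [
    "GeneResult",
    "StudyResult",
    "eligible_pairs",
    "call_match",
    "score_pairs",
    "aggregate_gene",
    "novel_vs_external",
    "lethality_rescue",
    "build_ic_corpus",
    "build_pair_table",
    "run_study",
]


@dataclass
class GeneResult:
    """Best model-disease comparison for one orthologous gene pair."""

    human_gene: str
    mouse_gene: str
    best_percentage: float
    best_model_id: str
    best_disease_id: str
    is_match: bool
    rescue: str = "none"           # none | pre_infant | childhood
    novel_vs_external: bool = False
    n_models_scored: int = 0
    n_diseases_scored: int = 0


def eligible_pairs(
    models: Sequence[ModelRecord],
    diseases: Sequence[DiseaseRecord],
    ortholog_map: Mapping[str, str],
) -> list[tuple[ModelRecord, DiseaseRecord]]:
    """All scoreable (model, disease) pairs under the ortholog bijection.

    Requires MP-encoded phenotypes on the model and HPO-encoded phenotypes
    on the disease; genes outside the one-to-one map are skipped.
    """
    mouse_to_human = {m: h for h, m in ortholog_map.items()}
    by_human: dict[str, list[DiseaseRecord]] = {}
    for d in diseases:
        if d.eligible:
            by_human.setdefault(d.human_gene, []).append(d)
    pairs: list[tuple[ModelRecord, DiseaseRecord]] = []
    for model in models:
        if not model.eligible:
            continue
        human = mouse_to_human.get(model.mouse_gene)
        if human is None:
            continue
        for disease in by_human.get(human, ()):
            pairs.append((model, disease))
    return pairs


def call_match(score: ScoreResult) -> bool:
    """A pair is a phenotype match iff its percentage score exceeds 0 (strict)."""
    return score.percentage > 0.0


def score_pairs(
    scorer: PhenodigmScorer,
    pairs: Iterable[tuple[ModelRecord, DiseaseRecord]],
) -> list[ScoreResult]:
    return [
        scorer.score(
            disease.hpo_terms,
            model.mp_terms,
            model_id=model.model_id,
            disease_id=disease.disease_id,
        )
        for model, disease in pairs
    ]


def aggregate_gene(
    scores: Sequence[ScoreResult],
    models: Sequence[ModelRecord],
    diseases: Sequence[DiseaseRecord],
    ortholog_map: Mapping[str, str],
) -> list[GeneResult]:
    """Collapse pair scores to one row per gene: the best pair wins.

    Ties on the maximum percentage are broken towards the lexicographically
    smallest (model_id, disease_id) pair for determinism.
    """
    disease_gene = {d.disease_id: d.human_gene for d in diseases}
    by_gene: dict[str, list[ScoreResult]] = {}
    for s in scores:
        by_gene.setdefault(disease_gene[s.disease_id], []).append(s)
    out: list[GeneResult] = []
    for human in sorted(by_gene):
        gene_scores = by_gene[human]
        best = min(
            gene_scores, key=lambda s: (-s.percentage, s.model_id, s.disease_id)
        )
        out.append(
            GeneResult(
                human_gene=human,
                mouse_gene=ortholog_map[human],
                best_percentage=best.percentage,
                best_model_id=best.model_id,
                best_disease_id=best.disease_id,
                is_match=call_match(best),
                n_models_scored=len({s.model_id for s in gene_scores}),
                n_diseases_scored=len({s.disease_id for s in gene_scores}),
            )
        )
    return out


def novel_vs_external(
    gene_results: Sequence[GeneResult],
    external_scores: Mapping[str, float],
) -> set[str]:
    """Genes whose match is novel relative to an external model catalogue.

    A matched gene is novel when the external catalogue has no model for it
    at all, or when no external model achieves a positive score against the
    same disorders.  Sets the ``novel_vs_external`` flag in place and returns
    the set of novel human genes.
    """
    novel: set[str] = set()
    for gr in gene_results:
        gr.novel_vs_external = gr.is_match and (
            external_scores.get(gr.human_gene, 0.0) <= 0.0
        )
        if gr.novel_vs_external:
            novel.add(gr.human_gene)
    return novel


def lethality_rescue(
    gene_results: Sequence[GeneResult],
    models: Sequence[ModelRecord],
    diseases: Sequence[DiseaseRecord],
    *,
    include_childhood: bool = False,
) -> list[GeneResult]:
    """Rescue non-matched genes through lethality concordance.

    A gene with no phenotype match is rescued when any of its mouse models
    shows preweaning lethality and the associated disorder carries a curated
    early-death report: ``pre_infant`` always rescues; ``childhood`` rescues
    only when ``include_childhood`` is set.  Matched genes are never
    relabelled, so the rescued set is additive to the PhenoDigm matches.
    """
    lethal_mouse = {m.mouse_gene for m in models if m.preweaning_lethal}
    death_by_gene: dict[str, set[str]] = {}
    for d in diseases:
        if d.early_death != "none":
            death_by_gene.setdefault(d.human_gene, set()).add(d.early_death)
    for gr in gene_results:
        gr.rescue = "none"
        if gr.is_match or gr.mouse_gene not in lethal_mouse:
            continue
        deaths = death_by_gene.get(gr.human_gene, set())
        if "pre_infant" in deaths:
            gr.rescue = "pre_infant"
        elif include_childhood and "childhood" in deaths:
            gr.rescue = "childhood"
    return list(gene_results)


# ---------------------------------------------------------------------------
# study orchestration
# ---------------------------------------------------------------------------

def build_ic_corpus(
    models: Sequence[ModelRecord],
    diseases: Sequence[DiseaseRecord],
    external: Sequence[ExternalModelRecord] = (),
) -> list[tuple[str, frozenset[str]]]:
    """Default IC corpus: every annotated disease and model is one entity."""
    corpus: list[tuple[str, frozenset[str]]] = []
    corpus.extend((d.disease_id, d.hpo_terms) for d in diseases if d.hpo_terms)
    corpus.extend((m.model_id, m.mp_terms) for m in models if m.mp_terms)
    corpus.extend((e.model_id, e.mp_terms) for e in external if e.mp_terms)
    return corpus


def build_pair_table(
    scores: Sequence[ScoreResult],
    models: Sequence[ModelRecord],
    diseases: Sequence[DiseaseRecord],
) -> pd.DataFrame:
    """Model-disease pair table with the features used by the statistical layer.

    ``homozygous`` pools hemizygous with homozygous models; ``early_death``
    is an indicator for any curated early-death report (pre-infant or
    childhood) on the disorder.
    """
    model_by_id = {m.model_id: m for m in models}
    disease_by_id = {d.disease_id: d for d in diseases}
    rows = []
    for s in scores:
        m = model_by_id[s.model_id]
        d = disease_by_id[s.disease_id]
        rows.append(
            {
                "model_id": s.model_id,
                "disease_id": s.disease_id,
                "human_gene": d.human_gene,
                "mouse_gene": m.mouse_gene,
                "percentage": s.percentage,
                "is_match": int(call_match(s)),
                "n_procedures": m.n_procedures,
                "n_mp_terms": len(m.mp_terms),
                "n_hpo_terms": len(d.hpo_terms),
                "zygosity": m.zygosity,
                "homozygous": int(m.zygosity in ("homozygous", "hemizygous")),
                "viability": m.viability,
                "life_stage": m.life_stage,
                "category": d.category,
                "early_death": int(d.early_death != "none"),
                "moi": d.moi,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """Everything the pipeline produces for one study."""

    scores: list[ScoreResult]
    gene_results: list[GeneResult]
    pair_table: pd.DataFrame
    external_scores: dict[str, float]
    summary: dict = field(default_factory=dict)

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(g) for g in self.gene_results])

    def pair_frame(self) -> pd.DataFrame:
        cols = [
            "model_id", "disease_id", "human_gene", "mouse_gene",
            "raw_max", "raw_mean", "percentage",
        ]
        df = self.pair_table[["model_id", "disease_id", "human_gene", "mouse_gene"]].copy()
        df["raw_max"] = [s.raw_max for s in self.scores]
        df["raw_mean"] = [s.raw_mean for s in self.scores]
        df["percentage"] = [round(s.percentage, 2) for s in self.scores]
        return df[cols]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pair_frame().to_csv(
            outdir / "pair_scores.tsv", sep="\t", index=False, float_format="%.6f"
        )
        gene = self.gene_frame()
        gene["best_percentage"] = gene["best_percentage"].round(2)
        gene.to_csv(
            outdir / "gene_results.tsv", sep="\t", index=False, float_format="%.6f"
        )
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_study(
    ont: Ontology,
    models: Sequence[ModelRecord],
    diseases: Sequence[DiseaseRecord],
    orthologs: Sequence[OrthologRecord],
    external: Sequence[ExternalModelRecord] = (),
    *,
    min_support: int = 5,
    include_childhood: bool = False,
    form: str = "geometric",
    bidirectional: bool = False,
    ic_corpus: Sequence[tuple[str, frozenset[str]]] | None = None,
) -> StudyResult:
    """Run the full pipeline and return a :class:`StudyResult`.

    The IC corpus defaults to the union of all annotated diseases and models
    (internal and external) supplied to the pipeline.
    """
    ortholog_map = one_to_one_orthologs(orthologs, min_support=min_support)
    corpus = ic_corpus if ic_corpus is not None else build_ic_corpus(
        models, diseases, external
    )
    ic = information_content(ont, corpus)
    scorer = PhenodigmScorer(ont, ic, form=form, bidirectional=bidirectional)

    pairs = eligible_pairs(models, diseases, ortholog_map)
    scores = score_pairs(scorer, pairs)
    gene_results = aggregate_gene(scores, models, diseases, ortholog_map)

    # external catalogue: per-gene best percentage against the same disorders
    external_scores: dict[str, float] = {}
    if external:
        ext_models = [
            ModelRecord(
                model_id=e.model_id,
                mouse_gene=e.mouse_gene,
                zygosity="homozygous",
                life_stage="early_adult",
                viability="unknown",
                mp_terms=e.mp_terms,
                n_procedures=0,
                preweaning_lethal=False,
            )
            for e in external
        ]
        mouse_to_human = {m: h for h, m in ortholog_map.items()}
        for e in external:
            human = mouse_to_human.get(e.mouse_gene)
            if human is not None:
                external_scores.setdefault(human, 0.0)
        for model, disease in eligible_pairs(ext_models, diseases, ortholog_map):
            s = scorer.score(disease.hpo_terms, model.mp_terms)
            human = mouse_to_human[model.mouse_gene]
            external_scores[human] = max(external_scores.get(human, 0.0), s.percentage)
    novel = novel_vs_external(gene_results, external_scores)
    lethality_rescue(
        gene_results, models, diseases, include_childhood=include_childhood
    )

    pair_table = build_pair_table(scores, models, diseases)
    n_match = sum(g.is_match for g in gene_results)
    summary = {
        "n_orthologs_one_to_one": len(ortholog_map),
        "n_pairs_scored": len(scores),
        "n_genes_scored": len(gene_results),
        "n_gene_matches": n_match,
        "gene_match_rate": (n_match / len(gene_results)) if gene_results else 0.0,
        "n_rescued": sum(g.rescue != "none" for g in gene_results),
        "n_novel_vs_external": len(novel),
        "include_childhood": include_childhood,
        "min_support": min_support,
        "pair_form": form,
    }
    return StudyResult(
        scores=scores,
        gene_results=gene_results,
        pair_table=pair_table,
        external_scores=external_scores,
        summary=summary,
    )
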