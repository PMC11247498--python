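"""PhenoDigm-style phenotype-profile similarity.

A mouse model (a set of MP terms) is compared with a Mendelian disease (a set
of HPO terms) on a merged cross-species ontology.  Each disease term (the
*query*) is matched to its best model term; the best and mean of those
per-query scores are normalised against the disease's theoretical optimum —
the score a hypothetical model mimicking every disease phenotype exactly
would achieve — to give a percentage in [0, 100].

Pairwise term score (default form)::

    s(q, h) = sqrt( J(q, h) * IC(MICA(q, h)) )

where ``J`` is the Jaccard index of the two reflexive ancestor sets and the
MICA is the most-informative common ancestor.  The form is configurable
(``"geometric"`` default, ``"resnik"`` = IC only, ``"jaccard"`` = J only).

Percentage score::

    percentage = 100 * ( raw_max / opt_max + raw_mean / opt_mean ) / 2

with ``raw_max`` / ``raw_mean`` the max and mean of the per-query best
scores and ``(opt_max, opt_mean)`` the same statistics of the disease terms'
self-similarities.  A disease annotated only to zero-IC roots has
``opt_max = 0`` and scores 0 by convention.  Direction matters: disease
terms are the queries by default (an optional bidirectional variant averages
both directions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import fmean

from .ontology import ICTable, Ontology, mica as _mica

__all__ = [
    "TermMatch",
    "ScoreResult",
    "PhenodigmScorer",
    "term_similarity",
    "best_matches",
    "optimal_self",
    "phenodigm_score",
]

PAIR_FORMS = ("geometric", "resnik", "jaccard")


@dataclass(frozen=True)
class TermMatch:
    """Best cross-species hit for one query term."""

    query_term: str
    hit_term: str | None
    pair_score: float
    subsumer: str | None


@dataclass
class ScoreResult:
    """One model-disease comparison."""

    model_id: str
    disease_id: str
    raw_max: float
    raw_mean: float
    percentage: float
    matches: list[TermMatch] = field(default_factory=list)


class PhenodigmScorer:
    """Scores model-disease pairs on a fixed ontology + IC table.

    Caches pairwise term scores and per-disease self-optima, which makes
    scoring thousands of pairs over a shared vocabulary cheap.
    """

    def __init__(
        self,
        ont: Ontology,
        ic: ICTable,
        *,
        form: str = "geometric",
        bidirectional: bool = False,
    ):
        if form not in PAIR_FORMS:
            raise ValueError(f"unknown pair-score form {form!r}; use one of {PAIR_FORMS}")
        self.ont = ont
        self.ic = ic
        self.form = form
        self.bidirectional = bidirectional
        self._pair_cache: dict[tuple[str, str], tuple[float, str | None]] = {}
        self._self_cache: dict[frozenset[str], tuple[float, float]] = {}

    # -- pairwise ------------------------------------------------------------
    def _pair(self, t1: str, t2: str) -> tuple[float, str | None]:
        """(score, subsumer) for a term pair; symmetric, cached."""
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        hit = self._pair_cache.get(key)
        if hit is not None:
            return hit
        a1 = self.ont.ancestors(t1)
        a2 = self.ont.ancestors(t2)
        subsumer, sub_ic = _mica(self.ont, self.ic, t1, t2)
        inter = len(a1 & a2)
        jac = inter / (len(a1) + len(a2) - inter) if inter else 0.0
        if self.form == "geometric":
            score = math.sqrt(jac * sub_ic)
        elif self.form == "resnik":
            score = sub_ic if jac > 0 else 0.0
        else:  # jaccard
            score = jac
        result = (score, subsumer)
        self._pair_cache[key] = result
        return result

    def term_similarity(self, t_query: str, t_hit: str) -> float:
        """Pairwise term score; symmetric in its arguments, >= 0."""
        return self._pair(t_query, t_hit)[0]

    # -- profile -------------------------------------------------------------
    def best_matches(
        self, query_terms: set[str] | frozenset[str], hit_terms: set[str] | frozenset[str]
    ) -> list[TermMatch]:
        """One TermMatch per query term: the argmax hit (ties -> smallest id)."""
        if not query_terms:
            raise ValueError("query term set is empty")
        if not hit_terms:
            raise ValueError("hit term set is empty")
        hits = sorted(hit_terms)
        out: list[TermMatch] = []
        for q in sorted(query_terms):
            best_score = -1.0
            best_hit: str | None = None
            best_sub: str | None = None
            for h in hits:
                score, sub = self._pair(q, h)
                if score > best_score:
                    best_score, best_hit, best_sub = score, h, sub
            out.append(
                TermMatch(
                    query_term=q,
                    hit_term=best_hit,
                    pair_score=best_score,
                    subsumer=best_sub if best_score > 0 else None,
                )
            )
        return out

    def optimal_self(
        self, terms: set[str] | frozenset[str]
    ) -> tuple[float, float]:
        """(max, mean) of each term's self-similarity: the perfect-model score."""
        if not terms:
            raise ValueError("term set is empty")
        key = frozenset(terms)
        hit = self._self_cache.get(key)
        if hit is not None:
            return hit
        selfs = [self._pair(t, t)[0] for t in key]
        result = (max(selfs), fmean(selfs))
        self._self_cache[key] = result
        return result

    def score(
        self,
        disease_terms: set[str] | frozenset[str],
        model_terms: set[str] | frozenset[str],
        *,
        model_id: str = "",
        disease_id: str = "",
    ) -> ScoreResult:
        """PhenoDigm percentage score of a model against a disease."""
        if not disease_terms:
            raise ValueError("disease term set is empty")
        if not model_terms:
            raise ValueError("model term set is empty")
        matches = self.best_matches(disease_terms, model_terms)
        opt_terms: frozenset[str] = frozenset(disease_terms)
        if self.bidirectional:
            matches = matches + self.best_matches(model_terms, disease_terms)
            opt_terms = opt_terms | frozenset(model_terms)
        raw_max = max(m.pair_score for m in matches)
        raw_mean = fmean(m.pair_score for m in matches)
        opt_max, opt_mean = self.optimal_self(opt_terms)
        if opt_max <= 0.0:
            percentage = 0.0
        else:
            percentage = 100.0 * (raw_max / opt_max + raw_mean / opt_mean) / 2.0
            percentage = min(100.0, max(0.0, percentage))
        return ScoreResult(
            model_id=model_id,
            disease_id=disease_id,
            raw_max=raw_max,
            raw_mean=raw_mean,
            percentage=percentage,
            matches=matches,
        )


# ---------------------------------------------------------------------------
# functional op surface (one-shot convenience wrappers)
# ---------------------------------------------------------------------------

def term_similarity(
    ont: Ontology, ic: ICTable, t_query: str, t_hit: str, *, form: str = "geometric"
) -> float:
    return PhenodigmScorer(ont, ic, form=form).term_similarity(t_query, t_hit)


def best_matches(
    ont: Ontology,
    ic: ICTable,
    query_terms: set[str],
    hit_terms: set[str],
    *,
    form: str = "geometric",
) -> list[TermMatch]:
    return PhenodigmScorer(ont, ic, form=form).best_matches(query_terms, hit_terms)


def optimal_self(
    ont: Ontology, ic: ICTable, disease_terms: set[str], *, form: str = "geometric"
) -> tuple[float, float]:
    return PhenodigmScorer(ont, ic, form=form).optimal_self(disease_terms)


def phenodigm_score(
    ont: Ontology,
    ic: ICTable,
    disease_terms: set[str],
    model_terms: set[str],
    *,
    form: str = "geometric",
    bidirectional: bool = False,
    model_id: str = "",
    disease_id: str = "",
) -> ScoreResult:
    scorer = PhenodigmScorer(ont, ic, form=form, bidirectional=bidirectional)
    return scorer.score(
        disease_terms, model_terms, model_id=model_id, disease_id=disease_id
    )
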