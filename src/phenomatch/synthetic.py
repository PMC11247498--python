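"""Synthetic study generator.

Builds, from a seed and a configuration, a complete self-contained study:

* a merged cross-species toy ontology — one root, a configurable number of
  shared "phenotype system" ancestors, and under each a pair of mirrored
  subtrees (one of HP-namespace ids, one of MP-namespace ids) so that every
  HP leaf has an MP counterpart with an informative shared ancestor;
* catalogues of mouse models, diseases, orthologs and an external model
  catalogue, with planted statistical structure: a logistic model of match
  propensity on model/disease features, category-specific odds multipliers,
  and an intercept calibrated so the expected gene-level match rate equals a
  configured target (default 55%, the fraction reported for real
  disease-gene knockouts);
* a ground-truth table (per-pair planted propensity and match label) for
  parameter-recovery tests.

Construction guarantees, given the default scorer:

* a planted *matcher* pair scores > 0 — the model carries at least one MP
  leaf from the mirror image of the disease's HPO set, so the pair shares a
  phenotype-system ancestor with positive information content;
* a planted *non-matcher* pair scores exactly 0 — its MP terms come from
  systems disjoint from every disorder of that gene, so the only shared
  ancestor is the zero-IC root.  Disorders of the same gene occupy disjoint
  systems, so a model can match one disorder and not another.

``mirror_copy`` mode instead annotates each model with the identity image of
its gene's disease term sets in the merged (species-neutral) graph, which
makes every scored pair attain exactly 100 — the self-calibration control.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .catalogs import (
    DiseaseRecord,
    ExternalModelRecord,
    ModelRecord,
    OrthologRecord,
    diseases_to_frame,
    external_to_frame,
    models_to_frame,
    orthologs_to_frame,
)
from .ontology import Ontology, parse_obo

__all__ = [
    "SimConfig",
    "OntologyLayout",
    "StudyTables",
    "generate_ontology",
    "generate_study",
    "simulate_study",
    "mirror_term",
]

ROOT_ID = "CP:0000000"


def _default_category_probs() -> dict[str, float]:
    return {
        "neurology": 0.30,
        "metabolic": 0.12,
        "dysmorphic": 0.12,
        "cardiovascular": 0.10,
        "endocrine": 0.08,
        "skeletal": 0.08,
        "respiratory": 0.05,
        "other": 0.15,
    }


def _default_category_odds() -> dict[str, float]:
    # endocrine-like disorders match far more often, respiratory-like less
    return {"endocrine": 3.0, "respiratory": 0.6}


def _default_coefficients() -> dict[str, float]:
    # planted log-odds effects; continuous features act per standard deviation
    return {
        "n_procedures": 0.5,
        "n_mp_terms": 0.8,
        "n_hpo_terms": -0.5,
        "homozygous": 0.4,
        "early_death": 0.6,
    }


def _default_moi_probs() -> dict[str, float]:
    return {"AD": 0.35, "AR": 0.45, "AD&AR": 0.10, "other": 0.10}


def _default_early_death_probs() -> dict[str, float]:
    return {"none": 0.78, "pre_infant": 0.15, "childhood": 0.07}


@dataclass
class SimConfig:
    """Study conditions for the generator.

    ``n_genes`` counts disease-associated genes (all annotated, hence all
    scoreable); ``fraction_disease_associated`` controls how many additional
    non-disease genes pad the catalogues.  ``base_match_rate`` is the target
    expected gene-level match fraction the planted intercept is calibrated
    to.  Viability probabilities follow the reported lethal/subviable/viable
    mix of the homozygote viability screen (24/8/68%).
    """

    seed: int = 0
    # ontology shape
    n_shared_ancestors: int = 8
    subtree_depth: int = 4
    branching_factor: int = 3
    # study size
    n_genes: int = 2400
    fraction_disease_associated: float = 0.31
    # planted structure
    base_match_rate: float = 0.55
    category_probs: dict[str, float] = field(default_factory=_default_category_probs)
    category_odds: dict[str, float] = field(default_factory=_default_category_odds)
    coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    # marginal distributions
    viability_probs: tuple[float, float, float] = (0.24, 0.08, 0.68)  # lethal/subviable/viable
    moi_probs: dict[str, float] = field(default_factory=_default_moi_probs)
    early_death_probs: dict[str, float] = field(default_factory=_default_early_death_probs)
    hpo_terms_per_disease: tuple[int, int] = (3, 12)
    mp_terms_per_model: tuple[int, int] = (2, 10)
    n_procedures_range: tuple[int, int] = (5, 25)
    p_second_disease: float = 0.2
    p_hemizygous: float = 0.02
    # external catalogue
    p_external_model: float = 0.85
    p_external_match: float = 0.8
    # controls
    mirror_copy: bool = False

    def validate(self) -> None:
        if not 1 <= self.n_shared_ancestors <= 99:
            raise ValueError("n_shared_ancestors must be in 1..99")
        if self.subtree_depth < 1 or self.branching_factor < 1:
            raise ValueError("subtree_depth and branching_factor must be >= 1")
        if abs(sum(self.viability_probs) - 1.0) > 1e-9:
            raise ValueError("viability probabilities must sum to 1")
        for name, probs in (
            ("category_probs", self.category_probs),
            ("moi_probs", self.moi_probs),
            ("early_death_probs", self.early_death_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has a negative probability")
        if not 0.0 <= self.base_match_rate <= 1.0:
            raise ValueError("base_match_rate must be in [0, 1]")
        for name, rng in (
            ("hpo_terms_per_disease", self.hpo_terms_per_disease),
            ("mp_terms_per_model", self.mp_terms_per_model),
            ("n_procedures_range", self.n_procedures_range),
        ):
            if rng[0] > rng[1] or rng[0] < 1:
                raise ValueError(f"{name} range {rng} is empty or non-positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("viability_probs", "hpo_terms_per_disease",
                    "mp_terms_per_model", "n_procedures_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# ontology construction
# ---------------------------------------------------------------------------

def mirror_term(term_id: str) -> str:
    """Cross-species counterpart of a mirrored term (HP:x <-> MP:x)."""
    if term_id.startswith("HP:"):
        return "MP:" + term_id[3:]
    if term_id.startswith("MP:"):
        return "HP:" + term_id[3:]
    raise ValueError(f"{term_id!r} has no mirror image")


@dataclass
class OntologyLayout:
    """A generated merged ontology plus its layout bookkeeping."""

    ontology: Ontology
    obo_text: str
    hp_leaves: dict[int, list[str]]    # system index -> HP leaf ids
    mp_leaves: dict[int, list[str]]
    n_systems: int

    @property
    def leaves_per_system(self) -> int:
        return len(self.hp_leaves[1])


def _heap_parent(i: int, b: int) -> int:
    return (i - 2) // b + 1


def generate_ontology(cfg: SimConfig) -> OntologyLayout:
    """Build the merged toy ontology (deterministic given the config).

    One zero-IC-destined root; ``n_shared_ancestors`` phenotype-system nodes
    under it; under each system two mirrored complete ``branching_factor``-ary
    subtrees of ``subtree_depth`` levels, one per namespace.  The OBO text is
    emitted sorted by term id, so identical configs give byte-identical
    output.
    """
    cfg.validate()
    b, depth, n_sys = cfg.branching_factor, cfg.subtree_depth, cfg.n_shared_ancestors
    n_nodes = sum(b ** level for level in range(depth))
    if n_nodes > 99_999:
        raise ValueError("subtree too large for the 7-digit id scheme")
    n_internal = sum(b ** level for level in range(depth - 1))

    stanzas: dict[str, tuple[str, str, list[str]]] = {
        ROOT_ID: ("cross-species phenotypic abnormality", "shared", [])
    }
    hp_leaves: dict[int, list[str]] = {}
    mp_leaves: dict[int, list[str]] = {}
    for s in range(1, n_sys + 1):
        sys_id = f"CP:{s:07d}"
        stanzas[sys_id] = (f"phenotype system {s}", "shared", [ROOT_ID])
        hp_leaves[s] = []
        mp_leaves[s] = []
        for prefix, namespace, leaves in (
            ("HP", "human-phenotype", hp_leaves),
            ("MP", "mammalian-phenotype", mp_leaves),
        ):
            for i in range(1, n_nodes + 1):
                tid = f"{prefix}:{s * 100_000 + i:07d}"
                parent = (
                    sys_id
                    if i == 1
                    else f"{prefix}:{s * 100_000 + _heap_parent(i, b):07d}"
                )
                stanzas[tid] = (
                    f"{prefix.lower()} phenotype system {s} node {i}",
                    namespace,
                    [parent],
                )
                if i > n_internal:
                    leaves[s].append(tid)

    lines = ["format-version: 1.2", "ontology: merged-phenotype", ""]
    for tid in sorted(stanzas):
        name, namespace, parents = stanzas[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {name}")
        lines.append(f"namespace: {namespace}")
        for p in parents:
            lines.append(f"is_a: {p} ! {stanzas[p][0]}")
        lines.append("")
    obo_text = "\n".join(lines)
    return OntologyLayout(
        ontology=parse_obo(obo_text),
        obo_text=obo_text,
        hp_leaves=hp_leaves,
        mp_leaves=mp_leaves,
        n_systems=n_sys,
    )


# ---------------------------------------------------------------------------
# study construction
# ---------------------------------------------------------------------------

@dataclass
class StudyTables:
    """All generated catalogues plus the ground truth."""

    models: list[ModelRecord]
    diseases: list[DiseaseRecord]
    orthologs: list[OrthologRecord]
    external: list[ExternalModelRecord]
    truth: pd.DataFrame
    params: dict

    def pair_feature_table(self) -> pd.DataFrame:
        """Scoreable-pair feature table with the planted match labels.

        Matches the shape of the pipeline's pair table (a planted matcher is
        guaranteed a positive score and a non-matcher a zero score, so the
        labels coincide with the realised ones) without running the scorer.
        """
        from .pipeline import build_pair_table
        from .similarity import ScoreResult

        scores = [
            ScoreResult(
                model_id=row.model_id,
                disease_id=row.disease_id,
                raw_max=0.0,
                raw_mean=0.0,
                percentage=float(row.is_match),
            )
            for row in self.truth.itertuples(index=False)
        ]
        return build_pair_table(scores, self.models, self.diseases)

    def write(self, outdir: str | Path, layout: OntologyLayout | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if layout is not None:
            (outdir / "merged.obo").write_text(layout.obo_text, encoding="utf-8")
        models_to_frame(self.models).to_csv(outdir / "models.tsv", sep="\t", index=False)
        diseases_to_frame(self.diseases).to_csv(
            outdir / "diseases.tsv", sep="\t", index=False
        )
        orthologs_to_frame(self.orthologs).to_csv(
            outdir / "orthologs.tsv", sep="\t", index=False
        )
        external_to_frame(self.external).to_csv(
            outdir / "external.tsv", sep="\t", index=False
        )
        self.truth.to_csv(
            outdir / "truth.tsv", sep="\t", index=False, float_format="%.8f"
        )
        with open(outdir / "truth_params.json", "w", encoding="utf-8") as fh:
            json.dump(self.params, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _rng(seed: int, stream: int) -> np.random.Generator:
    # per-table derived sub-seeds: partial regeneration is stable
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _pick_categorical(rng: np.random.Generator, probs: dict[str, float], n: int):
    labels = list(probs)
    return rng.choice(labels, size=n, p=[probs[k] for k in labels])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _calibrate_intercept(
    eta: np.ndarray, gene_starts: np.ndarray, target: float
) -> float:
    """Intercept such that the expected gene-level match rate equals target.

    A gene matches when any of its pairs matches; pairs are independent
    Bernoulli draws with p = sigmoid(b0 + eta).
    """

    def realised(b0: float) -> float:
        p = _sigmoid(b0 + eta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        gene_log_nomatch = np.add.reduceat(np.log1p(-p), gene_starts)
        return float(np.mean(1.0 - np.exp(gene_log_nomatch))) - target

    return float(brentq(realised, -30.0, 30.0, xtol=1e-10))


def generate_study(cfg: SimConfig, layout: OntologyLayout) -> StudyTables:
    """Generate the full synthetic study on a generated ontology."""
    cfg.validate()
    n_sys = layout.n_systems
    leaves_per_system = layout.leaves_per_system
    if cfg.hpo_terms_per_disease[0] > 3 * leaves_per_system:
        raise ValueError("hpo_terms_per_disease infeasible for this ontology")
    if cfg.mp_terms_per_model[0] > max(1, n_sys - 4) * leaves_per_system:
        raise ValueError("mp_terms_per_model infeasible for this ontology")
    if n_sys < 5:
        raise ValueError(
            "need at least 5 phenotype systems to keep matcher and "
            "non-matcher term pools disjoint"
        )

    rng_struct = _rng(cfg.seed, 0)
    rng_terms = _rng(cfg.seed, 1)
    rng_match = _rng(cfg.seed, 2)
    rng_external = _rng(cfg.seed, 3)
    rng_ortho = _rng(cfg.seed, 4)

    n_d = cfg.n_genes
    frac = cfg.fraction_disease_associated
    n_total = int(round(n_d / frac)) if frac > 0 else n_d
    n_total = max(n_total, n_d)
    human = [f"GENE{i:05d}" for i in range(1, n_total + 1)]
    mouse = [f"Gene{i:05d}" for i in range(1, n_total + 1)]

    # ---- diseases (first n_d genes are disease-associated) ----------------
    diseases: list[DiseaseRecord] = []
    gene_systems: list[set[int]] = []        # systems used by each gene's disorders
    gene_disease_idx: list[list[int]] = []   # indices into `diseases`
    disease_counter = 0
    hpo_lo, hpo_hi = cfg.hpo_terms_per_disease
    for g in range(n_d):
        n_dis = 1 + int(rng_struct.random() < cfg.p_second_disease)
        max_per = 3 if n_dis == 1 else 2
        sys_pool = rng_struct.permutation(np.arange(1, n_sys + 1))
        used: set[int] = set()
        idxs: list[int] = []
        cursor = 0
        for _ in range(n_dis):
            k = int(rng_struct.integers(1, max_per + 1))
            chosen = [int(s) for s in sys_pool[cursor:cursor + k]]
            cursor += k
            used.update(chosen)
            leaves = [t for s in chosen for t in layout.hp_leaves[s]]
            n_hpo = min(int(rng_struct.integers(hpo_lo, hpo_hi + 1)), len(leaves))
            hpo_terms = frozenset(
                rng_terms.choice(leaves, size=n_hpo, replace=False).tolist()
            )
            disease_counter += 1
            diseases.append(
                DiseaseRecord(
                    disease_id=f"OMIM:{600000 + disease_counter}",
                    human_gene=human[g],
                    hpo_terms=hpo_terms,
                    moi=str(_pick_categorical(rng_struct, cfg.moi_probs, 1)[0]),
                    category=str(_pick_categorical(rng_struct, cfg.category_probs, 1)[0]),
                    early_death=str(
                        _pick_categorical(rng_struct, cfg.early_death_probs, 1)[0]
                    ),
                    evidence=str(
                        rng_struct.choice(
                            ["green", "amber", "red"], p=[0.7, 0.2, 0.1]
                        )
                    ),
                )
            )
            idxs.append(len(diseases) - 1)
        gene_systems.append(used)
        gene_disease_idx.append(idxs)

    # ---- models ------------------------------------------------------------
    viab_labels = ("lethal", "subviable", "viable")
    proc_lo, proc_hi = cfg.n_procedures_range
    mp_lo, mp_hi = cfg.mp_terms_per_model

    @dataclass
    class _ModelDraft:
        model_id: str
        gene_idx: int
        zygosity: str
        life_stage: str
        viability: str
        preweaning_lethal: bool
        n_procedures: int
        n_mp_target: int

    drafts: list[_ModelDraft] = []
    model_counter = 0

    def _new_draft(gene_idx: int, zygosity: str, life_stage: str,
                   viability: str, lethal: bool) -> _ModelDraft:
        nonlocal model_counter
        model_counter += 1
        return _ModelDraft(
            model_id=f"IMPC:{model_counter:06d}",
            gene_idx=gene_idx,
            zygosity=zygosity,
            life_stage=life_stage,
            viability=viability,
            preweaning_lethal=lethal,
            n_procedures=int(rng_struct.integers(proc_lo, proc_hi + 1)),
            n_mp_target=int(rng_struct.integers(mp_lo, mp_hi + 1)),
        )

    gene_viability = rng_struct.choice(
        viab_labels, size=n_total, p=list(cfg.viability_probs)
    )
    for g in range(n_total):
        viab = str(gene_viability[g])
        if viab == "lethal":
            # lethal lines: a homozygous embryo model and a het adult model
            drafts.append(_new_draft(g, "homozygous", "embryo", viab, True))
            drafts.append(_new_draft(g, "heterozygous", "early_adult", viab, True))
        else:
            zyg = (
                "hemizygous"
                if rng_struct.random() < cfg.p_hemizygous
                else "homozygous"
            )
            drafts.append(_new_draft(g, zyg, "early_adult", viab, False))

    # ---- planted match structure over the scoreable pairs ------------------
    pair_model: list[int] = []    # index into drafts
    pair_disease: list[int] = []  # index into diseases
    gene_starts: list[int] = []
    drafts_by_gene: dict[int, list[int]] = {}
    for j, d in enumerate(drafts):
        drafts_by_gene.setdefault(d.gene_idx, []).append(j)
    for g in range(n_d):
        gene_starts.append(len(pair_model))
        for j in drafts_by_gene[g]:
            for di in gene_disease_idx[g]:
                pair_model.append(j)
                pair_disease.append(di)
    n_pairs = len(pair_model)

    feats = pd.DataFrame(
        {
            "n_procedures": [drafts[j].n_procedures for j in pair_model],
            "n_mp_terms": [drafts[j].n_mp_target for j in pair_model],
            "n_hpo_terms": [len(diseases[di].hpo_terms) for di in pair_disease],
            "homozygous": [
                int(drafts[j].zygosity in ("homozygous", "hemizygous"))
                for j in pair_model
            ],
            "early_death": [
                int(diseases[di].early_death != "none") for di in pair_disease
            ],
            "category": [diseases[di].category for di in pair_disease],
        }
    )
    coef = cfg.coefficients
    eta = np.zeros(n_pairs)
    for name in ("n_procedures", "n_mp_terms", "n_hpo_terms"):
        v = feats[name].to_numpy(dtype=float)
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        eta += coef.get(name, 0.0) * z
    eta += coef.get("homozygous", 0.0) * feats["homozygous"].to_numpy(dtype=float)
    eta += coef.get("early_death", 0.0) * feats["early_death"].to_numpy(dtype=float)
    eta += np.log(
        [cfg.category_odds.get(c, 1.0) for c in feats["category"]]
    )

    if cfg.mirror_copy or n_pairs == 0:
        intercept = math.inf
        propensity = np.ones(n_pairs)
        is_match = np.ones(n_pairs, dtype=bool)
    elif cfg.base_match_rate <= 0.0:
        intercept = -math.inf
        propensity = np.zeros(n_pairs)
        is_match = np.zeros(n_pairs, dtype=bool)
    elif cfg.base_match_rate >= 1.0:
        intercept = math.inf
        propensity = np.ones(n_pairs)
        is_match = np.ones(n_pairs, dtype=bool)
    else:
        intercept = _calibrate_intercept(
            eta, np.asarray(gene_starts), cfg.base_match_rate
        )
        propensity = _sigmoid(intercept + eta)
        is_match = rng_match.random(n_pairs) < propensity

    # ---- compose MP term sets ----------------------------------------------
    matched_by_model: dict[int, list[int]] = {}
    for k in range(n_pairs):
        if is_match[k]:
            matched_by_model.setdefault(pair_model[k], []).append(pair_disease[k])

    all_systems = set(range(1, n_sys + 1))
    models: list[ModelRecord] = []
    for j, d in enumerate(drafts):
        if cfg.mirror_copy and d.gene_idx < n_d:
            mp_terms = frozenset(
                t
                for di in gene_disease_idx[d.gene_idx]
                for t in diseases[di].hpo_terms
            )
        elif d.gene_idx < n_d:
            matched = matched_by_model.get(j, [])
            banned = gene_systems[d.gene_idx]
            filler_systems = sorted(all_systems - banned)
            filler_pool = [t for s in filler_systems for t in layout.mp_leaves[s]]
            chosen: list[str] = []
            mirror_pool: list[str] = []
            for di in matched:
                mirrors = sorted(mirror_term(t) for t in diseases[di].hpo_terms)
                pick = str(rng_terms.choice(mirrors))
                chosen.append(pick)
                mirror_pool.extend(m for m in mirrors if m != pick)
            n_mp = max(d.n_mp_target, len(chosen))
            remaining = n_mp - len(chosen)
            if remaining > 0 and matched:
                # matchers draw the rest preferentially from the mirror image
                take = min(remaining, len(mirror_pool))
                if take:
                    chosen.extend(
                        rng_terms.choice(
                            sorted(set(mirror_pool) - set(chosen)),
                            size=min(take, len(set(mirror_pool) - set(chosen))),
                            replace=False,
                        ).tolist()
                    )
                remaining = n_mp - len(chosen)
            if remaining > 0:
                pool = sorted(set(filler_pool) - set(chosen))
                chosen.extend(
                    rng_terms.choice(
                        pool, size=min(remaining, len(pool)), replace=False
                    ).tolist()
                )
            mp_terms = frozenset(chosen)
        else:
            # non-disease gene: annotated in 1-2 random systems, or not at all
            if rng_terms.random() < 0.08:
                mp_terms = frozenset()
            else:
                k = int(rng_terms.integers(1, 3))
                systems = rng_terms.choice(
                    np.arange(1, n_sys + 1), size=k, replace=False
                )
                pool = [t for s in systems for t in layout.mp_leaves[int(s)]]
                n_mp = min(d.n_mp_target, len(pool))
                mp_terms = frozenset(
                    rng_terms.choice(pool, size=n_mp, replace=False).tolist()
                )
        models.append(
            ModelRecord(
                model_id=d.model_id,
                mouse_gene=mouse[d.gene_idx],
                zygosity=d.zygosity,
                life_stage=d.life_stage,
                viability=d.viability,
                mp_terms=mp_terms,
                n_procedures=d.n_procedures,
                preweaning_lethal=d.preweaning_lethal,
            )
        )

    # ---- orthologs ----------------------------------------------------------
    orthologs: list[OrthologRecord] = []
    for g in range(n_total):
        support = (
            int(rng_ortho.integers(5, 13))
            if g < n_d
            else int(rng_ortho.integers(3, 13))
        )
        orthologs.append(OrthologRecord(human[g], mouse[g], support))
    # inject one-to-many pairs among the non-disease padding genes so the
    # bijectivity filter has something to reject
    n_dupes = min(10, max(0, (n_total - n_d) // 2))
    for k in range(n_dupes):
        g = n_d + 2 * k
        orthologs.append(OrthologRecord(human[g], mouse[g + 1], 7))

    # ---- external catalogue --------------------------------------------------
    external: list[ExternalModelRecord] = []
    ext_counter = 0
    for g in range(n_d):
        if rng_external.random() >= cfg.p_external_model:
            continue
        ext_counter += 1
        di = gene_disease_idx[g][0]
        if rng_external.random() < cfg.p_external_match:
            mirrors = sorted(mirror_term(t) for t in diseases[di].hpo_terms)
            n_take = min(int(rng_external.integers(1, 4)), len(mirrors))
            terms = frozenset(
                rng_external.choice(mirrors, size=n_take, replace=False).tolist()
            )
        else:
            banned = gene_systems[g]
            pool = [
                t
                for s in sorted(all_systems - banned)
                for t in layout.mp_leaves[s]
            ]
            n_take = min(int(rng_external.integers(2, 5)), len(pool))
            terms = frozenset(
                rng_external.choice(pool, size=n_take, replace=False).tolist()
            )
        external.append(
            ExternalModelRecord(
                model_id=f"MGI:{5_000_000 + ext_counter}",
                mouse_gene=mouse[g],
                mp_terms=terms,
            )
        )

    truth = pd.DataFrame(
        {
            "model_id": [drafts[j].model_id for j in pair_model],
            "disease_id": [diseases[di].disease_id for di in pair_disease],
            "human_gene": [diseases[di].human_gene for di in pair_disease],
            "eta": eta,
            "propensity": propensity,
            "is_match": is_match.astype(int),
        }
    )
    params = {
        "seed": cfg.seed,
        "target_match_rate": cfg.base_match_rate,
        "intercept": intercept if math.isfinite(intercept) else None,
        "coefficients": dict(cfg.coefficients),
        "category_odds": dict(cfg.category_odds),
        "n_disease_genes": n_d,
        "n_total_genes": n_total,
        "n_pairs": n_pairs,
        "mirror_copy": cfg.mirror_copy,
    }
    return StudyTables(
        models=models,
        diseases=diseases,
        orthologs=orthologs,
        external=external,
        truth=truth,
        params=params,
    )


def simulate_study(cfg: SimConfig) -> tuple[OntologyLayout, StudyTables]:
    """Convenience wrapper: ontology + study in one call."""
    layout = generate_ontology(cfg)
    return layout, generate_study(cfg, layout)
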