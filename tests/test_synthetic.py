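"""Synthetic study generator: ontology shape, determinism, planted structure."""

import numpy as np
import pytest

from phenomatch.catalogs import (
    read_diseases,
    read_external,
    read_models,
    read_orthologs,
)
from phenomatch.pipeline import run_study
from phenomatch.stats import category_enrichment, gene_category_table
from phenomatch.synthetic import (
    SimConfig,
    generate_ontology,
    generate_study,
    mirror_term,
)


def small_cfg(**kw):
    defaults = dict(n_genes=80, fraction_disease_associated=1.0, seed=0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGenerateOntology:
    def test_minimal_shape_has_four_terms(self):
        cfg = SimConfig(n_shared_ancestors=1, subtree_depth=1, branching_factor=1)
        layout = generate_ontology(cfg)
        # root + 1 system ancestor + 1 HP leaf + 1 MP leaf
        assert len(layout.ontology) == 4
        assert layout.hp_leaves[1] == ["HP:0100001"]
        assert layout.mp_leaves[1] == ["MP:0100001"]

    def test_cross_species_connectivity(self):
        layout = generate_ontology(SimConfig(n_shared_ancestors=3, subtree_depth=2))
        ont = layout.ontology
        (root,) = ont.roots
        for s in layout.hp_leaves:
            for hp, mp in zip(layout.hp_leaves[s], layout.mp_leaves[s]):
                shared = ont.ancestors(hp) & ont.ancestors(mp)
                assert root in shared
                assert f"CP:{s:07d}" in shared  # informative shared ancestor

    def test_mirror_leaves_correspond(self):
        layout = generate_ontology(SimConfig(n_shared_ancestors=2))
        for s in layout.hp_leaves:
            assert [mirror_term(t) for t in layout.hp_leaves[s]] == layout.mp_leaves[s]

    def test_obo_output_is_deterministic(self):
        cfg = SimConfig(seed=5)
        a = generate_ontology(cfg).obo_text
        b = generate_ontology(cfg).obo_text
        assert a == b
        assert a.encode() == b.encode()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            generate_ontology(SimConfig(n_shared_ancestors=0))
        with pytest.raises(ValueError):
            SimConfig(viability_probs=(0.5, 0.5, 0.5)).validate()


class TestGenerateStudy:
    def test_study_is_deterministic_given_seed(self):
        cfg = small_cfg(seed=9)
        layout = generate_ontology(cfg)
        a = generate_study(cfg, layout)
        b = generate_study(cfg, layout)
        assert a.models == b.models
        assert a.diseases == b.diseases
        assert a.orthologs == b.orthologs
        assert a.truth.equals(b.truth)

    def test_different_seeds_differ(self):
        layout = generate_ontology(small_cfg())
        a = generate_study(small_cfg(seed=1), layout)
        b = generate_study(small_cfg(seed=2), layout)
        assert not a.truth.equals(b.truth)

    def test_schema_round_trip_through_readers(self, tmp_path):
        cfg = small_cfg(seed=3, fraction_disease_associated=0.6)
        layout = generate_ontology(cfg)
        tables = generate_study(cfg, layout)
        tables.write(tmp_path, layout=layout)
        models = read_models(tmp_path / "models.tsv")
        diseases = read_diseases(tmp_path / "diseases.tsv")
        orthologs = read_orthologs(tmp_path / "orthologs.tsv")
        external = read_external(tmp_path / "external.tsv")
        assert [m.model_id for m in models] == [m.model_id for m in tables.models]
        assert len(diseases) == len(tables.diseases)
        assert len(orthologs) == len(tables.orthologs)
        assert len(external) == len(tables.external)

    def test_lethal_genes_get_embryo_hom_and_adult_het_models(self):
        cfg = small_cfg(seed=4)
        tables = generate_study(cfg, generate_ontology(cfg))
        by_gene = {}
        for m in tables.models:
            by_gene.setdefault(m.mouse_gene, []).append(m)
        lethal_seen = viable_seen = False
        for gene_models in by_gene.values():
            if gene_models[0].viability == "lethal":
                lethal_seen = True
                assert len(gene_models) == 2
                kinds = {(m.zygosity, m.life_stage) for m in gene_models}
                assert kinds == {
                    ("homozygous", "embryo"), ("heterozygous", "early_adult")
                }
                assert all(m.preweaning_lethal for m in gene_models)
            else:
                viable_seen = True
                assert len(gene_models) == 1
        assert lethal_seen and viable_seen

    def test_planted_labels_equal_realised_matches(self):
        cfg = small_cfg(seed=6)
        layout = generate_ontology(cfg)
        tables = generate_study(cfg, layout)
        res = run_study(layout.ontology, tables.models, tables.diseases,
                        tables.orthologs)
        obs = res.pair_table.set_index(["model_id", "disease_id"])["is_match"]
        for row in tables.truth.itertuples(index=False):
            assert bool(row.is_match) == bool(
                obs.loc[(row.model_id, row.disease_id)]
            )

    def test_mirror_copy_scores_exactly_100(self):
        cfg = small_cfg(seed=7, n_genes=25, mirror_copy=True, p_external_model=0.0)
        layout = generate_ontology(cfg)
        tables = generate_study(cfg, layout)
        res = run_study(layout.ontology, tables.models, tables.diseases,
                        tables.orthologs)
        assert len(res.scores) > 0
        assert all(s.percentage == 100.0 for s in res.scores)

    def test_zero_base_rate_and_no_effects_give_zero_matches(self):
        cfg = small_cfg(
            seed=8, base_match_rate=0.0, category_odds={},
            coefficients={k: 0.0 for k in (
                "n_procedures", "n_mp_terms", "n_hpo_terms",
                "homozygous", "early_death")},
            p_external_model=0.0,
        )
        layout = generate_ontology(cfg)
        tables = generate_study(cfg, layout)
        res = run_study(layout.ontology, tables.models, tables.diseases,
                        tables.orthologs)
        assert res.summary["gene_match_rate"] == 0.0

    def test_infeasible_term_ranges_rejected(self):
        cfg = SimConfig(n_shared_ancestors=5, subtree_depth=1, branching_factor=1,
                        hpo_terms_per_disease=(10, 12))
        with pytest.raises(ValueError, match="infeasible"):
            generate_study(cfg, generate_ontology(cfg))

    def test_ground_truth_matches_config(self):
        cfg = small_cfg(seed=10)
        tables = generate_study(cfg, generate_ontology(cfg))
        assert tables.params["coefficients"] == cfg.coefficients
        assert tables.params["target_match_rate"] == cfg.base_match_rate
        assert len(tables.truth) == tables.params["n_pairs"]
        assert set(tables.truth["is_match"].unique()) <= {0, 1}

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=42, n_genes=123, base_match_rate=0.4)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        again = SimConfig.from_yaml(path)
        assert again == cfg


class TestPlantedEnrichment:
    def _gene_level(self, tables):
        import pandas as pd

        gene_match = tables.truth.groupby("human_gene")["is_match"].max()
        genes = pd.DataFrame(
            {"human_gene": gene_match.index, "is_match": gene_match.to_numpy()}
        )
        diseases = pd.DataFrame(
            {"human_gene": [d.human_gene for d in tables.diseases],
             "category": [d.category for d in tables.diseases]}
        )
        return category_enrichment(gene_category_table(genes, diseases))

    def test_enriched_category_detected_and_nulls_quiet(self):
        # detection at the default study size under the 3x planting; false
        # flags under a configuration where every category multiplier is 1
        # (the one-vs-rest odds ratio of a multiplier-1 category is only
        # null in that case).  Fewer seeds than the acceptance run, which
        # repeats this over 50 seeds.
        n_seeds = 6
        layout = generate_ontology(SimConfig())
        detect = 0
        for seed in range(n_seeds):
            cfg = SimConfig(seed=1000 + seed, fraction_disease_associated=1.0,
                            p_external_model=0.0)
            tables = generate_study(cfg, layout)
            out = self._gene_level(tables).set_index("category")
            row = out.loc["endocrine"]
            detect += int(row.q_value < 0.05 and row.odds_ratio > 1)
        assert detect >= round(0.9 * n_seeds)

        false_flags = []
        for seed in range(n_seeds):
            cfg = SimConfig(seed=2000 + seed, fraction_disease_associated=1.0,
                            category_odds={}, p_external_model=0.0)
            tables = generate_study(cfg, layout)
            out = self._gene_level(tables)
            false_flags.append((out["q_value"] < 0.05).mean())
        assert np.mean(false_flags) <= 0.10
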