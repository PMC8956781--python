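import numpy as np
import pandas as pd
import pytest

from gaoscope import annotation
from gaoscope.attribution import attribute, genus_profile
from gaoscope.stoichiometry import ratios_from_cycle
from gaoscope.synthetic_data import (
    SyntheticConfig,
    build_taxonomy,
    generate_dataset,
    sibling_genus,
    simulate_community,
    simulate_cycle,
    simulate_expression,
    write_bundle,
)
from gaoscope.taxonomy import TaxonomyTree, load_taxonomy


def _true_genus(config: SyntheticConfig, unigene_id: str) -> str:
    """Planted genus of a synthetic unigene, recovered from its id."""
    return next(g for g in config.genera() if unigene_id.startswith(f"UG_{g}_"))


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dominant_initial": 0.0},
            {"dominant_final": 1.2},
            {"y_phb": -1.0},
            {"depletion_minute": 120.0},
            {"read_depth": 0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestCommunity:
    def test_dominant_fraction_strictly_increasing(self):
        comp = simulate_community(SyntheticConfig(seed=3))
        dom = comp.loc["Ca_Contendobacter"]
        assert (dom.diff().dropna() > 0).all()

    def test_planted_endpoints_hit_exactly(self):
        cfg = SyntheticConfig(seed=3)
        comp = simulate_community(cfg)
        assert comp.loc[cfg.dominant_genus, "day_1"] == pytest.approx(0.026)
        assert comp.loc[cfg.dominant_genus, "day_75"] == pytest.approx(0.069)
        assert comp.loc[cfg.second_genus, "day_75"] == pytest.approx(0.020)

    def test_columns_sum_to_one(self):
        comp = simulate_community(SyntheticConfig(seed=5))
        assert np.allclose(comp.sum(axis=0), 1.0)

    def test_zero_noise_is_deterministic_background(self):
        cfg = SyntheticConfig(seed=1, community_noise=0.0)
        a = simulate_community(cfg, np.random.default_rng(1))
        b = simulate_community(cfg, np.random.default_rng(999))
        pd.testing.assert_frame_equal(a, b)

    def test_same_seed_identical(self):
        a = simulate_community(SyntheticConfig(seed=8))
        b = simulate_community(SyntheticConfig(seed=8))
        pd.testing.assert_frame_equal(a, b)


class TestMetagenome:
    def test_taxonomy_tree_is_valid_and_pairs_siblings(self):
        cfg = SyntheticConfig()
        tree = TaxonomyTree(build_taxonomy(cfg).values())
        assert "Ca_Contendobacter" in tree
        # the two GAO genera are siblings under one family
        assert sibling_genus(cfg, "Ca_Contendobacter") == "Ca_Competibacter"
        lca = tree.lca({"Ca_Contendobacter", "Ca_Competibacter"})
        assert tree.nodes[lca].rank == "family"

    def test_noiseless_taxonomy_fully_recovered(self, default_dataset):
        ds = default_dataset  # default config has zero taxonomy noise
        tree = ds.tree()
        hits = {}
        for hit in ds.tax_hits:
            hits.setdefault(hit.query_id, []).append(hit)
        assigned = annotation.assign_taxonomy(hits, tree, ds.subject_to_taxon)
        for uid, taxon in assigned.items():
            assert taxon == _true_genus(ds.config, uid), uid

    def test_sibling_noise_drives_lca_to_family(self):
        cfg = SyntheticConfig(seed=2, taxonomy_noise=1.0)
        ds = generate_dataset(cfg)
        tree = ds.tree()
        hits = {}
        for hit in ds.tax_hits:
            hits.setdefault(hit.query_id, []).append(hit)
        assigned = annotation.assign_taxonomy(hits, tree, ds.subject_to_taxon)
        ranks = {tree.nodes[t].rank for t in assigned.values()}
        assert ranks == {"family"}

    def test_profile_error_shrinks_with_depth(self):
        errors = {}
        for depth in (2_000, 500_000):
            cfg = SyntheticConfig(seed=4, read_depth=depth)
            ds = generate_dataset(cfg)
            tree = ds.tree()
            ab = annotation.compute_abundance(ds.counts, ds.lengths)
            ann = annotation.UnigeneAnnotations(
                assignments=pd.DataFrame(
                    {"taxon_id": [_true_genus(cfg, u) for u in ab.index],
                     "ko_id": annotation.UNASSIGNED, "length": 1.0},
                    index=ab.index,
                ),
                abundance=ab,
            )
            profile = genus_profile(ann, tree).reindex(ds.composition.index)
            errors[depth] = float(
                (profile - ds.composition).abs().to_numpy().sum()
            )
        assert errors[500_000] < errors[2_000]


class TestCycle:
    def test_acetate_zero_at_depletion(self):
        cfg = SyntheticConfig(noise_sd=0.0)
        cycle = simulate_cycle(cfg)
        at_depletion = cycle[(cycle.phase == "anaerobic")
                             & (cycle.time_min >= cfg.depletion_minute)]
        assert (at_depletion.acetate_mg_L == 0).all()

    def test_phosphate_flat_and_p_per_vfa_zero(self):
        cfg = SyntheticConfig(noise_sd=0.0)
        ratios = ratios_from_cycle(simulate_cycle(cfg), cfg.mlss_g_L)
        assert ratios.p_per_vfa == 0.0

    def test_zero_noise_recovers_yields_exactly(self):
        cfg = SyntheticConfig(noise_sd=0.0)
        ratios = ratios_from_cycle(simulate_cycle(cfg), cfg.mlss_g_L)
        assert ratios.gly_per_vfa == pytest.approx(cfg.y_gly, rel=1e-9)
        assert ratios.phb_per_vfa == pytest.approx(cfg.y_phb, rel=1e-9)
        assert ratios.phv_per_vfa == pytest.approx(cfg.y_phv, rel=1e-9)
        assert round(ratios.phv_per_phb, 2) == 0.22

    def test_configured_phv_phb_ratio_propagates(self):
        cfg = SyntheticConfig(noise_sd=0.0, y_phb=1.0, y_phv=0.22)
        ratios = ratios_from_cycle(simulate_cycle(cfg), cfg.mlss_g_L)
        assert ratios.phv_per_phb == pytest.approx(0.22)

    def test_concentrations_never_negative(self):
        cycle = simulate_cycle(SyntheticConfig(seed=6, noise_sd=0.3))
        assert (cycle.iloc[:, 2:] >= 0).all().all()


class TestExpression:
    def test_planted_tiers_at_zero_noise(self):
        from gaoscope.expression import fold_change

        cfg = SyntheticConfig(expression_noise_sd=0.0)
        series = simulate_expression(cfg)
        final_tier = {g: fold_change(s).tier.iloc[-1] for g, s in series.items()}
        assert all(final_tier[g] == "gt4" for g in ("ccr", "mcd", "mch"))
        assert all(final_tier[g] == "gt2" for g in ("ecm", "mcl"))
        assert all(final_tier[g] == "down_or_flat" for g in ("phbB", "phaJ"))

    def test_baseline_fold_is_one(self):
        from gaoscope.expression import fold_change

        series = simulate_expression(SyntheticConfig(seed=2))
        for s in series.values():
            assert fold_change(s).fold_change.iloc[0] == 1.0


class TestBundle:
    def test_roundtrip_through_readers(self, default_dataset, default_bundle):
        paths = default_bundle
        tree = load_taxonomy(paths["taxonomy"])
        assert tree.nodes == default_dataset.taxonomy_nodes
        hits = annotation.read_hit_table(paths["tax_hits"])
        assert sum(len(v) for v in hits.values()) == len(default_dataset.tax_hits)
        counts = annotation.read_counts_table(paths["counts"])
        pd.testing.assert_frame_equal(
            counts, default_dataset.counts, check_names=False
        )
        lengths = annotation.read_lengths_table(paths["lengths"])
        assert (lengths == default_dataset.lengths).all()

    def test_end_to_end_determinism_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_bundle(generate_dataset(SyntheticConfig(seed=13)), d1)
        p2 = write_bundle(generate_dataset(SyntheticConfig(seed=13)), d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seeds_differ(self, tmp_path):
        p1 = write_bundle(generate_dataset(SyntheticConfig(seed=1)), tmp_path / "a")
        p2 = write_bundle(generate_dataset(SyntheticConfig(seed=2)), tmp_path / "b")
        assert p1["counts"].read_bytes() != p2["counts"].read_bytes()
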