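"""Synthetic Dollo-model generator: determinism, degenerate regimes,
ground-truth identifiability and fixture round-trips."""

import filecmp

import numpy as np
import pandas as pd
import pytest

import dollostrat as ds
from dollostrat.simulate import SimulationError


class TestSimulateTree:
    def test_caterpillar_shape(self):
        t = ds.simulate_tree(ds.SimulationConfig(n_leaves=4, topology="caterpillar"))
        assert t.to_newick() == "(((S1,S2),S3),S4);"

    def test_random_mode_deterministic(self):
        cfg = ds.SimulationConfig(n_leaves=15, seed=42)
        assert ds.simulate_tree(cfg).to_newick() == ds.simulate_tree(cfg).to_newick()

    def test_too_few_leaves(self):
        with pytest.raises(SimulationError):
            ds.simulate_tree(ds.SimulationConfig(n_leaves=1))

    def test_user_newick_topology(self):
        t = ds.simulate_tree(ds.SimulationConfig(n_leaves=3, topology="((X,Y),Z);"))
        assert set(t.leaf_names) == {"X", "Y", "Z"}


class TestSimulateFamilies:
    def test_zero_loss_keeps_whole_clade(self):
        cfg = ds.SimulationConfig(n_leaves=10, n_families=40, loss_prob=0.0, seed=1)
        tree = ds.simulate_tree(cfg)
        fams, truth = ds.simulate_families(tree, cfg)
        for row in truth.families.itertuples():
            expected = tree.subtree_leaf_names(row.gain_node_id)
            assert set(row.species.split(",")) == set(expected)

    def test_root_gains_without_loss_recover_ps1(self):
        weights = None
        cfg = ds.SimulationConfig(n_leaves=8, n_families=25, loss_prob=0.0, seed=3)
        tree = ds.simulate_tree(cfg)
        weights = np.zeros(tree.n_nodes)
        weights[tree.root] = 1.0
        cfg = ds.SimulationConfig(
            n_leaves=8, n_families=25, loss_prob=0.0, seed=3, gain_weights=tuple(weights)
        )
        fams, _ = ds.simulate_families(tree, cfg)
        events = ds.lineage_events(fams, tree, tree.leaf_names[0])
        assert (events.events.gain_ps == 1).all()
        assert events.events.loss_ps.isna().all()

    def test_family_count_exact_and_survivors_consistent(self):
        cfg = ds.SimulationConfig(n_leaves=12, n_families=80, loss_prob=0.3, seed=7)
        tree = ds.simulate_tree(cfg)
        fams, truth = ds.simulate_families(tree, cfg)
        assert fams.n_families == 80
        assert len(truth.families) == 80
        for row in truth.families.itertuples():
            survivors = set(row.species.split(","))
            gain_clade = tree.subtree_leaf_names(row.gain_node_id)
            assert survivors <= set(gain_clade)
            lost = {int(c) for c in row.loss_branch_child_ids.split(",") if c}
            for c in lost:
                assert not survivors & set(tree.subtree_leaf_names(c))

    def test_dollo_identifiability_against_ground_truth(self):
        cfg = ds.SimulationConfig(n_leaves=8, n_families=200, loss_prob=0.15, seed=7)
        tree = ds.simulate_tree(cfg)
        fams, truth = ds.simulate_families(tree, cfg)
        focal = tree.leaf_names[0]
        lineage = ds.focal_lineage(tree, focal)
        n_identifiable = 0
        for row in truth.families.itertuples():
            species = set(row.species.split(","))
            lca = tree.lca(species)
            inferred = ds.gain_node(tree, fams.species_set(row.family_id))
            if lca == row.gain_node_id:
                # survivors still witness the true gain node: exact recovery
                assert inferred == row.gain_node_id
                n_identifiable += 1
            else:
                # survivors confined below: Dollo returns the shallower LCA
                assert tree.is_ancestor_or_equal(row.gain_node_id, inferred)
            gain_ps = lineage.node_to_ps(inferred)
            if gain_ps is not None:
                loss_ps = ds.infer_loss(tree, lineage, species, gain_ps)
                assert (loss_ps is None) == (focal in species)
        assert n_identifiable > 0

    def test_paralog_counts_at_least_one(self):
        cfg = ds.SimulationConfig(n_leaves=6, n_families=30, paralog_mean=2.0, seed=5)
        tree = ds.simulate_tree(cfg)
        fams, _ = ds.simulate_families(tree, cfg)
        for fam in fams.family_ids:
            per_species: dict[str, int] = {}
            for p in fams.proteins(fam):
                sp = fams.species_of[p]
                per_species[sp] = per_species.get(sp, 0) + 1
            assert all(c >= 1 for c in per_species.values())


class TestPlantAnnotations:
    def _setup(self, planted, seed=2, **kw):
        cfg = ds.SimulationConfig(
            n_leaves=10, n_families=60, loss_prob=0.1, planted=planted, seed=seed, **kw
        )
        tree = ds.simulate_tree(cfg)
        fams, _ = ds.simulate_families(tree, cfg)
        fams = ds.drop_terminal_singletons(fams)
        events = ds.lineage_events(fams, tree, tree.leaf_names[0])
        return cfg, tree, fams, events

    def test_deterministic_plant_coincides_with_gain_set(self):
        planted = (ds.PlantedTerm("P", 1, 1.0, 0.0),)
        cfg, tree, fams, events = self._setup(planted)
        prot_terms = ds.plant_annotations(fams, events, cfg)
        ann = ds.transfer_annotations(fams, prot_terms, mode="any")
        gained_ps1 = set(events.events[events.events.gain_ps == 1].family_id)
        carriers = {f for f in fams.family_ids if "P" in ann.family_terms[f]}
        assert carriers == gained_ps1

    def test_null_plant_has_no_signal_structure(self):
        planted = (ds.PlantedTerm("P", 2, 0.3, 0.3),)
        cfg, tree, fams, events = self._setup(planted, background_rate=0.0, n_terms=1)
        prot_terms = ds.plant_annotations(fams, events, cfg)
        # same rate inside and outside the planted stratum: term is a null term
        rates = {f: "P" in prot_terms[fams.proteins(f)[0]] for f in fams.family_ids}
        assert 0 < sum(rates.values()) < len(rates)

    def test_out_of_range_ps_rejected(self):
        planted = (ds.PlantedTerm("P", 99, 0.8, 0.1),)
        cfg, tree, fams, events = self._setup(())
        bad_cfg = ds.SimulationConfig(n_leaves=10, planted=planted, seed=2)
        with pytest.raises(SimulationError):
            ds.plant_annotations(fams, events, bad_cfg)


class TestFixtureBundle:
    def _bundle(self, tmp_path, seed=6, sub="a"):
        cfg = ds.SimulationConfig(n_leaves=10, n_families=50, loss_prob=0.1, seed=seed)
        tree = ds.simulate_tree(cfg)
        fams, truth = ds.simulate_families(tree, cfg)
        events = ds.lineage_events(ds.drop_terminal_singletons(fams), tree, tree.leaf_names[0])
        ann = ds.plant_annotations(fams, events, cfg)
        return ds.write_fixture_bundle(tree, fams, ann, tmp_path / sub, truth), fams, tree

    def test_round_trip_partition_identity(self, tmp_path):
        paths, fams, tree = self._bundle(tmp_path)
        mm = ds.read_mmseqs_clusters(paths["mmseqs"])
        mcl = ds.read_mcl_clusters(paths["mcl"])
        original = {frozenset(p) for p in fams.members.values()}
        assert {frozenset(p) for p in mm.members.values()} == original
        assert {frozenset(p) for p in mcl.members.values()} == original
        back = ds.parse_newick(paths["tree"].read_text())
        assert back.to_newick() == tree.to_newick()

    def test_species_map_round_trip(self, tmp_path):
        paths, fams, _ = self._bundle(tmp_path)
        mapping = ds.read_species_map(paths["species_map"])
        assert mapping == fams.species_of

    def test_ground_truth_row_count(self, tmp_path):
        paths, fams, _ = self._bundle(tmp_path)
        truth = pd.read_csv(paths["ground_truth"], sep="\t")
        assert len(truth) == fams.n_families

    def test_byte_identical_bundles_for_same_seed(self, tmp_path):
        paths1, _, _ = self._bundle(tmp_path, seed=6, sub="one")
        paths2, _, _ = self._bundle(tmp_path, seed=6, sub="two")
        for key in paths1:
            assert filecmp.cmp(paths1[key], paths2[key], shallow=False), key
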