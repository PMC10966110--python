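import pytest

import dollostrat as ds


@pytest.fixture
def abc_tree():
    """((A,B),C); — node ids: 0 root, 1 AB, 2 A, 3 B, 4 C."""
    return ds.parse_newick("((A,B),C);")


@pytest.fixture
def six_leaf_tree():
    """(((A,B),(C,D)),(E,F));"""
    return ds.parse_newick("(((A,B),(C,D)),(E,F));")


@pytest.fixture
def family_factory():
    """Build a species-attached FamilyTable from family -> species multisets.

    Repeated species denote paralogs; protein ids follow the
    ``species|family|index`` convention so prefix attachment applies.
    """

    def build(spec: dict[str, list[str]], known_species=None) -> ds.FamilyTable:
        members = {}
        for fam, species_list in spec.items():
            counts: dict[str, int] = {}
            prots = []
            for sp in species_list:
                counts[sp] = counts.get(sp, 0) + 1
                prots.append(f"{sp}|{fam}|{counts[sp]}")
            members[fam] = tuple(prots)
        fams = ds.FamilyTable(members=members)
        return ds.attach_species(fams, convention="prefix", known_species=known_species)

    return build


@pytest.fixture
def simulated_run():
    """A seeded mid-sized simulation with events inferred for one focal leaf."""

    def build(seed=11, n_leaves=12, n_families=120, loss_prob=0.15, topology="bifurcating"):
        config = ds.SimulationConfig(
            n_leaves=n_leaves,
            topology=topology,
            n_families=n_families,
            loss_prob=loss_prob,
            seed=seed,
        )
        tree = ds.simulate_tree(config)
        fams, truth = ds.simulate_families(tree, config)
        fams = ds.drop_terminal_singletons(fams)
        focal = tree.leaf_names[0]
        lineage = ds.focal_lineage(tree, focal)
        events = ds.lineage_events(fams, tree, lineage)
        return tree, fams, truth, lineage, events

    return build
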