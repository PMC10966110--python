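"""Generate the synthetic study inputs: one species tree, three family
partitions at increasing coverage stringency, species maps and term
annotations with two planted term-phylostratum signals.

Writes one fixture bundle per coverage label under results/synthetic/.
"""

import numpy as np

import dollostrat as ds
from _common import C_LABELS, LOSS_PROB, N_FAMILIES, N_LEAVES, SEED, bundle_dir, focal_species, study_tree


def main():
    tree = study_tree()
    focals = focal_species(tree)
    primary = focals[0]
    lineage = ds.focal_lineage(tree, primary)
    planted_ps = (2, min(6, lineage.n_strata - 2))
    print(f"tree: {tree.n_leaves} leaves, focal species {focals}")
    print(f"primary lineage {primary}: {lineage.n_strata} phylostrata; "
          f"planting enrichment signals at ps{planted_ps[0]} and ps{planted_ps[1]}")

    # concentrate half the gain mass on the primary path: family birth in
    # real data clusters on deep, widely shared nodes, and it gives every
    # phylostratum of the primary lineage a workable sample size
    weights = np.full(tree.n_nodes, 0.5 / tree.n_nodes)
    for node in lineage.path:
        weights[node] += 0.5 / len(lineage.path)
    weights /= weights.sum()

    for i, c in enumerate(C_LABELS):
        config = ds.SimulationConfig(
            n_leaves=N_LEAVES,
            n_families=N_FAMILIES[c],
            loss_prob=LOSS_PROB,
            paralog_mean=1.5,
            n_terms=20,
            background_rate=0.08,
            gain_weights=tuple(weights),
            planted=(
                ds.PlantedTerm("P_early", planted_ps[0], 0.7, 0.08),
                ds.PlantedTerm("P_mid", planted_ps[1], 0.7, 0.08),
            ),
            seed=SEED,
        )
        rng = np.random.default_rng(SEED * 100 + i)
        fams, truth = ds.simulate_families(tree, config, rng=rng)
        events = ds.lineage_events(ds.drop_terminal_singletons(fams), tree, lineage)
        ann = ds.plant_annotations(fams, events, config, rng=rng)
        paths = ds.write_fixture_bundle(tree, fams, ann, bundle_dir(c), truth)
        print(f"c={c}: {fams.n_families} families, {fams.n_proteins} proteins "
              f"-> {paths['mmseqs'].parent}")


if __name__ == "__main__":
    main()
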