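"""Shared study design for the numbered analysis scripts.

One simulated species tree (the stand-in for a literature consensus
phylogeny) is clustered at three alignment-coverage stringencies; stringent
coverage splits remote homologs, so the family count grows with the c
label.  Four focal species — the deepest leaf plus three others spread over
the tree — play the role of the study's focal lineages.
"""

from pathlib import Path

import dollostrat as ds

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SYNTH = RESULTS / "synthetic"
RUNS = RESULTS / "runs"

SEED = 1
N_LEAVES = 32
C_LABELS = ["0.0", "0.4", "0.8"]
#: families per coverage label: finer partitions under stringent coverage
N_FAMILIES = {"0.0": 200, "0.4": 300, "0.8": 400}
LOSS_PROB = 0.15


def study_tree() -> ds.Phylogeny:
    return ds.simulate_tree(ds.SimulationConfig(n_leaves=N_LEAVES, seed=SEED))


def focal_species(tree: ds.Phylogeny) -> list[str]:
    """Four focal leaves: the deepest one plus three spread across the tree."""
    by_depth = sorted(tree.leaf_names, key=lambda n: -tree.depth(tree.leaf_id(n)))
    picks = [by_depth[0]]
    for name in by_depth[len(by_depth) // 3 :: max(1, len(by_depth) // 3)]:
        if name not in picks:
            picks.append(name)
        if len(picks) == 4:
            break
    return picks


def bundle_dir(c_label: str) -> Path:
    return SYNTH / f"c_{c_label}"


def run_dir(c_label: str) -> Path:
    return RUNS / f"c_{c_label}"


def run_config(c_label: str, **overrides) -> ds.RunConfig:
    b = bundle_dir(c_label)
    kw = dict(
        tree=b / "tree.nwk",
        clusters=((c_label, b / "clusters.mmseqs.tsv", "mmseqs"),),
        out_dir=run_dir(c_label),
        focal=tuple(focal_species(study_tree())),
        species_map=b / "species_map.tsv",
        annotations=b / "annotations.tsv",
        seed=SEED,
    )
    kw.update(overrides)
    return ds.RunConfig(**kw)
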