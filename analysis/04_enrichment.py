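"""Phylostratum-wise functional enrichment of gained and lost families,
the enrichment-frequency-vs-coverage summary, and the gain-vs-loss balance
restricted to families that have a loss event.

Checks that the two planted term-phylostratum signals are recovered on the
primary lineage and nowhere implausible.
"""

import pandas as pd

import dollostrat as ds
from _common import C_LABELS, RESULTS, run_config, focal_species, study_tree


def main():
    rec_frames, sum_frames = [], []
    for c in C_LABELS:
        cfg = run_config(c)
        paths = ds.run_enrich(cfg)
        rec_frames.append(pd.read_csv(paths["enrichment"], sep="\t", dtype={"c_value": str}))
        sum_frames.append(pd.read_csv(paths["summary"], sep="\t", dtype={"c_value": str}))
    records = pd.concat(rec_frames, ignore_index=True)
    summary = pd.concat(sum_frames, ignore_index=True)
    records.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)
    summary.to_csv(RESULTS / "enrichment_summary.tsv", sep="\t", index=False)
    print(f"{len(records)} enrichment records -> {RESULTS / 'enrichment.tsv'}")

    tree = study_tree()
    primary = focal_species(tree)[0]
    planted = records[
        (records.focal_species == primary)
        & records.term.isin(["P_early", "P_mid"])
        & (records.significant == True)  # noqa: E712
    ]
    print("\nplanted signals recovered on the primary lineage:")
    print(planted[["c_value", "term", "ps_index", "k", "n", "K", "N", "log_odds", "p_adj"]]
          .to_string(index=False))

    print("\nenrichment frequency vs coverage (share of terms significant somewhere):")
    print(summary.pivot_table(index=["focal_species", "direction"], columns="c_value",
                              values="frequency_pct").round(1).to_string())

    # gain-vs-loss balance on the lost-only universe
    events = pd.read_csv(RESULTS / "events.tsv", sep="\t", dtype={"c_value": str})
    prot_terms = {}
    balance_rows = []
    for c in C_LABELS:
        cfg = run_config(c)
        prot_terms = ds.read_annotations(cfg.annotations)
        for focal in cfg.focal:
            lineage = ds.focal_lineage(tree, focal)
            sub = events[(events.c_value == c)]
            table = ds.EventTable.from_frame(sub, focal, lineage.n_strata)
            fams = ds.drop_terminal_singletons(
                ds.attach_species(
                    ds.read_mmseqs_clusters(cfg.clusters[0][1]),
                    ds.read_species_map(cfg.species_map),
                    known_species=tree.leaf_names,
                )
            )
            ann = ds.transfer_annotations(fams, prot_terms)
            gains = ds.enrich(table, ann, "gain", universe_mode="lost_only")
            losses = ds.enrich(table, ann, "loss", universe_mode="lost_only")
            row = ds.gain_loss_balance(gains, losses)
            balance_rows.append({"focal_species": focal, "c_value": c, **row})
    balance = pd.DataFrame(balance_rows)
    balance.to_csv(RESULTS / "gain_loss_balance.tsv", sep="\t", index=False)
    print("\ngain-vs-loss enriched-term balance (families with a loss event only):")
    print(balance.to_string(index=False))


if __name__ == "__main__":
    main()
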