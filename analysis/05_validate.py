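"""Validation sweep: exhaustive small-tree checks of the Dollo closed form,
exact-test verification against integer enumeration, and the seeded
recovery / calibration / shape studies.

Writes results/validation.json; the same quantities are recomputed by
scripts/acceptance.py.
"""

import json

from _common import RESULTS
from dollostrat.exhaustive import (
    scan_hypergeom_exact,
    scan_loss_phylostrata,
    scan_oracle_agreement,
)
from dollostrat.studies import (
    burst_regime_study,
    conservation_study,
    null_calibration_study,
    planted_recovery_study,
)


def main():
    out = {}
    out["loss_scan"] = scan_loss_phylostrata((4, 5, 6), bifurcating_only=True)
    print(f"earliest loss over all bifurcating 4-6 leaf shapes/patterns: "
          f"ps{out['loss_scan']['min_loss_ps']} "
          f"({out['loss_scan']['n_bound_violations']} bound violations)")

    out["oracle"] = scan_oracle_agreement((2, 3, 4, 5, 6), bifurcating_only=False)
    print(f"LCA vs brute-force minimum-loss oracle: "
          f"{out['oracle']['n_disagreements']} disagreements over "
          f"{out['oracle']['n_patterns']} shape/pattern combinations")

    out["hypergeom"] = scan_hypergeom_exact(60)
    print(f"two-sided hypergeometric vs exact enumeration (N<=60): "
          f"max |error| {out['hypergeom']['max_abs_err']:.2e} over "
          f"{out['hypergeom']['n_tables']} tables")

    out["conservation"] = conservation_study(n_datasets=5, seed=1)
    print(f"gain-loss-content conservation: max residual "
          f"{out['conservation']['max_abs_residual']} over "
          f"{out['conservation']['n_lineages']} lineages")

    out["recovery"] = planted_recovery_study(n_replicates=100, seed=1)
    print(f"planted enrichment detected in {out['recovery']['detection_pct']:.0f}% "
          f"of replicates (min n at planted ps: {out['recovery']['min_n_at_planted_ps']})")

    out["null"] = null_calibration_study(n_replicates=100, seed=1)
    print(f"null significant fraction: {out['null']['significant_fraction_pct']:.3f}%")

    out["burst"] = burst_regime_study(n_replicates=100, seed=1)
    print(f"burst regime peaks before terminal ps in "
          f"{out['burst']['peak_before_terminal_pct']:.0f}% of replicates")

    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / "validation.json"
    path.write_text(json.dumps(out, default=float, indent=2) + "\n")
    print(f"-> {path}")


if __name__ == "__main__":
    main()
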