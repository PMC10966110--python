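# dollostrat

Dollo-parsimony phylostratigraphy of gene-family gain and loss on a rooted
species phylogeny.

Given (1) a rooted species tree, (2) homolog clusters ("gene families", e.g.
MMseqs2 or MCL output), (3) a protein→species map and (4) per-protein
functional annotations (COG categories or GO terms), the package:

* assigns every family a **gain phylostratum** on each focal lineage — the
  position of the family's last common ancestor on the root→species path —
  and, where the focal species no longer carries the family, a **loss
  phylostratum**, under Dollo parsimony (a family originates exactly once
  and can only be lost afterwards);
* reconstructs **gene-family content profiles**: cumulative family counts
  per phylostratum along a lineage, per-node ancestral content for the whole
  tree, and log2 gain/loss ratio profiles;
* tests **phylostratum-wise functional enrichment** of gained and lost
  families with an exact two-tailed hypergeometric test (minimum-likelihood
  convention), log2 odds-ratio effect sizes (Haldane–Anscombe corrected) and
  Benjamini–Hochberg control, plus enrichment-frequency and gain-vs-loss
  balance summaries;
* ships a **synthetic-data generator** that simulates Dollo-compatible
  family evolution with planted term–phylostratum enrichment, so the whole
  pipeline is testable without any genome download.

It is aimed at comparative genomicists tracing genome-content macroevolution
— when in a lineage's history gene families appeared, when they were lost,
and which functions those pulses carry.

## The model

Phylostrata ps1..psN are the internodes of the root→focal-species path:
ps1 is the root (ancestor of cellular organisms in a tree of life), psN the
focal species itself. For a family F with species set S(F):

* gain node g(F) = LCA(S(F)); the gain phylostratum is the path position of
  g(F), or the family never existed on that lineage if g(F) is off the path;
* F is *present* at node v iff g(F) is ancestor-or-equal of v and the
  subtree of v still contains a member of S(F);
* the loss phylostratum is the first path position where presence switches
  off; structurally, a loss can occur no earlier than ps3 and no earlier
  than two phylostrata after the gain. A gain at ps k followed immediately
  by a loss at ps k+1 (possible only at polytomies) means the family belongs
  to a side branch and is excluded from that lineage;
* species-specific clusters with fewer than two member proteins are dropped
  (terminal singleton filter);
* content obeys content_i = content_{i−1} + gains_i − losses_i, and the
  enrichment of term t among families gained (or lost) at ps i is judged
  against the lineage-wide universe with the exact test
  P = Σ { Pr(x) : Pr(x) ≤ Pr(k) } of the hypergeometric pmf with parameters
  (N, K, n).

## Worked example

```python
import dollostrat as ds

tree = ds.parse_newick("(((A,B),(C,D)),(E,F));")
lineage = ds.focal_lineage(tree, "A")          # ps1=root .. ps4=A

# a family found in C and E: gained at the root, lost before the AB ancestor
print(ds.infer_gain(tree, lineage, {"C", "E"}))       # 1
print(ds.infer_loss(tree, lineage, {"C", "E"}, 1))    # 3

# exact two-tailed test of a 4-of-5 vs 4-of-10 contingency
print(ds.hypergeom_two_sided(k=4, K=4, n=5, N=10))    # 0.047619047619047616
print(ds.log_odds(k=4, K=4, n=5, N=10))               # 5.044394119358453
```

The family `{C,E}` is gained at ps1 and lost at ps3: it is present at the
root and at the ABCD ancestor (through C) but absent from the AB ancestor.
The test value 0.047619 = 12/252 sums the two outcomes (x = 0 and x = 4)
that are no more likely than the observed table; the log-odds 5.04 is
log2(4.5·5.5 / (0.5·1.5)) after adding 0.5 to each cell.

## The analysis

`analysis/` holds the numbered drivers of the synthetic study (a 32-leaf
tree, three coverage stringencies c ∈ {0.0, 0.4, 0.8}, four focal species,
two planted enrichment signals):

```sh
cd analysis
python 01_simulate.py          # fixture bundles under results/synthetic/
python 02_infer_events.py      # Dollo events        -> results/events.tsv
python 03_content_profiles.py  # content + ratios    -> results/profiles.tsv
python 04_enrichment.py        # enrichment tables   -> results/enrichment.tsv
python 05_validate.py          # exhaustive checks   -> results/validation.json
```

On this synthetic study the drivers report, among other things, that the
earliest observed loss phylostratum is 3, that most (focal, c) content
profiles peak strictly before the terminal phylostratum (the
increase-peak-decrease shape), and that the planted term `P_mid` at ps6 of
the primary lineage is recovered at every coverage setting (e.g. at c = 0.8:
k = 13 of n = 18 families gained at ps6 carry it, against K = 27 of N = 176
in the universe, adjusted p ≈ 1e-06) — with the share of significantly
enriched terms growing with coverage stringency.

The same machinery is scriptable on real inputs through the CLI:

```sh
dollostrat infer --tree tree.nwk \
    --clusters 0.8:mmseqs:clusters.tsv \
    --species-map species.tsv --focal "Homo sapiens" --out-dir out/
```

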