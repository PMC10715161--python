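#!/usr/bin/env python
"""Diversity and ordination contrasts between enterotypes.

Alpha diversity (Shannon, Chao1) on the rarefied table, Bray-Curtis
PCoA, and a PERMANOVA of community structure between the discovered
enterotypes.
"""

import json
from pathlib import Path

import pandas as pd

from enteroeco import diversity as div
from enteroeco import groupstats as gs
from enteroeco import io as eio

SEED = 20230901
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "diversity"
    out.mkdir(parents=True, exist_ok=True)
    table = eio.read_feature_table(ROOT / "data" / "bacterial_like_counts.tsv")
    assignments = pd.read_csv(
        ROOT / "enterotype" / "bacterial_like_assignments.tsv",
        sep="\t", index_col=0)["enterotype"]

    alpha = div.alpha_diversity(table)
    alpha.to_csv(out / "alpha.tsv", sep="\t")
    shannon_res = gs.compare_groups(alpha["shannon"], assignments)
    print(f"Shannon by enterotype: {shannon_res.method} statistic = "
          f"{shannon_res.statistic:.2f}, p = {shannon_res.p_value:.3g}")

    bc = div.bray_curtis_matrix(table)
    ordination = div.pcoa(bc, n_axes=5)
    ordination.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t",
                                  index_label="sample_id")
    pct = 100 * ordination.proportion_explained[:2]
    print(f"PCoA: first two axes explain {pct[0]:.1f}% and {pct[1]:.1f}% "
          "of the embedded variance")

    perma = div.permanova(bc, assignments, n_perm=999, seed=SEED)
    with open(out / "permanova.json", "w") as fh:
        json.dump(perma.to_dict(), fh, indent=2, sort_keys=True)
    print(f"PERMANOVA between enterotypes: pseudo-F = {perma.statistic:.2f}, "
          f"R^2 = {perma.effect_size:.3f}, p = {perma.p_value:.3g}")


if __name__ == "__main__":
    main()
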