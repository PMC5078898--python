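#!/usr/bin/env python
"""Differential expression with Storey q-values, scored against truth."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import CONFIG, DATA_DIR, RESULTS  # noqa: E402

from dipseq.pipeline import stage_diff_expr  # noqa: E402


def main():
    out = RESULTS / "diff_expr"
    stage_diff_expr(CONFIG, DATA_DIR, out)
    res = pd.read_csv(out / "expression.tsv", sep="\t", index_col="gene_id")
    truth = pd.read_csv(DATA_DIR / "truth_de_genes.tsv", sep="\t")
    de = set(truth["gene_id"])
    sig = res["storey_q"] < CONFIG.expression_q_threshold
    tp = sum(sig.get(g, False) for g in de)
    fp = int(sig.sum()) - tp
    print(f"{int(sig.sum())} genes at q < {CONFIG.expression_q_threshold}; "
          f"{tp}/{len(de)} planted DE genes recovered, {fp} false positives "
          f"(FDP {fp / max(int(sig.sum()), 1):.3f})")
    direction_ok = (res.loc[truth["gene_id"], "log2fc"].to_numpy()
                    * truth["log2fc"].to_numpy() > 0).mean()
    print(f"log2fc sign agrees with truth for {direction_ok:.0%} of DE genes")


if __name__ == "__main__":
    main()
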