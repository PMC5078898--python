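#!/usr/bin/env python
"""Merge enrichment territory, test 5-kb units, call DMRs, score vs truth.

Also reports the Venn-style overlap of DMR direction classes against the
annotatable gene universe.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import CONFIG, DATA_DIR, RESULTS  # noqa: E402

from dipseq import io  # noqa: E402
from dipseq.genome import GenomicInterval  # noqa: E402
from dipseq.pipeline import stage_diff_meth  # noqa: E402
from dipseq.scoring import score_dmr_recovery  # noqa: E402


def main():
    out = RESULTS / "diff_meth"
    outputs = stage_diff_meth(CONFIG, DATA_DIR, RESULTS / "segment", out)
    for name, n in outputs.items():
        print(f"  {name}: {n} rows")

    truth = pd.read_csv(DATA_DIR / "truth_dmrs.tsv", sep="\t")
    for assay in ("5mC", "5hmC"):
        dmrs = io.read_regions(out / f"dmrs_{assay}.tsv")
        sub = truth[truth["assay"] == assay]
        ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end))
               for r in sub.itertuples(index=False)]
        score = score_dmr_recovery(dmrs, ivs, list(sub["direction"]))
        print(f"{assay}: called {score['n_called']} DMRs; "
              f"sensitivity {score['sensitivity']:.2f} vs {len(ivs)} planted, "
              f"empirical FDR {score['fdr']:.3f}")


if __name__ == "__main__":
    main()
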