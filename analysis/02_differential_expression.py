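"""Dual-context differential expression between MTC and non-MTC.

Runs the two-group NB Wald test separately in the FNAB and tissue contexts
and reports how many genes clear the feature-selection thresholds in both —
the guard against FNAB-specific artifacts.
"""

import pandas as pd

from _config import RESULTS, RUN_DIR, get_config
from mtcseq.diffexp import dual_context_de
from mtcseq.pipeline import Manifest, stage_de


def main() -> None:
    cfg = get_config()
    stage_de(cfg, RUN_DIR, Manifest(RUN_DIR))

    det = pd.read_csv(RUN_DIR / "de_table.tsv", sep="\t")
    strict = dual_context_de(det, 1e-6)
    strict_fc = dual_context_de(det, 1e-6, fc_cut=6.0)
    loose = dual_context_de(det, 0.01)
    print(f"dual-context adj_p<1e-6:            {len(strict)} genes")
    print(f"dual-context adj_p<1e-6 & log2FC>6: {len(strict_fc)} genes")
    print(f"dual-context adj_p<0.01 (clustering pool): {len(loose)} genes")

    top = (det[det.context == "train_fnab"]
           .nsmallest(25, "adj_p")[["gene_id", "base_mean", "log2fc",
                                    "se", "adj_p"]])
    top.to_csv(RESULTS / "de_top_genes.tsv", sep="\t", index=False)
    print(f"\ntop FNAB genes -> {RESULTS / 'de_top_genes.tsv'}")


if __name__ == "__main__":
    main()
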