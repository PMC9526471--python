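"""The 16-setting model competition: 8 feature sets x {SVM, elastic net}
under 10x stratified 5-fold CV, then the four-criterion selection."""

import json
import shutil

import pandas as pd

from _config import RESULTS, RUN_DIR, get_config
from mtcseq.pipeline import Manifest, stage_cv, stage_select


def main() -> None:
    cfg = get_config()
    manifest = Manifest(RUN_DIR)
    stage_cv(cfg, RUN_DIR, manifest)
    stage_select(cfg, RUN_DIR, manifest)

    summary = pd.read_csv(RUN_DIR / "cv_summary.tsv", sep="\t")
    perfect = summary[(summary.mean_sensitivity == 1.0)
                      & (summary.mean_specificity == 1.0)]
    print(f"{len(perfect)}/{len(summary)} settings reached perfect CV "
          f"sensitivity and specificity")
    for name in ("cv_summary.tsv", "criteria.tsv", "selection.json",
                 "resubstitution.tsv"):
        shutil.copy(RUN_DIR / name, RESULTS / name)
    winner = json.loads((RUN_DIR / "selection.json").read_text())["winner"]
    print(f"selected model: feature set {winner['set_id']}, "
          f"{winner['family']}, {winner['n_genes']} genes")


if __name__ == "__main__":
    main()
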