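"""Build the eight candidate feature sets (each includes the 34-gene
mandatory cassette)."""

import pandas as pd

from _config import RESULTS, RUN_DIR, get_config
from mtcseq.pipeline import Manifest, stage_features


def main() -> None:
    cfg = get_config()
    stage_features(cfg, RUN_DIR, Manifest(RUN_DIR))

    frame = pd.read_csv(RUN_DIR / "feature_sets.tsv", sep="\t")
    sizes = frame.groupby("set_id").size().rename("n_genes").reset_index()
    sizes.to_csv(RESULTS / "feature_set_sizes.tsv", sep="\t", index=False)
    print(sizes.to_string(index=False))


if __name__ == "__main__":
    main()
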