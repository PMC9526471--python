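"""Freeze the selected model and validate it blindly.

The lock stage records the model's hash in the run manifest; validation
refuses to proceed unless that hash still matches, so the reported
confusion statistics provably come from a model untouched since locking.
"""

import shutil

from _config import RESULTS, RUN_DIR, get_config
from mtcseq.pipeline import Manifest, stage_lock, stage_validate


def main() -> None:
    cfg = get_config()
    manifest = Manifest(RUN_DIR)
    stage_lock(cfg, RUN_DIR, manifest)
    stage_validate(cfg, RUN_DIR, manifest)

    for name in ("validation_report.json", "validation_report.txt"):
        shutil.copy(RUN_DIR / name, RESULTS / name)
    print((RUN_DIR / "validation_report.txt").read_text().strip())


if __name__ == "__main__":
    main()
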