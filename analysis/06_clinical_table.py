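"""Clinical derivations from the packaged validation-cohort MTC table:
AJCC-8 staging under the cohort's missing-data conventions, plus the
demographic summary row."""

import json
import shutil

from _config import RESULTS, RUN_DIR, get_config
from mtcseq.pipeline import Manifest, stage_report, stage_stage


def main() -> None:
    cfg = get_config()
    manifest = Manifest(RUN_DIR)
    stage_stage(cfg, RUN_DIR, manifest)
    stage_report(cfg, RUN_DIR, manifest)

    shutil.copy(RUN_DIR / "clinical_summary.json",
                RESULTS / "clinical_summary.json")
    s = json.loads((RUN_DIR / "clinical_summary.json").read_text())
    print(f"n = {s['n']} validation MTC cases")
    print(f"age: median {s['age']['median']:.0f} "
          f"(range {s['age']['min']:.0f}-{s['age']['max']:.0f})")
    print(f"sex: {s['sex']}")
    print(f"Bethesda: {s['bethesda']}")
    print(f"calcitonin ng/L: median {s['calcitonin_ng_l']['median']:.0f} "
          f"(range {s['calcitonin_ng_l']['min']:.0f}-"
          f"{s['calcitonin_ng_l']['max']:.0f})")
    print(f"nodule size cm: median {s['size_cm']['median']:.2f}, "
          f"mean {s['size_cm']['mean']:.2f} "
          f"(range {s['size_cm']['min']:.1f}-{s['size_cm']['max']:.1f})")
    print(f"AJCC-8 stage ({s['stage_evaluable_n']} evaluable): {s['stage']}")


if __name__ == "__main__":
    main()
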