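"""Shared run configuration for the numbered analysis scripts.

Large intermediate artifacts (count matrices, full DE tables, per-fold CV
records) live under ``scratch/analysis/run``; each script copies its small
summary tables into ``results/``.
"""

from pathlib import Path

from mtcseq.pipeline import RunConfig

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "analysis" / "run"
RESULTS = ROOT / "results"

SEED = 17


def get_config() -> RunConfig:
    cfg = RunConfig(seed=SEED, outdir=str(RUN_DIR))
    cfg.sim.seed = SEED
    RESULTS.mkdir(exist_ok=True)
    return cfg
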