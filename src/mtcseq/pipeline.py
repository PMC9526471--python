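"""End-to-end pipeline driver: simulate -> DE -> feature sets -> CV ->
select/lock -> blind-validate -> report.

Every stage reads its inputs from and writes its outputs to a single
artifact directory, and appends to a ``manifest.json`` recording, in
execution order, each completed stage and the SHA-256 of every file it
wrote.  The manifest is the lock-before-validation guard: the ``validate``
stage refuses to run unless a ``lock`` stage completed earlier and the
locked model file still hashes to the value recorded at lock time — so the
model provably predates any contact with the validation cohort's labels.

A single root seed deterministically derives per-stage seeds, so a config
rerun reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, diffexp, feature_sets, io as mio, model_selection
from . import clinical, simulate, validation_stats

ALL_STAGES = ("simulate", "de", "features", "cv", "select", "lock",
              "validate", "stage", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "pipeline_out"
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    cv_folds: int = 5
    cv_repeats: int = 10
    de_p_strict: float = 1e-6
    de_fc_cut: float = 6.0
    stages: tuple = ALL_STAGES

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000003 + ALL_STAGES.index(stage) + 1) % (2**31 - 1)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["sim"]["cohort_sizes"] = {
            k: list(v) for k, v in self.sim.cohort_sizes.items()}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim_d = d.pop("sim", {})
        if "cohort_sizes" in sim_d:
            sim_d["cohort_sizes"] = {
                k: tuple(v) for k, v in sim_d["cohort_sizes"].items()}
        for key in ("signature_log2fc_range", "libsize_lognormal_params",
                    "dispersion_gamma_params"):
            if key in sim_d:
                sim_d[key] = tuple(sim_d[key])
        stages = tuple(d.pop("stages", ALL_STAGES))
        return cls(sim=simulate.SimConfig(**sim_d), stages=stages, **d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Manifest:
    """Ordered record of completed stages and their artifact hashes."""

    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data = (json.loads(self.path.read_text())
                     if self.path.exists() else {"stages": []})

    def record(self, stage: str, files: list[Path]) -> None:
        self.data["stages"].append({
            "stage": stage,
            "order": len(self.data["stages"]),
            "files": {f.name: _sha256(f) for f in files},
        })
        self.path.write_text(json.dumps(self.data, indent=1))

    def find(self, stage: str) -> dict | None:
        hits = [s for s in self.data["stages"] if s["stage"] == stage]
        return hits[-1] if hits else None


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; returns the artifact dir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    manifest = Manifest(out)
    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise PipelineError(f"unknown stage {stage!r}")
        STAGE_FUNCS[stage](config, out, manifest)
    return out


# -- individual stages ----------------------------------------------------

def stage_simulate(config: RunConfig, out: Path, manifest: Manifest) -> None:
    cm = simulate.simulate_cohorts(config.sim)
    controls = simulate.simulate_controls(config.sim)
    params = simulate.gene_params(config.sim)
    files = [out / "counts.tsv", out / "samples.tsv",
             out / "controls_counts.tsv", out / "controls_samples.tsv",
             out / "mandatory_genes.txt"]
    mio.write_counts(cm, files[0], files[1])
    mio.write_counts(controls, files[2], files[3])
    mio.write_gene_list(params.cassette_genes, files[4])
    manifest.record("simulate", files)


def _load_cohorts(out: Path):
    cm = mio.read_counts(out / "counts.tsv", out / "samples.tsv")
    controls = mio.read_counts(out / "controls_counts.tsv",
                               out / "controls_samples.tsv")
    return cm, controls


def stage_de(config: RunConfig, out: Path, manifest: Manifest) -> None:
    cm, _ = _load_cohorts(out)
    train_and_tissue = cm.select_samples(
        cm.sample_meta["cohort"].isin(["train_fnab", "tissue"]).to_numpy())
    detable = diffexp.dual_context_table(train_and_tissue)
    detable.to_csv(out / "de_table.tsv", sep="\t", index=False)
    manifest.record("de", [out / "de_table.tsv"])


def stage_features(config: RunConfig, out: Path, manifest: Manifest) -> None:
    cm, _ = _load_cohorts(out)
    detable = pd.read_csv(out / "de_table.tsv", sep="\t")
    mandatory = mio.read_gene_list(out / "mandatory_genes.txt")
    sets = feature_sets.build_all_sets(detable, cm, mandatory)
    feature_sets.feature_sets_frame(sets).to_csv(
        out / "feature_sets.tsv", sep="\t", index=False)
    manifest.record("features", [out / "feature_sets.tsv"])


def _load_feature_sets(out: Path) -> list[feature_sets.CandidateFeatureSet]:
    frame = pd.read_csv(out / "feature_sets.tsv", sep="\t")
    mandatory = mio.read_gene_list(out / "mandatory_genes.txt")
    sets = []
    for sid, grp in frame.groupby("set_id", sort=True):
        sets.append(feature_sets.CandidateFeatureSet(
            set_id=int(sid), rule=f"set {sid} (from artifact)",
            genes=list(grp["gene_id"]), mandatory_genes=mandatory))
    return sets


def _settings(sets):
    return [(s, fam) for s in sets for fam in classify.FAMILIES]


def stage_cv(config: RunConfig, out: Path, manifest: Manifest) -> None:
    cm, _ = _load_cohorts(out)
    train = cm.cohort("train_fnab")
    sets = _load_feature_sets(out)
    report = model_selection.repeated_cv(
        train, _settings(sets), k=config.cv_folds,
        repeats=config.cv_repeats, seed=config.stage_seed("cv"))
    report.to_csv(out / "cv_report.tsv", sep="\t", index=False)
    model_selection.cv_summary(report).to_csv(
        out / "cv_summary.tsv", sep="\t", index=False)
    manifest.record("cv", [out / "cv_report.tsv", out / "cv_summary.tsv"])


def stage_select(config: RunConfig, out: Path, manifest: Manifest) -> None:
    cm, controls = _load_cohorts(out)
    train = cm.cohort("train_fnab")
    sets = _load_feature_sets(out)
    mandatory = mio.read_gene_list(out / "mandatory_genes.txt")
    core_cassette = mandatory[:5]
    summary = pd.read_csv(out / "cv_summary.tsv", sep="\t")

    ref = model_selection.reference_cassette_score(train, core_cassette)
    candidates, classifiers, resubstitution = [], {}, []
    for fset, family in _settings(sets):
        row = summary[(summary["set_id"] == fset.set_id)
                      & (summary["family"] == family)].iloc[0]
        clf = classify.train(train, fset.genes, family,
                             feature_set_id=fset.set_id,
                             seed=config.stage_seed("select"))
        sv = classify.predict(clf, train)
        tp, fn, tn, fp = validation_stats.confusion(sv, train.labels())
        resubstitution.append({
            "set_id": fset.set_id, "family": family,
            "resub_sensitivity": tp / (tp + fn),
            "resub_specificity": tn / (tn + fp)})
        # the competition is restricted to settings whose CV estimate tied
        # at perfect sensitivity and specificity
        if row["mean_sensitivity"] == 1.0 and row["mean_specificity"] == 1.0:
            crit = model_selection.compute_criteria(clf, train, controls, ref)
            candidates.append(crit)
            classifiers[(fset.set_id, family)] = clf
    if not candidates:
        raise PipelineError("no setting achieved perfect CV performance")
    winner, rank_table = model_selection.select_final(candidates)
    chosen = classifiers[(winner.set_id, winner.family)]
    mio.write_model(chosen, out / "model.json")
    pd.DataFrame(resubstitution).to_csv(out / "resubstitution.tsv",
                                        sep="\t", index=False)
    rank_table.to_csv(out / "criteria.tsv", sep="\t", index=False)
    (out / "selection.json").write_text(json.dumps({
        "winner": {"set_id": winner.set_id, "family": winner.family,
                   "n_genes": winner.n_genes},
        "rank_table": rank_table.to_dict(orient="records"),
    }, indent=1))
    manifest.record("select", [out / "model.json", out / "criteria.tsv",
                               out / "selection.json",
                               out / "resubstitution.tsv"])


def stage_lock(config: RunConfig, out: Path, manifest: Manifest) -> None:
    clf = mio.read_model(out / "model.json")
    clf.lock()
    mio.write_model(clf, out / "locked_model.json")
    manifest.record("lock", [out / "locked_model.json"])


def stage_validate(config: RunConfig, out: Path, manifest: Manifest) -> None:
    lock_entry = manifest.find("lock")
    if lock_entry is None:
        raise PipelineError(
            "ordering violation: validate requires a completed lock stage")
    recorded = lock_entry["files"]["locked_model.json"]
    current = _sha256(out / "locked_model.json")
    if recorded != current:
        raise PipelineError(
            "locked model was modified after locking (hash mismatch); "
            "refusing to validate")
    clf = mio.read_model(out / "locked_model.json")
    if not clf.locked:
        raise PipelineError("model is not locked")
    cm, _ = _load_cohorts(out)
    valid = cm.cohort("valid_fnab")
    sv = classify.predict(clf, valid)
    report = validation_stats.validation_report(sv, valid.labels())
    (out / "validation_report.json").write_text(
        json.dumps(report.to_dict(), indent=1))
    (out / "validation_report.txt").write_text(report.text() + "\n")
    scores = pd.DataFrame({"sample_id": sv.sample_ids, "score": sv.scores,
                           "call": sv.calls})
    scores.to_csv(out / "validation_scores.tsv", sep="\t", index=False)
    manifest.record("validate", [out / "validation_report.json",
                                 out / "validation_report.txt",
                                 out / "validation_scores.tsv"])


def stage_stage(config: RunConfig, out: Path, manifest: Manifest) -> None:
    """Clinical staging + demographic summary of the validation MTC table."""
    table = clinical.load_validation_mtc_table()
    summary = clinical.summarize_cohort(table)
    (out / "clinical_summary.json").write_text(json.dumps(summary, indent=1))
    manifest.record("stage", [out / "clinical_summary.json"])


def stage_report(config: RunConfig, out: Path, manifest: Manifest) -> None:
    report = {}
    for name in ("selection.json", "validation_report.json",
                 "clinical_summary.json"):
        p = out / name
        if p.exists():
            report[name.replace(".json", "")] = json.loads(p.read_text())
    (out / "report.json").write_text(json.dumps(report, indent=1))
    manifest.record("report", [out / "report.json"])


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "de": stage_de,
    "features": stage_features,
    "cv": stage_cv,
    "select": stage_select,
    "lock": stage_lock,
    "validate": stage_validate,
    "stage": stage_stage,
    "report": stage_report,
}
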