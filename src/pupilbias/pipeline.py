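"""End-to-end orchestration: synthetic generation -> pupil preprocessing ->
TPR -> SDT -> DDM -> pattern analyses, driven by a single serializable
config.  Every stage is a pure function of its inputs plus the config, so a
fixed seed reproduces the full report bundle bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ddm, patterns, pupil, sdt, synthetic
from .preproc import PupilPreprocessor

logger = logging.getLogger("pupilbias")

__all__ = ["PipelineConfig", "run"]


@dataclass
class PipelineConfig:
    """Fully determines a run given the seed.

    ``rt_residualization`` and ``baseline_split`` expose the control
    analyses: binning on raw TPR (no RT removal) and splitting trials by
    pre-cue baseline pupil size instead of TPR.
    """

    seed: int = 0
    n_trials: int = 400
    out_dir: str = "pupilbias_out"
    stages: dict = field(default_factory=lambda: {
        "pupil": True, "sdt": True, "ddm": True, "patterns": True})
    binning_scheme: str = "three_40_20_40"
    rt_residualization: bool = True
    baseline_split: bool = False
    ddm_free_per_bin: tuple = ("a", "t0", "v", "z", "dc")
    ddm_shared: tuple = ("sv",)
    ddm_n_starts: int = 3
    n_resamples: int = 1000

    @classmethod
    def from_file(cls, path):
        import yaml

        with open(path) as f:
            data = yaml.safe_load(f)
        return cls(**data)

    def to_json(self):
        d = asdict(self)
        d["ddm_free_per_bin"] = list(d["ddm_free_per_bin"])
        d["ddm_shared"] = list(d["ddm_shared"])
        return json.dumps(d, sort_keys=True)

    @property
    def hash(self):
        # provenance hash covers the analysis parameters, not the output path
        d = json.loads(self.to_json())
        d.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def _tpr_table(trace, table, config):
    records = pupil.compute_tpr(trace, table)
    ids = [r.trial_id for r in records if r.complete]
    amp_raw = np.array([r.amplitude_raw for r in records if r.complete])
    base = np.array([r.baseline for r in records if r.complete])
    sub = table.set_index("trial_id").loc[ids].reset_index()
    rt = sub["rt"].to_numpy()
    amp = pupil.residualize(amp_raw, rt) if config.rt_residualization else amp_raw
    split_values = base if config.baseline_split else amp
    bins = pupil.bin_trials(split_values, config.binning_scheme)
    return pd.DataFrame({
        "trial_id": ids, "baseline": base, "amplitude_raw": amp_raw,
        "amplitude": amp, "bin_label": bins,
        "stimulus": sub["stimulus"].to_numpy(),
        "choice": sub["choice"].to_numpy(),
        "rt": rt,
        "tpr_condition": sub["tpr_condition"].to_numpy(),
    })


def run(config: PipelineConfig, gt: synthetic.GroundTruth | None = None):
    """Execute the enabled stages in order and write the report bundle.

    Returns a dict with the in-memory results; artifacts (CSV/JSON, with the
    config hash, seed and package version as provenance) land in
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if gt is None:
        gt = synthetic.GroundTruth(seed=config.seed, n_trials=config.n_trials)
    report = {"provenance": {"config_hash": config.hash, "seed": config.seed,
                             "version": __version__}}

    logger.info("generating synthetic session (%d trials)", gt.n_trials)
    table = synthetic.generate_trial_table(gt)
    table.to_csv(out / "trial_table.csv", index=False)
    traces = synthetic.generate_pupil_trace(table, gt)
    results = {"trial_table": table, "config": config}

    if config.stages.get("pupil", True):
        prep = PupilPreprocessor()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clean = [prep.transform_one(t) for t in traces]
        trace = synthetic.session_trace(clean)
        tpr = _tpr_table(trace, table, config)
        tpr.to_csv(out / "tpr_records.csv", index=False)
        glm_res = pupil.fit_pupil_glm(trace, table[table["responded"]])
        report["pupil_glm"] = {
            "beta_cue": glm_res.beta_cue, "beta_choice": glm_res.beta_choice,
            "beta_sustained": glm_res.beta_sustained,
            "r_squared": glm_res.r_squared,
        }
        results["tpr"] = tpr
        results["trace"] = trace
    else:
        tpr = None

    if config.stages.get("sdt", True):
        if tpr is None:
            raise RuntimeError("sdt stage requires the pupil stage "
                               "(missing artifact: tpr_records)")
        analysis = tpr[tpr["bin_label"].isin(["low", "high"])]
        per_bin = {}
        for lbl in ("low", "high"):
            sub = analysis[analysis["bin_label"] == lbl]
            res = sdt.sdt_from_trials(sub["stimulus"], sub["choice"])
            per_bin[lbl] = dataclasses.asdict(res)
        fy = sdt.balanced_fraction_yes(
            analysis["stimulus"], analysis["choice"], analysis["bin_label"],
            n_resamples=config.n_resamples, seed=config.seed)
        for lbl in per_bin:
            per_bin[lbl]["balanced_fraction_yes"] = fy[lbl]
        report["sdt"] = per_bin
        results["sdt"] = per_bin

    if config.stages.get("ddm", True):
        if tpr is None:
            raise RuntimeError("ddm stage requires the pupil stage "
                               "(missing artifact: tpr_records)")
        analysis = tpr[tpr["bin_label"].isin(["low", "high"])]
        fitres = ddm.fit(
            analysis["rt"], analysis["choice"],
            2 * analysis["stimulus"].to_numpy() - 1,
            bins=analysis["bin_label"].to_numpy(),
            free_per_bin=config.ddm_free_per_bin, shared=config.ddm_shared,
            n_starts=config.ddm_n_starts, seed=config.seed)
        report["ddm"] = {
            str(lbl): dataclasses.asdict(p) for lbl, p in fitres.params.items()}
        report["ddm"]["loglik"] = fitres.loglik
        report["ddm"]["bic"] = fitres.bic
        results["ddm"] = fitres

    if config.stages.get("patterns", True):
        pset = synthetic.generate_patterns(table, gt)
        scores = patterns.template_response(pset, mode="orientation")
        idx_stim = patterns.roc_predictive_index(
            scores, pset.stimulus, balance_by=pset.choice)
        ch_scores = patterns.template_response(pset, mode="choice")
        idx_choice = patterns.roc_predictive_index(
            ch_scores, pset.choice, balance_by=pset.stimulus)
        report["patterns"] = {
            "stimulus_predictive_index": idx_stim,
            "choice_predictive_index": idx_choice,
        }
        if tpr is not None:
            roi = synthetic.generate_roi_responses(
                table, tpr["amplitude"].to_numpy(), gt)
            corr = patterns.tpr_brainstem_correlation(
                roi, tpr["stimulus"].to_numpy())
            corr.to_csv(out / "tpr_roi_correlations.csv")
            report["patterns"]["tpr_roi_r"] = corr["r"].to_dict()
        results["patterns"] = report["patterns"]

    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2, sort_keys=True, default=float)
    logger.info("report written to %s", out / "report.json")
    results["report"] = report
    return results
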