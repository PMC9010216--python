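"""End-to-end orchestration: simulate/load → connectivity → GLM → inference.

A :class:`PipelineConfig` fully specifies a run; :func:`run_pipeline` executes
it and writes TSV results plus a JSON provenance sidecar (all parameters, the
seed expansion, package version, and a config hash).  Identical config + seed
reproduces byte-identical outputs.

Input modes
-----------
``synthetic``
    No files needed: a cohort and per-subject Fisher-z matrices are generated
    from the package's generative model, with a planted interaction network.
``fc``
    A cohort TSV plus one square Fisher-z TSV per subject listed in a
    manifest TSV (columns subject_id, path).
``timeseries``
    A cohort TSV plus one time × ROI TSV per subject; the connectivity stage
    (optional percent-signal, band-pass, weighted correlation, Fisher z) runs
    first.

All randomness derives from one seed expanded with a counter-based
``SeedSequence`` scheme, so each stage is independently reproducible.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import group_table
from .connectivity import (
    bandpass,
    compute_fc_matrix,
    read_fc_tsv,
    read_timeseries_tsv,
    to_percent_signal,
    ROITimeSeries,
)
from .edge_glm import build_design, fit_edges_matrix
from .inference import TFNBSParams, bh_fdr, permutation_fwe
from .roi_model import ROISet, build_edge_mask, load_roi_table
from .synthetic_data import (
    CohortSpec,
    EffectSpec,
    default_planted_edges,
    simulate_cohort,
    simulate_fc,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "synthetic_roi_set"]


class StageError(RuntimeError):
    """An analysis stage failed; the message names the stage and entity."""


@dataclass
class PipelineConfig:
    mode: str = "synthetic"                 # synthetic | fc | timeseries
    output_dir: str = "fcmod_out"
    roi_table_path: str | None = None       # None → packaged atlas (real modes)
    config_name: str = "S-SP"
    model: str = "full"
    term: str = "group_x_psqi"
    tail: str = "two"
    fdr_q: float = 0.05
    n_perm: int = 1000
    dT: float = 0.1
    E: float = 0.5
    H: float = 2.0
    scheme: str = "freedman_lane"
    seed: int = 0
    # synthetic mode
    n_rois: int = 12
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    effects: EffectSpec | None = None
    # real-data modes
    cohort_path: str | None = None
    fc_manifest: str | None = None
    timeseries_manifest: str | None = None
    percent_signal: bool = False
    apply_bandpass: bool = False
    sampling_interval: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.mode not in ("synthetic", "fc", "timeseries"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def seeds(self) -> dict[str, int]:
        """Stage seeds expanded from the master seed (counter-based)."""
        state = np.random.SeedSequence(self.seed).generate_state(3)
        return {
            "cohort": int(state[0] % (2**31)),
            "noise": int(state[1] % (2**31)),
            "permutation": int(state[2] % (2**31)),
        }

    def tfnbs_params(self) -> TFNBSParams:
        return TFNBSParams(dT=self.dT, E=self.E, H=self.H, tail=self.tail,
                           n_perm=self.n_perm, seed=self.seeds()["permutation"],
                           scheme=self.scheme)

    def hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def synthetic_roi_set(n_rois: int) -> ROISet:
    """Toy atlas for synthetic runs: planted stand-ins flagged sleep+pain.

    ROIs 0–2 ("striatal") and 3–4 ("sensorimotor") carry both flags so the
    planted network lies inside every seed/target configuration; the next
    third of the atlas is sleep-only, the remainder unflagged.
    """
    if n_rois < 6:
        raise ValueError("synthetic atlas needs at least 6 ROIs")
    names, hemis, sleep, pain = [], [], [], []
    for k in range(n_rois):
        if k < 3:
            names.append(f"Striatal stand-in {k}")
            sleep.append(1), pain.append(1)
        elif k < 5:
            names.append(f"Sensorimotor stand-in {k - 3}")
            sleep.append(1), pain.append(1)
        elif k < 5 + max(1, (n_rois - 5) // 3):
            names.append(f"Sleep stand-in {k - 5}")
            sleep.append(1), pain.append(0)
        else:
            names.append(f"Filler stand-in {k}")
            sleep.append(0), pain.append(0)
        hemis.append("left" if k % 2 == 0 else "right")
    return ROISet(pd.DataFrame({
        "name": names, "hemisphere": hemis, "is_sleep": sleep, "is_pain": pain,
    }))


def _load_fc_stack(config: PipelineConfig, cohort: pd.DataFrame, rois: ROISet):
    base = Path(config.fc_manifest).parent
    manifest = pd.read_csv(config.fc_manifest, sep="\t")
    paths = dict(zip(manifest["subject_id"].astype(str), manifest["path"]))
    stack = []
    for sid in cohort["subject_id"].astype(str):
        if sid not in paths:
            raise StageError(f"fc-load: subject {sid} missing from FC manifest")
        fc = read_fc_tsv(base / paths[sid], subject_id=sid)
        if fc.roi_labels != rois.names:
            raise StageError(f"fc-load: ROI labels of {sid} do not match ROI table")
        stack.append(fc.z)
    return np.stack(stack)


def _fc_from_timeseries(config: PipelineConfig, cohort: pd.DataFrame, rois: ROISet):
    base = Path(config.timeseries_manifest).parent
    manifest = pd.read_csv(config.timeseries_manifest, sep="\t")
    paths = dict(zip(manifest["subject_id"].astype(str), manifest["path"]))
    stack = []
    for sid in cohort["subject_id"].astype(str):
        if sid not in paths:
            raise StageError(f"connect: subject {sid} missing from manifest")
        ts = read_timeseries_tsv(base / paths[sid])
        if ts.roi_labels != rois.names:
            raise StageError(f"connect: ROI labels of {sid} do not match ROI table")
        if config.percent_signal:
            ts = to_percent_signal(ts)
        if config.apply_bandpass:
            ts = bandpass(ts)
        stack.append(compute_fc_matrix(ts, subject_id=sid).z)
    return np.stack(stack)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analysis and write the result bundle.

    Writes ``edge_results.tsv`` (per-edge GLM + FDR + TFNBS columns),
    ``null_max.tsv`` (one permutation maximum per row), ``cohort.tsv``,
    ``group_table.tsv`` and ``provenance.json`` into ``config.output_dir``.
    Returns the bundle in memory as a dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.seeds()

    # --- inputs -----------------------------------------------------------
    if config.mode == "synthetic":
        rois = synthetic_roi_set(config.n_rois)
        cohort = simulate_cohort(
            CohortSpec(**{**asdict(config.cohort_spec), "seed": seeds["cohort"]})
        )
        effects = config.effects or EffectSpec(
            affected_edges=default_planted_edges(), beta_psqi=0.005
        )
        dataset = simulate_fc(cohort, config.n_rois, effects, seed=seeds["noise"])
        fc_stack = dataset.fc_observed
    else:
        rois = load_roi_table(config.roi_table_path)
        if config.cohort_path is None:
            raise StageError("input: real-data modes require cohort_path")
        cohort = pd.read_csv(config.cohort_path, sep="\t")
        if cohort.isna().any().any():  # listwise deletion, logged in provenance
            cohort = cohort.dropna().reset_index(drop=True)
        if config.mode == "fc":
            fc_stack = _load_fc_stack(config, cohort, rois)
        else:
            fc_stack = _fc_from_timeseries(config, cohort, rois)

    # --- GLM --------------------------------------------------------------
    try:
        X = build_design(cohort, config.model)
    except Exception as exc:
        raise StageError(f"design: {exc}") from exc
    if X.df_resid <= 0:
        raise StageError(f"design: non-positive residual df with n={X.n}")
    mask = build_edge_mask(config.config_name, rois)
    ii = np.array([e[0] for e in mask.edges])
    jj = np.array([e[1] for e in mask.edges])
    Y = fc_stack[:, ii, jj]
    t, p_left, p_right, beta, se = fit_edges_matrix(Y, X, config.term)
    p_two = np.minimum(1.0, 2 * np.minimum(p_left, p_right))
    p_raw = {"two": p_two, "left": p_left, "right": p_right}[config.tail]

    # --- inference --------------------------------------------------------
    fdr = bh_fdr(p_raw, q=config.fdr_q)
    tf = permutation_fwe(fc_stack, X, config.term, mask, config.tfnbs_params())
    f2 = t**2 / X.df_resid  # one-df term: f² = t²/df

    names = rois.names
    results = pd.DataFrame({
        "roi_i": [names[i] for i in ii],
        "roi_j": [names[j] for j in jj],
        "beta_term": beta, "se": se, "t": t, "df": X.df_resid,
        "p_two": p_two, "p_left": p_left,
        "p_fdr": fdr.p_adjusted, "fdr_rejected": fdr.rejected,
        "f2": f2,
        "tfnbs_score": tf.score[ii, jj], "p_fwe": tf.p_fwe[ii, jj],
        "tail": config.tail, "config": config.config_name,
        "scheme": config.scheme, "n_perm": config.n_perm,
        "seed": config.seed,
    }).sort_values("p_fwe", kind="stable").reset_index(drop=True)

    comparison = group_table(cohort)

    # --- outputs ----------------------------------------------------------
    results.to_csv(out / "edge_results.tsv", sep="\t", index=False)
    pd.DataFrame({"null_max": tf.null_max}).to_csv(
        out / "null_max.tsv", sep="\t", index=False)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    comparison.to_csv(out / "group_table.tsv", sep="\t", index=False)
    provenance = {
        "config": {k: v for k, v in asdict(config).items()},
        "config_hash": config.hash(),
        "seeds": seeds,
        "n_tests": mask.n_tests,
        "version": __version__,
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=str))
    return {
        "results": results, "null_max": tf.null_max, "cohort": cohort,
        "group_table": comparison, "mask": mask, "provenance": provenance,
    }


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Cross-file consistency checks; returns a list of failure messages.

    An empty list means the bundle is consistent.  Nothing is analysed.
    """
    failures: list[str] = []
    if config.mode == "synthetic":
        try:
            synthetic_roi_set(config.n_rois)
        except Exception as exc:
            failures.append(f"roi: {exc}")
        return failures
    try:
        rois = load_roi_table(config.roi_table_path)
    except Exception as exc:
        return [f"roi-table: {exc}"]
    if config.cohort_path is None or not Path(config.cohort_path).exists():
        return [f"cohort: file not found ({config.cohort_path})"]
    cohort = pd.read_csv(config.cohort_path, sep="\t")
    for col in ("subject_id", "age", "sex", "group", "psqi"):
        if col not in cohort.columns:
            failures.append(f"cohort: missing column {col!r}")
    if "psqi" in cohort.columns:
        bad = cohort[(cohort["psqi"] < 0) | (cohort["psqi"] > 21)]
        for sid in bad.get("subject_id", []):
            failures.append(f"cohort: subject {sid} has PSQI outside [0, 21]")
    na_rows = cohort[cohort.isna().any(axis=1)]
    for sid in na_rows.get("subject_id", []):
        failures.append(f"cohort: subject {sid} has missing values (listwise delete)")
    manifest_path = (config.fc_manifest if config.mode == "fc"
                     else config.timeseries_manifest)
    if manifest_path is None or not Path(manifest_path).exists():
        failures.append(f"manifest: file not found ({manifest_path})")
        return failures
    manifest = pd.read_csv(manifest_path, sep="\t")
    listed = set(manifest["subject_id"].astype(str))
    for sid in cohort.get("subject_id", pd.Series(dtype=str)).astype(str):
        if sid not in listed:
            failures.append(f"manifest: subject {sid} missing from manifest")
    base = Path(manifest_path).parent
    for _, row in manifest.iterrows():
        p = base / row["path"]
        if not p.exists():
            failures.append(f"manifest: file for {row['subject_id']} not found ({p})")
            continue
        header = pd.read_csv(p, sep="\t", nrows=1)
        labels = (list(header.columns[1:]) if config.mode == "timeseries"
                  else list(header.columns[1:]))
        if labels != rois.names:
            failures.append(
                f"labels: {row['subject_id']} ROI columns do not match ROI table")
    return failures
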