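"""Synthetic cohorts and connectivity data matching the analysis's assumptions.

The generator is the testing ground for every downstream stage.  It emulates
a community-dwelling older-adult cohort (default 34 chronic-pain / 14 no-pain
subjects, ages >= 60, PSQI 0–21) and produces per-subject Fisher-z
connectivity either directly from the generative linear model

    z[subject, edge] = b0 + b_age·age + b_sex·sex + b_group·group
                       + b_psqi·psqi + b_int·group·psqi + Gaussian noise

(the generative twin of the analysis GLM, so noiseless round trips recover
the coefficients exactly) or by sampling ROI time series from multivariate
normals with prescribed population correlation (default 300 time points at a
2 s sampling interval) and pushing them through the connectivity stage.

The default planted effect mimics a small dorsostriatal–sensorimotor network:
six edges between three "striatal" and two "sensorimotor" stand-in ROIs
carrying a negative group×PSQI interaction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "SyntheticDataset",
    "DEFAULT_COHORT",
    "simulate_cohort",
    "simulate_fc",
    "simulate_timeseries",
    "default_planted_edges",
    "nearest_correlation",
]

# Study-condition defaults: group sizes, age and PSQI moments, female
# proportions per group (no-pain first element? no: keyed by group code).
_AGE_MIN = 60.0
_PSQI_RANGE = (0.0, 21.0)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-generation parameters; defaults describe the emulated study."""

    n_pain: int = 34
    n_nopain: int = 14
    age_mean_by_group: tuple[float, float] = (74.50, 72.0)   # (no-pain, pain)
    age_sd_by_group: tuple[float, float] = (7.31, 6.78)
    psqi_mean_by_group: tuple[float, float] = (3.93, 6.88)
    psqi_sd_by_group: tuple[float, float] = (3.00, 3.46)
    female_prop_by_group: tuple[float, float] = (7 / 14, 26 / 34)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pain < 2 or self.n_nopain < 2:
            raise ValueError("need at least 2 subjects per group")
        if any(s < 0 for s in self.age_sd_by_group + self.psqi_sd_by_group):
            raise ValueError("standard deviations must be nonnegative")
        if any(not 0 <= p <= 1 for p in self.female_prop_by_group):
            raise ValueError("female proportions must lie in [0, 1]")


DEFAULT_COHORT = CohortSpec()


@dataclass(frozen=True)
class EffectSpec:
    """Generative coefficients (Fisher-z units) and observation noise.

    ``affected_edges`` carry ``beta_interaction``; all other edges have a zero
    interaction.  The default interaction sign is negative, matching a
    pain-group reversal of the sleep-quality slope.
    """

    affected_edges: tuple[tuple[int, int], ...] = ()
    beta_intercept: float = 0.3
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_group: float = 0.0
    beta_psqi: float = 0.0
    beta_interaction: float = -0.03
    noise_sd: float = 0.15
    noise_corr: float = 0.0  # exchangeable correlation across edges, default off

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.noise_corr < 1:
            raise ValueError("noise_corr must lie in [0, 1)")
        for i, j in self.affected_edges:
            if i == j or i < 0 or j < 0:
                raise ValueError(f"invalid edge ({i}, {j})")


@dataclass
class SyntheticDataset:
    cohort: pd.DataFrame
    fc_truth: np.ndarray | None = None     # subjects × ROI × ROI, noiseless
    fc_observed: np.ndarray | None = None  # subjects × ROI × ROI, with noise
    timeseries: np.ndarray | None = None   # subjects × time × ROI
    provenance: dict = field(default_factory=dict)


def _matched_parent_params(mean, sd, low, high):
    """Parent-normal (mu, sigma) whose [low, high]-truncation has the target
    mean and SD, so sample moments converge to the requested values despite
    truncation.  Falls back to the naive (mean, sd) if the solver fails."""
    def eqs(p):
        mu, log_sig = p
        sig = float(np.exp(log_sig))
        a, b = (low - mu) / sig, (high - mu) / sig
        tm, tv = sps.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(tm) - mean, float(np.sqrt(tv)) - sd]

    sol, info, ier, _ = optimize.fsolve(eqs, [mean, np.log(sd)], full_output=True)
    if ier != 1 or np.max(np.abs(info["fvec"])) > 1e-6:
        return mean, sd
    return float(sol[0]), float(np.exp(sol[1]))


def _truncated_normal(rng, mean, sd, low, high, size):
    """Moment-matched normal draws truncated to [low, high] by resampling."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, low, high)))
    mu, sig = _matched_parent_params(mean, sd, low, high)
    out = rng.normal(mu, sig, size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mu, sig, bad.sum())
        bad = (out < low) | (out > high)
    return out


def simulate_cohort(spec: CohortSpec = DEFAULT_COHORT) -> pd.DataFrame:
    """Draw a cohort table: subject_id, age, sex (0/1), group (0/1), psqi.

    Ages are truncated normal (>= 60), PSQI truncated normal on [0, 21], sex
    Bernoulli with the group's female proportion; covariates are independent
    within group.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, n in ((1, spec.n_pain), (0, spec.n_nopain)):
        age = _truncated_normal(rng, spec.age_mean_by_group[group],
                                spec.age_sd_by_group[group], _AGE_MIN, 110.0, n)
        psqi = _truncated_normal(rng, spec.psqi_mean_by_group[group],
                                 spec.psqi_sd_by_group[group], *_PSQI_RANGE, n)
        sex = (rng.random(n) < spec.female_prop_by_group[group]).astype(int)
        for k in range(n):
            rows.append({
                "subject_id": f"sub-{'pain' if group else 'ctrl'}{k:04d}",
                "age": float(age[k]), "sex": int(sex[k]),
                "group": group, "psqi": float(psqi[k]),
            })
    return pd.DataFrame(rows)


def default_planted_edges(striatal=(0, 1, 2), sensorimotor=(3, 4)):
    """Six edges linking striatal stand-ins to sensorimotor stand-ins."""
    return tuple(sorted((min(a, b), max(a, b))
                        for a in striatal for b in sensorimotor))


def _design_values(cohort: pd.DataFrame):
    age = cohort["age"].to_numpy(float)
    sex = cohort["sex"].to_numpy(float)
    group = cohort["group"].to_numpy(float)
    psqi = cohort["psqi"].to_numpy(float)
    return age, sex, group, psqi


def simulate_fc(
    cohort: pd.DataFrame,
    roi_count: int,
    effects: EffectSpec = EffectSpec(),
    seed: int = 0,
) -> SyntheticDataset:
    """Per-subject Fisher-z matrices from the generative linear model.

    Every edge receives the main-effect coefficients; only
    ``effects.affected_edges`` receive the interaction.  Observation noise is
    i.i.d. Gaussian in Fisher-z space across subjects and edges (optionally
    exchangeable-correlated across edges via ``noise_corr``).
    """
    if roi_count < 2:
        raise ValueError("roi_count must be >= 2")
    for i, j in effects.affected_edges:
        if j >= roi_count:
            raise IndexError(f"edge ({i}, {j}) outside ROI range {roi_count}")
    n = len(cohort)
    age, sex, group, psqi = _design_values(cohort)
    base = (effects.beta_intercept
            + effects.beta_age * age
            + effects.beta_sex * sex
            + effects.beta_group * group
            + effects.beta_psqi * psqi)
    inter = effects.beta_interaction * group * psqi

    iu, ju = np.triu_indices(roi_count, k=1)
    m = iu.size
    truth_flat = np.tile(base[:, None], (1, m))
    affected = {tuple(e) for e in effects.affected_edges}
    hit = np.fromiter(((int(a), int(b)) in affected for a, b in zip(iu, ju)),
                      bool, m)
    truth_flat[:, hit] += inter[:, None]

    rng = np.random.default_rng(seed)
    if effects.noise_sd > 0:
        eps = rng.standard_normal((n, m))
        if effects.noise_corr > 0:
            shared = rng.standard_normal((n, 1))
            rho = effects.noise_corr
            eps = np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps
        obs_flat = truth_flat + effects.noise_sd * eps
    else:
        obs_flat = truth_flat.copy()

    def to_stack(flat):
        stack = np.full((n, roi_count, roi_count), np.nan)
        stack[:, iu, ju] = flat
        stack[:, ju, iu] = flat
        return stack

    return SyntheticDataset(
        cohort=cohort.reset_index(drop=True),
        fc_truth=to_stack(truth_flat),
        fc_observed=to_stack(obs_flat),
        provenance={
            "generator": "simulate_fc", "seed": seed, "roi_count": roi_count,
            "effects": {k: (list(map(list, v)) if k == "affected_edges" else v)
                        for k, v in effects.__dict__.items()},
        },
    )


def nearest_correlation(target: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Nearest factorizable correlation matrix by eigenvalue clipping.

    Eigenvalues below *eig_floor* are raised to it and the matrix is rescaled
    back to unit diagonal, so arbitrary symmetric unit-diagonal targets become
    positive definite deterministically.
    """
    t = np.asarray(target, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("target must be square")
    if not np.allclose(t, t.T, atol=1e-10):
        raise ValueError("target correlation matrix must be symmetric")
    if not np.allclose(np.diag(t), 1.0, atol=1e-10):
        raise ValueError("target correlation matrix must have unit diagonal")
    vals, vecs = np.linalg.eigh((t + t.T) / 2)
    if vals.min() >= eig_floor:
        return (t + t.T) / 2
    vals = np.maximum(vals, eig_floor)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def simulate_timeseries(
    cohort: pd.DataFrame,
    target_corr_builder,
    n_timepoints: int = 300,
    seed: int = 0,
    sampling_interval: float = 2.0,
) -> SyntheticDataset:
    """Per-subject ROI time series with prescribed population correlation.

    *target_corr_builder* maps a cohort row (pandas Series) to that subject's
    target correlation matrix (symmetric, unit diagonal).  Draws zero-mean
    Gaussian samples whose population correlation equals the nearest
    positive-definite projection of the target, via Cholesky factorisation.
    Per-subject seeds are spawned from *seed* so subjects are independent and
    the whole dataset is reproducible.
    """
    n = len(cohort)
    streams = np.random.SeedSequence(seed).spawn(n)
    series = None
    for s, (_, row) in enumerate(cohort.iterrows()):
        target = nearest_correlation(np.asarray(target_corr_builder(row), float))
        chol = np.linalg.cholesky(target)
        rng = np.random.default_rng(streams[s])
        x = rng.standard_normal((n_timepoints, target.shape[0])) @ chol.T
        if series is None:
            series = np.empty((n, n_timepoints, target.shape[0]))
        series[s] = x
    return SyntheticDataset(
        cohort=cohort.reset_index(drop=True),
        timeseries=series,
        provenance={
            "generator": "simulate_timeseries", "seed": seed,
            "n_timepoints": n_timepoints, "sampling_interval": sampling_interval,
        },
    )
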