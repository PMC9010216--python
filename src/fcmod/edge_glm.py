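"""Per-edge second-level GLM: moderation of connectivity by pain group × PSQI.

Each tested connection's Fisher-z value across subjects is the dependent
variable of an ordinary least squares fit.  The full model is

    z ~ 1 + age + sex + group + psqi + group:psqi

(Wilkinson ``1 + Age + Sex + GROUP*PSQI``), with sex coded 0=male/1=female and
group 0=no-pain/1=pain so that the interaction coefficient is the change in
the PSQI slope induced by chronic pain.  The simple model drops group and the
interaction: ``z ~ 1 + age + sex + psqi``.

The fit is plain OLS via QR/least squares, vectorised across edges for the
permutation loop (:func:`fit_edges_matrix`).  Tail conventions: two-tailed
p = 2·min(left, right); left-tailed p = P(T <= t).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignMatrix",
    "EdgeStats",
    "EffectSize",
    "FULL_COLUMNS",
    "SIMPLE_COLUMNS",
    "build_design",
    "fit_edge",
    "fit_edges_matrix",
    "tmap",
    "cohens_f2",
    "f2_label",
    "adjust_fc",
]

FULL_COLUMNS = ("intercept", "age", "sex", "group", "psqi", "group_x_psqi")
SIMPLE_COLUMNS = ("intercept", "age", "sex", "psqi")


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable design matrix."""


@dataclass(frozen=True)
class DesignMatrix:
    X: np.ndarray
    columns: tuple[str, ...]
    model_name: str
    subject_ids: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    def column_index(self, term: str) -> int:
        try:
            return self.columns.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in design columns {self.columns}") from None

    def drop_term(self, term: str) -> "DesignMatrix":
        k = self.column_index(term)
        keep = [j for j in range(self.p) if j != k]
        return DesignMatrix(
            self.X[:, keep],
            tuple(c for j, c in enumerate(self.columns) if j != k),
            f"{self.model_name}-minus-{term}",
            self.subject_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.columns))
        if self.subject_ids:
            df.insert(0, "subject_id", list(self.subject_ids))
        return df


@dataclass(frozen=True)
class EdgeStats:
    """OLS results for one edge and one tested term."""

    beta: np.ndarray
    se: np.ndarray
    t: float
    p_two: float
    p_left: float
    p_right: float
    df: int
    term: str
    columns: tuple[str, ...]

    def coef(self, name: str) -> float:
        return float(self.beta[self.columns.index(name)])


@dataclass(frozen=True)
class EffectSize:
    f2: float
    label: str
    term: str


def build_design(cohort: pd.DataFrame, model_name: str = "full") -> DesignMatrix:
    """Design matrix from a cohort table with columns age, sex, group, psqi.

    Covariates enter in raw units (no centering by default); ``center=True``
    callers can pre-center the cohort columns themselves — the model matrix is
    a pure function of the table it is given.
    """
    for col in ("age", "sex", "psqi") + (("group",) if model_name == "full" else ()):
        if col not in cohort.columns:
            raise DesignError(f"cohort table missing column {col!r}")
    n = len(cohort)
    age = cohort["age"].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy(dtype=float)
    psqi = cohort["psqi"].to_numpy(dtype=float)
    if model_name == "full":
        group = cohort["group"].to_numpy(dtype=float)
        X = np.column_stack([np.ones(n), age, sex, group, psqi, group * psqi])
        cols = FULL_COLUMNS
    elif model_name == "simple":
        X = np.column_stack([np.ones(n), age, sex, psqi])
        cols = SIMPLE_COLUMNS
    else:
        raise DesignError(f"unknown model {model_name!r}; expected 'full' or 'simple'")
    if not np.all(np.isfinite(X)):
        raise DesignError("design matrix contains non-finite covariate values")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        culprit = [c for j, c in enumerate(cols) if j > 0 and np.ptp(X[:, j]) == 0]
        raise DesignError(
            f"design matrix is rank deficient (constant columns: {culprit or 'collinear'})"
        )
    ids = tuple(map(str, cohort["subject_id"])) if "subject_id" in cohort.columns else ()
    return DesignMatrix(X, cols, model_name, ids)


def _ols(X: np.ndarray, Y: np.ndarray):
    """Least-squares fit of columns of Y on X; returns beta, rss, XtX_inv diag."""
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise DesignError("singular design matrix")
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    return beta, resid, rss, xtx_inv


def fit_edge(y, X: DesignMatrix, term: str = "group_x_psqi") -> EdgeStats:
    """OLS fit of one edge's values with t/p for a single term."""
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    if y.shape[0] != X.n:
        raise ValueError(f"y has {y.shape[0]} rows, design has {X.n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("edge values contain non-finite entries")
    if X.df_resid <= 0:
        raise DesignError(f"non-positive residual df ({X.n} subjects, {X.p} columns)")
    k = X.column_index(term)
    beta, _, rss, xtx_inv = _ols(X.X, y)
    sigma2 = float(rss[0]) / X.df_resid
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    if se[k] == 0:
        t = 0.0 if beta[k, 0] == 0 else np.sign(beta[k, 0]) * np.inf
    else:
        t = float(beta[k, 0] / se[k])
    p_left = float(stats.t.cdf(t, X.df_resid))
    p_right = float(stats.t.sf(t, X.df_resid))
    return EdgeStats(
        beta=beta[:, 0],
        se=se,
        t=t,
        p_two=float(min(1.0, 2 * min(p_left, p_right))),
        p_left=p_left,
        p_right=p_right,
        df=X.df_resid,
        term=term,
        columns=X.columns,
    )


def fit_edges_matrix(Y: np.ndarray, X: DesignMatrix, term: str):
    """Vectorised per-edge t statistics for one term.

    *Y* is subjects × edges.  Returns ``(t, p_left, p_right, beta_term,
    se_term)`` arrays over edges; degenerate edges (zero residual variance and
    zero coefficient) get t = 0 and NaN se flagged via se = 0.
    """
    if Y.shape[0] != X.n:
        raise ValueError("Y rows must match design rows")
    if X.df_resid <= 0:
        raise DesignError("non-positive residual degrees of freedom")
    k = X.column_index(term)
    beta, _, rss, xtx_inv = _ols(X.X, Y)
    sigma2 = rss / X.df_resid
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[k, k], 0.0))
    bk = beta[k, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, bk / np.where(se > 0, se, 1.0), np.where(bk == 0, 0.0, np.inf * np.sign(bk)))
    p_left = stats.t.cdf(t, X.df_resid)
    p_right = stats.t.sf(t, X.df_resid)
    return t, p_left, p_right, bk, se


def tmap(fc_stack, X: DesignMatrix, term: str, mask):
    """t-statistic (and tail p) matrices over the masked edges only.

    *fc_stack* is subjects × ROI × ROI (aligned with the design rows); *mask*
    an :class:`~fcmod.roi_model.EdgeMask`.  Untested entries are NaN.
    """
    stack = np.asarray(fc_stack, dtype=float)
    if stack.shape[0] != X.n:
        raise ValueError(
            f"alignment error: {stack.shape[0]} FC subjects vs {X.n} design rows"
        )
    n_roi = stack.shape[1]
    edges = mask.edges
    ii = np.fromiter((e[0] for e in edges), int, len(edges))
    jj = np.fromiter((e[1] for e in edges), int, len(edges))
    if len(edges) and (ii.max() >= n_roi or jj.max() >= n_roi):
        raise IndexError("edge mask references ROI outside the FC matrices")
    Y = stack[:, ii, jj]
    t, p_left, p_right, beta, se = fit_edges_matrix(Y, X, term)
    out = {}
    for name, vec in (
        ("t", t), ("p_left", p_left), ("p_right", p_right), ("beta", beta), ("se", se),
    ):
        m = np.full((n_roi, n_roi), np.nan)
        m[ii, jj] = vec
        m[jj, ii] = vec
        out[name] = m
    out["p_two"] = np.minimum(1.0, 2 * np.minimum(out["p_left"], out["p_right"]))
    out["df"] = X.df_resid
    return out


def f2_label(f2: float) -> str:
    """Conventional effect-size bands: 0.02 small, 0.15 medium, 0.35 large."""
    if f2 >= 0.35:
        return "large"
    if f2 >= 0.15:
        return "medium"
    if f2 >= 0.02:
        return "small"
    return "below-small"


def cohens_f2(y, X_full: DesignMatrix, term: str = "group_x_psqi") -> EffectSize:
    """Cohen's local f² for one term: (R²_full − R²_reduced) / (1 − R²_full)."""
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    X_red = X_full.drop_term(term)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("response has zero variance; f² undefined")
    _, _, rss_full, _ = _ols(X_full.X, y)
    _, _, rss_red, _ = _ols(X_red.X, y)
    r2_full = 1.0 - float(rss_full[0]) / tss
    r2_red = 1.0 - float(rss_red[0]) / tss
    if 1.0 - r2_full <= 0:
        raise ZeroDivisionError("perfect full-model fit: f² unbounded")
    f2 = max(0.0, (r2_full - r2_red) / (1.0 - r2_full))
    return EffectSize(f2=f2, label=f2_label(f2), term=term)


def adjust_fc(y, X: DesignMatrix, nuisance: tuple[str, ...] = ("age", "sex")):
    """Remove demeaned nuisance contributions using full-model coefficients.

    Returns ``y − Σ_c b_c (x_c − mean(x_c))`` so the adjusted values retain the
    original mean level but have the age/sex contributions regressed out; the
    group-wise adjusted regression lines on PSQI then carry exactly the
    full-model implied slopes.
    """
    y = np.asarray(y, dtype=float)
    fit = fit_edge(y, X, term=X.columns[-1])
    adj = y.astype(float).copy()
    for c in nuisance:
        col = X.X[:, X.column_index(c)]
        adj -= fit.coef(c) * (col - col.mean())
    return adj
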