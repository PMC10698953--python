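"""Vertex-wise statistical parametric mapping of S2S distances.

The model is a mass univariate regression, Y = X beta + eps, fitted
independently at every template vertex (Y is subjects x vertices, X the
shared design matrix).  Inference on a covariate of interest proceeds by
threshold-free cluster enhancement (TFCE) of the vertex-wise t-map over the
mesh graph, Freedman-Lane permutation of reduced-model residuals to build the
vertex-wise null of the enhanced statistic, and Benjamini-Hochberg FDR across
vertices.  Summaries mirror the cohort tables: median (IQR) of the
standardised coefficients split by sign, and significance areas as a
percentage of vertices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse
from statsmodels.stats.multitest import multipletests

from .mesh import VertexGeometry
from .s2s import S2SMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "TFCEParams",
    "VertexStats",
    "MURFit",
    "standardise",
    "build_design",
    "add_interactions",
    "fit_mur",
    "tfce_enhance",
    "permutation_pvalues",
    "bh_fdr",
    "run_spm",
    "summarise_spm",
    "interaction_rate_map",
    "unstandardise",
]

T_CAP = 1e3  # cap for infinite t on zero-residual (perfect-fit) vertices


@dataclass
class DesignMatrix:
    """Design matrix with column names and the standardisation record.

    Continuous columns flagged for standardisation are centred and scaled to
    unit (population) SD, so their coefficients are in S2S-SD units per
    covariate SD.
    """

    X: np.ndarray
    names: list[str]
    intercept: bool = True
    standardisation: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("X columns must match names")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError(
                "design matrix is rank deficient; collinear columns: "
                + ", ".join(_collinear_columns(self.X, self.names))
            )

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]

    def drop(self, name: str) -> "DesignMatrix":
        j = self.names.index(name)
        return DesignMatrix(
            np.delete(self.X, j, axis=1),
            [n for n in self.names if n != name],
            intercept=self.intercept,
            standardisation=dict(self.standardisation),
        )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
            bad.append(names[j])
    return bad or names


def standardise(
    values: np.ndarray, columns: list[int] | None = None
) -> tuple[np.ndarray, dict[int, tuple[float, float]]]:
    """Centre and scale selected columns to mean 0, population SD 1.

    Returns the transformed array and a record {column: (mean, sd)} so mm
    units can be restored later.  Constant columns raise, naming the column.
    """
    values = np.array(values, float, copy=True)
    if values.ndim == 1:
        values = values[:, None]
        columns = [0] if columns is None else columns
    if columns is None:
        columns = list(range(values.shape[1]))
    record: dict[int, tuple[float, float]] = {}
    for j in columns:
        mu = float(values[:, j].mean())
        sd = float(values[:, j].std())  # population SD
        if sd <= 0:
            raise ValueError(f"column {j} is constant (SD = 0); cannot standardise")
        values[:, j] = (values[:, j] - mu) / sd
        record[j] = (mu, sd)
    return values, record


def build_design(
    table: pd.DataFrame,
    continuous: list[str],
    binary: list[str] | None = None,
    intercept: bool = True,
) -> DesignMatrix:
    """Assemble a design matrix from a phenotype table.

    Continuous covariates are standardised (units of one SD); binary flags
    pass through untouched.
    """
    binary = binary or []
    cols, names = [], []
    if intercept:
        cols.append(np.ones(len(table)))
        names.append("intercept")
    record: dict[str, tuple[float, float]] = {}
    for c in continuous:
        x = table[c].to_numpy(float)
        xs, rec = standardise(x)
        record[c] = rec[0]
        cols.append(xs.ravel())
        names.append(c)
    for c in binary:
        cols.append(table[c].to_numpy(float))
        names.append(c)
    return DesignMatrix(np.column_stack(cols), names, intercept, record)


def add_interactions(dm: DesignMatrix, pairs: list[tuple[str, str]]) -> DesignMatrix:
    """Append product columns (formed after standardisation of the parents)."""
    X, names = dm.X, list(dm.names)
    new_cols = []
    for a, b in pairs:
        name = f"{a}*{b}"
        if name in names:
            raise ValueError(f"duplicate interaction {name}")
        if a not in names or b not in names:
            raise ValueError(f"interaction parents {a!r}, {b!r} must be design columns")
        new_cols.append(dm.column(a) * dm.column(b))
        names.append(name)
    return DesignMatrix(
        np.column_stack([X] + new_cols),
        names,
        intercept=dm.intercept,
        standardisation=dict(dm.standardisation),
    )


@dataclass
class MURFit:
    beta: np.ndarray  # (p, n_v)
    t: np.ndarray  # (p, n_v)
    residuals: np.ndarray  # (n_s, n_v)
    names: list[str]
    dof: int

    def beta_for(self, name: str) -> np.ndarray:
        return self.beta[self.names.index(name)]

    def t_for(self, name: str) -> np.ndarray:
        return self.t[self.names.index(name)]


def fit_mur(Y: S2SMatrix | np.ndarray, X: DesignMatrix) -> MURFit:
    """Ordinary least squares at every vertex; t = beta / SE with n_s - p df.

    Perfect-fit vertices (zero residual variance) get |t| capped at 1e3 with a
    warning rather than +/- infinity, keeping TFCE finite.
    """
    y = Y.values if isinstance(Y, S2SMatrix) else np.asarray(Y, float)
    n_s, p = X.X.shape
    if y.shape[0] != n_s:
        raise ValueError("Y rows must match design rows")
    if n_s <= p:
        raise ValueError(f"need n_s > p (got n_s={n_s}, p={p})")
    pinv = np.linalg.pinv(X.X)
    beta = pinv @ y  # (p, n_v)
    resid = y - X.X @ beta
    dof = n_s - p
    sigma2 = (resid**2).sum(axis=0) / dof
    cjj = np.diag(np.linalg.inv(X.X.T @ X.X))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(cjj[:, None] * sigma2[None, :])
    bad = ~np.isfinite(t)
    if bad.any():
        logger.warning("capping %d non-finite t values (perfect fit) at %g", bad.sum(), T_CAP)
        t[bad] = np.sign(beta[bad]) * T_CAP
        t[bad & (beta == 0)] = 0.0
    np.clip(t, -T_CAP, T_CAP, out=t)
    return MURFit(beta=beta, t=t, residuals=resid, names=list(X.names), dof=dof)


@dataclass
class TFCEParams:
    """TFCE settings: enhanced(v) = sum_h extent(v, h)^E * h^H * dh.

    Extent is the surface area (mm^2, summed per-vertex areas) of the
    supra-threshold connected component containing v at height h.  ``dh`` of
    None means max|field| / n_steps per map.
    """

    E: float = 1.0
    H: float = 2.0
    dh: float | None = None
    n_steps: int = 100
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0")


@njit(cache=True)
def _tfce_sweep(order, f, areas, indptr, indices, hs, E, H, dh):  # pragma: no cover
    """Descending-threshold union-find sweep.

    Vertices are activated in decreasing field order; supra-threshold
    components are maintained with a union-find carrying component areas, and
    each active vertex accumulates extent^E * h^H * dh at every threshold.
    """
    n_v = f.shape[0]
    out = np.zeros(n_v)
    parent = np.full(n_v, -1, dtype=np.int64)
    comp_area = np.zeros(n_v)
    active = np.empty(n_v, dtype=np.int64)
    n_active = 0
    ptr = 0
    for k in range(hs.shape[0] - 1, -1, -1):
        h = hs[k]
        while ptr < n_v and f[order[ptr]] >= h:
            v = order[ptr]
            parent[v] = v
            comp_area[v] = areas[v]
            active[n_active] = v
            n_active += 1
            for j in range(indptr[v], indptr[v + 1]):
                u = indices[j]
                if parent[u] >= 0:
                    # find roots
                    ru = u
                    while parent[ru] != ru:
                        ru = parent[ru]
                    rv = v
                    while parent[rv] != rv:
                        rv = parent[rv]
                    if ru != rv:
                        parent[ru] = rv
                        comp_area[rv] += comp_area[ru]
                    # path compression
                    while parent[u] != rv:
                        u, parent[u] = parent[u], rv
            ptr += 1
        hH = h**H * dh
        for i in range(n_active):
            v = active[i]
            r = v
            while parent[r] != r:
                r = parent[r]
            out[v] += comp_area[r] ** E * hH
    return out


def _tfce_one_sided(
    f: np.ndarray, areas: np.ndarray, adjacency: sparse.csr_matrix,
    E: float, H: float, dh: float
) -> np.ndarray:
    fmax = f.max()
    if fmax <= 0:
        return np.zeros_like(f)
    n_steps = int(np.floor(fmax / dh + 1e-9))
    hs = dh * np.arange(1, n_steps + 1)  # ascending; sweep walks it backwards
    order = np.argsort(-f, kind="stable")
    return _tfce_sweep(
        order,
        np.asarray(f, np.float64),
        np.asarray(areas, np.float64),
        adjacency.indptr.astype(np.int64),
        adjacency.indices.astype(np.int64),
        hs,
        float(E),
        float(H),
        float(dh),
    )


def tfce_enhance(
    stat_field: np.ndarray, geometry: VertexGeometry, params: TFCEParams | None = None
) -> np.ndarray:
    """Threshold-free cluster enhancement of a vertex statistic field.

    Positive and negative excursions are enhanced separately (the negative
    side on the negated field) and recombined with sign, so inward and outward
    effects keep their direction.
    """
    params = params or TFCEParams()
    f = np.asarray(stat_field, float)
    if not np.all(np.isfinite(f)):
        raise ValueError("stat field must be finite")
    if geometry.areas.size == 0:
        raise ValueError("empty mesh geometry")
    if len(f) != len(geometry.areas):
        raise ValueError("field length != number of vertices")
    fmax = np.abs(f).max()
    if fmax == 0:
        return np.zeros_like(f)
    dh = params.dh if params.dh is not None else fmax / params.n_steps
    pos = _tfce_one_sided(np.maximum(f, 0.0), geometry.areas, geometry.adjacency,
                          params.E, params.H, dh)
    if not params.two_sided:
        return pos
    neg = _tfce_one_sided(np.maximum(-f, 0.0), geometry.areas, geometry.adjacency,
                          params.E, params.H, dh)
    return pos - neg


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    shape = p.shape
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(shape)


@dataclass
class VertexStats:
    """Per-vertex statistics for one covariate of interest."""

    name: str
    beta: np.ndarray
    t: np.ndarray
    tfce: np.ndarray
    p_perm: np.ndarray
    p_fdr: np.ndarray
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.p_fdr < self.alpha


def permutation_pvalues(
    Y: S2SMatrix | np.ndarray,
    X: DesignMatrix,
    target_columns: list[str],
    geometry: VertexGeometry,
    params: TFCEParams | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "freedman-lane",
) -> dict[str, dict[str, np.ndarray]]:
    """Vertex-wise permutation p-values for the TFCE-enhanced t statistic.

    Freedman-Lane: for each target column, fit the reduced model (all other
    columns), permute its residual rows, add back the reduced fit, refit the
    full model and TFCE-enhance the permuted t-map.  The add-one estimator
    p(v) = (1 + #{|TFCE_perm(v)| >= |TFCE_obs(v)|}) / (1 + n_perm) bounds the
    smallest attainable p at 1/(1 + n_perm).  ``scheme='label'`` permutes the
    target column itself instead (simple label permutation).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if scheme not in ("freedman-lane", "label"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    params = params or TFCEParams()
    y = Y.values if isinstance(Y, S2SMatrix) else np.asarray(Y, float)
    for name in target_columns:
        if name not in X.names:
            raise ValueError(f"target column {name!r} not in design")
    obs = fit_mur(y, X)
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, np.ndarray]] = {}
    n_s = y.shape[0]
    for name in target_columns:
        t_obs = obs.t_for(name)
        tfce_obs = tfce_enhance(t_obs, geometry, params)
        if scheme == "freedman-lane":
            Z = X.drop(name)
            pinv_z = np.linalg.pinv(Z.X)
            fitted = Z.X @ (pinv_z @ y)
            resid = y - fitted
        count = np.zeros(y.shape[1])
        for _ in range(n_perm):
            perm = rng.permutation(n_s)
            if scheme == "freedman-lane":
                y_star = fitted + resid[perm]
                fit_p = fit_mur(y_star, X)
            else:
                Xp = X.X.copy()
                j = X.names.index(name)
                Xp[:, j] = Xp[perm, j]
                fit_p = fit_mur(y, replace(X, X=Xp))
            tfce_p = tfce_enhance(fit_p.t_for(name), geometry, params)
            count += np.abs(tfce_p) >= np.abs(tfce_obs)
        p_perm = (1.0 + count) / (1.0 + n_perm)
        out[name] = {
            "beta": obs.beta_for(name),
            "t": t_obs,
            "tfce": tfce_obs,
            "p_perm": p_perm,
        }
    return out


def run_spm(
    Y: S2SMatrix | np.ndarray,
    X: DesignMatrix,
    target_columns: list[str],
    geometry: VertexGeometry,
    params: TFCEParams | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, VertexStats]:
    """Full inference for each target covariate: OLS, TFCE, permutation, FDR."""
    raw = permutation_pvalues(Y, X, target_columns, geometry, params, n_perm, seed)
    stats = {}
    for name, r in raw.items():
        stats[name] = VertexStats(
            name=name,
            beta=r["beta"],
            t=r["t"],
            tfce=r["tfce"],
            p_perm=r["p_perm"],
            p_fdr=bh_fdr(r["p_perm"]),
            alpha=alpha,
        )
    return stats


def _median_iqr(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return (np.nan, np.nan)
    q1, q3 = np.percentile(x, [25, 75])
    return float(np.median(x)), float(q3 - q1)


def summarise_spm(
    stats: dict[str, VertexStats] | list[VertexStats],
    alpha: float = 0.05,
    scope: str = "significant",
) -> pd.DataFrame:
    """Cohort-table summary: median (IQR) of beta split by sign + area %.

    ``scope='significant'`` computes the medians over significant vertices of
    each sign; ``scope='all'`` computes them over all vertices of each sign.
    Significance areas are always percentages of all vertices with FDR p <
    alpha, split by coefficient sign (a sign side with no significant vertex
    yields NaN medians — the table's blank cell).
    """
    if scope not in ("significant", "all"):
        raise ValueError("scope must be 'significant' or 'all'")
    items = stats.values() if isinstance(stats, dict) else stats
    rows = []
    for st in items:
        sig = st.p_fdr < alpha
        n_v = len(st.beta)
        neg_sig = sig & (st.beta < 0)
        pos_sig = sig & (st.beta > 0)
        if scope == "significant":
            neg_med, neg_iqr = _median_iqr(st.beta[neg_sig])
            pos_med, pos_iqr = _median_iqr(st.beta[pos_sig])
        else:
            neg_med, neg_iqr = _median_iqr(st.beta[st.beta < 0])
            pos_med, pos_iqr = _median_iqr(st.beta[st.beta > 0])
        rows.append(
            {
                "covariate": st.name,
                "beta_neg_median": neg_med,
                "beta_neg_iqr": neg_iqr,
                "area_neg_pct": 100.0 * neg_sig.sum() / n_v,
                "beta_pos_median": pos_med,
                "beta_pos_iqr": pos_iqr,
                "area_pos_pct": 100.0 * pos_sig.sum() / n_v,
                "area_total_pct": 100.0 * (neg_sig.sum() + pos_sig.sum()) / n_v,
            }
        )
    return pd.DataFrame(rows)


def interaction_rate_map(
    fit: MURFit | dict[str, VertexStats], main_term: str, interaction_term: str
) -> np.ndarray:
    """Combined per-vertex rate within a subgroup: beta_main + beta_interaction."""
    if isinstance(fit, MURFit):
        return fit.beta_for(main_term) + fit.beta_for(interaction_term)
    return fit[main_term].beta + fit[interaction_term].beta


def unstandardise(beta_std: float | np.ndarray, sd_s2s_mm: float) -> float | np.ndarray:
    """Convert a standardised coefficient to millimetres using the median
    per-vertex SD of the S2S distances."""
    if sd_s2s_mm <= 0:
        raise ValueError("sd must be > 0")
    return beta_std * sd_s2s_mm
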