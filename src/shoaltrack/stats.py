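"""Behavioural-syndrome statistics: PCA with varimax rotation and LMMs.

The seven behavioural variables are z-scored and decomposed by PCA on the
correlation matrix; the top k (default 3) components are varimax-rotated
(Kaiser-normalised) for interpretability, yielding axes conventionally
labelled sociability, boldness and activity.  Per-component scores are
then modelled with linear mixed models: experimental condition as a
categorical fixed effect (reference level "ambient") and experiment
number (batch) as a random intercept, because arenas recorded together
are not independent.

Varimax maximises the variance of squared loadings across components
under an orthogonal rotation; it preserves communalities, so the total
variance captured by the retained components is unchanged — only its
attribution moves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import PROFILE_FIELDS, BehaviouralProfile


@dataclass
class PCAResult:
    """Varimax-rotated PCA decomposition of a standardized variable matrix."""

    loadings: pd.DataFrame            # variables x components, rotated
    scores: np.ndarray                # units x components (regression method)
    variance_explained: np.ndarray    # per rotated component, proportion
    cumulative_variance: float        # total over retained components
    component_labels: list
    rotation_matrix: np.ndarray       # k x k orthogonal
    unrotated_loadings: pd.DataFrame
    eigenvalues: np.ndarray           # all p eigenvalues, descending
    score_correlation: pd.DataFrame = None  # reported, not assumed diagonal


@dataclass
class MixedModelResult:
    """One PC's mixed-model fit: condition contrasts + batch variance."""

    response: str
    table: pd.DataFrame               # rows: intercept + contrasts
    batch_variance: float
    residual_variance: float
    converged: bool = True


def profiles_to_matrix(profiles: Iterable[BehaviouralProfile],
                       impute_missing_time: bool = True) -> pd.DataFrame:
    """Units x 7 variable matrix (plus metadata columns left out).

    Fish that never reached the exploration threshold have
    ``time_to_explore_10pct`` imputed as the trial duration (conservative
    censoring at the recording length), flagged in the ``.attrs``.
    """
    from .io_trajectories import profiles_to_frame

    df = profiles_to_frame(profiles)
    X = df[list(PROFILE_FIELDS)].copy()
    n_imputed = 0
    if impute_missing_time:
        miss = ~np.isfinite(X["time_to_explore_10pct"])
        n_imputed = int(miss.sum())
        X.loc[miss, "time_to_explore_10pct"] = df.loc[miss, "duration_s"]
    X.attrs["n_time_imputed"] = n_imputed
    X.index = df["unit_id"]
    return X


def zscore(X: pd.DataFrame | np.ndarray
           ) -> Tuple[pd.DataFrame | np.ndarray, np.ndarray, np.ndarray]:
    """Standardize columns to mean 0, sd 1 (ddof=1).

    Raises on zero-variance columns, naming the variable.
    """
    arr = np.asarray(X, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 units to standardize")
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = (list(np.asarray(X.columns)[zero]) if hasattr(X, "columns")
                 else list(zero))
        raise ValueError(f"zero-variance column(s): {names}")
    Z = (arr - mu) / sd
    if hasattr(X, "columns"):
        Z = pd.DataFrame(Z, columns=X.columns, index=X.index)
    return Z, mu, sd


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            tol: float = 1e-8, max_iter: int = 1000
            ) -> Tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix).

    Classic pairwise-free SVD algorithm on the (optionally row-Kaiser-
    normalised) loading matrix.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.ones(p)
    if kaiser_normalize:
        h = np.sqrt((L ** 2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        B = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (B ** 3 - B @ np.diag((B ** 2).sum(axis=0)) / p))
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d - d_old < tol * d_old:
            break
        d_old = d
    rotated = (L @ R) * h[:, None]
    return rotated, R


def pca_varimax(Z: pd.DataFrame | np.ndarray, k: int = 3,
                component_labels: Sequence[str] | None = None) -> PCAResult:
    """PCA of the correlation matrix with varimax rotation of the top k.

    Input must already be standardized (see :func:`zscore`).  Scores are
    computed by the regression method from the rotated loadings; rotated
    components are sign-flipped so each one's largest-magnitude loading is
    positive.
    """
    arr = np.asarray(Z, dtype=float)
    n, p = arr.shape
    if k > p:
        raise ValueError(f"k={k} exceeds number of variables ({p})")
    corr = arr.T @ arr / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if k > int((evals > 1e-10).sum()):
        raise ValueError(f"k={k} exceeds the rank of the correlation matrix")
    # component loadings: correlations between variables and PCs
    L = evecs[:, :k] * np.sqrt(evals[:k])
    rotated, R = varimax(L)
    # sign convention: largest-|loading| entry of each component positive
    signs = np.sign(rotated[np.abs(rotated).argmax(axis=0),
                            np.arange(rotated.shape[1])])
    signs[signs == 0] = 1.0
    rotated = rotated * signs
    R = R * signs
    # regression-method factor scores
    W = np.linalg.solve(corr, rotated)
    scores = arr @ W

    var_names = (list(Z.columns) if hasattr(Z, "columns")
                 else [f"v{i+1}" for i in range(p)])
    labels = (list(component_labels) if component_labels
              else [f"PC{i+1}" for i in range(k)])
    rot_df = pd.DataFrame(rotated, index=var_names, columns=labels)
    unrot_df = pd.DataFrame(L, index=var_names,
                            columns=[f"PC{i+1}" for i in range(k)])
    sc = pd.DataFrame(scores, columns=labels)
    return PCAResult(
        loadings=rot_df,
        scores=scores,
        variance_explained=(rotated ** 2).sum(axis=0) / p,
        cumulative_variance=float(evals[:k].sum() / p),
        component_labels=labels,
        rotation_matrix=R,
        unrotated_loadings=unrot_df,
        eigenvalues=evals,
        score_correlation=sc.corr())


def fit_condition_lmm(scores: np.ndarray | Sequence[float],
                      condition: Sequence[str], batch: Sequence[str],
                      reference: str = "ambient",
                      response_label: str = "PC") -> MixedModelResult:
    """LMM: score ~ condition (fixed, treatment-coded vs ``reference``)
    + (1 | batch).

    Wald z p-values (normal approximation).  Singular fits are reported
    with a warning rather than raised.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = pd.DataFrame(dict(score=np.asarray(scores, dtype=float),
                           condition=list(condition), batch=list(batch)))
    levels = [reference] + sorted(set(df["condition"]) - {reference})
    df["condition"] = pd.Categorical(df["condition"], categories=levels)
    if df["condition"].isna().any():
        raise ValueError("condition contains levels outside the data")
    if df["condition"].nunique() < 2 or df["batch"].nunique() < 2:
        raise ValueError("need >= 2 conditions and >= 2 batches")

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate fits
        try:
            model = smf.mixedlm("score ~ condition", df, groups=df["batch"])
            fit = model.fit(reml=True, method="lbfgs")
            converged = bool(fit.converged)
        except np.linalg.LinAlgError:
            fit = smf.mixedlm("score ~ condition", df,
                              groups=df["batch"]).fit(reml=False)
            converged = False

    rows = []
    for name in fit.fe_params.index:
        if name == "Intercept":
            label = "intercept"
        else:
            lvl = name.split("T.")[-1].rstrip("]")
            label = f"{reference} versus {lvl}"
        rows.append(dict(term=label,
                         estimate=fit.fe_params[name],
                         se=fit.bse_fe[name],
                         t=fit.fe_params[name] / fit.bse_fe[name],
                         p=fit.pvalues[name]))
    table = pd.DataFrame(rows)
    return MixedModelResult(
        response=response_label,
        table=table,
        batch_variance=float(np.asarray(fit.cov_re)[0, 0]),
        residual_variance=float(fit.scale),
        converged=converged)


def fit_condition_lmms(pca: PCAResult, condition: Sequence[str],
                       batch: Sequence[str], reference: str = "ambient"
                       ) -> List[MixedModelResult]:
    """One mixed model per retained component."""
    return [fit_condition_lmm(pca.scores[:, j], condition, batch, reference,
                              response_label=pca.component_labels[j])
            for j in range(pca.scores.shape[1])]


def levene_variance_test(real_values: Sequence[float],
                         sim_values: Sequence[float]
                         ) -> Tuple[float, float]:
    """Median-centred Levene (Brown–Forsythe) test of equal variances."""
    from scipy import stats as sps

    a = np.asarray(real_values, dtype=float)
    b = np.asarray(sim_values, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 finite values in each sample")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("both samples are degenerate (zero spread)")
    res = sps.levene(a, b, center="median")
    return float(res.statistic), float(res.pvalue)
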