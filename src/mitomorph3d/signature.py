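"""Multivariate morphological disease signature: PLS-DA with VIP scores.

Eight per-individual features — percent simple/complex/small/large
mitochondria, median MCI, median volume, volume density and nanotunnels per
100 mitochondria — are assembled into a feature matrix and fed to a partial
least-squares discriminant analysis. PLS-DA regresses a one-hot group
response on the autoscaled features, extracting orthogonal score components
that maximise covariance with group membership; it is the standard choice
when features are collinear and n is small relative to p.

The NIPALS algorithm is implemented here directly (components are
deterministic given the input; no randomness is involved). Variable
importance in projection (VIP) summarises each feature's contribution,
weighted by the response variance each component explains; by construction
the mean squared VIP is 1, so features scoring above 1 contribute more than
average and are conventionally called discriminant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import CohortSummary

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureMatrix",
    "PLSDAModel",
    "assemble_features",
    "plsda_fit",
    "vip_scores",
    "predict_group",
]

FEATURE_COLUMNS = [
    "pct_simple",
    "pct_complex",
    "pct_small",
    "pct_large",
    "median_mci",
    "median_volume",
    "volume_density",
    "nanotunnels_per_100",
]

_SUMMARY_FIELD_OF = {
    "volume_density": "volume_density_pct",
}


@dataclass
class FeatureMatrix:
    """Individuals x morphological features, with aligned group labels."""

    X: pd.DataFrame  # index: subject_id; columns: FEATURE_COLUMNS order
    groups: pd.Series

    def __post_init__(self):
        if list(self.X.columns) != [c for c in FEATURE_COLUMNS if c in self.X.columns]:
            self.X = self.X[[c for c in FEATURE_COLUMNS if c in self.X.columns]]
        if self.X.isna().any().any():
            bad = self.X.columns[self.X.isna().any()].tolist()
            raise ValueError(f"missing feature values in columns {bad}")
        if not self.X.index.equals(self.groups.index):
            raise ValueError("group labels not aligned with feature rows")


@dataclass
class PLSDAModel:
    feature_names: list
    group_levels: list
    x_mean: np.ndarray
    x_scale: np.ndarray
    weights: np.ndarray  # p x a
    loadings: np.ndarray  # p x a
    y_loadings: np.ndarray  # g x a
    scores: np.ndarray  # n x a
    explained_x_variance: np.ndarray  # fraction per component
    explained_y_variance: np.ndarray
    centroids: dict = field(default_factory=dict)
    vip: np.ndarray | None = None
    dropped_columns: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


def assemble_features(summaries) -> FeatureMatrix:
    """Build the individuals x 8 feature matrix from cohort summaries.

    Accepts an iterable of :class:`CohortSummary` or a DataFrame with
    ``subject_id``, ``group`` and the eight feature columns. Missing values
    and duplicated subject ids are errors.
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries.copy()
    else:
        rows = []
        for s in summaries:
            if not isinstance(s, CohortSummary):
                raise TypeError(f"expected CohortSummary, got {type(s)!r}")
            row = {"subject_id": s.subject_id, "group": s.group}
            for col in FEATURE_COLUMNS:
                row[col] = getattr(s, _SUMMARY_FIELD_OF.get(col, col))
            rows.append(row)
        df = pd.DataFrame(rows)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicated subject id {dup!r}")
    missing_cols = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing feature columns {missing_cols}")
    for col in FEATURE_COLUMNS:
        if df[col].isna().any():
            who = df.loc[df[col].isna(), "subject_id"].iloc[0]
            raise ValueError(f"missing feature {col!r} for individual {who!r}")
    df = df.set_index("subject_id")
    return FeatureMatrix(X=df[FEATURE_COLUMNS].astype(float), groups=df["group"])


def plsda_fit(
    features: FeatureMatrix,
    n_components: int = 2,
    autoscale: bool = True,
    seed: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSDAModel:
    """Fit a PLS-DA model by NIPALS with a one-hot group response.

    Columns are mean-centred and (with ``autoscale``) scaled to unit
    variance; zero-variance columns are dropped with a warning. The fit is
    deterministic for a fixed row order — ``seed`` is reserved for
    permutation utilities and unused by NIPALS itself.
    """
    import warnings

    X_df = features.X
    groups = features.groups
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ValueError(f"need >= 2 individuals per group (group {lev!r})")
    n, p = X_df.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")

    x_sd_all = X_df.std(ddof=1)
    dropped = x_sd_all.index[x_sd_all == 0].tolist()
    if dropped:
        warnings.warn(f"dropping zero-variance feature columns {dropped}", stacklevel=2)
        X_df = X_df.drop(columns=dropped)
        p = X_df.shape[1]
    X = X_df.to_numpy(dtype=float)
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if autoscale else np.ones(p)
    E = (X - x_mean) / x_scale
    Y = np.column_stack([(groups == lev).astype(float) for lev in levels])
    F = Y - Y.mean(axis=0)

    ss_x_total = (E**2).sum()
    ss_y_total = (F**2).sum()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    T = np.zeros((n, n_components))
    expl_x = np.zeros(n_components)
    expl_y = np.zeros(n_components)
    for a in range(n_components):
        u = F[:, np.argmax((F**2).sum(axis=0))].copy()
        t_old = None
        for _ in range(max_iter):
            w = E.T @ u
            wn = np.linalg.norm(w)
            if wn < 1e-12:
                # X carries no covariance with the response (e.g. perfectly
                # confounded labels): fall back to the dominant X direction
                # so the component is still defined, with ~zero Y loading
                w = np.linalg.svd(E, full_matrices=False)[2][0]
            else:
                w = w / wn
            t = E @ w
            q = F.T @ t / (t @ t)
            if (q @ q) < 1e-24:
                break  # component carries no response variance
            u = F @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        p_load = E.T @ t / (t @ t)
        W[:, a] = w
        P[:, a] = p_load
        Q[:, a] = q
        T[:, a] = t
        expl_x[a] = (t @ t) * (p_load @ p_load) / ss_x_total
        expl_y[a] = (t @ t) * (q @ q) / ss_y_total
        E = E - np.outer(t, p_load)
        F = F - np.outer(t, q)

    model = PLSDAModel(
        feature_names=X_df.columns.tolist(),
        group_levels=levels,
        x_mean=x_mean,
        x_scale=x_scale,
        weights=W,
        loadings=P,
        y_loadings=Q,
        scores=T,
        explained_x_variance=expl_x,
        explained_y_variance=expl_y,
        dropped_columns=dropped,
    )
    model.centroids = {
        lev: T[(groups == lev).to_numpy()].mean(axis=0) for lev in levels
    }
    model.vip = vip_scores(model, ranked=False)
    return model


def vip_scores(model: PLSDAModel, ranked: bool = True):
    """Variable importance in projection per feature.

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ), with SSY_a the
    response variance explained by component a and w_a the (unit-norm)
    NIPALS weights. Mean squared VIP is exactly 1. With ``ranked`` a sorted
    DataFrame is returned, flagging features above the conventional VIP > 1
    line; otherwise the raw array in feature order.
    """
    W = model.weights
    ssy = model.explained_y_variance
    p = W.shape[0]
    denom = ssy.sum()
    if denom <= 0:
        vip = np.ones(p)
    else:
        vip = np.sqrt(p * (W**2 @ ssy) / denom)
    if not ranked:
        return vip
    df = pd.DataFrame({"feature": model.feature_names, "vip": vip})
    df["discriminant"] = df["vip"] > 1.0
    return df.sort_values("vip", ascending=False).reset_index(drop=True)


def _project(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    Xs = (X - model.x_mean) / model.x_scale
    W, P = model.weights, model.loadings
    # scores for new data: T = X W (P' W)^-1
    return Xs @ W @ np.linalg.inv(P.T @ W)


def predict_group(model: PLSDAModel, new_features) -> pd.DataFrame:
    """Project new individuals and call groups by nearest score centroid."""
    if isinstance(new_features, FeatureMatrix):
        df = new_features.X
    else:
        df = pd.DataFrame(new_features)
    missing = [c for c in model.feature_names if c not in df.columns]
    if missing:
        raise ValueError(f"feature columns missing from new data: {missing}")
    X = df[model.feature_names].to_numpy(dtype=float)
    scores = _project(model, X)
    calls = []
    for row in scores:
        dists = {lev: np.linalg.norm(row - c) for lev, c in model.centroids.items()}
        calls.append(min(dists, key=dists.get))
    out = pd.DataFrame(
        scores, columns=[f"comp{a + 1}" for a in range(model.n_components)], index=df.index
    )
    out["predicted_group"] = calls
    return out
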