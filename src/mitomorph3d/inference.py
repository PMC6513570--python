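"""Statistical comparisons for organelle-metric data.

Three tools cover the comparisons this kind of study needs: a Mann-Whitney
U test for two-group metric comparisons (exact by enumeration for small
samples, tie-corrected normal approximation otherwise), a Pearson chi-square
test for branching-class proportion tables, and a nested random-intercept
variance decomposition — mitochondria within cells within persons — fitted by
restricted maximum likelihood, optionally on log-transformed values (natural
log; metric distributions here are strongly right-skewed).

The REML fit optimises the restricted log-likelihood of the two-level
random-intercept model directly; the per-person covariance blocks are small,
so no sparse machinery is needed. A method-of-moments estimate provides the
starting point and the fallback for degenerate designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MannWhitneyResult",
    "NestedVarianceFit",
    "mann_whitney",
    "chi_square_proportions",
    "nested_variance_components",
]

EXACT_LIMIT = 20  # combined sample size up to which the U test is exact


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_two_sided: float
    method: str  # exact | normal


@dataclass
class NestedVarianceFit:
    """Random-intercept SDs (person, cell-within-person, residual)."""

    sd_person: float
    sd_cell: float
    sd_within: float
    fixed_effects: dict = field(default_factory=dict)
    method: str = "REML"
    log_transformed: bool = False
    flags: list = field(default_factory=list)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: #(x > y) + 0.5 #(x == y) over all pairs."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution by enumerating all group assignments of the
    pooled values when the combined sample size is at most 20 (ties handled
    exactly); otherwise the tie-corrected normal approximation with
    continuity correction. Two identical samples give p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    mean_u = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return MannWhitneyResult(u, 1.0, "exact")
    if n1 + n2 <= EXACT_LIMIT:
        # midranks make the per-assignment U a sum over chosen indices
        ranks = stats.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        dev = abs(u - mean_u)
        total = 0
        extreme = 0
        for idx in combinations(range(n1 + n2), n1):
            u_perm = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u_perm - mean_u) >= dev - 1e-12:
                extreme += 1
        return MannWhitneyResult(u, extreme / total, "exact")
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return MannWhitneyResult(u, 1.0, "normal")
    z = (abs(u - mean_u) - 0.5) / np.sqrt(var_u)
    p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
    return MannWhitneyResult(u, p, "normal")


def chi_square_proportions(counts) -> dict:
    """Pearson chi-square test on a k x m contingency table of class counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("counts must be a k x m table with k, m >= 2")
    expected = stats.contingency.expected_freq(counts)
    if (expected <= 0).any():
        raise ValueError("zero expected count; pool sparse classes before testing")
    statistic, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return {"statistic": float(statistic), "df": int(dof), "p": float(p)}


def _mom_components(df: pd.DataFrame) -> tuple[float, float, float]:
    """Method-of-moments starting values (variances, possibly crude)."""
    within = df.groupby(["_subject", "_cell"])["_y"].var(ddof=1).mean()
    within = float(np.nan_to_num(within, nan=0.0))
    cell_means = df.groupby(["_subject", "_cell"])["_y"].mean()
    n_per_cell = df.groupby(["_subject", "_cell"])["_y"].size().mean()
    cell_var = cell_means.groupby(level=0).var(ddof=1).mean()
    cell_var = float(np.nan_to_num(cell_var, nan=0.0)) - within / max(n_per_cell, 1.0)
    subj_means = df.groupby("_subject")["_y"].mean()
    n_cells = cell_means.groupby(level=0).size().mean()
    subj_var = float(subj_means.var(ddof=1)) - max(cell_var, 0.0) / max(n_cells, 1.0)
    total = float(df["_y"].var(ddof=1))
    floor = max(total, 1e-12) * 1e-6
    return (
        max(subj_var, floor),
        max(cell_var, floor),
        max(within, floor),
    )


def _reml_neg_loglik(log_vars, blocks, X_blocks, y_blocks):
    vp, vc, vw = np.exp(log_vars)
    logdet_v = 0.0
    xtvix = 0.0
    xtviy = 0.0
    ytviy = 0.0
    p = X_blocks[0].shape[1]
    xtvix = np.zeros((p, p))
    xtviy = np.zeros(p)
    for cells, X, y in zip(blocks, X_blocks, y_blocks):
        n_i = y.size
        Zc = np.zeros((n_i, len(cells)))
        start = 0
        for j, m in enumerate(cells):
            Zc[start : start + m, j] = 1.0
            start += m
        V = vw * np.eye(n_i) + vc * (Zc @ Zc.T) + vp * np.ones((n_i, n_i))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet_v += 2.0 * np.log(np.diag(L)).sum()
        Xi = np.linalg.solve(L, X)
        yi = np.linalg.solve(L, y)
        xtvix += Xi.T @ Xi
        xtviy += Xi.T @ yi
        ytviy += yi @ yi
    sign, logdet_x = np.linalg.slogdet(xtvix)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(xtvix, xtviy)
    rss = ytviy - beta @ xtviy
    return 0.5 * (logdet_v + logdet_x + rss)


def nested_variance_components(
    values,
    subject,
    cell,
    group=None,
    log_transform: bool = False,
) -> NestedVarianceFit:
    """REML variance components for mitochondria nested in cells in persons.

    Fits y = Xb + a_person + b_cell(person) + e with random intercepts at the
    person and cell level; ``group`` labels (if given) enter as fixed
    effects, whose estimated contrasts and standard errors are reported.
    With ``log_transform`` the response is natural-log transformed first
    (values must be positive), so the SDs are log-scale — the convention
    used for strongly skewed morphology metrics. Designs with a single cell
    per subject leave the cell component inestimable; it is reported as NaN
    with a flag.
    """
    df = pd.DataFrame({"_y": np.asarray(list(values), dtype=float)})
    df["_subject"] = np.asarray(list(subject))
    df["_cell"] = np.asarray(list(cell))
    if group is not None:
        df["_group"] = np.asarray(list(group))
    if log_transform:
        if (df["_y"] <= 0).any():
            raise ValueError("log_transform requires strictly positive values")
        df["_y"] = np.log(df["_y"])
    flags: list[str] = []
    if df["_subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if float(df["_y"].var(ddof=0)) == 0.0:
        return NestedVarianceFit(0.0, 0.0, 0.0, {}, "degenerate", log_transform, flags)

    cells_per_subject = df.groupby("_subject")["_cell"].nunique()
    cell_estimable = bool((cells_per_subject >= 2).any())
    if not cell_estimable:
        flags.append("cell_component_inestimable")

    # fixed-effect design: intercept + treatment-coded group contrasts
    if group is not None:
        levels = sorted(df["_group"].unique())
        ref = levels[0]
        X_cols = {"(intercept)": np.ones(len(df))}
        for lev in levels[1:]:
            X_cols[f"group[{lev}-{ref}]"] = (df["_group"] == lev).astype(float).to_numpy()
    else:
        X_cols = {"(intercept)": np.ones(len(df))}
    X_full = np.column_stack(list(X_cols.values()))

    blocks, X_blocks, y_blocks = [], [], []
    for _, sub in df.groupby("_subject", sort=True):
        sub = sub.sort_values("_cell", kind="stable")
        cells = sub.groupby("_cell", sort=True)["_y"].size().tolist()
        order = sub.index
        blocks.append(cells)
        X_blocks.append(X_full[df.index.get_indexer(order)])
        y_blocks.append(sub["_y"].to_numpy())

    vp0, vc0, vw0 = _mom_components(df)
    if not cell_estimable:
        vc0 = 1e-12

    if cell_estimable:
        x0 = np.log([vp0, vc0, vw0])
        objective = lambda lv: _reml_neg_loglik(lv, blocks, X_blocks, y_blocks)  # noqa: E731
    else:
        # one cell per subject: person and cell intercepts are confounded,
        # so pin the cell variance at zero and fit the two-level model
        x0 = np.log([vp0, vw0])
        objective = lambda lv: _reml_neg_loglik(  # noqa: E731
            np.array([lv[0], -60.0, lv[1]]), blocks, X_blocks, y_blocks
        )
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    if res.success or res.fun < objective(x0):
        if cell_estimable:
            vp, vc, vw = np.exp(res.x)
        else:
            vp, vw = np.exp(res.x)
            vc = 0.0
        method = "REML"
    else:  # pragma: no cover - optimizer failure falls back to moments
        vp, vc, vw = vp0, vc0, vw0
        method = "MoM"
        flags.append("reml_failed_mom_fallback")

    # fixed effects at the fitted covariance
    p = X_full.shape[1]
    xtvix = np.zeros((p, p))
    xtviy = np.zeros(p)
    for cells, X, y in zip(blocks, X_blocks, y_blocks):
        n_i = y.size
        Zc = np.zeros((n_i, len(cells)))
        start = 0
        for j, m in enumerate(cells):
            Zc[start : start + m, j] = 1.0
            start += m
        V = vw * np.eye(n_i) + vc * (Zc @ Zc.T) + vp * np.ones((n_i, n_i))
        L = np.linalg.cholesky(V)
        Xi = np.linalg.solve(L, X)
        yi = np.linalg.solve(L, y)
        xtvix += Xi.T @ Xi
        xtviy += Xi.T @ yi
    cov_beta = np.linalg.inv(xtvix)
    beta = cov_beta @ xtviy
    fixed = {
        name: {"estimate": float(b), "se": float(np.sqrt(cov_beta[i, i]))}
        for i, (name, b) in enumerate(zip(X_cols, beta))
    }
    return NestedVarianceFit(
        sd_person=float(np.sqrt(vp)),
        sd_cell=float(np.sqrt(vc)) if cell_estimable else float("nan"),
        sd_within=float(np.sqrt(vw)),
        fixed_effects=fixed,
        method=method,
        log_transformed=log_transform,
        flags=flags,
    )
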