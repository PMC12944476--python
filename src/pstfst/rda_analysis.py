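"""Redundancy analysis (RDA) with forward selection and permutation tests.

RDA is constrained ordination: the response matrix Y (sites x traits) is
regressed on the explanatory matrix X (sites x environmental variables) by
least squares, and the fitted values are eigen-decomposed into canonical
axes.  R^2 is the constrained fraction of the total response variance;
Ezekiel's adjustment corrects it for the number of explanatory variables.
Significance of the full model, of individual terms and of canonical axes
is assessed by permutation of a pseudo-F statistic.  Forward selection
admits variables one at a time under a double stopping rule: the marginal
permutation p-value of the added variable must not exceed alpha, and the
cumulative adjusted R^2 must not exceed that of the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import logger

__all__ = [
    "RdaModel",
    "rda_fit",
    "adjusted_r2",
    "permutation_tests",
    "forward_select",
]


@dataclass
class RdaModel:
    response_labels: list[str]
    explanatory_labels: list[str]
    r2: float
    adj_r2: float
    eigenvalues: np.ndarray
    site_scores: np.ndarray = field(repr=False)
    response_scores: np.ndarray = field(repr=False)
    biplot_scores: np.ndarray = field(repr=False)
    n: int = 0
    m: int = 0
    p_full: float | None = None
    p_terms: dict[str, float] | None = None
    p_axes: np.ndarray | None = None
    n_permutations: int = 0


def _as_matrix(data, name: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(c) for c in data.columns]
    arr = np.asarray(data, dtype=float)
    return arr, [f"{name}{i + 1}" for i in range(arr.shape[1])]


def _standardize(x: np.ndarray, scale: bool) -> np.ndarray:
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot standardise a constant column")
        x = x / sd
    return x


def _fit_r2(yc: np.ndarray, xc: np.ndarray) -> tuple[float, np.ndarray]:
    """(R^2, fitted values) of the multivariate least-squares projection."""
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    yhat = xc @ beta
    total = float((yc**2).sum())
    if total == 0:
        raise ValueError("response matrix has zero variance")
    return float((yhat**2).sum() / total), yhat


def adjusted_r2(r2: float, n_sites: int, m_vars: int) -> float:
    """Ezekiel's adjustment 1 - (1 - R^2)(n - 1)/(n - m - 1); may be
    negative for weak models."""
    if n_sites <= m_vars + 1:
        raise ValueError("adjusted R^2 requires n > m + 1")
    return 1.0 - (1.0 - r2) * (n_sites - 1) / (n_sites - m_vars - 1)


def _collinear_columns(xc: np.ndarray, labels: list[str]) -> list[str]:
    """Columns that do not increase the rank when added left to right."""
    bad = []
    rank = 0
    kept: list[int] = []
    for j in range(xc.shape[1]):
        r = np.linalg.matrix_rank(xc[:, kept + [j]])
        if r > rank:
            rank = r
            kept.append(j)
        else:
            bad.append(labels[j])
    return bad


def rda_fit(Y, X, standardize: bool = True) -> RdaModel:
    """Fit an RDA of Y on X.

    Columns are centred, and scaled to unit variance when ``standardize``.
    Canonical axes come from the SVD of the fitted values; axis signs are
    canonicalised so the first non-zero response loading is positive.
    """
    y, y_labels = _as_matrix(Y, "trait")
    x, x_labels = _as_matrix(X, "var")
    n, m = x.shape
    if y.shape[0] != n:
        raise ValueError("Y and X must have the same number of sites")
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("missing cells are not allowed in RDA input")
    if n <= m + 1:
        raise ValueError(f"RDA needs n > m + 1 sites (n={n}, m={m})")
    yc = _standardize(y, standardize)
    xc = _standardize(x, standardize)
    if np.linalg.matrix_rank(xc) < m:
        raise ValueError(
            f"explanatory matrix is rank deficient; collinear columns: "
            f"{_collinear_columns(xc, x_labels)}"
        )
    r2, yhat = _fit_r2(yc, xc)
    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    eig = s**2 / (n - 1)
    n_axes = min(m, y.shape[1])
    eig = eig[:n_axes]
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    # canonical sign: first non-zero response loading positive per axis
    for a in range(n_axes):
        load = vt[a]
        nz = np.nonzero(np.abs(load) > 1e-12)[0]
        if nz.size and load[nz[0]] < 0:
            vt[a] *= -1
            u[:, a] *= -1
    site_scores = u * s
    response_scores = vt.T
    xn = xc / np.sqrt((xc**2).sum(axis=0, keepdims=True))
    biplot = xn.T @ u  # correlation-like variable scores on the axes
    return RdaModel(
        response_labels=y_labels,
        explanatory_labels=x_labels,
        r2=r2,
        adj_r2=adjusted_r2(r2, n, m),
        eigenvalues=eig,
        site_scores=site_scores,
        response_scores=response_scores,
        biplot_scores=biplot,
        n=n,
        m=m,
    )


def _pseudo_f(r2: float, n: int, m: int) -> float:
    return (r2 / m) / ((1.0 - r2) / (n - m - 1))


def permutation_tests(
    Y,
    X,
    which: str = "full",
    n_perm: int = 999,
    seed: int | None = None,
    standardize: bool = True,
):
    """Permutation p-values for a fitted RDA.

    ``full``: rows of Y permuted, pseudo-F of the whole model.
    ``terms``: marginal test per variable by Freedman-Lane residual
    permutation under the model without that variable.
    ``axes``: per-axis pseudo-F with rows of Y permuted.
    p = (count + 1)/(n_perm + 1).
    """
    if n_perm < 99:
        logger.warning("n_perm < 99 gives a coarse p-value resolution")
    y, _ = _as_matrix(Y, "trait")
    x, x_labels = _as_matrix(X, "var")
    n, m = x.shape
    yc = _standardize(y, standardize)
    xc = _standardize(x, standardize)
    rng = np.random.default_rng(seed)
    r2, yhat = _fit_r2(yc, xc)
    if which == "full":
        f_obs = _pseudo_f(r2, n, m)
        count = 0
        for _ in range(n_perm):
            r2_p, _ = _fit_r2(yc[rng.permutation(n)], xc)
            if _pseudo_f(r2_p, n, m) >= f_obs:
                count += 1
        return (count + 1) / (n_perm + 1)
    if which == "terms":
        out: dict[str, float] = {}
        for j, label in enumerate(x_labels):
            reduced = np.delete(xc, j, axis=1)
            if reduced.shape[1]:
                r2_red, yhat_red = _fit_r2(yc, reduced)
            else:
                r2_red, yhat_red = 0.0, np.zeros_like(yc)
            resid = yc - yhat_red
            f_obs = (r2 - r2_red) / ((1.0 - r2) / (n - m - 1))
            count = 0
            for _ in range(n_perm):
                y_star = yhat_red + resid[rng.permutation(n)]
                r2_full_p, _ = _fit_r2(y_star, xc)
                r2_red_p, _ = _fit_r2(y_star, reduced) if reduced.shape[1] else (0.0, None)
                f_p = (r2_full_p - r2_red_p) / ((1.0 - r2_full_p) / (n - m - 1))
                if f_p >= f_obs:
                    count += 1
            out[label] = (count + 1) / (n_perm + 1)
        return out
    if which == "axes":
        total = float((yc**2).sum())
        _, s, _ = np.linalg.svd(yhat, full_matrices=False)
        n_axes = min(m, yc.shape[1])
        f_obs = (s[:n_axes] ** 2 / total) / ((1.0 - r2) / (n - m - 1))
        counts = np.zeros(n_axes)
        for _ in range(n_perm):
            r2_p, yhat_p = _fit_r2(yc[rng.permutation(n)], xc)
            _, s_p, _ = np.linalg.svd(yhat_p, full_matrices=False)
            f_p = (s_p[:n_axes] ** 2 / total) / ((1.0 - r2_p) / (n - m - 1))
            counts += f_p >= f_obs
        return (counts + 1) / (n_perm + 1)
    raise ValueError(f"unknown test {which!r}")


def forward_select(
    Y,
    X,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    standardize: bool = True,
) -> tuple[list[str], RdaModel | None, pd.DataFrame]:
    """Forward selection of explanatory variables for the RDA.

    At each step the candidate adding the most R^2 is tested; it is
    admitted only if (a) the step's permutation p <= alpha, where the null
    statistic is the *maximum* added-variance pseudo-F over all remaining
    candidates (so picking the best of several candidates does not inflate
    admission), and (b) from the second step onward, the cumulative
    adjusted R^2 stays at or below the full model's adjusted R^2 (the
    overfitting cap of the double stopping rule; the first admitted
    variable is exempt because a single strong predictor may legitimately
    beat the full model on the adjusted scale).  Returns the selected
    labels, the RDA refitted on the selection (None when nothing is
    admissible) and a per-step trace.
    """
    y, _ = _as_matrix(Y, "trait")
    x, x_labels = _as_matrix(X, "var")
    n, m = x.shape
    yc = _standardize(y, standardize)
    xc = _standardize(x, standardize)
    full_r2, _ = _fit_r2(yc, xc[:, _independent_columns(xc)])
    m_eff = len(_independent_columns(xc))
    adj_cap = adjusted_r2(full_r2, n, m_eff)
    rng = np.random.default_rng(seed)
    selected: list[int] = []
    trace_rows = []
    current_r2 = 0.0

    def step_f(y_mat: np.ndarray, cols: np.ndarray, r2_red: float, m_try: int) -> float:
        r2_f, _ = _fit_r2(y_mat, cols)
        return (r2_f - r2_red) / ((1.0 - r2_f) / (n - m_try - 1))

    while len(selected) < m:
        if n <= len(selected) + 2:
            break  # no residual degrees of freedom left
        candidates = []
        best_j, best_r2 = -1, current_r2
        for j in range(m):
            if j in selected:
                continue
            r2_try, _ = _fit_r2(yc, xc[:, selected + [j]])
            if r2_try > current_r2 + 1e-12:
                candidates.append(j)
            if r2_try > best_r2 + 1e-12:
                best_j, best_r2 = j, r2_try
        if best_j < 0:
            break
        # Freedman-Lane residual permutation; the null statistic is the
        # best candidate's pseudo-F under each permutation
        reduced = xc[:, selected]
        if reduced.shape[1]:
            r2_red, yhat_red = _fit_r2(yc, reduced)
        else:
            r2_red, yhat_red = 0.0, np.zeros_like(yc)
        resid = yc - yhat_red
        m_try = len(selected) + 1
        f_obs = (best_r2 - r2_red) / ((1.0 - best_r2) / (n - m_try - 1))
        count = 0
        for _ in range(n_perm):
            y_star = yhat_red + resid[rng.permutation(n)]
            if reduced.shape[1]:
                r2_red_p, _ = _fit_r2(y_star, reduced)
            else:
                r2_red_p = 0.0
            f_max = max(
                step_f(y_star, xc[:, selected + [j]], r2_red_p, m_try)
                for j in candidates
            )
            if f_max >= f_obs:
                count += 1
        p = (count + 1) / (n_perm + 1)
        adj_try = adjusted_r2(best_r2, n, m_try)
        admitted = p <= alpha and (not selected or adj_try <= adj_cap + 1e-12)
        trace_rows.append(
            (x_labels[best_j], best_r2, adj_try, p, admitted)
        )
        if not admitted:
            break
        selected.append(best_j)
        current_r2 = best_r2
    trace = pd.DataFrame(
        trace_rows, columns=["variable", "cum_r2", "cum_adj_r2", "p_value", "admitted"]
    )
    labels = [x_labels[j] for j in selected]
    if not labels:
        logger.warning("forward selection admitted no variables")
        return [], None, trace
    x_sel = x[:, selected]
    model = rda_fit(
        pd.DataFrame(y, columns=_as_matrix(Y, "trait")[1]),
        pd.DataFrame(x_sel, columns=labels),
        standardize=standardize,
    )
    return labels, model, trace


def _independent_columns(xc: np.ndarray) -> list[int]:
    kept: list[int] = []
    rank = 0
    for j in range(xc.shape[1]):
        r = np.linalg.matrix_rank(xc[:, kept + [j]])
        if r > rank:
            rank = r
            kept.append(j)
    return kept
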