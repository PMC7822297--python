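"""Multivariate-response conditional inference tree and node-wise tests.

Individuals are grouped by binary recursive partitioning in a conditional
inference (permutation-test) framework: at each node, the association
between every covariate and the bivariate (d13C, d18O) response is measured
by the linear statistic

    T = sum_i g(X_i) h(Y_i)^T,

standardized by its conditional expectation and covariance under the
permutation distribution (Strasser & Weber moments). The quadratic form of
the standardized statistic is referred to its asymptotic chi-square
distribution; p-values are Bonferroni-adjusted across the covariates tested
at the node. Splitting stops when no adjusted p-value falls below alpha or
a node is too small; otherwise the node splits on the most significant
covariate at the cutpoint maximizing the standardized two-sample statistic.

The classical follow-up tests used to describe the resulting groups
(Welch t, Pillai-trace MANOVA, one-way ANOVA with Tukey HSD) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult", "CITNode", "ConditionalInferenceTree",
    "fit_cit", "welch_t", "manova_pillai", "anova_tukey",
]

_RANK_TOL = 1e-10


@dataclass
class TestResult:
    """A classical test outcome: statistic, df (scalar or pair), p-value."""

    statistic: float
    df: object
    p: float
    estimate: float | None = None
    name: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


# ---------------------------------------------------------------------------
# permutation-framework independence test
# ---------------------------------------------------------------------------

def _independence_test(g: np.ndarray, h: np.ndarray):
    """Quadratic-form test of independence between transformed covariate g
    (n, p) and influence h (n, q) under the permutation distribution.

    Returns (statistic, df, p). With g column-centered the conditional
    expectation of T vanishes and its covariance is kron(GtG * n/(n-1), V)
    where V is the (biased) covariance of h.
    """
    n = g.shape[0]
    if n < 2:
        return 0.0, 0, 1.0
    gc = g - g.mean(axis=0, keepdims=True)
    hc = h - h.mean(axis=0, keepdims=True)
    d = (gc.T @ h).ravel()                      # T - mu, shape (p*q,)
    V = (hc.T @ hc) / n                         # cov of h under permutation
    A = (gc.T @ gc) * (n / (n - 1.0))
    sigma = np.kron(A, V)
    scale = np.abs(sigma).max()
    if scale == 0.0:
        return 0.0, 0, 1.0
    rank = np.linalg.matrix_rank(sigma, tol=_RANK_TOL * scale)
    if rank == 0:
        return 0.0, 0, 1.0
    stat = float(d @ np.linalg.pinv(sigma, rcond=_RANK_TOL) @ d)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, rank))
    return stat, int(rank), p


def _encode_covariate(x: pd.Series):
    """(g matrix, complete-case row mask, kind, levels) for one covariate."""
    if pd.api.types.is_numeric_dtype(x):
        vals = x.to_numpy(dtype=float)
        ok = np.isfinite(vals)
        return vals[ok, None], ok, "numeric", None
    codes, levels = pd.factorize(x, use_na_sentinel=True)
    ok = codes >= 0
    k = len(levels)
    g = np.zeros((int(ok.sum()), k))
    g[np.arange(int(ok.sum())), codes[ok]] = 1.0
    return g, ok, "categorical", list(levels)


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

@dataclass
class CITNode:
    node_id: int
    indices: np.ndarray                 # positions into the fitted table
    selected_covariate: str | None = None
    adjusted_p: float | None = None     # min Bonferroni-adjusted p at the node
    p_values: dict = field(default_factory=dict)
    cutpoint: object = None             # float (<=) or frozenset of levels
    children: tuple | None = None
    is_terminal: bool = True

    @property
    def n(self) -> int:
        return self.indices.size


class ConditionalInferenceTree:
    """Recursive partitioning with permutation-framework stopping rules.

    Parameters
    ----------
    alpha : float
        Significance level for the Bonferroni-adjusted node tests.
    min_node_size : int
        Smallest admissible child node; nodes with fewer than
        ``2 * min_node_size`` observations are not tested for splitting.
    max_depth : int or None
        Optional depth cap (root has depth 0).

    Attributes (after :meth:`fit`)
    ------------------------------
    root_ : CITNode
    nodes_ : list[CITNode]          in depth-first pre-order (ids match)
    labels_ : ndarray of int        terminal node id per fitted row
    """

    def __init__(self, alpha: float = 0.05, min_node_size: int = 7,
                 max_depth: int | None = None):
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        self.alpha = alpha
        self.min_node_size = min_node_size
        self.max_depth = max_depth

    # -- fitting ----------------------------------------------------------

    def fit(self, records: pd.DataFrame,
            covariates: list[str],
            response=("d13C_raw", "d18O_raw")):
        if len(records) < 2 * self.min_node_size:
            raise ValueError(
                f"need at least {2 * self.min_node_size} records to fit "
                f"(got {len(records)})"
            )
        self._df = records.reset_index(drop=True)
        self._Y = self._df[list(response)].to_numpy(dtype=float)
        if np.any(~np.isfinite(self._Y)):
            raise ValueError("response contains missing values; filter records first")
        self._covariates = list(covariates)
        self.response_ = tuple(response)
        self._next_id = 1
        self.nodes_ = []
        self.root_ = self._build(np.arange(len(self._df)), depth=0)
        self.labels_ = np.empty(len(self._df), dtype=int)
        for node in self.nodes_:
            if node.is_terminal:
                self.labels_[node.indices] = node.node_id
        return self

    def _build(self, indices: np.ndarray, depth: int) -> CITNode:
        node = CITNode(node_id=self._next_id, indices=indices)
        self._next_id += 1
        self.nodes_.append(node)

        if indices.size < 2 * self.min_node_size:
            return node
        if self.max_depth is not None and depth >= self.max_depth:
            return node

        best_name, best_p, pvals = self._test_node(indices)
        node.p_values = pvals
        if best_name is None:
            return node
        node.adjusted_p = best_p
        if best_p > self.alpha:
            return node

        split = self._best_split(indices, best_name)
        if split is None:
            return node
        cutpoint, left_idx, right_idx = split
        node.selected_covariate = best_name
        node.cutpoint = cutpoint
        node.is_terminal = False
        left = self._build(left_idx, depth + 1)
        right = self._build(right_idx, depth + 1)
        node.children = (left, right)
        return node

    def _test_node(self, indices):
        """Bonferroni-adjusted independence tests for every covariate."""
        sub = self._df.iloc[indices]
        h_full = self._Y[indices]
        raw = {}
        for name in self._covariates:
            g, ok, _, _ = _encode_covariate(sub[name])
            if ok.sum() < 2:
                continue
            _, _, p = _independence_test(g, h_full[ok])
            raw[name] = p
        if not raw:
            return None, None, {}
        m = len(raw)
        adjusted = {k: min(1.0, v * m) for k, v in raw.items()}
        best = min(adjusted, key=lambda k: (adjusted[k], self._covariates.index(k)))
        return best, adjusted[best], adjusted

    def _best_split(self, indices, name):
        """Cutpoint maximizing the standardized two-sample statistic.

        Returns (cutpoint, left_indices, right_indices) or None if no split
        satisfies the minimum node size. Rows with a missing split value are
        sent to the child with more complete-case observations.
        """
        sub = self._df.iloc[indices]
        g, ok, kind, levels = _encode_covariate(sub[name])
        h = self._Y[indices][ok]
        n = h.shape[0]
        if n < 2 * self.min_node_size:
            return None
        hc = h - h.mean(axis=0, keepdims=True)
        V = (hc.T @ hc) / n
        Vp = np.linalg.pinv(V, rcond=_RANK_TOL)
        obs_idx = indices[ok]
        miss_idx = indices[~ok]

        if kind == "numeric":
            x = g[:, 0]
            order = np.argsort(x, kind="stable")
            xs, hs = x[order], hc[order]
            csum = np.cumsum(hs, axis=0)
            # candidate boundaries: after each position where x changes
            change = np.flatnonzero(np.diff(xs) > 0) + 1   # left sizes
            valid = change[(change >= self.min_node_size)
                           & (n - change >= self.min_node_size)]
            if valid.size == 0:
                return None
            d = csum[valid - 1]                            # (m, q), sum of hc on left
            a = valid * (n - valid) / (n - 1.0)
            statv = np.einsum("ij,jk,ik->i", d, Vp, d) / a
            best = int(np.argmax(statv))                   # ties -> smaller cutpoint
            nl = int(valid[best])
            cutpoint = float(xs[nl - 1])                   # max observed left value
            left_local = order[:nl]
            right_local = order[nl:]
        else:
            k = g.shape[1]
            if k < 2:
                return None
            level_sums = g.T @ hc                          # (k, q)
            level_counts = g.sum(axis=0)
            best_stat, best_subset = -np.inf, None
            # enumerate proper subsets containing level 0 (complement symmetry)
            for code in range((1 << (k - 1)) - 1):
                sel = np.array([True] + [(code >> b) & 1 == 1 for b in range(k - 1)])
                nl = level_counts[sel].sum()
                if nl < self.min_node_size or n - nl < self.min_node_size:
                    continue
                d = level_sums[sel].sum(axis=0)
                a = nl * (n - nl) / (n - 1.0)
                s = float(d @ Vp @ d) / a
                if s > best_stat + 1e-12:
                    best_stat, best_subset = s, sel
            if best_subset is None:
                return None
            cutpoint = frozenset(levels[i] for i in range(k) if best_subset[i])
            member = g[:, best_subset].sum(axis=1) > 0
            left_local = np.flatnonzero(member)
            right_local = np.flatnonzero(~member)
        left_idx = obs_idx[left_local]
        right_idx = obs_idx[right_local]
        if miss_idx.size:
            if left_idx.size >= right_idx.size:
                left_idx = np.concatenate([left_idx, miss_idx])
            else:
                right_idx = np.concatenate([right_idx, miss_idx])
        return cutpoint, np.sort(left_idx), np.sort(right_idx)

    # -- inspection -------------------------------------------------------

    def terminal_nodes(self) -> list[CITNode]:
        return [nd for nd in self.nodes_ if nd.is_terminal]

    def assign_groups(self, label_format: str = "node_{id}") -> pd.DataFrame:
        """Fitted table with a ``group_label`` column (terminal node id)."""
        out = self._df.copy()
        out["group_label"] = [label_format.format(id=i) for i in self.labels_]
        out["group_label"] = out["group_label"].astype("string")
        return out

    def node_table(self) -> pd.DataFrame:
        rows = []
        for nd in self.nodes_:
            cut = nd.cutpoint
            if isinstance(cut, frozenset):
                cut = "{" + ",".join(sorted(map(str, cut))) + "}"
            rows.append({
                "node_id": nd.node_id,
                "n": nd.n,
                "terminal": nd.is_terminal,
                "split_var": nd.selected_covariate,
                "adjusted_p": nd.adjusted_p,
                "cutpoint": cut,
            })
        return pd.DataFrame(rows)


def fit_cit(records: pd.DataFrame, covariates, response=("d13C_raw", "d18O_raw"),
            alpha: float = 0.05, min_node_size: int = 7) -> ConditionalInferenceTree:
    """Convenience wrapper: fit a tree and return it."""
    return ConditionalInferenceTree(alpha=alpha, min_node_size=min_node_size).fit(
        records, covariates=list(covariates), response=response)


# ---------------------------------------------------------------------------
# classical follow-up tests
# ---------------------------------------------------------------------------

def welch_t(a, b) -> TestResult:
    """Welch's two-sample t-test (unequal variances), two-sided."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      estimate=float(a.mean() - b.mean()), name="welch_t")


def manova_pillai(groups) -> TestResult:
    """One-way MANOVA: Pillai trace with its approximate F.

    ``groups`` is a sequence of (n_i, q) arrays. Degenerate response
    dimensions (zero total scatter) are dropped before the F approximation,
    so a constant second response reduces exactly to the univariate ANOVA F.
    """
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    Y = np.vstack(groups)
    N, q = Y.shape
    grand = Y.mean(axis=0)
    H = np.zeros((q, q))
    E = np.zeros((q, q))
    for g in groups:
        m = g.mean(axis=0)
        H += g.shape[0] * np.outer(m - grand, m - grand)
        dc = g - m
        E += dc.T @ dc
    total = H + E
    scale = np.abs(total).max()
    if scale == 0.0:
        return TestResult(0.0, (0.0, 0.0), 1.0, name="manova_pillai")
    q_eff = int(np.linalg.matrix_rank(total, tol=_RANK_TOL * scale))
    pillai = float(np.trace(H @ np.linalg.pinv(total, rcond=_RANK_TOL)))
    s = min(q_eff, k - 1)
    if s == 0:
        return TestResult(0.0, (0.0, 0.0), 1.0, name="manova_pillai")
    m = (abs(q_eff - (k - 1)) - 1) / 2.0
    n_ = (N - k - q_eff - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_ + s + 1)
    if pillai >= s:                       # perfect separation
        return TestResult(np.inf, (df1, df2), 0.0, estimate=pillai,
                          name="manova_pillai")
    F = (pillai / (s - pillai)) * ((2 * n_ + s + 1) / (2 * m + s + 1))
    p = float(stats.f.sf(F, df1, df2)) if df2 > 0 else np.nan
    return TestResult(float(F), (float(df1), float(df2)), p,
                      estimate=pillai, name="manova_pillai")


def anova_tukey(groups, labels=None):
    """One-way ANOVA followed by Tukey HSD pairwise comparisons.

    Returns ``(anova, pairs)``; each pair (j > i) is labelled "j-i" with
    estimate mean(group_j) - mean(group_i), matching the later-minus-earlier
    orientation of standard post-hoc tables.
    """
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    if labels is None:
        labels = [str(i + 1) for i in range(k)]
    N = sum(g.size for g in groups)
    df = (float(k - 1), float(N - k))
    within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    grand = np.concatenate(groups).mean()
    between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    if within == 0.0 and between == 0.0:
        anova = TestResult(0.0, df, 1.0, name="anova")
        pairs = [TestResult(0.0, df[1], 1.0, estimate=0.0,
                            name=f"{labels[j]}-{labels[i]}")
                 for i in range(k) for j in range(i + 1, k)]
        return anova, pairs
    fres = stats.f_oneway(*groups)
    anova = TestResult(float(fres.statistic), df, float(fres.pvalue), name="anova")
    tk = stats.tukey_hsd(*groups)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            pairs.append(TestResult(
                statistic=float(tk.statistic[j, i]),
                df=df[1],
                p=float(tk.pvalue[j, i]),
                estimate=float(groups[j].mean() - groups[i].mean()),
                name=f"{labels[j]}-{labels[i]}",
            ))
    return anova, pairs
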