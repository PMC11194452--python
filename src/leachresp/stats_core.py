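"""Rank and permutation statistics implemented from first principles.

Every test statistic here (Kruskal–Wallis H, Dunn z, Spearman rho,
Bray–Curtis dissimilarity, PERMANOVA pseudo-F) is computed directly from
its defining formula rather than delegated to a statistics package, so the
whole inferential chain of the analysis is auditable in one module.
scipy is used only for distribution functions (chi-square and normal
survival functions) and rank assignment.

Conventions
-----------
* Ties are handled with mid-ranks throughout; the Kruskal–Wallis tie
  correction factor is applied.
* Permutation p-values use the add-one estimator
  ``p = (1 + #{perm stat >= observed}) / (1 + n_perm)`` so that
  ``p ∈ [1/(n_perm+1), 1]`` and the test is exact-valid.
* All permutation routines take an explicit seed and are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import rankdata as _rankdata

__all__ = [
    "GroupedValues",
    "DistanceMatrix",
    "TestResult",
    "PermanovaResult",
    "shannon_index",
    "pielou_evenness",
    "kruskal_wallis",
    "dunn_posthoc",
    "spearman",
    "bray_curtis",
    "permanova",
    "holm_adjust",
]


class DegenerateInputError(ValueError):
    """Raised when an input is structurally unable to support the statistic."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class GroupedValues:
    """A numeric vector with a categorical group label per observation."""

    values: np.ndarray
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        g = np.asarray(self.group_labels)
        if v.shape != g.shape or v.ndim != 1:
            raise ValueError("values and group_labels must be 1-D and equal length")
        if v.size < 2:
            raise DegenerateInputError("need at least 2 observations")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "group_labels", g)

    def split(self) -> dict:
        return {
            lab: self.values[self.group_labels == lab]
            for lab in pd.unique(self.group_labels)
        }


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with sample labels."""

    labels: tuple
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        labels = tuple(self.labels)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(labels) != d.shape[0]:
            raise ValueError("label count must match matrix size")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    pairwise: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class PermanovaResult:
    """Sequential (Type I) variance partition over a two-factor design."""

    table: pd.DataFrame  # rows: terms + Residual + Total; cols SS, df, R2, F, p_perm
    n_permutations: int
    seed: int | None

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p_perm"])


# ---------------------------------------------------------------------------
# diversity indices


def shannon_index(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log), zeros ignored."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero count vector has no diversity")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum()) + 0.0


def pielou_evenness(counts) -> float:
    """Pielou evenness J = H / ln(nASV), defined only for richness >= 2."""
    c = np.asarray(counts, dtype=float)
    richness = int((c > 0).sum())
    if richness < 2:
        raise DegenerateInputError(
            f"evenness undefined for richness {richness} (needs >= 2 taxa)"
        )
    return shannon_index(c) / np.log(richness)


# ---------------------------------------------------------------------------
# rank tests


def _tie_term(values: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def kruskal_wallis(g: GroupedValues) -> TestResult:
    """Kruskal–Wallis H test with mid-ranks and tie correction.

    H = 12/(N(N+1)) * sum n_j (Rbar_j - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from chi2 with k-1 df.
    """
    groups = g.split()
    k = len(groups)
    if k < 2:
        raise DegenerateInputError("Kruskal–Wallis needs >= 2 groups")
    for lab, v in groups.items():
        if v.size == 0:
            raise DegenerateInputError(f"group {lab!r} is empty")
    n = g.values.size
    ranks = _rankdata(g.values)
    mean_rank = (n + 1) / 2.0
    h = 0.0
    for lab in groups:
        r = ranks[g.group_labels == lab]
        h += r.size * (r.mean() - mean_rank) ** 2
    h *= 12.0 / (n * (n + 1))
    correction = 1.0 - _tie_term(g.values) / (n**3 - n)
    if correction <= 0:  # all observations identical
        return TestResult(0.0, 1.0, "kruskal-wallis")
    h /= correction
    p = float(_chi2.sf(h, k - 1))
    return TestResult(float(h), p, "kruskal-wallis", extra={"df": k - 1})


def dunn_posthoc(g: GroupedValues, adjust: str = "holm") -> TestResult:
    """Dunn's post hoc pairwise comparisons on mean ranks after Kruskal–Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt(sigma2 * (1/n_i + 1/n_j)) with
    sigma2 = N(N+1)/12 - tie_term/(12(N-1)); two-sided normal p, optionally
    Holm step-down adjusted.
    """
    if adjust not in ("none", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    kruskal_wallis(g)  # validates the grouping structure
    groups = g.split()
    n = g.values.size
    ranks = _rankdata(g.values)
    mean_ranks = {lab: ranks[g.group_labels == lab].mean() for lab in groups}
    sizes = {lab: int((g.group_labels == lab).sum()) for lab in groups}
    sigma2 = n * (n + 1) / 12.0 - _tie_term(g.values) / (12.0 * (n - 1))
    labs = list(groups)
    rows = []
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            a, b = labs[i], labs[j]
            se = np.sqrt(sigma2 * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
            p_raw = float(2.0 * _norm.sf(abs(z)))
            rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": min(p_raw, 1.0)})
    table = pd.DataFrame(rows)
    table["p_adj"] = (
        holm_adjust(table["p_raw"].to_numpy()) if adjust == "holm" else table["p_raw"]
    )
    zmax = float(table["z"].abs().max()) if len(table) else 0.0
    pmin = float(table["p_adj"].min()) if len(table) else 1.0
    return TestResult(zmax, pmin, f"dunn-{adjust}", pairwise=table)


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment with enforced monotonicity; p_adj >= p."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def spearman(x, y, n_perm: int = 9999, seed: int | None = None) -> TestResult:
    """Spearman rank correlation with a two-sided permutation p-value.

    rho is the Pearson correlation of mid-ranks; the null distribution is
    built by permuting y's ranks, which stays valid at the small sample
    sizes (n = 6–18) typical of replicated incubation designs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    rx = _rankdata(x)
    ry = _rankdata(y)

    def _pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float((a @ b) / np.sqrt((a @ a) * (b @ b)))

    rho = _pearson(rx, ry)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if abs(_pearson(rx, rng.permutation(ry))) >= abs(rho) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return TestResult(rho, float(p), "spearman-permutation", extra={"n_perm": n_perm})


# ---------------------------------------------------------------------------
# community dissimilarity and PERMANOVA


def bray_curtis(abund: pd.DataFrame) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between sample rows.

    d(a, b) = sum|a_i - b_i| / sum(a_i + b_i). Rows are samples, columns
    taxa; entries must be non-negative (counts or relative abundances).
    """
    x = np.asarray(abund, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    labels = (
        tuple(abund.index) if isinstance(abund, pd.DataFrame) else tuple(range(len(x)))
    )
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[i] + x[j]).sum()
            if denom == 0:
                raise DegenerateInputError(
                    f"samples {labels[i]!r} and {labels[j]!r} are both empty"
                )
            d[i, j] = d[j, i] = np.abs(x[i] - x[j]).sum() / denom
    return DistanceMatrix(labels, d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix G from a distance matrix."""
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of x (rank-safe via SVD)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s.max() * 1e-10).sum())
    u = u[:, :rank]
    return u @ u.T


def _dummy(levels: np.ndarray) -> np.ndarray:
    cats = pd.unique(levels)
    return np.column_stack([(levels == c).astype(float) for c in cats])


def permanova(
    dist: DistanceMatrix,
    design: pd.DataFrame,
    factors: tuple = ("plastic", "light"),
    n_perm: int = 1000,
    seed: int | None = None,
    permutations: np.ndarray | None = None,
) -> PermanovaResult:
    """PERMANOVA with sequential (Type I) SS; one factor, or two with
    their interaction.

    The Gower-centred matrix G of the squared distances carries the total
    sum of squares on its trace; each model term's SS is the increment in
    tr(H G) as the term's columns join the design, where H is the
    orthogonal projector onto the (intercept-included) design so far.
    Pseudo-F per term uses the residual mean square of the full model.
    Significance comes from unrestricted permutation of sample labels
    (rows/columns of G permuted jointly), with the add-one estimator.

    ``permutations`` may supply an explicit (n_perm, n) array of index
    permutations, e.g. the full enumeration on a tiny instance.
    """
    if len(factors) not in (1, 2):
        raise ValueError("permanova supports one factor, or two with interaction")
    if not set(dist.labels) <= set(design.index):
        missing = set(dist.labels) - set(design.index)
        raise ValueError(f"design table lacks samples: {sorted(missing)}")
    meta = design.loc[list(dist.labels)]
    levels = [meta[f].to_numpy() for f in factors]
    for name, lev in zip(factors, levels):
        if len(pd.unique(lev)) < 2:
            raise DegenerateInputError(f"factor {name!r} needs >= 2 levels")

    n = dist.n
    g = _gower_center(dist.d)
    ss_total = float(np.trace(g))
    if ss_total <= 1e-12:
        raise DegenerateInputError("all pairwise distances are zero (SS_total = 0)")

    ones = np.ones((n, 1))
    blocks = [_dummy(lev) for lev in levels]
    if len(factors) == 2:
        xab = np.einsum("ij,ik->ijk", blocks[0], blocks[1]).reshape(n, -1)
        blocks.append(xab)
        terms = [factors[0], factors[1], f"{factors[0]}:{factors[1]}"]
    else:
        terms = [factors[0]]

    designs, cols = [], [ones]
    for b in blocks:
        cols.append(b)
        designs.append(np.hstack(cols))
    hats = [_hat(ones)] + [_hat(x) for x in designs]
    projectors = [hats[i + 1] - hats[i] for i in range(len(blocks))]
    resid_proj = np.eye(n) - hats[-1]

    dfs, prev = [], 0
    for x in designs:
        r = np.linalg.matrix_rank(x) - 1
        dfs.append(r - prev)
        prev = r
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise DegenerateInputError("no residual degrees of freedom")

    def _stats(gm: np.ndarray):
        ss = np.array([float((p * gm.T).sum()) for p in projectors])
        ss_res = float((resid_proj * gm.T).sum())
        ms_res = ss_res / df_res
        f = np.array(
            [s / d / ms_res if d > 0 and ms_res > 0 else np.nan for s, d in zip(ss, dfs)]
        )
        return ss, ss_res, f

    ss_obs, ss_res_obs, f_obs = _stats(g)

    if permutations is not None:
        perms = np.asarray(permutations, dtype=int)
        n_perm = perms.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    hits = np.zeros(len(projectors), dtype=int)
    for p in perms:
        gp = g[np.ix_(p, p)]
        _, _, f_perm = _stats(gp)
        hits += f_perm >= f_obs - 1e-12
    p_perm = (hits + 1) / (n_perm + 1)
    table = pd.DataFrame(
        {
            "SS": list(ss_obs) + [ss_res_obs, ss_total],
            "df": dfs + [df_res, n - 1],
            "R2": list(ss_obs / ss_total) + [ss_res_obs / ss_total, 1.0],
            "F": list(f_obs) + [np.nan, np.nan],
            "p_perm": list(p_perm) + [np.nan, np.nan],
        },
        index=terms + ["Residual", "Total"],
    )
    return PermanovaResult(table, n_perm, seed)


def all_label_permutations(n: int) -> np.ndarray:
    """Every permutation of range(n) as an (n!, n) index array (tiny n only)."""
    if n > 8:
        raise ValueError("full enumeration is intended for n <= 8")
    return np.array(list(_iter_permutations(range(n))), dtype=int)
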