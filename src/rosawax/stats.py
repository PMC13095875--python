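"""Compositional and univariate statistics for wax profiles.

Wax compositions are relative data (parts of a whole), so multivariate
comparison uses the centred log-ratio (CLR) transform before
hierarchical clustering. Principal component analysis summarizes
associations between samples/species and wax traits. Per-trait species
comparisons use one-way ANOVA with Tukey's HSD and a compact-letter
display.

The CLR of a composition x is ln(x_i) - mean_j ln(x_j) after closure;
rows sum to zero and the transform is invariant to rescaling a row.
Zeros are handled by multiplicative replacement (default 0.65 x the
smallest positive value in the row), the standard compositional-data
practice that preserves the ratios of the positive parts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "clr_transform",
    "Dendrogram",
    "hca",
    "PcaResult",
    "pca",
    "AnovaTukeyResult",
    "anova_tukey",
    "compact_letter_display",
]


def clr_transform(
    m: pd.DataFrame,
    zero_policy: str = "multiplicative",
    zero_scale: float = 0.65,
) -> pd.DataFrame:
    """Centred log-ratio transform of a non-negative composition matrix.

    Each row: zeros replaced per ``zero_policy``, closed to sum 1, then
    ``x -> ln(x) - mean(ln(x))``. Every output row sums to 0.

    zero_policy
        ``"multiplicative"`` (default): zeros become ``zero_scale`` x
        the smallest positive entry of that row, positive entries are
        shrunk proportionally so the row total is preserved.
        ``"error"``: any zero raises.
    """
    X = m.to_numpy(dtype=float, copy=True)
    if (X < 0).any():
        raise ValueError("composition matrix has negative entries")
    out = np.empty_like(X)
    for i, row in enumerate(X):
        positive = row[row > 0]
        if positive.size < 2:
            raise ValueError(
                f"row {m.index[i]!r} has fewer than 2 positive entries"
            )
        zeros = row == 0
        if zeros.any():
            if zero_policy == "error":
                raise ValueError(
                    f"row {m.index[i]!r} contains zeros and zero_policy='error'"
                )
            if zero_policy != "multiplicative":
                raise ValueError(f"unknown zero_policy {zero_policy!r}")
            total = row.sum()
            delta = zero_scale * positive.min()
            row = row.copy()
            row[zeros] = delta
            # shrink positive parts so the total is preserved
            row[~zeros] *= (total - delta * zeros.sum()) / total
        closed = row / row.sum()
        logs = np.log(closed)
        out[i] = logs - logs.mean()
    return pd.DataFrame(out, index=m.index, columns=m.columns)


@dataclass(frozen=True)
class Dendrogram:
    """Result of agglomerative hierarchical clustering.

    ``linkage`` is a scipy linkage matrix; ``labels`` the row ids in the
    (sorted) order used for clustering.
    """

    linkage: np.ndarray
    labels: tuple[str, ...]

    def to_tree(self):
        return hierarchy.to_tree(self.linkage)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        node = self.to_tree()

        def walk(nd, parent_height: float) -> str:
            length = parent_height - nd.dist
            if nd.is_leaf():
                return f"{self.labels[nd.id]}:{length:g}"
            left = walk(nd.left, nd.dist)
            right = walk(nd.right, nd.dist)
            return f"({left},{right}):{length:g}"

        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right});"


def hca(
    m: pd.DataFrame, distance: str = "euclidean", linkage: str = "ward"
) -> Dendrogram:
    """Agglomerative hierarchical clustering of matrix rows.

    Defaults (Euclidean distance on CLR-transformed values, Ward
    linkage) follow standard Aitchison-geometry practice. Rows are
    sorted by label before clustering so the result is independent of
    input row order; remaining ties break deterministically by scipy's
    ordering of the sorted observations.
    """
    if len(m) < 2:
        raise ValueError("clustering requires at least 2 rows")
    order = np.argsort(m.index.astype(str))
    m = m.iloc[order]
    Z = hierarchy.linkage(
        m.to_numpy(dtype=float), method=linkage, metric=distance
    )
    return Dendrogram(linkage=Z, labels=tuple(str(i) for i in m.index))


@dataclass(frozen=True)
class PcaResult:
    """Scores, loadings and percent variance per principal component."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.variance_explained)


def pca(m: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """Principal component analysis of a samples x traits matrix.

    Columns are centred (and z-scored when ``standardize``, the default,
    so traits on different scales — e.g. percentages alongside total
    loads — are commensurable). All ``min(rows - 1, cols)`` components
    are returned; ``variance_explained`` sums to 100. Sign convention:
    the largest-magnitude loading of each component is positive.
    Zero-variance columns are dropped with a warning when standardizing.
    """
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("pca requires at least 2 rows and 2 columns")
    X = m.to_numpy(dtype=float)
    cols = list(m.columns)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [c for c, k in zip(cols, keep) if not k]
            warnings.warn(
                f"dropping zero-variance columns under standardization: "
                f"{dropped}",
                stacklevel=2,
            )
            X = X[:, keep]
            cols = [c for c, k in zip(cols, keep) if k]
            sd = sd[keep]
        X = X / sd
    n_comp = min(X.shape[0] - 1, X.shape[1])
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = U[:, :n_comp], s[:n_comp], Vt[:n_comp]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(n_comp):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = s**2
    explained = 100.0 * var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    scores = pd.DataFrame(U * s, index=m.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=cols, columns=comp_names)
    return PcaResult(
        scores=scores, loadings=loadings, variance_explained=explained
    )


# --- ANOVA / Tukey HSD / compact letter display ---------------------------

@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]
    alpha: float


def compact_letter_display(
    groups: list[str], significant_pairs: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-absorb compact-letter display.

    Groups sharing no letter are significantly different; every
    non-significant pair shares at least one letter. Groups are
    processed in alphabetical order for determinism.
    """
    groups = sorted(groups)
    letter_sets: list[set[str]] = [set(groups)]
    for g1, g2 in sorted(
        (tuple(sorted(p)) for p in significant_pairs if len(p) == 2)
    ):
        for ls in [s for s in letter_sets if g1 in s and g2 in s]:
            letter_sets.remove(ls)
            for new in (ls - {g1}, ls - {g2}):
                if new and not any(new <= other for other in letter_sets):
                    letter_sets.append(new)
            # absorb: drop sets now contained in another
            letter_sets = [
                s
                for idx, s in enumerate(letter_sets)
                if not any(
                    s < o or (s == o and idx > jdx)
                    for jdx, o in enumerate(letter_sets)
                    if jdx != idx
                )
            ]
    # deterministic letter order: by smallest member group
    letter_sets.sort(key=lambda s: (min(s), sorted(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment: dict[str, list[str]] = {g: [] for g in groups}
    for i, ls in enumerate(letter_sets):
        ch = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for g in sorted(ls):
            assignment[g].append(ch)
    return {g: "".join(chs) for g, chs in assignment.items()}


def anova_tukey(
    values: dict[str, list[float]] | pd.DataFrame,
    alpha: float = 0.05,
) -> AnovaTukeyResult:
    """One-way ANOVA and Tukey HSD with compact-letter display.

    ``values`` maps group (species) to replicate measurements, or is a
    long frame with columns ``group`` and ``value``. Tukey runs on the
    untransformed values; groups sharing no letter in the result differ
    significantly at ``alpha``.
    """
    if isinstance(values, pd.DataFrame):
        grouped = {
            str(g): grp["value"].tolist()
            for g, grp in values.groupby("group", sort=True)
        }
    else:
        grouped = {str(g): list(v) for g, v in values.items()}
    if len(grouped) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if not any(len(v) >= 2 for v in grouped.values()):
        raise ValueError("ANOVA requires replicates in at least one group")
    names = sorted(grouped)
    samples = [np.asarray(grouped[g], dtype=float) for g in names]
    flat = np.concatenate(samples)
    labels = np.concatenate([np.repeat(g, len(grouped[g])) for g in names])
    if np.ptp(flat) == 0:
        # identical values everywhere: no variation, nothing differs
        f_stat, p_val = 0.0, 1.0
        pairwise = pd.DataFrame(
            [(g1, g2, 0.0, 1.0, False) for g1, g2 in combinations(names, 2)],
            columns=["group1", "group2", "meandiff", "p_adj", "reject"],
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p_val = sps.f_oneway(*samples)
        if np.isnan(f_stat):
            f_stat, p_val = 0.0, 1.0
        res = pairwise_tukeyhsd(flat, labels, alpha=alpha)
        tbl = np.asarray(res._results_table.data[1:], dtype=object)
        pairwise = pd.DataFrame(
            {
                "group1": tbl[:, 0],
                "group2": tbl[:, 1],
                "meandiff": tbl[:, 2].astype(float),
                "p_adj": np.asarray(res.pvalues, dtype=float),
                "reject": np.asarray(res.reject, dtype=bool),
            }
        )
    sig = {
        frozenset((r.group1, r.group2))
        for r in pairwise.itertuples()
        if r.reject
    }
    letters = compact_letter_display(names, sig)
    return AnovaTukeyResult(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
    )
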