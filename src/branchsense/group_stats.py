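"""Group statistics, overlaps, RNA maps and clustering for splicing analyses.

The statistical toolbox behind the feature comparisons: two-sided
Mann-Whitney U tests between event groups (with an exact small-sample
path), Pearson chi-square enrichment on 2x2 tables, Welch t-tests for
replicate PSI values, expression-vs-splicing correlation, cross-drug set
overlaps, positional motif profiles (RNA maps), hierarchical clustering
for heatmap ordering, and Tukey boxplot summaries.

Significance stars follow the figure-legend convention used in this
field: ``*`` p < 0.01, ``**`` p < 0.001, ``***`` p < 0.0001.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .ss_features import match_degenerate

__all__ = [
    "GroupComparison",
    "RnaMapProfile",
    "BoxplotSummary",
    "OverlapResult",
    "HeatmapOrder",
    "significance_stars",
    "mann_whitney_u",
    "chi2_2x2",
    "t_test_psi",
    "expr_splicing_correlation",
    "overlap_matrix",
    "rna_map",
    "heatmap_order",
    "summarize_boxplot",
    "compare_features",
]


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation (ns above 0.01)."""
    if math.isnan(p):
        return "na"
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 0.01:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group Mann-Whitney comparison of one feature."""

    feature: str
    n1: int
    n2: int
    median1: float
    median2: float
    u_statistic: float
    p_value: float

    @property
    def direction(self) -> int:
        """Sign of median1 - median2 (+1, 0, -1)."""
        d = self.median1 - self.median2
        return 0 if d == 0 or math.isnan(d) else (1 if d > 0 else -1)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   feature: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U test between samples ``x`` and ``y``.

    U is the rank-sum statistic of ``x`` with midranks for ties.  The
    p-value is exact (enumeration over all C(n1+n2, n1) arrangements) when
    min(n1, n2) <= 8 and there are no ties, otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample in Mann-Whitney comparison")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return GroupComparison(
        feature=feature, n1=int(x.size), n2=int(y.size),
        median1=float(np.median(x)), median2=float(np.median(y)),
        u_statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
    )


def chi2_2x2(regulated: int, universe: int,
             regulated_ref: int, universe_ref: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 regulated-vs-not table, df=1, no Yates.

    Compares the fraction ``regulated/universe`` with a reference fraction
    ``regulated_ref/universe_ref`` (e.g. a drug's regulated events against
    all detected events).  Uses the closed form
    n*(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    a, c = regulated, regulated_ref
    b, d = universe - regulated, universe_ref - regulated_ref
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative and within their universes")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise ValueError("chi-square undefined: zero margin in 2x2 table")
    n = a + b + c + d
    chi2 = n * (a * d - b * c) ** 2 / math.prod(margins)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def t_test_psi(psi_a: Sequence[float], psi_b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sided t-test between replicate PSI measurements."""
    a = np.asarray(psi_a, dtype=float)
    b = np.asarray(psi_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group for a t-test")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def expr_splicing_correlation(abs_delta: Sequence[float], fpkm: Sequence[float],
                              log_transform: bool = True) -> float:
    """Pearson R between |delta PSI/PIR| and gene expression.

    FPKM is log10(FPKM + 1)-transformed by default (expression is heavy
    tailed); pass ``log_transform=False`` for raw FPKM.  Returns NaN when
    either variable has zero variance.
    """
    d = np.asarray(abs_delta, dtype=float)
    f = np.asarray(fpkm, dtype=float)
    if d.shape != f.shape:
        raise ValueError("abs_delta and fpkm must be paired")
    keep = ~(np.isnan(d) | np.isnan(f))
    d, f = d[keep], f[keep]
    if d.size < 3:
        raise ValueError("need at least 3 paired observations")
    if log_transform:
        f = np.log10(f + 1.0)
    if np.std(d) == 0 or np.std(f) == 0:
        return math.nan
    return float(stats.pearsonr(d, f).statistic)


@dataclass(frozen=True)
class OverlapResult:
    """Venn-partition counts and pairwise sharing percentages of id sets."""

    names: tuple[str, ...]
    region_counts: dict[tuple[str, ...], int]
    pct_shared: pd.DataFrame  # pct.loc[A, B] = 100 * |A & B| / |A|

    def count(self, *members: str) -> int:
        """Exclusive count of the region belonging to exactly ``members``."""
        return self.region_counts[tuple(sorted(members))]


def overlap_matrix(sets: Mapping[str, set]) -> OverlapResult:
    """All 2^k - 1 exclusive Venn-region counts and pairwise percentages.

    ``pct_shared.loc[A, B]`` is the percentage of A's events also in B.
    """
    names = tuple(sorted(sets))
    if len(names) < 2:
        raise ValueError("need at least 2 sets to overlap")
    region_counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(set(sets[m]) for m in members))
            outside = set.union(*(set(sets[m]) for m in names if m not in members), set())
            region_counts[tuple(members)] = len(inside - outside)
    pct = pd.DataFrame(index=list(names), columns=list(names), dtype=float)
    for a in names:
        for b in names:
            sa, sb = set(sets[a]), set(sets[b])
            pct.loc[a, b] = 100.0 * len(sa & sb) / len(sa) if sa else math.nan
    return OverlapResult(names=names, region_counts=region_counts, pct_shared=pct)


@dataclass
class RnaMapProfile:
    """Positional motif-coverage profile around the 3' splice site.

    ``positions`` runs from -width to -1 (-1 = last intron nucleotide);
    ``coverage[g][i]`` is the (smoothed) fraction of group-g sequences in
    which a motif match covers that position, among sequences long enough
    to be defined there.
    """

    positions: np.ndarray
    coverage: dict[str, np.ndarray]
    raw: dict[str, np.ndarray]
    n_sequences: dict[str, int]
    pattern: str
    smooth: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group in sorted(self.coverage):
            for pos, sm, rw in zip(self.positions, self.coverage[group], self.raw[group]):
                rows.append({"position": int(pos), "group": group,
                             "coverage": sm, "raw": rw})
        return pd.DataFrame(rows)


def rna_map(groups: Mapping[str, Sequence[str]], pattern: str,
            width: int = 150, smooth: int = 15) -> RnaMapProfile:
    """RNA map: per-position motif coverage for groups of 3'-end sequences.

    Sequences are right-aligned at the 3'ss; a position is "covered" in a
    sequence when any degenerate match of ``pattern`` spans it.  Coverage
    fractions are smoothed with a centered moving average of ``smooth`` nt
    (shrinking at the boundaries, which keeps values in [0, 1]).
    """
    if smooth < 1:
        raise ValueError("smooth must be >= 1")
    positions = np.arange(-width, 0)
    m = len(pattern)
    coverage, raw, n_seqs = {}, {}, {}
    kernel = np.ones(smooth)
    for group, seqs in groups.items():
        if len(seqs) == 0:
            raise ValueError(f"empty sequence group {group!r}")
        covered = np.zeros(width)
        defined = np.zeros(width)
        for seq in seqs:
            tail = seq[-width:] if len(seq) > width else seq
            L = len(tail)
            defined[width - L:] += 1
            mask = np.zeros(L, dtype=bool)
            for off in match_degenerate(tail, pattern):
                mask[off : off + m] = True
            covered[width - L:] += mask
        with np.errstate(invalid="ignore"):
            frac = np.where(defined > 0, covered / np.maximum(defined, 1), np.nan)
        valid = ~np.isnan(frac)
        num = np.convolve(np.where(valid, frac, 0.0), kernel, mode="same")
        den = np.convolve(valid.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore"):
            smoothed = np.where(den > 0, num / den, np.nan)
        coverage[group] = smoothed
        raw[group] = frac
        n_seqs[group] = len(seqs)
    return RnaMapProfile(positions=positions, coverage=coverage, raw=raw,
                         n_sequences=n_seqs, pattern=pattern, smooth=smooth)


@dataclass(frozen=True)
class HeatmapOrder:
    """Row/column orderings from hierarchical clustering of a delta matrix."""

    row_order: list[int]
    col_order: list[int]
    dropped_rows: list[int]
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None


def heatmap_order(delta_matrix: pd.DataFrame | np.ndarray) -> HeatmapOrder:
    """Agglomerative clustering order (Euclidean, complete linkage).

    Rows containing missing values are dropped and reported; with fewer
    than 2 complete rows the identity order is returned.
    """
    mat = np.asarray(delta_matrix, dtype=float)
    if mat.ndim != 2:
        raise ValueError("delta matrix must be 2-dimensional")
    complete = ~np.isnan(mat).any(axis=1)
    dropped = list(np.flatnonzero(~complete))
    kept = np.flatnonzero(complete)
    sub = mat[complete]
    if sub.shape[0] < 2:
        return HeatmapOrder(row_order=list(kept), col_order=list(range(mat.shape[1])),
                            dropped_rows=dropped)
    row_link = hierarchy.linkage(sub, method="complete", metric="euclidean")
    row_order = [int(kept[i]) for i in hierarchy.leaves_list(row_link)]
    if mat.shape[1] >= 2:
        col_link = hierarchy.linkage(sub.T, method="complete", metric="euclidean")
        col_order = [int(i) for i in hierarchy.leaves_list(col_link)]
    else:
        col_link, col_order = None, list(range(mat.shape[1]))
    return HeatmapOrder(row_order=row_order, col_order=col_order,
                        dropped_rows=dropped, row_linkage=row_link,
                        col_linkage=col_link)


@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey five-number summary; whiskers at the most extreme data points
    within 1.5 * IQR of the box, outliers listed but never discarded from
    any statistical test."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...] = field(default_factory=tuple)


def summarize_boxplot(values: Sequence[float]) -> BoxplotSummary:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no finite values to summarize")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(sorted(v[(v < lo_fence) | (v > hi_fence)]))
    return BoxplotSummary(median=float(med), q1=float(q1), q3=float(q3),
                          whisker_lo=float(inside.min()),
                          whisker_hi=float(inside.max()),
                          outliers=outliers)


def compare_features(features: pd.DataFrame, labels: Sequence[str],
                     group1: str, group2: str,
                     feature_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Mann-Whitney comparison of every feature column between two groups.

    ``labels`` assigns each row of ``features`` to a group (e.g. the event
    class).  Returns a tidy frame of :class:`GroupComparison` fields with
    star annotations, one row per feature.
    """
    labels = pd.Series(list(labels), index=features.index)
    if feature_names is None:
        feature_names = [c for c in features.columns
                         if pd.api.types.is_numeric_dtype(features[c])]
    rows = []
    for name in feature_names:
        x = features.loc[labels == group1, name]
        y = features.loc[labels == group2, name]
        if x.dropna().empty or y.dropna().empty:
            continue
        cmp = mann_whitney_u(x, y, feature=name)
        rows.append({
            "feature": name, "group1": group1, "group2": group2,
            "n1": cmp.n1, "n2": cmp.n2,
            "median1": cmp.median1, "median2": cmp.median2,
            "U": cmp.u_statistic, "p_value": cmp.p_value,
            "direction": cmp.direction, "stars": cmp.stars,
        })
    return pd.DataFrame(rows)
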