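"""ROI summaries and exact nonparametric group statistics.

The Mann-Whitney U test is exact: the null distribution of U is built over
all C(n1+n2, n1) equally likely group assignments (via an exact
subset/rank-sum count), and the two-sided p-value is twice the smaller tail
probability, capped at one. Multiple comparisons are adjusted with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .acquisition import LabelVolume

__all__ = [
    "TestResult",
    "roi_means",
    "null_counts",
    "mannwhitney_exact",
    "benjamini_hochberg",
    "compare_groups",
]

#: Largest group size handled by complete enumeration.
MAX_EXACT_N = 12


@dataclass
class TestResult:
    U: int
    p: float
    n1: int
    n2: int
    p_fdr: float | None = None


def roi_means(
    volume: np.ndarray,
    labels: LabelVolume,
    slices: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-ROI mean and sample s.d. of a map, optionally slice-restricted.

    ``slices=(z0, z1)`` keeps only voxels with z0 <= z < z1 (the analysis
    analogue of measuring across a few consecutive coronal slices).
    """
    volume = np.asarray(volume, dtype=float)
    lab = labels.labels
    if volume.shape != lab.shape:
        raise ValueError("volume and labels must share a grid")
    keep = np.ones(lab.shape, dtype=bool)
    if slices is not None:
        z0, z1 = slices
        keep[...] = False
        keep[:, :, z0:z1] = True
    rows = []
    for label in labels.present_labels():
        sel = (lab == label) & keep
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"ROI {labels.names[label]!r} is empty under the slice restriction")
        vals = volume[sel]
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        rows.append(
            {"label": label, "roi": labels.names[label], "mean": float(vals.mean()), "sd": sd, "n_voxels": n}
        )
    return pd.DataFrame(rows)


@lru_cache(maxsize=64)
def null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Exact null distribution of U: counts over all C(n1+n2, n1) assignments.

    ``counts[u]`` is the number of size-``n1`` rank subsets of ``1..n1+n2``
    whose U statistic equals ``u``. Computed by the standard subset-sum
    recursion, which enumerates the same C(n1+n2, n1) assignments without
    materializing them.
    """
    n = n1 + n2
    max_u = n1 * n2
    # f[k][s]: subsets of size k of the first j ranks with rank-sum s
    f = np.zeros((n1 + 1, n1 * n + 1), dtype=np.int64)
    f[0, 0] = 1
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            f[k, rank:] += f[k - 1, :-rank or None]
    offset = n1 * (n1 + 1) // 2  # U = ranksum - n1(n1+1)/2
    counts = f[n1, offset : offset + max_u + 1]
    assert counts.sum() == comb(n, n1)
    return tuple(int(c) for c in counts)


def mannwhitney_exact(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Exact two-sided Mann-Whitney U test (no ties, small samples).

    U counts the pairs with ``x_i > y_j``. The two-sided p-value is
    ``2 * min(P(U <= u), P(U >= u))`` under the exact permutation null,
    capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size > MAX_EXACT_N or y.size > MAX_EXACT_N:
        raise ValueError(f"exact enumeration limited to groups of <= {MAX_EXACT_N}")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size != pooled.size:
        raise ValueError("tied values: exact test requires a tie-free sample")
    u = int(np.sum(x[:, None] > y[None, :]))
    counts = np.asarray(null_counts(x.size, y.size), dtype=float)
    total = counts.sum()
    p_low = counts[: u + 1].sum() / total
    p_high = counts[u:].sum() / total
    p = min(1.0, 2.0 * min(p_low, p_high))
    return TestResult(U=u, p=float(p), n1=int(x.size), n2=int(y.size))


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR adjustment.

    Returns adjusted p-values (``p_adj[i] = min_{j>=i} (m/j) p_(j)`` in the
    sorted order, capped at 1, mapped back to input order) and the boolean
    rejection set ``p_adj <= q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj_sorted
    return p_adj, p_adj <= q


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    q: float = 0.05,
    tie_jitter: float | None = None,
    jitter_seed: int = 0,
) -> pd.DataFrame:
    """Per-ROI exact tests with BH correction across ROIs for one metric.

    ``table`` needs columns ``subject, group, roi, metric, value`` with two
    group labels and one row per (subject, roi, metric). ``tie_jitter``
    optionally breaks exact ties in degenerate synthetic data by adding
    uniform noise of that amplitude (seeded).
    """
    required = {"subject", "group", "roi", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    groups = sorted(sub["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    ga, gb = groups
    rng = np.random.default_rng(jitter_seed)

    rows = []
    for roi, roi_df in sub.groupby("roi", sort=True):
        x = roi_df.loc[roi_df["group"] == ga, "value"].to_numpy(dtype=float)
        y = roi_df.loc[roi_df["group"] == gb, "value"].to_numpy(dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError(f"ROI {roi!r}: need >= 2 subjects per group")
        if tie_jitter is not None:
            x = x + rng.uniform(-tie_jitter, tie_jitter, x.size)
            y = y + rng.uniform(-tie_jitter, tie_jitter, y.size)
        res = mannwhitney_exact(x, y)
        rows.append(
            {
                "roi": roi,
                f"mean_{ga}": float(x.mean()),
                f"sd_{ga}": float(x.std(ddof=1)),
                f"mean_{gb}": float(y.mean()),
                f"sd_{gb}": float(y.std(ddof=1)),
                "U": res.U,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    p_adj, reject = benjamini_hochberg(out["p"].to_numpy(), q=q)
    out["p_fdr"] = p_adj
    out["significant"] = reject
    return out
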