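"""Equal-frequency-binning features and subset-size selection.

Classification features are occupancies of a k x k grid laid over the pooled
(I_b/I_0, dwell) scatter of all glycans: along each axis independently, cut
points are placed at the k-quantiles of the pooled events (equal-frequency
binning), and each glycan subset then contributes a length-k^2 vector of
normalized cell counts. Subset size is chosen by comparing each subset's
EPDF against the full-table EPDF with a one-sided KL divergence: the mean KL
shrinks as subsets grow, and the working size trades that fidelity against
the number of subsets available for training.

The dwell axis is cut on the log10 scale (consistent with the rest of the
package); boundaries are reported back in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import EventTable, pool_tables
from .mixture import GridSpec, build_epdf

__all__ = [
    "BinBoundaries",
    "FeatureSet",
    "FeatureMatrix",
    "SubsetSizeReport",
    "equal_frequency_boundaries",
    "split_subsets",
    "extract_features",
    "build_feature_matrix",
    "kl_subset_curve",
]


@dataclass(frozen=True)
class BinBoundaries:
    """Interior cut points of the k x k equal-frequency grid.

    ``ratio_cuts`` are on the I_b/I_0 axis; ``dwell_cuts_ms`` on the dwell
    axis in milliseconds (computed on the log10 scale, reported in ms).
    ``degenerate`` flags collapsed cuts caused by heavy ties.
    """

    ratio_cuts: tuple[float, ...]
    dwell_cuts_ms: tuple[float, ...]
    k: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for name, cuts in (("ratio_cuts", self.ratio_cuts), ("dwell_cuts_ms", self.dwell_cuts_ms)):
            if len(cuts) != self.k - 1:
                raise ValueError(f"{name} must have k-1 = {self.k - 1} entries")
            if any(b < a for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"{name} must be non-decreasing")


@dataclass(frozen=True)
class FeatureSet:
    """Normalized k^2 cell occupancies of one event subset."""

    values: np.ndarray
    subset_id: str
    label: str

    def __post_init__(self) -> None:
        if abs(float(self.values.sum()) - 1.0) > 1e-9:
            raise ValueError("feature values must sum to 1")


@dataclass
class FeatureMatrix:
    """Stacked feature sets with class labels, ready for classification."""

    X: np.ndarray  # (n_rows, k^2)
    labels: list[str]
    subset_ids: list[str]
    k: int
    subset_size: int

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != self.k**2:
            raise ValueError(f"X must be (n, k^2) = (n, {self.k**2})")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("one label per row required")
        if len(set(self.labels)) < 1:
            raise ValueError("at least one class required")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"f{i + 1}" for i in range(self.X.shape[1])]
        frame = pd.DataFrame(self.X, columns=cols)
        frame.insert(0, "subset_id", self.subset_ids)
        frame.insert(0, "glycan", self.labels)
        return frame


@dataclass(frozen=True)
class SubsetSizeReport:
    """Mean subset-vs-overall KL divergence per candidate subset size."""

    sizes: tuple[int, ...]
    mean_kl: tuple[float, ...]
    n_subsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.sizes) == len(self.mean_kl) == len(self.n_subsets)):
            raise ValueError("one mean KL and subset count per size required")
        if any(v < 0 for v in self.mean_kl):
            raise ValueError("KL divergences cannot be negative")


def _quantile_cuts(values: np.ndarray, k: int) -> tuple[np.ndarray, bool]:
    """Cuts at the k-quantile order statistics, midway between brackets.

    With n sorted values, the i-th cut (i = 1..k-1) sits midway between the
    order statistics bracketing position i*n/k. Ties may collapse cuts; that
    is reported, not repaired.
    """
    x = np.sort(values)
    n = x.size
    cuts = np.empty(k - 1)
    for i in range(1, k):
        m = min(int(np.floor(i * n / k)), n - 1)  # n >= k guarantees m >= 1
        cuts[i - 1] = 0.5 * (x[m - 1] + x[m])
    degenerate = bool(np.unique(cuts).size < cuts.size)
    return cuts, degenerate


def equal_frequency_boundaries(pooled: EventTable, k: int) -> BinBoundaries:
    """Quantile cut points on each axis of the pooled scatter.

    Each of the k marginal stripes per axis holds an equal share of the
    pooled events (+/-1 with all-distinct values). The dwell axis is cut on
    log10(dwell) and the cuts back-transformed to milliseconds.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if pooled.n_events < k:
        raise ValueError(f"need at least k={k} events, got {pooled.n_events}")
    if k == 1:
        return BinBoundaries(ratio_cuts=(), dwell_cuts_ms=(), k=1)
    r_cuts, r_deg = _quantile_cuts(pooled.ratio, k)
    d_cuts_log, d_deg = _quantile_cuts(np.log10(pooled.dwell_ms), k)
    return BinBoundaries(
        ratio_cuts=tuple(r_cuts),
        dwell_cuts_ms=tuple(10.0**d_cuts_log),
        k=k,
        degenerate=r_deg or d_deg,
    )


def split_subsets(table: EventTable, subset_size: int, seed: int) -> list[EventTable]:
    """Randomly partition a table into disjoint subsets of ``subset_size``.

    Events are permuted with ``seed`` then cut into floor(n/size) contiguous
    chunks; the remainder is dropped (count recorded in each subset's
    ``meta["n_dropped"]``). Same seed, same partition.
    """
    if subset_size < 1:
        raise ValueError("subset_size must be >= 1")
    n = table.n_events
    if subset_size > n:
        raise ValueError(f"subset_size {subset_size} exceeds event count {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_subsets = n // subset_size
    n_dropped = n - n_subsets * subset_size
    out = []
    for j in range(n_subsets):
        idx = perm[j * subset_size : (j + 1) * subset_size]
        sub = EventTable(
            label=table.label,
            events=table.events.iloc[idx].reset_index(drop=True),
            meta={"parent": table.label, "subset_index": j, "n_dropped": n_dropped},
        )
        out.append(sub)
    return out


def _cell_index(table: EventTable, b: BinBoundaries) -> np.ndarray:
    """Flat cell index (row-major ratio x dwell) per event.

    Intervals are half-open [lo, hi) with the last stripe closed above, which
    is exactly what searchsorted(side='right') on the interior cuts yields.
    """
    ri = np.searchsorted(np.asarray(b.ratio_cuts), table.ratio, side="right")
    di = np.searchsorted(np.asarray(b.dwell_cuts_ms), table.dwell_ms, side="right")
    return ri * b.k + di


def extract_features(subset: EventTable, boundaries: BinBoundaries) -> FeatureSet:
    """Normalized k^2 cell occupancies of one subset on fixed boundaries."""
    if subset.n_events == 0:
        raise ValueError("cannot extract features from an empty subset")
    idx = _cell_index(subset, boundaries)
    counts = np.bincount(idx, minlength=boundaries.k**2).astype(float)
    sid = str(subset.meta.get("subset_index", ""))
    return FeatureSet(values=counts / counts.sum(), subset_id=sid, label=subset.label)


def build_feature_matrix(
    tables: Mapping[str, EventTable],
    k: int = 3,
    subset_size: int = 2000,
    seed: int = 0,
) -> FeatureMatrix:
    """Full feature-engineering pipeline over a labelled panel of glycans.

    Equal-frequency boundaries are computed once on the pooled events of all
    labels, then applied to each label's random subsets; each subset yields
    one feature row. With 4 glycans of 40,000 events at k=3 and subset size
    2,000 this gives the canonical 80 x 9 matrix (20 rows per glycan).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 labelled tables")
    for lbl, t in tables.items():
        if t.n_events < subset_size:
            raise ValueError(f"table {lbl!r} has {t.n_events} < subset_size {subset_size} events")
    pooled = pool_tables(list(tables.values()))
    bounds = equal_frequency_boundaries(pooled, k)
    rows, labels, sids = [], [], []
    for offset, (lbl, t) in enumerate(sorted(tables.items())):
        for sub in split_subsets(t, subset_size, seed=seed + offset):
            fs = extract_features(sub, bounds)
            rows.append(fs.values)
            labels.append(lbl)
            sids.append(f"{lbl}#{fs.subset_id}")
    return FeatureMatrix(
        X=np.vstack(rows), labels=labels, subset_ids=sids, k=k, subset_size=subset_size
    )


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """One-sided KL(p || q) for strictly positive mass vectors."""
    return float(np.sum(p * (np.log(p) - np.log(q))))


def kl_subset_curve(
    table: EventTable,
    sizes: Sequence[int],
    grid: GridSpec | None = None,
    seed: int = 0,
) -> SubsetSizeReport:
    """Mean KL(subset || overall) for each candidate subset size.

    For each size the table is partitioned with :func:`split_subsets`, a
    smoothed EPDF is built per subset and for the full table, and the mean
    one-sided KL divergence of subsets against the overall distribution is
    reported. Smaller means indicate subsets that better represent the full
    data; the curve decreases toward zero as size approaches n.
    """
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("sizes must be positive")
    if max(sizes) > table.n_events:
        raise ValueError("largest size exceeds the event count")
    if grid is None:
        grid = GridSpec.from_tables([table])
    overall = build_epdf(table, grid)
    means, counts = [], []
    for s in sizes:
        subs = split_subsets(table, s, seed=seed)
        kls = [kl_divergence(build_epdf(sub, grid).flat, overall.flat) for sub in subs]
        means.append(float(np.mean(kls)))
        counts.append(len(subs))
    return SubsetSizeReport(sizes=tuple(sizes), mean_kl=tuple(means), n_subsets=tuple(counts))
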