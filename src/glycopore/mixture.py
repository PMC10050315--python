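"""Mixture deconvolution by divergence minimization over the simplex.

Each glycan's event cloud is summarised as an empirical probability mass
function (EPDF) on a fixed 2-D grid over (I_b/I_0, log10 dwell). A measured
mixture of N glycans is modelled as the convex combination

    f_hat(x) = sum_i w_i f_i(x),      sum_i w_i = 1,  w_i >= 0,

and the weights are estimated by minimizing the symmetrized (Jeffreys)
Kullback-Leibler divergence between the mixture EPDF f_mix and f_hat:

    J(w) = sum_x f_mix log(f_mix / f_hat) + sum_x f_hat log(f_hat / f_mix).

J is convex in w (f_hat is affine in w and both KL terms are convex in
f_hat), so the projected-gradient solution is the unique optimum. A
brute-force simplex-lattice search is provided as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .events import EventTable

__all__ = [
    "GridSpec",
    "EPDF",
    "WeightEstimate",
    "build_epdf",
    "mixture_epdf",
    "symmetrized_divergence",
    "estimate_weights",
    "grid_search_weights",
    "simplex_lattice",
    "project_to_simplex",
]

DEFAULT_BINS = 50
DEFAULT_EPS = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Fixed 2-D binning grid for EPDFs.

    ``ratio_edges`` span [0, 1]; ``logdwell_edges`` span the pooled
    log10(dwell_ms) range with padding. ``smoothing_eps`` is the mass added
    to every bin before renormalisation so divergences stay finite.
    """

    ratio_edges: tuple[float, ...]
    logdwell_edges: tuple[float, ...]
    smoothing_eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        for name, edges in (("ratio_edges", self.ratio_edges), ("logdwell_edges", self.logdwell_edges)):
            arr = np.asarray(edges, dtype=float)
            if arr.size < 2:
                raise ValueError(f"{name} needs at least 2 edges")
            if not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.smoothing_eps <= 0:
            raise ValueError("smoothing_eps must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.ratio_edges) - 1, len(self.logdwell_edges) - 1)

    @property
    def n_bins(self) -> int:
        nr, nd = self.shape
        return nr * nd

    @classmethod
    def from_tables(
        cls,
        tables: Sequence[EventTable],
        bins: int = DEFAULT_BINS,
        eps: float = DEFAULT_EPS,
        pad_frac: float = 0.05,
    ) -> "GridSpec":
        """Default grid: equal-width bins, ratio on [0, 1], log-dwell padded.

        The log10-dwell axis spans the pooled data range of all supplied
        tables, padded by ``pad_frac`` of that range on each side so fresh
        samples from the same populations rarely fall outside.
        """
        if not tables:
            raise ValueError("need at least one table to infer the dwell range")
        logd = np.concatenate([np.log10(t.dwell_ms) for t in tables if t.n_events])
        if logd.size == 0:
            raise ValueError("all tables are empty")
        lo, hi = float(logd.min()), float(logd.max())
        pad = max((hi - lo) * pad_frac, 1e-6)
        return cls(
            ratio_edges=tuple(np.linspace(0.0, 1.0, bins + 1)),
            logdwell_edges=tuple(np.linspace(lo - pad, hi + pad, bins + 1)),
            smoothing_eps=eps,
        )


@dataclass(frozen=True)
class EPDF:
    """Smoothed, normalized empirical probability mass on a GridSpec."""

    grid: GridSpec
    mass: np.ndarray  # shape grid.shape, sums to 1, strictly positive

    def __post_init__(self) -> None:
        if self.mass.shape != self.grid.shape:
            raise ValueError(f"mass shape {self.mass.shape} != grid shape {self.grid.shape}")
        if abs(float(self.mass.sum()) - 1.0) > 1e-9:
            raise ValueError(f"mass must sum to 1, got {self.mass.sum()}")
        if not (self.mass > 0).all():
            raise ValueError("every bin must carry positive mass after smoothing")

    @property
    def flat(self) -> np.ndarray:
        return self.mass.ravel()


def build_epdf(table: EventTable, grid: GridSpec) -> EPDF:
    """Bin a table's events on ``grid`` and normalise to a smoothed EPDF.

    Every bin receives ``smoothing_eps`` additive mass before renormalisation
    so that divergences against this EPDF are always finite. Raises if the
    table is empty or any event falls outside the grid.
    """
    if table.n_events == 0:
        raise ValueError("cannot build an EPDF from an empty table")
    r = table.ratio
    d = np.log10(table.dwell_ms)
    re = np.asarray(grid.ratio_edges)
    de = np.asarray(grid.logdwell_edges)
    if (r < re[0]).any() or (r > re[-1]).any() or (d < de[0]).any() or (d > de[-1]).any():
        raise ValueError(f"events of {table.label!r} fall outside the grid bounds")
    counts, _, _ = np.histogram2d(r, d, bins=[re, de])
    mass = counts / counts.sum()
    mass = mass + grid.smoothing_eps
    mass /= mass.sum()
    return EPDF(grid=grid, mass=mass)


def _check_same_grid(epdfs: Sequence[EPDF]) -> None:
    g0 = epdfs[0].grid
    for e in epdfs[1:]:
        if e.grid != g0:
            raise ValueError("all EPDFs must share one GridSpec")


def mixture_epdf(components: Sequence[EPDF], weights: Sequence[float]) -> EPDF:
    """Bin-wise convex combination of component EPDFs (the projected mixture)."""
    if len(components) == 0:
        raise ValueError("need at least one component")
    _check_same_grid(components)
    w = np.asarray(weights, dtype=float)
    if w.size != len(components):
        raise ValueError("weights and components must have equal length")
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    mass = sum(wi * c.mass for wi, c in zip(w, components))
    mass = mass / mass.sum()  # guard float drift
    return EPDF(grid=components[0].grid, mass=mass)


def symmetrized_divergence(f: EPDF, g: EPDF) -> float:
    """Symmetrized KL (Jeffreys) divergence between two EPDFs, natural log.

    The two-term sum KL(f||g) + KL(g||f); non-negative, zero iff f == g
    bin-wise, symmetric in its arguments. Requires strictly positive bins,
    which the EPDF smoothing guarantees.
    """
    _check_same_grid([f, g])
    p, q = f.flat, g.flat
    log_ratio = np.log(p) - np.log(q)
    return float(np.sum(p * log_ratio) - np.sum(q * log_ratio))


def _objective_and_grad(
    w: np.ndarray, fmix: np.ndarray, F: np.ndarray
) -> tuple[float, np.ndarray]:
    """Jeffreys divergence between fmix and F @ w, with gradient in w.

    F has shape (n_bins, N). d/dw_j = sum_x f_j(x) [1 + log(fhat/fmix)
    - fmix/fhat].
    """
    fhat = F @ w
    log_ratio = np.log(fhat) - np.log(fmix)
    obj = float(np.sum(fhat * log_ratio) - np.sum(fmix * log_ratio))
    grad = F.T @ (1.0 + log_ratio - fmix / fhat)
    return obj, grad


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    ind = np.arange(1, v.size + 1)
    cond = u - css / ind > 0
    rho = ind[cond][-1]
    theta = css[cond][-1] / rho
    return np.maximum(v - theta, 0.0)


@dataclass(frozen=True)
class WeightEstimate:
    """Estimated mixture weights with the achieved divergence and diagnostics."""

    weights: np.ndarray
    objective: float
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        w = self.weights
        if (w < -1e-9).any() or abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError("weights must lie on the probability simplex")
        if self.objective < 0:
            raise ValueError("objective divergence cannot be negative")


def estimate_weights(
    mixture: EventTable | EPDF,
    components: Sequence[EventTable | EPDF],
    grid: GridSpec | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> WeightEstimate:
    """Estimate mixture weights by projected gradient descent on the simplex.

    Accepts raw event tables (EPDFs are then built on a shared ``grid``,
    default grid inferred from the pooled tables) or pre-built EPDFs.
    Descent starts at the uniform weight vector with backtracking line
    search; convexity of the objective makes the optimum unique. Iteration
    stops when the objective improves by less than ``tol``.
    """
    if len(components) < 2:
        raise ValueError("need at least 2 component tables")
    tabs = [t for t in [mixture, *components] if isinstance(t, EventTable)]
    if tabs and grid is None:
        grid = GridSpec.from_tables(tabs)

    def as_epdf(obj: EventTable | EPDF) -> EPDF:
        if isinstance(obj, EPDF):
            return obj
        assert grid is not None
        return build_epdf(obj, grid)

    fmix = as_epdf(mixture)
    comp = [as_epdf(c) for c in components]
    _check_same_grid([fmix, *comp])

    F = np.stack([c.flat for c in comp], axis=1)  # (n_bins, N)
    target = fmix.flat
    n = F.shape[1]
    w = np.full(n, 1.0 / n)
    obj, grad = _objective_and_grad(w, target, F)
    step = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # backtracking over the projected-gradient step
        improved = False
        for _ in range(60):
            w_new = project_to_simplex(w - step * grad)
            obj_new, grad_new = _objective_and_grad(w_new, target, F)
            if obj_new <= obj - 1e-4 * float(grad @ (w - w_new)) or obj_new < obj:
                improved = True
                break
            step *= 0.5
        if not improved:
            converged = True  # no descent direction left: at the optimum
            break
        delta = obj - obj_new
        w, obj, grad = w_new, obj_new, grad_new
        step = min(step * 2.0, 1e6)
        if delta < tol:
            converged = True
            break
    # clean tiny negatives from the projection arithmetic
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    return WeightEstimate(weights=w, objective=obj, iterations=it, converged=converged)


def simplex_lattice(n: int, resolution: float) -> Iterator[np.ndarray]:
    """Yield all points of the simplex lattice with step ``resolution``."""
    m = round(1.0 / resolution)
    if abs(m * resolution - 1.0) > 1e-9:
        raise ValueError("resolution must divide 1")

    def rec(prefix: list[int], remaining: int, slots: int):
        if slots == 1:
            yield np.array(prefix + [remaining], dtype=float) / m
            return
        for k in range(remaining + 1):
            yield from rec(prefix + [k], remaining - k, slots - 1)

    yield from rec([], m, n)


def grid_search_weights(
    mixture: EPDF, components: Sequence[EPDF], resolution: float = 0.01
) -> WeightEstimate:
    """Exhaustive divergence minimization on the simplex lattice (oracle).

    Evaluates the objective at every lattice point with step ``resolution``
    and returns the minimizer. Intended as an independent cross-check of
    :func:`estimate_weights`; guarded to N <= 4 components.
    """
    n = len(components)
    if n > 4:
        raise ValueError("grid search is limited to <= 4 components")
    _check_same_grid([mixture, *components])
    F = np.stack([c.flat for c in components], axis=1)
    target = mixture.flat
    best_w, best_obj = None, np.inf
    n_eval = 0
    for w in simplex_lattice(n, resolution):
        obj, _ = _objective_and_grad(w, target, F)
        n_eval += 1
        if obj < best_obj:
            best_obj, best_w = obj, w
    assert best_w is not None
    return WeightEstimate(weights=best_w, objective=best_obj, iterations=n_eval, converged=True)
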