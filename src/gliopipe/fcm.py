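"""Fuzzy c-means clustering on slice intensities, with inter-slice averaging.

Standard FCM alternates a membership update

    u_ip = [ sum_k (d_ip / d_ik)^(2/(q-1)) ]^(-1),   d_ip = |x_i - y_p|,

with the centroid update

    y_p = sum_i u_ip^q x_i / sum_i u_ip^q,

minimizing the fuzzified within-cluster objective sum_i sum_p u_ip^q d_ip^2.
The neighboring variant replaces each pixel's intensity x_i by its mean over
a window of consecutive slices (the slice itself plus ``window_halfwidth``
slices on each side, 2 by default), which regularizes the clustering when
the tumor cross-section varies smoothly through the stack.

A pixel coinciding exactly with a centroid receives one-hot membership.
Initial centroids sit at evenly spaced quantiles of the input intensities,
making the procedure deterministic and seed-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FCMParams",
    "FCMState",
    "standard_fcm",
    "neighboring_fcm",
    "window_average",
    "fcm_objective",
]


@dataclass(frozen=True)
class FCMParams:
    c: int = 4
    q: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    window_halfwidth: int = 2
    #: "clamp" replicates the first/last slice so the window always has
    #: 2*halfwidth+1 members; "shrink" averages only the slices that exist.
    edge_mode: str = "clamp"

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("need at least 2 clusters")
        if self.q <= 1:
            raise ValueError("fuzziness exponent q must exceed 1")
        if self.tol <= 0 or self.max_iter < 1 or self.window_halfwidth < 0:
            raise ValueError("invalid FCM parameters")
        if self.edge_mode not in ("clamp", "shrink"):
            raise ValueError("edge_mode must be 'clamp' or 'shrink'")


@dataclass
class FCMState:
    """Result of one fuzzy clustering run.

    ``memberships`` has shape (N, c) with rows summing to 1; ``centroids``
    is sorted in the order produced by the iteration (not re-sorted).
    ``grid_shape`` remembers the 2-D pixel layout of the flattened input.
    """

    memberships: np.ndarray
    centroids: np.ndarray
    iterations_run: int
    converged: bool
    grid_shape: tuple[int, int]
    objective_trace: np.ndarray

    def hard_labels(self) -> np.ndarray:
        """Per-pixel argmax cluster index, ties toward the higher index."""
        u = self.memberships
        # reversed argmax so equal memberships resolve to the larger index
        lab = u.shape[1] - 1 - np.argmax(u[:, ::-1], axis=1)
        return lab.reshape(self.grid_shape)


def _init_centroids(x: np.ndarray, c: int) -> np.ndarray:
    qs = (2 * np.arange(c) + 1) / (2 * c)
    cent = np.quantile(x, qs)
    if len(np.unique(cent)) < c:  # heavily peaked histogram: spread instead
        cent = np.linspace(x.min(), x.max(), c)
    return cent


def _memberships(x: np.ndarray, centroids: np.ndarray, q: float) -> np.ndarray:
    d = np.abs(x[:, None] - centroids[None, :])
    exact = d < 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        w = d ** (-2.0 / (q - 1.0))
        u = w / np.sum(w, axis=1, keepdims=True)
    hit = exact.any(axis=1)
    if hit.any():
        u[hit] = 0.0
        u[hit, np.argmax(exact[hit], axis=1)] = 1.0
    return u


def fcm_objective(x: np.ndarray, memberships: np.ndarray, centroids: np.ndarray, q: float) -> float:
    """Fuzzified within-cluster sum of squared distances."""
    d2 = (x[:, None] - centroids[None, :]) ** 2
    return float(np.sum(memberships**q * d2))


def _run_fcm(
    x: np.ndarray,
    grid_shape: tuple[int, int],
    params: FCMParams,
    initial_centroids: np.ndarray | None = None,
) -> FCMState:
    if len(np.unique(x)) < params.c:
        raise ValueError(
            f"only {len(np.unique(x))} distinct intensities for c={params.c} "
            "clusters; choose a smaller c"
        )
    if initial_centroids is not None:
        centroids = np.asarray(initial_centroids, dtype=np.float64).copy()
        if centroids.shape != (params.c,):
            raise ValueError("initial_centroids must have one value per cluster")
    else:
        centroids = _init_centroids(x, params.c)
    trace = []
    converged = False
    it = 0
    u = _memberships(x, centroids, params.q)
    for it in range(1, params.max_iter + 1):
        uq = u**params.q
        new_centroids = (uq * x[:, None]).sum(axis=0) / uq.sum(axis=0)
        delta = np.max(np.abs(new_centroids - centroids))
        centroids = new_centroids
        u = _memberships(x, centroids, params.q)
        trace.append(fcm_objective(x, u, centroids, params.q))
        if delta < params.tol:
            converged = True
            break
    return FCMState(u, centroids, it, converged, grid_shape, np.asarray(trace))


def window_average(stack: np.ndarray, slice_index: int, halfwidth: int, edge_mode: str = "clamp") -> np.ndarray:
    """Per-pixel mean over slices ``slice_index - halfwidth .. + halfwidth``.

    With ``edge_mode='clamp'`` out-of-range indices replicate the first or
    last slice so the window always averages the full member count.
    """
    stack = np.asarray(stack, dtype=np.float64)
    n = stack.shape[0]
    if not 0 <= slice_index < n:
        raise IndexError(f"slice index {slice_index} outside stack of {n}")
    idx = np.arange(slice_index - halfwidth, slice_index + halfwidth + 1)
    if edge_mode == "clamp":
        idx = np.clip(idx, 0, n - 1)
    else:
        idx = idx[(idx >= 0) & (idx < n)]
    return stack[idx].mean(axis=0)


def standard_fcm(
    slice_: np.ndarray,
    params: FCMParams = FCMParams(),
    initial_centroids: np.ndarray | None = None,
) -> FCMState:
    """Fuzzy c-means on a single 2-D slice.

    ``initial_centroids`` overrides the deterministic quantile
    initialization; permuting it permutes cluster indices but not the
    induced partition.
    """
    slice_ = np.asarray(slice_, dtype=np.float64)
    if slice_.ndim != 2:
        raise ValueError("expected a 2-D slice")
    if not np.all(np.isfinite(slice_)):
        raise ValueError("slice intensities must be finite")
    return _run_fcm(slice_.ravel(), slice_.shape, params, initial_centroids)


def neighboring_fcm(stack: np.ndarray, slice_index: int, params: FCMParams = FCMParams()) -> FCMState:
    """Fuzzy c-means where each pixel's feature is its window-averaged intensity.

    ``stack`` is an (S, H, W) array (an ``MRVolume.slices`` attribute works
    directly).  ``window_halfwidth=0`` degenerates to :func:`standard_fcm`
    on the indexed slice.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("expected an (S, H, W) slice stack")
    feature = window_average(stack, slice_index, params.window_halfwidth, params.edge_mode)
    return _run_fcm(feature.ravel(), feature.shape, params)
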