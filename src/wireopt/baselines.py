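"""Monte-Carlo random-placement null model for the total wiring length.

The null asks: if the free (inter-) neurons were placed uniformly at random
inside the body region instead of where they actually sit, what would the
total wiring length be on average?  The region defaults to the axis-aligned
bounding box of all real neuron positions; the convex hull of the real
positions is available as a tighter body proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .metrics import total_wiring_length
from .optimize import PlacementProblem

__all__ = ["BaselineResult", "random_baseline"]


@dataclass
class BaselineResult:
    """Random-layout TWL statistics with full seed provenance."""

    mean_twl: float
    sd_twl: float
    n_iter: int
    seed: int
    region: dict = field(default_factory=dict)

    @property
    def sem(self) -> float:
        """Standard error of the Monte-Carlo mean."""
        return self.sd_twl / np.sqrt(self.n_iter)


def _bbox(points: np.ndarray):
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    if np.any(hi - lo <= 0):
        raise ValueError("degenerate sampling region: zero area bounding box")
    return lo, hi


def _sample_region(rng, points, region, size):
    lo, hi = _bbox(points)
    if region == "bbox":
        return rng.uniform(lo, hi, size=(size, 2))
    if region == "hull":
        tri = Delaunay(points)
        out = np.empty((size, 2))
        filled = 0
        attempts = 0
        while filled < size:
            attempts += 1
            if attempts > 1000:
                raise RuntimeError("convex-hull rejection sampling did not converge")
            cand = rng.uniform(lo, hi, size=(2 * (size - filled) + 8, 2))
            inside = cand[tri.find_simplex(cand) >= 0]
            take = min(len(inside), size - filled)
            out[filled:filled + take] = inside[:take]
            filled += take
        return out
    raise ValueError(f"unknown region {region!r}; expected 'bbox' or 'hull'")


def random_baseline(
    problem: PlacementProblem,
    real_layout: np.ndarray,
    n_iter: int,
    seed: int,
    region: str = "bbox",
) -> BaselineResult:
    """Mean and SD of the TWL over random uniform placements of free nodes.

    Fixed nodes stay at their ``real_layout`` positions; free nodes are drawn
    i.i.d. uniform over ``region`` (computed from all real positions).  The
    draw sequence is fully reproducible from ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    real_layout = np.asarray(real_layout, dtype=float)
    rng = np.random.default_rng(seed)
    free = problem.free_idx
    layout = real_layout.copy()
    lo, hi = _bbox(real_layout)
    vals = np.empty(n_iter)
    for it in range(n_iter):
        layout[free] = _sample_region(rng, real_layout, region, len(free))
        vals[it] = total_wiring_length(layout, problem.weights, problem.spec)
    sd = float(np.std(vals, ddof=1)) if n_iter > 1 else 0.0
    return BaselineResult(
        mean_twl=float(vals.mean()),
        sd_twl=sd,
        n_iter=n_iter,
        seed=seed,
        region={"kind": region, "lo": lo.tolist(), "hi": hi.tolist()},
    )
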