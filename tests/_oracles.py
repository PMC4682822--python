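"""Independent brute-force oracles used to validate the solvers.

The grid-search oracle minimizes the wiring cost over one or two free nodes
by exhaustive evaluation on a multi-resolution grid (each round zooms into
the incumbent cell).  It shares no code path with the solvers beyond the
distance definitions, which it re-implements locally.
"""

import numpy as np
from scipy.spatial.distance import cdist


def _node_to_points_cost(cand, points, wts, spec):
    """Sum_j wts_j * d_spec(cand_k, points_j) for each candidate k."""
    if spec.family == "l1":
        D = cdist(cand, points, "cityblock")
    else:
        D = cdist(cand, points, "euclidean") ** spec.power
    return D @ wts


def _pair_cost(P, Q, w, spec):
    if spec.family == "l1":
        D = cdist(P, Q, "cityblock")
    else:
        D = cdist(P, Q, "euclidean") ** spec.power
    return w * D


def block_grid_descent(problem, lo, hi, grid=41, rounds=4, sweeps=30):
    """Brute-force block-coordinate descent: grid-search one free node at a
    time with the others held, sweeping until the objective stops improving.
    Valid as an oracle for the convex costs used here."""
    free = problem.free_idx
    s = problem.weights + problem.weights.T
    layout = problem.coords.copy()
    n = len(layout)
    prev = np.inf
    for _ in range(sweeps):
        for f in free:
            others = np.delete(np.arange(n), f)
            span_lo = np.array([lo, lo], float)
            span_hi = np.array([hi, hi], float)
            for _r in range(rounds):
                ax = np.linspace(span_lo[0], span_hi[0], grid)
                ay = np.linspace(span_lo[1], span_hi[1], grid)
                gx, gy = np.meshgrid(ax, ay, indexing="ij")
                cand = np.column_stack([gx.ravel(), gy.ravel()])
                vals = _node_to_points_cost(
                    cand, layout[others], s[f, others], problem.spec
                )
                best = cand[int(np.argmin(vals))]
                step = (span_hi - span_lo) / (grid - 1)
                span_lo, span_hi = best - step, best + step
            layout[f] = best
        if problem.spec.family == "l1":
            D = cdist(layout, layout, "cityblock")
        else:
            D = cdist(layout, layout, "euclidean") ** problem.spec.power
        obj = float(np.sum(problem.weights * D))
        if prev - obj < 1e-9:
            break
        prev = obj
    return obj, layout


def grid_search_objective(problem, lo, hi, grid=21, rounds=5):
    """Brute-force minimum objective for problems with 1 or 2 free nodes."""
    free = problem.free_idx
    m = len(free)
    assert m in (1, 2), "grid oracle supports at most 2 free nodes"
    s = problem.weights + problem.weights.T
    fixed_idx = np.flatnonzero(problem.fixed_mask)
    fx = problem.coords[fixed_idx]

    # constant part: fixed-fixed ordered-pair cost
    if spec_is_l1 := (problem.spec.family == "l1"):
        Dff = cdist(fx, fx, "cityblock")
    else:
        Dff = cdist(fx, fx, "euclidean") ** problem.spec.power
    Wff = problem.weights[np.ix_(fixed_idx, fixed_idx)]
    const = float(np.sum(Wff * Dff))

    span_lo = np.full((m, 2), float(lo))
    span_hi = np.full((m, 2), float(hi))
    best_val = None
    for _ in range(rounds):
        axes = []
        for k in range(m):
            axes.append(np.linspace(span_lo[k, 0], span_hi[k, 0], grid))
            axes.append(np.linspace(span_lo[k, 1], span_hi[k, 1], grid))
        if m == 1:
            gx, gy = np.meshgrid(axes[0], axes[1], indexing="ij")
            cand = np.column_stack([gx.ravel(), gy.ravel()])
            vals = _node_to_points_cost(
                cand, fx, s[free[0], fixed_idx], problem.spec
            )
            kbest = int(np.argmin(vals))
            best_val = const + float(vals[kbest])
            best_pts = cand[kbest][None, :]
        else:
            gx, gy = np.meshgrid(axes[0], axes[1], indexing="ij")
            P = np.column_stack([gx.ravel(), gy.ravel()])
            gx, gy = np.meshgrid(axes[2], axes[3], indexing="ij")
            Q = np.column_stack([gx.ravel(), gy.ravel()])
            c1 = _node_to_points_cost(P, fx, s[free[0], fixed_idx], problem.spec)
            c2 = _node_to_points_cost(Q, fx, s[free[1], fixed_idx], problem.spec)
            cross = _pair_cost(P, Q, s[free[0], free[1]], problem.spec)
            total = c1[:, None] + c2[None, :] + cross
            a, b = np.unravel_index(np.argmin(total), total.shape)
            best_val = const + float(total[a, b])
            best_pts = np.vstack([P[a], Q[b]])
        step = (span_hi - span_lo) / (grid - 1)
        span_lo = best_pts - step
        span_hi = best_pts + step
    return best_val
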