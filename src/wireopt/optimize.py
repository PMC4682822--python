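"""Anchored placement solvers minimizing the total wiring length.

The placement problem: motor and sensory neurons (and optionally some
designated interneurons) are anchored at given coordinates; the remaining
free nodes are placed to minimize the weighted total wiring length under a
chosen cost function.  Every unconstrained problem here is convex:

* squared Euclidean cost — a quadratic whose stationarity conditions form a
  weighted graph Laplacian system with Dirichlet (anchor) boundary values;
  solved exactly by one sparse linear solve per coordinate.
* Euclidean cost — a multifacility Weber problem; solved by iteratively
  reweighted least squares (a Weiszfeld generalization) on the smoothed cost
  sqrt(d^2 + eps^2) with eps driven toward zero.
* l1 cost — separable across coordinates; each coordinate is a weighted
  absolute-deviation minimization, solved exactly by weighted medians when
  free nodes only neighbour anchors, and by a linear program otherwise.
* cubed / fourth-power Euclidean cost — smooth convex minimization warm
  started from the squared-cost optimum.

An optional minimal inter-neuron distance constraint (soma-size exclusion)
makes the problem nonconvex; it is handled as a local refinement from the
convex optimum.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog, minimize
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .metrics import NormSpec, total_wiring_length

__all__ = [
    "PlacementProblem",
    "Solution",
    "DisconnectedFreeComponentError",
    "solve",
    "solve_squared_l2",
    "solve_weber_l2",
    "solve_l1",
    "solve_power_p",
    "solve_with_min_distance",
    "weighted_median",
]

logger = logging.getLogger("wireopt")


class DisconnectedFreeComponentError(ValueError):
    """A connected component of free nodes has edges but no path to an anchor.

    Such a component has a translation-invariant (unbounded-set) optimum, so
    the placement problem is ill-posed for it.
    """

    def __init__(self, component: list):
        self.component = list(component)
        super().__init__(
            "free component not connected to any fixed node: "
            f"indices {self.component}"
        )


@dataclass
class PlacementProblem:
    """Anchored total-wiring-length minimization instance.

    ``coords`` holds the full layout; rows where ``fixed_mask`` is True are
    the anchors (held exactly), the remaining rows serve as the reference /
    initial positions of the free nodes.  ``min_distance`` (mm), if set,
    requests the constrained local refinement after the convex solve.
    """

    weights: np.ndarray
    fixed_mask: np.ndarray
    coords: np.ndarray
    spec: NormSpec
    min_distance: float | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.fixed_mask)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be n x n matching fixed_mask length")
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be n x 2 matching fixed_mask length")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.min_distance is not None and self.min_distance < 0:
            raise ValueError("min_distance must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.fixed_mask)

    @property
    def free_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.fixed_mask)

    @property
    def sym_weights(self) -> np.ndarray:
        """Symmetric effective weights w = W + W^T (TWL = 0.5 * sum w_ij d_ij)."""
        return self.weights + self.weights.T


@dataclass
class Solution:
    """Solver output: full layout, objective, and convergence diagnostics."""

    layout: np.ndarray
    objective: float
    converged: bool
    iterations: int
    solver_name: str
    diagnostics: dict = field(default_factory=dict)

    def displacement_from(self, reference: np.ndarray) -> np.ndarray:
        """Per-node Euclidean distance between this layout and a reference."""
        return np.linalg.norm(self.layout - np.asarray(reference, float), axis=1)


# ---------------------------------------------------------------------------
# structural checks shared by all solvers


def _coordinate_scale(coords: np.ndarray) -> float:
    span = np.ptp(coords, axis=0)
    scale = float(np.hypot(*span))
    return scale if scale > 0 else 1.0


def _analyze_structure(problem: PlacementProblem):
    """Partition free nodes into active (solvable) and isolated; check anchoring.

    Returns (active_free, isolated_free) index arrays.  Raises
    :class:`DisconnectedFreeComponentError` if some free nodes form a
    weighted component without any anchor.
    """
    s = problem.sym_weights
    deg = s.sum(axis=1)
    free = ~problem.fixed_mask
    isolated = free & (deg == 0)
    ncomp, labels = connected_components(sp.csr_matrix(s > 0), directed=False)
    for c in range(ncomp):
        members = np.flatnonzero(labels == c)
        if len(members) < 2:
            continue
        if not problem.fixed_mask[members].any():
            raise DisconnectedFreeComponentError(members.tolist())
    active = free & ~isolated
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} free node(s) have no connections; "
            "their input positions are kept",
            stacklevel=3,
        )
    return np.flatnonzero(active), np.flatnonzero(isolated)


def _laplacian_solve(
    s: np.ndarray, active: np.ndarray, coords: np.ndarray
) -> np.ndarray:
    """Solve the weighted-Laplacian stationarity system for the active nodes.

    For each active node i:  x_i * sum_j s_ij = sum_j s_ij x_j, with all
    non-active nodes held at ``coords``.  Returns the active-node positions.
    """
    n = len(s)
    others = np.setdiff1d(np.arange(n), active)
    s_aa = s[np.ix_(active, active)]
    s_ao = s[np.ix_(active, others)]
    deg = s[active].sum(axis=1)
    L = sp.csc_matrix(np.diag(deg) - s_aa)
    rhs = s_ao @ coords[others]
    with warnings.catch_warnings():
        warnings.simplefilter("error", sp.linalg.MatrixRankWarning)
        try:
            sol = sp.linalg.spsolve(L, rhs)
        except sp.linalg.MatrixRankWarning:
            raise DisconnectedFreeComponentError(active.tolist()) from None
    return np.atleast_2d(sol)


def _finalize(problem, layout, converged, iterations, name, diagnostics):
    obj = total_wiring_length(layout, problem.weights, problem.spec)
    logger.debug("%s: objective=%.10g iterations=%d", name, obj, iterations)
    return Solution(layout, obj, converged, iterations, name, diagnostics)


# ---------------------------------------------------------------------------
# squared Euclidean cost: exact linear solve


def solve_squared_l2(problem: PlacementProblem) -> Solution:
    """Exact global minimizer under the squared Euclidean cost.

    The objective is quadratic; stationarity for every free node i reads
    ``x_i * sum_j w_ij = sum_j w_ij x_j`` with ``w = W + W^T``, i.e. each
    free node sits at the weighted barycentre of its neighbours.  This is a
    weighted graph Laplacian system with the anchors as Dirichlet boundary
    values, solved sparsely per coordinate.
    """
    if problem.spec != NormSpec.squared_l2():
        raise ValueError("solve_squared_l2 requires the squared Euclidean cost")
    active, isolated = _analyze_structure(problem)
    layout = problem.coords.copy()
    if len(active):
        layout[active] = _laplacian_solve(problem.sym_weights, active, layout)
    diag = {"isolated_free": isolated.tolist()}
    return _finalize(problem, layout, True, 1, "squared_l2_linear", diag)


# ---------------------------------------------------------------------------
# Euclidean cost: IRLS (generalized Weiszfeld)


def solve_weber_l2(
    problem: PlacementProblem,
    rel_tol: float = 1e-10,
    max_iter: int = 10_000,
    eps_start_factor: float = 1e-3,
    eps_end_factor: float = 1e-12,
) -> Solution:
    """Multifacility Weber solve (Euclidean cost) by smoothed IRLS.

    Minimizes ``sum w_ij sqrt(||x_i - x_j||^2 + eps^2)`` by iteratively
    reweighted Laplacian solves, with the smoothing eps annealed from
    ``eps_start_factor * scale`` down to ``eps_end_factor * scale`` (scale =
    anchor bounding-box diagonal).  Convergence at each eps level: relative
    change of the smoothed objective below ``rel_tol``.
    """
    if problem.spec != NormSpec.l2():
        raise ValueError("solve_weber_l2 requires the Euclidean cost (power 1)")
    active, isolated = _analyze_structure(problem)
    s = problem.sym_weights
    layout = problem.coords.copy()
    if len(active) == 0:
        return _finalize(problem, layout, True, 0, "weber_irls",
                         {"isolated_free": isolated.tolist()})

    # warm start at the quadratic optimum
    warm = dataclasses.replace(problem, spec=NormSpec.squared_l2(),
                               min_distance=None)
    layout = solve_squared_l2(warm).layout

    scale = _coordinate_scale(problem.coords)
    eps_levels = []
    eps = eps_start_factor * scale
    while eps > eps_end_factor * scale:
        eps_levels.append(eps)
        eps /= 10.0
    eps_levels.append(eps_end_factor * scale)

    mask = s > 0
    total_iters = 0
    converged = True
    for eps in eps_levels:
        prev = np.inf
        while True:
            if total_iters >= max_iter:
                converged = False
                break
            D = cdist(layout, layout)
            smooth = np.sqrt(D * D + eps * eps)
            t = np.where(mask, s / smooth, 0.0)
            layout[active] = _laplacian_solve(t, active, layout)
            total_iters += 1
            D = cdist(layout, layout)
            obj = 0.5 * float(np.sum(s * np.sqrt(D * D + eps * eps)))
            if abs(prev - obj) <= rel_tol * max(abs(obj), 1e-30):
                break
            prev = obj
        if not converged:
            break
    diag = {"isolated_free": isolated.tolist(), "final_eps": eps_levels[-1]}
    return _finalize(problem, layout, converged, total_iters, "weber_irls", diag)


# ---------------------------------------------------------------------------
# l1 cost: weighted medians / linear programming


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Minimizer of sum_k w_k |x - v_k|.

    When the optimum is an interval (total weight splits exactly in half),
    the midpoint of the interval is returned for determinism.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0 or w.sum() <= 0:
        raise ValueError("weighted_median needs at least one positive weight")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    half = cw[-1] / 2.0
    k = int(np.searchsorted(cw, half))
    # cw[k-1] < half <= cw[k]; if cw[k] == half the optimum is [v[k], v[k+1]]
    if k + 1 < len(v) and np.isclose(cw[k], half, rtol=1e-12, atol=0.0):
        return 0.5 * (v[k] + v[k + 1])
    return float(v[k])


def _l1_coordinate_lp(s, active, coords, axis):
    """Exact 1-D weighted absolute-deviation solve by LP (HiGHS).

    Variables: active-node coordinates plus one slack per weighted pair
    touching an active node; minimize sum w_e t_e s.t. t_e >= +-(x_i - x_j).
    """
    n = len(s)
    pos = {int(i): k for k, i in enumerate(active)}
    m = len(active)
    edges = []
    iu, ju = np.nonzero(np.triu(s, k=1))
    for i, j in zip(iu, ju):
        if i in pos or j in pos:
            edges.append((int(i), int(j), s[i, j]))
    if not edges:
        return coords[active, axis]
    ne = len(edges)
    c = np.concatenate([np.zeros(m), np.array([w for _, _, w in edges])])
    rows, cols, data, rhs = [], [], [], []
    r = 0
    for e, (i, j, _) in enumerate(edges):
        for sign in (1.0, -1.0):
            b = 0.0
            if i in pos:
                rows.append(r); cols.append(pos[i]); data.append(sign)
            else:
                b -= sign * coords[i, axis]
            if j in pos:
                rows.append(r); cols.append(pos[j]); data.append(-sign)
            else:
                b += sign * coords[j, axis]
            rows.append(r); cols.append(m + e); data.append(-1.0)
            rhs.append(b)
            r += 1
    A = sp.csr_matrix((data, (rows, cols)), shape=(r, m + ne))
    x0 = coords[active, axis]
    span = np.ptp(coords[:, axis])
    lo = coords[:, axis].min() - span - 1.0
    hi = coords[:, axis].max() + span + 1.0
    bounds = [(lo, hi)] * m + [(0.0, None)] * ne
    res = linprog(c, A_ub=A, b_ub=np.array(rhs), bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"l1 LP failed on axis {axis}: {res.message}")
    return res.x[:m]


def solve_l1(problem: PlacementProblem) -> Solution:
    """Exact l1 (Manhattan-cost) solve.

    The objective separates across coordinates.  Free nodes whose weighted
    neighbours are all fixed are placed at per-coordinate weighted medians
    (midpoint tie-break); coupled instances are solved per coordinate as a
    linear program, whose vertex solution is a global optimum.
    """
    if problem.spec != NormSpec.l1():
        raise ValueError("solve_l1 requires the l1 cost")
    active, isolated = _analyze_structure(problem)
    s = problem.sym_weights
    layout = problem.coords.copy()
    free_set = set(active.tolist())
    coupled = any(
        s[i, j] > 0 for i in active for j in active if j > i
    )
    if not coupled:
        for i in active:
            nbr = np.flatnonzero(s[i] > 0)
            for axis in (0, 1):
                layout[i, axis] = weighted_median(layout[nbr, axis], s[i, nbr])
        name = "l1_weighted_median"
    else:
        for axis in (0, 1):
            layout[active, axis] = _l1_coordinate_lp(s, active, problem.coords, axis)
        name = "l1_lp_highs"
    diag = {"isolated_free": isolated.tolist(), "coupled": bool(coupled)}
    return _finalize(problem, layout, True, 1, name, diag)


# ---------------------------------------------------------------------------
# higher Euclidean powers: smooth convex minimization


def _power_objective(xf, problem, active, p):
    layout = problem.coords.copy()
    layout[active] = xf.reshape(-1, 2)
    s = problem.sym_weights
    D = cdist(layout, layout)
    val = 0.5 * float(np.sum(s * D ** p))
    with np.errstate(invalid="ignore"):
        coef = s * p * D ** (p - 2) if p != 2 else s * p
    if p != 2:
        coef = np.nan_to_num(coef)
    grad_full = coef.sum(axis=1)[:, None] * layout - coef @ layout
    return val, grad_full[active].ravel()


def solve_power_p(problem: PlacementProblem, max_iter: int = 10_000) -> Solution:
    """Smooth convex solve for Euclidean-power costs p in {2, 3, 4}.

    Warm started from the squared-cost exact optimum; L-BFGS with analytic
    gradient, gradient-norm stopping at 1e-10 of the coordinate scale.
    """
    if problem.spec.family != "euclidean_power" or problem.spec.power not in (2, 3, 4):
        raise ValueError("solve_power_p requires a Euclidean power cost, p in {2,3,4}")
    p = problem.spec.power
    active, isolated = _analyze_structure(problem)
    layout = problem.coords.copy()
    diag = {"isolated_free": isolated.tolist()}
    if len(active) == 0:
        return _finalize(problem, layout, True, 0, f"power{p}_lbfgs", diag)
    warm = dataclasses.replace(problem, spec=NormSpec.squared_l2(), min_distance=None)
    layout = solve_squared_l2(warm).layout
    scale = _coordinate_scale(problem.coords)
    res = minimize(
        _power_objective,
        layout[active].ravel(),
        args=(problem, active, p),
        jac=True,
        method="L-BFGS-B",
        options={"gtol": 1e-10 * max(scale, 1.0), "ftol": 1e-16,
                 "maxiter": max_iter, "maxfun": 10 * max_iter},
    )
    layout[active] = res.x.reshape(-1, 2)
    diag["grad_norm"] = float(np.max(np.abs(res.jac))) if res.jac is not None else None
    return _finalize(problem, layout, bool(res.success), int(res.nit),
                     f"power{p}_lbfgs", diag)


# ---------------------------------------------------------------------------
# minimal inter-neuron distance refinement


def _free_pairs(problem):
    """All unordered pairs with at least one free endpoint."""
    n = problem.n
    free = ~problem.fixed_mask
    iu, ju = np.triu_indices(n, k=1)
    keep = free[iu] | free[ju]
    return iu[keep], ju[keep]


def _smooth_cost_and_grad(xf, problem, active, eps):
    layout = problem.coords.copy()
    layout[active] = xf.reshape(-1, 2)
    s = problem.sym_weights
    if problem.spec.family == "l1":
        val = 0.0
        grad_full = np.zeros_like(layout)
        for axis in (0, 1):
            diff = layout[:, axis][:, None] - layout[:, axis][None, :]
            sm = np.sqrt(diff * diff + eps * eps)
            val += 0.5 * float(np.sum(s * sm))
            g = s * diff / sm
            grad_full[:, axis] = g.sum(axis=1)
        return val, grad_full[active].ravel()
    p = problem.spec.power
    D = cdist(layout, layout)
    if p == 1:
        sm = np.sqrt(D * D + eps * eps)
        val = 0.5 * float(np.sum(s * sm))
        coef = s / sm
    else:
        val = 0.5 * float(np.sum(s * D ** p))
        with np.errstate(invalid="ignore"):
            coef = s * p * D ** (p - 2) if p != 2 else s * p
        if p != 2:
            coef = np.nan_to_num(coef)
    grad_full = coef.sum(axis=1)[:, None] * layout - coef @ layout
    return val, grad_full[active].ravel()


def _separate_pairs(layout, fixed_mask, pairs_i, pairs_j, delta, slack=1e-12):
    """Deterministically push violating pairs apart to distance >= delta."""
    moved = False
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i, j in zip(pairs_i, pairs_j):
        diff = layout[j] - layout[i]
        d = float(np.hypot(*diff))
        if d >= delta:
            continue
        moved = True
        if d == 0.0:
            theta = golden * (i * 131 + j)  # deterministic direction
            u = np.array([np.cos(theta), np.sin(theta)])
        else:
            u = diff / d
        need = delta * (1.0 + slack) - d
        fi, fj = fixed_mask[i], fixed_mask[j]
        if fi and fj:
            continue  # anchors cannot move; pair left as-is
        if fi:
            layout[j] += need * u
        elif fj:
            layout[i] -= need * u
        else:
            layout[i] -= 0.5 * need * u
            layout[j] += 0.5 * need * u
    return moved


def solve_with_min_distance(
    problem: PlacementProblem,
    warm: Solution,
    bounds: tuple | None = None,
    max_rounds: int = 20,
) -> Solution:
    """Enforce a minimal pairwise distance between every pair with a free node.

    The constraint makes the problem nonconvex; starting from the convex
    optimum ``warm``, violated pairs are deterministically separated and the
    layout is then polished with SLSQP on the active constraint set
    (constraints d_ij^2 >= delta^2 for every pair closer than twice delta),
    repeating until no pair violates.  If the unconstrained solution already
    satisfies the constraint it is returned unchanged.  ``bounds`` optionally
    clamps free nodes to an axis-aligned box ((xmin, ymin), (xmax, ymax)).
    """
    if problem.min_distance is None:
        raise ValueError("problem.min_distance is not set")
    delta = float(problem.min_distance)
    pi, pj = _free_pairs(problem)
    layout = warm.layout.copy()
    d = np.linalg.norm(layout[pi] - layout[pj], axis=1)
    if delta == 0.0 or (d >= delta).all():
        return warm

    active, _ = _analyze_structure(problem)
    scale = _coordinate_scale(problem.coords)
    eps = 1e-9 * scale
    fixed = problem.fixed_mask
    iterations = 0
    feasible = False
    for _round in range(max_rounds):
        _separate_pairs(layout, fixed, pi, pj, delta)
        if bounds is not None:
            lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
            layout[~fixed] = np.clip(layout[~fixed], lo, hi)
        # active constraint set: pairs currently within 2*delta
        d = np.linalg.norm(layout[pi] - layout[pj], axis=1)
        near = d < 2.0 * delta
        ai, aj = pi[near], pj[near]
        if len(ai):
            apos = {int(k): idx for idx, k in enumerate(active)}

            def cons_f(xf, ai=ai, aj=aj):
                lay = problem.coords.copy()
                lay[active] = xf.reshape(-1, 2)
                dd = lay[ai] - lay[aj]
                return np.sum(dd * dd, axis=1) - delta * delta

            def cons_jac(xf, ai=ai, aj=aj):
                lay = problem.coords.copy()
                lay[active] = xf.reshape(-1, 2)
                J = np.zeros((len(ai), 2 * len(active)))
                dd = lay[ai] - lay[aj]
                for r, (i, j) in enumerate(zip(ai, aj)):
                    if int(i) in apos:
                        J[r, 2 * apos[int(i)]:2 * apos[int(i)] + 2] = 2 * dd[r]
                    if int(j) in apos:
                        J[r, 2 * apos[int(j)]:2 * apos[int(j)] + 2] = -2 * dd[r]
                return J

            slsqp_bounds = None
            if bounds is not None:
                lo, hi = bounds
                slsqp_bounds = [(lo[k % 2], hi[k % 2]) for k in range(2 * len(active))]
            res = minimize(
                _smooth_cost_and_grad,
                layout[active].ravel(),
                args=(problem, active, eps),
                jac=True,
                method="SLSQP",
                bounds=slsqp_bounds,
                constraints=[{"type": "ineq", "fun": cons_f, "jac": cons_jac}],
                options={"maxiter": 500, "ftol": 1e-14},
            )
            iterations += int(res.nit)
            layout[active] = res.x.reshape(-1, 2)
        # final exact repair of residual numerical violations
        for _ in range(100):
            if not _separate_pairs(layout, fixed, pi, pj, delta):
                break
        d = np.linalg.norm(layout[pi] - layout[pj], axis=1)
        if (d >= delta * (1.0 - 1e-9)).all():
            feasible = True
            break
    sol = _finalize(problem, layout, feasible, max(iterations, 1),
                    "min_distance_slsqp", {"min_distance": delta,
                                           "n_constrained_pairs": int(len(pi))})
    if sol.objective < warm.objective * (1 - 1e-12):
        # cannot genuinely beat the unconstrained convex optimum
        sol.diagnostics["objective_below_warm"] = warm.objective - sol.objective
    return sol


# ---------------------------------------------------------------------------
# dispatcher


def _solve_unconstrained(problem: PlacementProblem) -> Solution:
    if problem.spec.family == "l1":
        return solve_l1(problem)
    p = problem.spec.power
    if p == 1:
        return solve_weber_l2(problem)
    if p == 2:
        return solve_squared_l2(problem)
    return solve_power_p(problem)


def solve(problem: PlacementProblem, bounds: tuple | None = None) -> Solution:
    """Solve a placement problem, dispatching on the cost function.

    If ``problem.min_distance`` is set, the convex problem is solved first
    and the minimal-distance refinement is applied from that warm start.
    """
    unconstrained = dataclasses.replace(problem, min_distance=None)
    warm = _solve_unconstrained(unconstrained)
    if problem.min_distance is None:
        return warm
    return solve_with_min_distance(problem, warm, bounds=bounds)
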