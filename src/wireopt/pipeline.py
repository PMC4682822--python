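"""Scenario orchestration: optimal/real/random comparison and derived statistics.

A *scenario* fixes the anchors (motor + sensory neurons, plus optionally a
set of designated interneurons), solves the placement problem under one cost
function and weighting scheme, and summarises how far the real layout is
from the wiring-length optimum:

* absolute and relative TWL reduction achieved by the optimal layout,
* how far the real TWL sits below the random-placement mean,
* the distribution of per-interneuron displacements (real vs optimal),
* displacement outliers — neurons whose displacement is separated from the
  rest by a large gap, the signature of e.g. tail-resident interneurons
  whose optimum lies near the head.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .baselines import random_baseline
from .io import ConnectivityData, NeuronTable, WeightScheme, build_weights
from .metrics import NormSpec, total_wiring_length
from .optimize import PlacementProblem, Solution, solve

__all__ = [
    "ScenarioReport",
    "DisplacementSummary",
    "SweepResult",
    "derive_comparisons",
    "run_scenario",
    "displacement_distribution",
    "detect_outliers",
    "weight_scheme_sweep",
    "write_report",
    "write_solution_tsv",
]

logger = logging.getLogger("wireopt")


def derive_comparisons(
    twl_real: float, twl_opt: float, twl_random_mean: float | None = None
) -> dict:
    """Derived comparison statistics from the three headline TWL values.

    reduction_abs   = twl_real - twl_opt
    reduction_pct   = 100 * reduction_abs / twl_real
    pct_below_random= 100 * (twl_random_mean - twl_real) / twl_random_mean
    random_excess_pct = 100 * (twl_random_mean - twl_real) / twl_real
        (how much *bigger* the random mean is than the real TWL)
    """
    out = {
        "reduction_abs": twl_real - twl_opt,
        "reduction_pct": 100.0 * (twl_real - twl_opt) / twl_real,
        "pct_below_random": None,
        "random_excess_pct": None,
    }
    if twl_random_mean is not None:
        out["pct_below_random"] = 100.0 * (twl_random_mean - twl_real) / twl_random_mean
        out["random_excess_pct"] = 100.0 * (twl_random_mean - twl_real) / twl_real
    return out


@dataclass
class DisplacementSummary:
    """Per-free-node distances between real and optimal positions (mm)."""

    ids: list
    values: np.ndarray
    mean: float
    bin_width: float
    counts: list
    bin_edges: list

    def as_dict(self) -> dict:
        return {
            "mean_mm": self.mean,
            "bin_width_mm": self.bin_width,
            "counts": list(self.counts),
            "bin_edges_mm": list(self.bin_edges),
        }


@dataclass
class ScenarioReport:
    """Full per-scenario comparison of optimal, real and random layouts."""

    norm: str
    scheme: str
    fixed_set: str
    n_fixed: int
    n_free: int
    units: str
    twl_real: float
    twl_opt: float
    reduction_abs: float
    reduction_pct: float
    twl_random_mean: float | None = None
    twl_random_sd: float | None = None
    pct_below_random: float | None = None
    random_excess_pct: float | None = None
    mean_displacement_mm: float = 0.0
    mean_displacement_norm_units: float = 0.0
    body_length_mm: float = 0.0
    mean_displacement_pct_body: float = 0.0
    displacement_histogram: dict = field(default_factory=dict)
    outlier_ids: list = field(default_factory=list)
    converged: bool = True
    solver_name: str = ""
    seed: int | None = None
    solution: Solution | None = None
    summary: DisplacementSummary | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items()
             if k not in ("solution", "summary")}
        return d


@dataclass
class SweepResult:
    """Reports per weighting scheme plus cross-scheme layout comparisons."""

    reports: list
    cross_scheme_mean_displacement: dict

    def to_dict(self) -> dict:
        return {
            "reports": [r.to_dict() for r in self.reports],
            "cross_scheme_mean_displacement_mm": {
                f"{a} vs {b}": v
                for (a, b), v in self.cross_scheme_mean_displacement.items()
            },
        }


def displacement_distribution(
    real: np.ndarray,
    opt: np.ndarray,
    free_mask: np.ndarray,
    bin_width: float = 0.05,
    ids=None,
) -> DisplacementSummary:
    """Per-free-node Euclidean displacement with half-open binning.

    A displacement d lands in bin ``[k*bin_width, (k+1)*bin_width)`` with
    ``k = floor(d / bin_width)``.
    """
    real = np.asarray(real, float)
    opt = np.asarray(opt, float)
    if real.shape != opt.shape:
        raise ValueError("layouts must have the same shape")
    free = np.asarray(free_mask, bool)
    disp = np.linalg.norm(opt[free] - real[free], axis=1)
    if ids is None:
        ids = [str(i) for i in np.flatnonzero(free)]
    else:
        ids = [str(i) for i in np.asarray(ids)[free]]
    if len(disp) == 0:
        return DisplacementSummary(ids, disp, 0.0, bin_width, [], [0.0])
    nbins = int(np.floor(disp.max() / bin_width)) + 1
    k = np.floor(disp / bin_width).astype(int)
    counts = np.bincount(k, minlength=nbins)
    edges = [i * bin_width for i in range(nbins + 1)]
    return DisplacementSummary(
        ids, disp, float(disp.mean()), bin_width, counts.tolist(), edges
    )


def detect_outliers(summary: DisplacementSummary, gap_threshold: float = 0.2) -> list:
    """Neurons separated from the rest by the largest displacement gap.

    Displacements are sorted; the largest gap between consecutive values
    exceeding ``gap_threshold`` splits the set, and every id above the gap is
    returned.  No qualifying gap -> empty list.
    """
    if len(summary.values) == 0:
        raise ValueError("empty displacement summary")
    order = np.argsort(summary.values, kind="stable")
    vals = summary.values[order]
    if len(vals) < 2:
        return []
    gaps = np.diff(vals)
    best = int(np.argmax(gaps))
    if gaps[best] <= gap_threshold:
        return []
    above = order[best + 1:]
    return [summary.ids[i] for i in above]


def _fixed_mask_with_extras(table: NeuronTable, extra_fixed) -> np.ndarray:
    mask = table.fixed_mask.copy()
    for nid in extra_fixed:
        i = table.index_of(str(nid))
        if table.classes[i] != "inter":
            raise ValueError(f"extra_fixed id {nid!r} is not an interneuron")
        mask[i] = True
    return mask


def run_scenario(
    table: NeuronTable,
    conn: ConnectivityData,
    spec: NormSpec,
    scheme: WeightScheme,
    extra_fixed=(),
    with_random: bool = False,
    n_iter: int = 1000,
    seed: int = 0,
    min_distance: float | str | None = None,
    region: str = "bbox",
    bin_width: float = 0.05,
    gap_threshold: float = 0.2,
) -> ScenarioReport:
    """Anchor motor + sensory (+ ``extra_fixed`` interneurons), solve, compare.

    ``min_distance="auto"`` uses the minimum pairwise distance in the real
    layout as the soma-exclusion radius.  ``with_random`` adds the
    Monte-Carlo random-placement mean (``n_iter`` draws seeded by ``seed``).
    """
    if tuple(table.ids) != tuple(conn.ids):
        raise ValueError("connectivity ids do not match the neuron table order")
    weights = build_weights(conn, scheme)
    fixed = _fixed_mask_with_extras(table, extra_fixed)
    real = table.coords
    if min_distance == "auto":
        from scipy.spatial.distance import pdist

        min_distance = float(pdist(real).min())
    problem = PlacementProblem(weights, fixed, real, spec, min_distance=min_distance)
    logger.info(
        "scenario norm=%s scheme=%s fixed=%d free=%d seed=%s",
        spec.label, scheme.label, int(fixed.sum()), int((~fixed).sum()), seed,
    )
    sol = solve(problem)
    twl_real = total_wiring_length(real, weights, spec)
    derived = derive_comparisons(twl_real, sol.objective)

    rand_mean = rand_sd = None
    if with_random:
        base = random_baseline(problem, real, n_iter=n_iter, seed=seed, region=region)
        rand_mean, rand_sd = base.mean_twl, base.sd_twl
        derived = derive_comparisons(twl_real, sol.objective, rand_mean)

    free = ~fixed
    summary = displacement_distribution(
        real, sol.layout, free, bin_width=bin_width, ids=table.ids
    )
    outliers = detect_outliers(summary, gap_threshold) if free.any() else []

    # spec-consistent displacement average (units of the cost function)
    if free.any():
        diff = sol.layout[free] - real[free]
        if spec.family == "l1":
            disp_norm = float(np.abs(diff).sum(axis=1).mean())
        else:
            disp_norm = float(
                (np.linalg.norm(diff, axis=1) ** spec.power).mean()
            )
    else:
        disp_norm = 0.0

    anchors = real[table.fixed_mask]
    body_length = float(np.ptp(anchors[:, 0])) if len(anchors) else 0.0
    mean_disp = summary.mean
    return ScenarioReport(
        norm=spec.label,
        scheme=scheme.label,
        fixed_set="motor+sensory"
        + (f"+{len(tuple(extra_fixed))} extra" if len(tuple(extra_fixed)) else ""),
        n_fixed=int(fixed.sum()),
        n_free=int(free.sum()),
        units=spec.units,
        twl_real=twl_real,
        twl_opt=sol.objective,
        reduction_abs=derived["reduction_abs"],
        reduction_pct=derived["reduction_pct"],
        twl_random_mean=rand_mean,
        twl_random_sd=rand_sd,
        pct_below_random=derived["pct_below_random"],
        random_excess_pct=derived["random_excess_pct"],
        mean_displacement_mm=mean_disp,
        mean_displacement_norm_units=disp_norm,
        body_length_mm=body_length,
        mean_displacement_pct_body=(
            100.0 * mean_disp / body_length if body_length > 0 else 0.0
        ),
        displacement_histogram=summary.as_dict(),
        outlier_ids=outliers,
        converged=sol.converged,
        solver_name=sol.solver_name,
        seed=seed,
        solution=sol,
        summary=summary,
    )


def weight_scheme_sweep(
    table: NeuronTable,
    conn: ConnectivityData,
    spec: NormSpec,
    schemes,
    **scenario_kwargs,
) -> SweepResult:
    """One scenario per weighting scheme plus cross-scheme layout distances.

    The cross-scheme entry for (a, b) is the mean Euclidean distance between
    the optimal free-node positions obtained under schemes a and b — how much
    the choice of weights moves the optimum.
    """
    schemes = list(schemes)
    if not schemes:
        raise ValueError("at least one weighting scheme is required")
    reports = [
        run_scenario(table, conn, spec, sch, **scenario_kwargs) for sch in schemes
    ]
    free = ~_fixed_mask_with_extras(table, scenario_kwargs.get("extra_fixed", ()))
    cross = {}
    for a in range(len(reports)):
        for b in range(a + 1, len(reports)):
            la = reports[a].solution.layout[free]
            lb = reports[b].solution.layout[free]
            cross[(reports[a].scheme, reports[b].scheme)] = float(
                np.linalg.norm(la - lb, axis=1).mean()
            )
    return SweepResult(reports, cross)


# ---------------------------------------------------------------------------
# output


def write_solution_tsv(
    table: NeuronTable, solution: Solution, fixed_mask: np.ndarray, path
) -> None:
    """Write the solved layout as TSV with per-neuron displacement."""
    import pandas as pd

    disp = solution.displacement_from(table.coords)
    df = pd.DataFrame(
        {
            "neuron_id": table.ids,
            "class": table.classes,
            "x_opt_mm": solution.layout[:, 0],
            "y_opt_mm": solution.layout[:, 1],
            "displacement_mm": disp,
            "is_fixed": np.asarray(fixed_mask, bool),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_report(reports, path, extra: dict | None = None) -> None:
    """Write scenario reports (and optional extra entries) as JSON."""
    payload = {"scenarios": [r.to_dict() for r in reports]}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
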