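"""Worm-like synthetic connectome instances.

Generates neuron tables and connectivity with the spatial statistics the
placement analysis assumes: anchors (motor/sensory neurons) concentrated in
a head cluster and a tail cluster at opposite ends of an elongated body,
plus a sparse ventral-cord line of anchors between them; interneurons
anywhere in the body; directed chemical connections and symmetric electrical
connections whose probability decays exponentially with inter-neuron
distance; small integer multiplicities.

A planted-optimum mode rewrites the free-node positions to the exact
quadratic-cost optimum, giving instances whose "real" layout is known to be
optimal — a recovery oracle for the solvers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import ConnectivityData, NeuronTable, WeightScheme, build_weights
from .metrics import NormSpec
from .optimize import PlacementProblem, solve_squared_l2

__all__ = ["SynthConfig", "generate_instance", "plant_sq_l2_optimum"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    Defaults emulate an adult-hermaphrodite-scale instance: 200 anchors
    (90 head, 70 tail, 40 ventral cord) and 80 free interneurons in a
    1.2 mm x 0.15 mm body; connection probability exp(-d / decay_scale)
    with a 0.1 mm decay scale, split 85% chemical / 15% electrical; synapse
    multiplicities geometric with mean 2.5 (a fairly even, low-variance
    distribution of synapses per connection).
    """

    n_anchors_head: int = 90
    n_anchors_tail: int = 70
    n_anchors_cord: int = 40
    n_free: int = 80
    body_length: float = 1.2
    body_height: float = 0.15
    decay_scale: float = 0.1
    chem_fraction: float = 0.85
    count_mean: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_anchors_head, self.n_anchors_tail,
               self.n_anchors_cord, self.n_free) < 0:
            raise ValueError("counts must be nonnegative")
        if self.body_length <= 0 or self.body_height <= 0:
            raise ValueError("body dimensions must be positive")
        if not self.decay_scale > 0:
            raise ValueError("decay_scale must be positive")
        if not 0.0 <= self.chem_fraction <= 1.0:
            raise ValueError("chem_fraction must lie in [0, 1]")
        if self.count_mean < 1.0:
            raise ValueError("count_mean must be >= 1 (geometric support)")


def _sample_positions(cfg: SynthConfig, rng) -> pd.DataFrame:
    L, H = cfg.body_length, cfg.body_height
    rows = []

    def add(prefix, n, xlo, xhi, ylo, yhi, klass_probs):
        xs = rng.uniform(xlo, xhi, n)
        ys = rng.uniform(ylo, yhi, n)
        classes = rng.choice(["motor", "sensory"], size=n, p=klass_probs)
        for k in range(n):
            rows.append((f"{prefix}{k + 1:03d}", classes[k], xs[k], ys[k]))

    # head ganglia: sensory-rich; tail ganglia and ventral cord: motor-rich
    add("HD", cfg.n_anchors_head, 0.0, 0.12 * L, 0.0, H, (0.4, 0.6))
    add("TL", cfg.n_anchors_tail, 0.88 * L, L, 0.0, H, (0.6, 0.4))
    add("VC", cfg.n_anchors_cord, 0.12 * L, 0.88 * L, 0.0, 0.25 * H, (0.8, 0.2))
    xs = rng.uniform(0.0, L, cfg.n_free)
    ys = rng.uniform(0.0, H, cfg.n_free)
    for k in range(cfg.n_free):
        rows.append((f"IN{k + 1:03d}", "inter", xs[k], ys[k]))
    return pd.DataFrame(rows, columns=["neuron_id", "class", "x_mm", "y_mm"])


def _wire(cfg: SynthConfig, coords: np.ndarray, rng):
    n = len(coords)
    D = cdist(coords, coords)
    if np.isinf(cfg.decay_scale):
        decay = np.ones_like(D)
    else:
        decay = np.exp(-D / cfg.decay_scale)
    p_geo = 1.0 / cfg.count_mean

    # directed chemical edges
    p_chem = cfg.chem_fraction * decay
    chem_hit = rng.random((n, n)) < p_chem
    np.fill_diagonal(chem_hit, False)
    chem = np.where(chem_hit, rng.geometric(p_geo, size=(n, n)), 0)

    # symmetric electrical edges, decided once per unordered pair
    p_elec = (1.0 - cfg.chem_fraction) * decay
    elec_hit = rng.random((n, n)) < p_elec
    elec_hit = np.triu(elec_hit, k=1)
    counts = np.where(elec_hit, rng.geometric(p_geo, size=(n, n)), 0)
    elec = counts + counts.T
    return chem.astype(int), elec.astype(int)


def generate_instance(cfg: SynthConfig, max_retries: int = 10):
    """Generate a (NeuronTable, ConnectivityData) pair from ``cfg``.

    Fully reproducible from ``cfg.seed``; regenerates (with a derived seed)
    up to ``max_retries`` times if sampling yields an empty graph.
    """
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, attempt]))
        df = _sample_positions(cfg, rng)
        coords = df[["x_mm", "y_mm"]].to_numpy(dtype=float)
        chem, elec = _wire(cfg, coords, rng)
        if chem.sum() + elec.sum() > 0:
            table = NeuronTable(df)
            return table, ConnectivityData(tuple(table.ids), chem, elec)
    raise RuntimeError(
        f"empty graph after {max_retries} attempts; increase decay_scale or sizes"
    )


def plant_sq_l2_optimum(
    table: NeuronTable,
    conn: ConnectivityData,
    scheme: WeightScheme | None = None,
) -> NeuronTable:
    """Rewrite free-node positions to the exact squared-cost optimum.

    The returned table's layout *is* the global minimizer of the quadratic
    wiring cost given the anchors, so a subsequent squared-cost solve must
    recover the positions (to numerical precision) and report zero
    reduction.  Requires every free node to be connected, through the
    weighted graph, to the anchor set.
    """
    scheme = scheme or WeightScheme.unit_joint()
    weights = build_weights(conn, scheme)
    s = weights + weights.T
    free = table.free_mask
    if (s[free].sum(axis=1) == 0).any():
        bad = [table.ids[i] for i in np.flatnonzero(free & (s.sum(axis=1) == 0))]
        raise ValueError(f"free nodes with no connections cannot be planted: {bad}")
    problem = PlacementProblem(
        weights, table.fixed_mask, table.coords, NormSpec.squared_l2()
    )
    sol = solve_squared_l2(problem)  # raises on disconnected free components
    return table.with_coords(sol.layout)
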