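"""Distance functions and the total-wiring-length (TWL) objective.

The wiring cost of a layout is the weighted sum of inter-neuron distances
over all directed links:

    TWL = sum_ij  A_ij * d(x_i, x_j)

where ``A`` is a link-weight matrix (see :mod:`wireopt.io`) and ``d`` is one
of the supported cost functions: the l1 (Manhattan) norm, the Euclidean
norm, or an integer power p of the Euclidean norm (p = 2 is the squared
Euclidean "distance", which is not a metric but is the classical quadratic
wiring cost; p = 3, 4 probe steeper cost growth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["NormSpec", "pairwise_distance", "total_wiring_length"]

_SUPPORTED_POWERS = (1, 2, 3, 4)


@dataclass(frozen=True)
class NormSpec:
    """Specification of the per-connection distance (cost) function.

    ``family == "l1"`` is the Manhattan distance; ``family ==
    "euclidean_power"`` is ``||x - y||_2 ** power`` with ``power`` in
    {1, 2, 3, 4} (1 = Euclidean, 2 = squared Euclidean, ...).
    """

    family: str
    power: int | None = None

    def __post_init__(self):
        if self.family == "l1":
            if self.power is not None:
                raise ValueError("l1 norm takes no power parameter")
        elif self.family == "euclidean_power":
            if self.power not in _SUPPORTED_POWERS:
                raise ValueError(
                    f"power must be one of {_SUPPORTED_POWERS}, got {self.power}"
                )
        else:
            raise ValueError(f"unknown norm family {self.family!r}")

    @classmethod
    def l1(cls) -> "NormSpec":
        return cls("l1")

    @classmethod
    def l2(cls) -> "NormSpec":
        return cls("euclidean_power", 1)

    @classmethod
    def squared_l2(cls) -> "NormSpec":
        return cls("euclidean_power", 2)

    @classmethod
    def euclidean_power(cls, power: int) -> "NormSpec":
        return cls("euclidean_power", power)

    @classmethod
    def from_label(cls, label: str) -> "NormSpec":
        try:
            return {
                "l1": cls.l1(),
                "l2": cls.l2(),
                "sq": cls.squared_l2(),
                "p3": cls.euclidean_power(3),
                "p4": cls.euclidean_power(4),
            }[label]
        except KeyError:
            raise ValueError(f"unknown norm label {label!r}") from None

    @property
    def label(self) -> str:
        if self.family == "l1":
            return "l1"
        return {1: "l2", 2: "sq"}.get(self.power, f"p{self.power}")

    @property
    def units(self) -> str:
        """Units of a cost value for positions in mm."""
        p = 1 if self.family == "l1" else self.power
        return "mm" if p == 1 else f"mm^{p}"

    @property
    def homogeneity_degree(self) -> int:
        """TWL scales as c**degree when all coordinates scale by c > 0."""
        return 1 if self.family == "l1" else self.power


def pairwise_distance(layout: np.ndarray, spec: NormSpec) -> np.ndarray:
    """Symmetric n x n matrix of pairwise costs d_spec(x_i, x_j)."""
    X = np.asarray(layout, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError(f"layout must be n x 2, got {X.shape}")
    if spec.family == "l1":
        return cdist(X, X, "cityblock")
    D = cdist(X, X, "euclidean")
    if spec.power != 1:
        D **= spec.power
    return D


def total_wiring_length(
    layout: np.ndarray, weights: np.ndarray, spec: NormSpec
) -> float:
    """Total wiring length: sum over ordered pairs of A_ij * d_spec(i, j).

    The sum runs over all ordered pairs; with the symmetric electrical
    halving convention of :func:`wireopt.io.build_weights` each electrical
    connection therefore contributes its distance exactly once in total.
    """
    W = np.asarray(weights, dtype=float)
    X = np.asarray(layout, dtype=float)
    if W.shape != (len(X), len(X)):
        raise ValueError(
            f"weights shape {W.shape} does not match layout with {len(X)} rows"
        )
    D = pairwise_distance(X, spec)
    # fixed elementwise order keeps repeated runs bit-identical
    return float(np.sum(W * D))
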