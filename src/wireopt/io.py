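"""Neuron position tables, connection edge lists, and connection-weight matrices.

The on-disk formats are deliberately minimal so that any connectome source can
be converted to them:

``positions.tsv``
    Tab-separated, header ``neuron_id  class  x_mm  y_mm``.  ``class`` is one
    of ``motor``, ``sensory``, ``inter``.  Coordinates are soma positions in
    millimetres; axis 1 runs anterior -> posterior, axis 2 ventral -> dorsal.
    Row order defines the canonical neuron index used everywhere downstream.

``edges.csv``
    Comma-separated, header ``pre,post,type[,count]``.  ``type`` is ``chem``
    (directed chemical connection) or ``gap`` (symmetric electrical
    connection / gap junction); ``count`` is the synapse or gap-junction
    multiplicity (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VALID_CLASSES",
    "NeuronTable",
    "ConnectivityData",
    "WeightScheme",
    "read_positions",
    "write_positions",
    "read_edges",
    "write_edges",
    "build_weights",
]

VALID_CLASSES = ("motor", "sensory", "inter")

_POSITION_COLUMNS = ["neuron_id", "class", "x_mm", "y_mm"]


class NeuronTable:
    """Ordered table of neurons: label, functional class, 2-D soma position.

    The row order is the canonical index: connectivity matrices, layouts and
    solver masks all follow it.  Motor and sensory neurons are the anchors
    (``fixed_mask``); interneurons are the free placement variables
    (``free_mask``).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _POSITION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"position table missing columns: {missing}")
        df = df.loc[:, _POSITION_COLUMNS].reset_index(drop=True)
        ids = df["neuron_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate neuron_id: {dup.iloc[0]!r}")
        bad = sorted(set(df["class"]) - set(VALID_CLASSES))
        if bad:
            raise ValueError(
                f"unknown class token(s) {bad}; expected one of {VALID_CLASSES}"
            )
        coords = df[["x_mm", "y_mm"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            row = int(np.argwhere(~np.isfinite(coords).all(axis=1))[0, 0])
            raise ValueError(f"non-finite coordinate in row {row + 1}")
        self._df = df.assign(neuron_id=ids)
        self._index = {nid: i for i, nid in enumerate(ids)}

    # -- accessors ---------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def ids(self) -> np.ndarray:
        return self._df["neuron_id"].to_numpy()

    @property
    def classes(self) -> np.ndarray:
        return self._df["class"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        """n x 2 array of positions in mm (row order = canonical index)."""
        return self._df[["x_mm", "y_mm"]].to_numpy(dtype=float)

    @property
    def free_mask(self) -> np.ndarray:
        return self.classes == "inter"

    @property
    def fixed_mask(self) -> np.ndarray:
        return ~self.free_mask

    @property
    def n_free(self) -> int:
        return int(self.free_mask.sum())

    def index_of(self, neuron_id: str) -> int:
        try:
            return self._index[neuron_id]
        except KeyError:
            raise KeyError(f"unknown neuron_id: {neuron_id!r}") from None

    def with_coords(self, coords: np.ndarray) -> "NeuronTable":
        """Return a copy of the table with positions replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n, 2):
            raise ValueError(f"coords must be {(self.n, 2)}, got {coords.shape}")
        df = self._df.copy()
        df[["x_mm", "y_mm"]] = coords
        return NeuronTable(df)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        counts = self._df["class"].value_counts().to_dict()
        return f"NeuronTable(n={self.n}, classes={counts})"


@dataclass
class ConnectivityData:
    """Chemical and electrical connectivity aligned with a NeuronTable order.

    ``chem[i, j]`` is the number of chemical synapses of the directed
    connection i -> j (``nsyn``); ``elec[i, j] == elec[j, i]`` is the number
    of gap junctions of the electrical connection between i and j (``ngap``).
    Both have zero diagonals.
    """

    ids: tuple
    chem: np.ndarray
    elec: np.ndarray

    def __post_init__(self):
        self.ids = tuple(str(i) for i in self.ids)
        n = len(self.ids)
        self.chem = np.asarray(self.chem)
        self.elec = np.asarray(self.elec)
        for name, m in (("chem", self.chem), ("elec", self.elec)):
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {(n, n)}, got {m.shape}")
            if not np.issubdtype(m.dtype, np.integer):
                if not np.allclose(m, np.round(m)):
                    raise ValueError(f"{name} counts must be integers")
                m = np.round(m).astype(int)
            if (m < 0).any():
                raise ValueError(f"{name} counts must be nonnegative")
            if np.diagonal(m).any():
                raise ValueError(f"{name} must have a zero diagonal (no self-edges)")
        self.chem = self.chem.astype(int)
        self.elec = self.elec.astype(int)
        if not np.array_equal(self.elec, self.elec.T):
            raise ValueError("elec matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def empty(cls, ids) -> "ConnectivityData":
        n = len(ids)
        z = np.zeros((n, n), dtype=int)
        return cls(tuple(ids), z, z.copy())


@dataclass(frozen=True)
class WeightScheme:
    """How chemical/electrical connections are turned into link weights.

    Modes
    -----
    ``unit_joint``
        Every connection has unit weight regardless of type: A_ij =
        1[chem_ij > 0] + 0.5 * 1[elec_ij > 0].  The 0.5 compensates for an
        electrical connection appearing twice in the symmetric elec matrix,
        so each connection contributes once to the total wiring length.
    ``synapse_counts``
        Weights are multiplicities: A_ij = nsyn_ij + elec_factor * ngap_ij
        (elec_factor defaults to the same 0.5 halving convention).
    ``binary_union``
        A_ij = 1 if any connection exists in either type; multiplicity and
        type are ignored.
    ``scaled``
        Per-type weights: A_ij = chem_scale * 1[chem_ij > 0]
        + 0.5 * elec_scale * 1[elec_ij > 0].
    """

    mode: str
    chem_scale: float = 1.0
    elec_scale: float = 1.0
    elec_factor: float = 0.5

    _MODES = ("unit_joint", "synapse_counts", "binary_union", "scaled")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {self._MODES}")
        if self.chem_scale < 0 or self.elec_scale < 0 or self.elec_factor < 0:
            raise ValueError("weight scales must be nonnegative")

    @classmethod
    def unit_joint(cls) -> "WeightScheme":
        return cls("unit_joint")

    @classmethod
    def synapse_counts(cls, elec_factor: float = 0.5) -> "WeightScheme":
        return cls("synapse_counts", elec_factor=elec_factor)

    @classmethod
    def binary_union(cls) -> "WeightScheme":
        return cls("binary_union")

    @classmethod
    def scaled(cls, chem_scale: float, elec_scale: float) -> "WeightScheme":
        return cls("scaled", chem_scale=chem_scale, elec_scale=elec_scale)

    @property
    def label(self) -> str:
        if self.mode == "scaled":
            return f"scaled({self.chem_scale:g},{self.elec_scale:g})"
        if self.mode == "synapse_counts" and self.elec_factor != 0.5:
            return f"synapse_counts(elec_factor={self.elec_factor:g})"
        return self.mode


# ---------------------------------------------------------------------------
# file IO


def read_positions(path) -> NeuronTable:
    """Read a positions TSV into a :class:`NeuronTable`.

    Raises ``ValueError`` on duplicate ids, unknown class tokens or
    non-numeric coordinates (reported with the 1-based data row number).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _POSITION_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("x_mm", "y_mm"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(
                f"{path}: non-numeric {col} value {raw[col][row - 1]!r} in row {row}"
            )
        raw[col] = vals
    return NeuronTable(raw)


def write_positions(table: NeuronTable, path) -> None:
    df = table.df
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edges(path, table: NeuronTable) -> ConnectivityData:
    """Read an edges CSV into a :class:`ConnectivityData` aligned with ``table``.

    Chemical rows accumulate: repeated ``(pre, post, chem)`` rows sum their
    counts.  Gap rows are per unordered pair: repeats with the same count are
    counted once; repeats with conflicting counts are an error.
    """
    raw = pd.read_csv(path, dtype={"pre": str, "post": str, "type": str})
    for col in ("pre", "post", "type"):
        if col not in raw.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if "count" in raw.columns:
        counts = pd.to_numeric(raw["count"], errors="coerce")
    else:
        counts = pd.Series(np.ones(len(raw)))

    n = table.n
    chem = np.zeros((n, n), dtype=int)
    elec = np.zeros((n, n), dtype=int)
    gap_counts: dict[tuple[int, int], int] = {}

    for k in range(len(raw)):
        row = k + 1  # 1-based data row for error messages
        pre, post, etype = raw["pre"][k], raw["post"][k], raw["type"][k]
        c = counts[k]
        if not np.isfinite(c) or c != int(c) or c <= 0:
            raise ValueError(f"{path}: nonpositive or non-integer count in row {row}")
        c = int(c)
        if etype not in ("chem", "gap"):
            raise ValueError(f"{path}: unknown type {etype!r} in row {row}")
        try:
            i, j = table.index_of(pre), table.index_of(post)
        except KeyError as exc:
            raise ValueError(f"{path}: row {row}: {exc.args[0]}") from None
        if i == j:
            raise ValueError(f"{path}: self-edge {pre!r} in row {row}")
        if etype == "chem":
            chem[i, j] += c
        else:
            key = (min(i, j), max(i, j))
            if key in gap_counts:
                if gap_counts[key] != c:
                    raise ValueError(
                        f"{path}: conflicting gap counts for pair "
                        f"({table.ids[key[0]]}, {table.ids[key[1]]}) in row {row}"
                    )
            else:
                gap_counts[key] = c
    for (i, j), c in gap_counts.items():
        elec[i, j] = elec[j, i] = c
    return ConnectivityData(tuple(table.ids), chem, elec)


def write_edges(conn: ConnectivityData, path) -> None:
    """Write a :class:`ConnectivityData` to the edges CSV format.

    ``read_edges(write_edges(conn))`` round-trips bit-exactly.
    """
    rows = []
    ids = conn.ids
    ii, jj = np.nonzero(conn.chem)
    for i, j in zip(ii, jj):
        rows.append((ids[i], ids[j], "chem", int(conn.chem[i, j])))
    ii, jj = np.nonzero(np.triu(conn.elec, k=1))
    for i, j in zip(ii, jj):
        rows.append((ids[i], ids[j], "gap", int(conn.elec[i, j])))
    pd.DataFrame(rows, columns=["pre", "post", "type", "count"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# weight matrices


def build_weights(conn: ConnectivityData, scheme: WeightScheme) -> np.ndarray:
    """Build the n x n link-weight matrix A under a :class:`WeightScheme`.

    The returned matrix is nonnegative with a zero diagonal; entry ij is the
    weight of the directed link i -> j that multiplies the i-j distance in
    the total wiring length.
    """
    chem_ind = (conn.chem > 0).astype(float)
    elec_ind = (conn.elec > 0).astype(float)
    if scheme.mode == "unit_joint":
        w = chem_ind + 0.5 * elec_ind
    elif scheme.mode == "synapse_counts":
        w = conn.chem.astype(float) + scheme.elec_factor * conn.elec.astype(float)
    elif scheme.mode == "binary_union":
        w = ((conn.chem > 0) | (conn.elec > 0)).astype(float)
    else:  # scaled
        w = scheme.chem_scale * chem_ind + 0.5 * scheme.elec_scale * elec_ind
    np.fill_diagonal(w, 0.0)
    return w
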