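"""Core connectome data structures, file I/O, weight assembly and density thresholding.

A connectome is represented at two levels: a :class:`WeightedConnectome`
carrying tractography-derived fiber-density weights ``w_ij``, and a
:class:`BinaryConnectome` obtained by retaining the strongest fraction of
possible connections (the density threshold) and binarizing.  Node identity
(region label, hemisphere, tissue class, homotopic partner) travels with the
matrices in a :class:`NodeTable`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite

__all__ = [
    "NodeTable",
    "StreamlineTable",
    "WeightedConnectome",
    "BinaryConnectome",
    "LengthMatrix",
    "assemble_weights",
    "threshold_to_density",
    "read_connectome",
    "write_connectome",
    "read_matrix",
    "write_matrix",
]

HEMISPHERES = {"L", "R", "M"}
TISSUE_CLASSES = {"cortical", "central", "cerebellar"}

NODE_COLUMNS = ["node_id", "label", "hemisphere", "tissue_class", "homotopic_partner"]


@dataclass
class NodeTable:
    """Region metadata: label, hemisphere, tissue class, homotopic partner.

    ``homotopic_partner`` is ``-1`` for unpaired (midline) nodes.  Pairing
    must be an involution across opposite hemispheres.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in NODE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"node table missing columns: {missing}")
        n = len(df)
        ids = df["node_id"].to_numpy()
        if not np.array_equal(np.sort(ids), np.arange(n)):
            raise ValueError("node_ids must be contiguous 0..n-1")
        df = df.sort_values("node_id").reset_index(drop=True)
        bad_hemi = set(df["hemisphere"]) - HEMISPHERES
        if bad_hemi:
            raise ValueError(f"unknown hemisphere codes: {bad_hemi}")
        bad_cls = set(df["tissue_class"]) - TISSUE_CLASSES
        if bad_cls:
            raise ValueError(f"unknown tissue classes: {bad_cls}")
        partner = df["homotopic_partner"].fillna(-1).astype(int).to_numpy()
        hemi = df["hemisphere"].to_numpy()
        for i in range(n):
            p = partner[i]
            if p == -1:
                continue
            if not (0 <= p < n):
                raise ValueError(f"node {i}: partner {p} out of range")
            if partner[p] != i:
                raise ValueError(f"homotopic pairing is not an involution at node {i}")
            if {hemi[i], hemi[p]} != {"L", "R"}:
                raise ValueError(f"partners {i},{p} must lie in opposite L/R hemispheres")
        for i in range(n):
            if hemi[i] == "M" and partner[i] != -1:
                raise ValueError(f"midline node {i} must not have a partner")
        df = df.copy()
        df["homotopic_partner"] = partner
        self.df = df

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def hemisphere(self) -> np.ndarray:
        return self.df["hemisphere"].to_numpy()

    @property
    def tissue_class(self) -> np.ndarray:
        return self.df["tissue_class"].to_numpy()

    @property
    def partner(self) -> np.ndarray:
        return self.df["homotopic_partner"].to_numpy()

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """(left, right) node-id pairs, each pair listed once."""
        out = []
        partner = self.partner
        hemi = self.hemisphere
        for i in range(self.n):
            if partner[i] != -1 and hemi[i] == "L":
                out.append((i, int(partner[i])))
        return out

    @classmethod
    def read_tsv(cls, path: str | Path) -> "NodeTable":
        df = pd.read_csv(path, sep="\t", dtype={"label": str, "hemisphere": str, "tissue_class": str})
        if "volume_norm" not in df.columns:
            df["volume_norm"] = np.nan
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.loc[out["homotopic_partner"] < 0, "homotopic_partner"] = pd.NA
        out.to_csv(path, sep="\t", index=False, na_rep="")

    @classmethod
    def trivial(cls, n: int) -> "NodeTable":
        """Unannotated table: n cortical nodes, alternating L/R with L/R pairing."""
        hemi = ["L" if i % 2 == 0 else "R" for i in range(n)]
        partner = [i + 1 if i % 2 == 0 else i - 1 for i in range(n)]
        if n % 2 == 1:
            hemi[-1] = "M"
            partner[-1] = -1
        df = pd.DataFrame(
            {
                "node_id": range(n),
                "label": [f"roi{i}" for i in range(n)],
                "hemisphere": hemi,
                "tissue_class": ["cortical"] * n,
                "homotopic_partner": partner,
                "volume_norm": np.nan,
            }
        )
        return cls(df)


@dataclass
class StreamlineTable:
    """Rows of (i, j, sc): streamline endpoint pairs with SIFT2 weights,
    plus the proportionality coefficient ``mu``."""

    rows: pd.DataFrame
    mu: float = 1.0

    def __post_init__(self) -> None:
        df = self.rows
        for c in ("i", "j", "sc"):
            if c not in df.columns:
                raise ValueError(f"streamline table missing column {c!r}")
        if len(df) and (df["sc"].to_numpy() < 0).any():
            raise ValueError("streamline weights must be nonnegative")
        if len(df) and (df["i"].to_numpy() == df["j"].to_numpy()).any():
            raise ValueError("self-pair streamline rows are not allowed")

    @classmethod
    def read_tsv(cls, path: str | Path, mu: float = 1.0) -> "StreamlineTable":
        return cls(pd.read_csv(path, sep="\t"), mu=mu)


def _check_square_symmetric(M: np.ndarray, name: str, tol: float = 1e-9) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=tol, rtol=0.0):
        raise ValueError(f"{name} is asymmetric beyond tolerance {tol}")
    return M


@dataclass
class WeightedConnectome:
    """Symmetric, hollow, nonnegative matrix of connection weights."""

    W: np.ndarray
    nodes: NodeTable

    def __post_init__(self) -> None:
        self.W = _check_square_symmetric(self.W, "weight matrix")
        if self.W.shape[0] != self.nodes.n:
            raise ValueError(
                f"matrix is {self.W.shape[0]}x{self.W.shape[0]} but node table has {self.nodes.n} rows"
            )
        if np.any(np.diag(self.W) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        if np.any(self.W < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class BinaryConnectome:
    """Hollow symmetric 0/1 adjacency with node metadata."""

    A: np.ndarray
    nodes: NodeTable
    density: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        A = _check_square_symmetric(A.astype(float), "adjacency").astype(np.int8)
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must be hollow")
        if A.shape[0] != self.nodes.n:
            raise ValueError("adjacency / node table size mismatch")
        self.A = A
        n = A.shape[0]
        realized = A.sum() / (n * (n - 1)) if n > 1 else 0.0
        if self.density is None:
            self.density = realized
        self.density = float(realized)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.A.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.A.sum(axis=1).astype(int)


@dataclass
class LengthMatrix:
    """Mean streamline length (mm) per connection; meaningful where A = 1."""

    L: np.ndarray

    def __post_init__(self) -> None:
        self.L = _check_square_symmetric(self.L, "length matrix")
        if np.any(self.L < 0):
            raise ValueError("lengths must be nonnegative")

    @property
    def n(self) -> int:
        return self.L.shape[0]


def assemble_weights(streamlines: StreamlineTable, nodes: NodeTable) -> WeightedConnectome:
    """Total connection weight w_ij = mu * sum of streamline weights with endpoints {i, j}."""
    n = nodes.n
    W = np.zeros((n, n))
    df = streamlines.rows
    if len(df):
        i = df["i"].to_numpy(dtype=int)
        j = df["j"].to_numpy(dtype=int)
        if (i < 0).any() or (i >= n).any() or (j < 0).any() or (j >= n).any():
            raise ValueError("streamline endpoint outside node table")
        np.add.at(W, (i, j), df["sc"].to_numpy(dtype=float))
        W = W + W.T
    return WeightedConnectome(streamlines.mu * W, nodes)


def edge_count_at_density(n: int, density: float) -> int:
    """Retained edge count m = floor(density * n(n-1)/2).

    A tiny epsilon protects exact integer products (e.g. a density that was
    itself computed as 2m/(n(n-1))) from floating-point round-down.
    """
    return math.floor(density * n * (n - 1) / 2 + 1e-9)


def threshold_to_density(W: WeightedConnectome, density: float) -> BinaryConnectome:
    """Keep the m strongest connections, m = floor(density * n(n-1)/2), and binarize.

    Ties are broken deterministically by (weight descending, i ascending,
    j ascending), which makes the edge sets nested across a density sweep.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = W.n
    m = edge_count_at_density(n, density)
    if m == 0:
        raise ValueError("density too low: zero edges would remain")
    iu, ju = np.triu_indices(n, k=1)
    w = W.W[iu, ju]
    # stable sort on -w keeps the lexicographic (i, j) order among equal weights
    order = np.argsort(-w, kind="stable")[:m]
    A = np.zeros((n, n), dtype=np.int8)
    A[iu[order], ju[order]] = 1
    A |= A.T
    return BinaryConnectome(A, W.nodes)


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a dense matrix from headerless CSV or MatrixMarket (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        M = mmread(str(path))
        if hasattr(M, "toarray"):
            M = M.toarray()
        return np.asarray(M, dtype=float)
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_matrix(M: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        mmwrite(str(path), np.asarray(M))
    else:
        # repr-precision floats so that read(write(x)) == x bit-exactly
        np.savetxt(path, np.asarray(M), delimiter=",", fmt="%.17g")


def read_connectome(matrix_path: str | Path, nodes_path: str | Path) -> WeightedConnectome:
    W = read_matrix(matrix_path)
    nodes = NodeTable.read_tsv(nodes_path)
    return WeightedConnectome(W, nodes)


def write_connectome(conn: WeightedConnectome, matrix_path: str | Path, nodes_path: str | Path) -> None:
    write_matrix(conn.W, matrix_path)
    conn.nodes.write_tsv(nodes_path)
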