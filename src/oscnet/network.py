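"""Undirected networks for oscillator simulations.

Generators for the two inhomogeneous-degree topologies used throughout the
package — Gilbert random graphs and scale-free graphs built with the
uncorrelated configuration model of Catanzaro, Boguna & Pastor-Satorras —
plus node classification into hubs/peripherals, conduction-delay matrices,
and plain-text load/save.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "DelayMatrix",
    "GenerationError",
    "generate_random_gilbert",
    "generate_scale_free_catanzaro",
    "classify_nodes",
    "build_delay_matrix",
    "load_network",
    "save_network",
]

#: delays above a quarter cycle of a 10 Hz rhythm destabilise the
#: hub-lag pattern; used as the warning threshold for delay matrices.
QUARTER_CYCLE_10HZ_S = 0.025

_MAX_RESAMPLE = 10_000


class GenerationError(RuntimeError):
    """Raised when a random-graph generator cannot produce a valid draw."""


@dataclass
class Network:
    """Undirected, unweighted graph with optional geometry.

    Parameters
    ----------
    adjacency : (N, N) ndarray
        Symmetric binary matrix with zero diagonal.
    coordinates : (N, 3) ndarray, optional
        Node positions in mm.
    distances : (N, N) ndarray, optional
        Pairwise euclidean distances in mm.  Derived from ``coordinates``
        automatically when those are given and ``distances`` is not.
    labels : list of str, optional
        Node names.
    """

    adjacency: np.ndarray
    coordinates: np.ndarray | None = None
    distances: np.ndarray | None = None
    labels: list[str] | None = None
    degrees: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = A.astype(np.int8)
        self.degrees = self.adjacency.sum(axis=1).astype(np.int64)
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (self.n_nodes, 3):
                raise ValueError("coordinates must be (N, 3)")
            if self.distances is None:
                diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
                self.distances = np.sqrt((diff**2).sum(axis=-1))
        if self.distances is not None:
            D = np.asarray(self.distances, dtype=float)
            if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
                raise ValueError("distances must be symmetric, non-negative, zero-diagonal")
            self.distances = D
        if self.labels is not None and len(self.labels) != self.n_nodes:
            raise ValueError("labels length must equal node count")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)

    def edge_list(self) -> np.ndarray:
        """Unordered edges as an (E, 2) array with i < j."""
        iu, ju = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([iu, ju])


@dataclass
class DelayMatrix:
    """Pairwise conduction delays in seconds.

    ``mode`` records how the delays were built: an identical value on every
    edge (``constant``) or distance divided by a propagation speed
    (``distance``, ``speed`` in m/s).
    """

    values: np.ndarray
    mode: str
    speed: float | None = None

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if not np.allclose(V, V.T) or np.any(np.diag(V) != 0) or np.any(V < 0):
            raise ValueError("delays must be symmetric, non-negative, zero-diagonal")
        self.values = V
        if np.any(V > QUARTER_CYCLE_10HZ_S):
            warnings.warn(
                "some delays exceed a quarter cycle at 10 Hz (25 ms); the "
                "hub phase-lag pattern is only guaranteed for shorter delays",
                UserWarning,
                stacklevel=2,
            )


def generate_random_gilbert(
    n: int, epsilon: float = 0.1, seed: int | np.random.Generator | None = None
) -> Network:
    """Connected Gilbert random graph G(n, p) with p = (1+epsilon)·ln(n)/n.

    The edge probability sits just above the connectivity threshold
    ln(n)/n; draws are repeated until a connected graph appears.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    p = (1.0 + epsilon) * math.log(n) / n
    if p >= 1:
        raise ValueError(f"edge probability {p:.3f} >= 1; reduce epsilon or increase n")
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_RESAMPLE):
        upper = rng.random((n, n)) < p
        A = np.triu(upper, 1)
        A = (A | A.T).astype(np.int8)
        net = Network(A)
        if net.is_connected():
            return net
    raise GenerationError(f"no connected G({n}, {p:.3g}) draw in {_MAX_RESAMPLE} tries")


def _sample_powerlaw_degrees(
    n: int,
    exponent: float,
    rng: np.random.Generator,
    cutoff_scale: float | None = None,
    require_connectable: bool = True,
) -> np.ndarray:
    """Degree sequence from P(k) ∝ k^(−exponent)·exp(−k/cutoff_scale).

    Support is k = 1 … ⌊√n⌋ (the structural cutoff keeping stub matching
    uncorrelated).  With ``require_connectable`` the whole sequence is
    redrawn until its sum is even and at least 2(n−1) — the conditioning
    implied by demanding connected realizations, since a graph with fewer
    than n−1 edges cannot be connected.  An odd-sum sequence has one
    entry redrawn.
    """
    kmax = int(math.isqrt(n))
    ks = np.arange(1, kmax + 1)
    pmf = ks.astype(float) ** (-exponent)
    if cutoff_scale is not None:
        pmf *= np.exp(-ks / cutoff_scale)
    pmf /= pmf.sum()
    max_draws = 5000 if require_connectable else 1
    for _ in range(max_draws):
        degrees = rng.choice(ks, size=n, p=pmf)
        if require_connectable and degrees.sum() < 2 * (n - 1):
            continue
        while degrees.sum() % 2 != 0:
            degrees[rng.integers(n)] = rng.choice(ks, p=pmf)
        if not require_connectable or degrees.sum() >= 2 * (n - 1):
            return degrees
    raise GenerationError(
        f"no connectable degree sequence (n={n}, exponent={exponent}) "
        f"in {max_draws} draws"
    )


def _stub_match(degrees: np.ndarray, rng: np.random.Generator, tries: int = 200) -> np.ndarray | None:
    """Uniform simple-graph realization of a degree sequence by stub matching.

    Pairings containing a self-loop or multi-edge are rejected wholesale,
    which is what keeps the sampled ensemble uncorrelated.  Returns the
    adjacency or None when every attempt was rejected.
    """
    n = len(degrees)
    stubs = np.repeat(np.arange(n), degrees)
    for _ in range(tries):
        rng.shuffle(stubs)
        a, b = stubs[0::2], stubs[1::2]
        if np.any(a == b):
            continue
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        keys = lo.astype(np.int64) * n + hi
        if len(np.unique(keys)) != len(keys):
            continue
        A = np.zeros((n, n), dtype=np.int8)
        A[a, b] = 1
        A[b, a] = 1
        return A
    return None


def _connect_components(A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Merge disconnected components by degree-preserving edge swaps.

    Each step removes a non-bridge edge (u,v) and an edge (x,y) from a
    different component, then adds (u,x) and (v,y).  Degrees are
    unchanged, no self-loop or multi-edge can appear (the endpoints lie
    in disjoint components), and because (u,v) sat on a cycle the swap is
    guaranteed to reduce the component count by one.  A disconnected
    graph with at least n−1 edges always owns a non-bridge edge, so the
    procedure terminates; fewer edges cannot be made connected at all.
    """
    from scipy.sparse.csgraph import connected_components

    A = A.copy()
    n = A.shape[0]
    if A.sum() // 2 < n - 1:
        raise GenerationError("degree sequence has too few edges to be connected")
    while True:
        ncomp, labels = connected_components(A, directed=False)
        if ncomp == 1:
            return A
        G = nx.from_numpy_array(A)
        bridges = set(frozenset(e) for e in nx.bridges(G))
        iu, ju = np.nonzero(np.triu(A, 1))
        non_bridge = np.array(
            [frozenset((int(a), int(b))) not in bridges for a, b in zip(iu, ju)]
        )
        ea = rng.choice(np.flatnonzero(non_bridge))
        u, v = int(iu[ea]), int(ju[ea])
        other = np.flatnonzero(labels[iu] != labels[u])
        eb = rng.choice(other)
        x, y = int(iu[eb]), int(ju[eb])
        A[u, v] = A[v, u] = 0
        A[x, y] = A[y, x] = 0
        A[u, x] = A[x, u] = 1
        A[v, y] = A[y, v] = 1


def generate_scale_free_catanzaro(
    n: int, exponent: float = 2.2, seed: int | np.random.Generator | None = None
) -> Network:
    """Connected scale-free graph via the uncorrelated configuration model.

    Node degrees are drawn from P(k) ∝ k^(−exponent) with minimum degree 1
    and structural cutoff ⌊√n⌋, then stub-matched with rejection of
    self-loops and multi-edges.  A disconnected realization (the rule, not
    the exception, when most nodes have degree 1) is made connected by
    degree-preserving cross-rewiring of component edges, which leaves the
    degree sequence untouched.  For very steep exponents no degree
    sequence can be connected at all (almost every node draws degree 1);
    there the sequence is used as drawn and the minimum number of extra
    bridging edges is added to join the components.
    """
    if n < 10:
        raise ValueError("need at least 10 nodes")
    if exponent <= 2:
        raise ValueError("exponent must exceed 2 (uncorrelated regime)")
    rng = np.random.default_rng(seed)
    try:
        sampler_kw = {"require_connectable": True}
        _sample_powerlaw_degrees(n, exponent, np.random.default_rng(rng.integers(2**31)), **sampler_kw)
    except GenerationError:
        sampler_kw = {"require_connectable": False}
    for _ in range(_MAX_RESAMPLE):
        degrees = _sample_powerlaw_degrees(n, exponent, rng, **sampler_kw)
        A = _stub_match(degrees, rng)
        if A is None:
            continue
        if sampler_kw["require_connectable"]:
            return Network(_connect_components(A, rng))
        return Network(_bridge_components(A, rng))
    raise GenerationError(
        f"could not realize a scale-free graph (n={n}, exponent={exponent}) "
        f"in {_MAX_RESAMPLE} attempts"
    )


def _bridge_components(A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Join components by adding one edge between consecutive components.

    Used only when the degree sequence cannot support a connected graph;
    adds the minimum number of edges (component count − 1), each incident
    to a random node of its component.
    """
    from scipy.sparse.csgraph import connected_components

    A = A.copy()
    ncomp, labels = connected_components(A, directed=False)
    if ncomp == 1:
        return A
    reps = [rng.choice(np.flatnonzero(labels == c)) for c in range(ncomp)]
    rng.shuffle(reps)
    for a, b in zip(reps[:-1], reps[1:]):
        A[a, b] = A[b, a] = 1
    return A


def classify_nodes(
    net: Network,
    hub_rule: str = "mean_plus_sd",
    peripheral_rule: str = "degree_one",
) -> tuple[np.ndarray, np.ndarray]:
    """Split nodes into hubs and peripherals by degree.

    Hubs are nodes with degree strictly above mean+sd of the degree
    distribution.  Peripherals are either the degree-1 nodes
    (``degree_one``, natural for scale-free graphs) or nodes strictly
    below mean−sd (``mean_minus_sd``).  Returns two index arrays.
    """
    if hub_rule != "mean_plus_sd":
        raise ValueError(f"unknown hub rule {hub_rule!r}")
    k = net.degrees
    mu, sd = k.mean(), k.std()
    if sd == 0:
        warnings.warn("all degrees equal; hub set is empty", UserWarning, stacklevel=2)
    hubs = np.flatnonzero(k > mu + sd)
    if peripheral_rule == "degree_one":
        peripherals = np.flatnonzero(k == 1)
    elif peripheral_rule == "mean_minus_sd":
        peripherals = np.flatnonzero(k < mu - sd)
    else:
        raise ValueError(f"unknown peripheral rule {peripheral_rule!r}")
    return hubs, peripherals


def build_delay_matrix(net: Network, mode: str, value: float) -> DelayMatrix:
    """Conduction delays per edge.

    ``constant`` puts ``value`` seconds on every edge; ``distance`` divides
    the network's distance matrix (mm) by ``value`` m/s.  Either way
    non-edges carry zero delay (they are never read by the simulator).
    """
    if mode == "constant":
        if value < 0:
            raise ValueError("delay must be non-negative")
        V = net.adjacency.astype(float) * value
        return DelayMatrix(V, mode="constant")
    if mode == "distance":
        if net.distances is None:
            raise ValueError("distance mode requires network distances")
        if value <= 0:
            raise ValueError("propagation speed must be positive")
        # mm / (m/s) = ms / 1000 → seconds
        V = net.adjacency * net.distances / value / 1000.0
        return DelayMatrix(V, mode="distance", speed=value)
    raise ValueError(f"unknown delay mode {mode!r}")


# ---------------------------------------------------------------------------
# plain-text I/O

def save_network(net: Network, path: str | Path, coords_path: str | Path | None = None) -> None:
    """Write adjacency as CSV (header = labels when present); coordinates
    optionally to a sidecar ``id,x,y,z`` CSV."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    lines = []
    if net.labels is not None:
        lines.append(delim.join(net.labels))
    for row in net.adjacency:
        lines.append(delim.join(str(int(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")
    if coords_path is not None:
        if net.coordinates is None:
            raise ValueError("network has no coordinates to save")
        cp = Path(coords_path)
        rows = ["id,x,y,z"]
        for i, (x, y, z) in enumerate(net.coordinates):
            rows.append(f"{i},{float(x)!r},{float(y)!r},{float(z)!r}")
        cp.write_text("\n".join(rows) + "\n")


def load_network(path: str | Path, coords_path: str | Path | None = None) -> Network:
    """Read a network from a square adjacency CSV/TSV or a 2/3-column edge
    list with 0-based integer ids; optional ``id,x,y,z`` coordinates sidecar."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path} is empty")
    lines = text.splitlines()
    delim = "\t" if "\t" in lines[0] else ("," if "," in lines[0] else None)
    labels: list[str] | None = None
    first = lines[0].split(delim)
    header = not all(_is_number(tok) for tok in first)
    rows = lines[1:] if header else lines
    if header:
        labels = [tok.strip() for tok in first]
    table = [[float(tok) for tok in ln.split(delim)] for ln in rows if ln.strip()]
    width = len(table[0])
    if any(len(r) != width for r in table):
        raise ValueError(f"{path}: ragged rows")
    arr = np.asarray(table)
    # square binary matrices are read as adjacency; anything else with <= 3
    # columns as an edge list (ambiguous 3x3 cases resolve to adjacency)
    looks_adjacency = (
        arr.shape[0] == arr.shape[1]
        and np.isin(arr, (0, 1)).all()
        and np.array_equal(arr, arr.T)
        and not np.any(np.diag(arr))
    )
    if looks_adjacency or header or width > 3:
        if arr.shape[0] != arr.shape[1]:
            raise ValueError(f"{path}: adjacency matrix is not square")
        if not np.array_equal(arr, arr.T):
            raise ValueError(f"{path}: adjacency matrix is not symmetric")
        if np.any(np.diag(arr) != 0):
            raise ValueError(f"{path}: adjacency diagonal must be zero")
        A = arr.astype(np.int8)
    else:
        # edge list: first two columns are node ids (third, if any, ignored)
        edges = arr[:, :2].astype(int)
        n = int(edges.max()) + 1
        A = np.zeros((n, n), dtype=np.int8)
        A[edges[:, 0], edges[:, 1]] = 1
        A[edges[:, 1], edges[:, 0]] = 1
        A[np.diag_indices(n)] = 0
        labels = None
    coords = None
    if coords_path is not None:
        ct = Path(coords_path).read_text().strip().splitlines()
        body = ct[1:] if not _is_number(ct[0].split(",")[0]) else ct
        crows = sorted(
            ([float(t) for t in ln.split(",")] for ln in body if ln.strip()),
            key=lambda r: r[0],
        )
        coords = np.asarray([r[1:4] for r in crows])
    return Network(A, coordinates=coords, labels=labels)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
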