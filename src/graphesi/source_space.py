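"""Source spaces, mesh adjacency, and analytic spherical lead fields.

The candidate sources of distributed EEG source imaging live on a
triangulated mesh; here the mesh is an icosphere, a geodesic sphere obtained
by recursive 4-to-1 subdivision of the icosahedron.  Each vertex is one
candidate source with a fixed outward (radial) dipole orientation.  The
forward operator uses the closed-form surface potential of a current dipole
inside a homogeneous conducting sphere, which keeps the whole pipeline
analytic and dependency-free while preserving the structure of the inverse
problem (an underdetermined linear map from m sources to n electrodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SourceSpace",
    "SourceGraph",
    "LeadField",
    "build_icosphere_source_space",
    "adjacency_from_mesh",
    "synthesize_lead_field",
    "sphere_dipole_potential",
    "fibonacci_electrodes",
]

#: refuse to build source spaces larger than this (dense eigendecomposition
#: of the graph Laplacian is the downstream consumer)
MAX_SOURCES = 50_000

#: brain conductivity, S/m — the conventional value for a homogeneous head
DEFAULT_CONDUCTIVITY = 0.33


@dataclass
class SourceSpace:
    """Triangulated mesh of candidate source locations (positions in mm)."""

    positions: np.ndarray  # (m, 3) float, mm
    triangles: np.ndarray  # (n_tri, 3) int, 0-based vertex indices

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (m, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (n_tri, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        m = self.positions.shape[0]
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= m
        ):
            raise ValueError("triangle indices out of range [0, m)")

    @property
    def m(self) -> int:
        return self.positions.shape[0]


@dataclass
class SourceGraph:
    """Undirected, binary-weighted neighborhood graph on the source mesh."""

    adjacency: np.ndarray  # (m, m), symmetric, zero diagonal
    neighbor_order: int = 1

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(a < 0):
            raise ValueError("adjacency weights must be nonnegative")
        self.adjacency = a

    @property
    def m(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        """Indices of vertices adjacent to vertex ``i``."""
        return np.flatnonzero(self.adjacency[i] > 0)


@dataclass
class LeadField:
    """Linear forward operator: gain[e, s] = potential at electrode e per
    unit dipole moment at source s."""

    gain: np.ndarray  # (n, m)
    electrode_positions: np.ndarray  # (n, 3), mm

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.electrode_positions = np.asarray(self.electrode_positions, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("gain must be 2-D")
        if self.electrode_positions.shape != (self.gain.shape[0], 3):
            raise ValueError("electrode_positions must be (n, 3)")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain must be finite")
        if np.any(np.all(self.gain == 0, axis=0)):
            raise ValueError("gain has an all-zero column (unobservable source)")

    @property
    def n(self) -> int:
        return self.gain.shape[0]

    @property
    def m(self) -> int:
        return self.gain.shape[1]


def build_icosphere_source_space(
    subdivisions: int, radius_mm: float = 80.0
) -> SourceSpace:
    """Build an icosphere source space with ``10 * 4**subdivisions + 2``
    vertices, all at ``radius_mm`` from the origin.

    Parameters
    ----------
    subdivisions : int
        Number of recursive 4-to-1 triangle subdivisions of the icosahedron.
    radius_mm : float
        Sphere radius in millimetres.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    n_vertices = 10 * 4**subdivisions + 2
    if n_vertices > MAX_SOURCES:
        raise ValueError(
            f"subdivisions={subdivisions} would produce {n_vertices} sources, "
            f"above the cap of {MAX_SOURCES}; use fewer subdivisions"
        )
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    positions = np.asarray(mesh.vertices, dtype=float)
    # trimesh subdivides then reprojects; enforce exact radius to tolerance
    positions *= radius_mm / np.linalg.norm(positions, axis=1, keepdims=True)
    return SourceSpace(positions=positions, triangles=np.asarray(mesh.faces))


def adjacency_from_mesh(
    space: SourceSpace, neighbor_order: int = 1, weighting: str = "binary"
) -> SourceGraph:
    """Adjacency from shared mesh edges.

    ``neighbor_order=1`` connects vertices sharing an edge;
    ``neighbor_order=2`` additionally connects vertices reachable in two
    edges.  ``weighting="binary"`` (default) sets all weights to 1;
    ``"inverse_distance"`` weights each connection by 1/distance (mm).
    """
    if neighbor_order not in (1, 2):
        raise ValueError("neighbor_order must be 1 or 2")
    if weighting not in ("binary", "inverse_distance"):
        raise ValueError("weighting must be 'binary' or 'inverse_distance'")
    m = space.m
    a1 = np.zeros((m, m), dtype=float)
    tri = space.triangles
    for u, v in ((0, 1), (1, 2), (2, 0)):
        a1[tri[:, u], tri[:, v]] = 1.0
        a1[tri[:, v], tri[:, u]] = 1.0
    np.fill_diagonal(a1, 0.0)
    n_comp, _ = connected_components(csr_matrix(a1), directed=False)
    if n_comp != 1:
        raise ValueError(
            f"mesh has {n_comp} connected components; the Laplacian spectral "
            "basis requires a single component"
        )
    if neighbor_order == 1:
        adj = a1
    else:
        # two-hop reachability (boolean), minus self loops
        adj = ((a1 @ a1 > 0) | (a1 > 0)).astype(float)
        np.fill_diagonal(adj, 0.0)
    if weighting == "inverse_distance":
        diff = space.positions[:, None, :] - space.positions[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        with np.errstate(divide="ignore"):
            adj = np.where(adj > 0, 1.0 / dist, 0.0)
    return SourceGraph(adjacency=adj, neighbor_order=neighbor_order)


def sphere_dipole_potential(
    electrode_positions: np.ndarray,
    source_positions: np.ndarray,
    scalp_radius_mm: float,
    conductivity: float = DEFAULT_CONDUCTIVITY,
) -> np.ndarray:
    """Surface potential of unit radial current dipoles inside a homogeneous
    conducting sphere.

    For a radial dipole at eccentricity ``f = a / R`` (source radius ``a``,
    scalp radius ``R``) and angle ``gamma`` to the electrode, summing the
    Legendre series for an insulated sphere boundary gives the closed form

        V = q / (4 pi sigma R^2 f) * (2 f (x - f) / g^3 + 1/g - 1)

    with ``x = cos(gamma)`` and ``g = sqrt(1 - 2 f x + f^2)``.  At ``f -> 0``
    this reduces to the central-dipole potential ``3 q cos(gamma) /
    (4 pi sigma R^2)``.

    Returns the (n_electrodes, n_sources) potential matrix, volts per
    (A*mm) of dipole moment when positions are in mm and conductivity in S/m
    (absolute units are immaterial downstream; the map is linear).
    """
    elec = np.asarray(electrode_positions, dtype=float)
    src = np.asarray(source_positions, dtype=float)
    big_r = float(scalp_radius_mm)
    a = np.linalg.norm(src, axis=1)  # (m,)
    if np.any(a >= big_r):
        raise ValueError("source radius must be strictly inside the scalp radius")
    f = a / big_r  # (m,)
    # cos(gamma) between each electrode direction and each source direction
    e_hat = elec / np.linalg.norm(elec, axis=1, keepdims=True)
    s_hat = src / a[:, None]
    x = np.clip(e_hat @ s_hat.T, -1.0, 1.0)  # (n, m)
    g = np.sqrt(1.0 - 2.0 * f[None, :] * x + f[None, :] ** 2)
    series = 2.0 * f[None, :] * (x - f[None, :]) / g**3 + 1.0 / g - 1.0
    scale = 1.0 / (4.0 * np.pi * conductivity * big_r**2)
    with np.errstate(invalid="ignore"):
        v = scale * series / f[None, :]
    # central dipole limit for f == 0
    if np.any(f == 0):
        v[:, f == 0] = scale * 3.0 * x[:, f == 0]
    return v


def fibonacci_electrodes(
    n_electrodes: int, scalp_radius_mm: float, seed: int = 0
) -> np.ndarray:
    """Quasi-uniform electrode positions on the upper hemisphere
    (z >= 0), via a Fibonacci lattice with a seeded azimuthal rotation."""
    if n_electrodes < 4:
        raise ValueError("need at least 4 electrodes")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    i = np.arange(n_electrodes)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    # z spread over the upper hemisphere only
    z = 1.0 - (i + 0.5) / n_electrodes  # in (0, 1)
    theta = 2.0 * np.pi * i / golden + phase
    rho = np.sqrt(1.0 - z**2)
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return scalp_radius_mm * pts


def synthesize_lead_field(
    space: SourceSpace,
    n_electrodes: int,
    scalp_radius_mm: float = 100.0,
    seed: int = 0,
    conductivity: float = DEFAULT_CONDUCTIVITY,
) -> LeadField:
    """Analytic lead field: radial unit dipoles at each source vertex,
    homogeneous-sphere potentials at seeded quasi-uniform scalp electrodes,
    each column average-referenced (zero mean over electrodes)."""
    max_src_radius = np.linalg.norm(space.positions, axis=1).max()
    if max_src_radius >= scalp_radius_mm:
        raise ValueError(
            f"source radius {max_src_radius:.1f} mm must be strictly inside "
            f"the scalp radius {scalp_radius_mm:.1f} mm"
        )
    elec = fibonacci_electrodes(n_electrodes, scalp_radius_mm, seed=seed)
    gain = sphere_dipole_potential(
        elec, space.positions, scalp_radius_mm, conductivity=conductivity
    )
    gain = gain - gain.mean(axis=0, keepdims=True)  # average reference
    return LeadField(gain=gain, electrode_positions=elec)
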