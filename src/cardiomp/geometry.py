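"""Idealized Purkinje conduction tree and rule-based fiber architecture.

The conduction tree is laid out in a simplified material frame on a truncated
ellipsoidal chamber surface built from the published chamber dimensions
(apicobasal extent 3.6 cm, equatorial radius 2.4 cm): two bundle branches
enter at the septal base, the left splitting into three minor bundles and the
right into anterior and posterior minors, each descending apicobasally and
emitting circumferential branches every centimetre whose endpoints are the
Purkinje-myocyte junctions (PMJs).  Fiber radius tapers linearly in path
length from 500 um at the bundle origin to 50 um at every PMJ.

Fiber fields on tissue grids rotate linearly from +60 deg at the endocardium
to -60 deg at the epicardium; conductivity tensors are assembled from the
local orthonormal triad as sigma = sf F@F + ss S@S + sn N@N.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dfield

import numpy as np
import networkx as nx

__all__ = [
    "TreeSpec",
    "PurkinjeTree",
    "build_purkinje_tree",
    "FiberField",
    "build_fiber_field",
    "conductivity_tensor",
    "TissueGrid",
    "build_tissue_grid",
]


# ---------------------------------------------------------------------------
# Purkinje tree


@dataclass
class TreeSpec:
    """Generator parameters for the idealized Purkinje tree.

    Bundle layout angles are exposed because the source figure gives them
    only graphically; defaults place the left minors around the septum at
    150/180/210 deg and the right anterior/posterior minors at +-45 deg from
    the septal entry.
    """

    apicobasal_extent: float = 3.6      # cm, base (z=0) to apex
    equatorial_radius: float = 2.4      # cm, chamber radius at the base
    branch_spacing: float = 1.0         # cm between circumferential levels
    n_left_minor: int = 3
    n_right_minor: int = 2
    r_max: float = 500.0                # um at the bundle origin
    r_min: float = 50.0                 # um at every PMJ
    trunk_length: float = 0.5           # cm of common bundle before the split
    fan_length: float = 1.0             # cm of descent over which minors fan out
    span_deg: float = 72.0              # circumferential span per minor bundle
    left_angles_deg: tuple = (150.0, 180.0, 210.0)
    right_angles_deg: tuple = (135.0, 225.0)
    septal_angle_deg: float = 180.0
    ds: float = 0.05                    # cm sampling step along branches

    def __post_init__(self):
        if self.branch_spacing <= 0:
            raise ValueError("branch_spacing must be positive")
        if not self.r_max > self.r_min > 0:
            raise ValueError("require r_max > r_min > 0")
        if len(self.left_angles_deg) != self.n_left_minor:
            raise ValueError("left_angles_deg must list n_left_minor angles")
        if len(self.right_angles_deg) != self.n_right_minor:
            raise ValueError("right_angles_deg must list n_right_minor angles")


class PurkinjeTree:
    """Rooted forest of 1D fiber segments with per-node radius.

    Thin wrapper over a networkx DiGraph (edges parent -> child).  Node
    attributes: ``pos`` (cm, 3-vector), ``radius`` (um), ``path_len`` (cm
    from the root).  Edge attribute: ``length`` (cm).
    """

    def __init__(self, graph: nx.DiGraph, root_ids: list[int],
                 pmj_ids: list[int], spec: TreeSpec | None = None):
        self.graph = graph
        self.root_ids = list(root_ids)
        self.pmj_ids = list(pmj_ids)
        self.spec = spec
        self.pmj_cell_map: dict[int, int] = {}

    # -- accessors ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def positions(self) -> np.ndarray:
        return np.array([self.graph.nodes[i]["pos"] for i in sorted(self.graph)])

    def radii(self) -> np.ndarray:
        return np.array([self.graph.nodes[i]["radius"] for i in sorted(self.graph)])

    def path_lengths(self) -> np.ndarray:
        return np.array([self.graph.nodes[i]["path_len"] for i in sorted(self.graph)])

    def leaves(self) -> list[int]:
        return [n for n in self.graph if self.graph.out_degree(n) == 0]

    def validate(self) -> None:
        g = self.graph
        und = g.to_undirected()
        if len(list(nx.cycle_basis(und))) > 0:
            raise ValueError("tree contains cycles")
        for pmj in self.pmj_ids:
            if g.out_degree(pmj) != 0:
                raise ValueError(f"PMJ node {pmj} is not a leaf")
        for u, v in g.edges:
            if g.nodes[v]["radius"] > g.nodes[u]["radius"] + 1e-9:
                raise ValueError("radius increases along a root-to-leaf path")
        for n in g:
            if g.nodes[n]["radius"] <= 0:
                raise ValueError("non-positive radius")

    def map_pmjs_to_grid(self, grid: "TissueGrid") -> dict[int, int]:
        """Nearest grid cell by Euclidean distance in material coordinates;
        ties broken by lowest flat cell index."""
        centers = grid.cell_centers().reshape(-1, grid.ndim)
        mapping = {}
        for pmj in self.pmj_ids:
            p = np.asarray(self.graph.nodes[pmj]["pos"])[: grid.ndim]
            d2 = np.sum((centers - p) ** 2, axis=1)
            mapping[pmj] = int(np.argmin(d2))  # argmin takes the lowest index on ties
        self.pmj_cell_map = mapping
        return mapping

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        g = self.graph
        payload = {
            "units": {"pos": "cm", "radius": "um", "length": "cm"},
            "nodes": [
                {
                    "id": int(n),
                    "pos": [float(x) for x in g.nodes[n]["pos"]],
                    "radius": float(g.nodes[n]["radius"]),
                    "path_len": float(g.nodes[n]["path_len"]),
                    "pmj": bool(n in set(self.pmj_ids)),
                }
                for n in sorted(g)
            ],
            "edges": [
                {"u": int(u), "v": int(v), "length": float(g.edges[u, v]["length"])}
                for u, v in g.edges
            ],
            "root_ids": [int(r) for r in self.root_ids],
            "pmj_cell_map": {str(k): int(v) for k, v in self.pmj_cell_map.items()},
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PurkinjeTree":
        payload = json.loads(text)
        g = nx.DiGraph()
        pmj_ids = []
        for nd in payload["nodes"]:
            g.add_node(nd["id"], pos=np.array(nd["pos"]),
                       radius=nd["radius"], path_len=nd["path_len"])
            if nd["pmj"]:
                pmj_ids.append(nd["id"])
        for ed in payload["edges"]:
            g.add_edge(ed["u"], ed["v"], length=ed["length"])
        tree = cls(g, payload["root_ids"], pmj_ids)
        tree.pmj_cell_map = {int(k): v for k, v in
                             payload.get("pmj_cell_map", {}).items()}
        return tree

    def to_graphml(self, path: str) -> None:
        g = nx.DiGraph()
        for n in self.graph:
            d = self.graph.nodes[n]
            g.add_node(n, x=float(d["pos"][0]), y=float(d["pos"][1]),
                       z=float(d["pos"][2]), radius_um=float(d["radius"]),
                       pmj=bool(n in set(self.pmj_ids)))
        for u, v in self.graph.edges:
            g.add_edge(u, v, length_cm=float(self.graph.edges[u, v]["length"]))
        nx.write_graphml(g, path)


class _TreeBuilder:
    def __init__(self, spec: TreeSpec):
        self.spec = spec
        self.g = nx.DiGraph()
        self._next = 0

    def surface_point(self, theta_deg: float, z: float) -> np.ndarray:
        s = self.spec
        frac = min(z / s.apicobasal_extent, 1.0)
        R = s.equatorial_radius * math.sqrt(max(1.0 - frac ** 2, 0.0))
        th = math.radians(theta_deg)
        return np.array([R * math.cos(th), R * math.sin(th), -z])

    def add_node(self, pos: np.ndarray, parent: int | None) -> int:
        nid = self._next
        self._next += 1
        if parent is None:
            plen = 0.0
        else:
            seg = float(np.linalg.norm(pos - self.g.nodes[parent]["pos"]))
            plen = self.g.nodes[parent]["path_len"] + seg
        self.g.add_node(nid, pos=pos, radius=0.0, path_len=plen)
        if parent is not None:
            seg = plen - self.g.nodes[parent]["path_len"]
            self.g.add_edge(parent, nid, length=seg)
        return nid

    def polyline(self, parent: int, points: list[np.ndarray]) -> int:
        """Append a chain of nodes subdividing each leg to <= spec.ds."""
        cur = parent
        for target in points:
            p0 = self.g.nodes[cur]["pos"]
            seg = float(np.linalg.norm(target - p0))
            nsub = max(1, int(math.ceil(seg / self.spec.ds)))
            for k in range(1, nsub + 1):
                cur = self.add_node(p0 + (target - p0) * (k / nsub), cur)
        return cur

    def descend(self, parent: int, theta0: float, theta1: float,
                z0: float, z1: float, n: int | None = None) -> int:
        """Path on the chamber surface, theta and z interpolated linearly."""
        if n is None:
            n = max(2, int(math.ceil(abs(z1 - z0) / self.spec.ds)) + 1)
        pts = [self.surface_point(theta0 + (theta1 - theta0) * k / n,
                                  z0 + (z1 - z0) * k / n)
               for k in range(1, n + 1)]
        return self.polyline(parent, pts)

    def arc(self, parent: int, theta0: float, dtheta: float, z: float) -> int:
        n = max(2, int(math.ceil(abs(math.radians(dtheta))
                                 * self._radius_at(z) / self.spec.ds)))
        pts = [self.surface_point(theta0 + dtheta * k / n, z)
               for k in range(1, n + 1)]
        return self.polyline(parent, pts)

    def _radius_at(self, z: float) -> float:
        s = self.spec
        frac = min(z / s.apicobasal_extent, 1.0)
        return max(s.equatorial_radius * math.sqrt(max(1.0 - frac ** 2, 0.0)), 0.1)


def build_purkinje_tree(spec: TreeSpec | None = None) -> PurkinjeTree:
    """Generate the idealized two-bundle Purkinje tree.

    Raises ValueError when branch_spacing exceeds the apicobasal extent (the
    spacing rule would emit no PMJ branches at all).
    """
    spec = spec or TreeSpec()
    if spec.branch_spacing > spec.apicobasal_extent:
        raise ValueError(
            "branch_spacing exceeds the apicobasal extent: no PMJ branches "
            "would be generated")

    b = _TreeBuilder(spec)
    levels = []
    z = spec.branch_spacing
    while z <= spec.apicobasal_extent + 1e-9:
        levels.append(min(z, spec.apicobasal_extent))
        z += spec.branch_spacing

    z_fan = min(spec.trunk_length + spec.fan_length, spec.apicobasal_extent)

    roots, pmjs = [], []
    for angles in (spec.left_angles_deg, spec.right_angles_deg):
        root = b.add_node(b.surface_point(spec.septal_angle_deg, 0.0), None)
        roots.append(root)
        split = b.descend(root, spec.septal_angle_deg, spec.septal_angle_deg,
                          0.0, spec.trunk_length)
        for theta in angles:
            # minors fan from the septal entry to their bundle angle over the
            # first fan_length of descent, then run straight apicobasally
            def theta_of(zz: float) -> float:
                frac = (zz - spec.trunk_length) / max(z_fan - spec.trunk_length, 1e-9)
                frac = min(max(frac, 0.0), 1.0)
                return spec.septal_angle_deg + (theta - spec.septal_angle_deg) * frac

            cur = split
            z_prev = spec.trunk_length
            for z_lvl in levels:
                if z_lvl <= z_prev + 1e-9:
                    continue
                # split the descent at the fan end so theta stays piecewise
                # linear in z
                for z_next in sorted({min(max(z_fan, z_prev), z_lvl), z_lvl}):
                    if z_next > z_prev + 1e-9:
                        cur = b.descend(cur, theta_of(z_prev), theta_of(z_next),
                                        z_prev, z_next)
                        z_prev = z_next
                for sign in (+1.0, -1.0):
                    tip = b.arc(cur, theta_of(z_lvl), sign * spec.span_deg / 2.0,
                                z_lvl)
                    pmjs.append(tip)

    _assign_taper(b.g, roots, spec)
    tree = PurkinjeTree(b.g, roots, pmjs, spec)
    tree.validate()
    return tree


def _assign_taper(g: nx.DiGraph, roots: list[int], spec: TreeSpec) -> None:
    """Linear radius taper in path length; a shared node takes the taper of
    the deepest leaf below it, so every leaf ends exactly at r_min and radius
    is non-increasing along every path."""
    deepest = {}

    def walk(n: int) -> float:
        children = list(g.successors(n))
        if not children:
            deepest[n] = g.nodes[n]["path_len"]
        else:
            deepest[n] = max(walk(c) for c in children)
        return deepest[n]

    for r in roots:
        walk(r)
    for n in g:
        L, M = g.nodes[n]["path_len"], deepest[n]
        frac = 0.0 if M <= 0 else L / M
        g.nodes[n]["radius"] = spec.r_max + (spec.r_min - spec.r_max) * frac


# ---------------------------------------------------------------------------
# fiber fields and conductivity


@dataclass
class FiberField:
    """Per-cell orthonormal triads and transmural metadata on a regular grid.

    ``F``, ``S``, ``N`` have shape ``grid_shape + (ndim,)``; for 2D grids the
    normal direction is dropped (reduced triad) and ``N`` is None.
    """

    shape: tuple
    transmural_axis: int
    angle_deg: np.ndarray
    transmural_coord: np.ndarray
    F: np.ndarray
    S: np.ndarray
    N: np.ndarray | None
    isotropic_mask: np.ndarray | None = None

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def to_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name, arr in (("F", self.F), ("S", self.S), ("N", self.N),
                              ("angle_deg", self.angle_deg),
                              ("transmural_coord", self.transmural_coord)):
                if arr is None:
                    continue
                d = f.create_dataset(name, data=arr)
                d.attrs["units"] = "deg" if name == "angle_deg" else "1"
            if self.isotropic_mask is not None:
                f.create_dataset("isotropic_mask",
                                 data=self.isotropic_mask.astype(np.uint8))
            f.attrs["transmural_axis"] = self.transmural_axis


def build_fiber_field(grid_shape: tuple, transmural_axis: int = 0,
                      isotropic_mask: np.ndarray | None = None) -> FiberField:
    """Rule-based fiber architecture: helix angle +60 deg at the endocardium
    (transmural coordinate 0) rotating linearly to -60 deg at the epicardium.

    The fiber lies in the plane orthogonal to the transmural axis; the sheet
    axis is transmural (sheets perpendicular to the endo/epicardial
    surfaces); the normal completes the right-handed triad.  2D grids carry
    the reduced in-plane triad.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    ndim = len(grid_shape)
    if ndim not in (2, 3):
        raise ValueError("grid must be 2D or 3D")
    if not 0 <= transmural_axis < ndim:
        raise ValueError("degenerate transmural axis")
    n_tm = grid_shape[transmural_axis]
    if n_tm < 2:
        raise ValueError("need >= 2 cells along the transmural axis")

    coord_1d = np.linspace(0.0, 1.0, n_tm)
    shape_ones = [1] * ndim
    shape_ones[transmural_axis] = n_tm
    coord = np.broadcast_to(coord_1d.reshape(shape_ones), grid_shape).copy()
    angle = 60.0 - 120.0 * coord
    rad = np.radians(angle)

    # in-plane axes: the two non-transmural directions (circumferential,
    # apicobasal) for 3D; the single remaining direction for 2D.
    axes = [i for i in range(ndim) if i != transmural_axis]
    F = np.zeros(grid_shape + (ndim,))
    S = np.zeros(grid_shape + (ndim,))
    S[..., transmural_axis] = 1.0
    if ndim == 3:
        circ, apic = axes
        F[..., circ] = np.cos(rad)
        F[..., apic] = np.sin(rad)
        N = np.cross(F, S)
        nrm = np.linalg.norm(N, axis=-1, keepdims=True)
        N = N / nrm
    else:
        # reduced triad: fiber projected in-plane, unit length
        (inplane,) = axes
        F[..., inplane] = 1.0
        N = None

    return FiberField(shape=grid_shape, transmural_axis=transmural_axis,
                      angle_deg=angle, transmural_coord=coord,
                      F=F, S=S, N=N, isotropic_mask=isotropic_mask)


def conductivity_tensor(field: FiberField, sigma_f: float, sigma_s: float,
                        sigma_n: float | None = None) -> np.ndarray:
    """Per-cell conductivity tensor sigma = sf F@F + ss S@S + sn N@N
    (mS cm^-1).  Cells in the isotropic mask get sigma_f * I."""
    if sigma_n is None:
        sigma_n = sigma_s
    if not (sigma_f >= sigma_s >= sigma_n > 0):
        raise ValueError("require sigma_f >= sigma_s >= sigma_n > 0")
    outer = lambda v: np.einsum("...i,...j->...ij", v, v)
    sig = sigma_f * outer(field.F) + sigma_s * outer(field.S)
    if field.N is not None:
        sig = sig + sigma_n * outer(field.N)
    if field.isotropic_mask is not None:
        eye = np.eye(field.ndim)
        sig[field.isotropic_mask] = sigma_f * eye
    return sig


@dataclass
class TissueGrid:
    """Regular material-frame grid carrying fibers and conductivities."""

    shape: tuple
    spacing: float                      # cm, isotropic
    field: FiberField
    sigma: np.ndarray                   # shape + (ndim, ndim), mS/cm
    a_map: np.ndarray | None = None     # per-cell excitation threshold

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def cell_centers(self) -> np.ndarray:
        axes = [(np.arange(s) + 0.5) * self.spacing for s in self.shape]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)

    def sigma_to_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("sigma", data=self.sigma)
            d.attrs["units"] = "mS/cm"
            f.attrs["spacing_cm"] = self.spacing


def build_tissue_grid(shape: tuple, spacing: float, sigma_f: float,
                      sigma_s: float | None = None,
                      sigma_n: float | None = None,
                      transmural_axis: int = 0,
                      transmural_a: bool = False,
                      isotropic_mask: np.ndarray | None = None) -> TissueGrid:
    """Convenience constructor: fiber field + 4:2:1 conductivity by default
    and, optionally, the linear transmural excitation-threshold gradient."""
    from . import cell as _cell

    if sigma_s is None:
        sigma_s = sigma_f / 2.0
    if sigma_n is None:
        sigma_n = sigma_f / 4.0
    field = build_fiber_field(shape, transmural_axis, isotropic_mask)
    sigma = conductivity_tensor(field, sigma_f, sigma_s, sigma_n)
    a_map = _cell.transmural_a(field.transmural_coord) if transmural_a else None
    return TissueGrid(shape=tuple(shape), spacing=spacing, field=field,
                      sigma=sigma, a_map=a_map)
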