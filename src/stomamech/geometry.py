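"""Parametric guard-cell-pair geometry and surface meshing.

The stomatal complex is built as a deformed torus: two ellipses in the leaf
plane describe the complex outline (semi-axes a_s, b_s) and the pore
(a_p, b_p).  Each guard cell is the half of the torus on one side of the
long axis, a tube whose cross-section at torus angle phi is centered midway
between the outline and pore ellipses with radius equal to half their
separation; the tube is capped at both poles by flat polar walls shared by
the two cells.  Coordinates: long axis = x, transverse = y, out-of-plane =
z, origin at the complex centroid, lengths in micrometres.

Patches: ventral (pore-facing), dorsal (epidermis-facing), periclinal_outer
(+z), periclinal_inner (-z), polar_wall (the shared end disks).  Each
element carries a scalar wall thickness and a unit fiber direction (the
cellulose-microfibril hoop around the tube cross-section).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np

__all__ = [
    "GeometryParams",
    "SurfaceMesh",
    "build_geometry",
    "assign_fiber_field",
    "thickness_field",
    "InvalidGeometryError",
]

PATCHES = ("ventral", "dorsal", "periclinal_outer", "periclinal_inner",
           "polar_wall")
PATCH_ID = {name: i for i, name in enumerate(PATCHES)}


class InvalidGeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric parameters."""


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions and meshing controls of the stomatal complex.

    Defaults are calibration stand-ins for a Vicia-faba-like complex; they
    are config values, not measurements.
    """

    complex_length: float = 45.0   # um, long-axis extent (2 a_s)
    complex_width: float = 30.0    # um, transverse extent (2 b_s)
    pore_length0: float = 18.0     # um, undeformed pore long-axis extent
    pore_width0: float = 4.0       # um, undeformed pore width
    cross_section_kind: str = "circular"  # or "rounded_triangular"
    t_wall: float = 1.0            # um, wall thickness (dorsal/reference)
    t_pole: float = 0.3            # um, polar wall thickness
    m_v: float = 1.0               # ventral-patch thickness multiplier
    mesh_resolution: int = 20000   # target element count per guard cell
    ventral_thickness_ratio: float = 1.5  # rounded_triangular max/dorsal
    section_blend: float = 0.1     # three-lobed blend (rounded_triangular)
    z_flatten: float = 1.0         # out-of-plane flattening of the section

    def __post_init__(self):
        for name in ("complex_length", "complex_width", "pore_length0",
                     "pore_width0", "t_wall", "t_pole"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be > 0")
        if self.m_v <= 0:
            raise InvalidGeometryError("m_v must be > 0")
        if self.a_p >= self.a_s or self.b_p >= self.b_s:
            raise InvalidGeometryError("pore must lie strictly inside the "
                                       "complex outline")
        if self.cross_section_kind not in ("circular", "rounded_triangular"):
            raise InvalidGeometryError(
                f"unknown cross_section_kind {self.cross_section_kind!r}")
        if not (0.0 < self.z_flatten <= 1.5):
            raise InvalidGeometryError("z_flatten out of range")

    # outline / pore ellipse semi-axes
    @property
    def a_s(self) -> float:
        return 0.5 * self.complex_length

    @property
    def b_s(self) -> float:
        return 0.5 * self.complex_width

    @property
    def a_p(self) -> float:
        return 0.5 * self.pore_length0

    @property
    def b_p(self) -> float:
        return 0.5 * self.pore_width0

    @classmethod
    def from_dict(cls, d: dict) -> "GeometryParams":
        names = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        kw = {k: v for k, v in d.items() if k in names}
        if "mesh_resolution" in kw:
            kw["mesh_resolution"] = int(kw["mesh_resolution"])
        return cls(**kw)

    def with_(self, **kw) -> "GeometryParams":
        return replace(self, **kw)


@dataclass
class SurfaceMesh:
    """Triangulated wall mid-surface of the guard-cell pair.

    Tube elements are oriented outward for the cell that owns them
    (``cell`` 0 or 1); polar-wall elements are shared (``cell`` -1) and are
    stored oriented outward for cell 0.
    """

    nodes: np.ndarray          # (N, 3) um
    elements: np.ndarray       # (M, 3) int
    thickness: np.ndarray      # (M,) um
    fiber: np.ndarray          # (M, 3) unit, tangent to each element
    patch: np.ndarray          # (M,) int, index into PATCHES
    cell: np.ndarray           # (M,) int: 0, 1, or -1 for shared polar walls
    psi: np.ndarray            # (M,) cross-section angle at centroid (caps: nan)
    phi: np.ndarray            # (M,) torus angle at centroid (caps: pole angle)
    axis_tangent: np.ndarray   # (M, 3) centerline tangent at the element
    cap_center: np.ndarray     # (M, 3) polar-wall center (caps only, else nan)
    node_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    params: GeometryParams | None = None

    # -- basic derived quantities ------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def tri_coords(self) -> np.ndarray:
        return self.nodes[self.elements]  # (M, 3, 3)

    def element_normals(self, normalized: bool = True) -> np.ndarray:
        x = self.tri_coords()
        n = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
        if normalized:
            a = np.linalg.norm(n, axis=1, keepdims=True)
            n = n / np.where(a > 0, a, 1.0)
        return n

    def element_areas(self) -> np.ndarray:
        x = self.tri_coords()
        return 0.5 * np.linalg.norm(
            np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1)

    def element_centroids(self) -> np.ndarray:
        return self.tri_coords().mean(axis=1)

    def patch_mask(self, name: str) -> np.ndarray:
        return self.patch == PATCH_ID[name]

    def cell_surface(self, cell: int):
        """Closed surface of one guard cell: (element rows, orientation).

        orientation +1 keeps the stored winding, -1 flips it; the polar
        walls are included for both cells with opposite orientations.
        """
        own = np.where(self.cell == cell)[0]
        caps = np.where(self.cell == -1)[0]
        rows = np.concatenate([own, caps])
        orient = np.concatenate([np.ones(len(own)),
                                 np.full(len(caps), 1.0 if cell == 0 else -1.0)])
        return rows, orient

    def enclosed_volume(self, cell: int, nodes: np.ndarray | None = None) -> float:
        """Signed volume enclosed by one guard cell's closed wall (um^3)."""
        nodes = self.nodes if nodes is None else nodes
        rows, orient = self.cell_surface(cell)
        tri = nodes[self.elements[rows]]
        v6 = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))
        return float(np.sum(orient * v6) / 6.0)

    def total_area(self) -> float:
        return float(self.element_areas().sum())

    # -- rigid transforms ---------------------------------------------------
    def rotated(self, R: np.ndarray) -> "SurfaceMesh":
        """Rigidly rotated copy (rotates nodes and all direction data)."""
        R = np.asarray(R, float)
        return replace(
            self,
            nodes=self.nodes @ R.T,
            fiber=self.fiber @ R.T,
            axis_tangent=self.axis_tangent @ R.T,
            cap_center=self.cap_center @ R.T,
            node_sets=dict(self.node_sets),
        )

    def translated(self, v) -> "SurfaceMesh":
        v = np.asarray(v, float)
        cc = self.cap_center + v
        return replace(self, nodes=self.nodes + v, cap_center=cc,
                       node_sets=dict(self.node_sets))

    # -- topology checks ----------------------------------------------------
    def cell_euler_characteristic(self, cell: int) -> int:
        rows, _ = self.cell_surface(cell)
        elems = self.elements[rows]
        verts = np.unique(elems)
        edges = np.sort(np.concatenate([elems[:, [0, 1]], elems[:, [1, 2]],
                                        elems[:, [2, 0]]]), axis=1)
        n_edges = len(np.unique(edges, axis=0))
        return int(len(verts) - n_edges + len(elems))

    def cell_is_closed(self, cell: int) -> bool:
        rows, _ = self.cell_surface(cell)
        elems = self.elements[rows]
        edges = np.sort(np.concatenate([elems[:, [0, 1]], elems[:, [1, 2]],
                                        elems[:, [2, 0]]]), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


# ---------------------------------------------------------------------------
# construction helpers

def _centerline(params: GeometryParams, phi):
    """Midcurve between outline and pore ellipses, and section frame."""
    phi = np.asarray(phi, float)
    ax, bx = 0.5 * (params.a_s + params.a_p), 0.5 * (params.b_s + params.b_p)
    m = np.stack([ax * np.cos(phi), bx * np.sin(phi), np.zeros_like(phi)],
                 axis=-1)
    dr = np.stack([(params.a_s - params.a_p) * np.cos(phi),
                   (params.b_s - params.b_p) * np.sin(phi),
                   np.zeros_like(phi)], axis=-1)
    sep = np.linalg.norm(dr, axis=-1)
    e_r = dr / sep[..., None]
    r = 0.5 * sep
    t = np.stack([-ax * np.sin(phi), bx * np.cos(phi), np.zeros_like(phi)],
                 axis=-1)
    t = t / np.linalg.norm(t, axis=-1)[..., None]
    return m, e_r, r, t


def _section_shape(params: GeometryParams, psi):
    """Radial modulation of the cross-section (1 = circle).

    ``rounded_triangular`` blends a three-lobed superellipse-like bump
    (flattened ventral face, lobes toward the dorsal side); the blend
    amplitude is a config value.  Normalized so the ventral vertex
    (psi = pi) stays on the pore ellipse, preserving the pore contract.
    """
    psi = np.asarray(psi, float)
    if params.cross_section_kind == "circular" or params.section_blend == 0.0:
        return np.ones_like(psi)
    eps = params.section_blend
    tri = 1.0 + eps * (0.5 * (1.0 - np.cos(3.0 * (psi - np.pi))) - 0.5)
    return tri / (1.0 - 0.5 * eps)


def _tube_point(params: GeometryParams, phi, psi):
    m, e_r, r, _ = _centerline(params, phi)
    rho = r * _section_shape(params, psi)
    off = (np.cos(psi)[..., None] * e_r
           + (params.z_flatten * np.sin(psi))[..., None]
           * np.array([0.0, 0.0, 1.0]))
    return m + rho[..., None] * off


def _grid_sizes(params: GeometryParams):
    """Pick (n_phi per cell, n_psi, cap rings) for the target element count."""
    target = params.mesh_resolution
    if target < 100:
        raise InvalidGeometryError(
            "mesh_resolution < 100 cannot close the wall surface")
    # mean tube radius and per-cell centerline length set the aspect ratio
    phis = np.linspace(0.0, np.pi, 101)
    m, _, r, _ = _centerline(params, phis)
    seg = np.linalg.norm(np.diff(m, axis=0), axis=1).sum()
    circ = 2.0 * np.pi * float(r.mean())
    aspect = max(0.5, min(2.0, seg / circ))
    # n_psi a multiple of 8 keeps the four tube patches element-aligned and
    # mirror-symmetric; n_phi even guarantees node rings on the long-axis
    # midplane (phi = pi/2) used for aperture measurement
    n_psi = 8 * max(1, int(round(np.sqrt(target / (2.0 * aspect)) / 8.0)))
    h = circ / n_psi
    n_rings = max(2, int(round(float(r[0]) / h)))
    cap_elems = n_psi * (2 * n_rings - 1)          # per cap
    n_phi = 2 * max(2, int(round((target - cap_elems) / (4.0 * n_psi))))
    return n_phi, n_psi, n_rings


def build_geometry(params: GeometryParams) -> SurfaceMesh:
    """Mesh the two-guard-cell complex with labeled, decorated elements.

    The returned mesh has both cells explicitly, joined at the two shared
    polar walls; each cell's own surface (tube + polar walls) is closed and
    consistently oriented outward.
    """
    n_phi, n_psi, n_rings = _grid_sizes(params)
    n_phi_tot = 2 * n_phi                       # rings around the full torus
    phis = np.arange(n_phi_tot) * (np.pi / n_phi)
    psis = np.arange(n_psi) * (2.0 * np.pi / n_psi)

    PH, PS = np.meshgrid(phis, psis, indexing="ij")
    tube_nodes = _tube_point(params, PH.ravel(), PS.ravel())
    node_id = np.arange(n_phi_tot * n_psi).reshape(n_phi_tot, n_psi)

    nodes = [tube_nodes]
    next_id = n_phi_tot * n_psi

    def add_nodes(arr):
        nonlocal next_id
        nodes.append(arr)
        ids = np.arange(next_id, next_id + len(arr))
        next_id += len(arr)
        return ids

    elems, psi_c, phi_c, cell_of, patch_of = [], [], [], [], []
    cap_center_of, axis_of, is_cap = [], [], []

    def add_tri(tri, psi_cent, phi_cent, cell, cap_c=None):
        elems.append(tri)
        psi_c.append(psi_cent)
        phi_c.append(phi_cent)
        cell_of.append(cell)
        cap_center_of.append(cap_c if cap_c is not None
                             else (np.nan, np.nan, np.nan))
        is_cap.append(cap_c is not None)

    # -- tube --------------------------------------------------------------
    for j in range(n_phi_tot):
        jn = (j + 1) % n_phi_tot
        cell = 0 if j < n_phi else 1
        pm = phis[j] + 0.5 * np.pi / n_phi
        for k in range(n_psi):
            kn = (k + 1) % n_psi
            pmid = psis[k] + np.pi / n_psi
            a, b, c, d = node_id[j, k], node_id[jn, k], node_id[jn, kn], node_id[j, kn]
            add_tri((a, b, c), pmid, pm, cell)
            add_tri((a, c, d), pmid, pm, cell)

    # -- polar caps (shared walls), oriented outward for cell 0 ------------
    cap_fix = []   # (element index, outward-for-cell-0 direction)
    for pole_phi in (0.0, np.pi):
        m, e_r, r, t = _centerline(params, pole_phi)
        r = float(r)
        outward0 = -t if pole_phi == 0.0 else t   # outward for cell 0 (-y ish)
        ring_ids = [node_id[0 if pole_phi == 0.0 else n_phi, :]]
        # interior rings from rim (fraction 1) toward the center
        fracs = np.linspace(1.0, 0.0, n_rings + 1)[1:-1]
        shape = _section_shape(params, psis)
        for f in fracs:
            pts = (m + (f * r * shape * np.cos(psis))[:, None] * e_r
                   + (f * r * params.z_flatten * shape
                      * np.sin(psis))[:, None] * np.array([0.0, 0.0, 1.0]))
            ring_ids.append(add_nodes(pts))
        center = add_nodes(m[None, :])[0]
        cap_c = tuple(m)

        def cap_tri(tri):
            cap_fix.append((len(elems), outward0))
            add_tri(tri, np.nan, pole_phi, -1, cap_c=cap_c)

        for i in range(len(ring_ids) - 1):
            outer, inner = ring_ids[i], ring_ids[i + 1]
            for k in range(n_psi):
                kn = (k + 1) % n_psi
                cap_tri((outer[k], outer[kn], inner[k]))
                cap_tri((inner[k], outer[kn], inner[kn]))
        inner = ring_ids[-1]
        for k in range(n_psi):
            kn = (k + 1) % n_psi
            cap_tri((inner[k], inner[kn], center))

    nodes = np.concatenate(nodes, axis=0)
    elements = np.asarray(elems, dtype=np.int64)
    psi_c = np.asarray(psi_c)
    phi_c = np.asarray(phi_c)
    cell_of = np.asarray(cell_of, dtype=np.int64)
    cap_center = np.asarray(cap_center_of, dtype=float)
    is_cap = np.asarray(is_cap)

    # flip cap triangles whose winding is inward for cell 0
    if cap_fix:
        idx = np.array([i for i, _ in cap_fix])
        outs = np.array([o for _, o in cap_fix])
        tri = nodes[elements[idx]]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        flip = np.einsum("ij,ij->i", n, outs) < 0
        rows = idx[flip]
        elements[rows] = elements[rows][:, [0, 2, 1]]

    # patch labels from the centroid cross-section angle
    psi_w = np.mod(psi_c, 2.0 * np.pi)
    patch = np.full(len(elements), PATCH_ID["polar_wall"], dtype=np.int64)
    tube = ~is_cap
    quad = np.mod(np.where(tube, psi_w, 0.0) + 0.25 * np.pi, 2.0 * np.pi)
    sector = np.floor(quad / (0.5 * np.pi)).astype(int) % 4
    names = ["dorsal", "periclinal_outer", "ventral", "periclinal_inner"]
    for s, nm in enumerate(names):
        patch[tube & (sector == s)] = PATCH_ID[nm]

    # centerline tangent at each element
    _, _, _, t_all = _centerline(params, phi_c)
    axis_tangent = t_all

    mesh = SurfaceMesh(
        nodes=nodes, elements=elements,
        thickness=np.full(len(elements), params.t_wall),
        fiber=np.zeros((len(elements), 3)),
        patch=patch, cell=cell_of, psi=psi_c, phi=phi_c,
        axis_tangent=axis_tangent, cap_center=cap_center,
        params=params,
    )

    # ensure per-cell outward orientation (positive enclosed volume)
    for cell in (0, 1):
        if mesh.enclosed_volume(cell) < 0 and cell == 0:
            raise InvalidGeometryError("cell 0 surface oriented inward")
    if mesh.enclosed_volume(1) < 0:
        own = mesh.cell == 1
        mesh.elements[own] = mesh.elements[own][:, [0, 2, 1]]

    mesh.node_sets = _node_sets(mesh, params, node_id, n_phi, n_psi)
    mesh = assign_fiber_field(mesh)
    mesh.thickness = thickness_field(params, mesh)

    # contract: undeformed pore outline reproduces the requested pore
    va = mesh.node_sets["ventral_equator_0"]
    pl = nodes[va][:, 0].max() - nodes[va][:, 0].min()
    if abs(pl - params.pore_length0) > 0.01 * params.pore_length0:
        raise InvalidGeometryError("meshed pore length deviates from spec")
    return mesh


def _node_sets(mesh: SurfaceMesh, params: GeometryParams, node_id,
               n_phi, n_psi) -> Dict[str, np.ndarray]:
    nodes = mesh.nodes
    tol = 1e-9 * max(params.complex_length, params.complex_width)
    n_tube = node_id.size
    cap_nodes = np.arange(n_tube, mesh.n_nodes)

    sets: Dict[str, np.ndarray] = {}
    # the "poles" of the complex: the shared polar walls plus the outer
    # half of the tube region beyond the pore ends, whose bulging is what
    # elongates the complex
    x_pole = 0.5 * (params.a_p + params.a_s)
    polar_tube = np.where(np.abs(nodes[:n_tube, 0]) >= x_pole - 1e-9)[0]
    sets["pole_tips"] = np.unique(np.concatenate([cap_nodes, polar_tube]))
    # polar-wall nodes on the long axis (y = z = 0): pinning their
    # transverse dofs removes rigid-body drift without constraining a
    # mirror-symmetric deformation (such nodes stay on the axis)
    cap_xy = nodes[cap_nodes]
    on_axis = (np.abs(cap_xy[:, 1]) < 1e-9) & (np.abs(cap_xy[:, 2]) < 1e-9)
    sets["pole_centers"] = cap_nodes[on_axis]
    sets["long_axis_midplane"] = np.where(np.abs(nodes[:, 0]) < 1e-6)[0]
    sets["equatorial_ring"] = np.where(np.abs(nodes[:, 2]) < 1e-6)[0]

    k_ventral = n_psi // 2        # psi = pi row
    ventral_all = node_id[:, k_ventral]
    n_phi_tot = 2 * n_phi
    # rows 0..n_phi belong to cell 0 (phi in [0, pi]); row n_phi is shared
    sets["ventral_equator_0"] = ventral_all[np.arange(0, n_phi + 1) % n_phi_tot]
    sets["ventral_equator_1"] = ventral_all[np.arange(n_phi, 2 * n_phi + 1) % n_phi_tot]
    # dorsal equator lines, handy for profiles
    dorsal_all = node_id[:, 0]
    sets["dorsal_equator_0"] = dorsal_all[np.arange(0, n_phi + 1) % n_phi_tot]
    sets["dorsal_equator_1"] = dorsal_all[np.arange(n_phi, 2 * n_phi + 1) % n_phi_tot]
    # every node of the ventral patch per cell, for pore contact handling
    third = n_psi // 8
    vent_rows = [(k_ventral + d) % n_psi for d in range(-third, third + 1)]
    sets["ventral_nodes_0"] = node_id[np.arange(0, n_phi + 1) % n_phi_tot][:, vent_rows].ravel()
    sets["ventral_nodes_1"] = node_id[np.arange(n_phi, 2 * n_phi + 1) % n_phi_tot][:, vent_rows].ravel()
    return sets


def assign_fiber_field(mesh: SurfaceMesh) -> SurfaceMesh:
    """Attach the circumferential (hoop) microfibril direction per element.

    Tube elements: fiber = axis_tangent x element_normal, which is exactly
    tangent to the facet and circumferential around the tube.  Polar walls:
    hoop around the cap center within the cap plane.  Unit length everywhere.
    """
    normals = mesh.element_normals()
    areas = mesh.element_areas()
    bad = np.where(areas <= 1e-14)[0]
    if len(bad):
        raise InvalidGeometryError(f"zero-area element(s): {bad[:10].tolist()}")

    fiber = np.cross(mesh.axis_tangent, normals)
    caps = mesh.cell == -1
    if np.any(caps):
        u = mesh.element_centroids()[caps] - mesh.cap_center[caps]
        f_cap = np.cross(normals[caps], u)
        # cap-center fan elements can have tiny u; fall back to axis hint
        nrm = np.linalg.norm(f_cap, axis=1)
        weak = nrm < 1e-12
        if np.any(weak):
            f_cap[weak] = np.cross(normals[caps][weak],
                                   np.array([0.0, 0.0, 1.0]))
            nrm = np.linalg.norm(f_cap, axis=1)
        fiber[caps] = f_cap
    # project exactly onto each facet plane and normalize
    fiber = fiber - np.einsum("ij,ij->i", fiber, normals)[:, None] * normals
    nrm = np.linalg.norm(fiber, axis=1)
    if np.any(nrm < 1e-12):
        raise InvalidGeometryError("degenerate fiber direction")
    mesh.fiber = fiber / nrm[:, None]
    return mesh


def thickness_field(params: GeometryParams, mesh: SurfaceMesh) -> np.ndarray:
    """Per-element wall thickness (um).

    circular: uniform t_wall on the tube, t_pole on polar walls.
    rounded_triangular: smooth bump from t_wall at the dorsal line to
    ventral_thickness_ratio * t_wall at the ventral line.  The ventral-patch
    thickness is additionally scaled by m_v.
    """
    t = np.full(mesh.n_elements, params.t_wall, dtype=float)
    caps = mesh.cell == -1
    if params.cross_section_kind == "rounded_triangular":
        w = (0.5 * (1.0 - np.cos(mesh.psi))) ** 2   # 0 dorsal, 1 ventral
        w = np.where(np.isnan(w), 0.0, w)
        t = params.t_wall * (1.0 + (params.ventral_thickness_ratio - 1.0) * w)
    if params.m_v != 1.0:
        t[mesh.patch_mask("ventral")] *= params.m_v
    t[caps] = params.t_pole
    return t
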