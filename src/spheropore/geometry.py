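"""Prolate-spheroid cell geometry and octant mesh generation.

The cell is a prolate spheroid (semi-axes a >= b = b, long axis along +x)
centred in a cubic simulation box.  Mirror symmetry in the three coordinate
planes lets the model cover only the octant x, y, z >= 0 -- one eighth of
cell and box.

The mesh is structured and radial: each node lies on a ray from the origin
through a direction sampled from a barycentric subdivision of the spherical
octant.  Along each ray, nodes are placed on scaled spheroid shells inside
the cell and blended shells between the membrane and the cube surface
outside.  Because every shell is a strictly increasing radial scaling, the
mesh is valid by construction and bitwise deterministic.  The membrane is a
conforming triangulated surface with duplicated nodes (intracellular /
extracellular copies) so the thin-membrane contact-impedance condition can
couple the two sides with a potential jump.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellGeometry", "Mesh", "make_geometry", "build_mesh",
           "prolate_surface_area", "spheroid_volume"]


def prolate_surface_area(a: float, b: float) -> float:
    """Analytic surface area of a prolate spheroid with semi-axes (a, b, b)."""
    if a < b:
        raise ValueError("prolate spheroid requires a >= b")
    if a == b:
        return 4.0 * np.pi * a * a
    e = np.sqrt(1.0 - (b / a) ** 2)
    return 2.0 * np.pi * b * b * (1.0 + (a / b) * np.arcsin(e) / e)


def spheroid_volume(a: float, b: float) -> float:
    """Volume of a spheroid with semi-axes (a, b, b)."""
    return 4.0 / 3.0 * np.pi * a * b * b


@dataclass(frozen=True)
class CellGeometry:
    """Prolate-spheroid cell in a cubic box, 1/8 symmetry.

    ``d_long`` is the long-axis diameter (m); the short-axis diameter is
    ``d_long / aspect_ratio``.  Semi-axes are (a, b, b) with a = d_long/2.
    """

    d_long: float
    aspect_ratio: float
    box_edge: float
    symmetry_fraction: float = 0.125

    def __post_init__(self) -> None:
        if self.d_long <= 0:
            raise ValueError(f"d_long must be > 0, got {self.d_long}")
        if self.aspect_ratio < 1:
            raise ValueError(f"aspect_ratio must be >= 1, got {self.aspect_ratio}")
        a = self.d_long / 2.0
        clearance = self.box_edge / 2.0 - a
        if clearance < a:
            raise ValueError(
                f"box_edge {self.box_edge} too small: clearance to the box face is "
                f"{clearance} but must be at least the long semi-axis {a} "
                f"(requires box_edge >= {4.0 * a})"
            )

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        a = self.d_long / 2.0
        b = a / self.aspect_ratio
        return (a, b, b)

    @property
    def a(self) -> float:
        return self.d_long / 2.0

    @property
    def b(self) -> float:
        return self.a / self.aspect_ratio

    @property
    def surface_area(self) -> float:
        """Analytic full-spheroid surface area."""
        return prolate_surface_area(self.a, self.b)

    @property
    def volume(self) -> float:
        """Analytic full-spheroid volume."""
        return spheroid_volume(self.a, self.b)

    def to_config(self) -> dict:
        return {
            "d_long_um": self.d_long * 1e6,
            "aspect_ratio": self.aspect_ratio,
            "box_edge_um": self.box_edge * 1e6,
        }


def make_geometry(d_long: float, aspect_ratio: float, box_edge: float) -> CellGeometry:
    """Build a :class:`CellGeometry` (all lengths in metres)."""
    return CellGeometry(d_long=d_long, aspect_ratio=aspect_ratio, box_edge=box_edge)


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Conforming tetrahedral octant mesh with a duplicated membrane surface.

    Node bookkeeping:
      * ``vertices``: (n_v, 3) Cartesian coordinates, origin at cell centre.
      * ``tets``: (n_t, 4) node indices, positively oriented.
      * ``tet_region``: 0 = intracellular, 1 = extracellular.
      * ``mem_tris_in`` / ``mem_tris_out``: (n_f, 3) membrane facet triangles
        referencing the intracellular / extracellular node copies; facet i on
        both arrays is the same geometric triangle.
      * ``mem_pairs``: (n_p, 2) matched (inner, outer) node indices with
        identical coordinates.
    """

    geometry: CellGeometry
    vertices: np.ndarray
    tets: np.ndarray
    tet_region: np.ndarray
    mem_tris_in: np.ndarray
    mem_tris_out: np.ndarray
    mem_pairs: np.ndarray
    facet_area: np.ndarray = field(init=False)
    facet_normal: np.ndarray = field(init=False)
    facet_centroid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        v = self.vertices
        t_in = self.mem_tris_in
        p0, p1, p2 = v[t_in[:, 0]], v[t_in[:, 1]], v[t_in[:, 2]]
        cr = np.cross(p1 - p0, p2 - p0)
        area2 = np.linalg.norm(cr, axis=1)
        self.facet_area = 0.5 * area2
        n = cr / area2[:, None]
        c = (p0 + p1 + p2) / 3.0
        # orient outward (away from the cell centre at the origin)
        flip = np.einsum("ij,ij->i", n, c) < 0
        n[flip] *= -1.0
        self.facet_normal = n
        self.facet_centroid = c

    # -- derived quantities --------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_facets(self) -> int:
        return len(self.mem_tris_in)

    @property
    def membrane_area(self) -> float:
        """Meshed membrane area of the octant (1/8 of the spheroid)."""
        return float(self.facet_area.sum())

    def tet_volumes(self) -> np.ndarray:
        v = self.vertices[self.tets]
        return np.abs(np.einsum(
            "ij,ij->i",
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
            v[:, 3] - v[:, 0],
        )) / 6.0

    def intracellular_volume(self) -> float:
        vol = self.tet_volumes()
        return float(vol[self.tet_region == 0].sum())

    def node_mask_plane(self, axis: int) -> np.ndarray:
        """Nodes lying on the symmetry plane with normal along ``axis``."""
        tol = 1e-9 * self.geometry.box_edge
        return np.abs(self.vertices[:, axis]) < tol

    def node_mask_box_face(self, axis: int) -> np.ndarray:
        """Nodes on the outer box face normal to ``axis``."""
        half = self.geometry.box_edge / 2.0
        tol = 1e-9 * self.geometry.box_edge
        return np.abs(self.vertices[:, axis] - half) < tol

    def facet_polar_angle(self, axis: int) -> np.ndarray:
        """Polar angle (rad) of each facet centroid from the given field axis."""
        c = self.facet_centroid
        r = np.linalg.norm(c, axis=1)
        return np.arccos(np.clip(np.abs(c[:, axis]) / r, 0.0, 1.0))

    @property
    def patch_area(self) -> np.ndarray:
        """Dual-patch membrane area per node pair (one third of each adjacent
        facet); sums to the meshed membrane area."""
        if not hasattr(self, "_patch_area"):
            n_pairs = len(self.mem_pairs)
            pair_of = {int(n): i for i, n in enumerate(self.mem_pairs[:, 0])}
            area = np.zeros(n_pairs)
            third = np.repeat(self.facet_area / 3.0, 3)
            idx = np.array([pair_of[int(n)] for n in self.mem_tris_in.ravel()])
            np.add.at(area, idx, third)
            self._patch_area = area
        return self._patch_area

    def patch_polar_angle(self, axis: int) -> np.ndarray:
        """Polar angle (rad) of each membrane node pair from the field axis."""
        v = self.vertices[self.mem_pairs[:, 0]]
        r = np.linalg.norm(v, axis=1)
        return np.arccos(np.clip(np.abs(v[:, axis]) / r, 0.0, 1.0))

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.vertices.tobytes())
        h.update(self.tets.tobytes())
        h.update(self.tet_region.tobytes())
        h.update(self.mem_pairs.tobytes())
        return h.hexdigest()


def _octant_directions(n_ang: int) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric subdivision of the spherical octant x, y, z >= 0.

    Returns unit directions (n_dir, 3) and triangles (n_tri, 3) indexing them.
    Directions with a zero barycentric coordinate lie exactly in the
    corresponding coordinate plane.
    """
    index = {}
    dirs = []
    for i in range(n_ang + 1):
        for j in range(n_ang + 1 - i):
            k = n_ang - i - j
            index[(i, j)] = len(dirs)
            p = np.array([i, j, k], dtype=float) / n_ang
            dirs.append(p / np.linalg.norm(p))
    tris = []
    for i in range(n_ang):
        for j in range(n_ang - i):
            tris.append([index[(i, j)], index[(i + 1, j)], index[(i, j + 1)]])
            if i + j < n_ang - 1:
                tris.append([index[(i + 1, j)], index[(i + 1, j + 1)], index[(i, j + 1)]])
    return np.array(dirs), np.array(tris, dtype=np.int64)


def _graded_spacings(n: int, ratio: float) -> np.ndarray:
    """n positive spacings summing to 1, each ``ratio`` times the previous."""
    d = ratio ** np.arange(n)
    return d / d.sum()


_PRISM_ROTATIONS = [
    (0, 1, 2, 3, 4, 5),
    (1, 2, 0, 4, 5, 3),
    (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1),
    (4, 3, 5, 1, 0, 2),
    (5, 4, 3, 2, 1, 0),
]


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split prisms (n, 6) into 3 tets each with globally consistent diagonals.

    Quad-face diagonals always pass through the face's smallest global node
    index, so neighbouring prisms (and hexahedral neighbours built the same
    way) share diagonals and the mesh stays conforming.
    """
    prisms = np.asarray(prisms, dtype=np.int64)
    n = len(prisms)
    rot = np.argmin(prisms, axis=1)
    perm = np.array(_PRISM_ROTATIONS, dtype=np.int64)
    p = np.take_along_axis(prisms, perm[rot], axis=1)
    # after rotation p[:,0] is the smallest index; choose the diagonal of the
    # quad face (1,2,5,4) through its smallest vertex
    use_15 = np.minimum(p[:, 1], p[:, 5]) < np.minimum(p[:, 2], p[:, 4])
    tets = np.empty((n, 3, 4), dtype=np.int64)
    a = p[use_15]
    tets[use_15] = np.stack([
        a[:, [0, 1, 2, 5]],
        a[:, [0, 1, 5, 4]],
        a[:, [0, 4, 5, 3]],
    ], axis=1)
    b = p[~use_15]
    tets[~use_15] = np.stack([
        b[:, [0, 1, 2, 4]],
        b[:, [0, 4, 2, 5]],
        b[:, [0, 4, 5, 3]],
    ], axis=1)
    return tets.reshape(-1, 4)


def build_mesh(
    geom: CellGeometry,
    resolution: float,
    n_radial_in: int | None = None,
    n_radial_out: int | None = None,
) -> Mesh:
    """Mesh the octant at the given characteristic membrane edge length (m).

    ``resolution`` controls the angular subdivision (membrane triangle edge
    <= resolution) and the near-membrane radial spacing; radial layer counts
    can be overridden for convergence studies.
    """
    a, b, _ = geom.semi_axes
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if resolution > b:
        raise ValueError(
            f"resolution {resolution} exceeds the short semi-axis {b}; "
            "the membrane would be unresolved"
        )
    half = geom.box_edge / 2.0

    # angular subdivision from the quarter-meridian arc length (Ramanujan)
    h = (a - b) ** 2 / (a + b) ** 2
    perimeter = np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))
    n_ang = max(4, int(np.ceil(perimeter / 4.0 / resolution)))

    dirs, tris = _octant_directions(n_ang)
    n_dir = len(dirs)

    # radial shell scalings
    inv_r = np.sqrt((dirs[:, 0] / a) ** 2 + (dirs[:, 1] / b) ** 2 + (dirs[:, 2] / b) ** 2)
    r_mem = 1.0 / inv_r                        # spheroid radius along each ray
    r_box = half / dirs.max(axis=1)            # cube radius along each ray

    if n_radial_in is None:
        n_radial_in = max(4, int(np.ceil(b / resolution)) + 1)
    if n_radial_out is None:
        # geometric grading outward: first layer ~ resolution/2 at the
        # membrane, where the exterior field gradient sets Um accuracy
        gap = float((r_box - r_mem).max())
        g = 1.7
        n_radial_out = max(5, int(np.ceil(
            np.log1p(2.0 * gap / resolution * (g - 1.0)) / np.log(g))))

    # inner shells: s in (0, 1], graded finer toward the membrane
    d_in = _graded_spacings(n_radial_in, 1.0 / 1.3)  # finest at the membrane end
    s_in = np.cumsum(d_in)
    s_in[-1] = 1.0
    # outer shells: t in (0, 1], graded finer toward the membrane
    d_out = _graded_spacings(n_radial_out, 1.7)
    t_out = np.cumsum(d_out)
    t_out[-1] = 1.0

    verts: list[np.ndarray] = [np.zeros((1, 3))]      # node 0: centre
    shell_ids: list[np.ndarray] = []

    def add_shell(points: np.ndarray) -> np.ndarray:
        start = sum(len(v) for v in verts)
        verts.append(points)
        return np.arange(start, start + len(points), dtype=np.int64)

    # intracellular shells (last one is the inner membrane copy)
    inner_shells = [add_shell(dirs * (s * r_mem)[:, None] * 1.0)
                    for s in s_in]
    mem_in = inner_shells[-1]
    # extracellular membrane copy (duplicate coordinates)
    mem_out = add_shell(dirs * r_mem[:, None])
    outer_shells = [mem_out]
    for t in t_out:
        rho = r_mem + t * (r_box - r_mem)
        outer_shells.append(add_shell(dirs * rho[:, None]))

    vertices = np.vstack(verts)

    # volume cells
    tet_blocks: list[np.ndarray] = []
    region_blocks: list[np.ndarray] = []
    # centre fan
    fan = np.column_stack([
        np.zeros(len(tris), dtype=np.int64),
        inner_shells[0][tris[:, 0]],
        inner_shells[0][tris[:, 1]],
        inner_shells[0][tris[:, 2]],
    ])
    tet_blocks.append(fan)
    region_blocks.append(np.zeros(len(fan), dtype=np.uint8))

    def layer_prisms(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        return np.column_stack([
            lo[tris[:, 0]], lo[tris[:, 1]], lo[tris[:, 2]],
            hi[tris[:, 0]], hi[tris[:, 1]], hi[tris[:, 2]],
        ])

    for lo, hi in zip(inner_shells[:-1], inner_shells[1:]):
        t = _split_prisms(layer_prisms(lo, hi))
        tet_blocks.append(t)
        region_blocks.append(np.zeros(len(t), dtype=np.uint8))
    for lo, hi in zip(outer_shells[:-1], outer_shells[1:]):
        t = _split_prisms(layer_prisms(lo, hi))
        tet_blocks.append(t)
        region_blocks.append(np.ones(len(t), dtype=np.uint8))

    tets = np.vstack(tet_blocks)
    tet_region = np.concatenate(region_blocks)

    # enforce positive orientation
    v = vertices[tets]
    signed = np.einsum(
        "ij,ij->i",
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
        v[:, 3] - v[:, 0],
    )
    neg = signed < 0
    tets[neg, 2], tets[neg, 3] = tets[neg, 3].copy(), tets[neg, 2].copy()

    mesh = Mesh(
        geometry=geom,
        vertices=vertices,
        tets=tets,
        tet_region=tet_region,
        mem_tris_in=mem_in[tris],
        mem_tris_out=mem_out[tris],
        mem_pairs=np.column_stack([mem_in, mem_out]),
    )
    return mesh
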