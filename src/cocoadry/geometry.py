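"""Axisymmetric bean geometry and structured two-layer meshing.

The CCN51 bean is idealized as a prolate spheroid (major axis 22 mm along
the symmetry axis, minor diameter 12 mm) with a 0.55 mm testa shell.  The
computational domain is the half cross-section in (r, z) coordinates with
z the symmetry axis and r >= 0.

The mesh is structured: the outer ellipse is sampled in the elliptic angle,
the shell is a layered band bounded inside by the constant-normal-offset
curve of the ellipse, and the core is filled by scaling the offset curve
toward the center (a polar fan), mildly graded so cells are finer near the
shell/core interface where moisture gradients are steepest.  Triangles are
kept close to right-angled so the assembled diffusion operators are
M-matrices (discrete maximum principle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CORE",
    "SHELL",
    "BeanGeometry",
    "Mesh",
    "build_geometry",
    "generate_mesh",
    "revolved_measures",
    "export_vtk",
]

CORE = 0
SHELL = 1
_TAG_NAMES = {CORE: "core", SHELL: "shell"}


@dataclass(frozen=True)
class BeanGeometry:
    """Prolate-spheroid bean: full length/width (m) and shell thickness (m)."""

    length: float = 0.022
    width: float = 0.012
    shell_thickness: float = 0.00055

    def __post_init__(self):
        if min(self.length, self.width) <= 0 or self.shell_thickness < 0:
            raise ValueError("dimensions must be positive (shell may be zero)")
        if self.shell_thickness >= self.width / 2:
            raise ValueError("shell thickness must be below the minor semi-axis")

    @property
    def a(self) -> float:
        """Semi-axis along the symmetry axis (m)."""
        return self.length / 2

    @property
    def b(self) -> float:
        """Equatorial semi-axis (m)."""
        return self.width / 2

    @property
    def volume(self) -> float:
        """Analytic spheroid volume (m^3)."""
        return 4.0 / 3.0 * np.pi * self.a * self.b**2

    @property
    def surface_area(self) -> float:
        """Analytic prolate-spheroid surface area (m^2)."""
        a, b = self.a, self.b
        if abs(a - b) < 1e-12:
            return 4 * np.pi * a * a
        e = np.sqrt(1 - (b / a) ** 2)
        return 2 * np.pi * b**2 * (1 + a / (b * e) * np.arcsin(e))

    @property
    def equivalent_sphere_diameter(self) -> float:
        """Diameter of the sphere with the same volume (m)."""
        return 2.0 * (self.a * self.b**2) ** (1.0 / 3.0)


def build_geometry(
    length: float = 0.022, width: float = 0.012, shell_thickness: float = 0.00055
) -> BeanGeometry:
    """Canonical bean geometry; defaults are the measured CCN51 dimensions."""
    return BeanGeometry(length=length, width=width, shell_thickness=shell_thickness)


@dataclass
class Mesh:
    """Conforming triangle mesh of the (r, z) half cross-section.

    points       (N, 2) node coordinates, columns (r, z), meters
    triangles    (M, 3) node indices
    element_tags (M,)   CORE or SHELL
    exterior_edges (E, 2) node pairs on the solid-air surface
    axis_edges     (A, 2) node pairs on the symmetry axis (r = 0)
    """

    points: np.ndarray
    triangles: np.ndarray
    element_tags: np.ndarray
    exterior_edges: np.ndarray
    axis_edges: np.ndarray
    geometry: BeanGeometry | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def element_centroid_r(self) -> np.ndarray:
        return self.points[self.triangles, 0].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        """Revolved (Pappus) volume of each element: 2*pi*r_centroid*area."""
        return 2 * np.pi * self.element_centroid_r() * self.element_areas()

    def exterior_edge_areas(self) -> np.ndarray:
        """Revolved surface area of each exterior edge: 2*pi*r_mid*length."""
        p0 = self.points[self.exterior_edges[:, 0]]
        p1 = self.points[self.exterior_edges[:, 1]]
        length = np.linalg.norm(p1 - p0, axis=1)
        r_mid = 0.5 * (p0[:, 0] + p1[:, 0])
        return 2 * np.pi * r_mid * length


def _ellipse_and_offset(geom: BeanGeometry, theta: np.ndarray):
    """Outer ellipse points and the inward constant-normal offset curve."""
    a, b, t = geom.a, geom.b, geom.shell_thickness
    r = b * np.sin(theta)
    z = a * np.cos(theta)
    # outward normal of (r/b)^2 + (z/a)^2 = 1
    nr = np.sin(theta) / b
    nz = np.cos(theta) / a
    norm = np.hypot(nr, nz)
    outer = np.column_stack([r, z])
    inner = outer - t * np.column_stack([nr / norm, nz / norm])
    return outer, inner


def generate_mesh(
    geom: BeanGeometry, target_size: float = 5e-4, shell_layers: int = 3
) -> Mesh:
    """Structured two-layer mesh at a requested characteristic size.

    Deterministic for fixed inputs.  ``target_size`` controls the angular and
    core-radial resolution; the shell band always carries ``shell_layers``
    element layers across its thickness.
    """
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    if geom.shell_thickness > 0 and shell_layers < 1:
        raise ValueError("shell_layers must be >= 1 when a shell is present")
    # Ramanujan half-perimeter of the outer ellipse
    a, b = geom.a, geom.b
    h = ((a - b) / (a + b)) ** 2
    perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h))) / 2
    # floor keeps the inscribed-polygon volume deficit below ~0.6%
    n_theta = max(20, int(round(perim / target_size)))
    if n_theta > 4000:
        raise ValueError(
            f"target_size {target_size} m needs {n_theta} angular divisions; "
            "refine the shell with shell_layers instead"
        )
    inner_radius = 0.5 * (a + b) - geom.shell_thickness
    n_s = max(4, int(round(inner_radius / target_size)))

    theta = np.linspace(0.0, np.pi, n_theta + 1)
    outer, inner = _ellipse_and_offset(geom, theta)
    outer[0, 0] = outer[-1, 0] = 0.0  # poles exactly on the axis
    inner[0, 0] = inner[-1, 0] = 0.0

    # mild grading: finer core rings near the shell/core interface
    j = np.arange(n_s + 1)
    s = np.sin(0.5 * np.pi * j / n_s)

    points = [np.array([0.0, 0.0])]
    ring_ids = []  # ring_ids[level][i] -> node index; level 0..n_s core, then shell
    center = 0
    for jj in range(1, n_s + 1):
        ids = np.arange(len(points), len(points) + n_theta + 1)
        points.extend(s[jj] * inner)
        ring_ids.append(ids)
    n_layers = shell_layers if geom.shell_thickness > 0 else 0
    for ll in range(1, n_layers + 1):
        frac = ll / n_layers
        ring = inner + frac * (outer - inner)
        ring[0, 0] = ring[-1, 0] = 0.0
        ids = np.arange(len(points), len(points) + n_theta + 1)
        points.extend(ring)
        ring_ids.append(ids)
    points = np.asarray(points)

    tris = []
    tags = []
    # center fan (core)
    first = ring_ids[0]
    for i in range(n_theta):
        tris.append((center, first[i], first[i + 1]))
        tags.append(CORE)
    # ring-to-ring quads, split along alternating diagonals
    for lev in range(len(ring_ids) - 1):
        lo, hi = ring_ids[lev], ring_ids[lev + 1]
        # ring levels 0..n_s-2 lie between core rings; levels >= n_s-1 are the band
        tag = CORE if (lev < n_s - 1 or n_layers == 0) else SHELL
        for i in range(n_theta):
            A, B, C, D = lo[i], lo[i + 1], hi[i + 1], hi[i]
            if (i + lev) % 2 == 0:
                tris.append((A, B, C))
                tris.append((A, C, D))
            else:
                tris.append((A, B, D))
                tris.append((B, C, D))
            tags.extend((tag, tag))
    triangles = np.asarray(tris, dtype=np.int64)
    element_tags = np.asarray(tags, dtype=np.int8)

    outer_ring = ring_ids[-1]
    exterior_edges = np.column_stack([outer_ring[:-1], outer_ring[1:]])
    # axis chains at theta=0 (i=0) and theta=pi (i=n_theta)
    north = [center] + [ring[0] for ring in ring_ids]
    south = [center] + [ring[-1] for ring in ring_ids]
    axis_edges = np.array(
        [(north[i], north[i + 1]) for i in range(len(north) - 1)]
        + [(south[i], south[i + 1]) for i in range(len(south) - 1)],
        dtype=np.int64,
    )

    mesh = Mesh(
        points=points,
        triangles=triangles,
        element_tags=element_tags,
        exterior_edges=exterior_edges,
        axis_edges=axis_edges,
        geometry=geom,
        meta={
            "target_size": target_size,
            "n_theta": n_theta,
            "n_s": n_s,
            "shell_layers": n_layers,
        },
    )
    _validate_mesh(mesh)
    return mesh


def _validate_mesh(mesh: Mesh):
    if np.any(mesh.points[:, 0] < -1e-15):
        raise ValueError("mesh has nodes with negative radius")
    areas = mesh.element_areas()
    if np.any(areas <= 0):
        raise ValueError("mesh contains degenerate elements")
    if mesh.geometry is not None:
        vol = mesh.element_volumes().sum()
        exact = mesh.geometry.volume
        if abs(vol - exact) / exact > 0.01:
            raise ValueError(
                f"revolved mesh volume {vol:.4e} deviates >1% from analytic {exact:.4e}"
            )


def revolved_measures(mesh: Mesh) -> dict:
    """Per-subdomain revolved volumes (m^3) and exterior surface area (m^2)."""
    vols = mesh.element_volumes()
    out = {}
    for tag, name in _TAG_NAMES.items():
        sel = mesh.element_tags == tag
        if sel.any():
            out[f"volume_{name}"] = float(vols[sel].sum())
    out["volume_total"] = float(vols.sum())
    out["surface_exterior"] = float(mesh.exterior_edge_areas().sum())
    return out


def export_vtk(mesh: Mesh, path, point_data: dict | None = None):
    """Write the mesh (and optional nodal fields) as legacy-ASCII VTK.

    Points are embedded as (r, z, 0); subdomain tags go out as cell data.
    """
    pts = mesh.points
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncocoadry axisymmetric mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pts)} double\n")
        for r, z in pts:
            f.write(f"{r:.9e} {z:.9e} 0.0\n")
        tris = mesh.triangles
        f.write(f"CELLS {len(tris)} {4 * len(tris)}\n")
        for t in tris:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        f.write(f"CELL_TYPES {len(tris)}\n")
        f.write("5\n" * len(tris))
        f.write(f"CELL_DATA {len(tris)}\nSCALARS subdomain int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(str(int(t)) for t in mesh.element_tags) + "\n")
        if point_data:
            f.write(f"POINT_DATA {len(pts)}\n")
            for name, arr in point_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(f"{v:.9e}" for v in np.asarray(arr)) + "\n")
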