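"""Parametric 2D retinal-vessel bifurcation geometry and meshing.

The en-face section holds three tissue domains: blood (lumen), vessel wall
(a constant-thickness shell around the lumen) and retina/choroid (the rest
of the bounding box).  The default topology is a Y-plus-side-branch: an
inlet trunk (i1) that bifurcates once, with one branch bifurcating again,
yielding three outlets (o1, o2, o3).  Four points of interest (POIs) sit on
the wall mid-thickness line near the bifurcations and the bend.

Configuration lengths are micrometres; meshes are emitted in SI metres.
Meshing uses a structured triangular background grid whose nodes are
snapped onto the lumen and outer-wall boundary curves, which keeps the mesh
conforming, deterministic, and exactly scale-equivariant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely
import yaml
from shapely.geometry import LineString, Point, Polygon, box as shapely_box
from shapely.ops import nearest_points, unary_union

UM = 1e-6  # metres per micrometre

DOMAIN_RETINA, DOMAIN_WALL, DOMAIN_BLOOD = 0, 1, 2
DOMAIN_NAMES = {DOMAIN_RETINA: "retina", DOMAIN_WALL: "wall", DOMAIN_BLOOD: "blood"}
DOMAIN_CODES = {v: k for k, v in DOMAIN_NAMES.items()}


class GeometryError(ValueError):
    """Raised when a parametric geometry cannot be constructed."""


def _unit(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a)])


@dataclass(frozen=True)
class GeometryParams:
    """Branching spec for the synthetic fundus section (lengths in µm).

    ``outlet_widths`` of length 1 selects the degenerate straight-channel
    topology (a single rectangular lumen crossing the box), used as the
    plane-Poiseuille verification domain.
    """

    inlet_width: float = 120.0
    outlet_widths: tuple = (20.0, 16.0, 18.0)
    wall_thickness: float = 15.0
    box: tuple = (600.0, 420.0)
    junction1_frac: float = 0.38      # J1 position along the box width
    branch_up_angle: float = 18.0     # deg; branch A leaving J1
    branch_down_angle: float = -20.0  # deg; branch B leaving J1
    branch_a_len: float = 95.0       # µm centerline J1 -> J2
    branch_a_width: float = 70.0
    branch_a_end_width: float = 40.0
    branch_b_width: float = 60.0
    branch_b_mid_width: float = 36.0
    o1_angle: float = 5.0
    o2_angle: float = 48.0
    bend_len: float = 60.0            # µm along branch B before the bend
    bend_turn: float = 28.0           # deg turn (to the left) at the bend
    junction_split: float = 0.6       # lateral separation of child branches
    width_band: tuple = (72.0, 185.0)  # plausibility band for the main lumen

    def scaled(self, k: float) -> "GeometryParams":
        """All geometric lengths multiplied by k (angles and fracs kept)."""
        return replace(
            self,
            inlet_width=self.inlet_width * k,
            outlet_widths=tuple(w * k for w in self.outlet_widths),
            wall_thickness=self.wall_thickness * k,
            box=(self.box[0] * k, self.box[1] * k),
            branch_a_len=self.branch_a_len * k,
            branch_a_width=self.branch_a_width * k,
            branch_a_end_width=self.branch_a_end_width * k,
            branch_b_width=self.branch_b_width * k,
            branch_b_mid_width=self.branch_b_mid_width * k,
            bend_len=self.bend_len * k,
            width_band=(self.width_band[0] * k, self.width_band[1] * k),
        )

    @classmethod
    def from_yaml(cls, path) -> "GeometryParams":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("outlet_widths", "box", "width_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class Segment:
    """Straight vessel piece with linearly varying lumen width.

    ``cap0``, when given, is the unit direction of the parent's end-cap
    plane; the start edge is laid along it (its half-length scaled so the
    width perpendicular to the axis stays w0), which lets child branches
    tile a junction without double-covering the parent lumen.
    """

    name: str
    p0: np.ndarray
    p1: np.ndarray
    w0: float
    w1: float
    cap0: np.ndarray | None = None

    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    def polygon(self) -> Polygon:
        d = self.p1 - self.p0
        d = d / np.linalg.norm(d)
        n = np.array([-d[1], d[0]])
        if self.cap0 is None:
            a0, b0 = self.p0 + n * self.w0 / 2, self.p0 - n * self.w0 / 2
        else:
            c = np.asarray(self.cap0, dtype=float)
            s = self.w0 / (2 * abs(c @ n))
            back = 0.01 * self.w0 * d  # slight overlap into the parent keeps the union tight
            a0, b0 = self.p0 + s * c - back, self.p0 - s * c - back
        return Polygon([
            a0, self.p1 + n * self.w1 / 2, self.p1 - n * self.w1 / 2, b0,
        ])


@dataclass(frozen=True)
class Port:
    name: str
    center: np.ndarray   # µm, on the box boundary
    outward: np.ndarray  # unit vector pointing out of the box
    width: float         # µm


@dataclass(frozen=True)
class Junction:
    point: np.ndarray
    child_dirs: tuple      # unit vectors of the two child branches
    parent_width: float
    parent_dir: np.ndarray = None  # unit vector of the feeding segment


@dataclass(frozen=True)
class Bend:
    point: np.ndarray
    dir_in: np.ndarray
    dir_out: np.ndarray
    width: float


@dataclass
class VesselGeometry:
    """Planar multi-domain vessel geometry (µm units)."""

    params: GeometryParams
    segments: list
    ports: dict               # name -> Port; inlet is "i1"
    junctions: list           # Junction, ordered from the inlet
    bends: list
    lumen: Polygon = field(init=False)
    outer: Polygon = field(init=False)     # lumen dilated by wall thickness
    wall: Polygon = field(init=False)
    retina: Polygon = field(init=False)
    poi_coords: np.ndarray | None = None   # (4, 2) µm, filled by place_pois

    def __post_init__(self):
        bx = shapely_box(0.0, 0.0, *self.params.box)
        raw = unary_union([s.polygon() for s in self.segments])
        self.lumen = raw.intersection(bx)
        t = self.params.wall_thickness
        self.outer = raw.buffer(t, quad_segs=16).intersection(bx)
        self.wall = self.outer.difference(self.lumen)
        self.retina = bx.difference(self.outer)
        if self.lumen.geom_type != "Polygon":
            raise GeometryError("lumen is not a single connected polygon")

    @property
    def wall_thickness(self) -> float:
        return self.params.wall_thickness

    def midline(self) -> LineString:
        """Wall mid-thickness curve (boundary of the half-dilated lumen)."""
        raw = unary_union([s.polygon() for s in self.segments])
        return raw.buffer(self.params.wall_thickness / 2, quad_segs=16).boundary

    def segment_area_estimate(self) -> float:
        """Sum of width x centerline length over segments (µm^2)."""
        return sum(0.5 * (s.w0 + s.w1) * s.length() for s in self.segments)


def _ray_box_exit(p: np.ndarray, d: np.ndarray, box: tuple) -> np.ndarray:
    """First intersection of the ray p + s*d (s>0) with the box boundary."""
    W, H = box
    best = math.inf
    for lo, hi, comp in ((0.0, W, 0), (0.0, H, 1)):
        if abs(d[comp]) > 1e-12:
            for target in (lo, hi):
                s = (target - p[comp]) / d[comp]
                if s > 1e-9:
                    q = p + s * d
                    other = 1 - comp
                    if -1e-9 <= q[other] <= (H if comp == 0 else W) + 1e-9:
                        best = min(best, s)
    if not math.isfinite(best):
        raise GeometryError("branch ray does not reach the bounding box")
    return p + best * d


def build_vessel_geometry(params: GeometryParams | None = None) -> VesselGeometry:
    """Construct the parametric vessel geometry.

    Raises GeometryError when the main lumen width falls outside the
    plausibility band or when non-adjacent branches overlap after
    offsetting by the wall thickness.
    """
    params = params or GeometryParams()
    lo, hi = params.width_band
    if not (lo <= params.inlet_width <= hi):
        raise GeometryError(
            f"inlet width {params.inlet_width} µm outside plausibility band {params.width_band}"
        )
    if any(w <= 0 for w in params.outlet_widths):
        raise GeometryError("outlet widths must be strictly positive")
    W, H = params.box
    yc = H / 2

    if len(params.outlet_widths) == 1:
        w_out = params.outlet_widths[0]
        seg = Segment("trunk", np.array([0.0, yc]), np.array([W, yc]),
                      params.inlet_width, w_out)
        ports = {
            "i1": Port("i1", np.array([0.0, yc]), np.array([-1.0, 0.0]), params.inlet_width),
            "o1": Port("o1", np.array([W, yc]), np.array([1.0, 0.0]), w_out),
        }
        return VesselGeometry(params, [seg], ports, [], [])
    if len(params.outlet_widths) != 3:
        raise GeometryError("outlet_widths must have length 1 (channel) or 3")

    j1 = np.array([params.junction1_frac * W, yc])
    trunk = Segment("trunk", np.array([0.0, yc]), j1, params.inlet_width, params.inlet_width)

    trunk_dir = np.array([1.0, 0.0])
    cap_j1 = np.array([0.0, 1.0])     # trunk end-cap plane
    kappa = params.junction_split

    def child_start(junction, cap, direction, width):
        """Start point of a child branch, shifted along the parent cap so
        sibling branches tile the junction instead of double-covering it."""
        n = np.array([-direction[1], direction[0]])
        s = width / (2 * abs(cap @ n))
        side = np.sign(cap @ direction)
        return junction + kappa * s * side * cap

    da = _unit(params.branch_up_angle)
    p0a = child_start(j1, cap_j1, da, params.branch_a_width)
    j2 = p0a + params.branch_a_len * da
    seg_a = Segment("branch_a", p0a, j2, params.branch_a_width,
                    params.branch_a_end_width, cap0=cap_j1)

    cap_j2 = np.array([-da[1], da[0]])
    d1 = _unit(params.o1_angle)
    p01 = child_start(j2, cap_j2, d1, params.branch_a_end_width)
    e1 = _ray_box_exit(p01, d1, params.box)
    seg_o1 = Segment("o1", p01, e1, params.branch_a_end_width,
                     params.outlet_widths[0], cap0=cap_j2)
    d2 = _unit(params.o2_angle)
    p02 = child_start(j2, cap_j2, d2, params.branch_a_end_width)
    e2 = _ray_box_exit(p02, d2, params.box)
    seg_o2 = Segment("o2", p02, e2, params.branch_a_end_width,
                     params.outlet_widths[1], cap0=cap_j2)

    # the bend is filleted: two half-turns around a short chord, so the
    # outer lumen boundary has no stress-singular sharp corner
    db = _unit(params.branch_down_angle)
    p0b = child_start(j1, cap_j1, db, params.branch_b_width)
    bv = p0b + params.bend_len * db
    seg_b1 = Segment("branch_b", p0b, bv, params.branch_b_width,
                     params.branch_b_mid_width, cap0=cap_j1)
    d_half = _unit(params.branch_down_angle + params.bend_turn / 2)
    db2 = _unit(params.branch_down_angle + params.bend_turn)
    fl = params.branch_b_mid_width
    b_post = bv + fl * d_half
    seg_bf = Segment("bend_fillet", bv, b_post, params.branch_b_mid_width,
                     params.branch_b_mid_width, cap0=np.array([-db[1], db[0]]))
    e3 = _ray_box_exit(b_post, db2, params.box)
    seg_o3 = Segment("o3", b_post, e3, params.branch_b_mid_width,
                     params.outlet_widths[2],
                     cap0=np.array([-d_half[1], d_half[0]]))

    segments = [trunk, seg_a, seg_o1, seg_o2, seg_b1, seg_bf, seg_o3]

    adjacent = {("trunk", "branch_a"), ("trunk", "branch_b"),
                ("branch_a", "branch_b"), ("branch_a", "o1"),
                ("branch_a", "o2"), ("o1", "o2"), ("branch_b", "bend_fillet"),
                ("bend_fillet", "o3")}
    _check_branch_overlap(segments, params.wall_thickness, adjacent)

    ports = {
        "i1": Port("i1", np.array([0.0, yc]), np.array([-1.0, 0.0]), params.inlet_width),
        "o1": Port("o1", e1, _boundary_outward(e1, params.box), params.outlet_widths[0]),
        "o2": Port("o2", e2, _boundary_outward(e2, params.box), params.outlet_widths[1]),
        "o3": Port("o3", e3, _boundary_outward(e3, params.box), params.outlet_widths[2]),
    }
    junctions = [
        Junction(j1, (da, db), params.inlet_width, parent_dir=trunk_dir),
        Junction(j2, (_unit(params.o1_angle), _unit(params.o2_angle)),
                 params.branch_a_width, parent_dir=da),
    ]
    bends = [Bend(bv + 0.5 * fl * d_half, db, db2, params.branch_b_mid_width)]
    return VesselGeometry(params, segments, ports, junctions, bends)


def _check_branch_overlap(segments: list, wall_thickness: float,
                          adjacent_pairs: set) -> None:
    """Reject geometries where distant branches collide after wall offset.

    Segments within graph distance 2 of each other (sharing a junction or
    flanking one) legitimately meet; any other pair whose wall-offset
    polygons intersect indicates a self-intersecting vessel tree.
    """
    n = len(segments)
    names = [s.name for s in segments]
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if (names[i], names[j]) in adjacent_pairs or (names[j], names[i]) in adjacent_pairs:
                adj[i][j] = adj[j][i] = True
    dist2 = set()
    for i in range(n):
        for j in range(n):
            if adj[i][j]:
                dist2.add((min(i, j), max(i, j)))
                for k in range(n):
                    if adj[j][k] and k != i:
                        dist2.add((min(i, k), max(i, k)))
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in dist2:
                continue
            a, b = segments[i], segments[j]
            if a.polygon().buffer(wall_thickness).intersects(b.polygon().buffer(wall_thickness)):
                raise GeometryError(
                    f"branches '{a.name}' and '{b.name}' overlap after offsetting "
                    f"by the wall thickness")


def _boundary_outward(p: np.ndarray, box: tuple) -> np.ndarray:
    W, H = box
    tol = 1e-6 * max(W, H)
    if abs(p[0]) < tol:
        return np.array([-1.0, 0.0])
    if abs(p[0] - W) < tol:
        return np.array([1.0, 0.0])
    if abs(p[1]) < tol:
        return np.array([0.0, -1.0])
    if abs(p[1] - H) < tol:
        return np.array([0.0, 1.0])
    raise GeometryError("port center not on the bounding box")


def _first_midline_hit(geom: VesselGeometry, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    span = max(geom.params.box)
    ray = LineString([origin, origin + direction * span])
    hits = ray.intersection(geom.midline())
    if hits.is_empty:
        raise GeometryError("POI ray does not reach the wall mid-thickness line")
    pts = []
    for g in getattr(hits, "geoms", [hits]):
        if g.geom_type == "Point":
            pts.append(g)
        else:
            pts.extend(Point(c) for c in g.coords)
    pts.sort(key=lambda q: origin_dist(q, origin))
    return np.array([pts[0].x, pts[0].y])


def origin_dist(q: Point, origin: np.ndarray) -> float:
    return math.hypot(q.x - origin[0], q.y - origin[1])


def place_pois(geom: VesselGeometry) -> np.ndarray:
    """Deterministic placement of the four probe points (µm).

    POI1: apex (carina) of the first bifurcation; POI2: apex of the second
    bifurcation; POI3: outer side of the maximum-curvature bend; POI4:
    inner side of the widest junction.  All lie on the wall mid-thickness
    line, found by casting a ray from the feature point.
    """
    if len(geom.junctions) < 2:
        raise GeometryError("geometry has fewer than 2 junctions; POIs undefined")
    if len(geom.junctions) + len(geom.bends) + 1 < 4:
        raise GeometryError("fewer than 4 candidate features; add bends to the geometry")

    j1, j2 = geom.junctions[0], geom.junctions[1]

    def bisector(a, b):
        v = a / np.linalg.norm(a) + b / np.linalg.norm(b)
        return v / np.linalg.norm(v)

    poi1 = _first_midline_hit(geom, j1.point, bisector(*j1.child_dirs))
    poi2 = _first_midline_hit(geom, j2.point, bisector(*j2.child_dirs))

    bend = max(geom.bends, key=lambda b: abs(math.atan2(
        b.dir_in[0] * b.dir_out[1] - b.dir_in[1] * b.dir_out[0], b.dir_in @ b.dir_out)))
    avg = bisector(bend.dir_in, bend.dir_out)
    turn = bend.dir_in[0] * bend.dir_out[1] - bend.dir_in[1] * bend.dir_out[0]
    # the outer side of the turn is opposite the turning direction
    normal = np.array([avg[1], -avg[0]]) if turn > 0 else np.array([-avg[1], avg[0]])
    poi3 = _first_midline_hit(geom, bend.point, normal)

    # inner side of the widest junction: the parent wall opposite the
    # first child branch, reached perpendicular to the parent axis
    widest = max(geom.junctions, key=lambda j: j.parent_width)
    perp = np.array([-widest.parent_dir[1], widest.parent_dir[0]])
    if perp @ widest.child_dirs[0] < 0:
        perp = -perp
    poi4 = _first_midline_hit(geom, widest.point, -perp)

    pois = np.array([poi1, poi2, poi3, poi4])
    for k, p in enumerate(pois):
        if not geom.wall.buffer(1e-6).contains(Point(p)):
            raise GeometryError(f"POI{k + 1} fell outside the wall domain")
    geom.poi_coords = pois
    return pois


@dataclass
class DomainMesh:
    """Conforming triangle mesh of all three domains (coords in metres)."""

    coords: np.ndarray        # (n, 2) m
    tris: np.ndarray          # (m, 3)
    domain: np.ndarray        # (m,) codes DOMAIN_*
    bedges: np.ndarray        # (k, 2) vertex pairs: box boundary + interfaces
    btags: np.ndarray         # (k,) str tags: i1, o1..o3, outer, interface
    bedge_tri: np.ndarray     # (k,) adjacent triangle (blood side for blood-wall)
    iface_kind: np.ndarray    # (k,) '', 'blood-wall', 'wall-retina'
    ports: dict               # name -> Port (converted to metres)
    resolution_um: float
    geometry: VesselGeometry | None = None

    def areas(self) -> np.ndarray:
        p0, p1, p2 = (self.coords[self.tris[:, k]] for k in range(3))
        return 0.5 * ((p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1])
                      - (p1[:, 1] - p0[:, 1]) * (p2[:, 0] - p0[:, 0]))

    def domain_area(self, name: str) -> float:
        return float(self.areas()[self.domain == DOMAIN_CODES[name]].sum())

    def edges_with_tag(self, tag: str):
        m = self.btags == tag
        return self.bedges[m], self.bedge_tri[m]

    def blood_wall_edges(self):
        m = self.iface_kind == "blood-wall"
        return self.bedges[m], self.bedge_tri[m]

    def port_names(self):
        return [t for t in ("i1", "o1", "o2", "o3") if np.any(self.btags == t)]

    def save_vtk(self, path) -> None:
        """Legacy ASCII VTK export with the domain code as cell data."""
        n, m = len(self.coords), len(self.tris)
        with open(path, "w") as f:
            f.write("# vtk DataFile Version 3.0\nretmech mesh\nASCII\n")
            f.write("DATASET UNSTRUCTURED_GRID\n")
            f.write(f"POINTS {n} double\n")
            for x, y in self.coords:
                f.write(f"{x:.9e} {y:.9e} 0.0\n")
            f.write(f"CELLS {m} {4 * m}\n")
            for t in self.tris:
                f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
            f.write(f"CELL_TYPES {m}\n")
            f.write("5\n" * m)
            f.write(f"CELL_DATA {m}\nSCALARS domain int 1\nLOOKUP_TABLE default\n")
            for d in self.domain:
                f.write(f"{d}\n")

    def export_pois_csv(self, path) -> None:
        if self.geometry is None or self.geometry.poi_coords is None:
            raise GeometryError("mesh carries no POI coordinates")
        with open(path, "w") as f:
            f.write("id,x_um,y_um,domain\n")
            for k, (x, y) in enumerate(self.geometry.poi_coords):
                f.write(f"POI{k + 1},{x:.4f},{y:.4f},wall\n")


def generate_mesh(geom: VesselGeometry, resolution: float = 4.0) -> DomainMesh:
    """Mesh the geometry at a target edge length (µm).

    Structured background grid; nodes within 0.45 cell sizes of the lumen or
    outer-wall curve are snapped onto it (nodes on the box boundary slide
    along it); triangles are classified by centroid.  Deterministic.
    """
    if resolution > geom.params.wall_thickness / 2 + 1e-9:
        raise GeometryError("resolution must not exceed half the wall thickness")
    W, H = geom.params.box
    nx, ny = max(2, round(W / resolution)), max(2, round(H / resolution))
    hx, hy = W / nx, H / ny
    xs = np.linspace(0.0, W, nx + 1)
    ys = np.linspace(0.0, H, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    n00 = nid(I, J).ravel()
    n10 = nid(I + 1, J).ravel()
    n01 = nid(I, J + 1).ravel()
    n11 = nid(I + 1, J + 1).ravel()
    tris = np.vstack([
        np.column_stack([n00, n10, n11]),
        np.column_stack([n00, n11, n01]),
    ])

    # --- snap nodes to the two material boundary curves ---
    curves = unary_union([geom.lumen.boundary, geom.outer.boundary])
    pts = shapely.points(nodes)
    dist = shapely.distance(pts, curves)
    tol = 0.45 * min(hx, hy)
    cand = np.nonzero(dist < tol)[0]
    snapped = nodes.copy()
    moved = np.zeros(len(nodes), dtype=bool)
    for idx in cand:
        x, y = nodes[idx]
        on_x = x < 1e-12 or abs(x - W) < 1e-12
        on_y = y < 1e-12 or abs(y - H) < 1e-12
        if on_x and on_y:
            continue  # never move the corners
        target = nearest_points(curves, Point(x, y))[0]
        tx, ty = target.x, target.y
        if on_x:
            tx = x
        if on_y:
            ty = y
        if math.hypot(tx - x, ty - y) <= tol:
            snapped[idx] = (tx, ty)
            moved[idx] = True

    # --- revert snaps that degenerate triangles ---
    min_area = 0.1 * hx * hy / 2
    for _ in range(5):
        p0, p1, p2 = snapped[tris[:, 0]], snapped[tris[:, 1]], snapped[tris[:, 2]]
        area = 0.5 * ((p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1])
                      - (p1[:, 1] - p0[:, 1]) * (p2[:, 0] - p0[:, 0]))
        bad = area < min_area
        if not bad.any():
            break
        bad_nodes = np.unique(tris[bad])
        bad_nodes = bad_nodes[moved[bad_nodes]]
        if len(bad_nodes) == 0:
            raise GeometryError("meshing failure: degenerate triangle in background grid")
        snapped[bad_nodes] = nodes[bad_nodes]
        moved[bad_nodes] = False

    # --- classify triangles by centroid ---
    cen = snapped[tris].mean(axis=1)
    lum, out = geom.lumen, geom.outer
    shapely.prepare(lum)
    shapely.prepare(out)
    in_lum = shapely.contains_xy(lum, cen[:, 0], cen[:, 1])
    in_out = shapely.contains_xy(out, cen[:, 0], cen[:, 1])
    domain = np.full(len(tris), DOMAIN_RETINA, dtype=np.int8)
    domain[in_out] = DOMAIN_WALL
    domain[in_lum] = DOMAIN_BLOOD

    # --- edge adjacency, boundary + interface tags ---
    raw = np.concatenate([tris[:, [1, 2]], tris[:, [2, 0]], tris[:, [0, 1]]])
    raw_tri = np.tile(np.arange(len(tris)), 3)
    key = np.sort(raw, axis=1)
    edges_u, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    order = np.argsort(inv, kind="stable")
    # adjacency lists per unique edge
    tri_of = raw_tri[order]
    starts = np.searchsorted(inv[order], np.arange(len(edges_u)))

    bedges, btags, bedge_tri, iface_kind = [], [], [], []
    caps = {name: _cap_segment(p) for name, p in geom.ports.items()}
    for e in range(len(edges_u)):
        adj = tri_of[starts[e]:starts[e] + counts[e]]
        if counts[e] == 1:
            t0 = adj[0]
            mid = snapped[edges_u[e]].mean(axis=0)
            if domain[t0] == DOMAIN_BLOOD:
                tag = _match_port(mid, caps, 2 * max(hx, hy))
            else:
                tag = "outer"
            bedges.append(edges_u[e])
            btags.append(tag)
            bedge_tri.append(t0)
            iface_kind.append("")
        elif domain[adj[0]] != domain[adj[1]]:
            pair = sorted(domain[adj])
            if pair == [DOMAIN_WALL, DOMAIN_BLOOD]:
                kind = "blood-wall"
                keep = adj[0] if domain[adj[0]] == DOMAIN_BLOOD else adj[1]
            elif pair == [DOMAIN_RETINA, DOMAIN_WALL]:
                kind = "wall-retina"
                keep = adj[0] if domain[adj[0]] == DOMAIN_WALL else adj[1]
            else:
                raise GeometryError(
                    "lumen and retina are adjacent: wall does not separate the domains")
            bedges.append(edges_u[e])
            btags.append("interface")
            bedge_tri.append(keep)
            iface_kind.append(kind)

    ports_si = {
        name: Port(name, p.center * UM, p.outward, p.width * UM)
        for name, p in geom.ports.items()
    }
    mesh = DomainMesh(
        coords=snapped * UM,
        tris=tris,
        domain=domain,
        bedges=np.array(bedges, dtype=np.int64),
        btags=np.array(btags, dtype=object),
        bedge_tri=np.array(bedge_tri, dtype=np.int64),
        iface_kind=np.array(iface_kind, dtype=object),
        ports=ports_si,
        resolution_um=resolution,
        geometry=geom,
    )
    for name in geom.ports:
        if not np.any(mesh.btags == name):
            raise GeometryError(f"meshing failure: port '{name}' has no boundary edges")
    return mesh


def _cap_segment(port: Port):
    t = np.array([-port.outward[1], port.outward[0]])
    a = port.center - t * port.width / 2
    b = port.center + t * port.width / 2
    return LineString([a, b])


def _match_port(mid: np.ndarray, caps: dict, tol: float) -> str:
    best, best_d = None, math.inf
    p = Point(mid)
    for name, cap in caps.items():
        d = cap.distance(p)
        if d < best_d:
            best, best_d = name, d
    if best_d > tol:
        raise GeometryError("blood boundary edge not matched to any inlet/outlet cap")
    return best


# ---------------------------------------------------------------------------
# benchmark meshes (analytic-oracle domains)
# ---------------------------------------------------------------------------

def make_rect_mesh(width_um: float, height_um: float, nx: int, ny: int,
                   domain: str = "wall") -> DomainMesh:
    """Uniform rectangle mesh of a single solid domain, for patch tests.

    Boundary edges are tagged 'left', 'right', 'bottom', 'top'.
    """
    xs = np.linspace(0, width_um, nx + 1)
    ys = np.linspace(0, height_um, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    coords = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            tris.append([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1)])
            tris.append([nid(i, j), nid(i + 1, j + 1), nid(i, j + 1)])
    tris = np.array(tris)
    bedges, btags = [], []
    tri_lookup = _edge_to_tri(tris)
    for i in range(nx):
        bedges.append((nid(i, 0), nid(i + 1, 0))); btags.append("bottom")
        bedges.append((nid(i, ny), nid(i + 1, ny))); btags.append("top")
    for j in range(ny):
        bedges.append((nid(0, j), nid(0, j + 1))); btags.append("left")
        bedges.append((nid(nx, j), nid(nx, j + 1))); btags.append("right")
    btri = [tri_lookup[tuple(sorted(e))][0] for e in bedges]
    code = DOMAIN_CODES[domain]
    return DomainMesh(
        coords=coords * UM, tris=tris,
        domain=np.full(len(tris), code, dtype=np.int8),
        bedges=np.array(bedges, dtype=np.int64),
        btags=np.array(btags, dtype=object),
        bedge_tri=np.array(btri, dtype=np.int64),
        iface_kind=np.array([""] * len(bedges), dtype=object),
        ports={}, resolution_um=width_um / nx, geometry=None,
    )


def make_annulus_mesh(r_inner_um: float, r_outer_um: float, nr: int, ntheta: int) -> DomainMesh:
    """Structured annulus of wall material: the Lame thick-cylinder benchmark.

    Inner-ring edges are tagged 'interface' (pressure is applied there);
    outer-ring edges are tagged 'outer' (traction free).
    """
    r = np.linspace(r_inner_um, r_outer_um, nr + 1)
    th = np.linspace(0, 2 * math.pi, ntheta, endpoint=False)
    R, T = np.meshgrid(r, th, indexing="ij")
    coords = np.column_stack([(R * np.cos(T)).ravel(), (R * np.sin(T)).ravel()])

    def nid(i, j):
        return i * ntheta + (j % ntheta)

    tris = []
    for i in range(nr):
        for j in range(ntheta):
            tris.append([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1)])
            tris.append([nid(i, j), nid(i + 1, j + 1), nid(i, j + 1)])
    tris = np.array(tris)
    tri_lookup = _edge_to_tri(tris)
    bedges, btags = [], []
    for j in range(ntheta):
        bedges.append((nid(0, j), nid(0, j + 1))); btags.append("interface")
        bedges.append((nid(nr, j), nid(nr, j + 1))); btags.append("outer")
    btri = [tri_lookup[tuple(sorted(e))][0] for e in bedges]
    kinds = ["blood-wall" if t == "interface" else "" for t in btags]
    return DomainMesh(
        coords=coords * UM, tris=tris,
        domain=np.full(len(tris), DOMAIN_WALL, dtype=np.int8),
        bedges=np.array(bedges, dtype=np.int64),
        btags=np.array(btags, dtype=object),
        bedge_tri=np.array(btri, dtype=np.int64),
        iface_kind=np.array(kinds, dtype=object),
        ports={}, resolution_um=(r_outer_um - r_inner_um) / nr, geometry=None,
    )


def _edge_to_tri(tris: np.ndarray) -> dict:
    lookup: dict = {}
    for t, tri in enumerate(tris):
        for a, b in ((tri[1], tri[2]), (tri[2], tri[0]), (tri[0], tri[1])):
            lookup.setdefault(tuple(sorted((int(a), int(b)))), []).append(t)
    return lookup
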