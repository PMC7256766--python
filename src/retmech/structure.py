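"""Plane-strain linear elasticity of the vessel wall and retina.

The thin en-face retinal section is embedded in the globe, which resists
out-of-plane stretch, so plane strain is used: eps_zz = 0 and
sigma_zz = nu * (sigma_xx + sigma_yy) enters the von Mises stress.  Loads
are the fluid traction on the blood-wall interface and, during shaking,
an inertial body force F = rho * r * sign(omega) * omega^2 per unit
volume (r = chest-to-eye distance).  The outer box boundary of the solid
is clamped by default: the section is excised from continuous tissue.

Displacements are micrometre scale on a ~100 µm domain, so geometric
nonlinearity is neglected and superposition holds exactly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.tri import Triangulation, TrapezoidMapTriFinder

from . import fem
from .geometry import DOMAIN_RETINA, DOMAIN_WALL, DomainMesh


class StructureError(RuntimeError):
    pass


@dataclass(frozen=True)
class Material:
    density: float       # kg/m^3
    poisson: float
    youngs: float        # Pa

    def __post_init__(self):
        if not (0 < self.poisson < 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if self.youngs <= 0 or self.density <= 0:
            raise ValueError("modulus and density must be positive")


@dataclass(frozen=True)
class MaterialTable:
    """Tissue properties: retina/choroid, vessel wall, and blood density."""

    retina: Material = Material(density=1098.0, poisson=0.49, youngs=90_000.0)
    wall: Material = Material(density=1147.0, poisson=0.17, youngs=192_000.0)
    blood_density: float = 1057.0

    def for_domain(self, code: int) -> Material:
        return {DOMAIN_RETINA: self.retina, DOMAIN_WALL: self.wall}[code]


@dataclass(frozen=True)
class BodyLoad:
    """Inertial load from angular head motion.

    The force density applied to a domain of density rho is
    rho * r * sign(omega) * omega^2 along ``direction``.
    """

    chest_eye_distance: float       # m
    omega: float                    # rad/s
    direction: np.ndarray           # unit vector in the model plane

    def __post_init__(self):
        if self.chest_eye_distance <= 0:
            raise ValueError("chest-to-eye distance must be positive")
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-8):
            raise ValueError("direction must be a unit vector")

    def acceleration(self) -> np.ndarray:
        """Signed centripetal acceleration vector r*sign(w)*w^2 * d (m/s^2)."""
        return (self.chest_eye_distance * np.sign(self.omega) * self.omega ** 2
                * np.asarray(self.direction, dtype=float))


def body_force(load: BodyLoad, density: float) -> np.ndarray:
    """Force density (N/m^3) for a domain of the given mass density."""
    return density * load.acceleration()


def von_mises(sxx, syy, szz, sxy):
    """Equivalent (von Mises) stress from a symmetric tensor with sigma_zz."""
    return np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
                   + 3.0 * np.asarray(sxy) ** 2)


def _plane_strain_D(E: float, nu: float) -> np.ndarray:
    c = E / ((1 + nu) * (1 - 2 * nu))
    return c * np.array([
        [1 - nu, nu, 0.0],
        [nu, 1 - nu, 0.0],
        [0.0, 0.0, (1 - 2 * nu) / 2],
    ])


@dataclass
class StressField:
    """Solution of one elastostatic solve on the solid submesh."""

    sub: fem.SubMesh
    space: fem.P2Space
    u: np.ndarray            # (2*nn,) interleaved displacement dofs, m
    strain: np.ndarray       # (m, 3) exx, eyy, gxy at element centroids
    stress: np.ndarray       # (m, 4) sxx, syy, sxy, szz
    materials: MaterialTable

    D_elem: np.ndarray = None        # (m, 3, 3) per-element elasticity matrices
    nu_elem: np.ndarray = None       # (m,) per-element Poisson ratio

    def __post_init__(self):
        self._finder = None

    @property
    def displacement(self) -> np.ndarray:
        """Vertex displacements (nv, 2) in metres."""
        return self.u[: 2 * self.space.nv].reshape(-1, 2)

    @property
    def von_mises_e(self) -> np.ndarray:
        s = self.stress
        return von_mises(s[:, 0], s[:, 1], s[:, 3], s[:, 2])

    @property
    def vol_strain_e(self) -> np.ndarray:
        """Volumetric strain per element (eps_zz = 0 in plane strain)."""
        return self.strain[:, 0] + self.strain[:, 1]

    def _locate(self, points: np.ndarray):
        if self._finder is None:
            tr = Triangulation(self.sub.coords[:, 0], self.sub.coords[:, 1], self.sub.tris)
            self._finder = TrapezoidMapTriFinder(tr)
        pts = np.atleast_2d(points)
        tri = self._finder(pts[:, 0], pts[:, 1])
        if np.any(tri < 0):
            bad = np.nonzero(tri < 0)[0]
            raise StructureError(f"point(s) {bad.tolist()} lie outside the solid domain")
        return pts, tri

    def _point_stress(self, p: np.ndarray, t: int, lam: np.ndarray) -> np.ndarray:
        """(sxx, syy, sxy, szz, vol) from element t's quadratic field."""
        eps = fem.strain_single(self.space, self.u, t, lam)
        s3 = self.D_elem[t] @ eps
        return np.array([s3[0], s3[1], s3[2],
                         self.nu_elem[t] * (s3[0] + s3[1]), eps[0] + eps[1]])

    def state_at(self, points: np.ndarray, probe_radius: float = 0.0) -> dict:
        """Stress tensor, displacement and volumetric strain at points.

        With ``probe_radius`` = 0 strains come from the quadratic
        displacement field of the containing element (pointwise, unbiased
        at boundaries).  A positive radius reports the average of the
        pointwise stress over a fixed 17-point disc (center plus two rings
        of 8), restricted to sampling points landing in the center point's
        domain: a through-thickness-representative probe that is stable
        against the steep stress gradient across the thin wall.
        Displacement is always pointwise.
        """
        pts, tri = self._locate(points)
        offsets = [np.zeros(2)]
        for frac in (0.5, 1.0):
            for k in range(8):
                a = 2 * np.pi * k / 8
                offsets.append(probe_radius * frac * np.array([np.cos(a), np.sin(a)]))
        out = {k: np.empty(len(pts)) for k in ("sxx", "syy", "sxy", "szz", "vol", "ux", "uy")}
        for i, (p, t) in enumerate(zip(pts, tri)):
            t = int(t)
            verts = self.sub.tris[t]
            lam = _bary(self.sub.coords[verts], p)
            if probe_radius > 0:
                acc, nacc = np.zeros(5), 0
                for off in offsets:
                    q = p + off
                    try:
                        _, tq = self._locate(q[None, :])
                    except StructureError:
                        continue
                    tq = int(tq[0])
                    if self.sub.domain[tq] != self.sub.domain[t]:
                        continue
                    lamq = _bary(self.sub.coords[self.sub.tris[tq]], q)
                    acc += self._point_stress(q, tq, lamq)
                    nacc += 1
                s = acc / nacc
            else:
                s = self._point_stress(p, t, lam)
            out["sxx"][i], out["syy"][i], out["sxy"][i], out["szz"][i], out["vol"][i] = s
            N = fem.p2_shape(lam[None, :])[0]
            dofs = self.space.conn[t]
            out["ux"][i] = N @ self.u[2 * dofs]
            out["uy"][i] = N @ self.u[2 * dofs + 1]
        return out

    def export_csv(self, path) -> None:
        with open(path, "w") as f:
            f.write("x_m,y_m,domain,sxx,syy,sxy,szz,von_mises,vol_strain\n")
            cen = self.sub.coords[self.sub.tris].mean(axis=1)
            vm = self.von_mises_e
            vol = self.vol_strain_e
            for i in range(len(self.sub.tris)):
                s = self.stress[i]
                f.write(f"{cen[i, 0]:.9e},{cen[i, 1]:.9e},{self.sub.domain[i]},"
                        f"{s[0]:.6e},{s[1]:.6e},{s[2]:.6e},{s[3]:.6e},"
                        f"{vm[i]:.6e},{vol[i]:.6e}\n")


def _bary(tri_coords: np.ndarray, p: np.ndarray) -> np.ndarray:
    T = np.column_stack([tri_coords[1] - tri_coords[0], tri_coords[2] - tri_coords[0]])
    l12 = np.linalg.solve(T, p - tri_coords[0])
    return np.array([1 - l12.sum(), l12[0], l12[1]])


def solve_elasticity(mesh: DomainMesh, materials: MaterialTable = MaterialTable(),
                     traction=None, body: BodyLoad | None = None,
                     anchors="outer") -> StressField:
    """Plane-strain solve on the wall + retina domains.

    traction: EdgeLoad (global vertex pairs + Pa vectors), typically from
    hemodynamics.wall_traction.
    anchors: 'outer' clamps every solid node on edges tagged 'outer';
    alternatively a list of (predicate(x, y) -> bool mask, comps) pairs
    with comps a subset of 'xy', evaluated on P2 node coordinates.
    """
    sub = fem.extract_submesh(mesh.coords, mesh.tris, mesh.domain,
                              [DOMAIN_RETINA, DOMAIN_WALL])
    if len(sub.tris) == 0:
        raise StructureError("mesh has no solid domain")
    space = fem.P2Space(sub.coords, sub.tris)
    nn = space.nn

    D = np.empty((len(sub.tris), 3, 3))
    for code in (DOMAIN_RETINA, DOMAIN_WALL):
        m = sub.domain == code
        if m.any():
            mat = materials.for_domain(code)
            D[m] = _plane_strain_D(mat.youngs, mat.poisson)
    K = fem.assemble_strain_stiffness(space, D)

    rhs = np.zeros(2 * nn)
    if traction is not None and len(traction.edges):
        ledges = sub.to_local(traction.edges)
        rhs += fem.assemble_edge_load(space, ledges, np.asarray(traction.tractions))
    if body is not None:
        acc = body.acceleration()
        rho = np.array([materials.for_domain(int(c)).density for c in sub.domain])
        rhs += fem.assemble_body_load(space, rho[:, None] * acc[None, :])

    fixed_dofs, fixed_vals = _anchor_dofs(mesh, sub, space, anchors)
    if len(fixed_dofs) < 3:
        raise StructureError(
            "anchors do not prevent rigid-body motion: fix at least three "
            "displacement components (e.g. anchors='outer')")
    A, b = fem.apply_dirichlet(K, rhs, fixed_dofs, fixed_vals)
    u = fem.solve_sparse(A, b, spd=True)
    if not np.all(np.isfinite(u)):
        raise StructureError("singular stiffness: solve produced non-finite displacements")

    strain = fem.strain_at_centroid(space, u)
    stress = np.empty((len(sub.tris), 4))
    s3 = np.einsum("mab,mb->ma", D, strain)
    stress[:, 0], stress[:, 1], stress[:, 2] = s3[:, 0], s3[:, 1], s3[:, 2]
    nu = np.array([materials.for_domain(int(c)).poisson for c in sub.domain])
    stress[:, 3] = nu * (stress[:, 0] + stress[:, 1])
    return StressField(sub, space, u, strain, stress, materials,
                       D_elem=D, nu_elem=nu)


def _anchor_dofs(mesh: DomainMesh, sub: fem.SubMesh, space: fem.P2Space, anchors):
    nodes_xy = space.node_coords
    fixed = []
    if isinstance(anchors, str):
        if anchors != "outer":
            raise ValueError(f"unknown anchor spec '{anchors}'")
        outer_edges = mesh.bedges[mesh.btags == "outer"]
        sel = set()
        for ga, gb in outer_edges:
            la, lb = sub.to_local(np.array([ga, gb]))
            m = space.midnode(np.array([la]), np.array([lb]))[0]
            sel.update((int(la), int(lb), int(m)))
        for n in sorted(sel):
            fixed.extend([2 * n, 2 * n + 1])
    else:
        for predicate, comps in anchors:
            mask = predicate(nodes_xy[:, 0], nodes_xy[:, 1])
            for n in np.nonzero(mask)[0]:
                if "x" in comps:
                    fixed.append(2 * n)
                if "y" in comps:
                    fixed.append(2 * n + 1)
    fixed = np.unique(np.array(fixed, dtype=np.int64))
    return fixed, np.zeros(len(fixed))


@dataclass
class PoiMetrics:
    """Stress metrics at the four probe points."""

    von_mises: np.ndarray        # (4,) Pa
    displacement_um: np.ndarray  # (4,) µm
    vol_strain: np.ndarray       # (4,) signed (negative = compression)

    @classmethod
    def from_state(cls, state: dict) -> "PoiMetrics":
        vm = von_mises(state["sxx"], state["syy"], state["szz"], state["sxy"])
        disp = np.hypot(state["ux"], state["uy"]) / 1e-6
        return cls(vm, disp, state["vol"].copy())


@dataclass
class SweepPoiMetrics:
    """Per-POI maximum and average over a quasi-static load sweep.

    Volumetric strain is compressive throughout; max/average are taken on
    magnitudes and reported with the negative sign restored.
    """

    max: PoiMetrics
    avg: PoiMetrics

    @classmethod
    def reduce(cls, steps: list) -> "SweepPoiMetrics":
        vm = np.array([s.von_mises for s in steps])
        disp = np.array([s.displacement_um for s in steps])
        vol = np.array([s.vol_strain for s in steps])
        sgn = np.where(np.mean(vol, axis=0) < 0, -1.0, 1.0)
        mag = np.abs(vol)
        mx = PoiMetrics(vm.max(axis=0), disp.max(axis=0), sgn * mag.max(axis=0))
        av = PoiMetrics(vm.mean(axis=0), disp.mean(axis=0), sgn * mag.mean(axis=0))
        return cls(mx, av)


def sample_pois(field: StressField, pois_m: np.ndarray,
                probe_radius: float = 0.0) -> PoiMetrics:
    """Interpolate the stress metrics at the POIs (coordinates in metres)."""
    return PoiMetrics.from_state(field.state_at(np.asarray(pois_m), probe_radius))
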