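"""Steady generalized-Newtonian flow on the blood domain.

Blood is shear thinning; its dynamic viscosity follows the power law
mu = K * gamma_dot**e with K = 28.52 mPa*s (at unit shear rate) and
e = -0.385.  The consistency is interpreted in mPa*s: at 100 1/s this
gives ~4.8 mPa*s, physiologic for whole blood, whereas Pa*s would be off
by three orders of magnitude.  Inertia is neglected (Re << 1 at the
100 µm / cm-per-second scale of retinal arterioles), so the momentum
balance is a Stokes problem whose viscosity is updated by Picard
iteration on the shear-rate field.

Discretization: Taylor-Hood P2 velocity / P1 pressure on the blood
submesh.  Prescribed port pressures enter as natural boundary tractions
-p*n; prescribed port velocities are parabolic Dirichlet profiles;
vessel-wall (interface) edges are no slip.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import fem
from .geometry import DOMAIN_BLOOD, DomainMesh


class FlowError(RuntimeError):
    pass


@dataclass(frozen=True)
class ViscosityLaw:
    """Power-law rheology mu = K * gamma_dot**e.

    consistency_mpa_s: K in mPa*s at gamma_dot = 1/s.
    exponent: e (negative: shear thinning; 0 recovers a Newtonian fluid).
    shear_clamp: gamma_dot is clamped into this band (1/s) before the
    power is evaluated, the standard regularization of the power-law
    singularity at vanishing shear.
    """

    consistency_mpa_s: float = 28.52
    exponent: float = -0.385
    shear_clamp: tuple = (1.0, 1.0e4)

    def __post_init__(self):
        if self.consistency_mpa_s <= 0:
            raise ValueError("consistency must be positive")
        if self.exponent > 0:
            raise ValueError("exponent must be <= 0 for a shear-thinning law")
        if self.shear_clamp[0] <= 0:
            raise ValueError("lower shear clamp must be positive")


def viscosity(shear_rate, law: ViscosityLaw = ViscosityLaw()):
    """Dynamic viscosity in Pa*s at the given shear rate(s) in 1/s."""
    g = np.clip(np.asarray(shear_rate, dtype=float), *law.shear_clamp)
    return law.consistency_mpa_s * 1e-3 * g ** law.exponent


@dataclass(frozen=True)
class PortBC:
    """Boundary condition at one tagged port.

    kind 'pressure': value in Pa, applied as uniform normal traction.
    kind 'velocity': mean normal speed in m/s with a parabolic profile;
    positive means flow through the port in its natural direction
    (into the domain at i1, out of the domain at outlets).
    """

    kind: str
    value: float

    def __post_init__(self):
        if self.kind not in ("pressure", "velocity"):
            raise ValueError(f"unknown BC kind '{self.kind}'")


@dataclass
class FlowBC:
    ports: dict                       # tag -> PortBC
    body_force: np.ndarray | None = None   # (2,) N/m^3 on the blood domain

    def validate(self, mesh: DomainMesh) -> None:
        names = mesh.port_names()
        missing = [n for n in names if n not in self.ports]
        if missing:
            raise FlowError(f"no boundary condition for port(s) {missing}")
        extra = [n for n in self.ports if n not in names]
        if extra:
            raise FlowError(f"boundary condition references unknown port(s) {extra}")


@dataclass
class FlowField:
    """Converged flow solution on the blood submesh."""

    sub: fem.SubMesh
    space: fem.P2Space
    u: np.ndarray              # (2*nn,) interleaved P2 velocity dofs, m/s
    p: np.ndarray              # (nv,) P1 pressure, Pa
    shear_rate: np.ndarray     # (m,) 1/s per element
    visc: np.ndarray           # (m,) Pa*s per element
    iterations: int
    port_edge_map: dict = field(default_factory=dict)  # tag -> (local edges, outward normal)

    @property
    def velocity(self) -> np.ndarray:
        """Vertex velocities (nv, 2)."""
        return self.u[: 2 * self.sub.coords.shape[0]].reshape(-1, 2)

    @property
    def pressure(self) -> np.ndarray:
        return self.p

    def port_flux(self, tag: str) -> float:
        """Volumetric outflow (per unit depth, m^2/s) through a port."""
        edges, n_out = self.port_edge_map[tag]
        total = 0.0
        for a, b in edges:
            m = self.space.midnode(np.array([a]), np.array([b]))[0]
            L = float(np.linalg.norm(self.space.coords[b] - self.space.coords[a]))
            un = [self.u[2 * k] * n_out[0] + self.u[2 * k + 1] * n_out[1] for k in (a, b, m)]
            total += L * (un[0] + un[1] + 4 * un[2]) / 6
        return total

    def mass_balance(self) -> float:
        """|net outflow| / gross throughflow across all ports (0 if static)."""
        fluxes = list(self.port_flux(t) for t in self.port_edge_map)
        gross = 0.5 * sum(abs(f) for f in fluxes)
        if gross < 1e-15:
            return 0.0
        return abs(sum(fluxes)) / gross

    def export_csv(self, path) -> None:
        with open(path, "w") as f:
            f.write("x_m,y_m,u_m_s,v_m_s,p_pa\n")
            v = self.velocity
            for i, (x, y) in enumerate(self.sub.coords):
                f.write(f"{x:.9e},{y:.9e},{v[i, 0]:.9e},{v[i, 1]:.9e},{self.p[i]:.9e}\n")


def _shear_rate(space: fem.P2Space, u: np.ndarray) -> np.ndarray:
    """gamma_dot = sqrt(2 eps:eps) per element at the centroid."""
    e = fem.strain_at_centroid(space, u)       # exx, eyy, gxy (= 2 exy)
    return np.sqrt(2 * e[:, 0] ** 2 + 2 * e[:, 1] ** 2 + e[:, 2] ** 2)


def _viscous_D(mu: np.ndarray) -> np.ndarray:
    D = np.zeros((len(mu), 3, 3))
    D[:, 0, 0] = 2 * mu
    D[:, 1, 1] = 2 * mu
    D[:, 2, 2] = mu
    return D


def _parabolic_values(space: fem.P2Space, edges_local: np.ndarray, port, mean_speed: float,
                      sign: float) -> dict:
    """Dirichlet velocity values for all P2 nodes on a port's edges."""
    t_hat = np.array([-port.outward[1], port.outward[0]])
    vals = {}
    nodes = set()
    for a, b in edges_local:
        m = space.midnode(np.array([a]), np.array([b]))[0]
        nodes.update((int(a), int(b), int(m)))
    # profile spans the actual meshed port chord (oblique ports are wider
    # than the nominal lumen width)
    svals = {n: float(space.node_coords[n] @ t_hat) for n in nodes}
    smin, smax = min(svals.values()), max(svals.values())
    mid, half = 0.5 * (smin + smax), 0.5 * (smax - smin)
    for n in nodes:
        xi = np.clip((svals[n] - mid) / half, -1.0, 1.0)
        speed = 1.5 * mean_speed * (1 - xi * xi)
        vals[n] = sign * speed * port.outward
    return vals


def solve_flow(mesh: DomainMesh, bc: FlowBC, law: ViscosityLaw = ViscosityLaw(),
               tol: float = 1e-6, max_iter: int = 100) -> FlowField:
    """Solve steady power-law Stokes flow on the blood domain.

    Picard iteration: assemble with the current element viscosities,
    solve the linear saddle problem, update viscosities from the new
    shear-rate field, and stop when the relative L2 change of the
    viscosity field drops below ``tol``.
    """
    bc.validate(mesh)
    sub = fem.extract_submesh(mesh.coords, mesh.tris, mesh.domain, [DOMAIN_BLOOD])
    if len(sub.tris) == 0:
        raise FlowError("mesh has no blood domain")
    space = fem.P2Space(sub.coords, sub.tris)
    nv, nn = space.nv, space.nn

    # no-slip on the blood-wall interface
    iface_edges, _ = mesh.blood_wall_edges()
    iface_local = sub.to_local(iface_edges)
    dir_vals: dict = {}
    for a, b in iface_local:
        m = space.midnode(np.array([a]), np.array([b]))[0]
        for n in (int(a), int(b), int(m)):
            dir_vals[n] = np.zeros(2)

    neumann_rhs = np.zeros(2 * nn)
    port_edge_map = {}
    has_pressure_bc = False
    tangential_pins: set = set()
    for tag, pbc in bc.ports.items():
        gedges, _ = mesh.edges_with_tag(tag)
        ledges = sub.to_local(gedges)
        port = mesh.ports[tag]
        port_edge_map[tag] = (ledges, port.outward)
        if pbc.kind == "pressure":
            has_pressure_bc = True
            trac = np.tile(-pbc.value * port.outward, (len(ledges), 1))
            neumann_rhs += fem.assemble_edge_load(space, ledges, trac)
            # no tangential flow across a pressure port: the normal-direction
            # natural condition then imposes exactly sigma_nn = -p
            tang_comp = 1 if abs(port.outward[0]) > abs(port.outward[1]) else 0
            for a, b in ledges:
                m = space.midnode(np.array([a]), np.array([b]))[0]
                for n in (int(a), int(b), int(m)):
                    if n not in dir_vals:
                        tangential_pins.add(2 * n + tang_comp)
        else:
            sign = -1.0 if tag == "i1" else 1.0
            vals = _parabolic_values(space, ledges, port, pbc.value, sign)
            # wall-adjacent cap corners keep no-slip
            for n, v in vals.items():
                if n not in dir_vals:
                    dir_vals[n] = v

    if not has_pressure_bc:
        imposed = 0.0
        for tag, pbc in bc.ports.items():
            if pbc.kind == "velocity":
                sign = -1.0 if tag == "i1" else 1.0
                imposed += sign * pbc.value * mesh.ports[tag].width
        if abs(imposed) > 1e-12 * max(abs(p.value) * mesh.ports[t].width
                                      for t, p in bc.ports.items()):
            raise FlowError(
                "all-velocity boundary conditions with nonzero net flux are inconsistent")

    body_rhs = np.zeros(2 * nn)
    if bc.body_force is not None:
        f = np.tile(np.asarray(bc.body_force, dtype=float), (len(sub.tris), 1))
        body_rhs = fem.assemble_body_load(space, f)

    Bdiv = fem.assemble_divergence(space)
    ndof = 2 * nn + nv
    fixed_u = np.array(sorted(dir_vals), dtype=np.int64)
    fixed_dofs = np.concatenate([2 * fixed_u, 2 * fixed_u + 1])
    fixed_vals = np.concatenate([
        np.array([dir_vals[n][0] for n in fixed_u]),
        np.array([dir_vals[n][1] for n in fixed_u]),
    ])
    pins = np.array(sorted(tangential_pins.difference(fixed_dofs)), dtype=np.int64)
    fixed_dofs = np.concatenate([fixed_dofs, pins])
    fixed_vals = np.concatenate([fixed_vals, np.zeros(len(pins))])
    if not has_pressure_bc:
        fixed_dofs = np.append(fixed_dofs, 2 * nn)  # pressure gauge at vertex 0
        fixed_vals = np.append(fixed_vals, 0.0)

    mu = np.full(len(sub.tris), float(viscosity(100.0, law)))
    u = np.zeros(2 * nn)
    p = np.zeros(nv)
    iterations = 0
    for it in range(1, max_iter + 1):
        K = fem.assemble_strain_stiffness(space, _viscous_D(mu))
        A = sp.bmat([[K, -Bdiv.T], [-Bdiv, None]], format="csr")
        rhs = np.concatenate([neumann_rhs + body_rhs, np.zeros(nv)])
        A, rhs = fem.apply_dirichlet(A, rhs, fixed_dofs, fixed_vals)
        sol = fem.solve_sparse(A, rhs)
        u, p = sol[: 2 * nn], sol[2 * nn:]
        gdot = _shear_rate(space, u)
        mu_new = viscosity(gdot, law)
        rel = np.linalg.norm(mu_new - mu) / np.linalg.norm(mu)
        mu = mu_new
        iterations = it
        if rel < tol:
            break
    else:
        raise FlowError(
            f"Picard iteration did not converge in {max_iter} iterations "
            f"(last relative viscosity change {rel:.3e})")

    flow = FlowField(sub, space, u, p, _shear_rate(space, u), mu, iterations, port_edge_map)
    mb = flow.mass_balance()
    if mb > 1e-3:
        warnings.warn(f"mass balance violated: |net|/inflow = {mb:.2e}", stacklevel=2)
    return flow


@dataclass
class EdgeLoad:
    """Traction vectors on explicit solid boundary edges (global node ids)."""

    edges: np.ndarray       # (k, 2) global vertex pairs
    tractions: np.ndarray   # (k, 2) Pa


def wall_traction(flow: FlowField, mesh: DomainMesh) -> EdgeLoad:
    """Fluid stress traction on every blood-wall interface edge.

    t = (-p I + 2 mu eps(u)) . n evaluated on the blood side at the edge
    midpoint, with n the outward normal of the fluid domain; this is the
    load the fluid transmits to the vessel wall.
    """
    edges, blood_tris = mesh.blood_wall_edges()
    sub, space = flow.sub, flow.space
    local_tri = {int(g): l for l, g in enumerate(sub.tri_map)}
    tractions = np.empty((len(edges), 2))
    for k, ((ga, gb), gt) in enumerate(zip(edges, blood_tris)):
        lt = local_tri[int(gt)]
        la, lb = sub.to_local(np.array([ga, gb]))
        a, b = sub.coords[la], sub.coords[lb]
        mid = 0.5 * (a + b)
        # outward normal: away from the blood triangle centroid
        cen = sub.coords[sub.tris[lt]].mean(axis=0)
        e = b - a
        n = np.array([e[1], -e[0]])
        n /= np.linalg.norm(n)
        if n @ (mid - cen) < 0:
            n = -n
        # pressure interpolated linearly at the midpoint
        lam = _barycentric(sub.coords[sub.tris[lt]], mid)
        p_mid = float(lam @ flow.p[sub.tris[lt]])
        mu = flow.visc[lt]
        exx, eyy, gxy = fem.strain_single(space, flow.u, lt, lam)
        sxx = -p_mid + 2 * mu * exx
        syy = -p_mid + 2 * mu * eyy
        sxy = mu * gxy
        tractions[k] = (sxx * n[0] + sxy * n[1], sxy * n[0] + syy * n[1])
    return EdgeLoad(edges=np.asarray(edges), tractions=tractions)


def _barycentric(tri_coords: np.ndarray, p: np.ndarray) -> np.ndarray:
    T = np.column_stack([tri_coords[1] - tri_coords[0], tri_coords[2] - tri_coords[0]])
    l12 = np.linalg.solve(T, p - tri_coords[0])
    return np.array([1 - l12.sum(), l12[0], l12[1]])
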