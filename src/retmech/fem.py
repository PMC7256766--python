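"""Shared finite-element machinery on unstructured triangle meshes.

Quadratic (P2) Lagrange elements for vector fields (velocity, displacement)
and linear (P1) elements for pressure, assembled with vectorized numpy and
scipy.sparse.  Degrees of freedom for vector fields are interleaved
(ux0, uy0, ux1, uy1, ...).  All lengths are SI metres.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

# 3-point midpoint quadrature rule, exact for quadratics: sufficient for
# P2 stiffness (linear gradients), the P2/P1 divergence coupling, and
# element-constant body loads.
QUAD_LAM = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])
QUAD_W = np.array([1.0, 1.0, 1.0]) / 3.0

# local edges, edge k opposite local vertex k
LOCAL_EDGES = ((1, 2), (2, 0), (0, 1))


def tri_geometry(coords: np.ndarray, tris: np.ndarray):
    """Signed areas and barycentric-function gradients per triangle.

    Returns (areas (m,), grad_lam (m, 3, 2)).
    """
    p0, p1, p2 = (coords[tris[:, k]] for k in range(3))
    d1, d2 = p1 - p0, p2 - p0
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    areas = 0.5 * det
    g = np.empty((len(tris), 3, 2))
    # grad lam_i = rot90(opposite edge) / (2A)
    g[:, 0, 0] = p1[:, 1] - p2[:, 1]
    g[:, 0, 1] = p2[:, 0] - p1[:, 0]
    g[:, 1, 0] = p2[:, 1] - p0[:, 1]
    g[:, 1, 1] = p0[:, 0] - p2[:, 0]
    g[:, 2, 0] = p0[:, 1] - p1[:, 1]
    g[:, 2, 1] = p1[:, 0] - p0[:, 0]
    g /= det[:, None, None]
    return areas, g


def build_edge_table(tris: np.ndarray):
    """Unique undirected edges and the per-triangle edge indices.

    Returns (edges (ne, 2) with sorted node pairs, tri_edges (m, 3)) where
    tri_edges[t, k] is the edge opposite local vertex k.
    """
    raw = np.concatenate([tris[:, list(e)] for e in LOCAL_EDGES])
    raw = np.sort(raw, axis=1)
    edges, inv = np.unique(raw, axis=0, return_inverse=True)
    tri_edges = inv.reshape(3, -1).T
    return edges, tri_edges


@dataclass
class P2Space:
    """Quadratic Lagrange space: vertex nodes followed by edge-midpoint nodes."""

    coords: np.ndarray            # (nv, 2) vertex coords
    tris: np.ndarray              # (m, 3)
    edges: np.ndarray = field(init=False)
    tri_edges: np.ndarray = field(init=False)
    conn: np.ndarray = field(init=False)        # (m, 6) P2 connectivity
    node_coords: np.ndarray = field(init=False)  # (nn, 2) all P2 nodes
    areas: np.ndarray = field(init=False)
    grad_lam: np.ndarray = field(init=False)

    def __post_init__(self):
        self.edges, self.tri_edges = build_edge_table(self.tris)
        nv = len(self.coords)
        self.conn = np.hstack([self.tris, nv + self.tri_edges])
        mids = 0.5 * (self.coords[self.edges[:, 0]] + self.coords[self.edges[:, 1]])
        self.node_coords = np.vstack([self.coords, mids])
        self.areas, self.grad_lam = tri_geometry(self.coords, self.tris)
        if np.any(self.areas <= 0):
            raise ValueError("mesh contains non-positively oriented triangles")

    @property
    def nv(self) -> int:
        return len(self.coords)

    @property
    def nn(self) -> int:
        return len(self.node_coords)

    def midnode(self, n0: np.ndarray, n1: np.ndarray) -> np.ndarray:
        """P2 node index of the midpoint of vertex pair(s) (n0, n1)."""
        pairs = np.sort(np.column_stack([np.atleast_1d(n0), np.atleast_1d(n1)]), axis=1)
        # locate rows in the sorted-unique edge table
        idx = np.searchsorted(
            self.edges[:, 0] * (self.nv + 1) + self.edges[:, 1],
            pairs[:, 0] * (self.nv + 1) + pairs[:, 1],
        )
        ok = (idx < len(self.edges)) & np.all(self.edges[np.minimum(idx, len(self.edges) - 1)] == pairs, axis=1)
        if not np.all(ok):
            raise KeyError("edge not present in mesh")
        return self.nv + idx


def p2_shape(lam: np.ndarray) -> np.ndarray:
    """P2 shape function values at barycentric points lam (nq, 3) -> (nq, 6)."""
    l0, l1, l2 = lam[:, 0], lam[:, 1], lam[:, 2]
    return np.column_stack([
        l0 * (2 * l0 - 1), l1 * (2 * l1 - 1), l2 * (2 * l2 - 1),
        4 * l1 * l2, 4 * l2 * l0, 4 * l0 * l1,
    ])


def p2_grads(lam: np.ndarray, grad_lam: np.ndarray) -> np.ndarray:
    """Gradients of the 6 P2 shape functions.

    lam (nq, 3); grad_lam (m, 3, 2) -> (m, nq, 6, 2).
    """
    m = grad_lam.shape[0]
    nq = lam.shape[0]
    g = np.empty((m, nq, 6, 2))
    for i in range(3):
        g[:, :, i, :] = (4 * lam[None, :, i, None] - 1) * grad_lam[:, None, i, :]
    for k, (i, j) in enumerate(LOCAL_EDGES):
        g[:, :, 3 + k, :] = 4 * (
            lam[None, :, i, None] * grad_lam[:, None, j, :]
            + lam[None, :, j, None] * grad_lam[:, None, i, :]
        )
    return g


def _strain_B(space: P2Space, lam: np.ndarray) -> np.ndarray:
    """Voigt strain-displacement matrices (m, nq, 3, 12); rows exx, eyy, gxy."""
    G = p2_grads(lam, space.grad_lam)
    m, nq = G.shape[:2]
    B = np.zeros((m, nq, 3, 12))
    B[:, :, 0, 0::2] = G[..., 0]
    B[:, :, 1, 1::2] = G[..., 1]
    B[:, :, 2, 0::2] = G[..., 1]
    B[:, :, 2, 1::2] = G[..., 0]
    return B


def vector_dofs(space: P2Space) -> np.ndarray:
    """Interleaved dof indices per element (m, 12)."""
    c = space.conn
    d = np.empty((c.shape[0], 12), dtype=np.int64)
    d[:, 0::2] = 2 * c
    d[:, 1::2] = 2 * c + 1
    return d


def assemble_strain_stiffness(space: P2Space, D: np.ndarray) -> sp.csr_matrix:
    """Stiffness for the symmetric-gradient form with per-element 3x3 Voigt D.

    Integrates B^T D B; D may encode viscosity (2*mu*diag(1,1,0.5)) or a
    plane-strain elasticity matrix.
    """
    B = _strain_B(space, QUAD_LAM)
    Ke = np.einsum("q,mqai,mab,mqbj->mij", QUAD_W, B, D, B, optimize=True)
    Ke *= space.areas[:, None, None]
    dofs = vector_dofs(space)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n = 2 * space.nn
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def assemble_divergence(space: P2Space) -> sp.csr_matrix:
    """Mixed matrix Bdiv (nv x 2nn): Bdiv[a, j] = int lam_a div N_j."""
    G = p2_grads(QUAD_LAM, space.grad_lam)
    m, nq = G.shape[:2]
    div = np.zeros((m, nq, 12))
    div[:, :, 0::2] = G[..., 0]
    div[:, :, 1::2] = G[..., 1]
    Ce = np.einsum("q,qa,mqj->maj", QUAD_W, QUAD_LAM, div, optimize=True)
    Ce *= space.areas[:, None, None]
    dofs = vector_dofs(space)
    rows = np.repeat(space.tris, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 3)).ravel()
    return sp.coo_matrix((Ce.ravel(), (rows, cols)), shape=(space.nv, 2 * space.nn)).tocsr()


def assemble_body_load(space: P2Space, f_elem: np.ndarray) -> np.ndarray:
    """RHS for per-element constant force density f_elem (m, 2) -> (2nn,)."""
    N = p2_shape(QUAD_LAM)                      # (nq, 6)
    w_n = QUAD_W @ N                            # integral of each N over ref tri
    contrib = space.areas[:, None, None] * w_n[None, :, None] * f_elem[:, None, :]
    rhs = np.zeros(2 * space.nn)
    np.add.at(rhs, 2 * space.conn, contrib[..., 0])
    np.add.at(rhs, 2 * space.conn + 1, contrib[..., 1])
    return rhs


def assemble_edge_load(space: P2Space, edges: np.ndarray, tractions: np.ndarray) -> np.ndarray:
    """RHS for constant traction per boundary edge (Simpson on P2 edges).

    edges (k, 2) vertex pairs; tractions (k, 2) Pa.  Per edge of length L the
    consistent load is L/6 at each vertex and 2L/3 at the midpoint node.
    """
    rhs = np.zeros(2 * space.nn)
    if len(edges) == 0:
        return rhs
    edges = np.asarray(edges)
    L = np.linalg.norm(space.coords[edges[:, 1]] - space.coords[edges[:, 0]], axis=1)
    mid = space.midnode(edges[:, 0], edges[:, 1])
    for c in range(2):
        np.add.at(rhs, 2 * edges[:, 0] + c, L / 6 * tractions[:, c])
        np.add.at(rhs, 2 * edges[:, 1] + c, L / 6 * tractions[:, c])
        np.add.at(rhs, 2 * mid + c, 2 * L / 3 * tractions[:, c])
    return rhs


def strain_single(space: P2Space, u: np.ndarray, tri: int, lam: np.ndarray) -> np.ndarray:
    """Voigt strain (exx, eyy, gxy) of one element at barycentric point lam."""
    G = p2_grads(lam[None, :], space.grad_lam[tri:tri + 1])[0, 0]   # (6, 2)
    dofs = vector_dofs(space)[tri]
    ue = u[dofs]
    ux = ue[0::2] @ G
    uy = ue[1::2] @ G
    return np.array([ux[0], uy[1], ux[1] + uy[0]])


def strain_at_centroid(space: P2Space, u: np.ndarray) -> np.ndarray:
    """Voigt strains (exx, eyy, gxy) per element at the centroid from dofs u."""
    lam = np.array([[1 / 3, 1 / 3, 1 / 3]])
    B = _strain_B(space, lam)[:, 0]             # (m, 3, 12)
    ue = u[vector_dofs(space)]                  # (m, 12)
    return np.einsum("maj,mj->ma", B, ue)


def apply_dirichlet(A: sp.spmatrix, rhs: np.ndarray, fixed: np.ndarray, values: np.ndarray):
    """Eliminate Dirichlet dofs symmetrically; returns (A_mod csr, rhs_mod)."""
    A = A.tocsr()
    n = A.shape[0]
    x0 = np.zeros(n)
    x0[fixed] = values
    rhs = rhs - A @ x0
    keep = np.ones(n, dtype=bool)
    keep[fixed] = False
    d = sp.diags(keep.astype(float))
    A = d @ A @ d + sp.diags((~keep).astype(float))
    rhs[fixed] = values
    return A.tocsr(), rhs


def solve_sparse(A: sp.spmatrix, rhs: np.ndarray, spd: bool = False) -> np.ndarray:
    """Direct sparse solve; SPD stiffness matrices factor faster under MMD
    ordering while the indefinite Stokes saddle prefers COLAMD."""
    perm = "MMD_AT_PLUS_A" if spd else "COLAMD"
    return spla.spsolve(A.tocsc(), rhs, permc_spec=perm)


@dataclass
class SubMesh:
    """A domain-restricted view of a DomainMesh with local numbering."""

    coords: np.ndarray      # (nvs, 2)
    tris: np.ndarray        # (ms, 3) local indices
    vmap: np.ndarray        # local vertex -> global vertex
    tri_map: np.ndarray     # local tri -> global tri
    domain: np.ndarray      # (ms,) domain code per triangle
    _g2l: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._g2l = {g: l for l, g in enumerate(self.vmap)}

    def to_local(self, global_nodes: np.ndarray) -> np.ndarray:
        out = np.array([self._g2l[int(g)] for g in np.ravel(global_nodes)], dtype=np.int64)
        return out.reshape(np.shape(global_nodes))


def extract_submesh(coords, tris, domain, wanted) -> SubMesh:
    mask = np.isin(domain, wanted)
    tri_map = np.nonzero(mask)[0]
    sel = tris[mask]
    vmap = np.unique(sel)
    lookup = -np.ones(len(coords), dtype=np.int64)
    lookup[vmap] = np.arange(len(vmap))
    return SubMesh(coords[vmap], lookup[sel], vmap, tri_map, domain[mask])
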