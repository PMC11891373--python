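"""Small-strain linear-elastic finite elements on tetrahedra.

Vectorized assembly for 4-node (constant-strain) and 10-node (quadratic)
tetrahedra.  Quadratic elements are generated on the fly by promoting the
unique edges of a linear mesh to midside nodes; corner-node indexing is
preserved so boundary conditions and interface pairs defined on the linear
mesh carry over unchanged.

Voigt order: [xx, yy, zz, xy, yz, zx] with engineering shear strains.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu

# 4-point Gauss rule on the reference tetrahedron (degree 2)
_GA = 0.5854101966249685
_GB = 0.13819660112501053
_GAUSS_BARY = np.array(
    [
        [_GA, _GB, _GB, _GB],
        [_GB, _GA, _GB, _GB],
        [_GB, _GB, _GA, _GB],
        [_GB, _GB, _GB, _GA],
    ]
)

_EDGES = np.array([[0, 1], [1, 2], [2, 0], [0, 3], [1, 3], [2, 3]])


def elastic_D(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Isotropic constitutive matrices, shape (M, 6, 6)."""
    E = np.atleast_1d(np.asarray(E, float))
    nu = np.atleast_1d(np.asarray(nu, float))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((len(E), 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
        D[:, 3 + i, 3 + i] = mu
    return D


def _tet_gradients(nodes: np.ndarray, elems: np.ndarray):
    """Barycentric shape-function gradients (M, 4, 3) and volumes (M,)."""
    X = nodes[elems]
    J = X[:, 1:] - X[:, :1]  # (M, 3, 3) rows = edge vectors
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    invJ = np.linalg.inv(J)
    # gradients of N1..N3 are rows of invJ^T; N0 = 1 - sum
    g = np.transpose(invJ, (0, 2, 1))
    grads = np.empty((len(elems), 4, 3))
    grads[:, 1:] = g
    grads[:, 0] = -g.sum(axis=1)
    return grads, vol


def _B_from_grads(g: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (M, 6, 3*n) from gradients (M, n, 3)."""
    m, n, _ = g.shape
    B = np.zeros((m, 6, 3 * n))
    idx = np.arange(n)
    B[:, 0, 3 * idx + 0] = g[:, :, 0]
    B[:, 1, 3 * idx + 1] = g[:, :, 1]
    B[:, 2, 3 * idx + 2] = g[:, :, 2]
    B[:, 3, 3 * idx + 0] = g[:, :, 1]
    B[:, 3, 3 * idx + 1] = g[:, :, 0]
    B[:, 4, 3 * idx + 1] = g[:, :, 2]
    B[:, 4, 3 * idx + 2] = g[:, :, 1]
    B[:, 5, 3 * idx + 0] = g[:, :, 2]
    B[:, 5, 3 * idx + 2] = g[:, :, 0]
    return B


def promote_to_tet10(nodes: np.ndarray, elems: np.ndarray):
    """Unique-edge midside nodes: returns (nodes10, elems10).

    Corner nodes keep their ids; midside nodes are appended."""
    pairs = np.sort(elems[:, _EDGES], axis=2).reshape(-1, 2)
    uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
    mid = nodes[uniq].mean(axis=1)
    elems10 = np.empty((len(elems), 10), dtype=elems.dtype)
    elems10[:, :4] = elems
    elems10[:, 4:] = len(nodes) + inv.reshape(-1, 6)
    return np.vstack([nodes, mid]), elems10, uniq


def _tet10_B_one_gauss(grads_l: np.ndarray, gp: int) -> np.ndarray:
    """B matrices (m, 6, 30) at one Gauss point from corner gradients."""
    m = len(grads_l)
    lam = _GAUSS_BARY[gp]
    g = np.empty((m, 10, 3))
    for i in range(4):
        g[:, i] = (4.0 * lam[i] - 1.0) * grads_l[:, i]
    for e, (a, b) in enumerate(_EDGES):
        g[:, 4 + e] = 4.0 * (lam[a] * grads_l[:, b] + lam[b] * grads_l[:, a])
    return _B_from_grads(g)


def assemble_stiffness(
    nodes: np.ndarray,
    elems: np.ndarray,
    E: np.ndarray,
    nu: np.ndarray,
    order: int = 1,
    chunk: int = 20000,
):
    """Global stiffness matrix (CSR, 3*n_nodes dofs).

    For ``order == 2`` the mesh is promoted to TET10 internally; the
    returned ``info`` carries everything stress recovery needs.
    """
    D = elastic_D(E, nu)
    if order == 1:
        grads, vol = _tet_gradients(nodes, elems)
        if np.any(vol <= 0):
            raise ValueError("inverted element in assembly")
        B = _B_from_grads(grads)
        Ke = np.einsum("mji,mjk,mkl,m->mil", B, D, B, vol, optimize=True)
        conn, ndof_node = elems, len(nodes)
        info = {"order": 1, "B": B, "D": D, "elems": elems, "n_nodes": len(nodes)}
    else:
        nodes10, elems10, edge_corners = promote_to_tet10(nodes, elems)
        grads_l, vol = _tet_gradients(nodes10, elems10[:, :4])
        if np.any(vol <= 0):
            raise ValueError("inverted element in assembly")
        m = len(elems10)
        Ke = np.zeros((m, 30, 30))
        for s in range(0, m, chunk):
            e = slice(s, min(s + chunk, m))
            for gp in range(4):
                Bg = _tet10_B_one_gauss(grads_l[e], gp)
                Ke[e] += np.einsum(
                    "mji,mjk,mkl,m->mil", Bg, D[e], Bg, vol[e] / 4.0, optimize=True
                )
        conn, ndof_node = elems10, len(nodes10)
        info = {
            "order": 2,
            "grads_l": grads_l,
            "D": D,
            "elems": elems10,
            "n_nodes": len(nodes10),
            "n_corner_nodes": len(nodes),
            "edge_corners": edge_corners,
        }

    nn = conn.shape[1]
    dofs = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(len(conn), 3 * nn)
    rows = np.repeat(dofs, 3 * nn, axis=1).reshape(-1)
    cols = np.tile(dofs, (1, 3 * nn)).reshape(-1)
    K = coo_matrix(
        (Ke.reshape(-1), (rows, cols)), shape=(3 * ndof_node, 3 * ndof_node)
    ).tocsr()
    return K, info


def recover_stresses(info: dict, u: np.ndarray):
    """Per-element stress (M, 6) and von Mises (M,); for TET10 the tensor
    is the Gauss-point mean and von Mises the Gauss-point max."""
    elems = info["elems"]
    ue = u.reshape(-1)[
        (3 * elems[:, :, None] + np.arange(3)[None, None, :]).reshape(len(elems), -1)
    ]
    if info["order"] == 1:
        eps = np.einsum("mij,mj->mi", info["B"], ue)
        sig = np.einsum("mij,mj->mi", info["D"], eps)
        vm = von_mises(sig)
        return sig, vm
    m = len(elems)
    sig = np.zeros((m, 6))
    vm = np.zeros(m)
    for gp in range(4):
        Bg = _tet10_B_one_gauss(info["grads_l"], gp)
        sg = np.einsum("mij,mjk,mk->mi", info["D"], Bg, ue, optimize=True)
        sig += sg / 4.0
        vm = np.maximum(vm, von_mises(sg))
    return sig, vm


def extend_dirichlet_to_midside(info: dict, fixed_dofs: np.ndarray, fixed_vals: np.ndarray):
    """For TET10 meshes, also fix a midside node's component whenever both
    of its edge corners are fixed for that component (value = their mean)."""
    if info["order"] != 2:
        return fixed_dofs, fixed_vals
    nc = info["n_corner_nodes"]
    ec = info["edge_corners"]
    add_dofs, add_vals = [], []
    for k in range(3):
        sel = fixed_dofs % 3 == k
        lut = np.full(nc, np.nan)
        lut[fixed_dofs[sel] // 3] = fixed_vals[sel]
        va, vb = lut[ec[:, 0]], lut[ec[:, 1]]
        both = np.isfinite(va) & np.isfinite(vb)
        mids = np.flatnonzero(both)
        add_dofs.append(3 * (nc + mids) + k)
        add_vals.append(0.5 * (va[both] + vb[both]))
    return (
        np.concatenate([fixed_dofs] + add_dofs),
        np.concatenate([fixed_vals] + add_vals),
    )


def von_mises(sig: np.ndarray) -> np.ndarray:
    sx, sy, sz, txy, tyz, tzx = sig.T
    return np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )


class LinearSystem:
    """K u = f with Dirichlet elimination and a reusable factorization."""

    def __init__(self, K: csr_matrix, fixed_dofs: np.ndarray, fixed_vals: np.ndarray):
        n = K.shape[0]
        self.n = n
        self.fixed = np.asarray(fixed_dofs, int)
        self.vals = np.asarray(fixed_vals, float)
        mask = np.ones(n, bool)
        mask[self.fixed] = False
        self.free = np.flatnonzero(mask)
        self.K = K
        self.Kff = K[self.free][:, self.free].tocsc()
        self.Kfc = K[self.free][:, self.fixed]
        self._lu = None

    def factor(self):
        self._lu = splu(self.Kff)
        return self

    def solve(self, f: np.ndarray) -> np.ndarray:
        if self._lu is None:
            self.factor()
        rhs = f[self.free] - self.Kfc @ self.vals
        uf = self._lu.solve(rhs)
        u = np.zeros(self.n)
        u[self.free] = uf
        u[self.fixed] = self.vals
        return u

    def residual(self, u: np.ndarray, f: np.ndarray) -> float:
        r = self.K @ u - f
        denom = np.linalg.norm(f[self.free]) or 1.0
        return float(np.linalg.norm(r[self.free]) / denom)
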