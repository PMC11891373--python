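"""Internal mesh container and voxel-grid tetrahedral meshing.

Meshes are built on a regular grid: every retained cell is split into the
six Kuhn tetrahedra around its main diagonal, which tile space conformally
without parity bookkeeping.  Elements are classified (region, anatomical
part) at their centroids.  The grid indices of every element are kept so
that scalar fields can be attached reproducibly after re-meshing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

# region codes
CORTICAL, CANCELLOUS, BOLT, ARS, PLATE, LOCKSCREW = range(6)
REGION_NAMES = {
    CORTICAL: "cortical",
    CANCELLOUS: "cancellous",
    BOLT: "bolt",
    ARS: "antirotation_screw",
    PLATE: "plate",
    LOCKSCREW: "locking_screw",
}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}
IMPLANT_REGIONS = (BOLT, ARS, PLATE, LOCKSCREW)

# anatomical part codes (bone only; implant elements get IMPLANT_PART)
HEAD_PART, NECK_PART, SHAFT_PART, IMPLANT_PART = range(4)

# Kuhn decomposition: cube corner k = dx + 2*dy + 4*dz; six path tetrahedra
# around the 0-7 diagonal, each reordered to positive signed volume.
_KUHN_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 3, 2, 7],
        [0, 2, 6, 7],
        [0, 6, 4, 7],
        [0, 4, 5, 7],
        [0, 5, 1, 7],
    ],
    dtype=np.int64,
)
_CORNER_OFFSETS = np.array(
    [[k & 1, (k >> 1) & 1, (k >> 2) & 1] for k in range(8)], dtype=np.int64
)

_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


@dataclass
class InterfacePairs:
    """Coincident node pairs across a split interface.

    ``normal`` points from the b-side into the a-side, so the signed gap
    of a pair is ``(u_a - u_b) @ normal`` (positive = opening).  ``area``
    is the tributary interface area of the pair in mm^2.
    """

    node_a: np.ndarray
    node_b: np.ndarray
    normal: np.ndarray
    area: np.ndarray

    def __len__(self) -> int:
        return len(self.node_a)


@dataclass
class VolumeMesh:
    """Region-tagged linear tetrahedral mesh on a regular grid.

    ``elems`` are 4-node tetrahedra; quadratic (10-node) behaviour is an
    assembly-time option that promotes edges to midside nodes.  ``region``
    holds material/implant codes, ``part`` the anatomical part, and
    ``fragment`` the fracture side (-1 implant, 0 shaft, 1 head).
    """

    nodes: np.ndarray
    elems: np.ndarray
    region: np.ndarray
    part: np.ndarray
    fragment: np.ndarray
    cell_index: np.ndarray  # (M, 3) grid cell of each element
    cell_tet: np.ndarray  # (M,) Kuhn tet index within the cell
    node_sets: dict = field(default_factory=dict)
    facet_sets: dict = field(default_factory=dict)
    interfaces: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elems)

    def bone_mask(self) -> np.ndarray:
        return self.region <= CANCELLOUS

    def implant_mask(self) -> np.ndarray:
        return self.region >= BOLT

    def element_volumes(self) -> np.ndarray:
        return element_volumes(self.nodes, self.elems)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elems].mean(axis=1)

    def region_mask(self, *names: str) -> np.ndarray:
        codes = [REGION_CODES[n] for n in names]
        return np.isin(self.region, codes)

    def validate(self, min_quality: float = 0.05) -> None:
        """Quality gate: positive volumes and a floor on the scaled
        Jacobian (volume vs. ideal volume at the element's edge scale)."""
        vols = self.element_volumes()
        if np.any(vols <= 0):
            raise ValueError(f"{int(np.sum(vols <= 0))} inverted element(s)")
        X = self.nodes[self.elems]
        edges = X[:, [0, 0, 0, 1, 1, 2]] - X[:, [1, 2, 3, 2, 3, 3]]
        lmax = np.sqrt((edges**2).sum(-1)).max(axis=1)
        # regular tet of edge a has volume a^3 / (6*sqrt(2))
        q = vols / (lmax**3 / (6.0 * np.sqrt(2.0)))
        if q.min() < min_quality:
            raise ValueError(
                f"mesh quality below floor: min scaled volume ratio {q.min():.3g}"
            )


def element_volumes(nodes: np.ndarray, elems: np.ndarray) -> np.ndarray:
    X = nodes[elems]
    a, b, c = X[:, 1] - X[:, 0], X[:, 2] - X[:, 0], X[:, 3] - X[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def triangle_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    X = nodes[tris]
    return 0.5 * np.linalg.norm(np.cross(X[:, 1] - X[:, 0], X[:, 2] - X[:, 0]), axis=1)


def build_grid_mesh(origin, h: float, dims, classify) -> VolumeMesh:
    """Mesh every Kuhn tetrahedron whose centroid classifies as inside.

    ``classify(points) -> (inside bool, region, part)`` arrays evaluated at
    tet centroids.  ``dims`` is the cell count per axis.
    """
    origin = np.asarray(origin, float)
    nx, ny, nz = dims
    if nx * ny * nz == 0:
        raise ValueError("empty grid")
    cells = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), -1
    ).reshape(-1, 3)

    # tet centroids for all cells x 6 tets, in units of h relative to origin
    corner = _CORNER_OFFSETS[_KUHN_TETS]  # (6, 4, 3)
    tet_centroid_local = corner.mean(axis=1)  # (6, 3)
    cent = (
        cells[:, None, :].astype(float) + tet_centroid_local[None, :, :]
    ).reshape(-1, 3) * h + origin

    inside, region, part = classify(cent)
    keep = np.flatnonzero(inside)
    if keep.size == 0:
        raise ValueError("no element centroid falls inside the geometry")

    cell_of = np.repeat(np.arange(len(cells)), 6)[keep]
    tet_of = np.tile(np.arange(6), len(cells))[keep]

    # global integer corner coordinates of every kept tet
    corner_coords = (
        cells[cell_of][:, None, :] + _CORNER_OFFSETS[_KUHN_TETS[tet_of]]
    )  # (K, 4, 3)
    flat = corner_coords.reshape(-1, 3)
    key = (flat[:, 0] * (ny + 1) + flat[:, 1]) * (nz + 1) + flat[:, 2]
    uniq, inv = np.unique(key, return_inverse=True)
    elems = inv.reshape(-1, 4).astype(np.int64)
    kz = uniq % (nz + 1)
    ky = (uniq // (nz + 1)) % (ny + 1)
    kx = uniq // ((nz + 1) * (ny + 1))
    nodes = np.stack([kx, ky, kz], axis=1).astype(float) * h + origin

    vols = element_volumes(nodes, elems)
    neg = vols < 0
    if np.any(neg):  # fix orientation once
        elems[neg] = elems[neg][:, [0, 1, 3, 2]]

    mesh = VolumeMesh(
        nodes=nodes,
        elems=elems,
        region=np.asarray(region)[keep].astype(np.int8),
        part=np.asarray(part)[keep].astype(np.int8),
        fragment=np.zeros(keep.size, dtype=np.int8),
        cell_index=cells[cell_of].astype(np.int32),
        cell_tet=tet_of.astype(np.int8),
        meta={"origin": origin, "h": float(h), "dims": tuple(int(d) for d in dims)},
    )
    mesh.fragment[mesh.implant_mask()] = -1
    return mesh


def _face_keys(tris: np.ndarray) -> np.ndarray:
    return np.sort(tris, axis=1)


def boundary_facets(elems: np.ndarray, element_mask=None) -> np.ndarray:
    """Facets of the selected element set that are not shared by another
    selected element (outer surface of the set)."""
    sel = elems if element_mask is None else elems[element_mask]
    faces = sel[:, _FACE_LOCAL].reshape(-1, 3)
    keys = _face_keys(faces)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def shared_facets(elems: np.ndarray, mask_a, mask_b) -> np.ndarray:
    """Triangles shared between an element of set A and one of set B."""
    fa = _face_keys(elems[mask_a][:, _FACE_LOCAL].reshape(-1, 3))
    fb = _face_keys(elems[mask_b][:, _FACE_LOCAL].reshape(-1, 3))
    if len(fa) == 0 or len(fb) == 0:
        return np.empty((0, 3), dtype=elems.dtype)
    both = np.concatenate([fa, fb])
    _, inv, counts = np.unique(both, axis=0, return_inverse=True, return_counts=True)
    hit = counts[inv[: len(fa)]] >= 2
    return fa[hit]


def connected_fragment_count(mesh: VolumeMesh, element_mask) -> int:
    """Connected components (by shared nodes) of the selected elements."""
    idx = np.flatnonzero(element_mask)
    if idx.size == 0:
        return 0
    sub = mesh.elems[idx]
    rows = np.repeat(np.arange(idx.size), 4)
    cols = sub.reshape(-1)
    _, cols = np.unique(cols, return_inverse=True)
    A = coo_matrix((np.ones(rows.size), (rows, cols)))
    n, _ = connected_components((A @ A.T) > 0, directed=False)
    return int(n)


def split_interface(
    mesh: VolumeMesh,
    tag: str,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    normal_fn,
    exclude_nodes: np.ndarray | None = None,
) -> int:
    """Duplicate the nodes shared between element sets A and B; B-side
    elements get the copies.  Creates ``mesh.interfaces[tag]`` with pair
    normals from ``normal_fn(points) -> unit vectors pointing b->a`` and
    tributary areas from the shared facets.  Returns the pair count.
    """
    nodes_a = np.unique(mesh.elems[mask_a])
    nodes_b = np.unique(mesh.elems[mask_b])
    shared = np.intersect1d(nodes_a, nodes_b, assume_unique=True)
    if exclude_nodes is not None and len(exclude_nodes):
        shared = np.setdiff1d(shared, exclude_nodes, assume_unique=False)
    if shared.size == 0:
        return 0

    tris = shared_facets(mesh.elems, mask_a, mask_b)
    area_per_node = np.zeros(mesh.n_nodes)
    if len(tris):
        areas = triangle_areas(mesh.nodes, tris)
        np.add.at(area_per_node, tris.reshape(-1), np.repeat(areas / 3.0, 3))

    n0 = mesh.n_nodes
    new_ids = np.arange(n0, n0 + shared.size)
    mesh.nodes = np.vstack([mesh.nodes, mesh.nodes[shared]])
    remap = np.arange(n0 + shared.size)
    remap[shared] = new_ids
    be = np.flatnonzero(mask_b)
    mesh.elems[be] = remap[mesh.elems[be]]

    normals = np.atleast_2d(normal_fn(mesh.nodes[shared]))
    if normals.shape[0] == 1:
        normals = np.repeat(normals, shared.size, axis=0)
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    # pair normal must point b -> a; node_a keeps the original id (A side),
    # node_b is the copy used by the B side
    mesh.interfaces[tag] = InterfacePairs(
        node_a=shared.copy(),
        node_b=new_ids,
        normal=normals,
        area=area_per_node[shared],
    )
    return int(shared.size)
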