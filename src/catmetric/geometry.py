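"""Analysis of the categorical geometry: sizes, distortion and embeddings.

Once colour space carries a Riemannian tensor field, familiar questions
become measurable: how long is a path, how big is a surface or the whole
cube, how many categorically distinct regions fit inside, and how much do
two metrics disagree about the shape of the space.

Sizes are expressed in *grains*, the natural categorical units.  One
linear grain is the distance pi/2 between two naming distributions with
no responses in common; areal and volumetric grains are the measures of
the 1- and 2-sphere enclosures of radius pi/4:

    G1 = 2 (pi/4) = pi/2,  G2 = pi (pi/4)^2 = pi^3/16,
    G3 = (4/3) pi (pi/4)^3 = pi^4/48.

The capacity of a manifold R of dimension n, the estimated count of
categorically distinct regions it holds, is
``C(R) = |R|/G_n + 1/2 |dR|/G_{n-1}``, the boundary term crediting edge
regions that need only half the usual extent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .colour import MeshSpec, PathSpec, tensor_from_distance_many

__all__ = [
    "G1",
    "G2",
    "G3",
    "CallableTensorField",
    "ConstantTensorField",
    "identity_field",
    "cie_tensor_field",
    "path_length",
    "mesh_area",
    "cube_volume",
    "area_and_volume",
    "capacity",
    "cube_capacity",
    "restrict_tensor",
    "local_distortion",
    "spd_geometric_mean",
    "global_distortion",
    "distortion_range",
    "embed_1d",
    "laplace_surface",
    "embed_sphere",
]

G1 = math.pi / 2.0
G2 = math.pi ** 3 / 16.0
G3 = math.pi ** 4 / 48.0


# ---------------------------------------------------------------------------
# Tensor field wrappers
# ---------------------------------------------------------------------------

class CallableTensorField:
    """Wrap a function ``(N,3) -> (N,3,3)`` as a queryable tensor field."""

    def __init__(self, fn):
        self._fn = fn

    def tensor(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        out = np.asarray(self._fn(np.atleast_2d(z)), dtype=float)
        return out[0] if single else out


class ConstantTensorField(CallableTensorField):
    def __init__(self, tensor):
        t = np.asarray(tensor, dtype=float)
        super().__init__(lambda pts: np.broadcast_to(t, (len(pts), 3, 3)).copy())


def identity_field() -> ConstantTensorField:
    """The sRGB metric: identity tensor everywhere."""
    return ConstantTensorField(np.eye(3))


def cie_tensor_field(formula: str, delta: float = 0.1) -> CallableTensorField:
    """Tensor field of a CIE difference formula (see
    :func:`catmetric.colour.tensor_from_distance`)."""
    return CallableTensorField(
        lambda pts: tensor_from_distance_many(formula, pts, delta))


# ---------------------------------------------------------------------------
# Lengths, areas, volumes, capacities
# ---------------------------------------------------------------------------

def path_length(field, path: PathSpec, density: float | None = None) -> dict:
    """Length of a piecewise-linear path under a tensor field.

    Trapezoidal integration of sqrt(v^T Gamma v) along each segment at
    ``density`` samples per unit sRGB length.  Returns raw length and the
    value in linear grains (raw / G1).
    """
    density = density or path.density
    raw = 0.0
    for p0, p1 in path.segments:
        length = float(np.linalg.norm(p1 - p0))
        n = max(int(np.ceil(length * density)), 2)
        t = np.linspace(0.0, 1.0, n + 1)
        pts = p0 + t[:, None] * (p1 - p0)
        tan = (p1 - p0) / length
        gam = field.tensor(pts)
        speed = np.sqrt(np.maximum(np.einsum("i,nij,j->n", tan, gam, tan), 0.0))
        raw += float(np.trapezoid(speed, dx=length / n))
    return {"raw": raw, "grains": raw / G1}


def _plane_basis(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray):
    """Orthonormal in-plane basis of a triangle, or None if degenerate."""
    u = p1 - p0
    v = p2 - p0
    nu = np.linalg.norm(u)
    if nu == 0:
        return None
    x = u / nu
    v_perp = v - (v @ x) * x
    nv = np.linalg.norm(v_perp)
    if nv < 1e-12:
        return None
    return x, v_perp / nv


def mesh_area(field, mesh: MeshSpec) -> dict:
    """Categorical area of a triangulated surface.

    Per triangle the tensor at the centroid is restricted to the triangle
    plane; the categorical area is sqrt(det T2) times the Euclidean
    triangle area, summed and expressed in areal grains (/ G2).
    """
    verts = mesh.vertices
    tris = mesh.triangles
    centroids = verts[tris].mean(axis=1)
    gam = field.tensor(centroids)
    raw = 0.0
    for tri, t in zip(tris, gam):
        p0, p1, p2 = verts[tri]
        basis = _plane_basis(p0, p1, p2)
        if basis is None:
            raise ValueError(f"degenerate triangle {tri.tolist()}")
        x, y = basis
        t2 = restrict_tensor(t, x, y)
        area_eucl = 0.5 * float(np.linalg.norm(np.cross(p1 - p0, p2 - p0)))
        raw += math.sqrt(max(np.linalg.det(t2), 0.0)) * area_eucl
    return {"raw": raw, "grains": raw / G2}


def cube_volume(field, resolution: int = 20) -> dict:
    """Categorical volume of the cube: midpoint rule on sqrt(det Gamma)."""
    m = int(resolution)
    g = (np.arange(m) + 0.5) / m
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    raw = 0.0
    for start in range(0, len(pts), 4096):
        gam = field.tensor(pts[start:start + 4096])
        raw += float(np.sqrt(np.maximum(np.linalg.det(gam), 0.0)).sum())
    raw /= m ** 3
    return {"raw": raw, "grains": raw / G3}


def area_and_volume(field, mesh: MeshSpec | None = None,
                    resolution: int = 20) -> dict:
    """Areal grains of ``mesh`` (if given) and volumetric grains of the cube."""
    out = {}
    if mesh is not None:
        out["area"] = mesh_area(field, mesh)
    out["volume"] = cube_volume(field, resolution)
    return out


def capacity(measure_grains: float, boundary_grains: float = 0.0,
             dim: int = 1) -> float:
    """Boundary-corrected capacity C = |R|/G_n + 1/2 |dR|/G_{n-1}.

    Both arguments are already expressed in grains of the appropriate
    dimension (for dim=1 the boundary measure is the endpoint count).
    """
    if measure_grains < 0 or boundary_grains < 0:
        raise ValueError("measures must be nonnegative")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    return float(measure_grains + 0.5 * boundary_grains)


def _face_area(field, axis: int, value: float, resolution: int) -> float:
    """Categorical area of one cube face via restricted tensors."""
    m = int(resolution)
    g = (np.arange(m) + 0.5) / m
    a, b = np.meshgrid(g, g, indexing="ij")
    pts = np.empty((m * m, 3))
    others = [i for i in range(3) if i != axis]
    pts[:, axis] = value
    pts[:, others[0]] = a.ravel()
    pts[:, others[1]] = b.ravel()
    gam = field.tensor(pts)
    ex = np.eye(3)[others[0]]
    ey = np.eye(3)[others[1]]
    t2 = np.einsum("ai,nij,bj->nab", np.stack([ex, ey]), gam, np.stack([ex, ey]))
    dets = np.maximum(np.linalg.det(t2), 0.0)
    return float(np.sqrt(dets).sum()) / (m * m)


def cube_capacity(field, resolution: int = 20, include_boundary: bool = True) -> dict:
    """Capacity of the full RGB cube.

    Volume in volumetric grains plus (optionally) half the total area of
    the six faces in areal grains.  Face areas integrate the tensor
    restricted to each face plane.  Both the boundary-corrected and the
    uncorrected counts are reported.
    """
    vol = cube_volume(field, resolution)["grains"]
    faces_raw = sum(_face_area(field, axis, v, resolution)
                    for axis in range(3) for v in (0.0, 1.0))
    faces = faces_raw / G2
    return {
        "volume_grains": vol,
        "boundary_area_grains": faces,
        "capacity": vol + 0.5 * faces if include_boundary else vol,
        "capacity_uncorrected": vol,
    }


def restrict_tensor(t: np.ndarray, x, y) -> np.ndarray:
    """Restrict a 3x3 tensor to the plane spanned by orthonormal x, y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isclose(x @ x, 1.0, atol=1e-8) and np.isclose(y @ y, 1.0, atol=1e-8)
            and np.isclose(x @ y, 0.0, atol=1e-8)):
        raise ValueError("plane vectors must be orthonormal")
    basis = np.stack([x, y], axis=1)  # (3, 2)
    t2 = basis.T @ np.asarray(t, dtype=float) @ basis
    return 0.5 * (t2 + t2.T)


# ---------------------------------------------------------------------------
# Distortion between metrics
# ---------------------------------------------------------------------------

def local_distortion(a: np.ndarray, b: np.ndarray, v: np.ndarray) -> float:
    """1/2 log2 of the ratio of squared lengths two tensors give direction v."""
    v = np.asarray(v, dtype=float)
    qa = float(v @ np.asarray(a) @ v)
    qb = float(v @ np.asarray(b) @ v)
    if qa <= 0 or qb <= 0:
        raise ValueError("tensors must be positive along v")
    return 0.5 * math.log2(qa / qb)


def _sqrtm_spd(t: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(t)
    w = np.sqrt(np.clip(w, 0.0, None))
    return np.einsum("...ij,...j,...kj->...ik", v, w, v)


def _invsqrtm_spd(t: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(t)
    if np.any(w <= 0):
        raise ValueError("matrix not positive definite")
    w = 1.0 / np.sqrt(w)
    return np.einsum("...ij,...j,...kj->...ik", v, w, v)


def spd_geometric_mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """The SPD geometric mean A # B = A^1/2 (A^-1/2 B A^-1/2)^1/2 A^1/2.

    Works on single matrices or stacks; equals A when A = B, and is
    symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ah = _sqrtm_spd(a)
    aih = _invsqrtm_spd(a)
    inner = _sqrtm_spd(aih @ b @ aih)
    return ah @ inner @ ah


def _floor_spd(t: np.ndarray, name: str, z: np.ndarray,
               rel_floor: float = 1e-8, rel_reject: float = 1e-6) -> np.ndarray:
    """Regularize near-singular tensors; reject meaningfully indefinite ones.

    Tensorized difference formulas can come out positive *semi*-definite
    at isolated points (a clipped tiny negative eigenvalue of the
    least-squares fit); those are floored at ``rel_floor`` times the local
    leading eigenvalue so the comparison measure stays invertible.  A
    tensor whose smallest eigenvalue is negative beyond ``rel_reject``
    relative tolerance is a genuine error and is reported with location.
    """
    w, v = np.linalg.eigh(t)
    scale = np.maximum(w[..., -1], 1e-300)
    rel = w[..., 0] / scale
    if np.any(rel < -rel_reject):
        loc = z[int(np.argmin(rel))]
        raise ValueError(f"tensor field {name} not positive definite "
                         f"near {np.round(loc, 3).tolist()}")
    w = np.maximum(w, rel_floor * scale[..., None])
    return np.einsum("...ij,...j,...kj->...ik", v, w, v)


def global_distortion(field_a, field_b, n_samples: int = 100_000,
                      seed: int = 0, measure: str = "geometric_mean",
                      return_samples: bool = False):
    """Standard deviation of local distortion between two tensor fields.

    Monte Carlo over the cube: sample a location z uniformly, a direction
    ``v ~ N(0, C_z^{-1})`` and weight ``|C_z|``, where the measure tensor
    ``C`` is the SPD geometric mean of the two fields (``measure="squared"``
    uses its square, the literal printed form of the comparison measure).
    The weighted standard deviation of ``1/2 log2(v^T A v / v^T B v)`` is
    returned; it is symmetric in (A, B) and invariant to uniform rescaling
    of either field.
    """
    rng = np.random.default_rng(seed)
    z = rng.uniform(0.0, 1.0, size=(n_samples, 3))
    a = np.asarray(field_a.tensor(z), dtype=float)
    b = np.asarray(field_b.tensor(z), dtype=float)
    a, b = (_floor_spd(t, name, z) for name, t in (("A", a), ("B", b)))
    c = spd_geometric_mean(a, b)
    if measure == "squared":
        c = c @ c
    elif measure != "geometric_mean":
        raise ValueError("measure must be 'geometric_mean' or 'squared'")

    w_eig, v_eig = np.linalg.eigh(c)
    noise = rng.standard_normal((n_samples, 3))
    # v ~ N(0, C^{-1}): scale eigen-directions by 1/sqrt(eigenvalue)
    v = np.einsum("nij,nj->ni", v_eig, noise / np.sqrt(w_eig))
    qa = np.einsum("ni,nij,nj->n", v, a, v)
    qb = np.einsum("ni,nij,nj->n", v, b, v)
    local = 0.5 * np.log2(qa / qb)
    weights = np.prod(w_eig, axis=1)  # |C_z|
    weights = weights / weights.sum()
    mean = float(np.sum(weights * local))
    sd = float(np.sqrt(np.sum(weights * (local - mean) ** 2)))
    if return_samples:
        return sd, {"local": local, "weights": weights, "mean": mean}
    return sd


def distortion_range(global_sd: float, coverage: float = 0.95) -> tuple:
    """Range of local distortion ratios implied by a global distortion.

    Assuming normally distributed local distortions, the central
    ``coverage`` mass lies between ``2**(-z sd)`` and ``2**(+z sd)``
    (z = 1.96 at 95%), returned as ratio fractions (0.51, 1.97 at sd 0.50).
    """
    from scipy.stats import norm

    zval = float(norm.ppf(0.5 + coverage / 2.0))
    return (2.0 ** (-global_sd * zval), 2.0 ** (global_sd * zval))


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

def embed_1d(field, path: PathSpec, density: float | None = None) -> dict:
    """Isometric embedding of a 1-D sub-manifold into Euclidean space.

    Returns the monotone arc-length map (cumulative categorical length at
    the sampled points).  A closed path is additionally embedded as a
    circle of circumference equal to its categorical length, always
    possible with zero distortion; regions where the naming distribution
    is constant collapse to points.
    """
    density = density or path.density
    pts_all, cum_all = [], []
    total = 0.0
    for p0, p1 in path.segments:
        length = float(np.linalg.norm(p1 - p0))
        n = max(int(np.ceil(length * density)), 2)
        t = np.linspace(0.0, 1.0, n + 1)
        pts = p0 + t[:, None] * (p1 - p0)
        tan = (p1 - p0) / length
        gam = field.tensor(pts)
        speed = np.sqrt(np.maximum(np.einsum("i,nij,j->n", tan, gam, tan), 0.0))
        dl = length / n
        seg_cum = np.concatenate([[0.0], np.cumsum((speed[1:] + speed[:-1]) * 0.5 * dl)])
        pts_all.append(pts if not cum_all else pts[1:])
        cum_all.append(seg_cum + total if not cum_all else seg_cum[1:] + total)
        total += float(seg_cum[-1])
    points = np.vstack(pts_all)
    cumulative = np.concatenate(cum_all)
    out = {"points": points, "arc_length": cumulative, "total": total,
           "grains": total / G1}
    if path.closed and total > 0:
        radius = total / (2 * math.pi)
        # first vertex at angle 0, counter-clockwise
        ang = cumulative / radius
        out["radius"] = radius
        out["circle"] = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    return out


def laplace_surface(boundary: PathSpec, rings: int = 10,
                    segments: int | None = None) -> MeshSpec:
    """Span a closed boundary path with a graph-harmonic surface.

    The boundary is sampled at uniform sRGB arc length into ``segments``
    points forming the outer ring of a disk mesh with ``rings`` concentric
    rings and a centre vertex.  Interior coordinates solve the graph
    Laplace equation (each vertex the average of its mesh neighbours),
    with the boundary fixed -- the discrete analogue of a harmonic span.
    Applied to the full colour locus this yields the saddle-shaped full
    colour surface through the cube centre.
    """
    if not boundary.closed:
        raise ValueError("laplace_surface needs a closed boundary path")
    m = int(rings)
    if m < 2:
        raise ValueError("need at least 2 rings")
    n = int(segments or 6 * m)

    # sample boundary at uniform arc length
    segs = boundary.segments
    lengths = np.linalg.norm(segs[:, 1] - segs[:, 0], axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    total = cum[-1]
    s = np.arange(n) * total / n
    ring_pts = np.empty((n, 3))
    for i, si in enumerate(s):
        j = min(int(np.searchsorted(cum, si, side="right")) - 1, len(segs) - 1)
        f = (si - cum[j]) / lengths[j]
        ring_pts[i] = segs[j, 0] + f * (segs[j, 1] - segs[j, 0])

    # vertex layout: centre (0), rings 1..m each with n vertices
    def vid(ring: int, i: int) -> int:
        return 1 + (ring - 1) * n + (i % n)

    n_verts = 1 + m * n
    verts = np.zeros((n_verts, 3))
    verts[[vid(m, i) for i in range(n)]] = ring_pts

    # triangles: centre fan + split quads between rings
    tris = []
    for i in range(n):
        tris.append([0, vid(1, i), vid(1, i + 1)])
    for ring in range(1, m):
        for i in range(n):
            a, b = vid(ring, i), vid(ring, i + 1)
            c, d = vid(ring + 1, i), vid(ring + 1, i + 1)
            tris.append([a, c, d])
            tris.append([a, d, b])
    boundary_loop = np.array([vid(m, i) for i in range(n)])
    mesh = MeshSpec(vertices=verts, triangles=np.asarray(tris),
                    boundary=boundary_loop)

    # graph-harmonic interior: vertex = mean of its triangle-edge
    # neighbours, boundary fixed; one sparse solve per coordinate block
    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    neighbours = [[] for _ in range(n_verts)]
    for u, v in mesh.edges:
        neighbours[u].append(v)
        neighbours[v].append(u)
    interior = list(range(1 + (m - 1) * n))  # centre + rings 1..m-1
    pos = {u: i for i, u in enumerate(interior)}
    lap = lil_matrix((len(interior), len(interior)))
    rhs = np.zeros((len(interior), 3))
    for u in interior:
        lap[pos[u], pos[u]] = len(neighbours[u])
        for nb in neighbours[u]:
            if nb in pos:
                lap[pos[u], pos[nb]] = lap[pos[u], pos[nb]] - 1.0
            else:
                rhs[pos[u]] += verts[nb]
    sol = spsolve(lap.tocsr(), rhs)
    mesh.vertices[interior] = sol
    return mesh


def _edge_lengths(field, mesh: MeshSpec, samples: int = 5) -> np.ndarray:
    """Categorical length of each mesh edge (trapezoid along the chord)."""
    edges = mesh.edges
    p0 = mesh.vertices[edges[:, 0]]
    p1 = mesh.vertices[edges[:, 1]]
    t = np.linspace(0.0, 1.0, samples)
    pts = p0[:, None, :] + t[None, :, None] * (p1 - p0)[:, None, :]
    gam = field.tensor(pts.reshape(-1, 3)).reshape(len(edges), samples, 3, 3)
    d = p1 - p0
    speed = np.sqrt(np.maximum(
        np.einsum("ei,esij,ej->es", d, gam, d), 0.0))
    return np.trapezoid(speed, t, axis=1)


def embed_sphere(field, mesh: MeshSpec, seed: int = 0, restarts: int = 3,
                 maxiter: int = 500, edge_samples: int = 5) -> dict:
    """Least-distortion embedding of a 2-D sub-manifold onto a sphere.

    Mesh vertices are placed on a sphere of optimized radius so that
    geodesic (great-circle) distances between edge endpoints match the
    categorical edge lengths: the objective is the length-weighted mean
    square of log2(embedded / categorical) over mesh edges.  The initial
    layout is a spherical cap built from a planar PCA of the mesh;
    restarts jitter it.  Returns the radius, the vertex positions, the
    per-edge length ratios and their realized central 95% range.
    """
    if not mesh.interior_mask().any():
        raise ValueError("mesh needs at least one interior vertex")
    lengths = _edge_lengths(field, mesh, edge_samples)
    if np.any(lengths <= 0):
        raise ValueError("mesh edges must have positive categorical length")
    edges = mesh.edges
    weights = lengths / lengths.sum()
    nv = len(mesh.vertices)

    # planar PCA layout -> polar coordinates for the initial cap
    centred = mesh.vertices - mesh.vertices.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    plane = centred @ vt[:2].T
    rho = np.linalg.norm(plane, axis=1)
    phi = np.arctan2(plane[:, 1], plane[:, 0])
    colat = rho / max(rho.max(), 1e-12)  # cap of ~1 radian

    def directions(theta):
        u = np.empty((nv, 3))
        sin_t = np.sin(theta[:, 0])
        u[:, 0] = sin_t * np.cos(theta[:, 1])
        u[:, 1] = sin_t * np.sin(theta[:, 1])
        u[:, 2] = np.cos(theta[:, 0])
        return u

    u0 = directions(np.column_stack([colat, phi]))
    ang0 = np.arccos(np.clip(np.einsum("ei,ei->e", u0[edges[:, 0]],
                                       u0[edges[:, 1]]), -1.0, 1.0))
    r0 = float(np.median(lengths / np.maximum(ang0, 1e-9)))

    ln2 = math.log(2.0)

    def objective(params):
        logr = params[0]
        x = params[1:].reshape(nv, 3)
        norm = np.maximum(np.linalg.norm(x, axis=1, keepdims=True), 1e-12)
        u = x / norm
        ui, uj = u[edges[:, 0]], u[edges[:, 1]]
        dots = np.clip(np.einsum("ei,ei->e", ui, uj), -1.0, 1.0 - 1e-12)
        ang = np.maximum(np.arccos(dots), 1e-9)
        log_ratio = (logr + np.log(ang) - np.log(lengths)) / ln2
        val = float(np.sum(weights * log_ratio ** 2))

        grad = np.zeros_like(params)
        coef = 2.0 * weights * log_ratio / ln2  # d val / d log_ratio-source
        grad[0] = float(coef.sum())
        # d/d ang of log(ang) term, then chain through arccos and the
        # normalized dot product
        dang = coef / ang
        ddot = -dang / np.sqrt(1.0 - dots ** 2)
        gi = ddot[:, None] * (uj - dots[:, None] * ui)
        gj = ddot[:, None] * (ui - dots[:, None] * uj)
        gu = np.zeros((nv, 3))
        np.add.at(gu, edges[:, 0], gi)
        np.add.at(gu, edges[:, 1], gj)
        grad[1:] = (gu / norm).ravel()
        return val, grad

    rng = np.random.default_rng(seed)
    best_val, best_x = np.inf, None
    for trial in range(max(restarts, 1)):
        x0 = np.concatenate([[math.log(r0)], u0.ravel()])
        if trial:
            x0[0] += rng.normal(0, 0.2)
            x0[1:] += rng.normal(0, 0.05, size=3 * nv)
        res = optimize.minimize(objective, x0, method="L-BFGS-B", jac=True,
                                options={"maxiter": maxiter, "ftol": 1e-14,
                                         "gtol": 1e-10})
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x

    radius = float(np.exp(best_x[0]))
    u = best_x[1:].reshape(nv, 3)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    dots = np.einsum("ei,ei->e", u[edges[:, 0]], u[edges[:, 1]])
    ratios = radius * np.arccos(np.clip(dots, -1.0, 1.0)) / lengths
    lo, hi = np.quantile(ratios, [0.025, 0.975])
    return {
        "radius": radius,
        "positions": radius * u,
        "edge_ratios": ratios,
        "range95": (float(lo), float(hi)),
        "objective": float(best_val),
    }
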