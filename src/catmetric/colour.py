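"""Colour coordinates, CIE difference formulas and standard sub-manifolds.

Everything downstream works in two coordinate systems at once: nonlinear
sRGB, whose unit cube is used as a convenient approximation of the solid of
surface colours, and CIELAB (D65, 2 degree observer), in which Euclidean
distance approximates discriminability.  Conversions go through
:mod:`skimage.color`, which implements the IEC sRGB transfer function and
the CIE definitions of the Lab coordinates and of the CIE76 / CIE94 /
CIEDE2000 difference formulas.

The module also turns any colour-difference formula into a field of 3x3
metric tensors over the sRGB cube (:func:`tensor_from_distance`), which is
how non-Euclidean formulas such as CIEDE2000 are compared against the
categorical metric, and constructs the standard probe sub-manifolds: the
achromatic axis, the full colour locus (the closed hexagon of saturated
colours along six cube edges) and the hue triangles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "ColourPoint",
    "PathSpec",
    "MeshSpec",
    "srgb_to_lab",
    "lab_to_srgb",
    "cie_distance",
    "cie_pair_distances",
    "tensor_from_distance",
    "tensor_from_distance_many",
    "standard_paths",
    "achromatic_axis",
    "full_colour_locus",
    "hue_triangle",
    "CHROMATIC_VERTICES",
]

# The six chromatic vertices of the sRGB cube, in hue order around the
# full colour locus: red, yellow, green, cyan, blue, magenta.
CHROMATIC_VERTICES = {
    "red": (1.0, 0.0, 0.0),
    "yellow": (1.0, 1.0, 0.0),
    "green": (0.0, 1.0, 0.0),
    "cyan": (0.0, 1.0, 1.0),
    "blue": (0.0, 0.0, 1.0),
    "magenta": (1.0, 0.0, 1.0),
}


def _validate_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("sRGB input must have 3 components in the last axis")
    if np.any(rgb < -1e-9) or np.any(rgb > 1 + 1e-9):
        raise ValueError("sRGB components must lie in [0, 1]")
    return np.clip(rgb, 0.0, 1.0)


def srgb_to_lab(rgb) -> np.ndarray:
    """Convert nonlinear sRGB triples in [0,1]^3 to CIELAB (D65/2deg).

    Accepts a single triple or an (..., 3) array; returns the same shape.
    Out-of-range components are rejected.
    """
    rgb = _validate_rgb(rgb)
    return _skcolor.rgb2lab(rgb)


def lab_to_srgb(lab) -> np.ndarray:
    """Inverse of :func:`srgb_to_lab` (values clipped to the sRGB gamut)."""
    lab = np.asarray(lab, dtype=float)
    if lab.shape[-1] != 3:
        raise ValueError("CIELAB input must have 3 components in the last axis")
    return _skcolor.lab2rgb(lab)


@dataclass(frozen=True)
class ColourPoint:
    """A colour carried simultaneously in sRGB and CIELAB coordinates.

    ``lab`` is a deterministic function of ``rgb``; construct through
    :meth:`from_rgb` (or :meth:`from_lab`) to keep the pair consistent.
    """

    rgb: tuple
    lab: tuple

    @classmethod
    def from_rgb(cls, rgb) -> "ColourPoint":
        rgb = _validate_rgb(rgb)
        if rgb.shape != (3,):
            raise ValueError("ColourPoint.from_rgb expects a single triple")
        return cls(rgb=tuple(rgb), lab=tuple(srgb_to_lab(rgb)))

    @classmethod
    def from_lab(cls, lab) -> "ColourPoint":
        rgb = lab_to_srgb(np.asarray(lab, dtype=float))
        return cls(rgb=tuple(rgb), lab=tuple(np.asarray(lab, dtype=float)))


def _as_rgb_array(points) -> np.ndarray:
    """Accept ColourPoint, triple, or (N,3) array; return (N,3) sRGB."""
    if isinstance(points, ColourPoint):
        return np.asarray(points.rgb, dtype=float)[None, :]
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


_CIE_FORMULAS = ("CIE76", "CIE94", "CIE2000")


def cie_pair_distances(lab_a: np.ndarray, lab_b: np.ndarray, formula: str) -> np.ndarray:
    """Vectorized CIE colour differences between paired CIELAB arrays."""
    formula = formula.upper()
    lab_a = np.asarray(lab_a, dtype=float)
    lab_b = np.asarray(lab_b, dtype=float)
    if formula == "CIE76":
        return _skcolor.deltaE_cie76(lab_a, lab_b)
    if formula == "CIE94":
        return _skcolor.deltaE_ciede94(lab_a, lab_b)
    if formula == "CIE2000":
        return _skcolor.deltaE_ciede2000(lab_a, lab_b)
    raise ValueError(f"unknown colour difference formula {formula!r}; "
                     f"expected one of {_CIE_FORMULAS}")


def cie_distance(a, b, formula: str = "CIE76") -> float:
    """CIE colour difference between two colours.

    ``a`` and ``b`` may be :class:`ColourPoint` instances or sRGB triples.
    CIE76 is Euclidean distance in CIELAB; CIE94 and CIEDE2000 follow the
    published CIE definitions (they are not guaranteed to satisfy the
    triangle inequality).
    """
    lab_a = np.asarray(a.lab if isinstance(a, ColourPoint) else srgb_to_lab(a), dtype=float)
    lab_b = np.asarray(b.lab if isinstance(b, ColourPoint) else srgb_to_lab(b), dtype=float)
    return float(cie_pair_distances(lab_a, lab_b, formula))


# ---------------------------------------------------------------------------
# Tensorization of a distance formula
# ---------------------------------------------------------------------------

def _probe_directions() -> np.ndarray:
    """The 13 unit probe directions of the RGB frame.

    3 axes, 6 face diagonals and 4 body diagonals -- one representative per
    +-v pair.
    """
    dirs = []
    dirs += [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    dirs += [(1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1)]
    dirs += [(1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)]
    dirs = np.asarray(dirs, dtype=float)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


_PROBES = _probe_directions()


def _clip_psd(t: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix (stack) onto the PSD cone."""
    t = 0.5 * (t + np.swapaxes(t, -1, -2))
    w, v = np.linalg.eigh(t)
    w = np.clip(w, 0.0, None)
    return np.einsum("...ij,...j,...kj->...ik", v, w, v)


def tensor_from_distance_many(formula, z, delta: float = 0.1) -> np.ndarray:
    """Vectorized :func:`tensor_from_distance` over an (N,3) array of points.

    The 13 probe directions and separations are shared across points, so
    the least-squares solve reduces to one pseudoinverse applied to all
    squared-distance vectors at once.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    sep = delta
    half = sep / 2.0
    centre = np.clip(z, half, 1.0 - half)
    a = centre[:, None, :] - half * _PROBES[None, :, :]
    b = centre[:, None, :] + half * _PROBES[None, :, :]
    if callable(formula):
        d = np.asarray(formula(a.reshape(-1, 3), b.reshape(-1, 3)), dtype=float)
    else:
        d = cie_pair_distances(srgb_to_lab(a.reshape(-1, 3)),
                               srgb_to_lab(b.reshape(-1, 3)), formula)
    d2 = (d ** 2).reshape(len(z), len(_PROBES))

    v = sep * _PROBES
    design = np.column_stack([
        v[:, 0] ** 2, v[:, 1] ** 2, v[:, 2] ** 2,
        2 * v[:, 0] * v[:, 1], 2 * v[:, 0] * v[:, 2], 2 * v[:, 1] * v[:, 2],
    ])
    sol = d2 @ np.linalg.pinv(design).T  # (N, 6)
    t = np.empty((len(z), 3, 3))
    t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = sol[:, 0], sol[:, 1], sol[:, 2]
    t[:, 0, 1] = t[:, 1, 0] = sol[:, 3]
    t[:, 0, 2] = t[:, 2, 0] = sol[:, 4]
    t[:, 1, 2] = t[:, 2, 1] = sol[:, 5]
    return _clip_psd(t)


def tensor_from_distance(formula, z, delta: float = 0.1) -> np.ndarray:
    """Estimate the metric tensor of a colour-difference formula at ``z``.

    Distances are computed for 13 colour pairs whose two points sit
    ``delta/2`` either side of ``z`` (pair separation ``delta`` sRGB
    units, matching the half-offset convention of the finite-difference
    derivatives used for the categorical tensor), aligned with the axes,
    face diagonals and body diagonals of the RGB frame.  The symmetric
    tensor ``T`` whose quadratic form best reproduces the squared probe
    distances (``v^T T v ~ d^2`` in least squares) is returned after
    projection onto the PSD cone.

    ``formula`` is one of ``"CIE76" | "CIE94" | "CIE2000"`` or a callable
    ``f(rgb_a, rgb_b) -> distances`` acting on (N,3) sRGB arrays.  Near the
    cube faces the probe set is translated inward so that both ends of
    every pair stay in gamut.
    """
    z = np.asarray(z.rgb if isinstance(z, ColourPoint) else z, dtype=float)
    if z.shape != (3,):
        raise ValueError("z must be a single sRGB triple")
    sep = delta  # probe pair separation in sRGB units
    half = sep / 2.0
    centre = np.clip(z, half, 1.0 - half)

    a = centre[None, :] - half * _PROBES
    b = centre[None, :] + half * _PROBES
    if callable(formula):
        d = np.asarray(formula(a, b), dtype=float)
    else:
        d = cie_pair_distances(srgb_to_lab(a), srgb_to_lab(b), formula)

    v = sep * _PROBES  # separation vectors
    design = np.column_stack([
        v[:, 0] ** 2, v[:, 1] ** 2, v[:, 2] ** 2,
        2 * v[:, 0] * v[:, 1], 2 * v[:, 0] * v[:, 2], 2 * v[:, 1] * v[:, 2],
    ])
    sol, _, rank, _ = np.linalg.lstsq(design, d ** 2, rcond=None)
    if rank < 6:
        raise np.linalg.LinAlgError("degenerate probe set: normal equations singular")
    t11, t22, t33, t12, t13, t23 = sol
    t = np.array([[t11, t12, t13], [t12, t22, t23], [t13, t23, t33]])
    return _clip_psd(t)


# ---------------------------------------------------------------------------
# Standard paths and meshes
# ---------------------------------------------------------------------------

@dataclass
class PathSpec:
    """A sampled 1-D path through the sRGB cube.

    ``vertices`` is an ordered (K,3) array of sRGB triples defining a
    piecewise-linear path; ``closed`` joins the last vertex back to the
    first; ``density`` is the default sampling density in points per unit
    sRGB length used by integrators.
    """

    vertices: np.ndarray
    closed: bool = False
    density: float = 200.0

    def __post_init__(self):
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if len(self.vertices) < 2:
            raise ValueError("a path needs at least two vertices")
        segs = np.diff(self.vertices, axis=0)
        if np.any(np.linalg.norm(segs, axis=1) == 0):
            raise ValueError("consecutive path vertices must be distinct")
        if self.closed and np.allclose(self.vertices[0], self.vertices[-1]):
            # closure is implied by the flag; drop an explicit duplicate
            self.vertices = self.vertices[:-1]

    @property
    def segments(self) -> np.ndarray:
        """(S, 2, 3) array of segment endpoints (including closure)."""
        verts = self.vertices
        if self.closed:
            verts = np.vstack([verts, verts[:1]])
        return np.stack([verts[:-1], verts[1:]], axis=1)

    def euclidean_length(self) -> float:
        """Length of the path in plain sRGB units."""
        segs = self.segments
        return float(np.linalg.norm(segs[:, 1] - segs[:, 0], axis=1).sum())

    def sample(self, density: float | None = None):
        """Sample the path uniformly per segment.

        Returns ``(points, tangents, dl)`` where ``points`` is (M,3),
        ``tangents`` the matching unit tangents and ``dl`` the sRGB length
        step between consecutive samples of the same segment.
        """
        density = density or self.density
        pts, tans, steps = [], [], []
        for p0, p1 in self.segments:
            length = float(np.linalg.norm(p1 - p0))
            n = max(int(np.ceil(length * density)), 2)
            t = np.linspace(0.0, 1.0, n + 1)
            pts.append(p0 + t[:, None] * (p1 - p0))
            tans.append(np.repeat(((p1 - p0) / length)[None, :], n + 1, axis=0))
            steps.append(np.full(n + 1, length / n))
        return np.vstack(pts), np.vstack(tans), np.concatenate(steps)


@dataclass
class MeshSpec:
    """A triangulated 2-D sub-manifold of the sRGB cube.

    ``vertices`` (V,3) sRGB, ``triangles`` (T,3) vertex indices, and
    ``boundary`` an ordered loop of vertex indices (empty for a closed
    surface).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    boundary: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.boundary = np.asarray(self.boundary, dtype=int)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E,2) index array."""
        e = np.vstack([self.triangles[:, [0, 1]],
                       self.triangles[:, [1, 2]],
                       self.triangles[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def interior_mask(self) -> np.ndarray:
        mask = np.ones(len(self.vertices), dtype=bool)
        mask[self.boundary] = False
        return mask


def achromatic_axis(density: float = 200.0) -> PathSpec:
    """The black-to-white diagonal of the sRGB cube."""
    return PathSpec(np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]), density=density)


def full_colour_locus(density: float = 200.0) -> PathSpec:
    """The closed hexagon R->Y->G->C->B->M->R along six cube edges."""
    order = ["red", "yellow", "green", "cyan", "blue", "magenta"]
    verts = np.array([CHROMATIC_VERTICES[k] for k in order])
    return PathSpec(verts, closed=True, density=density)


def standard_paths(density: float = 200.0) -> dict:
    """The two standard 1-D probe paths of the cube."""
    return {
        "achromatic_axis": achromatic_axis(density),
        "full_colour_locus": full_colour_locus(density),
    }


def hue_triangle(corner: str | tuple, subdivisions: int = 20) -> MeshSpec:
    """Planar triangle spanned by black, white and one chromatic vertex.

    Uniform barycentric triangulation with ``subdivisions`` rows; the
    boundary loop runs black -> chromatic corner -> white.
    """
    if isinstance(corner, str):
        try:
            corner = CHROMATIC_VERTICES[corner.lower()]
        except KeyError:
            raise ValueError(f"unknown chromatic vertex {corner!r}; "
                             f"expected one of {sorted(CHROMATIC_VERTICES)}")
    corner = np.asarray(corner, dtype=float)
    if not any(np.allclose(corner, v) for v in CHROMATIC_VERTICES.values()):
        raise ValueError("hue triangle corner must be a chromatic cube vertex")

    black = np.zeros(3)
    white = np.ones(3)
    n = int(subdivisions)
    if n < 1:
        raise ValueError("subdivisions must be >= 1")

    # barycentric lattice: rows i=0..n from black toward white, j=0..i
    verts, index = [], {}
    for i in range(n + 1):
        for j in range(i + 1):
            index[(i, j)] = len(verts)
            # weights: black (1 - i/n), corner along the row, white j/i
            wi = i / n
            wj = (j / i) if i else 0.0
            verts.append((1 - wi) * black + wi * ((1 - wj) * corner + wj * white))
    tris = []
    for i in range(n):
        for j in range(i + 1):
            tris.append([index[(i, j)], index[(i + 1, j)], index[(i + 1, j + 1)]])
            if j < i:
                tris.append([index[(i, j)], index[(i + 1, j + 1)], index[(i, j + 1)]])
    # boundary loop: black -> corner edge (j=0), corner -> white (row n),
    # white -> black (j=i diagonal, descending)
    loop = [index[(i, 0)] for i in range(n + 1)]
    loop += [index[(n, j)] for j in range(1, n + 1)]
    loop += [index[(i, i)] for i in range(n - 1, 0, -1)]
    return MeshSpec(np.asarray(verts), np.asarray(tris), np.asarray(loop))
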