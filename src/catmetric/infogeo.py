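"""Information geometry of naming distributions and the metric tensor field.

A population naming model assigns to every colour ``z`` a probability
distribution over names.  Treating the square roots of those distributions
as points on the unit hypersphere turns colour space into a statistical
manifold: the categorical distance between two infinitesimally close
colours is the angle between their square-rooted naming distributions
(the Bhattacharyya angle), and the Riemannian metric tensor of that
distance can be computed from spatial derivatives of the square-rooted
distribution field.

Numerically the pipeline follows a blur-then-difference scheme: the
distribution field is smoothed with a separable five-point comb filter
(spacing ``delta/3``, weights [1 3 4 3 1]/12, 1-D spread 0.36*delta) and
central differences of the square-rooted, renormalized field with step
``delta`` give the derivative vectors ``dR, dG, dB``; the tensor is
``Gamma = (dR dG dB)^T (dR dG dB)``.  For speed the tensor is pre-computed
on a regular grid (default spacing ``delta/2 = 0.05``) and queried through
separable piecewise-quadratic interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .colour import _clip_psd

__all__ = [
    "kld",
    "jsd",
    "jsd_distance",
    "bhattacharyya_angle",
    "normal_fisher_example",
    "DistributionField",
    "CallableDistributionField",
    "BlurredField",
    "blur_field",
    "comb_filter_sd",
    "metric_tensor",
    "TensorField",
    "tensor_grid",
    "write_tensor_grid",
    "read_tensor_grid",
]


# ---------------------------------------------------------------------------
# Divergences and angles between discrete distributions
# ---------------------------------------------------------------------------

def _check_pair(p, q):
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    return p, q


def kld(p, q) -> float:
    """Kullback-Leibler divergence D(P||Q) in bits.

    Returns ``inf`` when Q lacks mass somewhere P has it (absolute
    continuity failure).
    """
    p, q = _check_pair(p, q)
    support = p > 0
    if np.any(q[support] == 0):
        return math.inf
    return float(np.sum(p[support] * np.log2(p[support] / q[support])))


def jsd(p, q) -> float:
    """Jensen-Shannon divergence in bits: 1/2 [D(P||M) + D(Q||M)], M=(P+Q)/2."""
    p, q = _check_pair(p, q)
    m = 0.5 * (p + q)
    return 0.5 * (kld(p, m) + kld(q, m))


def jsd_distance(p, q) -> float:
    """The metric form sqrt(JSD)."""
    return math.sqrt(jsd(p, q))


def bhattacharyya_angle(p, q) -> float:
    """Angle in [0, pi/2] between sqrt(P) and sqrt(Q) on the unit sphere.

    arccos of the Bhattacharyya coefficient sum(sqrt(P*Q)); for close
    distributions it equals the Euclidean norm of sqrt(P)-sqrt(Q).
    """
    p, q = _check_pair(p, q)
    coeff = float(np.sum(np.sqrt(p * q)))
    return math.acos(min(max(coeff, 0.0), 1.0))


def normal_fisher_example(mu1: float, sigma1: float, mu2: float, sigma2: float) -> float:
    """Infinitesimal Fisher distance on the univariate normal manifold.

    ds = sqrt(dmu^2/4 + dsigma^2/2) / sigma, evaluated at the base point
    ``(mu1, sigma1)``.  Serves as a closed-form oracle for the
    sqrt-embedding pipeline on a parametric family: for small
    displacements the numerical Bhattacharyya angle between the two
    normal densities converges to this value.
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("sigma must be positive")
    dmu = mu2 - mu1
    dsig = sigma2 - sigma1
    return math.sqrt(0.25 * dmu ** 2 + 0.5 * dsig ** 2) / sigma1


# ---------------------------------------------------------------------------
# Distribution fields over the sRGB cube
# ---------------------------------------------------------------------------

class DistributionField:
    """A map from sRGB colours to probability vectors over a name vocabulary.

    Subclasses implement :meth:`rates` returning an (N, V) row-stochastic
    array for an (N, 3) array of sRGB points.
    """

    vocabulary: tuple

    @property
    def n_names(self) -> int:
        return len(self.vocabulary)

    def rates(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.rates(pts)


class CallableDistributionField(DistributionField):
    """Wrap a plain function ``(N,3) -> (N,V)`` as a distribution field."""

    def __init__(self, fn, vocabulary):
        self._fn = fn
        self.vocabulary = tuple(vocabulary)

    def rates(self, points: np.ndarray) -> np.ndarray:
        out = np.asarray(self._fn(points), dtype=float)
        return out


COMB_WEIGHTS = np.array([1.0, 3.0, 4.0, 3.0, 1.0]) / 12.0


def comb_filter_sd(delta: float = 0.1) -> float:
    """1-D spatial spread (standard deviation) of the comb filter: 0.36*delta."""
    offsets = (delta / 3.0) * np.arange(-2, 3)
    return float(np.sqrt(np.sum(COMB_WEIGHTS * offsets ** 2)))


class BlurredField(DistributionField):
    """A distribution field smoothed by the separable 5-point comb filter.

    The filter is the 3-D outer product of a 1-D dirac-comb with spacing
    ``delta/3`` and weights [1 3 4 3 1]/12.  Sample points falling outside
    the cube are clamped to it (replicate boundary), and the blurred rates
    are renormalized to unit sum.
    """

    def __init__(self, base: DistributionField, delta: float = 0.1):
        self.base = base
        self.delta = float(delta)
        self.vocabulary = tuple(base.vocabulary)
        step = self.delta / 3.0
        g = step * np.arange(-2, 3)
        ox, oy, oz = np.meshgrid(g, g, g, indexing="ij")
        self._offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
        w = COMB_WEIGHTS
        self._weights = np.einsum("i,j,k->ijk", w, w, w).ravel()

    def rates(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        probe = np.clip(pts[:, None, :] + self._offsets[None, :, :], 0.0, 1.0)
        raw = self.base.rates(probe.reshape(-1, 3))
        raw = raw.reshape(len(pts), len(self._weights), -1)
        out = np.einsum("k,nkv->nv", self._weights, raw)
        return out / out.sum(axis=1, keepdims=True)


def blur_field(field: DistributionField, delta: float = 0.1) -> BlurredField:
    """Apply the comb-filter blur used before computing metric tensors."""
    return BlurredField(field, delta)


# ---------------------------------------------------------------------------
# Metric tensors from the sqrt-distribution field
# ---------------------------------------------------------------------------

def _sqrt_derivatives(field: DistributionField, points: np.ndarray, delta: float) -> np.ndarray:
    """Central differences of sqrt(field) along R, G, B at each point.

    Returns (N, 3, V): derivative vector per axis.  Near a cube face the
    step is clamped to stay in gamut (one-sided exactly on the face) and
    the normalisation uses the realised step length.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    half = delta / 2.0
    probes = np.empty((n, 3, 2, 3))
    spans = np.empty((n, 3))
    for axis in range(3):
        h_lo = np.minimum(half, pts[:, axis])
        h_hi = np.minimum(half, 1.0 - pts[:, axis])
        lo = pts.copy()
        hi = pts.copy()
        lo[:, axis] -= h_lo
        hi[:, axis] += h_hi
        probes[:, axis, 0] = lo
        probes[:, axis, 1] = hi
        spans[:, axis] = h_lo + h_hi
    rates = field.rates(probes.reshape(-1, 3))
    v = rates.shape[-1]
    rates = np.sqrt(rates.reshape(n, 3, 2, v))
    return (rates[:, :, 1] - rates[:, :, 0]) / spans[:, :, None]


def metric_tensor(field: DistributionField, z, delta: float = 0.1) -> np.ndarray:
    """The categorical metric tensor Gamma at colour(s) ``z``.

    ``field`` should normally be the blurred, fitted distribution field
    (see :func:`blur_field`).  For a single triple a (3,3) array is
    returned, for an (N,3) array an (N,3,3) stack.  Tensors are symmetric
    PSD by construction (Gamma = D^T D with D the per-axis derivative
    vectors of the square-rooted field).
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    d = _sqrt_derivatives(field, z, delta)
    gamma = np.einsum("nav,nbv->nab", d, d)
    return gamma[0] if single else gamma


# ---------------------------------------------------------------------------
# Tensor grids and interpolation
# ---------------------------------------------------------------------------

@dataclass
class TensorField:
    """3x3 symmetric PSD metric tensors sampled on a regular cube grid.

    ``data`` has shape (n, n, n, 3, 3) with node ``(i, j, k)`` at sRGB
    location ``(i, j, k) * spacing`` -- the R index varies fastest in the
    serialized form.  Queries between nodes use separable piecewise-
    quadratic interpolation (3-point Lagrange stencil centred on the
    nearest node), PSD-clipped after interpolation.
    """

    spacing: float
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if self.data.shape != (n, n, n, 3, 3):
            raise ValueError("tensor grid must have shape (n, n, n, 3, 3)")
        if not np.isclose((n - 1) * self.spacing, 1.0, atol=1e-9):
            raise ValueError("grid must cover [0,1]^3 inclusive: "
                             "(n-1) * spacing must equal 1")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    def nodes(self) -> np.ndarray:
        g = np.arange(self.n_nodes) * self.spacing
        x, y, z = np.meshgrid(g, g, g, indexing="ij")
        return np.column_stack([x.ravel(), y.ravel(), z.ravel()])

    def tensor(self, z) -> np.ndarray:
        """Interpolated tensor at sRGB point(s) ``z`` inside [0,1]^3."""
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        pts = np.atleast_2d(z)
        if np.any(pts < -1e-9) or np.any(pts > 1 + 1e-9):
            raise ValueError("tensor field query outside [0,1]^3")
        pts = np.clip(pts, 0.0, 1.0)
        n = self.n_nodes
        u = pts / self.spacing
        centre = np.clip(np.rint(u).astype(int), 1, n - 2)
        t = u - centre  # in [-1, 1] around the stencil centre
        # Lagrange weights on offsets (-1, 0, +1) per axis: (N, 3axes, 3)
        w = np.stack([0.5 * t * (t - 1.0), 1.0 - t ** 2, 0.5 * t * (t + 1.0)],
                     axis=-1)
        out = np.zeros((len(pts), 3, 3))
        for a in (-1, 0, 1):
            for b in (-1, 0, 1):
                wab = w[:, 0, a + 1] * w[:, 1, b + 1]
                for c in (-1, 0, 1):
                    coef = wab * w[:, 2, c + 1]
                    out += coef[:, None, None] * self.data[
                        centre[:, 0] + a, centre[:, 1] + b, centre[:, 2] + c]
        out = _clip_psd(out)
        return out[0] if single else out


def tensor_grid(field: DistributionField, spacing: float = 0.05,
                delta: float = 0.1, chunk: int = 512) -> TensorField:
    """Pre-compute the metric tensor on a regular grid over the cube.

    ``spacing`` must divide 1 evenly (default delta/2 = 0.05 giving 21^3
    nodes).  Node tensors equal :func:`metric_tensor` evaluated at the
    node exactly; evaluation is chunked to bound memory.
    """
    n = round(1.0 / spacing) + 1
    if not np.isclose((n - 1) * spacing, 1.0, atol=1e-9):
        raise ValueError("spacing must divide 1 evenly")
    g = np.arange(n) * spacing
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    out = np.empty((len(pts), 3, 3))
    for start in range(0, len(pts), chunk):
        sl = slice(start, start + chunk)
        out[sl] = metric_tensor(field, pts[sl], delta)
    return TensorField(spacing=spacing, data=out.reshape(n, n, n, 3, 3))


_UT = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def write_tensor_grid(tf: TensorField, path) -> None:
    """Serialize a tensor grid as plain text.

    Header comments record the spacing and ordering; each row is
    ``i j k T11 T12 T13 T22 T23 T33`` (upper triangle), R index fastest.
    """
    n = tf.n_nodes
    with open(path, "w") as fh:
        fh.write("# catmetric tensor grid\n")
        fh.write(f"# spacing: {tf.spacing!r}\n")
        fh.write(f"# nodes per axis: {n}\n")
        fh.write("# order: R-fastest; columns: i j k T11 T12 T13 T22 T23 T33\n")
        for k in range(n):
            for j in range(n):
                for i in range(n):
                    t = tf.data[i, j, k]
                    comps = " ".join(f"{t[a, b]:.17g}" for a, b in _UT)
                    fh.write(f"{i} {j} {k} {comps}\n")


def _tensor_from_components(vals: np.ndarray) -> np.ndarray:
    """(N,6) upper-triangle components or (N,9) row-major -> (N,3,3)."""
    if vals.shape[1] == 9:
        return vals.reshape(-1, 3, 3)
    t = np.empty((len(vals), 3, 3))
    for idx, (a, b) in enumerate(_UT):
        t[:, a, b] = vals[:, idx]
        t[:, b, a] = vals[:, idx]
    return t


def read_tensor_grid(path, dialect: str = "catmetric") -> TensorField:
    """Read a tensor grid written by :func:`write_tensor_grid`.

    ``dialect="serial"`` is a tolerant import shim for externally released
    tensor-grid supplements: comment lines are skipped and each data row
    may carry 6 (upper triangle) or 9 (full row-major) tensor components,
    optionally preceded by three node indices or coordinates; rows are
    assumed R-fastest.  The assumed layout is a documented guess -- it
    cannot be validated without the external file.
    """
    spacing = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "spacing:" in line:
                    spacing = float(line.split("spacing:")[1].strip())
                continue
            try:
                rows.append([float(x) for x in line.replace(",", " ").split()])
            except ValueError:
                raise ValueError(f"{path}: malformed row at line {lineno}")
    if not rows:
        raise ValueError(f"{path}: empty tensor grid")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: inconsistent row widths")
    arr = np.asarray(rows, dtype=float)

    if dialect == "catmetric":
        if width != 9:
            raise ValueError(f"{path}: expected 9 columns (i j k + 6 components)")
        idx, vals = arr[:, :3].astype(int), arr[:, 3:]
    elif dialect == "serial":
        if width in (6, 9):
            idx, vals = None, arr
        elif width in (9 + 3, 6 + 3):
            idx, vals = arr[:, :3], arr[:, 3:]
        else:
            raise ValueError(f"{path}: unrecognized serial-layout row width {width}")
    else:
        raise ValueError(f"unknown tensor grid dialect {dialect!r}")

    n = round(len(arr) ** (1.0 / 3.0))
    if n ** 3 != len(arr):
        raise ValueError(f"{path}: {len(arr)} rows is not a cubic node count")
    if spacing is None:
        spacing = 1.0 / (n - 1)
    if round(1.0 / spacing) + 1 != n:
        raise ValueError(f"{path}: {n} nodes per axis inconsistent with "
                         f"spacing {spacing}")

    tensors = _tensor_from_components(vals)
    bad = np.nonzero(~np.isfinite(tensors).all(axis=(1, 2)))[0]
    if len(bad):
        raise ValueError(f"{path}: non-finite tensor at row {bad[0] + 1}")
    if dialect == "catmetric":
        data = np.empty((n, n, n, 3, 3))
        i, j, k = idx[:, 0].astype(int), idx[:, 1].astype(int), idx[:, 2].astype(int)
        data[i, j, k] = tensors
    else:
        # serial R-fastest order: row index = k*n^2 + j*n + i
        data = np.transpose(tensors.reshape(n, n, n, 3, 3), (2, 1, 0, 3, 4))
    return TensorField(spacing=spacing, data=data)
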