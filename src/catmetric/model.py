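"""Parametric model of population colour-naming rates.

Each name ``n`` gets a unimodal response-rate function over CIELAB

    Q_n(z) = gamma * g_n + (1 - gamma) * k_n * exp(-1/2 * m(z)^alpha_n),
    m(z)   = (z - mu_n)^T Sigma_n^{-1} (z - mu_n),

with peak rate ``k_n`` at location ``mu_n``, a 3x3 SPD covariance
``Sigma_n`` (eigenvalues floored at 3.0^2 CIELAB^2 so categories cannot be
implausibly tight), a sharpness exponent ``alpha_n`` in [0.5, 3.0]
(alpha=1 is a Gaussian falloff, larger values plateau then drop faster),
and a small stimulus-independent lapse process ``gamma * g_n`` fed by the
name's global rate ``g_n``.

Names are fitted independently by gradient ascent of the binomial
log-likelihood minus the penalty ``lambda * (k_n |Sigma_n|)^0.12``
-- the 0.12 power matching the empirically exponential law of transformed
global rates, so the penalty acts as a prior pulling response functions
toward smaller support and lower peaks.  Normalizing the fitted rates,
P_n(z) = Q_n(z) / sum_s Q_s(z), yields the distribution field from which
the categorical metric is computed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from .colour import srgb_to_lab
from .infogeo import DistributionField
from .naming import NamingTable, global_rates

__all__ = [
    "NameParams",
    "ResponseModel",
    "ModelField",
    "q_rate",
    "name_log_likelihood",
    "fit_name",
    "fit_model",
    "normalize_model",
    "model_comparison",
    "bhattacharyya_bias_demo",
    "model_to_json",
    "model_from_json",
]

SIGMA_EIGENVALUE_FLOOR = 3.0 ** 2  # CIELAB^2
ALPHA_BOUNDS = (0.5, 3.0)
DEFAULT_GAMMA = 0.01
DEFAULT_LAMBDA = 100.0
PENALTY_EXPONENT = 0.12


@dataclass
class NameParams:
    """Parameters of one name's response-rate function (CIELAB units)."""

    k: float
    mu: np.ndarray
    sigma: np.ndarray
    alpha: float
    g: float

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).reshape(3)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(3, 3)

    def validate(self) -> "NameParams":
        """Check the box constraints and the covariance eigenvalue floor."""
        if not (0.0 < self.k <= 1.0):
            raise ValueError("peak rate k must lie in (0, 1]")
        if not (ALPHA_BOUNDS[0] - 1e-9 <= self.alpha <= ALPHA_BOUNDS[1] + 1e-9):
            raise ValueError(f"alpha must lie in {ALPHA_BOUNDS}")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("Sigma must be symmetric")
        w = np.linalg.eigvalsh(self.sigma)
        tol = 1e-6 + 1e-10 * float(abs(w).max())
        if w.min() < SIGMA_EIGENVALUE_FLOOR - tol:
            raise ValueError("Sigma eigenvalues must be >= 3.0^2 CIELAB^2")
        return self


def q_rate(params: NameParams, gamma: float, z, coords: str = "rgb") -> np.ndarray:
    """Response rate Q_n at colour(s) ``z``.

    ``z`` is a triple or (N,3) array, in sRGB by default or CIELAB with
    ``coords="lab"``.  Strictly positive, bounded below by the lapse floor
    ``gamma * g`` and monotone nonincreasing in the Mahalanobis distance
    from the peak.
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    lab = np.atleast_2d(z if coords == "lab" else srgb_to_lab(z))
    diff = lab - params.mu
    try:
        sol = np.linalg.solve(params.sigma, diff.T).T
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular Sigma in q_rate")
    m = np.einsum("ni,ni->n", diff, sol)
    rate = gamma * params.g + (1 - gamma) * params.k * np.exp(-0.5 * m ** params.alpha)
    return float(rate[0]) if single else rate


@dataclass
class ResponseModel:
    """A fitted set of per-name rate functions plus the lapse rate.

    ``params`` maps each vocabulary name to its :class:`NameParams`;
    global rates carried inside the params sum to 1 over the vocabulary.
    ``diagnostics`` holds per-name fit records (objective values etc.).
    """

    params: dict
    gamma: float = DEFAULT_GAMMA
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must lie in [0, 1)")
        gsum = sum(p.g for p in self.params.values())
        if abs(gsum - 1.0) > 1e-6:
            raise ValueError("global rates g_n must sum to 1 over the vocabulary")

    @property
    def vocabulary(self) -> tuple:
        return tuple(self.params)

    def q_matrix(self, z, coords: str = "rgb") -> np.ndarray:
        """(N, V) matrix of un-normalized rates Q_n."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        lab = z if coords == "lab" else srgb_to_lab(z)
        return np.column_stack([
            q_rate(p, self.gamma, lab, coords="lab") for p in self.params.values()
        ])

    def predict(self, z, coords: str = "rgb") -> np.ndarray:
        """Normalized naming distribution(s) P_n(z) = Q_n / sum_s Q_s."""
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        q = self.q_matrix(np.atleast_2d(z), coords=coords)
        p = q / q.sum(axis=1, keepdims=True)
        return p[0] if single else p

    def field(self, normalized: bool = True) -> "ModelField":
        return ModelField(self, normalized=normalized)


class ModelField(DistributionField):
    """The model's naming distributions as a field over sRGB.

    By default the normalized P_n; with ``normalized=False`` the raw
    rates Q_n, for pipelines that blur before normalizing (the blur
    stage renormalizes its output either way).
    """

    def __init__(self, model: ResponseModel, normalized: bool = True):
        self.model = model
        self.normalized = normalized
        self.vocabulary = model.vocabulary

    def rates(self, points: np.ndarray) -> np.ndarray:
        if self.normalized:
            return self.model.predict(points)
        return self.model.q_matrix(points)


def normalize_model(model: ResponseModel, z) -> np.ndarray:
    """Probability vector over the vocabulary at colour ``z`` (sums to 1,
    all entries positive thanks to the lapse floor)."""
    return model.predict(z)


# ---------------------------------------------------------------------------
# Likelihood and fitting
# ---------------------------------------------------------------------------

def _binomial_terms(r: np.ndarray, s: np.ndarray) -> np.ndarray:
    return gammaln(r + s + 1) - gammaln(r + 1) - gammaln(s + 1)


def name_log_likelihood(table: NamingTable, name: str, params: NameParams,
                        gamma: float = DEFAULT_GAMMA) -> float:
    """Binomial log-likelihood (natural log) of one name's counts.

    L_n = sum_c [ b_n(c) + r_n(c) ln Q_n(c) + s_n(c) ln(1 - Q_n(c)) ]
    with b_n the log binomial coefficient ln C(r+s, r).
    """
    idx = table.vocabulary.index(name)
    r = table.counts[:, idx].astype(float)
    s = table.row_totals().astype(float) - r
    q = q_rate(params, gamma, table.chips)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("model rate hit 0 or 1 exactly; likelihood undefined")
    return float(np.sum(_binomial_terms(r, s) + r * np.log(q) + s * np.log1p(-q)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


_MU_SCALE = 25.0  # CIELAB units per unit of the optimizer's mu coordinates


def _unpack(theta: np.ndarray, g: float) -> NameParams:
    k = float(_sigmoid(np.clip(theta[0], -30, 30)))
    mu = _MU_SCALE * theta[1:4]
    ell = np.zeros((3, 3))
    ell[0, 0], ell[1, 1], ell[2, 2] = np.exp(np.clip(theta[4:7], -6.0, 8.0))
    ell[1, 0], ell[2, 0], ell[2, 1] = np.clip(theta[7:10], -1e3, 1e3)
    sigma = ell @ ell.T + SIGMA_EIGENVALUE_FLOOR * np.eye(3)
    alpha = ALPHA_BOUNDS[0] + (ALPHA_BOUNDS[1] - ALPHA_BOUNDS[0]) * float(
        _sigmoid(np.clip(theta[10], -30, 30)))
    return NameParams(k=max(k, 1e-12), mu=mu, sigma=sigma, alpha=alpha, g=g)


def _initial_theta(lab: np.ndarray, r: np.ndarray, s: np.ndarray) -> np.ndarray:
    w = r / r.sum()
    mu0 = w @ lab
    diff = lab - mu0
    cov0 = (w[:, None] * diff).T @ diff
    rates = np.divide(r, r + s, out=np.zeros_like(r, dtype=float), where=(r + s) > 0)
    k0 = float(np.clip(rates.max(initial=0.0), 0.05, 0.95))
    # Sigma = L L^T + floor * I  =>  target L L^T = cov0 - floor * I (PSD part)
    wv, vv = np.linalg.eigh(0.5 * (cov0 + cov0.T))
    wv = np.clip(wv - SIGMA_EIGENVALUE_FLOOR, 1.0, None)
    ell = np.linalg.cholesky(vv @ np.diag(wv) @ vv.T + 1e-9 * np.eye(3))
    theta = np.empty(11)
    theta[0] = np.log(k0 / (1 - k0))
    theta[1:4] = mu0 / _MU_SCALE
    theta[4:7] = np.log(np.diag(ell))
    theta[7:10] = ell[1, 0], ell[2, 0], ell[2, 1]
    theta[10] = 0.0  # alpha = 1.75 midpoint of [0.5, 3.0]
    return theta


def fit_name(table: NamingTable, name: str, lam: float = DEFAULT_LAMBDA,
             gamma: float = DEFAULT_GAMMA, restarts: int = 5,
             seed: int = 0, maxiter: int = 300):
    """Fit one name's rate function by penalized maximum likelihood.

    Maximizes ``L_n - lam * (k_n |Sigma_n|)**0.12`` by quasi-Newton
    (L-BFGS) ascent in an unconstrained parameterization (logistic boxes
    for k and alpha, scaled location, log-Cholesky covariance with an
    additive eigenvalue floor), from ``restarts`` starts -- the first
    seeded from the name's response-weighted mean/covariance, the rest
    jittered.  The restart
    jitter stream is derived from ``seed`` and a stable hash of the name,
    so per-name fits are independent of vocabulary or execution order.
    Returns ``(NameParams, info)`` with the objective and convergence
    status of the best start.
    """
    idx = table.vocabulary.index(name)
    r = table.counts[:, idx].astype(float)
    if r.sum() < 2:
        raise ValueError(f"name {name!r} has fewer than 2 responses")
    s = table.row_totals().astype(float) - r
    lab = srgb_to_lab(table.chips)
    g = float(global_rates(table)[idx])
    bsum = float(np.sum(_binomial_terms(r, s)))

    def objective(theta: np.ndarray) -> float:
        p = _unpack(theta, g)
        q = q_rate(p, gamma, lab, coords="lab")
        q = np.clip(q, 1e-300, 1 - 1e-12)
        loglik = bsum + float(np.sum(r * np.log(q) + s * np.log1p(-q)))
        penalty = lam * (p.k * np.linalg.det(p.sigma)) ** PENALTY_EXPONENT
        return -(loglik - penalty)

    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))
    theta0 = _initial_theta(lab, r, s)
    best, best_val, converged = None, np.inf, False
    for trial in range(max(restarts, 1)):
        start = theta0.copy()
        if trial:
            start[0] += rng.normal(0, 0.5)
            start[1:4] += rng.normal(0, 5.0 / _MU_SCALE, size=3)
            start[4:7] += rng.normal(0, 0.3, size=3)
            start[10] += rng.normal(0, 0.5)
        res = optimize.minimize(objective, start, method="L-BFGS-B",
                                options={"maxiter": maxiter})
        for cand_val, cand_x, cand_ok in ((res.fun, res.x, res.success),
                                          (objective(start), start, False)):
            if cand_val < best_val:
                best_val, best, converged = cand_val, cand_x, cand_ok
    info = {"objective": -best_val, "converged": bool(converged)}
    return _unpack(best, g).validate(), info


def fit_model(table: NamingTable, lam: float = DEFAULT_LAMBDA,
              gamma: float = DEFAULT_GAMMA, restarts: int = 5,
              seed: int = 0, maxiter: int = 300) -> ResponseModel:
    """Fit every vocabulary name independently; see :func:`fit_name`."""
    params, diags = {}, {}
    for name in table.vocabulary:
        p, info = fit_name(table, name, lam=lam, gamma=gamma,
                           restarts=restarts, seed=seed, maxiter=maxiter)
        params[name] = p
        diags[name] = info
    return ResponseModel(params=params, gamma=gamma, diagnostics=diags)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def _multinomial_loglik(counts: np.ndarray, probs: np.ndarray) -> float:
    """Multinomial log-likelihood per chip (natural log), coefficient included."""
    counts = counts.astype(float)
    tot = counts.sum(axis=1)
    coeff = gammaln(tot + 1) - gammaln(counts + 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(probs), 0.0)
    return float(coeff.sum() + np.nansum(terms))


def model_comparison(table: NamingTable, model: ResponseModel) -> dict:
    """Compare baseline / fitted / saturated models on one response table.

    * baseline: the global rates g_n at every chip (V - 1 parameters);
    * fitted: the normalized model P_n at each chip (12 V parameters --
      1 peak + 3 location + 6 covariance + 1 sharpness + 1 global rate);
    * saturated: the empirical per-chip frequencies (C (V - 1) parameters).

    Deviances (twice the log-likelihood difference) are judged against the
    parameter-count difference, the AIC rule of thumb for nested models.
    """
    if set(model.vocabulary) != set(table.vocabulary):
        raise ValueError("model and table vocabularies differ")
    counts = table.counts
    n_chips, v = counts.shape
    g = global_rates(table)

    # align model columns with the table's vocabulary ordering
    order = [model.vocabulary.index(n) for n in table.vocabulary]
    ll_base = _multinomial_loglik(counts, np.tile(g, (n_chips, 1)))
    ll_fit = _multinomial_loglik(counts, model.predict(table.chips)[:, order])
    row = counts.sum(axis=1, keepdims=True).astype(float)
    ll_sat = _multinomial_loglik(counts, counts / row)

    out = {
        "baseline": {"log_likelihood": ll_base, "n_parameters": v - 1},
        "fitted": {"log_likelihood": ll_fit, "n_parameters": 12 * v},
        "saturated": {"log_likelihood": ll_sat,
                      "n_parameters": n_chips * (v - 1)},
    }
    dev_fb = 2 * (ll_fit - ll_base)
    dpar_fb = out["fitted"]["n_parameters"] - out["baseline"]["n_parameters"]
    dev_sf = 2 * (ll_sat - ll_fit)
    dpar_sf = out["saturated"]["n_parameters"] - out["fitted"]["n_parameters"]
    out["fitted_vs_baseline"] = {
        "deviance": dev_fb, "parameter_difference": dpar_fb,
        "preferred": "fitted" if dev_fb > dpar_fb else "baseline",
    }
    out["saturated_vs_fitted"] = {
        "deviance": dev_sf, "parameter_difference": dpar_sf,
        "preferred": "saturated" if dev_sf > dpar_sf else "fitted",
    }
    return out


# ---------------------------------------------------------------------------
# Sampling-bias demonstration
# ---------------------------------------------------------------------------

def bhattacharyya_bias_demo(n_samples: int = 31, exponent: float = 1.4,
                            support: int = 804, reps: int = 10_000,
                            seed: int = 0) -> dict:
    """Monte Carlo demonstration of the sampling bias of the angle.

    Draws pairs of ``n_samples``-sample empirical distributions from the
    rank-power-law multinomial (probabilities proportional to
    rank^-exponent over ``support`` ranks) and measures the Bhattacharyya
    angle between the two empirical frequency vectors of each pair.  For
    identical population distributions the true angle is zero, so any
    positive mean is pure small-sample bias.  Also reports the number of
    distinct names and the empirical entropy of the sampled sets, the
    statistics used to match the simulation to a typical chip.
    """
    from .synth import rank_power_distribution

    if support < 1:
        raise ValueError("support must be >= 1")
    p = rank_power_distribution(exponent=exponent, support=support)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_samples, p, size=(reps, 2))
    freq = counts / n_samples
    coeff = np.sqrt(freq[:, 0] * freq[:, 1]).sum(axis=1)
    angles = np.arccos(np.clip(coeff, 0.0, 1.0))

    first = freq[:, 0]
    distinct = (counts[:, 0] > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(first > 0, first * np.log2(first), 0.0).sum(axis=1)
    return {
        "mean_angle": float(angles.mean()),
        "sd_angle": float(angles.std(ddof=1)),
        "median_distinct": float(np.median(distinct)),
        "mean_entropy": float(ent.mean()),
        "median_entropy": float(np.median(ent)),
        "leading_probabilities": p[:4].copy(),
    }


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_UT6 = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def model_to_json(model: ResponseModel, path=None) -> str:
    """Serialize a model to JSON (Sigma as 6 upper-triangle entries)."""
    doc = {
        "gamma": model.gamma,
        "names": [
            {
                "name": n,
                "k": p.k,
                "mu": list(map(float, p.mu)),
                "sigma_upper": [float(p.sigma[a, b]) for a, b in _UT6],
                "alpha": p.alpha,
                "g": p.g,
            }
            for n, p in model.params.items()
        ],
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def model_from_json(source) -> ResponseModel:
    """Load a model written by :func:`model_to_json` (path or JSON text)."""
    try:
        with open(source) as fh:
            doc = json.load(fh)
    except (OSError, TypeError):
        doc = json.loads(source)
    params = {}
    for rec in doc["names"]:
        sigma = np.empty((3, 3))
        for val, (a, b) in zip(rec["sigma_upper"], _UT6):
            sigma[a, b] = sigma[b, a] = val
        params[rec["name"]] = NameParams(k=rec["k"], mu=rec["mu"], sigma=sigma,
                                         alpha=rec["alpha"], g=rec["g"])
    return ResponseModel(params=params, gamma=doc["gamma"])
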