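"""Synthetic data generators for the categorical-geometry pipeline.

Three generators make every stage testable without any collected dataset:

* toy 1-D colour manifolds with a handful of overlapping unimodal naming
  categories (broad *chromatic* names, narrow low-peak *tonal* names),
  pushed through the full sqrt-embedding pipeline in closed form;
* the rank-power-law multinomial (probabilities proportional to
  rank^-1.4) that mimics the naming distribution of a typical chip and
  drives the sampling-bias demonstration;
* full synthetic naming datasets drawn from a known response model over a
  jittered chip grid, with subject blocks of 20 presentations (the 18th a
  repeat of the 3rd) so agreement statistics are exercised.

Generator defaults emulate the study conditions: ~512 chips spanning the
cube (a jittered 8x8x8 grid), ~31 responses per chip, a 1% lapse rate and
global rates that are exponential after a 0.12 power transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colour import srgb_to_lab
from .infogeo import bhattacharyya_angle
from .model import NameParams, ResponseModel

__all__ = [
    "ToyName",
    "ToyCategorySpec",
    "chromatic_spec",
    "tonal_spec",
    "combined_spec",
    "toy_manifold",
    "rank_power_distribution",
    "RankPowerMultinomial",
    "chip_grid",
    "demo_model",
    "binomial_name_table",
    "synthetic_naming_dataset",
]


# ---------------------------------------------------------------------------
# Toy 1-D manifolds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyName:
    """One category on the toy 1-D manifold t in [0, 1].

    A Gaussian bump ``peak * exp(-(t-loc)^2 / 2 width^2)`` by default; with
    ``hard=True`` an indicator ``peak * 1[|t-loc| < width]`` for building
    exactly disjoint categories.
    """

    name: str
    loc: float
    width: float
    peak: float
    kind: str = "chromatic"
    hard: bool = False

    def rate(self, t: np.ndarray) -> np.ndarray:
        if self.hard:
            return self.peak * (np.abs(t - self.loc) < self.width)
        return self.peak * np.exp(-0.5 * ((t - self.loc) / self.width) ** 2)


@dataclass(frozen=True)
class ToyCategorySpec:
    names: tuple

    def distributions(self, t: np.ndarray) -> np.ndarray:
        q = np.column_stack([n.rate(t) for n in self.names])
        tot = q.sum(axis=1, keepdims=True)
        if np.any(tot <= 0):
            raise ValueError("toy rates must have positive sum everywhere")
        return q / tot


def chromatic_spec() -> ToyCategorySpec:
    """Three broad chromatic categories; the middle one never reaches 100%."""
    return ToyCategorySpec((
        ToyName("blue", -0.15, 0.18, 1.0),
        ToyName("turquoise", 0.45, 0.10, 0.55),
        ToyName("green", 1.15, 0.18, 1.0),
    ))


def tonal_spec() -> ToyCategorySpec:
    """Five narrow, low-peak, barely overlapping tonal categories."""
    return ToyCategorySpec(tuple(
        ToyName(f"tone{i}", 0.1 + 0.2 * i, 0.045, 0.12, kind="tonal")
        for i in range(5)
    ))


def combined_spec() -> ToyCategorySpec:
    return ToyCategorySpec(chromatic_spec().names + tonal_spec().names)


def toy_manifold(spec: ToyCategorySpec, n_points: int = 2001) -> dict:
    """Run the full 1-D categorical pipeline on a toy naming spec.

    The sqrt-distribution curve lives on the unit hypersphere; summing the
    Bhattacharyya angles between consecutive sample points gives the
    categorical length (exact even across instantaneous handovers).
    Returns the sampled distributions, the local metric (squared
    categorical speed per unit t), the isometric warp (cumulative length),
    the length in grains, the 1-D capacity (two endpoints) and the spread
    of log2 of the metric where it is positive.
    """
    from .geometry import G1, capacity

    t = np.linspace(0.0, 1.0, n_points)
    p = spec.distributions(t)
    sq = np.sqrt(p)
    dots = np.clip(np.einsum("nv,nv->n", sq[:-1], sq[1:]), -1.0, 1.0)
    steps = np.arccos(dots)
    cumulative = np.concatenate([[0.0], np.cumsum(steps)])
    total = float(cumulative[-1])
    dt = t[1] - t[0]
    speed = steps / dt
    metric = speed ** 2
    positive = metric > 1e-20
    sd_log2 = float(np.std(np.log2(metric[positive]))) if positive.any() else 0.0
    return {
        "t": t,
        "distributions": p,
        "speed": speed,
        "metric": metric,
        "warp": cumulative,
        "raw_length": total,
        "grains": total / G1,
        "capacity": capacity(total / G1, boundary_grains=2, dim=1),
        "sd_log2_metric": sd_log2,
    }


# ---------------------------------------------------------------------------
# Rank-power-law multinomial
# ---------------------------------------------------------------------------

def rank_power_distribution(exponent: float = 1.4, support: int = 804) -> np.ndarray:
    """Probabilities proportional to rank^-exponent over ``support`` ranks."""
    if support < 1:
        raise ValueError("support must be >= 1")
    p = np.arange(1, support + 1, dtype=float) ** (-exponent)
    return p / p.sum()


@dataclass
class RankPowerMultinomial:
    """The rank-decay multinomial used to model a typical chip's responses."""

    exponent: float = 1.4
    support: int = 804
    probabilities: np.ndarray = field(init=False)

    def __post_init__(self):
        self.probabilities = rank_power_distribution(self.exponent, self.support)

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Counts over the support from ``n`` draws (deterministic per seed)."""
        rng = np.random.default_rng(seed)
        return rng.multinomial(n, self.probabilities)

    def empirical_angle(self, n: int, seed=None) -> float:
        """Bhattacharyya angle between two fresh n-sample empirical copies."""
        rng = np.random.default_rng(seed)
        a = rng.multinomial(n, self.probabilities) / n
        b = rng.multinomial(n, self.probabilities) / n
        return bhattacharyya_angle(a, b)


# ---------------------------------------------------------------------------
# Synthetic naming datasets
# ---------------------------------------------------------------------------

def chip_grid(n: int = 8, jitter: float = 0.3, seed=0) -> np.ndarray:
    """A jittered n^3 grid of chips spanning the sRGB cube (default 512,
    emulating the ~600 well-spaced stimuli of a naming study)."""
    rng = np.random.default_rng(seed)
    g = (np.arange(n) + 0.5) / n
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    pts = pts + rng.uniform(-0.5, 0.5, size=pts.shape) * (jitter / n)
    return np.clip(pts, 0.0, 1.0)


_DEMO_ANCHORS = {
    # name -> (sRGB anchor, peak rate k, sd in CIELAB, sharpness alpha)
    # chosen so the categories tile the whole cube: the summed raw rates
    # stay well above the lapse floor everywhere, as in real naming data
    # where every colour has names.
    "green": ((0.15, 0.75, 0.25), 0.80, 33.0, 1.2),
    "blue": ((0.2, 0.3, 0.85), 0.80, 32.0, 1.1),
    "red": ((0.85, 0.15, 0.15), 0.75, 30.0, 1.2),
    "purple": ((0.55, 0.15, 0.7), 0.70, 30.0, 1.0),
    "yellow": ((0.92, 0.88, 0.2), 0.70, 27.0, 1.3),
    "brown": ((0.45, 0.3, 0.15), 0.65, 27.0, 1.1),
    "pink": ((0.95, 0.65, 0.75), 0.60, 26.0, 1.0),
    "grey": ((0.55, 0.55, 0.55), 0.55, 36.0, 1.2),
    "white": ((0.97, 0.97, 0.97), 0.70, 24.0, 1.3),
    "black": ((0.04, 0.04, 0.04), 0.80, 26.0, 1.3),
    "cyan": ((0.2, 0.85, 0.85), 0.65, 28.0, 1.1),
    "orange": ((0.95, 0.55, 0.1), 0.60, 24.0, 1.2),
    "magenta": ((0.9, 0.2, 0.8), 0.60, 27.0, 1.1),
}


def demo_model(n_names: int = 13, gamma: float = 0.01) -> ResponseModel:
    """A known response model covering the cube, for tests and examples.

    Categories sit at familiar anchor colours with isotropic CIELAB
    covariances; global rates follow the rank-power law (exponent 1.4)
    over the chosen names, echoing the heavy-tailed rates of real naming
    data.  Fully deterministic.  With fewer than ~10 names parts of the
    cube fall back to the lapse floor, so keep the default for anything
    that exercises the normalized field.
    """
    if not (1 <= n_names <= len(_DEMO_ANCHORS)):
        raise ValueError(f"n_names must be in [1, {len(_DEMO_ANCHORS)}]")
    names = list(_DEMO_ANCHORS)[:n_names]
    g = rank_power_distribution(1.4, n_names)
    params = {}
    for i, name in enumerate(names):
        rgb, k, sd, alpha = _DEMO_ANCHORS[name]
        mu = srgb_to_lab(np.asarray(rgb, dtype=float))
        params[name] = NameParams(k=k, mu=mu, sigma=(sd ** 2) * np.eye(3),
                                  alpha=alpha, g=float(g[i]))
    return ResponseModel(params=params, gamma=gamma)


def binomial_name_table(params, chips=None, n_trials: int = 50,
                        gamma: float = 0.01, seed: int = 0,
                        name: str = "x"):
    """Exact-model recovery harness for a single name's rate function.

    Draws ``r(c) ~ Binomial(n_trials, Q(c))`` per chip directly from the
    rate function -- the very process the per-name fit assumes -- and
    packs the counts into a two-name table (``name`` vs ``"other"``).
    Unlike a full dataset drawn from the normalized field, this generator
    has no normalization distortion, so the fitted parameters converge to
    the generating ones and the harness measures pure estimator error.
    """
    from .model import q_rate
    from .naming import NamingTable

    rng = np.random.default_rng(seed)
    chips = chip_grid(seed=0) if chips is None else np.asarray(chips, dtype=float)
    q = q_rate(params, gamma, chips)
    r = rng.binomial(n_trials, q)
    other = n_trials - r
    counts = np.column_stack([r, other])
    vocab = (name, "other")
    if other.sum() > r.sum():  # vocabulary ordered by descending count
        counts = counts[:, ::-1]
        vocab = ("other", name)
    return NamingTable(chips=chips, vocabulary=vocab, counts=counts)


def synthetic_naming_dataset(model: ResponseModel, chips=None,
                             responses_per_chip: int = 31, seed: int = 0,
                             subjects: bool = True) -> pd.DataFrame:
    """Draw a long-format naming table from a known response model.

    Per chip, ``responses_per_chip`` names are drawn i.i.d. from the
    model's normalized distribution.  With ``subjects=True`` records are
    shuffled and assigned to subjects in blocks of 20 presentations, and
    each complete block's 18th presentation is replaced by a repeat of its
    3rd chip (response drawn fresh), mirroring the session design that
    intra-subject agreement is estimated from.  Returns the records
    DataFrame; aggregate with
    :func:`catmetric.naming.clean_records` / ``table_from_records``.
    """
    rng = np.random.default_rng(seed)
    chips = chip_grid(seed=rng.integers(2 ** 31)) if chips is None else np.asarray(chips, dtype=float)
    probs = model.predict(chips)
    vocab = np.asarray(model.vocabulary)

    rows = []
    for c, chip in enumerate(chips):
        counts = rng.multinomial(responses_per_chip, probs[c])
        for v in np.nonzero(counts)[0]:
            rows += [(chip[0], chip[1], chip[2], vocab[v], c)] * int(counts[v])
    df = pd.DataFrame(rows, columns=["r", "g", "b", "name", "chip_id"])

    if subjects:
        order = rng.permutation(len(df))
        df = df.iloc[order].reset_index(drop=True)
        df["subject"] = [f"s{i // 20:04d}" for i in range(len(df))]
        df["presentation_index"] = [i % 20 + 1 for i in range(len(df))]
        # repeat presentations: 18th shows the 3rd chip again
        for start in range(0, len(df) - len(df) % 20, 20):
            third = df.iloc[start + 2]
            cid = int(third["chip_id"])
            name = vocab[rng.choice(len(vocab), p=probs[cid])]
            df.iloc[start + 17, df.columns.get_indexer(
                ["r", "g", "b", "name", "chip_id"])] = (
                third["r"], third["g"], third["b"], name, cid)
    else:
        df["subject"] = [f"s{i:05d}" for i in range(len(df))]
    return df
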