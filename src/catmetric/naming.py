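"""Colour-naming response tables: data model, cleaning and statistics.

A naming experiment yields one record per (subject, chip, response): a
subject saw a colour chip and typed an unconstrained name for it.  This
module reads such long-format tables, applies the standard cleaning rules
-- case/whitespace normalisation, a spelling-variant merge map, removal of
names used by only a single subject (idiosyncratic responses), removal of
flagged repeat presentations -- and aggregates them into per-chip response
counts over the surviving vocabulary.

Descriptive statistics mirror the quantities used to characterise such
datasets: global name rates and their exponential law after a power
transform, global/per-chip response entropies (bits), the mutual
information between chips and names, and inter-/intra-subject agreement
rates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NamingTable",
    "CleaningReport",
    "normalize_name",
    "clean_records",
    "table_from_records",
    "read_naming_table",
    "write_naming_table",
    "global_rates",
    "rate_law_fit",
    "naming_statistics",
]

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Lower-case and whitespace-normalize a raw response string."""
    return _WS.sub(" ", str(name).strip().lower())


@dataclass
class CleaningReport:
    """Record of what cleaning did to a raw response table."""

    variant_map: dict
    n_input: int
    n_repeat_dropped: int
    n_unique_dropped: int
    unique_names_dropped: tuple = ()

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_repeat_dropped - self.n_unique_dropped


@dataclass
class NamingTable:
    """Per-chip response counts over a name vocabulary.

    ``chips`` is a (C,3) array of sRGB triples, ``vocabulary`` a tuple of
    names ordered by descending global count (ties lexicographic), and
    ``counts`` the (C,V) nonnegative integer response matrix r_n(c).  The
    matrix is small enough at realistic sizes (~600 x ~800) to keep dense.
    ``records`` optionally retains the cleaned long-format records
    (with subject / presentation metadata) for agreement statistics.
    """

    chips: np.ndarray
    vocabulary: tuple
    counts: np.ndarray
    records: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.chips = np.asarray(self.chips, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        if self.counts.shape != (len(self.chips), len(self.vocabulary)):
            raise ValueError("counts shape must be (n_chips, n_names)")
        if np.any(self.chips < -1e-9) or np.any(self.chips > 1 + 1e-9):
            raise ValueError("chip coordinates must lie in the sRGB cube")
        if np.any(self.counts.sum(axis=0) < 1):
            raise ValueError("every vocabulary entry needs total count >= 1")

    @property
    def n_chips(self) -> int:
        return len(self.chips)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def clean_records(df: pd.DataFrame, variant_map: dict | None = None):
    """Apply the cleaning rules to long-format records.

    Steps, in order: name normalisation and variant merging; removal of
    flagged repeat presentations (an ``is_repeat`` column, else records
    with ``presentation_index == 18``, the repeat slot of the session
    design); removal of names whose every use comes from one subject.
    Returns ``(records, report)`` where ``records`` keeps all rows with
    boolean columns ``dropped_repeat`` / ``dropped_unique``.
    """
    variant_map = {normalize_name(k): normalize_name(v)
                   for k, v in (variant_map or {}).items()}
    df = df.copy()
    if "subject" not in df.columns or "name" not in df.columns:
        raise ValueError("records need 'subject' and 'name' columns")
    df["name"] = df["name"].map(normalize_name).replace(variant_map)

    if "is_repeat" in df.columns:
        repeat = df["is_repeat"].astype(bool)
    elif "presentation_index" in df.columns:
        repeat = df["presentation_index"].astype("Int64") == 18
        repeat = repeat.fillna(False).astype(bool)
    else:
        repeat = pd.Series(False, index=df.index)
    df["dropped_repeat"] = repeat

    kept = df[~repeat]
    per_name_subjects = kept.groupby("name")["subject"].nunique()
    unique_names = set(per_name_subjects[per_name_subjects <= 1].index)
    df["dropped_unique"] = (~repeat) & df["name"].isin(unique_names)

    report = CleaningReport(
        variant_map=variant_map,
        n_input=len(df),
        n_repeat_dropped=int(repeat.sum()),
        n_unique_dropped=int(df["dropped_unique"].sum()),
        unique_names_dropped=tuple(sorted(unique_names)),
    )
    return df, report


def table_from_records(records: pd.DataFrame) -> NamingTable:
    """Aggregate cleaned records into a :class:`NamingTable`.

    Chips are the unique (r,g,b) triples in order of first appearance;
    vocabulary is ordered by descending total count, ties lexicographic.
    """
    live = records
    for col in ("dropped_repeat", "dropped_unique"):
        if col in live.columns:
            live = live[~live[col].astype(bool)]
    if live.empty:
        raise ValueError("no records left after cleaning")

    rgb = live[["r", "g", "b"]].to_numpy(dtype=float)
    chip_key = [tuple(np.round(row, 12)) for row in rgb]
    chips, chip_idx = [], {}
    rows = np.empty(len(live), dtype=int)
    for i, key in enumerate(chip_key):
        if key not in chip_idx:
            chip_idx[key] = len(chips)
            chips.append(key)
        rows[i] = chip_idx[key]

    tallies = live.groupby("name").size()
    vocab = sorted(tallies.index, key=lambda n: (-tallies[n], n))
    vmap = {n: i for i, n in enumerate(vocab)}
    cols = live["name"].map(vmap).to_numpy()

    counts = np.zeros((len(chips), len(vocab)), dtype=int)
    np.add.at(counts, (rows, cols), 1)
    return NamingTable(chips=np.asarray(chips), vocabulary=tuple(vocab),
                       counts=counts, records=records)


def read_naming_table(path, variant_map: dict | None = None, sep: str | None = None):
    """Read and clean a long-format naming table (CSV/TSV, UTF-8, header).

    Required columns: ``subject``, ``name`` and either ``r,g,b`` sRGB
    components or ``chip_id`` (with an ``r,g,b`` lookup elsewhere in the
    file); optional ``presentation_index`` / ``is_repeat``.  Malformed
    rows are reported with their line numbers.  Returns
    ``(NamingTable, CleaningReport)``.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.empty:
        raise ValueError(f"{path}: empty naming table")
    needed = {"subject", "name"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    if not {"r", "g", "b"}.issubset(df.columns):
        raise ValueError(f"{path}: chip coordinates require columns r,g,b")

    rgb = df[["r", "g", "b"]].apply(pd.to_numeric, errors="coerce")
    bad = rgb.isna().any(axis=1) | (rgb < 0).any(axis=1) | (rgb > 1).any(axis=1)
    bad |= df["name"].isna()
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:10]]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    df[["r", "g", "b"]] = rgb

    records, report = clean_records(df, variant_map)
    return table_from_records(records), report


def write_naming_table(records: pd.DataFrame, path, sep: str = ",") -> None:
    """Write long-format records (cleaning flag columns excluded)."""
    drop = [c for c in ("dropped_repeat", "dropped_unique") if c in records.columns]
    records.drop(columns=drop).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def global_rates(table: NamingTable) -> np.ndarray:
    """Global response rates g_n = sum_c r_n(c) / total, aligned with the
    vocabulary (which is ordered by descending count, ties lexicographic)."""
    totals = table.counts.sum(axis=0)
    return totals / totals.sum()


def rate_law_fit(g, exponent: float = 0.12) -> dict:
    """Fit an exponential law to power-transformed global rates.

    The transformed values ``x = g ** exponent`` are fit by maximum
    likelihood with a shifted exponential (location at the smallest
    transformed rate); a Kolmogorov-Smirnov statistic quantifies fit.
    A degenerate (near-constant) transformed sample is flagged instead of
    fit.  The law justifies the ``(k |Sigma|)**0.12`` penalty used when
    fitting per-name response functions.
    """
    g = np.asarray(g, dtype=float)
    if len(g) < 3:
        raise ValueError("rate-law fit needs at least 3 names")
    if np.any(g <= 0):
        raise ValueError("global rates must be strictly positive")
    x = g ** exponent
    if np.ptp(x) < 1e-12:
        return {"transformed": x, "loc": float(x[0]), "rate": np.nan,
                "ks_statistic": np.nan, "degenerate": True}
    loc, scale = sps.expon.fit(x)
    ks = sps.kstest(x, "expon", args=(loc, scale))
    return {
        "transformed": x,
        "loc": float(loc),
        "rate": float(1.0 / scale),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "degenerate": False,
    }


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def naming_statistics(table: NamingTable) -> dict:
    """Entropies, mutual information and agreement rates of a table.

    All entropies are in bits.  The mutual information is computed from
    the empirical joint chip x name distribution, so the identity
    H(name|chip) = H(name) - I(chip;name) holds exactly for the
    count-weighted conditional entropy.  Inter-subject agreement uses the
    unbiased per-chip pair-coincidence estimator
    mean_c sum_n r_n(r_n - 1) / (R_c (R_c - 1)); intra-subject agreement
    (fraction of repeat-presentation pairs given the same name) is
    included only when repeat metadata is available.
    """
    counts = table.counts.astype(float)
    total = counts.sum()
    joint = counts / total
    p_name = joint.sum(axis=0)
    p_chip = joint.sum(axis=1)

    global_entropy = _entropy_bits(p_name)
    per_chip = np.array([
        _entropy_bits(row / row.sum()) if row.sum() else 0.0 for row in counts
    ])
    cond_entropy = float(np.sum(p_chip * per_chip))
    mutual_information = global_entropy - cond_entropy

    row_tot = counts.sum(axis=1)
    ok = row_tot >= 2
    coincidence = (counts * (counts - 1)).sum(axis=1)[ok] / (
        row_tot[ok] * (row_tot[ok] - 1))
    inter = float(coincidence.mean()) if ok.any() else np.nan

    stats = {
        "global_entropy": global_entropy,
        "per_chip_entropy": per_chip,
        "mean_chip_entropy": float(per_chip.mean()),
        "conditional_entropy": cond_entropy,
        "mutual_information": float(mutual_information),
        "inter_subject_agreement": inter,
    }

    rec = table.records
    if rec is not None and "presentation_index" in getattr(rec, "columns", ()):
        pivot = rec[rec["presentation_index"].isin([3, 18])]
        pairs = pivot.pivot_table(index="subject", columns="presentation_index",
                                  values="name", aggfunc="first")
        if {3, 18}.issubset(pairs.columns):
            both = pairs.dropna(subset=[3, 18])
            if len(both):
                stats["intra_subject_agreement"] = float(
                    (both[3] == both[18]).mean())
    return stats
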