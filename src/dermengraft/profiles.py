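"""Count tables, relative-abundance profiles, alpha diversity and genus co-occurrence.

A study is represented by one integer count table per taxonomic level
(``slst`` for *Cutibacterium acnes* strain types, ``genus`` for 16S genera)
plus one sample-metadata table shared by both.  Counts are normalised per
sample to relative abundances on a 0-100 scale: each value is divided by the
sample's total count and multiplied by 100.  Taxa absent from a sample are
kept as explicit zeros so that downstream distance computations (Jensen-
Shannon, Pearson) operate over a common, aligned taxon universe.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

LEVELS = ("slst", "genus")

#: total abundance of every emitted profile, in percent
PROFILE_TOTAL = 100.0

#: metadata columns required by the pipeline
METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "area",
    "day",
    "solution_id",
    "dose_cfu_per_ml",
)

VALID_DOSES = (1e4, 1e6, 1e8)


class AllZeroSampleError(ValueError):
    """A sample row has zero total count and cannot be normalised."""

    def __init__(self, sample_ids: Sequence[str]):
        self.sample_ids = list(sample_ids)
        super().__init__(
            "cannot normalise all-zero sample row(s): " + ", ".join(map(str, self.sample_ids))
        )


@dataclasses.dataclass
class CountTable:
    """Integer read counts, samples x taxa, at one taxonomic level.

    Parameters
    ----------
    counts:
        DataFrame indexed by sample id with one column per taxon; values are
        non-negative integers.
    level:
        ``"slst"`` or ``"genus"``.
    """

    counts: pd.DataFrame
    level: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon id(s): {dups}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValueError("counts must be non-negative")
        self.counts.index.name = "sample_id"
        self.counts.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def __len__(self) -> int:
        return len(self.counts)


def validate_metadata(meta: pd.DataFrame, counts: CountTable | None = None) -> pd.DataFrame:
    """Check a sample-metadata table and return it with canonical dtypes.

    Enforces: required columns present; area in 1..8; a dose is present iff a
    solution is present (control/untreated areas carry neither); every sample
    of ``counts`` (if given) has a metadata row.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing column(s): {missing}")
    meta = meta.copy()
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate metadata sample id(s): {dups}")
    meta["area"] = meta["area"].astype(int)
    meta["day"] = meta["day"].astype(int)
    if ((meta["area"] < 1) | (meta["area"] > 8)).any():
        bad = meta.loc[(meta["area"] < 1) | (meta["area"] > 8), "sample_id"].tolist()
        raise ValueError(f"area out of range 1-8 for sample(s): {bad}")
    if (meta["day"] < 0).any():
        raise ValueError("negative day in metadata")
    has_sol = meta["solution_id"].notna() & (meta["solution_id"].astype(str) != "")
    has_dose = meta["dose_cfu_per_ml"].notna()
    mismatch = meta.loc[has_sol != has_dose, "sample_id"].tolist()
    if mismatch:
        raise ValueError(f"dose present iff solution present violated for: {mismatch}")
    if has_dose.any():
        doses = meta.loc[has_dose, "dose_cfu_per_ml"].astype(float)
        bad = ~doses.apply(lambda d: any(math.isclose(d, v) for v in VALID_DOSES))
        if bad.any():
            raise ValueError(
                f"dose must be one of {VALID_DOSES}; offending samples: "
                f"{meta.loc[has_dose][bad.to_numpy()]['sample_id'].tolist()}"
            )
    if counts is not None:
        absent = set(counts.sample_ids) - set(meta["sample_id"])
        if absent:
            raise ValueError(f"count-table sample(s) missing from metadata: {sorted(absent)}")
    return meta


def normalize_matrix(weights: pd.DataFrame, total: float = PROFILE_TOTAL) -> pd.DataFrame:
    """Scale each row of a non-negative weight matrix to sum to ``total``.

    Idempotent on already-normalised rows.  Raises :class:`AllZeroSampleError`
    naming the offending samples if any row sums to zero.
    """
    arr = weights.to_numpy(dtype=float)
    sums = arr.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        raise AllZeroSampleError(list(weights.index[zero]))
    out = arr * (total / sums[:, None])
    return pd.DataFrame(out, index=weights.index, columns=weights.columns)


def normalize_counts(table: CountTable, min_total_count: int = 0) -> pd.DataFrame:
    """Convert a count table to relative abundances (rows sum to 100).

    ``min_total_count`` optionally drops samples whose library size is below
    the gate (default 0 = keep everything); all-zero rows always raise.
    """
    counts = table.counts
    if min_total_count > 0:
        keep = counts.sum(axis=1) >= min_total_count
        counts = counts.loc[keep]
    return normalize_matrix(counts)


def shannon_diversity(profile: Sequence[float] | pd.Series, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i of one abundance profile.

    The profile may be on any positive scale (it is renormalised to
    probabilities).  Natural log by default; pass ``base`` to change it.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1:
        raise ValueError("profile must be one-dimensional")
    if (p < 0).any():
        raise ValueError("negative abundance in profile")
    s = p.sum()
    if s <= 0:
        raise ValueError("profile has zero total abundance")
    p = p[p > 0] / s
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return max(h, 0.0)


def genus_cooccurrence(
    abundances: pd.DataFrame,
    pairs: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Pairwise Pearson co-occurrence of taxa across samples.

    Parameters
    ----------
    abundances:
        Relative-abundance matrix (samples x taxa).
    pairs:
        Iterable of ``(taxon_a, taxon_b)`` id pairs; both must be columns.

    Returns a DataFrame with one row per pair: ``taxon_a, taxon_b, n, r, p,
    defined``.  A pair in which either taxon has zero variance across samples
    is flagged ``defined=False`` with ``r``/``p`` as NaN rather than a number.
    """
    if len(abundances) < 3:
        raise ValueError("co-occurrence needs at least 3 samples")
    rows = []
    for a, b in pairs:
        for t in (a, b):
            if t not in abundances.columns:
                raise KeyError(f"taxon {t!r} not in abundance table")
        x = abundances[a].to_numpy(dtype=float)
        y = abundances[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"taxon_a": a, "taxon_b": b, "n": len(x),
                         "r": np.nan, "p": np.nan, "defined": False})
            continue
        r, p = _sps.pearsonr(x, y)
        rows.append({"taxon_a": a, "taxon_b": b, "n": len(x),
                     "r": float(r), "p": float(p), "defined": True})
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "n", "r", "p", "defined"])
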