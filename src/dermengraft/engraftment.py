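"""Donor-to-recipient engraftment scoring and longitudinal significance testing.

Engraftment of a topically applied probiotic solution is quantified as the
Pearson correlation r between the relative-abundance profile of a recipient
sample and the composition of the solution applied to that skin area, over
the union of their taxa (absent taxa filled with zero).  Higher r means the
site looks more like the applied solution; the distance form is 1 - r.

Per (solution x dose) arm, post-application days are compared with the
pre-application baseline day by two-sided Wilcoxon-Mann-Whitney rank-sum
tests, with Benjamini-Hochberg adjustment across the full family of
(group, day) tests.  Arm-level contrasts (solution, dose, or dermatotype)
use Tukey's HSD on subject-area mean engraftment so that repeated days do
not pseudo-replicate.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .profiles import shannon_diversity
from .stats import bh_adjust, rank_sum_test

__all__ = [
    "DonorSolution",
    "SolutionSet",
    "engraftment_score",
    "engraftment_timecourse",
    "engraftment_significance",
    "group_contrasts",
    "diversity_vs_engraftment",
]


@dataclasses.dataclass
class DonorSolution:
    """Composition of one applied probiotic solution.

    ``compositions`` maps taxonomic level ("slst"/"genus") to an abundance
    Series summing to 100; ``default_level`` is the level engraftment is
    scored at for this solution (SLST for defined *C. acnes* strain mixes,
    genus for complete-microbiome preparations).
    """

    solution_id: str
    compositions: dict[str, pd.Series]
    default_level: str

    def __post_init__(self) -> None:
        if self.default_level not in self.compositions:
            raise ValueError(
                f"solution {self.solution_id}: default level {self.default_level!r} "
                "has no composition"
            )
        for level, comp in self.compositions.items():
            total = float(comp.sum())
            if not math.isclose(total, 100.0, rel_tol=1e-6):
                raise ValueError(
                    f"solution {self.solution_id} ({level}): composition sums to "
                    f"{total}, expected 100"
                )
            if (comp < 0).any():
                raise ValueError(f"solution {self.solution_id}: negative abundance")


class SolutionSet(dict):
    """Mapping solution_id -> :class:`DonorSolution`."""

    @classmethod
    def from_solutions(cls, solutions: Sequence[DonorSolution]) -> "SolutionSet":
        obj = cls()
        for s in solutions:
            if s.solution_id in obj:
                raise ValueError(f"duplicate solution id {s.solution_id}")
            obj[s.solution_id] = s
        return obj


def engraftment_score(sample: pd.Series, solution: pd.Series) -> float:
    """Pearson correlation between a sample profile and a solution composition.

    Computed over the union of the two taxon sets with absent taxa as zero.
    Returns NaN (undefined) if either vector is constant after alignment.
    """
    union = sample.index.union(solution.index)
    x = sample.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    y = solution.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def _group_label(solution_id: str, dose: float | None, is_control: bool) -> str:
    if is_control:
        return f"control({solution_id})"
    exp = int(round(math.log10(dose)))
    return f"{solution_id}@1e{exp}"


def engraftment_timecourse(
    abundances: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    solutions: SolutionSet,
    control_policy: str = "per_solution",
) -> pd.DataFrame:
    """Score every sampled (subject, area, day) against its applied solution.

    Parameters
    ----------
    abundances:
        Mapping level -> relative-abundance table (samples x taxa); only the
        levels actually needed by the solutions must be present.
    metadata:
        Validated sample metadata.  Rows with a ``solution_id`` are treated
        areas; rows without are controls.
    solutions:
        The applied-solution compositions.
    control_policy:
        ``"per_solution"`` (default) scores each control sample against every
        solution, providing an untreated contrast arm per solution;
        ``"skip"`` leaves controls unscored.

    Returns a long DataFrame with columns ``sample_id, subject_id, area, day,
    solution_id, dose_cfu_per_ml, level, is_control, group, score``.  A
    treated sample whose solution is unknown raises, listing the offenders.
    """
    treated = metadata[metadata["solution_id"].notna()]
    unknown = sorted(set(treated["solution_id"]) - set(solutions))
    if unknown:
        bad = treated.loc[treated["solution_id"].isin(unknown), "sample_id"].tolist()
        raise ValueError(
            f"no composition for solution(s) {unknown}; offending samples: {bad}"
        )
    def _profile(level: str, sample_id: str) -> pd.Series:
        tab = abundances.get(level)
        if tab is None:
            raise KeyError(f"no {level}-level abundance table supplied")
        try:
            return tab.loc[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} missing from {level} table") from None

    rows = []
    n_undefined = 0
    for rec in metadata.itertuples(index=False):
        is_control = pd.isna(rec.solution_id) or rec.solution_id == ""
        targets: list[tuple[str, float | None]]
        if is_control:
            if control_policy == "skip":
                continue
            targets = [(sid, None) for sid in sorted(solutions)]
        else:
            targets = [(rec.solution_id, float(rec.dose_cfu_per_ml))]
        for sid, dose in targets:
            sol = solutions[sid]
            level = sol.default_level
            score = engraftment_score(_profile(level, rec.sample_id),
                                      sol.compositions[level])
            if np.isnan(score):
                n_undefined += 1
            rows.append({
                "sample_id": rec.sample_id,
                "subject_id": rec.subject_id,
                "area": rec.area,
                "day": rec.day,
                "solution_id": sid,
                "dose_cfu_per_ml": dose,
                "level": level,
                "is_control": is_control,
                "group": _group_label(sid, dose, is_control),
                "score": score,
            })
    if n_undefined:
        warnings.warn(f"{n_undefined} sample(s) had undefined (constant-vector) scores")
    return pd.DataFrame(rows)


def engraftment_significance(
    series: pd.DataFrame,
    baseline_day: int = 1,
    test_days: Sequence[int] | None = None,
    family: str = "joint",
) -> pd.DataFrame:
    """Wilcoxon rank-sum tests of post- vs pre-application engraftment.

    Within each group (solution x dose arm, or control contrast arm), the
    scores at each test day are compared two-sidedly with the scores at
    ``baseline_day``.  Groups/days with fewer than 3 observations on either
    side are recorded as NA with a reason instead of being tested.  BH
    adjustment is applied across all tests jointly (``family="joint"``) or
    within each group (``family="per_group"``).

    Returns columns ``group, day, n_baseline, n_day, statistic, p, q, reason``.
    """
    if family not in ("joint", "per_group"):
        raise ValueError("family must be 'joint' or 'per_group'")
    ser = series.dropna(subset=["score"])
    if test_days is None:
        test_days = sorted(d for d in ser["day"].unique() if d > baseline_day)
    rows = []
    for group, g in ser.groupby("group", sort=True):
        base = g.loc[g["day"] == baseline_day, "score"].to_numpy()
        for day in test_days:
            cur = g.loc[g["day"] == day, "score"].to_numpy()
            row = {"group": group, "day": int(day),
                   "n_baseline": len(base), "n_day": len(cur),
                   "statistic": np.nan, "p": np.nan, "q": np.nan, "reason": ""}
            if len(base) < 3 or len(cur) < 3:
                row["reason"] = "insufficient_n"
            else:
                u, p = rank_sum_test(cur, base)
                row["statistic"], row["p"] = u, p
            rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        if family == "joint":
            out["q"] = bh_adjust(out["p"].to_numpy())
        else:
            out["q"] = (
                out.groupby("group")["p"]
                .transform(lambda p: bh_adjust(p.to_numpy()))
            )
    return out


def _subject_area_means(
    series: pd.DataFrame, baseline_day: int, include_controls: bool = False
) -> pd.DataFrame:
    s = series.dropna(subset=["score"])
    if not include_controls:
        s = s[~s["is_control"]]
    post = s[s["day"] > baseline_day]
    keys = ["subject_id", "area", "solution_id", "dose_cfu_per_ml", "group"]
    return post.groupby(keys, dropna=False)["score"].mean().reset_index()


def group_contrasts(
    series: pd.DataFrame,
    grouping: str = "solution",
    dermatotypes: pd.Series | None = None,
    baseline_day: int = 1,
    min_subjects: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group engraftment summaries and all-pairs Tukey HSD contrasts.

    One observation = one treated subject-area's mean score over
    post-application days (days > ``baseline_day``).  ``grouping`` is one of
    ``solution``, ``dose`` or ``dermatotype``; the latter requires a
    ``dermatotypes`` Series mapping subject_id -> dermatotype label.  Groups
    with fewer than ``min_subjects`` distinct subjects are excluded with a
    warning.  With a single remaining group, summaries are returned and the
    contrast table is empty.

    Returns ``(summary, contrasts)``.
    """
    means = _subject_area_means(series, baseline_day)
    if grouping == "solution":
        means["contrast_group"] = means["solution_id"]
    elif grouping == "dose":
        means["contrast_group"] = means["dose_cfu_per_ml"].map(
            lambda d: f"1e{int(round(math.log10(d)))}"
        )
    elif grouping == "dermatotype":
        if dermatotypes is None:
            raise ValueError("grouping='dermatotype' requires a dermatotypes mapping")
        means["contrast_group"] = means["subject_id"].map(dermatotypes)
        means = means.dropna(subset=["contrast_group"])
        means["contrast_group"] = means["contrast_group"].map(lambda v: f"dermatotype_{v}")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    kept = {}
    for name, g in means.groupby("contrast_group", sort=True):
        if g["subject_id"].nunique() < min_subjects:
            warnings.warn(f"group {name!r} excluded: fewer than {min_subjects} subjects")
            continue
        kept[name] = g["score"].to_numpy()
    summary = pd.DataFrame(
        [
            {
                "group": name,
                "n": len(v),
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
            }
            for name, v in kept.items()
        ]
    ).sort_values("mean", ascending=False, ignore_index=True) if kept else pd.DataFrame(
        columns=["group", "n", "mean", "median", "sd"]
    )
    if len(kept) < 2:
        return summary, pd.DataFrame(columns=["group_a", "group_b", "diff", "p"])
    names = sorted(kept)
    res = _sps.tukey_hsd(*[kept[n] for n in names])
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({
                "group_a": names[i],
                "group_b": names[j],
                "diff": float(np.mean(kept[names[i]]) - np.mean(kept[names[j]])),
                "p": float(res.pvalue[i, j]),
            })
    return summary, pd.DataFrame(rows)


def diversity_vs_engraftment(
    series: pd.DataFrame,
    abundances: pd.DataFrame,
    metadata: pd.DataFrame,
    baseline_day: int = 1,
) -> dict:
    """Correlate subject baseline Shannon diversity with mean engraftment.

    Baseline diversity = mean Shannon H (natural log) of a subject's samples
    at days <= ``baseline_day`` in the supplied abundance table; engraftment
    = the subject's mean treated post-application score.  Requires >= 4
    subjects; a constant diversity vector returns ``defined=False``.
    """
    base_meta = metadata[metadata["day"] <= baseline_day]
    div = {}
    for subj, g in base_meta.groupby("subject_id"):
        ids = [s for s in g["sample_id"] if s in abundances.index]
        if ids:
            div[subj] = float(np.mean([shannon_diversity(abundances.loc[s]) for s in ids]))
    eng = (
        series[~series["is_control"] & (series["day"] > baseline_day)]
        .dropna(subset=["score"])
        .groupby("subject_id")["score"]
        .mean()
    )
    subjects = sorted(set(div) & set(eng.index))
    if len(subjects) < 4:
        raise ValueError(f"need >= 4 subjects with both measures, have {len(subjects)}")
    x = np.array([div[s] for s in subjects])
    y = eng.loc[subjects].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"n": len(subjects), "r": float("nan"), "p": float("nan"), "defined": False}
    r, p = _sps.pearsonr(x, y)
    return {"n": len(subjects), "r": float(r), "p": float(p), "defined": True}
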