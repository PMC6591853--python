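"""Synthetic probiotic-application study generator.

Emulates the longitudinal design the analysis modules expect: 18 subjects,
8 skin areas each (area 4 an untreated negative control), topical solutions
applied on days 1-3 at 1e4/1e6/1e8 CFU/mL with the (solution, dose) arm
rotated across subject areas, sampling on a 13-day grid from day 0 to day
52, and ~10,000 reads per sample.

Community structure is archetype-based: each subject's baseline composition
is a Dirichlet draw around one of five SLST-level archetypes (driven by
*C. acnes* L1; D1; C3+A5; D1+H1; A1) and one of three genus-level archetypes
(Cutibacterium-dominated; Cutibacterium+Corynebacterium; Leifsonia-enriched).
Application mixes the baseline toward the applied solution's composition
with a dose-dependent mixing fraction lambda that rises over the three
application days and decays exponentially afterwards; sequencing is
multinomial at the configured read depth.  Everything is reproducible from
a single seed, and the generator returns the ground truth (archetype per
subject, lambda per sample) needed for recovery tests.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engraftment import DonorSolution, SolutionSet
from .profiles import CountTable, normalize_matrix
from .slst import AmpliconRead, SLSTDatabase

__all__ = [
    "StudyDesign",
    "ArchetypeSet",
    "EngraftmentKinetics",
    "SimulatedStudy",
    "default_archetypes",
    "default_solutions",
    "simulate_study",
    "sample_archetype_profiles",
    "make_slst_database",
    "simulate_reads",
]

SLST_TAXA = ("A1", "A2", "A5", "C3", "D1", "F4", "H1", "K1", "K8", "L1")
GENUS_TAXA = (
    "Cutibacterium",
    "Corynebacterium",
    "Staphylococcus",
    "Leifsonia",
    "Streptococcus",
    "Micrococcus",
)

DEFAULT_SAMPLING_DAYS = (0, 1, 2, 3, 4, 5, 8, 10, 12, 17, 24, 38, 52)


@dataclasses.dataclass
class StudyDesign:
    """Layout of the application/sampling protocol."""

    n_subjects: int = 18
    areas: Sequence[int] = tuple(range(1, 9))
    control_areas: Sequence[int] = (4,)
    application_days: Sequence[int] = (1, 2, 3)
    sampling_days: Sequence[int] = DEFAULT_SAMPLING_DAYS
    doses: Sequence[float] = (1e4, 1e6, 1e8)
    reads_per_sample: int = 10_000
    #: Dirichlet concentration of day-to-day variation around a subject's
    #: baseline (repeat strip samples of the same site are not identical);
    #: larger = more stable sites.  None disables the jitter.
    within_subject_concentration: float | None = 400.0

    @property
    def treated_areas(self) -> list[int]:
        return [a for a in self.areas if a not in self.control_areas]


def _series(level_taxa: Sequence[str], d: Mapping[str, float]) -> pd.Series:
    s = pd.Series(0.0, index=list(level_taxa))
    for k, v in d.items():
        s[k] = v
    return s


@dataclasses.dataclass
class ArchetypeSet:
    """Baseline community archetypes at each taxonomic level.

    Compositions sum to 1; ``concentration`` scales the Dirichlet draw around
    each archetype (larger = tighter clusters).
    """

    slst: dict[str, pd.Series]
    genus: dict[str, pd.Series]
    concentration: float = 50.0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("Dirichlet concentration must be > 0")
        for group in (self.slst, self.genus):
            for name, comp in group.items():
                if not np.isclose(comp.sum(), 1.0):
                    raise ValueError(f"archetype {name!r} does not sum to 1")
                if (comp <= 0).any():
                    raise ValueError(f"archetype {name!r} has non-positive entries")


def default_archetypes() -> ArchetypeSet:
    slst = {
        "L1": _series(SLST_TAXA, {"L1": 0.60, "A1": 0.08, "A2": 0.03, "A5": 0.04,
                                  "C3": 0.04, "D1": 0.06, "F4": 0.04, "H1": 0.06,
                                  "K1": 0.03, "K8": 0.02}),
        "D1": _series(SLST_TAXA, {"D1": 0.60, "A1": 0.08, "A2": 0.03, "A5": 0.04,
                                  "C3": 0.04, "F4": 0.04, "H1": 0.08, "K1": 0.04,
                                  "K8": 0.02, "L1": 0.03}),
        "C3+A5": _series(SLST_TAXA, {"A5": 0.33, "C3": 0.33, "A1": 0.07, "A2": 0.02,
                                     "D1": 0.06, "F4": 0.04, "H1": 0.07, "K1": 0.04,
                                     "K8": 0.02, "L1": 0.02}),
        "D1+H1": _series(SLST_TAXA, {"H1": 0.40, "D1": 0.28, "A1": 0.12, "A2": 0.02,
                                     "A5": 0.03, "C3": 0.03, "F4": 0.03, "K1": 0.04,
                                     "K8": 0.02, "L1": 0.03}),
        "A1": _series(SLST_TAXA, {"A1": 0.60, "A2": 0.04, "A5": 0.04, "C3": 0.04,
                                  "D1": 0.06, "F4": 0.04, "H1": 0.08, "K1": 0.04,
                                  "K8": 0.03, "L1": 0.03}),
    }
    genus = {
        "Cutibacterium": _series(GENUS_TAXA, {
            "Cutibacterium": 0.75, "Corynebacterium": 0.05, "Staphylococcus": 0.10,
            "Leifsonia": 0.03, "Streptococcus": 0.04, "Micrococcus": 0.03}),
        "Cutibacterium+Corynebacterium": _series(GENUS_TAXA, {
            "Cutibacterium": 0.50, "Corynebacterium": 0.28, "Staphylococcus": 0.10,
            "Leifsonia": 0.04, "Streptococcus": 0.05, "Micrococcus": 0.03}),
        "Leifsonia": _series(GENUS_TAXA, {
            "Cutibacterium": 0.22, "Corynebacterium": 0.16, "Staphylococcus": 0.16,
            "Leifsonia": 0.28, "Streptococcus": 0.10, "Micrococcus": 0.08}),
    }
    return ArchetypeSet(slst=slst, genus=genus)


def default_solutions() -> SolutionSet:
    """Applied solutions: three defined strain mixes (PA) and two
    complete-microbiome donor preparations (CM).

    PA solutions are pure *C. acnes*, so their genus-level composition is
    100% Cutibacterium; CM donor 2 carries a 1.8-fold greater
    Cutibacterium/Staphylococcus ratio than donor 1.
    """
    cuti = pd.Series({"Cutibacterium": 100.0})
    sols = [
        DonorSolution("H1", {"slst": pd.Series({"H1": 100.0}), "genus": cuti.copy()}, "slst"),
        DonorSolution("H1+A1", {"slst": pd.Series({"H1": 90.0, "A1": 10.0}),
                                "genus": cuti.copy()}, "slst"),
        DonorSolution("H1+D1+A1", {"slst": pd.Series({"H1": 45.0, "D1": 45.0, "A1": 10.0}),
                                   "genus": cuti.copy()}, "slst"),
        # CM preparations are culture-expanded, which enriches fast-growing
        # staphylococci relative to the skin baseline; donor 2 keeps a
        # 1.8-fold greater Cutibacterium/Staphylococcus ratio than donor 1.
        DonorSolution("CM1", {"genus": pd.Series({
            "Cutibacterium": 40.0, "Staphylococcus": 40.0, "Corynebacterium": 10.0,
            "Leifsonia": 4.0, "Streptococcus": 4.0, "Micrococcus": 2.0})}, "genus"),
        DonorSolution("CM2", {"genus": pd.Series({
            "Cutibacterium": 54.0, "Staphylococcus": 30.0, "Corynebacterium": 8.0,
            "Leifsonia": 4.0, "Streptococcus": 3.0, "Micrococcus": 1.0})}, "genus"),
    ]
    return SolutionSet.from_solutions(sols)


@dataclasses.dataclass
class EngraftmentKinetics:
    """Dose-response mixing kinetics of the applied solution.

    The mixing fraction lambda in [0, 1] gives the weight of the solution
    composition in the sampled community.  Each application moves lambda a
    fraction ``application_gain`` of the remaining way to the dose's ceiling
    ``dose_lambda_max``; after the last application lambda decays with
    half-life ``washout_half_life_days``.  ``susceptibility`` multiplies
    lambda for named recipient archetypes (capped at 1), modelling recipient
    communities that accept donors more readily.
    """

    application_gain: float = 0.8
    dose_lambda_max: Mapping[float, float] = dataclasses.field(
        default_factory=lambda: {1e4: 0.2, 1e6: 0.5, 1e8: 0.8})
    washout_half_life_days: float = 4.0
    susceptibility: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"D1+H1": 1.3})

    def __post_init__(self) -> None:
        if not 0.0 <= self.application_gain <= 1.0:
            raise ValueError("application_gain must be in [0, 1]")
        for dose, lmax in self.dose_lambda_max.items():
            if not 0.0 <= lmax <= 1.0:
                raise ValueError(f"lambda_max for dose {dose:g} outside [0, 1]: {lmax}")
        if self.washout_half_life_days <= 0:
            raise ValueError("washout half-life must be positive")
        for name, mult in self.susceptibility.items():
            if mult < 0:
                raise ValueError(f"negative susceptibility for {name!r}")

    @classmethod
    def null(cls) -> "EngraftmentKinetics":
        """No-effect kinetics (lambda identically zero) for calibration runs."""
        return cls(dose_lambda_max={1e4: 0.0, 1e6: 0.0, 1e8: 0.0}, susceptibility={})

    def lambda_at(
        self,
        day: int,
        dose: float,
        application_days: Sequence[int] = (1, 2, 3),
        archetype: str | None = None,
    ) -> float:
        """Mixing fraction at a sampling day (sampling precedes that day's
        application)."""
        lmax = self.dose_lambda_max.get(dose)
        if lmax is None:
            matches = [v for k, v in self.dose_lambda_max.items() if np.isclose(k, dose)]
            if not matches:
                raise KeyError(f"no lambda_max configured for dose {dose:g}")
            lmax = matches[0]
        g = self.application_gain
        n_app = sum(1 for a in application_days if a < day)
        t_peak = max(application_days) + 1
        if day <= t_peak:
            lam = lmax * (1.0 - (1.0 - g) ** n_app)
        else:
            peak = lmax * (1.0 - (1.0 - g) ** len(application_days))
            lam = peak * 0.5 ** ((day - t_peak) / self.washout_half_life_days)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"kinetics produced lambda={lam} outside [0, 1]")
        if archetype is not None:
            lam = min(1.0, lam * self.susceptibility.get(archetype, 1.0))
        return lam


@dataclasses.dataclass
class SimulatedStudy:
    slst_counts: CountTable
    genus_counts: CountTable
    metadata: pd.DataFrame
    solutions: SolutionSet
    truth: dict


def _mix(baseline: np.ndarray, solution: pd.Series | None,
         taxa: Sequence[str], lam: float) -> np.ndarray:
    if solution is None or lam == 0.0:
        return baseline
    sol = solution.reindex(taxa, fill_value=0.0).to_numpy(dtype=float)
    sol = sol / sol.sum()
    return (1.0 - lam) * baseline + lam * sol


def simulate_study(
    design: StudyDesign | None = None,
    archetypes: ArchetypeSet | None = None,
    kinetics: EngraftmentKinetics | None = None,
    solutions: SolutionSet | None = None,
    seed: int = 0,
) -> SimulatedStudy:
    """Generate a complete synthetic study at both taxonomic levels.

    For every (subject, area, sampling day) the true community is
    ``(1 - lambda) * baseline + lambda * solution`` at each level the
    solution has a composition for, and observed counts are a multinomial
    draw of ``reads_per_sample`` reads.  Subject baselines are drawn once
    per subject (areas share them); sampling days are conditionally
    independent given lambda.  Identical seeds give identical output.
    """
    design = design or StudyDesign()
    archetypes = archetypes or default_archetypes()
    kinetics = kinetics or EngraftmentKinetics()
    solutions = solutions or default_solutions()
    rng = np.random.default_rng(seed)

    slst_names = list(archetypes.slst)
    genus_names = list(archetypes.genus)
    slst_taxa = list(next(iter(archetypes.slst.values())).index)
    genus_taxa = list(next(iter(archetypes.genus.values())).index)

    subjects = [f"S{i + 1:02d}" for i in range(design.n_subjects)]
    subj_slst_arch = {s: slst_names[i % len(slst_names)] for i, s in enumerate(subjects)}
    subj_genus_arch = {s: genus_names[i % len(genus_names)] for i, s in enumerate(subjects)}
    base_slst = {
        s: rng.dirichlet(archetypes.concentration
                         * archetypes.slst[subj_slst_arch[s]].to_numpy())
        for s in subjects
    }
    base_genus = {
        s: rng.dirichlet(archetypes.concentration
                         * archetypes.genus[subj_genus_arch[s]].to_numpy())
        for s in subjects
    }

    arm_list = [(sid, dose) for sid in sorted(solutions) for dose in design.doses]
    treated = design.treated_areas
    arms: dict[tuple[str, int], tuple[str, float]] = {}
    for si, s in enumerate(subjects):
        for ai, area in enumerate(treated):
            arms[(s, area)] = arm_list[(si * len(treated) + ai) % len(arm_list)]

    meta_rows = []
    slst_rows, genus_rows, sample_ids = [], [], []
    lam_truth = {}
    for s in subjects:
        for area in design.areas:
            control = area in design.control_areas
            sol_id, dose = (None, None) if control else arms[(s, area)]
            sol = None if control else solutions[sol_id]
            for day in design.sampling_days:
                sid = f"{s}.A{area}.D{day:02d}"
                if control:
                    lam = 0.0
                else:
                    lam = kinetics.lambda_at(day, dose, design.application_days,
                                             archetype=subj_slst_arch[s])
                lam_truth[sid] = lam
                b_slst, b_genus = base_slst[s], base_genus[s]
                cw = design.within_subject_concentration
                if cw is not None:
                    b_slst = rng.dirichlet(np.maximum(cw * b_slst, 1e-8))
                    b_genus = rng.dirichlet(np.maximum(cw * b_genus, 1e-8))
                p_slst = _mix(b_slst,
                              None if sol is None else sol.compositions.get("slst"),
                              slst_taxa, lam)
                p_genus = _mix(b_genus,
                               None if sol is None else sol.compositions.get("genus"),
                               genus_taxa, lam)
                slst_rows.append(rng.multinomial(design.reads_per_sample, p_slst))
                genus_rows.append(rng.multinomial(design.reads_per_sample, p_genus))
                sample_ids.append(sid)
                meta_rows.append({
                    "sample_id": sid, "subject_id": s, "area": area, "day": day,
                    "solution_id": sol_id,
                    "dose_cfu_per_ml": dose,
                })
    slst_counts = CountTable(
        pd.DataFrame(np.asarray(slst_rows), index=sample_ids, columns=slst_taxa), "slst")
    genus_counts = CountTable(
        pd.DataFrame(np.asarray(genus_rows), index=sample_ids, columns=genus_taxa), "genus")
    metadata = pd.DataFrame(meta_rows)
    truth = {
        "subject_slst_archetype": subj_slst_arch,
        "subject_genus_archetype": subj_genus_arch,
        "lambda": pd.Series(lam_truth, name="lambda"),
        "arms": arms,
        "seed": seed,
    }
    return SimulatedStudy(slst_counts, genus_counts, metadata, solutions, truth)


def sample_archetype_profiles(
    archetypes: Mapping[str, pd.Series],
    n_per_archetype: int = 30,
    concentration: float = 50.0,
    reads_per_sample: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw baseline-only samples around each archetype.

    Returns ``(abundances, labels)``: a relative-abundance table (rows sum to
    100) of ``n_per_archetype`` Dirichlet-multinomial samples per archetype,
    and the true archetype label of each sample.  This is the fixture for
    dermatotype-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    taxa = list(next(iter(archetypes.values())).index)
    rows, ids, labels = [], [], []
    for name, comp in archetypes.items():
        for i in range(n_per_archetype):
            p = rng.dirichlet(concentration * comp.to_numpy())
            rows.append(rng.multinomial(reads_per_sample, p))
            ids.append(f"{name}.{i:03d}")
            labels.append(name)
    counts = pd.DataFrame(np.asarray(rows), index=ids, columns=taxa)
    return normalize_matrix(counts), pd.Series(labels, index=ids, name="archetype")


def make_slst_database(
    taxon_ids: Sequence[str] = SLST_TAXA,
    length: int = 400,
    n_distinct: int = 20,
    seed: int = 0,
) -> SLSTDatabase:
    """Generate a synthetic SLST allele database with controlled geometry.

    Alleles share a random backbone; allele i is substituted at its own
    disjoint block of ``n_distinct`` positions, so every pair of alleles is
    exactly ``2 * n_distinct`` substitutions apart (default 40).  These are
    synthetic sequences for simulation and testing, not real SLST alleles.
    """
    if length < len(taxon_ids) * n_distinct:
        raise ValueError("length too short for the requested number of distinct blocks")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    backbone = rng.integers(0, 4, size=length)
    alleles = {}
    for i, tid in enumerate(taxon_ids):
        arr = backbone.copy()
        pos = np.arange(i * n_distinct, (i + 1) * n_distinct)
        arr[pos] = (arr[pos] + rng.integers(1, 4, size=n_distinct)) % 4
        alleles[tid] = bases[arr].tobytes().decode()
    return SLSTDatabase(alleles)


def simulate_reads(
    profile: pd.Series,
    db: SLSTDatabase,
    n_reads: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[AmpliconRead], list[str]]:
    """Simulate amplicon reads from a strain-abundance profile.

    Reads are full-length copies of alleles drawn multinomially in the
    profile's proportions, with iid substitution errors at ``error_rate``
    and a constant Phred quality matching that rate.  Returns the reads and
    the true source allele of each (in read order).
    """
    if not 0.0 <= error_rate < 0.75:
        raise ValueError("error_rate must be in [0, 0.75)")
    missing = [t for t in profile.index if t not in db.alleles]
    if missing:
        raise ValueError(f"profile taxa absent from database: {missing}")
    rng = np.random.default_rng(seed)
    p = profile.to_numpy(dtype=float)
    if p.sum() <= 0:
        raise ValueError("profile has zero total abundance")
    p = p / p.sum()
    alleles = list(profile.index)
    counts = rng.multinomial(n_reads, p)
    q = 40 if error_rate == 0 else max(2, min(40, int(round(-10 * np.log10(error_rate)))))
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    base_idx = {b: i for i, b in enumerate(bases)}
    reads: list[AmpliconRead] = []
    truth: list[str] = []
    r = 0
    for aid, c in zip(alleles, counts):
        if c == 0:
            continue
        arr = db._arrays[aid]
        idx = np.array([base_idx[b] for b in arr], dtype=np.int64)
        mat = np.tile(idx, (c, 1))
        if error_rate > 0:
            mask = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=mat.shape)
            mat = np.where(mask, (mat + shift) % 4, mat)
        seqs = bases[mat]
        quals = [q] * arr.size
        for row in seqs:
            reads.append(AmpliconRead(f"read{r:06d}", row.tobytes().decode(), list(quals)))
            truth.append(aid)
            r += 1
    return reads, truth
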