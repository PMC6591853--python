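"""Readers and writers for the pipeline's on-disk formats.

Everything tabular is UTF-8 TSV with an optional provenance header of
``#``-prefixed comment lines (tool version, config hash, seed); ``NA`` is
the missing-value literal.  Count tables put ``sample_id`` in the first
column and one taxon per remaining column; abundances are written with six
decimal places.  Solutions are long-format
``solution_id, level, taxon_id, abundance``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .engraftment import DonorSolution, SolutionSet
from .profiles import CountTable, validate_metadata
from .slst import AmpliconRead

NA = "NA"

__all__ = [
    "read_count_table", "write_count_table",
    "read_metadata", "write_metadata",
    "read_solutions", "write_solutions",
    "read_abundances", "write_abundances",
    "read_distance_matrix", "write_distance_matrix",
    "write_fastq", "provenance_lines", "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(seed: int | None = None, cfg_hash: str | None = None) -> list[str]:
    lines = [f"# dermengraft {__version__}"]
    if cfg_hash is not None:
        lines.append(f"# config_hash: {cfg_hash}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def _write_tsv(df: pd.DataFrame, path: str | Path, header: Sequence[str] | None,
               index_label: str | None = None, float_format: str | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header or ():
            fh.write(line.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", na_rep=NA, index=index_label is not None,
                  index_label=index_label, float_format=float_format)


def read_count_table(path: str | Path, level: str) -> CountTable:
    """Read a TSV count table (first column ``sample_id``).

    Raises on empty files, duplicate sample ids, negative or non-integer
    counts; malformed numeric cells are reported with their row and column.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"{path}: empty or headerless count table")
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "sample_id"
    parsed = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            parsed[col] = df[col].astype(np.int64)
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise ValueError(
                f"{path}: non-integer count in column {col!r}, row(s) {bad}"
            ) from None
    return CountTable(parsed, level)


def write_count_table(table: CountTable, path: str | Path,
                      header: Sequence[str] | None = None) -> None:
    _write_tsv(table.counts, path, header, index_label="sample_id")


def read_abundances(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "sample_id"
    return df.astype(float)


def write_abundances(abund: pd.DataFrame, path: str | Path,
                     header: Sequence[str] | None = None) -> None:
    _write_tsv(abund, path, header, index_label="sample_id", float_format="%.6f")


def read_metadata(path: str | Path, counts: CountTable | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample_id": str, "subject_id": str, "solution_id": str},
                     na_values=[NA], keep_default_na=True)
    return validate_metadata(df, counts)


def write_metadata(meta: pd.DataFrame, path: str | Path,
                   header: Sequence[str] | None = None) -> None:
    _write_tsv(meta, path, header)


def read_solutions(path: str | Path) -> SolutionSet:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"solution_id": str,
                                                         "level": str, "taxon_id": str})
    need = {"solution_id", "level", "taxon_id", "abundance"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: solutions file needs columns {sorted(need)}")
    sols = []
    for sid, g in df.groupby("solution_id", sort=True):
        comps = {
            level: pd.Series(gg["abundance"].to_numpy(dtype=float),
                             index=list(gg["taxon_id"]))
            for level, gg in g.groupby("level")
        }
        default = "slst" if "slst" in comps else sorted(comps)[0]
        sols.append(DonorSolution(sid, comps, default))
    return SolutionSet.from_solutions(sols)


def write_solutions(solutions: SolutionSet, path: str | Path,
                    header: Sequence[str] | None = None) -> None:
    rows = []
    for sid in sorted(solutions):
        sol = solutions[sid]
        for level in sorted(sol.compositions):
            for taxon, ab in sol.compositions[level].items():
                rows.append({"solution_id": sid, "level": level,
                             "taxon_id": taxon, "abundance": float(ab)})
    _write_tsv(pd.DataFrame(rows), path, header)


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0).astype(float)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column sample ids differ")
    return df


def write_distance_matrix(d: pd.DataFrame, path: str | Path,
                          header: Sequence[str] | None = None) -> None:
    _write_tsv(d, path, header, index_label="sample_id", float_format="%.8f")


def write_fastq(reads: Iterable[AmpliconRead], path: str | Path) -> None:
    """Write reads as Sanger/Phred+33 FASTQ."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quals}\n")
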