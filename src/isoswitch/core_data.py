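"""Core data model: time-course expression matrices and relative abundance.

Sample layout convention
------------------------
Columns of a :class:`TimeCourseMatrix` are **time-major, replicate-minor**:
for time points ``t0..t{T-1}`` and replicates ``r0..r{R-1}`` the column order
is ``t0_r0, t0_r1, ..., t0_r{R-1}, t1_r0, ...``.  The reader enforces this
ordering and all downstream code relies on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourseMatrix",
    "RelativeAbundance",
    "read_expression",
    "write_expression",
    "read_gene_map",
    "read_gene_map_gtf",
    "read_domain_map",
    "filter_low_expression",
    "relative_abundance",
]


def _sample_columns(time_points: Sequence[str], n_replicates: int) -> list[str]:
    return [f"{t}_r{r + 1}" for t in time_points for r in range(n_replicates)]


@dataclass
class TimeCourseMatrix:
    """Transcript-level expression over a (time point x replicate) grid.

    Parameters
    ----------
    values
        Non-negative matrix of shape ``(n_transcripts, T * R)``, columns
        time-major, replicate-minor.
    transcript_ids
        Unique transcript identifiers, one per row.
    time_points
        Ordered time-point labels (length ``T >= 2``).
    n_replicates
        Number of replicates ``R`` per time point.
    gene_map
        Mapping ``transcript_id -> gene_id`` covering every transcript.
    """

    values: np.ndarray
    transcript_ids: list[str]
    time_points: list[str]
    n_replicates: int
    gene_map: dict[str, str]
    _row_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.transcript_ids = [str(t) for t in self.transcript_ids]
        self.time_points = [str(t) for t in self.time_points]
        T, R = len(self.time_points), int(self.n_replicates)
        if T < 2:
            raise ValueError("need at least two time points")
        if R < 1:
            raise ValueError("n_replicates must be positive")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != len(self.transcript_ids):
            raise ValueError("row count does not match transcript_ids")
        if self.values.shape[1] != T * R:
            raise ValueError(
                f"expected {T}x{R}={T * R} sample columns, got {self.values.shape[1]}"
            )
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            raise ValueError("duplicate transcript ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if np.any(self.values < 0):
            raise ValueError("negative expression values")
        missing = [t for t in self.transcript_ids if t not in self.gene_map]
        if missing:
            raise ValueError(f"transcripts missing from gene_map: {missing[:5]}")
        self._row_index = {t: i for i, t in enumerate(self.transcript_ids)}

    # -- geometry -----------------------------------------------------------
    @property
    def n_timepoints(self) -> int:
        return len(self.time_points)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def sample_columns(self) -> list[str]:
        return _sample_columns(self.time_points, self.n_replicates)

    def row(self, transcript_id: str) -> np.ndarray:
        return self.values[self._row_index[transcript_id]]

    def course(self, transcript_id: str) -> np.ndarray:
        """Return one transcript's values reshaped to ``(T, R)``."""
        return self.row(transcript_id).reshape(self.n_timepoints, self.n_replicates)

    def gene_groups(self) -> dict[str, list[int]]:
        """Map gene_id -> row indices of its transcripts (input order)."""
        groups: dict[str, list[int]] = {}
        for i, t in enumerate(self.transcript_ids):
            groups.setdefault(self.gene_map[t], []).append(i)
        return groups

    def subset(self, transcript_ids: Iterable[str]) -> "TimeCourseMatrix":
        keep = [t for t in self.transcript_ids if t in set(transcript_ids)]
        idx = [self._row_index[t] for t in keep]
        return TimeCourseMatrix(
            values=self.values[idx].copy(),
            transcript_ids=keep,
            time_points=list(self.time_points),
            n_replicates=self.n_replicates,
            gene_map={t: self.gene_map[t] for t in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.transcript_ids, name="transcript_id"),
            columns=self.sample_columns,
        )


@dataclass
class RelativeAbundance:
    """Per-gene isoform fractions on the same axes as the source matrix.

    For each (gene, sample) the fractions of the gene's isoforms sum to 1 when
    the gene has nonzero total expression in that sample, and are all 0
    otherwise.
    """

    values: np.ndarray
    transcript_ids: list[str]
    time_points: list[str]
    n_replicates: int
    gene_map: dict[str, str]
    _row_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self._row_index = {t: i for i, t in enumerate(self.transcript_ids)}

    @property
    def n_timepoints(self) -> int:
        return len(self.time_points)

    def row(self, transcript_id: str) -> np.ndarray:
        return self.values[self._row_index[transcript_id]]

    def course(self, transcript_id: str) -> np.ndarray:
        """One transcript's fractions reshaped to ``(T, R)``."""
        return self.row(transcript_id).reshape(self.n_timepoints, self.n_replicates)

    def gene_groups(self) -> dict[str, list[int]]:
        groups: dict[str, list[int]] = {}
        for i, t in enumerate(self.transcript_ids):
            groups.setdefault(self.gene_map[t], []).append(i)
        return groups


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_expression(
    path: str | Path,
    time_points: Sequence[str],
    n_replicates: int,
    gene_map: Mapping[str, str] | None = None,
) -> TimeCourseMatrix:
    """Read a delimited expression table into a :class:`TimeCourseMatrix`.

    The first column must hold transcript ids; the remaining ``T * R`` numeric
    columns are interpreted time-major, replicate-minor in file order.

    Raises
    ------
    ValueError
        On a column-count mismatch, duplicate transcript ids or negative
        values.
    """
    df = _read_table(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    numeric = df.iloc[:, 1:]
    T, R = len(time_points), int(n_replicates)
    if numeric.shape[1] != T * R:
        raise ValueError(
            f"{path}: expected {T}x{R}={T * R} sample columns, "
            f"found {numeric.shape[1]}"
        )
    values = numeric.to_numpy(dtype=float)
    gm = dict(gene_map) if gene_map is not None else {t: t for t in ids}
    return TimeCourseMatrix(
        values=values,
        transcript_ids=ids,
        time_points=list(time_points),
        n_replicates=R,
        gene_map={t: gm[t] for t in ids},
    )


def write_expression(m: TimeCourseMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV/CSV (full ``repr`` float precision)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    m.to_frame().to_csv(path, sep=sep, float_format="%.17g")


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (transcript_id, gene_id) delimited file."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: gene map needs two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_gene_map(gene_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"transcript_id": list(gene_map.keys()), "gene_id": list(gene_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gene_map_gtf(path: str | Path) -> dict[str, str]:
    """Extract transcript_id -> gene_id from a GTF file (attributes only)."""
    import re

    out: dict[str, str] = {}
    pat_t = re.compile(r'transcript_id "([^"]+)"')
    pat_g = re.compile(r'gene_id "([^"]+)"')
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            mt, mg = pat_t.search(fields[8]), pat_g.search(fields[8])
            if mt and mg:
                out.setdefault(mt.group(1), mg.group(1))
    return out


def read_domain_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a (transcript_id, domain_id) pair list into transcript -> domains.

    Transcripts absent from the returned mapping have *unknown* domain
    content, which downstream code treats differently from an empty set.
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: domain map needs two columns")
    acc: dict[str, set[str]] = {}
    for t, d in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        acc.setdefault(t, set()).add(d)
    return {t: frozenset(s) for t, s in acc.items()}


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def filter_low_expression(
    m: TimeCourseMatrix, min_mean_tpm: float = 1.0
) -> TimeCourseMatrix:
    """Drop transcripts whose mean expression over all samples is below cutoff.

    Transcripts with mean exactly equal to ``min_mean_tpm`` are retained
    (strict-less removal).
    """
    means = m.values.mean(axis=1)
    keep = [t for t, mu in zip(m.transcript_ids, means) if mu >= min_mean_tpm]
    if not keep:
        warnings.warn("filter_low_expression removed every transcript")
    return m.subset(keep)


def relative_abundance(m: TimeCourseMatrix) -> RelativeAbundance:
    """Within-gene isoform fractions per sample.

    Genes with zero total expression in a sample get all-zero fractions there
    (not NaN) so that downstream metrics remain defined.
    """
    fractions = np.zeros_like(m.values)
    for rows in m.gene_groups().values():
        block = m.values[rows]
        totals = block.sum(axis=0)
        nz = totals > 0
        fractions[np.ix_(rows, np.flatnonzero(nz))] = block[:, nz] / totals[nz]
    return RelativeAbundance(
        values=fractions,
        transcript_ids=list(m.transcript_ids),
        time_points=list(m.time_points),
        n_replicates=m.n_replicates,
        gene_map=dict(m.gene_map),
    )
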