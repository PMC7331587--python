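"""Tabular I/O for abundance matrices and sample trait tables.

The pipeline's primary input is a proteins x samples matrix of label-free
spectral counts (the number of MS/MS spectra assigned to each protein) or
already-normalized abundances, plus a per-sample trait table assigning each
sample one EGFR mutation status (Ex19del / L858R / none) and optional numeric
covariates such as age or tumour size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical mutation-status tokens and their accepted case-insensitive aliases.
STATUS_ALIASES: dict[str, str] = {
    "EX19DEL": "EX19DEL",
    "19DEL": "EX19DEL",
    "L858R": "L858R",
    "NONE": "NONE",
    "NEGATIVE": "NONE",
    "WT": "NONE",
}

#: Trait columns in fixed order: M1 = L858R, M2 = Ex19del, NM = no mutation.
TRAIT_COLUMNS: tuple[str, str, str] = ("M1", "M2", "NM")

_STATUS_TO_TRAIT = {"L858R": "M1", "EX19DEL": "M2", "NONE": "NM"}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dupes = []
    for x in ids:
        if x in seen:
            dupes.append(x)
        seen[x] = 1
    if dupes:
        raise ValueError(f"duplicate {what}: {sorted(set(dupes))}")


@dataclass
class AbundanceMatrix:
    """Proteins x samples non-negative abundance matrix.

    ``value_kind`` records whether values are raw spectral counts or
    normalized abundances; count-specific operations check it.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        self.protein_ids = list(map(str, self.protein_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.protein_ids, "protein ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite abundance values")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at protein {self.protein_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.value_kind not in ("counts", "normalized"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.sample_ids)

    def subset_proteins(self, keep: Sequence[str]) -> "AbundanceMatrix":
        idx = {p: i for i, p in enumerate(self.protein_ids)}
        rows = [idx[p] for p in keep]
        return AbundanceMatrix(list(keep), self.sample_ids, self.values[rows], self.value_kind)

    def reorder_samples(self, order: Sequence[str]) -> "AbundanceMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in order]
        return AbundanceMatrix(self.protein_ids, list(order), self.values[:, cols], self.value_kind)


@dataclass
class TraitDesign:
    """Per-sample mutation status with its one-hot trait encoding.

    ``trait_matrix`` is a samples x 3 binary DataFrame with columns M1
    (L858R), M2 (Ex19del) and NM (no Ex19del/L858R); each row sums to 1.
    Optional numeric covariates (age in years, tumour sizes in mm, ...) are
    carried as named per-sample vectors.
    """

    sample_ids: list[str]
    status: list[str]
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        _check_unique(self.sample_ids, "sample ids")
        if len(self.status) != len(self.sample_ids):
            raise ValueError("status length does not match sample ids")
        self.status = [normalize_status(s) for s in self.status]
        if len(self.covariates) == 0:
            self.covariates = pd.DataFrame(index=self.sample_ids)
        else:
            self.covariates = self.covariates.astype(float)
            self.covariates.index = pd.Index(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def trait_matrix(self) -> pd.DataFrame:
        tm = pd.DataFrame(
            0, index=self.sample_ids, columns=list(TRAIT_COLUMNS), dtype=int
        )
        for sid, st in zip(self.sample_ids, self.status):
            tm.loc[sid, _STATUS_TO_TRAIT[st]] = 1
        return tm

    def groups(self) -> dict[str, list[str]]:
        """Sample ids per status, keyed EX19DEL / L858R / NONE."""
        out: dict[str, list[str]] = {"EX19DEL": [], "L858R": [], "NONE": []}
        for sid, st in zip(self.sample_ids, self.status):
            out[st].append(sid)
        return out

    def reorder(self, order: Sequence[str]) -> "TraitDesign":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in order]
        cov = self.covariates.iloc[rows] if len(self.covariates.columns) else pd.DataFrame()
        return TraitDesign(list(order), [self.status[i] for i in rows], cov)


def normalize_status(token: str) -> str:
    """Map a status token to its canonical form, case-insensitively."""
    key = str(token).strip().upper()
    if key not in STATUS_ALIASES:
        raise ValueError(
            f"unknown status {token!r}; expected one of {sorted(set(STATUS_ALIASES))}"
        )
    return STATUS_ALIASES[key]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})


def read_abundance(
    path: str | Path, orientation: str = "proteins_in_rows", value_kind: str = "counts"
) -> AbundanceMatrix:
    """Read an abundance matrix from TSV/CSV (one header row, id column first).

    ``orientation`` declares whether rows are proteins or samples; the result
    is always proteins x samples.  Empty cells are read as 0 (spectral
    counting: unobserved means zero count).
    """
    if orientation not in ("proteins_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path)
    _check_unique([str(x) for x in df.index], "row ids")
    _check_unique([str(x) for x in df.columns], "column ids")
    df = df.fillna(0.0)
    try:
        vals = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if np.any(vals < 0):
        i, j = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative value at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    if orientation == "samples_in_rows":
        df = df.T
        vals = vals.T
    return AbundanceMatrix(
        [str(x) for x in df.index], [str(x) for x in df.columns], vals, value_kind
    )


def read_traits(path: str | Path) -> TraitDesign:
    """Read a trait table: columns sample_id, status, then numeric covariates."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("trait table needs at least sample_id and status columns")
    sample_ids = [str(x) for x in df.iloc[:, 0]]
    _check_unique(sample_ids, "sample ids")
    status = [str(x) for x in df.iloc[:, 1]]
    cov = df.iloc[:, 2:].apply(pd.to_numeric, errors="raise") if df.shape[1] > 2 else pd.DataFrame()
    return TraitDesign(sample_ids, status, cov)


def aggregate_replicates(
    m: AbundanceMatrix,
    replicate_map: Mapping[str, Iterable[str]],
    rule: str = "mean",
) -> AbundanceMatrix:
    """Collapse technical-replicate runs into per-sample profiles.

    ``replicate_map`` maps each output sample id to the run ids (columns of
    ``m``) belonging to it.  Default rule is the arithmetic mean of the runs;
    ``rule='sum'`` totals them instead.
    """
    if rule not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    col = {s: j for j, s in enumerate(m.sample_ids)}
    out_ids = list(replicate_map)
    cols = np.empty((m.n_proteins, len(out_ids)))
    for k, sid in enumerate(out_ids):
        runs = list(replicate_map[sid])
        if not runs:
            raise ValueError(f"sample {sid!r} has no runs")
        missing = [r for r in runs if r not in col]
        if missing:
            raise ValueError(f"run ids not in matrix: {missing}")
        block = m.values[:, [col[r] for r in runs]]
        cols[:, k] = block.sum(axis=1) if rule == "sum" else block.mean(axis=1)
    return AbundanceMatrix(m.protein_ids, out_ids, cols, m.value_kind)


def write_table(obj, path: str | Path) -> None:
    """Write a pipeline result as TSV, round-trippable by the matching reader.

    Accepts an :class:`AbundanceMatrix`, a :class:`TraitDesign`, or any
    pandas DataFrame result table.  Floats keep >= 6 significant digits.
    """
    path = Path(path)
    if path.is_dir():
        raise IsADirectoryError(f"{path} is a directory")
    if isinstance(obj, AbundanceMatrix):
        obj.to_frame().to_csv(path, sep="\t", float_format="%.10g")
    elif isinstance(obj, TraitDesign):
        df = pd.DataFrame({"sample_id": obj.sample_ids, "status": obj.status})
        for c in obj.covariates.columns:
            df[c] = obj.covariates[c].to_numpy()
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", float_format="%.10g")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
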