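"""Tabular data types and readers/writers.

All tables are UTF-8 delimited text (comma or tab, sniffed from the header
line) with a header row, matching the shape of FreeSurfer
``aparcstats2table`` exports: one subject per row for thickness and clinical
tables, one region per row for network-overlap tables, one term per row for
term-activation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CANONICAL_NETWORKS = ("DMN", "CEN", "DAN", "VAN", "AFN", "SMN", "VN")


class TableFormatError(ValueError):
    """Raised when an input table violates the documented format."""


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


@dataclass
class ThicknessMatrix:
    """Subjects x regions cortical-thickness measurements (mm)."""

    subject_ids: list[str]
    region_labels: list[str]
    values: np.ndarray  # (n_subjects, n_regions) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TableFormatError("thickness values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.subject_ids) or m != len(self.region_labels):
            raise TableFormatError("shape does not match subject/region labels")
        if len(set(self.subject_ids)) != n:
            dup = _first_duplicate(self.subject_ids)
            raise TableFormatError(f"duplicate subject ID: {dup!r}")
        if len(set(self.region_labels)) != m:
            dup = _first_duplicate(self.region_labels)
            raise TableFormatError(f"duplicate region label: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise TableFormatError(
                f"missing/non-finite value at subject {self.subject_ids[i]!r}, "
                f"region {self.region_labels[j]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def subset(self, subject_ids: Sequence[str]) -> "ThicknessMatrix":
        index = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [index[s] for s in subject_ids]
        return ThicknessMatrix(list(subject_ids), list(self.region_labels), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.region_labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return ""


def read_thickness_table(path: str | Path) -> ThicknessMatrix:
    """Read a subjects x regions table: first column subject ID, rest numeric.

    Raises :class:`TableFormatError` on duplicate subject IDs, non-numeric
    cells or missing values, naming the offending row/column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={0: str},
                     float_precision="round_trip")
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: expected subject-ID column plus regions")
    subject_col = df.columns[0]
    subjects = df[subject_col].astype(str).tolist()
    regions = [str(c) for c in df.columns[1:]]
    values = np.empty((len(subjects), len(regions)), dtype=float)
    for j, col in enumerate(df.columns[1:]):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableFormatError(
                f"{path}: non-numeric or missing value at row {subjects[row]!r}, "
                f"column {col!r}"
            )
        values[:, j] = numeric.to_numpy(dtype=float)
    return ThicknessMatrix(subjects, regions, values)


def write_thickness_table(tm: ThicknessMatrix, path: str | Path, sep: str = "\t") -> None:
    tm.to_frame().to_csv(path, sep=sep, index=False)


@dataclass
class ClinicalTable:
    """Per-subject clinical/demographic covariates.

    ``group`` partitions subjects into exactly two labels (control/patient).
    ``caps`` and ``sex`` are required; other fields may be absent (NaN).
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject_id", "group", "caps", "sex")
    NUMERIC = ("caps", "pcl_c", "age", "education", "time_since_trauma")

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise TableFormatError(f"clinical table missing required column {col!r}")
        df["subject_id"] = df["subject_id"].astype(str)
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise TableFormatError(f"duplicate subject ID: {dup!r}")
        groups = sorted(df["group"].astype(str).unique())
        if len(groups) != 2:
            raise TableFormatError(
                f"group column must have exactly two labels, got {groups}"
            )
        if (pd.to_numeric(df["caps"], errors="coerce") < 0).any():
            raise TableFormatError("caps scores must be nonnegative")
        self.frame = df

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].astype(str).unique())

    def subject_ids(self, group: str | None = None) -> list[str]:
        df = self.frame
        if group is not None:
            df = df[df["group"] == group]
        return df["subject_id"].tolist()


def read_clinical_table(path: str | Path) -> ClinicalTable:
    path = Path(path)
    return ClinicalTable(pd.read_csv(path, sep=_sniff_sep(path),
                                     float_precision="round_trip"))


def write_clinical_table(ct: ClinicalTable, path: str | Path, sep: str = "\t") -> None:
    ct.frame.to_csv(path, sep=sep, index=False)


@dataclass
class NetworkOverlapTable:
    """Region -> canonical-network voxel overlap counts.

    For each region the overlaps across networks may not exceed the region
    size (a region may also have voxels outside every canonical network).
    """

    region_labels: list[str]
    network_names: list[str]
    overlap: np.ndarray  # (M, n_networks) nonnegative
    region_size: np.ndarray  # (M,) positive

    def __post_init__(self) -> None:
        self.overlap = np.asarray(self.overlap, dtype=float)
        self.region_size = np.asarray(self.region_size, dtype=float)
        m = len(self.region_labels)
        if self.overlap.shape != (m, len(self.network_names)):
            raise TableFormatError("overlap shape mismatch")
        if (self.overlap < 0).any():
            raise TableFormatError("negative overlap count")
        if (self.region_size <= 0).any():
            bad = self.region_labels[int(np.argmax(self.region_size <= 0))]
            raise TableFormatError(f"non-positive region size for {bad!r}")
        excess = self.overlap.sum(axis=1) > self.region_size + 1e-9
        if excess.any():
            bad = self.region_labels[int(np.argmax(excess))]
            raise TableFormatError(
                f"overlap sum exceeds region size for region {bad!r}"
            )

    def row(self, region: str) -> int:
        try:
            return self.region_labels.index(region)
        except ValueError:
            raise KeyError(f"region {region!r} not in overlap table") from None


def read_network_overlap(path: str | Path) -> NetworkOverlapTable:
    """Read a region-per-row table with network overlap columns + region_size."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    cols = list(df.columns)
    if "region_size" not in cols:
        raise TableFormatError(f"{path}: missing 'region_size' column")
    region_col = cols[0]
    networks = [c for c in cols if c not in (region_col, "region_size")]
    if not networks:
        raise TableFormatError(f"{path}: no network columns found")
    return NetworkOverlapTable(
        region_labels=df[region_col].astype(str).tolist(),
        network_names=networks,
        overlap=df[networks].to_numpy(dtype=float),
        region_size=df["region_size"].to_numpy(dtype=float),
    )


def write_network_overlap(t: NetworkOverlapTable, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(t.overlap, columns=t.network_names)
    df.insert(0, "region", t.region_labels)
    df["region_size"] = t.region_size
    df.to_csv(path, sep=sep, index=False)


@dataclass
class TermActivationTable:
    """Terms x regions mean activation of each term's probabilistic map."""

    term_names: list[str]
    region_labels: list[str]
    activation: np.ndarray  # (T, M) nonnegative

    def __post_init__(self) -> None:
        self.activation = np.asarray(self.activation, dtype=float)
        if self.activation.shape != (len(self.term_names), len(self.region_labels)):
            raise TableFormatError("activation shape mismatch")
        if (self.activation < 0).any():
            t, r = np.argwhere(self.activation < 0)[0]
            raise TableFormatError(
                f"negative activation for term {self.term_names[t]!r}, "
                f"region {self.region_labels[r]!r}"
            )


def read_term_activation(path: str | Path) -> TermActivationTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    term_col = df.columns[0]
    regions = [str(c) for c in df.columns[1:]]
    return TermActivationTable(
        term_names=df[term_col].astype(str).tolist(),
        region_labels=regions,
        activation=df[regions].to_numpy(dtype=float),
    )


def write_term_activation(t: TermActivationTable, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(t.activation, columns=t.region_labels)
    df.insert(0, "term", t.term_names)
    df.to_csv(path, sep=sep, index=False)


def destrieux_labels() -> list[str]:
    """The 148 Destrieux cortical labels (74 per hemisphere), atlas order.

    Shipped as a convenience; region labels elsewhere in the package are
    free strings and need not come from this list.
    """
    from importlib.resources import files

    text = files("idscn").joinpath("data/destrieux_148.txt").read_text("utf-8")
    labels = [line.strip() for line in text.splitlines() if line.strip()]
    return labels
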