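"""Readers, writers and in-memory containers for pipeline inputs and outputs.

The pipeline starts from a quantified protein table (MaxQuant
``proteinGroups``-style layout: one row per protein group, one
``LFQ intensity <sample>`` column per run, zeros encoding missing values),
a sample-design table mapping runs to patients, groups and technical
replicates, and — for the enrichment stages — GMT gene-set files and a
tab-separated interaction edge list.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_TREATED = "treated"
GROUP_CONTROL = "control"
_VALID_GROUPS = (GROUP_TREATED, GROUP_CONTROL)

_SCALES = ("linear", "log2", "zscore")


class FormatError(ValueError):
    """Raised when an input file violates its expected layout."""


@dataclass
class IntensityMatrix:
    """Protein-by-sample intensity matrix with an explicit missing mask.

    ``values`` is a float array of shape (n_proteins, n_samples); missing
    cells are ``NaN``.  On the linear scale all observed values are
    non-negative (MaxQuant LFQ intensities); after :func:`~lfqdiff.preprocess.log2_transform`
    the ``scale`` flag is ``"log2"`` and after row standardisation
    ``"zscore"``.
    """

    protein_ids: list[str]
    samples: list[str]
    values: np.ndarray
    gene_names: list[str] | None = None
    peptide_counts: np.ndarray | None = None
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.protein_ids), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise FormatError(f"duplicated sample columns: {dupes}")
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if self.gene_names is None:
            self.gene_names = ["" for _ in self.protein_ids]
        if len(self.gene_names) != len(self.protein_ids):
            raise ValueError("gene_names length does not match protein count")
        if self.scale == "linear":
            observed = self.values[~np.isnan(self.values)]
            if observed.size and (observed < 0).any():
                raise ValueError("linear-scale intensities must be non-negative")

    # -- basic geometry -------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where a cell is missing."""
        return np.isnan(self.values)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            protein_ids=list(self.protein_ids),
            samples=list(self.samples),
            values=self.values.copy(),
            gene_names=list(self.gene_names),
            peptide_counts=None if self.peptide_counts is None else self.peptide_counts.copy(),
            scale=self.scale,
        )

    def select_proteins(self, row_idx: np.ndarray) -> "IntensityMatrix":
        row_idx = np.asarray(row_idx)
        return IntensityMatrix(
            protein_ids=[self.protein_ids[i] for i in row_idx],
            samples=list(self.samples),
            values=self.values[row_idx],
            gene_names=[self.gene_names[i] for i in row_idx],
            peptide_counts=None if self.peptide_counts is None else self.peptide_counts[row_idx],
            scale=self.scale,
        )

    def primary_gene_symbols(self) -> list[str]:
        """First symbol of each (possibly semicolon-joined) gene-name entry."""
        return [g.split(";")[0].strip() if g else "" for g in self.gene_names]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.samples)


@dataclass
class StudyDesign:
    """Maps each sample (MS run) to a patient, a group and a technical replicate.

    Technical replicates are repeated measurements of the same lysate and are
    never treated as independent statistical units downstream.
    """

    table: pd.DataFrame  # columns: sample, patient, group, replicate

    def __post_init__(self) -> None:
        required = {"sample", "patient", "group", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["sample"] = t["sample"].astype(str)
        t["patient"] = t["patient"].astype(str)
        t["group"] = t["group"].astype(str).str.strip().str.lower()
        t["replicate"] = t["replicate"].astype(int)
        bad = sorted(set(t["group"]) - set(_VALID_GROUPS))
        if bad:
            raise FormatError(f"unknown group labels: {bad}; expected {_VALID_GROUPS}")
        if t["sample"].duplicated().any():
            raise FormatError("duplicated sample ids in design")
        per_patient_groups = t.groupby("patient")["group"].nunique()
        conflicted = per_patient_groups[per_patient_groups > 1].index.tolist()
        if conflicted:
            raise FormatError(f"patients assigned to more than one group: {conflicted}")
        if t.duplicated(subset=["patient", "replicate"]).any():
            raise FormatError("replicate indices not unique within patient")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, int]]
    ) -> "StudyDesign":
        """Build from (sample, patient, group, replicate) tuples."""
        df = pd.DataFrame(records, columns=["sample", "patient", "group", "replicate"])
        return cls(df)

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.table["patient"]:
            seen.setdefault(p, None)
        return list(seen)

    def group_of(self, patient: str) -> str:
        rows = self.table[self.table["patient"] == patient]
        if rows.empty:
            raise KeyError(patient)
        return rows["group"].iloc[0]

    @property
    def patient_groups(self) -> dict[str, str]:
        return {p: self.group_of(p) for p in self.patients}

    def samples_of(self, patient: str) -> list[str]:
        rows = self.table[self.table["patient"] == patient].sort_values("replicate")
        return rows["sample"].tolist()

    def group_sizes(self) -> dict[str, int]:
        out = {g: 0 for g in _VALID_GROUPS}
        for g in self.patient_groups.values():
            out[g] += 1
        return out

    def validate_matrix(self, matrix: IntensityMatrix) -> None:
        """Every matrix sample must have a design entry."""
        known = set(self.samples)
        orphans = [s for s in matrix.samples if s not in known]
        if orphans:
            raise FormatError(f"matrix samples missing from design: {orphans}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets (flat symbol lists, GMT-style)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())

    def add(self, name: str, description: str, members: Sequence[str]) -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene-set name: {name}")
        dedup = tuple(dict.fromkeys(members))
        if not dedup:
            raise FormatError(f"gene set {name!r} has no members")
        self.sets[name] = GeneSet(name, description, dedup)


# ----------------------------------------------------------------------
# readers
# ----------------------------------------------------------------------

def read_intensity_table(
    path, column_pattern: str = "LFQ intensity "
) -> IntensityMatrix:
    """Parse a tab-separated protein-group table into an :class:`IntensityMatrix`.

    Intensity columns are identified by the ``column_pattern`` prefix; the
    sample id is the remainder of the header.  Zeros (the MaxQuant missing
    encoding) and empty/NaN cells become missing values.
    """
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter="\t"))
    intensity_cols = [c for c in header if c.startswith(column_pattern)]
    if not intensity_cols:
        raise FormatError(
            f"no column matches intensity pattern {column_pattern!r} in {path}"
        )
    dupes = sorted({c for c in intensity_cols if intensity_cols.count(c) > 1})
    if dupes:
        raise FormatError(f"duplicated sample column(s): {dupes}")

    df = pd.read_csv(
        path, sep="\t", dtype={c: float for c in intensity_cols},
        float_precision="round_trip",
    )
    samples = [c[len(column_pattern):] for c in intensity_cols]
    values = df[intensity_cols].to_numpy(dtype=float)
    values[values == 0.0] = np.nan

    def _annotation(*names: str) -> pd.Series | None:
        for n in names:
            if n in df.columns:
                return df[n]
        return None

    ids_col = _annotation("Protein IDs", "protein_ids", "Majority protein IDs")
    protein_ids = (
        ids_col.astype(str).tolist() if ids_col is not None else [f"row{i}" for i in range(len(df))]
    )
    genes_col = _annotation("Gene names", "gene_names")
    gene_names = genes_col.fillna("").astype(str).tolist() if genes_col is not None else None
    pep_col = _annotation("Peptides", "peptides")
    peptide_counts = pep_col.to_numpy(dtype=int) if pep_col is not None else None

    return IntensityMatrix(
        protein_ids=protein_ids,
        samples=samples,
        values=values,
        gene_names=gene_names,
        peptide_counts=peptide_counts,
        scale="linear",
    )


def write_intensity_table(
    matrix: IntensityMatrix, path, column_pattern: str = "LFQ intensity "
) -> None:
    """Write a matrix in the same dialect :func:`read_intensity_table` consumes.

    Missing cells are serialised as 0 (linear scale only, lossless because
    observed linear intensities are positive).
    """
    if matrix.scale != "linear":
        raise ValueError("only linear-scale matrices can be written as intensity tables")
    out = pd.DataFrame({"Protein IDs": matrix.protein_ids, "Gene names": matrix.gene_names})
    if matrix.peptide_counts is not None:
        out["Peptides"] = matrix.peptide_counts
    # repr() gives the shortest round-tripping decimal form, so write->read
    # is bit-exact on observed values
    for j, s in enumerate(matrix.samples):
        col = matrix.values[:, j]
        out[f"{column_pattern}{s}"] = [
            "0" if np.isnan(v) else repr(float(v)) for v in col
        ]
    out.to_csv(path, sep="\t", index=False)


def read_design(path) -> StudyDesign:
    """Read a sample-design TSV with columns sample, patient, group, replicate."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    return StudyDesign(df)


def write_design(design: StudyDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file (set name, description, then tab-separated members)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need >= 3 fields, got {len(fields)}"
                )
            name, description, *members = fields
            members = [m.strip() for m in members if m.strip()]
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no members")
            coll.add(name, description, members)
    return coll


def read_network(path) -> nx.Graph:
    """Read an undirected interaction network from an edge-list TSV.

    Two node columns, optional numeric confidence weight in the third.
    Self-loops are dropped with a warning; duplicated edges (either node
    order) collapse to one.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: need at least two node columns")
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                logger.warning("%s: line %d: dropping self-loop on %s", path, lineno, a)
                continue
            attrs = {}
            if len(fields) >= 3 and fields[2].strip():
                attrs["weight"] = float(fields[2])
            graph.add_edge(a, b, **attrs)
    return graph


# ----------------------------------------------------------------------
# packaged fixture
# ----------------------------------------------------------------------

def load_significant_table_fixture() -> pd.DataFrame:
    """Packaged reference table: 55 differentially abundant liver proteins.

    The table lists, for a published FOLFOX-treated vs control liver cohort,
    the proteins called significant by the s0-moderated Welch procedure
    (gene names, protein names, Welch p, signed fold change, coefficient of
    variation, peptide counts).  It serves as a worked-example input for the
    summary and enrichment utilities.
    """
    with resources.files("lfqdiff.data").joinpath("significant_proteins.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if len(df) != 55:
        raise RuntimeError("packaged significant-protein table corrupted: expected 55 rows")
    fc = df["fold_change"].to_numpy()
    if ((fc > -1) & (fc < 1)).any():
        raise RuntimeError("fixture violates |fold change| >= 1 invariant")
    return df


def write_results_table(results: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a results DataFrame as TSV with stable column order.

    Signed fold-change columns are serialised at 2 decimals (reference-table
    style); other floats use ``float_format``.
    """
    out = results.copy()
    if "fold_change" in out.columns:
        out["fold_change"] = out["fold_change"].map(lambda v: f"{v:.2f}")
    out.to_csv(path, sep="\t", index=False, float_format=float_format)
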