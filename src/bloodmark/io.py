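"""Shared data containers and tabular I/O.

The pipeline moves four kinds of data around:

* :class:`ExpressionMatrix` — probe × sample intensities (raw or log2) with
  per-probe gene symbols and control flags, as exported from bead-array
  scanners in plain text.
* :class:`SampleTable` — per-sample clinical/technical annotations
  (survival, censoring, treatment center, PBMC/DC material, pairing,
  timepoint).
* :class:`CtTable` — long-format qPCR cycle-threshold measurements.
* :class:`GeneSetCollection` — named gene sets in the Broad GMT convention.

All on-disk formats are TSV (gzip transparently supported); missing
expression values are a parse error because no downstream stage defines
missing-value handling.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd

SCALE_RAW = "raw"
SCALE_LOG2 = "log2"

#: Columns every sample table must provide, in canonical order.
REQUIRED_SAMPLE_COLUMNS = (
    "sample_id",
    "patient_id",
    "material",
    "center",
    "stage",
    "survival_months",
    "event",
    "timepoint",
)

MATERIALS = ("PBMC", "DC")


class FormatError(ValueError):
    """A file does not conform to its declared tabular format."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probe × sample expression grid with probe metadata.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per sample id.
    gene_symbols
        Per-probe gene symbol (may repeat or be empty), aligned to ``values``.
    is_control
        Per-probe boolean control flag, aligned to ``values``.
    scale
        Either ``"raw"`` (linear intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series
    is_control: pd.Series
    scale: str = SCALE_RAW

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_RAW, SCALE_LOG2):
            raise ValidationError(f"unknown scale flag: {self.scale!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate probe_id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample_id: {dup!r}")
        for name, meta in (("gene_symbols", self.gene_symbols),
                           ("is_control", self.is_control)):
            if len(meta) != len(self.values.index):
                raise ValidationError(
                    f"{name} length {len(meta)} != probe count "
                    f"{len(self.values.index)}")
        self.gene_symbols = pd.Series(
            np.asarray(self.gene_symbols, dtype=object),
            index=self.values.index, name="gene_symbol").fillna("")
        self.is_control = pd.Series(
            np.asarray(self.is_control, dtype=bool),
            index=self.values.index, name="is_control")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        self.values.index.name = "probe_id"
        self.values.columns.name = "sample_id"

    # -- convenience accessors -------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"unknown sample ids: {sorted(missing)}")
        return ExpressionMatrix(self.values[ids], self.gene_symbols,
                                self.is_control, self.scale)

    def subset_probes(self, probe_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(probe_ids)
        missing = set(ids) - set(self.probe_ids)
        if missing:
            raise ValidationError(f"unknown probe ids: {sorted(missing)}")
        return ExpressionMatrix(self.values.loc[ids],
                                self.gene_symbols.loc[ids],
                                self.is_control.loc[ids], self.scale)

    def probes_for_gene(self, gene: str) -> list[str]:
        return list(self.probe_ids[self.gene_symbols == gene])

    def gene_row(self, gene: str) -> pd.Series:
        """Per-sample values for *gene*, using its highest-mean probe."""
        probes = self.probes_for_gene(gene)
        if not probes:
            raise ValidationError(f"gene not on matrix: {gene!r}")
        sub = self.values.loc[probes]
        best = sub.mean(axis=1).idxmax()
        return sub.loc[best]

    def probe_to_gene(self) -> pd.Series:
        """Probe id → gene symbol map (empty symbols included)."""
        return self.gene_symbols.copy()


def read_expression_matrix(path: str | Path,
                           scale: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix TSV.

    The file may start with a ``# scale=raw|log2`` metadata line; otherwise
    *scale* must be given (defaulting to raw). The header row is
    ``probe_id  gene_symbol  is_control  <sample ids...>``.
    """
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    lineno = 0
    file_scale = None
    while lineno < len(lines) and lines[lineno].startswith("#"):
        meta = lines[lineno][1:].strip()
        if meta.startswith("scale="):
            file_scale = meta.split("=", 1)[1].strip()
        lineno += 1
    if lineno >= len(lines):
        raise FormatError(f"{path}: no header row")
    header = lines[lineno].split("\t")
    lineno += 1
    if header[:3] != ["probe_id", "gene_symbol", "is_control"]:
        raise FormatError(
            f"{path}: header must start with probe_id, gene_symbol, "
            f"is_control; got {header[:3]}")
    sample_ids = header[3:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    n_fields = len(header)
    probe_ids: list[str] = []
    symbols: list[str] = []
    controls: list[bool] = []
    rows: list[list[float]] = []
    for i, line in enumerate(lines[lineno:], start=lineno + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise FormatError(
                f"{path}: line {i}: expected {n_fields} fields, "
                f"got {len(fields)}")
        probe_ids.append(fields[0])
        symbols.append(fields[1])
        controls.append(_parse_bool(fields[2], path, i))
        try:
            rows.append([float(v) for v in fields[3:]])
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from None
    if len(set(probe_ids)) != len(probe_ids):
        seen: set[str] = set()
        dup = next(p for p in probe_ids if p in seen or seen.add(p))
        raise FormatError(f"{path}: duplicate probe_id {dup!r}")
    values = pd.DataFrame(np.asarray(rows, dtype=float),
                          index=pd.Index(probe_ids, name="probe_id"),
                          columns=pd.Index(sample_ids, name="sample_id"))
    return ExpressionMatrix(values,
                            pd.Series(symbols, index=values.index),
                            pd.Series(controls, index=values.index),
                            scale=file_scale or scale or SCALE_RAW)


def write_expression_matrix(matrix: ExpressionMatrix,
                            path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        fh.write("\t".join(["probe_id", "gene_symbol", "is_control",
                            *map(str, matrix.sample_ids)]) + "\n")
        vals = matrix.values.to_numpy()
        for i, probe in enumerate(matrix.probe_ids):
            row = "\t".join(repr(float(v)) for v in vals[i])
            fh.write(f"{probe}\t{matrix.gene_symbols.iloc[i]}\t"
                     f"{int(matrix.is_control.iloc[i])}\t{row}\n")


def _parse_bool(text: str, path: object, lineno: int) -> bool:
    t = text.strip().upper()
    if t in ("1", "TRUE", "T", "YES"):
        return True
    if t in ("0", "FALSE", "F", "NO"):
        return False
    raise FormatError(f"{path}: line {lineno}: invalid boolean {text!r}")


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Validated per-sample annotation table.

    The backing ``df`` keeps one row per sample with the columns in
    :data:`REQUIRED_SAMPLE_COLUMNS` (plus ``pairing_id`` when PBMC/DC pairing
    is used and any extra columns carried through untouched).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in self.df.columns:
                raise ValidationError(f"missing column: {col}")
        df = self.df.copy()
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id: {dup!r}")
        df["event"] = _coerce_event(df["event"])
        df["survival_months"] = pd.to_numeric(df["survival_months"])
        if (df["survival_months"] < 0).any():
            bad = df.loc[df["survival_months"] < 0, "sample_id"].iloc[0]
            raise ValidationError(
                f"negative survival_months for sample {bad!r}")
        unknown = set(df["material"]) - set(MATERIALS)
        if unknown:
            raise ValidationError(f"unknown material values: {sorted(unknown)}")
        df = df.set_index(df["sample_id"].astype(str), drop=False)
        df.index.name = None
        self.df = df
        self._check_pairing()

    def _check_pairing(self) -> None:
        if "pairing_id" not in self.df.columns:
            return
        dc = self.df[self.df["material"] == "DC"]
        pbmc = self.df[self.df["material"] == "PBMC"]
        counts = pbmc["pairing_id"].value_counts()
        for pid in dc["pairing_id"].dropna():
            if counts.get(pid, 0) != 1:
                raise ValidationError(
                    f"DC pairing_id {pid!r} matches "
                    f"{counts.get(pid, 0)} PBMC samples (expected 1)")

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    def material(self, which: str) -> "SampleTable":
        return SampleTable(self.df[self.df["material"] == which]
                           .reset_index(drop=True))

    def pbmc_ids(self) -> list[str]:
        return list(self.df.index[self.df["material"] == "PBMC"])

    def dc_ids(self) -> list[str]:
        return list(self.df.index[self.df["material"] == "DC"])

    def pbmc_dc_pairs(self) -> list[tuple[str, str]]:
        """(PBMC sample, DC sample) tuples joined on pairing_id."""
        if "pairing_id" not in self.df.columns:
            raise ValidationError("sample table has no pairing_id column")
        pbmc = self.df[self.df["material"] == "PBMC"].set_index("pairing_id")
        dc = self.df[self.df["material"] == "DC"]
        return [(pbmc.loc[pid, "sample_id"], sid)
                for pid, sid in zip(dc["pairing_id"], dc["sample_id"])
                if pid in pbmc.index]

    def survival(self, sample_ids: Iterable[str] | None = None
                 ) -> tuple[pd.Series, pd.Series]:
        """(survival_months, event) aligned to *sample_ids*."""
        df = self.df if sample_ids is None else self.df.loc[list(sample_ids)]
        return df["survival_months"], df["event"]


def _coerce_event(col: pd.Series) -> pd.Series:
    def one(v: object) -> bool:
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        t = str(v).strip().upper()
        if t in ("1", "TRUE", "1.0"):
            return True
        if t in ("0", "FALSE", "0.0"):
            return False
        raise ValidationError(f"invalid event value: {v!r}")
    return col.map(one)


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                            "patient_id": str})
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CtTable
# ---------------------------------------------------------------------------

#: Replicate-to-replicate Ct spread above which a well pair is flagged.
REPLICATE_SD_FLAG = 0.5


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold table.

    Columns: ``sample_id, gene, ct, replicate``. A missing well is an NaN
    ``ct``; valid wells satisfy 0 < Ct < 50.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample_id", "gene", "ct", "replicate"):
            if col not in self.df.columns:
                raise ValidationError(f"missing column: {col}")
        df = self.df.copy()
        df["ct"] = pd.to_numeric(df["ct"])
        valid = df["ct"].isna() | ((df["ct"] > 0) & (df["ct"] < 50))
        if not valid.all():
            bad = df.loc[~valid].iloc[0]
            raise ValidationError(
                f"Ct out of range for sample {bad['sample_id']!r} "
                f"gene {bad['gene']!r}: {bad['ct']}")
        self.df = df

    def mean_ct(self) -> pd.DataFrame:
        """Sample × gene mean Ct, replicates averaged, missing wells excluded."""
        return self.df.pivot_table(index="sample_id", columns="gene",
                                   values="ct", aggfunc="mean")

    def replicate_flags(self) -> pd.DataFrame:
        """Wells whose replicate SD exceeds :data:`REPLICATE_SD_FLAG`."""
        sd = self.df.pivot_table(index="sample_id", columns="gene",
                                 values="ct", aggfunc="std")
        flagged = sd.stack()
        flagged = flagged[flagged > REPLICATE_SD_FLAG]
        return flagged.rename("replicate_sd").reset_index()


def read_ct_table(path: str | Path) -> CtTable:
    return CtTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                                      "gene": str}))


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GeneSetCollection (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (Broad GMT convention)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"empty gene set: {name!r}")
            # collapse duplicates, preserving first-seen order
            self.sets[name] = list(dict.fromkeys(genes))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {i}: GMT line needs >=3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}: line {i}: duplicate set {name!r}")
            sets[name] = [g for g in genes if g]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
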