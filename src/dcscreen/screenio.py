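"""Reading and writing of pooled-screen tables.

All interchange formats are plain tab-separated text with a header row
(UTF-8, no quoting): the sgRNA library, per-sample raw count tables, the
sample sheet, and per-gene score tables.  Gene symbols are treated
case-sensitively and are never re-mapped; scoring stays faithful to the
library annotation as given.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SEQ_RE = re.compile(r"^[ACGT]{15,23}$")

VALID_TIMEPOINTS = ("initial", "final")


@dataclass(frozen=True)
class SgRNARecord:
    """One guide in the library.

    ``sequence`` is optional; guide lengths between 15 and 23 nt are
    accepted (libraries mix canonical 20-mers with shorter non-targeting
    controls).
    """

    sgrna_id: str
    gene: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.sgrna_id:
            raise ValueError("sgrna_id must be non-empty")
        if not self.gene:
            raise ValueError(f"guide {self.sgrna_id!r}: gene symbol must be non-empty")
        if self.sequence is not None and not _SEQ_RE.match(self.sequence):
            raise ValueError(
                f"guide {self.sgrna_id!r}: sequence must be 15-23 nt over ACGT, "
                f"got {self.sequence!r}"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced sample.

    ``cpd`` is the cumulative population doublings elapsed when the sample
    was collected; initial samples are at 0 CPD by definition.
    """

    sample_id: str
    background: str
    timepoint: str
    cpd: float

    def __post_init__(self) -> None:
        if self.timepoint not in VALID_TIMEPOINTS:
            raise ValueError(
                f"sample {self.sample_id!r}: timepoint must be one of "
                f"{VALID_TIMEPOINTS}, got {self.timepoint!r}"
            )
        if self.cpd < 0:
            raise ValueError(f"sample {self.sample_id!r}: cpd must be >= 0")
        if self.timepoint == "initial" and self.cpd != 0:
            raise ValueError(f"initial sample {self.sample_id!r} must have cpd = 0")


@dataclass
class CountTable:
    """Raw sequencing counts: one row per library guide, one column per sample.

    ``counts`` is indexed by sgrna_id in library order with sample_id
    columns; entries are non-negative integers.
    """

    guides: list[SgRNARecord]
    samples: list[SampleMeta]
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        guide_ids = [g.sgrna_id for g in self.guides]
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.counts.index) != guide_ids or list(self.counts.columns) != sample_ids:
            raise ValueError("counts matrix is not aligned to guide/sample lists")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_of(self) -> pd.Series:
        """sgrna_id -> gene symbol, in library order."""
        return pd.Series(
            [g.gene for g in self.guides],
            index=[g.sgrna_id for g in self.guides],
            name="gene",
        )

    def sample(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"sample {sample_id!r} not found")


def read_library(path: str | Path) -> list[SgRNARecord]:
    """Read a guide library TSV with columns sgrna_id, gene[, sequence].

    Records are returned in file order.  Duplicate sgrna_id is an error.
    """
    df = _read_tsv(path)
    for col in ("sgrna_id", "gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = df["sgrna_id"][df["sgrna_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sgrna_id {dup.iloc[0]!r}")
    has_seq = "sequence" in df.columns
    records = []
    for row in df.itertuples(index=False):
        seq = getattr(row, "sequence", None) if has_seq else None
        if seq is not None and (pd.isna(seq) or seq == ""):
            seq = None
        records.append(SgRNARecord(str(row.sgrna_id), str(row.gene), seq))
    return records


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a sample sheet TSV with columns sample_id, background, timepoint, cpd."""
    df = _read_tsv(path)
    for col in ("sample_id", "background", "timepoint", "cpd"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    samples = [
        SampleMeta(str(r.sample_id), str(r.background), str(r.timepoint), float(r.cpd))
        for r in df.itertuples(index=False)
    ]
    seen: set[tuple[str, str]] = set()
    for s in samples:
        key = (s.background, s.timepoint)
        if key in seen:
            raise ValueError(f"{path}: duplicate (background, timepoint) pair {key}")
        seen.add(key)
    return samples


def read_counts(
    path: str | Path,
    library: Sequence[SgRNARecord],
    samples: Sequence[SampleMeta],
) -> CountTable:
    """Read a raw count TSV (sgrna_id column plus one column per sample).

    Counts are re-aligned to library order.  Guides present in the file but
    absent from the library are an error; library guides absent from the
    file are zero-filled (dropout to zero reads is an expected outcome) and
    logged as a warning.
    """
    df = _read_tsv(path)
    if "sgrna_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sgrna_id'")
    sample_ids = [s.sample_id for s in samples]
    extra = [c for c in df.columns if c not in sample_ids and c != "sgrna_id"]
    if extra:
        raise ValueError(f"{path}: unknown sample column(s) {extra}")
    missing_cols = [c for c in sample_ids if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing sample column(s) {missing_cols}")
    dup = df["sgrna_id"][df["sgrna_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sgrna_id {dup.iloc[0]!r}")

    lib_ids = [g.sgrna_id for g in library]
    unknown = set(df["sgrna_id"].astype(str)) - set(lib_ids)
    if unknown:
        raise ValueError(
            f"{path}: {len(unknown)} sgRNA(s) not present in the library, "
            f"e.g. {sorted(unknown)[:3]}"
        )

    df = df.set_index("sgrna_id")[sample_ids]
    for col in sample_ids:
        vals = df[col]
        if not np.all(np.asarray(vals, dtype=float) == np.floor(np.asarray(vals, dtype=float))):
            raise ValueError(f"{path}: non-integer count in sample column {col!r}")
        if (np.asarray(vals, dtype=float) < 0).any():
            raise ValueError(f"{path}: negative count in sample column {col!r}")

    absent = [gid for gid in lib_ids if gid not in df.index]
    if absent:
        logger.warning(
            "%s: %d library guide(s) absent from count file, zero-filled (e.g. %s)",
            path, len(absent), absent[:3],
        )
    counts = df.reindex(lib_ids).fillna(0).astype(np.int64)
    return CountTable(list(library), list(samples), counts)


def write_counts(table: CountTable, path: str | Path) -> None:
    """Write a CountTable back to its TSV interchange form."""
    out = table.counts.copy()
    out.insert(0, "sgrna_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def write_scores(table, path: str | Path) -> None:
    """Write a per-gene score table (CS or dCS) to TSV.

    Columns are gene, score, and n_sgrna (CS tables) or rank (dCS tables).
    Scores are written with 12 significant digits so that a read/write
    round trip reproduces them to that precision.  Background labels are
    preserved in leading ``#``-comment lines.
    """
    from .scoring import DifferentialScoreTable, GeneScoreTable

    if len(table.table) == 0:
        raise ValueError("refusing to write an empty score table")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if isinstance(table, GeneScoreTable):
            fh.write(f"# background={table.background}\n")
            fh.write("gene\tscore\tn_sgrna\n")
            for gene, row in table.table.iterrows():
                fh.write(f"{gene}\t{row['cs']:.12g}\t{int(row['n_sgrna'])}\n")
        elif isinstance(table, DifferentialScoreTable):
            fh.write(f"# test_background={table.test_background}\n")
            fh.write(f"# ref_background={table.ref_background}\n")
            fh.write("gene\tscore\trank\n")
            ordered = table.table.sort_values("rank")
            for gene, row in ordered.iterrows():
                fh.write(f"{gene}\t{row['dcs']:.12g}\t{int(row['rank'])}\n")
        else:
            raise TypeError(f"cannot serialize {type(table).__name__}")


def read_scores(path: str | Path):
    """Read a score TSV written by :func:`write_scores`.

    Returns a GeneScoreTable or DifferentialScoreTable depending on whether
    the file carries an n_sgrna or a rank column.
    """
    from .scoring import DifferentialScoreTable, GeneScoreTable

    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    if "n_sgrna" in df.columns:
        tab = pd.DataFrame(
            {"cs": df["score"].to_numpy(float), "n_sgrna": df["n_sgrna"].to_numpy(int)},
            index=pd.Index(df["gene"].astype(str), name="gene"),
        )
        return GeneScoreTable(meta.get("background", ""), tab)
    if "rank" in df.columns:
        tab = pd.DataFrame(
            {"dcs": df["score"].to_numpy(float), "rank": df["rank"].to_numpy(int)},
            index=pd.Index(df["gene"].astype(str), name="gene"),
        )
        return DifferentialScoreTable(
            meta.get("test_background", ""), meta.get("ref_background", ""), tab
        )
    raise ValueError(f"{path}: not a recognized score table (no n_sgrna or rank column)")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sgrna_id": str, "gene": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    return df
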