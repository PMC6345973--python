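"""Readers and writers for the external formats the pipeline touches.

Formats: STAR ``SJ.out.tab`` splice-junction tables (9 tab-separated
columns, 1-based inclusive intron coordinates), GMT gene-set collections,
gene-level count matrices (TSV) with a sample-to-group design (CSV),
survival cohorts (CSV) and flat result tables (TSV).

All readers validate strictly and raise rather than silently coercing
malformed input.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("xbp1flux")

__all__ = [
    "JunctionRecord",
    "JunctionTable",
    "CountMatrix",
    "GeneSetCollection",
    "SurvivalCohort",
    "ParseError",
    "ValidationError",
    "read_sj_tab",
    "write_sj_tab",
    "read_gmt",
    "write_gmt",
    "read_counts",
    "read_survival",
    "write_results",
    "read_results",
]


class ParseError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# strand encoding used by STAR: 0 undefined, 1 '+', 2 '-'
STRAND_CODES = {0: ".", 1: "+", 2: "-"}
STRAND_SYMBOLS = {v: k for k, v in STRAND_CODES.items()}


@dataclass(frozen=True)
class JunctionRecord:
    """One spliced junction: 1-based inclusive intron bounds plus counts.

    ``motif_code`` (0-6) and ``annotated`` (0/1) are carried through from
    the aligner but never used in any statistic.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: int  # 0 unknown, 1 '+', 2 '-'
    motif_code: int = 0
    annotated: int = 0
    unique_reads: int = 0
    multi_reads: int = 0
    max_overhang: int = 0

    def __post_init__(self) -> None:
        if self.intron_start <= 0 or self.intron_end <= 0:
            raise ValidationError(
                f"junction coordinates must be positive 1-based: "
                f"{self.chrom}:{self.intron_start}-{self.intron_end}"
            )
        if self.intron_start > self.intron_end:
            raise ValidationError(
                f"intron_start > intron_end for {self.chrom}:"
                f"{self.intron_start}-{self.intron_end}"
            )
        if self.strand not in (0, 1, 2):
            raise ValidationError(f"strand code must be 0/1/2, got {self.strand}")
        if not 0 <= self.motif_code <= 6:
            raise ValidationError(f"motif code must be 0-6, got {self.motif_code}")
        if self.annotated not in (0, 1):
            raise ValidationError(f"annotated flag must be 0/1, got {self.annotated}")
        for name in ("unique_reads", "multi_reads", "max_overhang"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def key(self) -> tuple[str, int, int, int]:
        """Identity key: (chrom, intron_start, intron_end, strand)."""
        return (self.chrom, self.intron_start, self.intron_end, self.strand)


@dataclass
class JunctionTable:
    """Ordered junction records for one sample; duplicate keys rejected."""

    sample_id: str
    records: list[JunctionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValidationError(
                    f"duplicate junction key {rec.key} in sample {self.sample_id}"
                )
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample counts with a group design.

    ``counts`` is a genes x samples DataFrame; ``design`` maps every sample
    id to its group label.
    """

    counts: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise ValidationError(f"samples absent from design: {missing}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), rtol=0, atol=0):
                raise ValidationError("count matrix contains non-integer entries")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValidationError("count matrix contains negative entries")
        self.design = self.design.loc[list(self.counts.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.design:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.design[s] == group]


@dataclass
class GeneSetCollection:
    """Named gene sets: set_name -> (description, unique member labels)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class SurvivalCohort:
    """Per-sample time-to-event data, optionally with expression.

    ``expression`` is genes x samples; its column order must match
    ``sample_ids``.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    expression: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in cohort")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValidationError("time/event length mismatch with sample ids")
        if (self.time < 0).any():
            raise ValidationError("negative survival times")
        if not np.isin(self.event, [0, 1]).all():
            raise ValidationError("event indicator must be 0/1")
        self.event = self.event.astype(int)
        if self.expression is not None:
            if list(self.expression.columns) != list(self.sample_ids):
                raise ValidationError(
                    "expression column order does not match cohort sample ids"
                )

    def __len__(self) -> int:
        return len(self.sample_ids)


# ---------------------------------------------------------------------------
# STAR SJ.out.tab


def read_sj_tab(path: str | os.PathLike, sample_id: str | None = None) -> JunctionTable:
    """Read a STAR ``SJ.out.tab`` file (9 tab-separated integer columns).

    Columns: chrom, intron start (1-based), intron end (1-based inclusive),
    strand code, motif code, annotated flag, unique reads, multi reads,
    maximum overhang.
    """
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    records: list[JunctionRecord] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                ints = [int(x) for x in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            records.append(
                JunctionRecord(
                    chrom=chrom,
                    intron_start=ints[0],
                    intron_end=ints[1],
                    strand=ints[2],
                    motif_code=ints[3],
                    annotated=ints[4],
                    unique_reads=ints[5],
                    multi_reads=ints[6],
                    max_overhang=ints[7],
                )
            )
    return JunctionTable(sample_id=sample_id, records=records)


def write_sj_tab(table: JunctionTable, path: str | os.PathLike) -> None:
    """Write a JunctionTable back to the STAR 9-column dialect."""
    with open(path, "wt") as fh:
        for rec in table.records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        rec.chrom,
                        rec.intron_start,
                        rec.intron_end,
                        rec.strand,
                        rec.motif_code,
                        rec.annotated,
                        rec.unique_reads,
                        rec.multi_reads,
                        rec.max_overhang,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line needs >=3 fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            dupes = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dupes += 1
                    continue
                seen.add(g)
                members.append(g)
            if dupes:
                logger.warning(
                    "gene set %s: %d duplicate member label(s) removed", name, dupes
                )
            sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# counts + design


def read_counts(path: str | os.PathLike, design_path: str | os.PathLike) -> CountMatrix:
    """Read a gene x sample counts TSV and its sample,group design CSV.

    The counts file has gene ids in the first column and a header row of
    sample ids. Every sample column must appear in the design.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    design_df = pd.read_csv(design_path)
    expected = {"sample", "group"}
    if not expected.issubset(design_df.columns):
        raise ParseError(f"{design_path}: design needs columns {sorted(expected)}")
    if design_df["sample"].duplicated().any():
        raise ValidationError(f"{design_path}: duplicate sample in design")
    design = pd.Series(
        design_df["group"].to_numpy(), index=design_df["sample"].astype(str)
    )
    counts.columns = counts.columns.astype(str)
    counts.index = counts.index.astype(str)
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric entries in count matrix")
    if not np.issubdtype(values.dtype, np.integer):
        if not (values == np.round(values)).all():
            raise ValidationError(f"{path}: non-integer count entries")
    return CountMatrix(counts=counts, design=design)


def write_counts(
    m: CountMatrix, path: str | os.PathLike, design_path: str | os.PathLike
) -> None:
    m.counts.to_csv(path, sep="\t", index_label="gene")
    pd.DataFrame({"sample": m.sample_ids, "group": m.design.to_numpy()}).to_csv(
        design_path, index=False
    )


# ---------------------------------------------------------------------------
# survival


def read_survival(
    path: str | os.PathLike, expression_path: str | os.PathLike | None = None
) -> SurvivalCohort:
    """Read a cohort CSV (columns sample, time, event) and optional
    expression TSV (genes x samples, restricted/ordered to cohort samples)."""
    df = pd.read_csv(path)
    expected = {"sample", "time", "event"}
    if not expected.issubset(df.columns):
        raise ParseError(f"{path}: cohort CSV needs columns {sorted(expected)}")
    sample_ids = [str(s) for s in df["sample"]]
    expression = None
    if expression_path is not None:
        expression = pd.read_csv(expression_path, sep="\t", index_col=0)
        expression.columns = expression.columns.astype(str)
        missing = [s for s in sample_ids if s not in expression.columns]
        if missing:
            raise ValidationError(
                f"{expression_path}: cohort samples missing from expression: {missing}"
            )
        expression = expression.loc[:, sample_ids]
    return SurvivalCohort(
        sample_ids=sample_ids,
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(),
        expression=expression,
    )


def write_survival(cohort: SurvivalCohort, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"sample": cohort.sample_ids, "time": cohort.time, "event": cohort.event}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# generic result tables


def write_results(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table as TSV with a deterministic column order
    (the DataFrame's own order) and full float precision."""
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
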