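"""Reading, validating, filtering and writing aligned cfDNA fragments.

Two on-disk dialects are supported:

* ``fragment-table`` — a 9-column tab-separated text format with a
  ``#``-prefixed header line; columns are
  ``chrom  start  end  strand  mapq  mismatches  proper_pair  duplicate
  multimapped`` with 0-based half-open coordinates and 0/1 booleans.
* ``alignment`` — standard SAM/BAM semantics; mate pairs are collapsed to
  one fragment per template and 1-based alignment positions are converted
  to 0-based half-open intervals at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: Fixed charging order: a removed fragment is attributed to the first rule
#: in this order that it fails.
RULE_ORDER = ("duplicate", "multimapped", "mapq", "mismatches", "proper_pair", "insert")

TABLE_COLUMNS = (
    "chrom",
    "start",
    "end",
    "strand",
    "mapq",
    "mismatches",
    "proper_pair",
    "duplicate",
    "multimapped",
)

TABLE_HEADER = "#" + "\t".join(TABLE_COLUMNS)


class FragmentError(ValueError):
    """Invalid fragment record or fragment file."""


class ParseError(FragmentError):
    """Malformed record in a fragment file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned cfDNA fragment (template-level, 0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand_of_read1: str = "+"
    mapq: int = 60
    mismatches: int = 0
    proper_pair: bool = True
    duplicate: bool = False
    multimapped: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise FragmentError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand_of_read1 not in STRANDS:
            raise FragmentError(f"strand must be one of {STRANDS}, got {self.strand_of_read1!r}")
        if not (0 <= self.mapq <= 255):
            raise FragmentError(f"mapq must be in [0, 255], got {self.mapq}")
        if self.mismatches < 0:
            raise FragmentError(f"mismatches must be >= 0, got {self.mismatches}")

    @property
    def insert_size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FilterConfig:
    """Post-alignment retention thresholds.

    Defaults retain fragments with mapping quality >= 30, at most five
    mismatches, proper pairing, insert size strictly below 600 bp, and drop
    duplicates and multi-mapped templates.
    """

    min_mapq: int = 30
    max_mismatches: int = 5
    max_insert: int = 600  # exclusive upper bound on insert size
    require_proper_pair: bool = True
    drop_duplicates: bool = True
    drop_multimapped: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0 or self.max_mismatches < 0 or self.max_insert < 0:
            raise FragmentError("filter thresholds must be non-negative")


@dataclass
class FilterStats:
    input_count: int = 0
    retained_count: int = 0
    removed_by_rule: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in RULE_ORDER}
    )

    @property
    def removed_count(self) -> int:
        return sum(self.removed_by_rule.values())

    def validate(self) -> None:
        if self.input_count != self.retained_count + self.removed_count:
            raise FragmentError("filter accounting does not sum")

    def as_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "retained_count": self.retained_count,
            "removed_by_rule": dict(self.removed_by_rule),
        }


class FragmentFrame:
    """Columnar container of fragments; the fast path for whole-sample work.

    Mirrors :class:`FragmentRecord` field-for-field but holds numpy arrays,
    so filtering, motif extraction and depth computation can be vectorized.
    """

    __slots__ = (
        "chrom",
        "start",
        "end",
        "strand",
        "mapq",
        "mismatches",
        "proper_pair",
        "duplicate",
        "multimapped",
    )

    def __init__(
        self,
        chrom,
        start,
        end,
        strand=None,
        mapq=None,
        mismatches=None,
        proper_pair=None,
        duplicate=None,
        multimapped=None,
    ):
        n = len(start)
        self.chrom = np.asarray(chrom, dtype=object)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.strand = (
            np.asarray(strand, dtype=object)
            if strand is not None
            else np.full(n, "+", dtype=object)
        )
        self.mapq = (
            np.asarray(mapq, dtype=np.int64) if mapq is not None else np.full(n, 60)
        )
        self.mismatches = (
            np.asarray(mismatches, dtype=np.int64)
            if mismatches is not None
            else np.zeros(n, dtype=np.int64)
        )
        self.proper_pair = (
            np.asarray(proper_pair, dtype=bool)
            if proper_pair is not None
            else np.ones(n, dtype=bool)
        )
        self.duplicate = (
            np.asarray(duplicate, dtype=bool)
            if duplicate is not None
            else np.zeros(n, dtype=bool)
        )
        self.multimapped = (
            np.asarray(multimapped, dtype=bool)
            if multimapped is not None
            else np.zeros(n, dtype=bool)
        )
        if np.any(self.start < 0) or np.any(self.end <= self.start):
            raise FragmentError("fragment intervals must satisfy 0 <= start < end")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def insert_size(self) -> np.ndarray:
        return self.end - self.start

    @classmethod
    def from_records(cls, records: Iterable[FragmentRecord]) -> "FragmentFrame":
        records = list(records)
        return cls(
            chrom=[r.chrom for r in records],
            start=[r.start for r in records],
            end=[r.end for r in records],
            strand=[r.strand_of_read1 for r in records],
            mapq=[r.mapq for r in records],
            mismatches=[r.mismatches for r in records],
            proper_pair=[r.proper_pair for r in records],
            duplicate=[r.duplicate for r in records],
            multimapped=[r.multimapped for r in records],
        )

    def to_records(self) -> list[FragmentRecord]:
        return [
            FragmentRecord(
                chrom=self.chrom[i],
                start=int(self.start[i]),
                end=int(self.end[i]),
                strand_of_read1=self.strand[i],
                mapq=int(self.mapq[i]),
                mismatches=int(self.mismatches[i]),
                proper_pair=bool(self.proper_pair[i]),
                duplicate=bool(self.duplicate[i]),
                multimapped=bool(self.multimapped[i]),
            )
            for i in range(len(self))
        ]

    def subset(self, mask: np.ndarray) -> "FragmentFrame":
        return FragmentFrame(
            chrom=self.chrom[mask],
            start=self.start[mask],
            end=self.end[mask],
            strand=self.strand[mask],
            mapq=self.mapq[mask],
            mismatches=self.mismatches[mask],
            proper_pair=self.proper_pair[mask],
            duplicate=self.duplicate[mask],
            multimapped=self.multimapped[mask],
        )

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chrom == chrom


def _coerce_frame(fragments) -> FragmentFrame:
    if isinstance(fragments, FragmentFrame):
        return fragments
    return FragmentFrame.from_records(fragments)


# ---------------------------------------------------------------------------
# fragment-table dialect
# ---------------------------------------------------------------------------

_BOOL = {"0": False, "1": True}


def _parse_table_line(line: str, line_number: int) -> FragmentRecord:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != len(TABLE_COLUMNS):
        raise ParseError(
            f"expected {len(TABLE_COLUMNS)} tab-separated fields, got {len(parts)}",
            line_number,
        )
    try:
        return FragmentRecord(
            chrom=parts[0],
            start=int(parts[1]),
            end=int(parts[2]),
            strand_of_read1=parts[3],
            mapq=int(parts[4]),
            mismatches=int(parts[5]),
            proper_pair=_BOOL[parts[6]],
            duplicate=_BOOL[parts[7]],
            multimapped=_BOOL[parts[8]],
        )
    except KeyError as exc:
        raise ParseError(f"boolean fields must be 0/1, got {exc}", line_number) from exc
    except (ValueError, FragmentError) as exc:
        raise ParseError(str(exc), line_number) from exc


def read_fragments(path, dialect: str = "fragment-table") -> Iterator[FragmentRecord]:
    """Yield :class:`FragmentRecord` from ``path`` in file order.

    ``dialect`` is ``fragment-table`` (tab-separated) or ``alignment``
    (SAM/BAM; mate pairs collapsed, orphan reads skipped with a logged
    count).
    """
    if dialect == "fragment-table":
        yield from _read_table(path)
    elif dialect == "alignment":
        records, orphans = read_alignment(path)
        if orphans:
            logger.info("alignment %s: skipped %d orphan read(s)", path, orphans)
        yield from records
    else:
        raise FragmentError(f"unknown dialect {dialect!r}")


def _read_table(path) -> Iterator[FragmentRecord]:
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            yield _parse_table_line(line, line_number)


def read_fragment_frame(path) -> FragmentFrame:
    """Fast columnar read of a fragment-table file."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=TABLE_COLUMNS,
        dtype={
            "chrom": str,
            "start": np.int64,
            "end": np.int64,
            "strand": str,
            "mapq": np.int64,
            "mismatches": np.int64,
            "proper_pair": np.int64,
            "duplicate": np.int64,
            "multimapped": np.int64,
        },
    )
    if df.empty:
        return FragmentFrame(chrom=[], start=[], end=[])
    bad = np.flatnonzero(df["start"].to_numpy() >= df["end"].to_numpy())
    if bad.size:
        raise ParseError("start >= end", int(bad[0]) + 2)  # +1 header, +1 1-based
    return FragmentFrame(
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(),
        end=df["end"].to_numpy(),
        strand=df["strand"].to_numpy(dtype=object),
        mapq=df["mapq"].to_numpy(),
        mismatches=df["mismatches"].to_numpy(),
        proper_pair=df["proper_pair"].to_numpy(dtype=bool),
        duplicate=df["duplicate"].to_numpy(dtype=bool),
        multimapped=df["multimapped"].to_numpy(dtype=bool),
    )


def write_fragments(records, path) -> None:
    """Write fragments to the fragment-table dialect (round-trip lossless)."""
    path = Path(path)
    if isinstance(records, FragmentFrame):
        frame = records
        with open(path, "w") as fh:
            fh.write(TABLE_HEADER + "\n")
            for c in frame.chrom:
                if "\t" in c or "\n" in c:
                    raise FragmentError(f"chromosome name {c!r} contains a tab/newline")
            cols = np.column_stack(
                [
                    frame.chrom,
                    frame.start.astype(str),
                    frame.end.astype(str),
                    frame.strand,
                    frame.mapq.astype(str),
                    frame.mismatches.astype(str),
                    frame.proper_pair.astype(int).astype(str),
                    frame.duplicate.astype(int).astype(str),
                    frame.multimapped.astype(int).astype(str),
                ]
            )
            fh.writelines("\t".join(row) + "\n" for row in cols)
        return
    with open(path, "w") as fh:
        fh.write(TABLE_HEADER + "\n")
        for rec in records:
            if "\t" in rec.chrom or "\n" in rec.chrom:
                raise FragmentError(f"chromosome name {rec.chrom!r} contains a tab/newline")
            fh.write(
                "\t".join(
                    (
                        rec.chrom,
                        str(rec.start),
                        str(rec.end),
                        rec.strand_of_read1,
                        str(rec.mapq),
                        str(rec.mismatches),
                        str(int(rec.proper_pair)),
                        str(int(rec.duplicate)),
                        str(int(rec.multimapped)),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# alignment dialect
# ---------------------------------------------------------------------------


def read_alignment(path) -> tuple[list[FragmentRecord], int]:
    """Collapse a SAM/BAM file to template-level fragments.

    Returns ``(fragments, orphan_count)`` where orphans are primary reads
    whose mate never appears. Secondary/supplementary records are not
    emitted themselves but mark their template as multi-mapped. Mismatch
    count per fragment is the max of the two reads' NM tags.
    """
    import pysam

    pending: dict[str, list] = {}
    order: list[str] = []
    multimapped_templates: set[str] = set()
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af:
            if read.is_secondary or read.is_supplementary:
                multimapped_templates.add(read.query_name)
                continue
            if read.is_unmapped:
                continue
            if read.query_name not in pending:
                order.append(read.query_name)
            pending.setdefault(read.query_name, []).append(read)

    fragments: list[FragmentRecord] = []
    orphans = 0
    for qname in order:
        reads = pending[qname]
        if len(reads) != 2:
            orphans += len(reads)
            continue
        r1 = next((r for r in reads if r.is_read1), reads[0])
        start = min(r.reference_start for r in reads)
        end = max(r.reference_end for r in reads)
        nm = max(int(r.get_tag("NM")) if r.has_tag("NM") else 0 for r in reads)
        fragments.append(
            FragmentRecord(
                chrom=reads[0].reference_name,
                start=start,
                end=end,
                strand_of_read1="-" if r1.is_reverse else "+",
                mapq=min(r.mapping_quality for r in reads),
                mismatches=nm,
                proper_pair=all(r.is_proper_pair for r in reads),
                duplicate=any(r.is_duplicate for r in reads),
                multimapped=qname in multimapped_templates,
            )
        )
    return fragments, orphans


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def failing_rule(record: FragmentRecord, cfg: FilterConfig) -> str | None:
    """First retention rule (in RULE_ORDER) the record fails, or None."""
    if cfg.drop_duplicates and record.duplicate:
        return "duplicate"
    if cfg.drop_multimapped and record.multimapped:
        return "multimapped"
    if record.mapq < cfg.min_mapq:
        return "mapq"
    if record.mismatches > cfg.max_mismatches:
        return "mismatches"
    if cfg.require_proper_pair and not record.proper_pair:
        return "proper_pair"
    if record.insert_size >= cfg.max_insert:
        return "insert"
    return None


def filter_fragments(fragments, cfg: FilterConfig | None = None):
    """Apply retention rules; returns ``(retained, FilterStats)``.

    ``fragments`` may be an iterable of :class:`FragmentRecord` (returns a
    list) or a :class:`FragmentFrame` (returns a frame, vectorized).
    """
    cfg = cfg or FilterConfig()
    if isinstance(fragments, FragmentFrame):
        return _filter_frame(fragments, cfg)
    stats = FilterStats()
    retained: list[FragmentRecord] = []
    for record in fragments:
        stats.input_count += 1
        rule = failing_rule(record, cfg)
        if rule is None:
            retained.append(record)
            stats.retained_count += 1
        else:
            stats.removed_by_rule[rule] += 1
    stats.validate()
    return retained, stats


def _filter_frame(frame: FragmentFrame, cfg: FilterConfig):
    n = len(frame)
    fails = {
        "duplicate": frame.duplicate if cfg.drop_duplicates else np.zeros(n, bool),
        "multimapped": frame.multimapped if cfg.drop_multimapped else np.zeros(n, bool),
        "mapq": frame.mapq < cfg.min_mapq,
        "mismatches": frame.mismatches > cfg.max_mismatches,
        "proper_pair": (~frame.proper_pair) if cfg.require_proper_pair else np.zeros(n, bool),
        "insert": frame.insert_size >= cfg.max_insert,
    }
    stats = FilterStats(input_count=n)
    charged = np.zeros(n, dtype=bool)
    for rule in RULE_ORDER:
        hit = fails[rule] & ~charged
        stats.removed_by_rule[rule] = int(hit.sum())
        charged |= fails[rule]
    retained = frame.subset(~charged)
    stats.retained_count = len(retained)
    stats.validate()
    return retained, stats
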