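"""PAF alignment ingestion and per-(query, reference) coverage.

The classifier consumes alignments through the minimap2 PAF interchange
format (tab-separated, 12 mandatory columns, 0-based half-open query and
target coordinates).  Coverage of a query by a reference is the size of the
union of its aligned query intervals divided by the query length —
overlapping alignments are merged, never summed, so coverage stays in
[0, 1].  An alignment counts as an exact match only when it spans the whole
query without a single mismatch or gap: n_matches = block_len =
query_end − query_start = query_len.
"""

from __future__ import annotations

import shlex
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "PafRecord",
    "PafFormatError",
    "QueryRefCoverage",
    "read_paf",
    "write_paf",
    "query_coverage",
    "group_coverages",
    "is_exact_match",
    "AlignerConfig",
    "minimap2_command",
    "run_minimap2",
]


class PafFormatError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"PAF line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class PafRecord:
    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    n_matches: int
    block_len: int
    mapq: int

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(
                f"query interval [{self.query_start}, {self.query_end}) out of "
                f"range for length {self.query_len}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(
                f"target interval [{self.target_start}, {self.target_end}) out of "
                f"range for length {self.target_len}"
            )
        if self.n_matches > self.block_len:
            raise ValueError(
                f"n_matches {self.n_matches} exceeds block_len {self.block_len}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def to_line(self) -> str:
        return "\t".join(
            str(v)
            for v in (
                self.query_id,
                self.query_len,
                self.query_start,
                self.query_end,
                self.strand,
                self.target_id,
                self.target_len,
                self.target_start,
                self.target_end,
                self.n_matches,
                self.block_len,
                self.mapq,
            )
        )


@dataclass(frozen=True)
class QueryRefCoverage:
    query_id: str
    ref_id: str
    coverage: float
    n_alignments: int
    exact: bool


def read_paf(source: str | Path | Iterable[str]) -> Iterator[PafRecord]:
    """Parse PAF lines into validated records; optional SAM-like tags beyond
    column 12 are ignored.  Malformed lines raise with their line number."""
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text().splitlines()
    else:
        lines = source
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise PafFormatError(lineno, f"expected >= 12 columns, got {len(cols)}")
        try:
            rec = PafRecord(
                query_id=cols[0],
                query_len=int(cols[1]),
                query_start=int(cols[2]),
                query_end=int(cols[3]),
                strand=cols[4],
                target_id=cols[5],
                target_len=int(cols[6]),
                target_start=int(cols[7]),
                target_end=int(cols[8]),
                n_matches=int(cols[9]),
                block_len=int(cols[10]),
                mapq=int(cols[11]),
            )
        except ValueError as exc:
            raise PafFormatError(lineno, str(exc)) from exc
        yield rec


def write_paf(records: Iterable[PafRecord], path: str | Path) -> None:
    Path(path).write_text("".join(rec.to_line() + "\n" for rec in records))


def is_exact_match(record: PafRecord) -> bool:
    """Full-length, mismatch-free alignment of the entire query."""
    span = record.query_end - record.query_start
    return (
        record.n_matches == record.block_len == span == record.query_len
    )


def query_coverage(records: Sequence[PafRecord]) -> QueryRefCoverage:
    """Coverage of one (query, reference) pair: union of aligned query
    intervals over query length.  Order-invariant; abutting or overlapping
    intervals merge."""
    if not records:
        raise ValueError("query_coverage needs at least one record; use "
                         "group_coverages for whole files")
    query_id = records[0].query_id
    ref_id = records[0].target_id
    qlen = records[0].query_len
    for rec in records:
        if rec.query_id != query_id or rec.target_id != ref_id:
            raise ValueError(
                f"records mix ({rec.query_id}, {rec.target_id}) with "
                f"({query_id}, {ref_id})"
            )
        if rec.query_len != qlen:
            raise ValueError(
                f"inconsistent query_len for {query_id}: {rec.query_len} vs {qlen}"
            )
    intervals = sorted((r.query_start, r.query_end) for r in records)
    covered = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end:
            covered += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    covered += cur_end - cur_start
    return QueryRefCoverage(
        query_id=query_id,
        ref_id=ref_id,
        coverage=covered / qlen,
        n_alignments=len(records),
        exact=any(is_exact_match(r) for r in records),
    )


def group_coverages(
    records: Iterable[PafRecord],
) -> dict[str, list[QueryRefCoverage]]:
    """Per-query lists of QueryRefCoverage, one entry per aligned reference."""
    buckets: dict[tuple[str, str], list[PafRecord]] = {}
    for rec in records:
        buckets.setdefault((rec.query_id, rec.target_id), []).append(rec)
    out: dict[str, list[QueryRefCoverage]] = {}
    for (query_id, _), recs in sorted(buckets.items()):
        out.setdefault(query_id, []).append(query_coverage(recs))
    return out


# ---------------------------------------------------------------------------
# Optional external-aligner hook.  The tested pipeline surface consumes PAF;
# this merely builds (and can run) a minimap2 invocation for users who want
# the alignment produced in-line: preset asm10 for contig/genome queries,
# sr for short reads.


@dataclass(frozen=True)
class AlignerConfig:
    preset: str = "asm10"
    threads: int = 1
    extra_flags: str = ""

    def __post_init__(self) -> None:
        if self.preset not in ("asm10", "sr"):
            raise ValueError(f"preset must be asm10 or sr, got {self.preset!r}")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


def minimap2_command(
    config: AlignerConfig, reference_fasta: str | Path, query_fasta: str | Path
) -> list[str]:
    cmd = ["minimap2", "-x", config.preset, "-t", str(config.threads)]
    if config.extra_flags:
        cmd.extend(shlex.split(config.extra_flags))
    cmd.extend([str(reference_fasta), str(query_fasta)])
    return cmd


def run_minimap2(
    config: AlignerConfig,
    reference_fasta: str | Path,
    query_fasta: str | Path,
    out_paf: str | Path,
) -> None:
    cmd = minimap2_command(config, reference_fasta, query_fasta)
    with open(out_paf, "w") as fh:
        subprocess.run(cmd, stdout=fh, check=True)
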