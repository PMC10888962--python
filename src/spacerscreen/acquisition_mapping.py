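"""Strand-resolved genome coverage of naively acquired spacers.

Acquired spacers are aligned to the phage genome by ungapped two-strand
Hamming matching; uniquely-mapped hits are piled into per-nucleotide coverage
on their matched strand and normalized to reads per million (RPM) against an
explicit total-aligned-reads denominator. Multi-hit queries are dropped from
coverage and tallied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._sequtils import ExactIndex, hamming_hits
from .library_design import GenomeRecord

RPM_SCALE = 1_000_000


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    start: int
    end: int
    strand: str  # "plus" | "minus"
    mismatches: int


@dataclass
class StrandCoverageTrack:
    """Per-position counts (and optionally RPM) on each strand of a genome."""

    genome_id: str
    length: int
    plus_counts: np.ndarray
    minus_counts: np.ndarray
    plus_rpm: np.ndarray | None = None
    minus_rpm: np.ndarray | None = None
    total_aligned: int = 0

    @classmethod
    def zeros(cls, genome_id: str, length: int) -> "StrandCoverageTrack":
        return cls(
            genome_id=genome_id,
            length=length,
            plus_counts=np.zeros(length, dtype=np.int64),
            minus_counts=np.zeros(length, dtype=np.int64),
        )


def align_spacer(
    query: str,
    genome: GenomeRecord,
    max_mismatches: int = 1,
    query_id: str = "query",
    index: ExactIndex | None = None,
) -> list[AlignmentHit]:
    """All ungapped two-strand matches of ``query`` within the mismatch budget.

    Hits are sorted best-first (fewest mismatches, then position); callers
    wanting a single placement should check for ties among the best hits.
    """
    if max_mismatches == 0 and index is not None and index.k == len(query):
        raw = index.lookup(query.upper())
    else:
        raw = hamming_hits(genome.sequence, query, max_mismatches)
    return [
        AlignmentHit(query_id=query_id, start=s, end=s + len(query), strand=strand, mismatches=mm)
        for s, strand, mm in raw
    ]


def best_unique_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit | None:
    """The single best hit, or None when unmapped or tied (multi-hit)."""
    if not hits:
        return None
    best_mm = min(h.mismatches for h in hits)
    best = [h for h in hits if h.mismatches == best_mm]
    return best[0] if len(best) == 1 else None


def map_spacers(
    queries: Iterable[tuple[str, str]],
    genome: GenomeRecord,
    max_mismatches: int = 1,
) -> tuple[list[AlignmentHit], dict]:
    """Uniquely place each (query_id, sequence); returns hits and a QC tally."""
    index: ExactIndex | None = None
    qc = {"n_queries": 0, "unique": 0, "multi": 0, "unmapped": 0}
    hits = []
    lengths = set()
    queries = list(queries)
    if max_mismatches == 0 and queries:
        lengths = {len(seq) for _, seq in queries}
        if len(lengths) == 1:
            index = ExactIndex(genome.sequence, k=next(iter(lengths)))
    for qid, seq in queries:
        qc["n_queries"] += 1
        best = best_unique_hit(align_spacer(seq, genome, max_mismatches, query_id=qid, index=index))
        if best is None:
            all_hits = align_spacer(seq, genome, max_mismatches, query_id=qid, index=index)
            qc["unmapped" if not all_hits else "multi"] += 1
        else:
            qc["unique"] += 1
            hits.append(best)
    return hits, qc


def strand_coverage(hits: Iterable[AlignmentHit], length: int, genome_id: str = "genome") -> StrandCoverageTrack:
    """Single-nucleotide pileup of uniquely mapped hits, per strand."""
    track = StrandCoverageTrack.zeros(genome_id, length)
    for h in hits:
        if h.start < 0 or h.end > length:
            raise ValueError(f"hit {h.query_id} [{h.start}, {h.end}) outside genome of length {length}")
        arr = track.plus_counts if h.strand == "plus" else track.minus_counts
        arr[h.start : h.end] += 1
        track.total_aligned += 1
    return track


def rpm_normalize(track: StrandCoverageTrack, total_aligned_reads: int) -> StrandCoverageTrack:
    """Fill RPM arrays: rpm = 1e6 * counts / total aligned reads (both strands).

    The denominator is explicit — all reads that aligned anywhere, including
    any non-phage fraction — so the normalization stays auditable.
    """
    if total_aligned_reads <= 0:
        raise ValueError("total_aligned_reads must be positive")
    track.plus_rpm = RPM_SCALE * track.plus_counts / total_aligned_reads
    track.minus_rpm = RPM_SCALE * track.minus_counts / total_aligned_reads
    return track


def _write_bedgraph(path: Path, genome_id: str, values: np.ndarray) -> None:
    """Run-length encoded bedGraph; floats written with repr so reads are exact."""
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[run_start]:
                v = values[run_start]
                text = str(int(v)) if float(v).is_integer() else repr(float(v))
                fh.write(f"{genome_id}\t{run_start}\t{i}\t{text}\n")
                run_start = i


def write_coverage_bedgraph(track: StrandCoverageTrack, prefix: str | Path) -> list[Path]:
    """Write counts (and RPM when present) per strand as four bedGraph files."""
    prefix = Path(prefix)
    written = []
    layers = [("counts.plus", track.plus_counts), ("counts.minus", track.minus_counts)]
    if track.plus_rpm is not None:
        layers += [("rpm.plus", track.plus_rpm), ("rpm.minus", track.minus_rpm)]
    for tag, values in layers:
        path = prefix.parent / f"{prefix.name}.{tag}.bedgraph"
        _write_bedgraph(path, track.genome_id, values)
        written.append(path)
    return written


def read_bedgraph(path: str | Path, length: int) -> np.ndarray:
    """Dense per-position array from a bedGraph file (positions absent = 0)."""
    values = np.zeros(length, dtype=float)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            _, start, end, v = line.rstrip("\n").split("\t")
            values[int(start) : int(end)] = float(v)
    return values
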