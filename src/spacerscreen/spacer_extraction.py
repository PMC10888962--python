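"""Recovery of spacers from amplicon sequencing reads.

Amplicons of a CRISPR array read as repeat–spacer–repeat(–spacer–repeat…), so
a spacer is any insert that lies between two consecutive occurrences of the
direct repeat (DR). Occurrences are found by ungapped (Hamming) matching
within a mismatch budget, selected greedily left-to-right so that consecutive
repeats never share bases; inserts outside the configured length window are
discarded. Inserts are counted verbatim — no error correction or clustering —
so a sequencing error inside a spacer produces a distinct key. Base qualities
are ignored.

Reads are optionally scanned in both orientations; an insert found on the
reverse complement is reported in the orientation that places the repeat
5'→3' as configured.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from ._sequtils import encode, hamming_offsets, revcomp

_CHUNK_READS = 200_000
_PAD_BYTE = 0  # never equal to any base, so padding cannot fake a match


@dataclass(frozen=True)
class RepeatSpec:
    """The direct-repeat anchor and how loosely it may match."""

    repeat_sequence: str
    max_mismatches: int = 1

    def __post_init__(self):
        object.__setattr__(self, "repeat_sequence", self.repeat_sequence.upper())
        if len(self.repeat_sequence) < 8:
            raise ValueError("repeat must be at least 8 nt")
        if self.max_mismatches < 0 or self.max_mismatches >= len(self.repeat_sequence) / 2:
            raise ValueError("max_mismatches must be in [0, repeat_length/2)")


@dataclass(frozen=True)
class ExtractionConfig:
    repeat: RepeatSpec
    min_insert_len: int = 30
    max_insert_len: int = 45
    search_reverse_complement: bool = True

    def __post_init__(self):
        if not (0 < self.min_insert_len <= self.max_insert_len):
            raise ValueError("need 0 < min_insert_len <= max_insert_len")


@dataclass
class SpacerCountTable:
    """Per-sample spacer counts plus processing totals."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    total_reads_processed: int = 0
    total_spacers_extracted: int = 0


def _greedy_nonoverlapping(offsets: np.ndarray, repeat_len: int) -> list[int]:
    """Leftmost-first selection of repeat occurrences that share no bases."""
    chosen: list[int] = []
    last_end = -1
    for o in offsets:
        if o >= last_end:
            chosen.append(int(o))
            last_end = int(o) + repeat_len
    return chosen


def _inserts_between(read: str, repeat_starts: list[int], repeat_len: int, lo: int, hi: int) -> list[str]:
    inserts = []
    for a, b in zip(repeat_starts, repeat_starts[1:]):
        ins = read[a + repeat_len : b]
        if lo <= len(ins) <= hi:
            inserts.append(ins)
    return inserts


def _scan_one_orientation(read: str, config: ExtractionConfig) -> list[str]:
    rep = config.repeat
    offsets = hamming_offsets(encode(read), encode(rep.repeat_sequence), rep.max_mismatches)
    starts = _greedy_nonoverlapping(offsets, len(rep.repeat_sequence))
    return _inserts_between(read, starts, len(rep.repeat_sequence), config.min_insert_len, config.max_insert_len)


def find_repeat_flanked_inserts(read: str, config: ExtractionConfig) -> list[str]:
    """All repeat-flanked inserts of a single read, forward orientation first."""
    read = read.upper()
    inserts = _scan_one_orientation(read, config)
    if config.search_reverse_complement:
        inserts += _scan_one_orientation(revcomp(read), config)
    return inserts


def _parse_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a (optionally gzipped) FASTQ file.

    Minimal four-line parsing with structural checks; malformed records raise
    with the 1-based record index.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            idx += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or len(qual) != len(seq):
                raise ValueError(f"malformed FASTQ record #{idx} in {path}")
            yield seq.upper()


def _extract_chunk(reads: list[str], config: ExtractionConfig, counts: Counter) -> int:
    """Vectorised repeat scan over a chunk of reads; returns inserts found."""
    rep = config.repeat
    rep_arr = encode(rep.repeat_sequence)
    rl = len(rep_arr)
    lens = np.fromiter((len(r) for r in reads), dtype=np.int64, count=len(reads))
    lmax = int(lens.max()) if len(reads) else 0
    if lmax < rl:
        return 0
    arr = np.full((len(reads), lmax), _PAD_BYTE, dtype=np.uint8)
    for i, r in enumerate(reads):
        arr[i, : len(r)] = encode(r)

    orientations = [(arr, reads, lens)]
    if config.search_reverse_complement:
        rc_reads = [revcomp(r) for r in reads]
        rc_arr = np.full_like(arr, _PAD_BYTE)
        for i, r in enumerate(rc_reads):
            rc_arr[i, : len(r)] = encode(r)
        orientations.append((rc_arr, rc_reads, lens))

    n_found = 0
    n_off = lmax - rl + 1
    for mat, texts, tlens in orientations:
        ok = np.zeros((len(texts), n_off), dtype=bool)
        for o in range(n_off):
            mm = (mat[:, o : o + rl] != rep_arr).sum(axis=1)
            ok[:, o] = mm <= rep.max_mismatches
        # a window may not extend past the true read end
        ok &= np.arange(n_off)[None, :] <= (tlens - rl)[:, None]
        rows = np.nonzero(ok.any(axis=1))[0]
        for i in rows:
            starts = _greedy_nonoverlapping(np.nonzero(ok[i])[0], rl)
            for ins in _inserts_between(texts[i], starts, rl, config.min_insert_len, config.max_insert_len):
                counts[ins] += 1
                n_found += 1
    return n_found


def _extract_chunk_exact(reads: list[str], config: ExtractionConfig, counts: Counter) -> int:
    """str.find fast path for a zero-mismatch repeat."""
    rep = config.repeat.repeat_sequence
    rl = len(rep)
    n_found = 0
    texts: Iterable[str]
    for read in reads:
        variants = (read,) if not config.search_reverse_complement else (read, revcomp(read))
        for text in variants:
            starts = []
            pos = text.find(rep)
            while pos != -1:
                starts.append(pos)
                pos = text.find(rep, pos + rl)
            for ins in _inserts_between(text, starts, rl, config.min_insert_len, config.max_insert_len):
                counts[ins] += 1
                n_found += 1
    return n_found


def extract_counts(fastq_path: str | Path, config: ExtractionConfig, sample_id: str) -> SpacerCountTable:
    """Count every repeat-flanked insert in a FASTQ file.

    Deterministic for a fixed input; an empty file yields an empty table with
    zero totals.
    """
    counts: Counter = Counter()
    n_reads = 0
    n_inserts = 0
    chunk_fn = _extract_chunk_exact if config.repeat.max_mismatches == 0 else _extract_chunk
    chunk: list[str] = []
    for seq in _parse_fastq(fastq_path):
        chunk.append(seq)
        if len(chunk) >= _CHUNK_READS:
            n_reads += len(chunk)
            n_inserts += chunk_fn(chunk, config, counts)
            chunk = []
    if chunk:
        n_reads += len(chunk)
        n_inserts += chunk_fn(chunk, config, counts)
    return SpacerCountTable(
        sample_id=sample_id,
        counts=dict(counts),
        total_reads_processed=n_reads,
        total_spacers_extracted=n_inserts,
    )


def merge_counts(tables: Iterable[SpacerCountTable]) -> SpacerCountTable:
    """Element-wise sum of count tables from the same sample (e.g. lane merging)."""
    tables = list(tables)
    if not tables:
        raise ValueError("nothing to merge")
    sample_ids = {t.sample_id for t in tables}
    if len(sample_ids) > 1:
        raise ValueError(f"refusing to merge different samples: {sorted(sample_ids)}")
    merged: Counter = Counter()
    for t in tables:
        merged.update(t.counts)
    return SpacerCountTable(
        sample_id=tables[0].sample_id,
        counts=dict(merged),
        total_reads_processed=sum(t.total_reads_processed for t in tables),
        total_spacers_extracted=sum(t.total_spacers_extracted for t in tables),
    )


def write_counts(table: SpacerCountTable, path: str | Path, config: ExtractionConfig | None = None) -> Path:
    """Write counts as TSV (spacer_sequence, count) plus a JSON totals sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("spacer_sequence\tcount\n")
        for seq in sorted(table.counts):
            fh.write(f"{seq}\t{table.counts[seq]}\n")
    sidecar = {
        "sample_id": table.sample_id,
        "total_reads_processed": table.total_reads_processed,
        "total_spacers_extracted": table.total_spacers_extracted,
    }
    if config is not None:
        sidecar["config"] = {
            "repeat_sequence": config.repeat.repeat_sequence,
            "max_mismatches": config.repeat.max_mismatches,
            "min_insert_len": config.min_insert_len,
            "max_insert_len": config.max_insert_len,
            "search_reverse_complement": config.search_reverse_complement,
        }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return path


def read_counts(path: str | Path, sample_id: str | None = None) -> SpacerCountTable:
    """Read a counts TSV written by :func:`write_counts`."""
    path = Path(path)
    counts: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["spacer_sequence", "count"]:
            raise ValueError(f"unexpected counts header in {path}: {header}")
        for line in fh:
            seq, c = line.rstrip("\n").split("\t")
            counts[seq] = int(c)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    totals_reads = 0
    total_spacers = sum(counts.values())
    sid = sample_id
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        sid = sid or sidecar.get("sample_id")
        totals_reads = sidecar.get("total_reads_processed", 0)
        total_spacers = sidecar.get("total_spacers_extracted", total_spacers)
    return SpacerCountTable(
        sample_id=sid or path.stem,
        counts=counts,
        total_reads_processed=totals_reads,
        total_spacers_extracted=total_spacers,
    )
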