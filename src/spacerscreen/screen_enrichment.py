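"""Enrichment landscapes for a tiled spacer-library infection screen.

Frequencies are raw count fractions per sample; the enrichment ratio of a
spacer is its post-infection frequency divided by its frequency in the
uninfected (t0) library. Spacers below a minimum t0 count are excluded
(no pseudocounts) rather than inflated. Landscapes place each spacer at the
start of its plus-strand interval and are split by the strand the spacer
matches; region summaries report mean ± sample SD of the ratio per region and
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._sequtils import ExactIndex, hamming_hits
from .library_design import GenomeRecord, SpacerDesign
from .spacer_extraction import SpacerCountTable

DEFAULT_MIN_T0_COUNT = 5

STATUS_OK = "ok"
STATUS_ABSENT_T0 = "absent_t0"
STATUS_ABSENT_T = "absent_t"


@dataclass
class SampleFrequencies:
    """Count fractions for one sample; frequencies sum to 1 over counted spacers."""

    sample_id: str
    freq: dict[str, float]
    counts: dict[str, int]
    depth: int


@dataclass(frozen=True)
class RegionSpec:
    """A genome region with the strand its transcript is made from."""

    name: str
    start: int
    end: int
    strand_of_transcription: str = "plus"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad region interval [{self.start}, {self.end})")

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class LocateResult:
    status: str  # "unique" | "ambiguous" | "unmapped"
    start: int | None = None
    strand: str | None = None
    n_hits: int = 0


@dataclass
class StrandProfiles:
    """Per-position enrichment tracks, one per matched strand, plus a QC tally."""

    plus: pd.DataFrame
    minus: pd.DataFrame
    qc: dict = field(default_factory=dict)


def spacer_frequencies(table: SpacerCountTable) -> SampleFrequencies:
    """Frequencies f_s = c_s / sum(c) over the spacers present in a count table."""
    depth = sum(table.counts.values())
    if depth == 0:
        raise ValueError(f"empty sample {table.sample_id!r}")
    freq = {s: c / depth for s, c in table.counts.items()}
    return SampleFrequencies(sample_id=table.sample_id, freq=freq, counts=dict(table.counts), depth=depth)


def enrichment_ratios(
    ft: SampleFrequencies,
    f0: SampleFrequencies,
    min_t0_count: int = DEFAULT_MIN_T0_COUNT,
) -> pd.DataFrame:
    """Per-spacer enrichment E = f_t / f_0 against the uninfected library.

    Spacers whose t0 count is below ``min_t0_count`` are reported with status
    ``absent_t0`` and no ratio; spacers undetected post-infection keep a ratio
    of 0 with status ``absent_t``. Returns a DataFrame with columns
    spacer, count0, count_t, f0, ft, ratio, status.
    """
    rows = []
    for spacer, c0 in f0.counts.items():
        ct = ft.counts.get(spacer, 0)
        fre0 = f0.freq[spacer]
        fret = ft.freq.get(spacer, 0.0)
        if c0 < min_t0_count:
            rows.append((spacer, c0, ct, fre0, fret, np.nan, STATUS_ABSENT_T0))
        else:
            status = STATUS_ABSENT_T if ct == 0 else STATUS_OK
            rows.append((spacer, c0, ct, fre0, fret, fret / fre0, status))
    # spacers seen only post-infection have no t0 frequency to divide by
    for spacer, ct in ft.counts.items():
        if spacer not in f0.counts:
            rows.append((spacer, 0, ct, 0.0, ft.freq[spacer], np.nan, STATUS_ABSENT_T0))
    return pd.DataFrame(rows, columns=["spacer", "count0", "count_t", "f0", "ft", "ratio", "status"])


def locate_spacer(
    sequence: str,
    genome: GenomeRecord | str,
    max_mismatches: int = 0,
    index: ExactIndex | None = None,
) -> LocateResult:
    """Find a spacer's genomic origin by two-strand Hamming search.

    A plus-strand location means the spacer equals the genome substring; a
    minus-strand location means it equals the reverse complement. Multi-hit
    queries are flagged ambiguous, zero-hit queries unmapped. ``index`` may
    supply a precomputed exact k-mer index for the mismatch-free case.
    """
    seq = (genome.sequence if isinstance(genome, GenomeRecord) else genome).upper()
    sequence = sequence.upper()
    if max_mismatches == 0 and index is not None and index.k == len(sequence):
        hits = index.lookup(sequence)
    else:
        hits = hamming_hits(seq, sequence, max_mismatches)
    if not hits:
        return LocateResult(status="unmapped")
    if len(hits) > 1:
        return LocateResult(status="ambiguous", n_hits=len(hits))
    start, strand, _ = hits[0]
    return LocateResult(status="unique", start=start, strand=strand, n_hits=1)


def position_profile(records: pd.DataFrame, designs: Sequence[SpacerDesign]) -> StrandProfiles:
    """Lay enrichment records onto the genome, split by matched strand.

    Each record is resolved to (start, strand) through the library design by
    spacer sequence. Sequences not in the design (typically sequencing-error
    keys), designs flagged ambiguous, and records without a ratio
    (status ``absent_t0``) are excluded and tallied in the QC dict.
    """
    lookup: dict[str, SpacerDesign] = {}
    for d in designs:
        lookup[d.sequence] = d
    qc = {"n_records": len(records), "unmapped": 0, "ambiguous": 0, "absent_t0": 0}
    rows = {"plus": [], "minus": []}
    for rec in records.itertuples(index=False):
        d = lookup.get(rec.spacer)
        if d is None:
            qc["unmapped"] += 1
            continue
        if d.ambiguous:
            qc["ambiguous"] += 1
            continue
        if rec.status == STATUS_ABSENT_T0:
            qc["absent_t0"] += 1
            continue
        rows[d.strand].append((d.start, d.spacer_id, rec.ratio, rec.ft, rec.count_t))
    cols = ["position", "spacer_id", "enrichment", "ft", "count_t"]
    plus = pd.DataFrame(rows["plus"], columns=cols).sort_values("position", kind="stable").reset_index(drop=True)
    minus = pd.DataFrame(rows["minus"], columns=cols).sort_values("position", kind="stable").reset_index(drop=True)
    return StrandProfiles(plus=plus, minus=minus, qc=qc)


def region_summary(profile: StrandProfiles, regions: Iterable[RegionSpec], genome_length: int | None = None) -> pd.DataFrame:
    """Mean ± SD of enrichment per region and matched strand.

    SD uses the n-1 denominator and is null for fewer than two spacers;
    ``n_detected`` counts spacers with non-zero post-infection frequency.
    """
    rows = []
    for region in regions:
        if genome_length is not None and region.end > genome_length:
            raise ValueError(f"region {region.name} extends past the genome end ({genome_length})")
        for strand, track in (("plus", profile.plus), ("minus", profile.minus)):
            sub = track[(track["position"] >= region.start) & (track["position"] < region.end)]
            vals = sub["enrichment"].to_numpy(dtype=float)
            n = len(vals)
            mean = float(np.mean(vals)) if n else np.nan
            sd = float(np.std(vals, ddof=1)) if n >= 2 else np.nan
            rows.append(
                {
                    "region": region.name,
                    "region_start": region.start,
                    "region_end": region.end,
                    "strand_matched": strand,
                    "n_spacers": n,
                    "mean_enrichment": mean,
                    "sd_enrichment": sd,
                    "n_detected": int((sub["ft"] > 0).sum()),
                }
            )
    return pd.DataFrame(rows)


def unique_detection_by_region(
    table: SpacerCountTable,
    designs: Sequence[SpacerDesign],
    regions: Iterable[RegionSpec],
) -> pd.DataFrame:
    """Distinct designed spacers with count > 0, per region and matched strand."""
    detected = {seq for seq, c in table.counts.items() if c > 0}
    rows = []
    for region in regions:
        for strand in ("plus", "minus"):
            in_region = [d for d in designs if d.strand == strand and region.contains(d.start)]
            n_det = sum(1 for d in in_region if d.sequence in detected)
            rows.append(
                {
                    "region": region.name,
                    "strand_matched": strand,
                    "n_designed": len(in_region),
                    "n_detected": n_det,
                }
            )
    return pd.DataFrame(rows)


def read_regions_bed(path: str | Path) -> list[RegionSpec]:
    """Regions from a BED file (chrom, start, end, name, score, strand)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            name = fields[3] if len(fields) > 3 else f"region_{len(regions)}"
            strand = "minus" if len(fields) > 5 and fields[5] == "-" else "plus"
            regions.append(RegionSpec(name=name, start=int(fields[1]), end=int(fields[2]), strand_of_transcription=strand))
    _check_disjoint(regions)
    return regions


def read_regions_yaml(path: str | Path) -> list[RegionSpec]:
    """Regions from YAML: a list of {name, start, end, strand_of_transcription}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    regions = [
        RegionSpec(
            name=r["name"],
            start=int(r["start"]),
            end=int(r["end"]),
            strand_of_transcription=r.get("strand_of_transcription", "plus"),
        )
        for r in raw
    ]
    _check_disjoint(regions)
    return regions


def _check_disjoint(regions: Sequence[RegionSpec]) -> None:
    ordered = sorted(regions, key=lambda r: r.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"regions {a.name} and {b.name} overlap")
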