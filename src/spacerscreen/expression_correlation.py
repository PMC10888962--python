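"""Timepoint normalization of transcript coverage and expression–enrichment correlation.

RNA-seq coverage tracks from different timepoints are made comparable by
scaling each to the smallest library among them (down-scaling never
extrapolates). A minus-strand spacer's target expression is the mean
normalized coverage over its genomic interval on the transcribed strand;
plus-strand spacers have no transcript target. Correlation is the plain
product-moment (Pearson) coefficient computed from its definition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .library_design import SpacerDesign


@dataclass(frozen=True)
class ExpressionTrack:
    """Per-position coverage on the transcribed strand at one timepoint.

    ``library_size`` is the sequencing depth of the track; defaults to the
    track's total coverage mass when not given explicitly.
    """

    timepoint_min: float
    coverage: np.ndarray
    library_size: float
    normalized: bool = False

    @classmethod
    def from_coverage(cls, timepoint_min: float, coverage: np.ndarray, library_size: float | None = None) -> "ExpressionTrack":
        coverage = np.asarray(coverage, dtype=float)
        if (coverage < 0).any():
            raise ValueError("coverage must be non-negative")
        size = float(coverage.sum()) if library_size is None else float(library_size)
        return cls(timepoint_min=timepoint_min, coverage=coverage, library_size=size)


def normalize_timepoints(tracks: Sequence[ExpressionTrack]) -> list[ExpressionTrack]:
    """Scale every track by (smallest library size) / (its library size)."""
    if not tracks:
        raise ValueError("no tracks to normalize")
    for t in tracks:
        if t.library_size <= 0:
            raise ValueError(f"track at t={t.timepoint_min} min has non-positive library size")
    reference = min(t.library_size for t in tracks)
    return [
        replace(t, coverage=t.coverage * (reference / t.library_size), normalized=True)
        for t in tracks
    ]


def target_expression(spacer: SpacerDesign, track: ExpressionTrack) -> float | None:
    """Mean coverage over the spacer's target interval; None for plus-strand spacers.

    Only minus-strand spacers yield crRNAs complementary to the plus-strand
    transcript, so plus-strand spacers are flagged as having no target.
    """
    if spacer.strand != "minus":
        return None
    if spacer.end > len(track.coverage):
        raise ValueError(f"spacer {spacer.spacer_id} extends past the coverage track")
    return float(track.coverage[spacer.start : spacer.end].mean())


def pearson_r(x: Iterable[float], y: Iterable[float]) -> float:
    """Product-moment correlation from the sum formulas.

    Requires at least three pairs and non-zero variance in both vectors.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.dot(dx, dx))
    syy = float(np.dot(dy, dy))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("degenerate input: zero variance")
    return float(np.dot(dx, dy) / np.sqrt(sxx * syy))


def correlate_enrichment_expression(
    records: pd.DataFrame,
    designs: Sequence[SpacerDesign],
    track: ExpressionTrack,
    log_transform: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Pair each minus-strand spacer's enrichment with its target expression.

    ``records`` is an enrichment table (columns spacer, ratio, status); only
    records with a ratio and a minus-strand design are used. With
    ``log_transform`` both axes are log10(1 + value). Returns the paired table
    and the Pearson r.
    """
    lookup = {d.sequence: d for d in designs}
    rows = []
    for rec in records.itertuples(index=False):
        d = lookup.get(rec.spacer)
        if d is None or d.strand != "minus" or not np.isfinite(rec.ratio):
            continue
        expr = target_expression(d, track)
        rows.append((d.spacer_id, d.start, float(rec.ratio), expr))
    paired = pd.DataFrame(rows, columns=["spacer_id", "position", "enrichment", "expression"])
    x = paired["enrichment"].to_numpy()
    y = paired["expression"].to_numpy()
    if log_transform:
        x = np.log10(1 + x)
        y = np.log10(1 + y)
    return paired, pearson_r(x, y)


def read_coverage_tsv(path: str | Path, length: int, timepoint_min: float, library_size: float | None = None) -> ExpressionTrack:
    """Coverage track from a two-column TSV (position, coverage)."""
    df = pd.read_csv(path, sep="\t", names=["position", "coverage"], comment="#")
    coverage = np.zeros(length, dtype=float)
    coverage[df["position"].to_numpy(dtype=int)] = df["coverage"].to_numpy(dtype=float)
    return ExpressionTrack.from_coverage(timepoint_min, coverage, library_size)


def write_coverage_tsv(track: ExpressionTrack, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for pos, v in enumerate(track.coverage):
            fh.write(f"{pos}\t{v!r}\n")
    return path
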