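"""Design of dense tiled CRISPR spacer libraries over a phage genome.

A tiled library places one spacer every ``stride`` nucleotides on each strand
of the target genome. A plus-strand spacer is the genome substring itself; a
minus-strand spacer is the reverse complement, i.e. the crRNA it encodes is
complementary to the transcript made from the plus strand. Each spacer is
wrapped into a fixed-length cloning oligo (universal priming sites, type II-S
restriction sites and repeat homology on either side of the spacer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._sequtils import revcomp

_VALID_CHARS = set("ACGTN")
_STRICT_CHARS = set("ACGT")

MANIFEST_COLUMNS = ("spacer_id", "start", "end", "strand", "sequence", "oligo")


@dataclass(frozen=True)
class GenomeRecord:
    """A genome sequence with its identifier.

    The sequence is uppercased on construction and must contain only
    A/C/G/T/N.
    """

    id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValueError(f"genome {self.id!r} contains invalid characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate_strict(self) -> None:
        """Raise if the genome contains any base outside A/C/G/T."""
        bad_positions = [i for i, c in enumerate(self.sequence) if c not in _STRICT_CHARS]
        if bad_positions:
            shown = bad_positions[:20]
            raise ValueError(
                f"genome {self.id!r} has {len(bad_positions)} non-ACGT positions "
                f"(first ones: {shown})"
            )


@dataclass(frozen=True)
class SpacerDesign:
    """One designed spacer.

    Coordinates are 0-based half-open on the plus strand for both strands;
    ``sequence`` is the genome substring (plus) or its reverse complement
    (minus). ``ambiguous`` flags spacers overlapping an N in the genome.
    """

    spacer_id: str
    start: int
    end: int
    strand: str  # "plus" | "minus"
    sequence: str
    oligo: str = ""
    ambiguous: bool = False

    def __post_init__(self):
        if self.strand not in ("plus", "minus"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.end - self.start != len(self.sequence):
            raise ValueError("interval length does not match sequence length")


@dataclass(frozen=True)
class OligoLayout:
    """Constant flanks placed around every spacer in a cloning oligo."""

    upstream_flank: str
    downstream_flank: str
    total_length: int

    def flank_length(self) -> int:
        return len(self.upstream_flank) + len(self.downstream_flank)


# Placeholder flanks: 20-nt universal forward primer site + BsaI site (GGTCTC)
# with spacer on one side, and the mirrored arrangement downstream. With the
# default 35-nt spacer these give the conventional 90-nt pool oligo.
DEFAULT_UPSTREAM_FLANK = "GTTCACTGCCGTATAGGCAG" + "GGTCTCA" + "CAC"  # 30 nt
DEFAULT_DOWNSTREAM_FLANK = "GTG" + "TGAGACC" + "CGACTCGGTGCCACT"  # 25 nt
DEFAULT_OLIGO_LENGTH = 90

DEFAULT_LAYOUT = OligoLayout(DEFAULT_UPSTREAM_FLANK, DEFAULT_DOWNSTREAM_FLANK, DEFAULT_OLIGO_LENGTH)

DEFAULT_SPACER_LENGTH = 35
DEFAULT_STRIDE = 2


def read_genome(path: str | Path) -> GenomeRecord:
    """Read the first record of a FASTA file as a GenomeRecord."""
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            return GenomeRecord(id=rec.id, sequence=str(rec.seq))
    raise ValueError(f"no FASTA records in {path}")


def expected_tile_count(L: int, k: int, stride: int) -> int:
    """Number of spacers a full two-strand tiling produces: 2*(floor((L-k)/stride)+1)."""
    if k > L:
        raise ValueError("spacer longer than genome")
    return 2 * (math.floor((L - k) / stride) + 1)


def design_tiled_spacers(
    genome: GenomeRecord,
    k: int = DEFAULT_SPACER_LENGTH,
    stride: int = DEFAULT_STRIDE,
    strict: bool = False,
) -> list[SpacerDesign]:
    """Tile both strands of ``genome`` with spacers of length ``k`` every ``stride`` nt.

    Plus-strand spacers come first in ascending start order, then minus-strand
    spacers in ascending start order. Spacers overlapping an N are flagged
    ``ambiguous`` (or rejected up front under ``strict``).
    """
    if k < 1 or stride < 1:
        raise ValueError("k and stride must be >= 1")
    if k > genome.length:
        raise ValueError("spacer longer than genome")
    if strict:
        genome.validate_strict()
    seq = genome.sequence
    designs: list[SpacerDesign] = []
    for strand, tag in (("plus", "p"), ("minus", "m")):
        for start in range(0, genome.length - k + 1, stride):
            sub = seq[start : start + k]
            spacer_seq = sub if strand == "plus" else revcomp(sub)
            designs.append(
                SpacerDesign(
                    spacer_id=f"spc_{tag}_{start:06d}",
                    start=start,
                    end=start + k,
                    strand=strand,
                    sequence=spacer_seq,
                    ambiguous="N" in sub,
                )
            )
    return designs


def build_oligo(spacer: SpacerDesign, layout: OligoLayout = DEFAULT_LAYOUT) -> str:
    """Flank a spacer with the layout's constant arms, checking the total length."""
    oligo = layout.upstream_flank + spacer.sequence + layout.downstream_flank
    if len(oligo) != layout.total_length:
        raise ValueError(
            f"oligo length mismatch for {spacer.spacer_id}: "
            f"expected {layout.total_length}, got {len(oligo)}"
        )
    return oligo


def attach_oligos(spacers: Iterable[SpacerDesign], layout: OligoLayout = DEFAULT_LAYOUT) -> list[SpacerDesign]:
    """Return copies of the designs with their oligo field filled in."""
    out = []
    for s in spacers:
        out.append(
            SpacerDesign(
                spacer_id=s.spacer_id,
                start=s.start,
                end=s.end,
                strand=s.strand,
                sequence=s.sequence,
                oligo=build_oligo(s, layout),
                ambiguous=s.ambiguous,
            )
        )
    return out


def expected_uniform_frequency(n: int) -> float:
    """Frequency each member of an n-spacer library should have if perfectly uniform."""
    if n <= 0:
        raise ValueError("library size must be positive")
    return 1.0 / n


def write_library(spacers: Sequence[SpacerDesign], prefix: str | Path) -> tuple[Path, Path]:
    """Write a library as ``<prefix>.manifest.tsv`` + ``<prefix>.spacers.fasta``.

    The manifest holds one row per spacer with columns
    spacer_id, start, end, strand, sequence, oligo. Returns both paths.
    """
    spacers = list(spacers)
    if not spacers:
        raise ValueError("refusing to write an empty library")
    prefix = Path(prefix)
    manifest_path = prefix.with_suffix(".manifest.tsv")
    fasta_path = prefix.with_suffix(".spacers.fasta")
    try:
        with open(manifest_path, "w") as fh:
            fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
            for s in spacers:
                fh.write(f"{s.spacer_id}\t{s.start}\t{s.end}\t{s.strand}\t{s.sequence}\t{s.oligo}\n")
        records = [SeqRecord(Seq(s.sequence), id=s.spacer_id, description="") for s in spacers]
        SeqIO.write(records, str(fasta_path), "fasta")
    except OSError as exc:
        raise OSError(f"failed writing library to {prefix}: {exc}") from exc
    return manifest_path, fasta_path


def read_library(manifest_path: str | Path) -> list[SpacerDesign]:
    """Read a manifest TSV written by :func:`write_library`."""
    designs = []
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MANIFEST_COLUMNS:
            raise ValueError(f"unexpected manifest header in {manifest_path}: {header}")
        for line in fh:
            sid, start, end, strand, sequence, oligo = line.rstrip("\n").split("\t")
            sub = sequence if strand == "plus" else revcomp(sequence)
            designs.append(
                SpacerDesign(
                    spacer_id=sid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    sequence=sequence,
                    oligo=oligo,
                    ambiguous="N" in sub,
                )
            )
    return designs
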