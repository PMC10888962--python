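"""Synthetic inputs with the statistical structure the screen analysis assumes.

The generator emulates a ~42 kb lytic phage whose genome is transcribed from
the plus strand as two operons: an early operon (PE, ~1–15 kb) active within
minutes of infection and a late operon (PL, ~15–42 kb) switching on later.
From it the module fabricates every pipeline input: repeat–spacer–repeat
amplicon FASTQ reads of a tiled spacer library before and after selection,
strand-aware RNA-seq coverage tracks, naively acquired spacers biased toward
the minus strand of the early operon, and bimodal single-cell well regrowth
curves. Every generator is seeded, returns its ground truth alongside the
files it writes, and derives per-component substreams from one top-level
seed.

Selection acts on spacer classes defined by matched strand and region:
plus-strand spacers (no transcript target), and minus-strand spacers split
into PE-upstream, PE-downstream and PL. Fitness and dropout magnitudes are
simulator conventions chosen to reproduce qualitative orderings only — they
are not measurements.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._sequtils import encode, revcomp
from .expression_correlation import ExpressionTrack
from .library_design import GenomeRecord, SpacerDesign
from .phenotype_stats import WellRecord
from .screen_enrichment import RegionSpec

# A 36-nt type III-A-style direct repeat used as the simulator's default
# amplicon anchor (the extraction modules always take the repeat as input).
DEFAULT_REPEAT = "GATATAAACCTAATTACCTCGAGAGGGGACGGAAAC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

CLASS_PLUS = "plus_strand"
CLASS_PE_UP = "minus_PE_up"
CLASS_PE_DOWN = "minus_PE_down"
CLASS_PL = "minus_PL"
SPACER_CLASSES = (CLASS_PLUS, CLASS_PE_UP, CLASS_PE_DOWN, CLASS_PL)

_UNIQUE_KMER = 20  # no k-mer of this length repeats (either strand) in a sim genome


def component_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic substream for a named component of the simulation."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])


@dataclass(frozen=True)
class SimGenomeConfig:
    """Layout of the simulated phage genome and its two operons."""

    length: int = 42_000
    pe_start: int = 1_000
    pe_end: int = 15_000
    pl_start: int = 15_000
    pl_end: int = 42_000
    pe_split: int | None = None  # boundary between PE-upstream and PE-downstream
    transcribed_strand: str = "plus"
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.pe_start < self.pe_end <= self.pl_start < self.pl_end <= self.length):
            raise ValueError("operon intervals must be disjoint, ordered, and inside the genome")

    @property
    def split(self) -> int:
        return self.pe_split if self.pe_split is not None else (self.pe_start + self.pe_end) // 2

    def regions(self) -> list[RegionSpec]:
        s = self.transcribed_strand
        return [
            RegionSpec("PE_upstream", self.pe_start, self.split, s),
            RegionSpec("PE_downstream", self.split, self.pe_end, s),
            RegionSpec("PL", self.pl_start, self.pl_end, s),
        ]

    def pe_region(self) -> RegionSpec:
        return RegionSpec("PE", self.pe_start, self.pe_end, self.transcribed_strand)

    def pl_region(self) -> RegionSpec:
        return RegionSpec("PL", self.pl_start, self.pl_end, self.transcribed_strand)


@dataclass(frozen=True)
class SelectionModel:
    """Class-wise post-infection relative fitness and lineage-dropout probabilities."""

    genotype: str
    fitness: dict[str, float]
    dropout: dict[str, float]

    def __post_init__(self):
        for cls in SPACER_CLASSES:
            if cls not in self.fitness or cls not in self.dropout:
                raise ValueError(f"model missing class {cls}")
            if self.fitness[cls] < 0 or not (0 <= self.dropout[cls] <= 1):
                raise ValueError("fitness must be >= 0 and dropout in [0, 1]")


def selection_model(genotype: str) -> SelectionModel:
    """Preset models reproducing the qualitative genotype orderings.

    wt: early-operon targeting wins strongly; dcsm6: PE-downstream and PL
    spacers lose protection (heavy dropout); cas10HD: late-operon targeting
    mildly outgrows early-operon targeting.
    """
    presets = {
        "wt": (
            {CLASS_PLUS: 0.3, CLASS_PE_UP: 10.0, CLASS_PE_DOWN: 8.0, CLASS_PL: 0.3},
            {CLASS_PLUS: 0.0, CLASS_PE_UP: 0.0, CLASS_PE_DOWN: 0.0, CLASS_PL: 0.0},
        ),
        "dcsm6": (
            {CLASS_PLUS: 0.3, CLASS_PE_UP: 10.0, CLASS_PE_DOWN: 0.1, CLASS_PL: 0.05},
            {CLASS_PLUS: 0.8, CLASS_PE_UP: 0.0, CLASS_PE_DOWN: 0.5, CLASS_PL: 0.9},
        ),
        "cas10hd": (
            {CLASS_PLUS: 0.3, CLASS_PE_UP: 0.8, CLASS_PE_DOWN: 0.8, CLASS_PL: 2.0},
            {CLASS_PLUS: 0.0, CLASS_PE_UP: 0.0, CLASS_PE_DOWN: 0.0, CLASS_PL: 0.0},
        ),
    }
    key = genotype.lower().replace("-", "").replace("_", "")
    if key not in presets:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {sorted(presets)}")
    fitness, dropout = presets[key]
    return SelectionModel(genotype=key, fitness=fitness, dropout=dropout)


@dataclass(frozen=True)
class SimConfig:
    """Sequencing-simulation knobs shared by the FASTQ generators."""

    n_reads: int = 1_000_000
    error_rate: float = 0.001
    read_length: int = 150
    repeat_sequence: str = DEFAULT_REPEAT
    host_decoy_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for p in (self.error_rate, self.host_decoy_fraction):
            if not (0 <= p < 1):
                raise ValueError("probabilities must be in [0, 1)")


def make_genome(config: SimGenomeConfig) -> tuple[GenomeRecord, list[RegionSpec]]:
    """Seeded random genome with no repeated 20-mer on either strand.

    Duplicate-free short k-mers guarantee every tiled spacer (k >= 20) maps to
    a single position on a single strand, so ground-truth localisation is
    exact. Collisions are resolved by rejection-resampling the offending
    windows.
    """
    rng = component_rng(config.seed, "genome")
    arr = _BASES[rng.integers(0, 4, config.length)]
    for _ in range(100):
        seq = arr.tobytes().decode()
        positions: dict[str, list[int]] = {}
        for i in range(config.length - _UNIQUE_KMER + 1):
            km = seq[i : i + _UNIQUE_KMER]
            canon = min(km, revcomp(km))
            positions.setdefault(canon, []).append(i)
        dup_windows = [pos[1:] for pos in positions.values() if len(pos) > 1]
        if not dup_windows:
            break
        for extras in dup_windows:
            for p in extras:
                arr[p : p + _UNIQUE_KMER] = _BASES[rng.integers(0, 4, _UNIQUE_KMER)]
    else:
        raise RuntimeError("could not build a duplicate-free genome")
    genome = GenomeRecord(id=f"simphage_L{config.length}", sequence=arr.tobytes().decode())
    return genome, config.regions()


def write_genome_fasta(genome: GenomeRecord, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i : i + 70] + "\n")
    return path


def classify_spacer(design: SpacerDesign, config: SimGenomeConfig) -> str:
    """Selection class of a designed spacer by matched strand and start position.

    Minus-strand spacers outside both operons have no transcript target and
    behave as non-targeting guides, so they share the plus-strand class.
    """
    if design.strand != "minus":
        return CLASS_PLUS
    if config.pe_start <= design.start < config.split:
        return CLASS_PE_UP
    if config.split <= design.start < config.pe_end:
        return CLASS_PE_DOWN
    if config.pl_start <= design.start < config.pl_end:
        return CLASS_PL
    return CLASS_PLUS


@dataclass
class SelectionTruth:
    """Ground truth returned with a simulated selection FASTQ."""

    counts: dict[str, int]  # spacer sequence -> planted read count
    classes: dict[str, str]  # spacer_id -> selection class
    survived: dict[str, bool]  # spacer_id -> lineage survived dropout


def _write_fastq_reads(
    fh,
    designs: Sequence[SpacerDesign],
    idx: np.ndarray,
    sim: SimConfig,
    rng: np.random.Generator,
    start_read: int,
) -> None:
    rep = encode(sim.repeat_sequence)
    rl = len(rep)
    k = len(designs[0].sequence)
    core = 2 * rl + k
    if core > sim.read_length:
        raise ValueError(f"read length {sim.read_length} too short for repeat+spacer+repeat ({core})")
    filler = sim.read_length - core
    spacer_mat = np.vstack([encode(d.sequence) for d in designs])
    qual = "I" * sim.read_length
    chunk_size = 100_000
    read_no = start_read
    for lo in range(0, len(idx), chunk_size):
        chunk = idx[lo : lo + chunk_size]
        m = len(chunk)
        arr = np.empty((m, sim.read_length), dtype=np.uint8)
        arr[:, :rl] = rep
        arr[:, rl : rl + k] = spacer_mat[chunk]
        arr[:, rl + k : core] = rep
        if filler:
            arr[:, core:] = _BASES[rng.integers(0, 4, (m, filler))]
        if sim.error_rate > 0:
            mask = rng.random((m, sim.read_length)) < sim.error_rate
            n_err = int(mask.sum())
            if n_err:
                shifted = (_BASE_INDEX[arr[mask]] + rng.integers(1, 4, n_err)) % 4
                arr[mask] = _BASES[shifted]
        blob = arr.tobytes()
        parts = []
        for i in range(m):
            seq = blob[i * sim.read_length : (i + 1) * sim.read_length].decode()
            parts.append(f"@read_{read_no}\n{seq}\n+\n{qual}\n")
            read_no += 1
        fh.write("".join(parts))


def simulate_library_fastq(
    designs: Sequence[SpacerDesign],
    sim: SimConfig,
    out_fastq: str | Path,
    weights: np.ndarray | None = None,
    stream: str = "library",
) -> dict[str, int]:
    """Amplicon FASTQ of a spacer library; reads drawn multinomially.

    Each read is repeat+spacer+repeat plus random filler up to the read
    length, with i.i.d. substitution errors at the configured rate. Returns
    the planted (pre-error) count per spacer sequence.
    """
    designs = list(designs)
    if not designs:
        raise ValueError("no designs to sequence")
    k_set = {len(d.sequence) for d in designs}
    if len(k_set) != 1:
        raise ValueError("all spacers must share one length")
    rng = component_rng(sim.seed, stream)
    if weights is None:
        probs = np.full(len(designs), 1.0 / len(designs))
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.sum() <= 0:
            raise ValueError("weights sum to zero: nothing to sequence")
        probs = weights / weights.sum()
    counts = rng.multinomial(sim.n_reads, probs)
    idx = np.repeat(np.arange(len(designs)), counts)
    rng.shuffle(idx)
    with open(out_fastq, "w") as fh:
        _write_fastq_reads(fh, designs, idx, sim, rng, start_read=0)
    return {d.sequence: int(c) for d, c in zip(designs, counts) if c > 0}


def simulate_selection_fastq(
    designs: Sequence[SpacerDesign],
    model: SelectionModel,
    sim: SimConfig,
    genome_config: SimGenomeConfig,
    out_fastq: str | Path,
    f0: np.ndarray | None = None,
) -> SelectionTruth:
    """Post-infection FASTQ under class-dependent selection.

    Each spacer lineage survives with probability 1 - dropout(class); a
    surviving lineage's sampling weight is its pre-infection frequency times
    the class fitness. ``f0`` defaults to uniform.
    """
    designs = list(designs)
    classes = {d.spacer_id: classify_spacer(d, genome_config) for d in designs}
    rng = component_rng(sim.seed, f"selection:{model.genotype}")
    n = len(designs)
    f0_arr = np.full(n, 1.0 / n) if f0 is None else np.asarray(f0, dtype=float)
    drop = np.array([model.dropout[classes[d.spacer_id]] for d in designs])
    fit = np.array([model.fitness[classes[d.spacer_id]] for d in designs])
    survived = rng.random(n) >= drop
    weights = f0_arr * fit * survived
    counts = simulate_library_fastq(
        designs, sim, out_fastq, weights=weights, stream=f"selection-reads:{model.genotype}"
    )
    return SelectionTruth(
        counts=counts,
        classes=classes,
        survived={d.spacer_id: bool(s) for d, s in zip(designs, survived)},
    )


# RNA-seq shape conventions: the early operon is expressed from the first
# sampled minute with a linear 5'->3' within-operon decay (so downstream PE
# targets see less transcript); the late operon switches on between the 5 and
# 15 minute samples with a flat profile. Per-timepoint depth factors introduce
# the library-size variability the normalization step must undo.
_PE_AMPLITUDE = 200.0
_PE_DECAY_TO = 0.2
_PL_AMPLITUDE = 150.0
_PL_ONSET_MIN = 15.0
_DEPTH_FACTORS = (1.0, 1.4, 1.8)


def simulate_rnaseq_coverage(
    config: SimGenomeConfig,
    timepoints: Sequence[float] = (5.0, 15.0, 30.0),
    seed: int | None = None,
) -> list[ExpressionTrack]:
    """Poisson coverage tracks on the transcribed strand, one per timepoint."""
    seed = config.seed if seed is None else seed
    tracks = []
    for j, t in enumerate(timepoints):
        rng = component_rng(seed, f"rnaseq:{t}")
        lam = np.zeros(config.length)
        if t >= 5.0:
            pe_len = config.pe_end - config.pe_start
            lam[config.pe_start : config.pe_end] = _PE_AMPLITUDE * np.linspace(
                1.0, _PE_DECAY_TO, pe_len
            )
        if t >= _PL_ONSET_MIN:
            lam[config.pl_start : config.pl_end] = _PL_AMPLITUDE
        depth = _DEPTH_FACTORS[j % len(_DEPTH_FACTORS)]
        coverage = rng.poisson(lam * depth).astype(float)
        tracks.append(ExpressionTrack.from_coverage(t, coverage))
    return tracks


_ACQ_WEIGHTS = {
    "wt": {("minus", "PE"): 0.90, ("minus", "PL"): 0.05, ("plus", "ALL"): 0.05},
    "dcsm6": {("minus", "PE_up"): 0.90, ("minus", "PL"): 0.05, ("plus", "ALL"): 0.05},
    "cas10hd": {("minus", "ALL"): 0.5, ("plus", "ALL"): 0.5},
}
_CAS10HD_YIELD = 0.01  # acquisition yield relative to wt


def simulate_acquisition_reads(
    genome: GenomeRecord,
    genotype: str,
    n_spacers: int,
    config: SimGenomeConfig,
    k: int = 35,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Naively acquired spacers as exact genome substrings/revcomps.

    wt acquisition is dominated by the minus strand of the early operon;
    dcsm6 concentrates further into PE-upstream; cas10HD yields only a
    uniform strand-balanced background at ~1% of the wt count. Returns
    (records, truth) where records are (query_id, sequence) pairs.
    """
    key = genotype.lower().replace("-", "").replace("_", "")
    if key not in _ACQ_WEIGHTS:
        raise ValueError(f"unknown genotype {genotype!r}")
    seed = config.seed if seed is None else seed
    rng = component_rng(seed, f"acquisition:{key}")
    if key == "cas10hd":
        n_spacers = int(round(n_spacers * _CAS10HD_YIELD))
    if n_spacers == 0:
        return [], pd.DataFrame(columns=["query_id", "position", "strand", "category"])
    intervals = {
        "PE": (config.pe_start, config.pe_end),
        "PE_up": (config.pe_start, config.split),
        "PL": (config.pl_start, config.pl_end),
        "ALL": (0, config.length),
    }
    cats = list(_ACQ_WEIGHTS[key].items())
    probs = np.array([w for _, w in cats])
    choice = rng.choice(len(cats), size=n_spacers, p=probs / probs.sum())
    records, rows = [], []
    for i, c in enumerate(choice):
        (strand, region), _ = cats[c]
        lo, hi = intervals[region]
        start = int(rng.integers(lo, hi - k + 1))
        sub = genome.sequence[start : start + k]
        seq = sub if strand == "plus" else revcomp(sub)
        qid = f"acq_{i:06d}"
        records.append((qid, seq))
        rows.append({"query_id": qid, "position": start, "strand": strand, "category": f"{strand}:{region}"})
    return records, pd.DataFrame(rows)


def write_spacer_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for qid, seq in records:
            fh.write(f">{qid}\n{seq}\n")
    return path


@dataclass(frozen=True)
class WellSimConfig:
    """Single-cell regrowth simulation: bimodal outcome with logistic regrowth."""

    p_regrow: float = 0.44
    n_replicates: int = 5
    wells_per_replicate: int = 96
    lag_range_h: tuple[float, float] = (10.0, 15.0)
    od_baseline: float = 0.05
    od_plateau: float = 1.2
    growth_rate: float = 1.5  # 1/h logistic steepness
    t_half_after_lag_h: float = 2.0
    od_noise_sd: float = 0.003
    gfp_mean: float = 1000.0
    gfp_sd: float = 200.0
    gfp_nonregrow_shift: float = 300.0  # non-proliferating cells carry more phage GFP
    t_max_h: float = 24.0
    dt_h: float = 0.5
    seed: int = 0


def simulate_wells(config: WellSimConfig = WellSimConfig()) -> tuple[list[WellRecord], pd.DataFrame]:
    """Simulated 96-well sorts: (wells, truth) with per-well regrowth labels."""
    rng = component_rng(config.seed, "wells")
    times = np.arange(0.0, config.t_max_h + config.dt_h / 2, config.dt_h)
    wells, rows = [], []
    for rep in range(1, config.n_replicates + 1):
        for w in range(config.wells_per_replicate):
            regrow = bool(rng.random() < config.p_regrow)
            if regrow:
                lag = rng.uniform(*config.lag_range_h)
                od = config.od_baseline + config.od_plateau / (
                    1 + np.exp(-config.growth_rate * (times - lag - config.t_half_after_lag_h))
                )
                gfp = rng.normal(config.gfp_mean, config.gfp_sd)
            else:
                od = np.full_like(times, config.od_baseline)
                gfp = rng.normal(config.gfp_mean + config.gfp_nonregrow_shift, config.gfp_sd)
            od = np.clip(od + rng.normal(0, config.od_noise_sd, len(times)), 0, None)
            wid = f"r{rep}_w{w:02d}"
            wells.append(WellRecord(well_id=wid, times_h=times, od=od, initial_gfp=float(gfp), replicate=rep))
            rows.append({"well_id": wid, "replicate": rep, "regrew_true": regrow, "initial_gfp": float(gfp)})
    return wells, pd.DataFrame(rows)
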