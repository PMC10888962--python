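"""Phenotype readouts: single-cell well regrowth, group comparisons, escaper fractions.

Sorted single infected cells are grown in microplate wells; a well "regrew"
when its OD600 series crosses a threshold within the observation horizon.
Regrowth fractions are reported per replicate (with binomial SD) and pooled.
Group differences in initial fluorescence use Welch's unequal-variance
t-test computed from the formulas (two-sided p from the t distribution with
Welch–Satterthwaite degrees of freedom). The escaper fraction of a phage
population is the ratio of plaque counts on a targeting versus a naive host.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_OD_THRESHOLD = 0.5


@dataclass
class WellRecord:
    """One sorted well: an OD600 time series plus initial fluorescence."""

    well_id: str
    times_h: np.ndarray
    od: np.ndarray
    initial_gfp: float = float("nan")
    replicate: int = 0

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.times_h) != len(self.od):
            raise ValueError(f"well {self.well_id}: time/OD length mismatch")
        if len(self.times_h) and (np.diff(self.times_h) <= 0).any():
            raise ValueError(f"well {self.well_id}: times must be strictly increasing")
        if (self.od < 0).any():
            raise ValueError(f"well {self.well_id}: negative OD")


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    df: float
    degenerate: bool = False


@dataclass
class RegrowthSummary:
    per_replicate: pd.DataFrame  # replicate, n_wells, n_regrew, fraction, binom_sd
    mean_fraction: float
    sd_fraction: float
    pooled_fraction: float
    n_excluded: int


def time_to_threshold(well: WellRecord, od_threshold: float = DEFAULT_OD_THRESHOLD) -> float | None:
    """First time the OD series reaches the threshold, linearly interpolated.

    Returns 0 when the series starts at/above the threshold, None when it
    never crosses.
    """
    od = well.od
    t = well.times_h
    if len(od) == 0:
        return None
    if od[0] >= od_threshold:
        return 0.0
    above = np.nonzero(od >= od_threshold)[0]
    if len(above) == 0:
        return None
    i = int(above[0])
    t0, t1 = t[i - 1], t[i]
    y0, y1 = od[i - 1], od[i]
    return float(t0 + (od_threshold - y0) * (t1 - t0) / (y1 - y0))


def regrowth_fraction(
    wells: Iterable[WellRecord],
    od_threshold: float = DEFAULT_OD_THRESHOLD,
    horizon_h: float | None = None,
) -> RegrowthSummary:
    """Fraction of wells whose OD crosses the threshold within the horizon.

    The horizon defaults to the last timepoint common to all wells. Wells with
    empty series are excluded and tallied. Reports per-replicate fractions
    with their binomial SD, their mean ± SD across replicates, and the pooled
    fraction over all wells.
    """
    wells = [w for w in wells]
    usable = [w for w in wells if len(w.times_h) > 0]
    n_excluded = len(wells) - len(usable)
    if not usable:
        raise ValueError("no usable wells")
    if horizon_h is None:
        horizon_h = min(w.times_h[-1] for w in usable)
    rows: dict[int, list[bool]] = {}
    for w in usable:
        t = time_to_threshold(w, od_threshold)
        regrew = t is not None and t <= horizon_h
        rows.setdefault(w.replicate, []).append(regrew)
    per_rep = []
    for rep in sorted(rows):
        calls = rows[rep]
        n = len(calls)
        k = sum(calls)
        p = k / n
        per_rep.append(
            {
                "replicate": rep,
                "n_wells": n,
                "n_regrew": k,
                "fraction": p,
                "binom_sd": math.sqrt(p * (1 - p) / n),
            }
        )
    per_rep_df = pd.DataFrame(per_rep)
    fracs = per_rep_df["fraction"].to_numpy()
    pooled = per_rep_df["n_regrew"].sum() / per_rep_df["n_wells"].sum()
    return RegrowthSummary(
        per_replicate=per_rep_df,
        mean_fraction=float(fracs.mean()),
        sd_fraction=float(fracs.std(ddof=1)) if len(fracs) >= 2 else float("nan"),
        pooled_fraction=float(pooled),
        n_excluded=n_excluded,
    )


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> GroupComparison:
    """Welch's unequal-variance two-sample t-test, two-sided.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch–Satterthwaite degrees of freedom. Zero variance in both groups with
    equal means yields t = 0, p = 1; zero variance with unequal means is
    flagged degenerate with p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa2n, sb2n = va / na, vb / nb
    se2 = sa2n + sb2n
    if se2 == 0.0:
        equal = math.isclose(ma, mb, rel_tol=0, abs_tol=0)
        return GroupComparison(
            mean_a=float(ma), sd_a=0.0, n_a=na,
            mean_b=float(mb), sd_b=0.0, n_b=nb,
            t_statistic=0.0 if equal else math.copysign(math.inf, ma - mb),
            p_value=1.0 if equal else 0.0,
            df=float(na + nb - 2),
            degenerate=not equal,
        )
    t_stat = (ma - mb) / math.sqrt(se2)
    df = se2**2 / (sa2n**2 / (na - 1) + sb2n**2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t_stat), df)
    return GroupComparison(
        mean_a=float(ma), sd_a=float(math.sqrt(va)), n_a=na,
        mean_b=float(mb), sd_b=float(math.sqrt(vb)), n_b=nb,
        t_statistic=float(t_stat), p_value=float(p), df=float(df),
    )


def escape_fraction(pfu_on_targeting_host: float, pfu_on_naive_host: float) -> float:
    """Fraction of plaque-formers escaping immunity: targeting titer / naive titer."""
    if pfu_on_naive_host <= 0:
        raise ValueError("no reference titer: naive-host PFU must be positive")
    if pfu_on_targeting_host < 0:
        raise ValueError("PFU counts must be non-negative")
    return pfu_on_targeting_host / pfu_on_naive_host


def read_wells_tsv(od_path: str | Path, meta_path: str | Path | None = None) -> list[WellRecord]:
    """Wells from a long-format TSV (well_id, replicate, time_h, od600).

    Optional metadata TSV supplies initial_gfp per well_id.
    """
    df = pd.read_csv(od_path, sep="\t")
    required = {"well_id", "replicate", "time_h", "od600"}
    if not required.issubset(df.columns):
        raise ValueError(f"wells TSV must have columns {sorted(required)}")
    gfp: dict[str, float] = {}
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t")
        gfp = dict(zip(meta["well_id"], meta["initial_gfp"]))
    wells = []
    for (wid, rep), sub in df.groupby(["well_id", "replicate"], sort=True):
        sub = sub.sort_values("time_h")
        wells.append(
            WellRecord(
                well_id=str(wid),
                times_h=sub["time_h"].to_numpy(),
                od=sub["od600"].to_numpy(),
                initial_gfp=float(gfp.get(wid, float("nan"))),
                replicate=int(rep),
            )
        )
    return wells


def write_wells_tsv(wells: Sequence[WellRecord], od_path: str | Path, meta_path: str | Path | None = None) -> None:
    rows = []
    for w in wells:
        for t, od in zip(w.times_h, w.od):
            rows.append({"well_id": w.well_id, "replicate": w.replicate, "time_h": t, "od600": od})
    pd.DataFrame(rows).to_csv(od_path, sep="\t", index=False)
    if meta_path is not None:
        meta = pd.DataFrame(
            {"well_id": [w.well_id for w in wells], "initial_gfp": [w.initial_gfp for w in wells]}
        )
        meta.to_csv(meta_path, sep="\t", index=False)
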