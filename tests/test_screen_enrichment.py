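"""Frequencies, enrichment ratios, genome localisation and region summaries."""

import numpy as np
import pandas as pd
import pytest

from spacerscreen import (
    GenomeRecord,
    RegionSpec,
    SpacerCountTable,
    enrichment_ratios,
    locate_spacer,
    position_profile,
    read_regions_bed,
    read_regions_yaml,
    region_summary,
    spacer_frequencies,
    unique_detection_by_region,
)
from spacerscreen._sequtils import revcomp


def table(counts, sample="s"):
    return SpacerCountTable(sample, counts, sum(counts.values()), sum(counts.values()))


class TestFrequencies:
    def test_single_spacer(self):
        f = spacer_frequencies(table({"A" * 35: 7}))
        assert f.freq == {"A" * 35: 1.0}

    def test_three_to_one(self):
        f = spacer_frequencies(table({"A" * 35: 3, "C" * 35: 1}))
        assert f.freq["A" * 35] == 0.75 and f.freq["C" * 35] == 0.25

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(10)
        counts = {f"S{i}": int(c) for i, c in enumerate(rng.integers(1, 1000, 500))}
        f = spacer_frequencies(table(counts))
        assert abs(sum(f.freq.values()) - 1.0) < 1e-9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty sample"):
            spacer_frequencies(table({}))


class TestEnrichmentRatios:
    def test_identity_sample_gives_unit_ratios(self):
        f = spacer_frequencies(table({"A": 50, "B": 30, "C": 20}))
        rec = enrichment_ratios(f, f, min_t0_count=5)
        assert (rec["ratio"] == 1.0).all()
        assert (rec["status"] == "ok").all()

    def test_fivefold_enrichment(self):
        f0 = spacer_frequencies(table({"A": 2, "B": 99998}))
        ft = spacer_frequencies(table({"A": 10, "B": 99990}))
        rec = enrichment_ratios(ft, f0, min_t0_count=1).set_index("spacer")
        assert rec.loc["A", "ratio"] == pytest.approx(5.0, rel=1e-4)

    def test_low_t0_count_excluded_not_inflated(self):
        f0 = spacer_frequencies(table({"A": 2, "B": 100}))
        ft = spacer_frequencies(table({"A": 50, "B": 100}))
        rec = enrichment_ratios(ft, f0, min_t0_count=5).set_index("spacer")
        assert rec.loc["A", "status"] == "absent_t0"
        assert np.isnan(rec.loc["A", "ratio"])

    def test_absent_at_t_keeps_zero_ratio(self):
        f0 = spacer_frequencies(table({"A": 10, "B": 10}))
        ft = spacer_frequencies(table({"B": 10}))
        rec = enrichment_ratios(ft, f0, min_t0_count=5).set_index("spacer")
        assert rec.loc["A", "ratio"] == 0.0
        assert rec.loc["A", "status"] == "absent_t"

    def test_spacer_only_at_t_has_no_ratio(self):
        f0 = spacer_frequencies(table({"A": 10}))
        ft = spacer_frequencies(table({"A": 5, "Z": 5}))
        rec = enrichment_ratios(ft, f0, min_t0_count=5).set_index("spacer")
        assert rec.loc["Z", "status"] == "absent_t0"


def brute_force_locate(genome, query, max_mm):
    """Independent all-position scan with early-exit mismatch counting."""
    hits = []
    for strand, q in (("plus", query), ("minus", revcomp(query))):
        for p in range(len(genome) - len(q) + 1):
            mm = 0
            for a, b in zip(genome[p : p + len(q)], q):
                if a != b:
                    mm += 1
                    if mm > max_mm:
                        break
            else:
                hits.append((p, strand))
    return hits


class TestLocateSpacer:
    def test_exact_plus_strand_prefix(self, small_genome):
        res = locate_spacer(small_genome.sequence[0:35], small_genome)
        assert (res.status, res.start, res.strand) == ("unique", 0, "plus")

    def test_revcomp_maps_to_minus_strand(self, small_genome):
        res = locate_spacer(revcomp(small_genome.sequence[10:45]), small_genome)
        assert (res.status, res.start, res.strand) == ("unique", 10, "minus")

    def test_planted_duplication_is_ambiguous(self):
        rng = np.random.default_rng(11)
        block = "".join(rng.choice(list("ACGT"), 40))
        mid = "".join(rng.choice(list("ACGT"), 60))
        g = GenomeRecord(id="dup", sequence=block + mid + block)
        res = locate_spacer(block[:35], g)
        assert res.status == "ambiguous" and res.n_hits == 2

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(12)
        genome = "".join(rng.choice(list("ACGT"), 800))
        g = GenomeRecord(id="g", sequence=genome)
        for trial in range(40):
            if trial % 2 == 0:  # planted query, possibly damaged
                p = int(rng.integers(0, 800 - 35))
                q = list(genome[p : p + 35])
                for pos in rng.integers(0, 35, int(rng.integers(0, 3))):
                    q[pos] = "ACGT"[rng.integers(4)]
                query = "".join(q)
                if rng.random() < 0.5:
                    query = revcomp(query)
            else:
                query = "".join(rng.choice(list("ACGT"), 35))
            for mm in (0, 1, 2):
                expected = brute_force_locate(genome, query, mm)
                got = locate_spacer(query, g, mm)
                if len(expected) == 0:
                    assert got.status == "unmapped"
                elif len(expected) == 1:
                    assert (got.start, got.strand) == expected[0]
                else:
                    assert got.status == "ambiguous" and got.n_hits == len(expected)


def records_frame(rows):
    return pd.DataFrame(rows, columns=["spacer", "count0", "count_t", "f0", "ft", "ratio", "status"])


class TestProfilesAndRegions:
    def test_flat_unit_tracks(self, small_designs):
        rows = [(d.sequence, 10, 10, 0.1, 0.1, 1.0, "ok") for d in small_designs[:50]]
        prof = position_profile(records_frame(rows), small_designs)
        assert (prof.plus["enrichment"] == 1.0).all()
        assert (prof.minus["enrichment"] == 1.0).all()
        assert len(prof.plus) + len(prof.minus) == 50

    def test_strand_separation(self, small_designs):
        rows = [(d.sequence, 10, 10, 0.1, 0.1, 1.0, "ok") for d in small_designs]
        prof = position_profile(records_frame(rows), small_designs)
        assert set(prof.plus["spacer_id"]).isdisjoint(set(prof.minus["spacer_id"]))

    def test_unknown_sequences_tallied_not_plotted(self, small_designs):
        rows = [("X" * 35, 10, 10, 0.1, 0.1, 1.0, "ok")]
        prof = position_profile(records_frame(rows), small_designs)
        assert prof.qc["unmapped"] == 1
        assert len(prof.plus) == len(prof.minus) == 0

    def test_empty_records_give_empty_tracks(self, small_designs):
        prof = position_profile(records_frame([]), small_designs)
        assert prof.plus.empty and prof.minus.empty
        assert prof.qc["n_records"] == 0

    def test_region_mean_and_sd_closed_form(self, small_designs):
        plus = [d for d in small_designs if d.strand == "plus"][:3]
        rows = [(d.sequence, 10, 10, 0.1, 0.1, e, "ok") for d, e in zip(plus, (1.0, 2.0, 3.0))]
        prof = position_profile(records_frame(rows), small_designs)
        summ = region_summary(prof, [RegionSpec("all", 0, 2000)])
        row = summ[(summ["strand_matched"] == "plus")].iloc[0]
        assert row["mean_enrichment"] == pytest.approx(2.0)
        assert row["sd_enrichment"] == pytest.approx(1.0)
        assert row["n_spacers"] == 3

    def test_single_spacer_sd_is_null(self, small_designs):
        d = small_designs[0]
        rows = [(d.sequence, 10, 10, 0.1, 0.1, 2.0, "ok")]
        prof = position_profile(records_frame(rows), small_designs)
        summ = region_summary(prof, [RegionSpec("all", 0, 2000)])
        row = summ[summ["strand_matched"] == "plus"].iloc[0]
        assert row["mean_enrichment"] == 2.0
        assert np.isnan(row["sd_enrichment"])

    def test_region_outside_genome_rejected(self, small_designs):
        prof = position_profile(records_frame([]), small_designs)
        with pytest.raises(ValueError, match="past the genome end"):
            region_summary(prof, [RegionSpec("bad", 0, 99999)], genome_length=2000)

    def test_all_present_detection_equals_design(self, small_sim, small_designs):
        cfg, genome, regions = small_sim
        counts = {d.sequence: 1 for d in small_designs}
        det = unique_detection_by_region(
            SpacerCountTable("s", counts, len(counts), len(counts)), small_designs, regions
        )
        assert (det["n_detected"] == det["n_designed"]).all()

    def test_empty_sample_detects_nothing(self, small_sim, small_designs):
        _, _, regions = small_sim
        det = unique_detection_by_region(SpacerCountTable("s", {}, 0, 0), small_designs, regions)
        assert (det["n_detected"] == 0).all()


class TestRegionIO:
    def test_bed_round_trip(self, tmp_path):
        bed = tmp_path / "regions.bed"
        bed.write_text("phage\t1000\t15000\tPE\t0\t+\nphage\t15000\t42000\tPL\t0\t+\n")
        regions = read_regions_bed(bed)
        assert regions[0] == RegionSpec("PE", 1000, 15000, "plus")
        assert regions[1].name == "PL"

    def test_yaml_regions(self, tmp_path):
        y = tmp_path / "regions.yaml"
        y.write_text("- {name: PE, start: 1000, end: 15000}\n- {name: PL, start: 15000, end: 42000}\n")
        regions = read_regions_yaml(y)
        assert [r.name for r in regions] == ["PE", "PL"]

    def test_overlapping_regions_rejected(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("phage\t0\t100\tA\t0\t+\nphage\t50\t150\tB\t0\t+\n")
        with pytest.raises(ValueError, match="overlap"):
            read_regions_bed(bed)
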