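"""Footprint generation, A-site calibration, dwelling occupancy."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from silentspeed.errors import ValidationError
from silentspeed.footprints import (SENSE_CODONS, FootprintSpec, Transcript,
                                    generate_footprints, random_transcripts)
from silentspeed.ribo import (OffsetTable, assign_a_sites, calibrate_offsets,
                              dwelling_occupancy, occupancy_report)


def cds_frame(transcripts):
    return pd.DataFrame(
        [(t.transcript_id, t.cds_start, t.cds_end) for t in transcripts],
        columns=["transcript_id", "cds_start", "cds_end"])


def uniform_weights(value=1.0):
    return {c: value for c in SENSE_CODONS}


class TestGenerateFootprints:
    def test_uniform_weights_multinomial(self):
        txs = random_transcripts(2, 200, seed=0)
        spec = FootprintSpec(txs, uniform_weights(), total_reads=50_000,
                             init_peak_weight=1.0, seed=1)
        aln, _ = generate_footprints(spec)
        # A-site codon index via known offsets; counts ~ uniform multinomial
        off = spec.offsets
        counts, _ = assign_a_sites(aln, OffsetTable(off), cds_frame(txs))
        obs = counts["count"].to_numpy(float)
        _, p = chisquare(obs)
        assert p > 1e-3

    def test_doubled_weight_doubles_counts(self):
        tx = random_transcripts(1, 100, seed=2)
        weights = uniform_weights()
        weights["ACG"] = 2.0
        spec = FootprintSpec(tx, weights, total_reads=200_000,
                             init_peak_weight=1.0, seed=3)
        aln, _ = generate_footprints(spec)
        counts, _ = assign_a_sites(aln, OffsetTable(spec.offsets),
                                   cds_frame(tx))
        codons = tx[0].codons
        merged = counts.assign(codon=[codons[i] for i in counts.codon_index])
        per_codon = merged.groupby("codon")["count"].sum()
        n_acg = sum(c == "ACG" for c in codons)
        n_other = sum(c not in ("ACG", "ATG", "TAA") for c in codons[2:])
        acg_rate = per_codon.get("ACG", 0) / n_acg
        other = merged[~merged.codon.isin(["ACG", "ATG", "TAA"])]
        other = other[other.codon_index >= 2]
        other_rate = other["count"].sum() / n_other
        assert acg_rate / other_rate == pytest.approx(2.0, rel=0.1)

    def test_zero_reads_empty_table(self):
        txs = random_transcripts(1, 50, seed=4)
        aln, report = generate_footprints(
            FootprintSpec(txs, uniform_weights(), total_reads=0))
        assert aln.empty
        assert report["n_reads"] == 0

    def test_reproducible_for_fixed_seed(self):
        txs = random_transcripts(1, 50, seed=5)
        spec = FootprintSpec(txs, uniform_weights(), total_reads=1000, seed=6)
        a, _ = generate_footprints(spec)
        b, _ = generate_footprints(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_offset_rejected(self):
        txs = random_transcripts(1, 50, seed=7)
        with pytest.raises(ValidationError):
            FootprintSpec(txs, uniform_weights(), total_reads=10,
                          offsets={27: 30, 28: 16, 29: 16})


class TestCalibrateOffsets:
    def test_known_offsets_recovered(self, footprint_dataset):
        table = calibrate_offsets(footprint_dataset["alignments"],
                                  footprint_dataset["cds"])
        assert table.offsets == footprint_dataset["spec"].offsets

    def test_two_lengths_with_distinct_offsets(self):
        txs = random_transcripts(4, 150, seed=8)
        spec = FootprintSpec(txs, uniform_weights(), total_reads=60_000,
                             length_probs={27: 0.5, 29: 0.5},
                             offsets={27: 14, 29: 17}, seed=9)
        aln, _ = generate_footprints(spec)
        table = calibrate_offsets(aln, cds_frame(txs),
                                  lengths_retained=(27, 29))
        assert table.offsets == {27: 14, 29: 17}

    def test_empty_alignments_rejected(self, footprint_dataset):
        with pytest.raises(ValidationError):
            calibrate_offsets(pd.DataFrame(columns=["transcript", "start",
                                                    "end", "length"]),
                              footprint_dataset["cds"])

    def test_flat_metagene_rejected(self):
        # no initiation peak and few reads: no mode above background
        txs = random_transcripts(1, 300, seed=10)
        spec = FootprintSpec(txs, uniform_weights(), total_reads=3000,
                             init_peak_weight=1.0, seed=11)
        aln, _ = generate_footprints(spec)
        with pytest.raises(ValidationError, match="peak|reads"):
            calibrate_offsets(aln, cds_frame(txs))


class TestAssignASites:
    def test_worked_coordinate_arithmetic(self):
        # 5' = 30, length 28, offset 16 -> A-site middle nt 46 -> codon 15
        tx = Transcript("t1", "A" * 200, 0, 198)
        aln = pd.DataFrame({"transcript": ["t1"], "start": [30], "end": [58],
                            "length": [28]})
        counts, tallies = assign_a_sites(aln, OffsetTable({28: 16}),
                                         cds_frame([tx]))
        assert counts.iloc[0]["codon_index"] == 15
        assert tallies["assigned"] == 1

    def test_read_outside_cds_tallied(self):
        tx = Transcript("t1", "A" * 200, 90, 198)
        aln = pd.DataFrame({"transcript": ["t1"], "start": [10], "end": [38],
                            "length": [28]})
        counts, tallies = assign_a_sites(aln, OffsetTable({28: 16}),
                                         cds_frame([tx]))
        assert counts.empty
        assert tallies["outside_cds"] == 1

    def test_unknown_length_skipped_and_tallied(self):
        tx = Transcript("t1", "A" * 200, 0, 198)
        aln = pd.DataFrame({"transcript": ["t1"], "start": [30], "end": [65],
                            "length": [35]})
        counts, tallies = assign_a_sites(aln, OffsetTable({28: 16}),
                                         cds_frame([tx]))
        assert tallies["length_not_calibrated"] == 1


def toy_gene_with_counts(acg_positions=10, count_acg=2, count_other=1):
    """Gene whose included region has exactly 100 codons: 10 ACG, 90 GCT."""
    body = ["GCT"] * 116          # sense codons 1..116; included are 17..116
    for i in range(20, 20 + acg_positions):
        body[i - 1] = "ACG"
    cds = "ATG" + "".join(body) + "TAA"
    tx = Transcript("toy", cds, 0, len(cds))
    rows = []
    for i in range(17, 117):
        codon = tx.codons[i]
        rows.append(("toy", i, count_acg if codon == "ACG" else count_other))
    counts = pd.DataFrame(rows, columns=["transcript", "codon_index", "count"])
    return tx, counts


class TestDwellingOccupancy:
    def test_uniform_counts_give_unit_occupancy(self):
        tx = random_transcripts(1, 120, seed=12)[0]
        rows = [("gene0", i, 3) for i in range(17, tx.n_codons - 1)]
        counts = pd.DataFrame(rows, columns=["transcript", "codon_index",
                                             "count"])
        occ = dwelling_occupancy(counts, [tx])
        assert np.allclose(occ.table["occupancy"], 1.0)

    def test_worked_arithmetic_oracle(self):
        # 100 included codons, 10 ACG at count 2, 90 others at count 1:
        # gene mean 1.1; ACG ratio 2/1.1, others 1/1.1; ACG/other = 2
        tx, counts = toy_gene_with_counts()
        occ = dwelling_occupancy(counts, [tx])
        acg = occ.occupancy("ACG")
        gct = occ.occupancy("GCT")
        assert acg == pytest.approx(2.0 / 1.1, abs=1e-9)
        assert gct == pytest.approx(1.0 / 1.1, abs=1e-9)
        assert acg / gct == pytest.approx(2.0)

    def test_counts_only_in_excluded_region_skip_gene(self):
        tx = random_transcripts(1, 120, seed=13)[0]
        rows = [("gene0", i, 5) for i in range(0, 17)]
        counts = pd.DataFrame(rows, columns=["transcript", "codon_index",
                                             "count"])
        occ = dwelling_occupancy(counts, [tx])
        assert occ.n_genes_used == 0
        assert occ.n_genes_skipped == 1

    def test_atg_flagged_excluded(self, footprint_dataset):
        counts, _ = assign_a_sites(
            footprint_dataset["alignments"],
            OffsetTable(footprint_dataset["spec"].offsets),
            footprint_dataset["cds"])
        occ = dwelling_occupancy(counts, footprint_dataset["transcripts"])
        atg = occ.table[occ.table["codon"] == "ATG"]
        assert not atg.empty and not atg["included"].iloc[0]
        assert len(occ.table) <= 61

    def test_per_gene_normalization_identity(self, footprint_dataset):
        counts, _ = assign_a_sites(
            footprint_dataset["alignments"],
            OffsetTable(footprint_dataset["spec"].offsets),
            footprint_dataset["cds"])
        # the mean position ratio over included positions is 1 per gene
        for tid, g in counts.groupby("transcript"):
            tx = next(t for t in footprint_dataset["transcripts"]
                      if t.transcript_id == tid)
            codons = tx.codons
            inc = [i for i in range(17, len(codons))
                   if codons[i] not in ("TAA", "TAG", "TGA")]
            vec = np.zeros(len(codons))
            vec[g["codon_index"].to_numpy()] = g["count"].to_numpy()
            ratios = vec[inc] / vec[inc].mean()
            assert np.mean(ratios) == pytest.approx(1.0)

    def test_dwell_weight_recovery(self, footprint_dataset):
        counts, _ = assign_a_sites(
            footprint_dataset["alignments"],
            OffsetTable(footprint_dataset["spec"].offsets),
            footprint_dataset["cds"])
        occ = dwelling_occupancy(counts, footprint_dataset["transcripts"])
        tab = occ.table[occ.table["included"]]
        w = np.array([footprint_dataset["weights"][c] for c in tab["codon"]])
        r = np.corrcoef(w, tab["occupancy"])[0, 1]
        assert r > 0.95


class TestOccupancyReport:
    @staticmethod
    def usage_for(codons, values=None):
        vals = values if values is not None else np.full(len(codons), 20.0)
        return pd.DataFrame({"codon": list(codons), "per_thousand": vals})

    def test_slow_codon_flagged(self, footprint_dataset):
        counts, _ = assign_a_sites(
            footprint_dataset["alignments"],
            OffsetTable(footprint_dataset["spec"].offsets),
            footprint_dataset["cds"])
        occ = dwelling_occupancy(counts, footprint_dataset["transcripts"])
        inc = occ.table[occ.table["included"]]
        rep = occupancy_report(occ, self.usage_for(inc["codon"]),
                               boundary_quantile=0.90)
        slowest = rep.iloc[0]["codon"]
        assert rep.loc[rep["codon"] == slowest, "slow"].iloc[0]
        # flagged fraction consistent with a 90% boundary
        assert 0.0 < rep["slow"].mean() <= 0.15

    def test_flat_occupancies_flag_nothing(self):
        tx = random_transcripts(1, 120, seed=14)[0]
        rows = [("gene0", i, 2) for i in range(17, tx.n_codons - 1)]
        counts = pd.DataFrame(rows, columns=["transcript", "codon_index",
                                             "count"])
        occ = dwelling_occupancy(counts, [tx])
        inc = occ.table[occ.table["included"]]
        rep = occupancy_report(occ, self.usage_for(inc["codon"]))
        assert not rep["slow"].any()

    def test_perfect_inverse_relation_gives_minus_one(self):
        tx, counts = toy_gene_with_counts()
        occ = dwelling_occupancy(counts, [tx])
        inc = occ.table[occ.table["included"]]
        # usage strictly decreasing in occupancy rank
        order = inc.sort_values("occupancy")
        usage = self.usage_for(order["codon"],
                               np.linspace(40, 10, len(order)))
        rep = occupancy_report(occ, usage)
        assert rep.attrs["rank_correlation"] == pytest.approx(-1.0)

    def test_missing_codon_rejected(self, footprint_dataset):
        counts, _ = assign_a_sites(
            footprint_dataset["alignments"],
            OffsetTable(footprint_dataset["spec"].offsets),
            footprint_dataset["cds"])
        occ = dwelling_occupancy(counts, footprint_dataset["transcripts"])
        with pytest.raises(ValidationError, match="missing"):
            occupancy_report(occ, self.usage_for(["AAA"]))
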