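"""FISH decoding and co-bursting statistics."""

import numpy as np
import pandas as pd
import pytest

from crossacd import fish, simulate as sim


@pytest.fixture(scope="module")
def codebook():
    return fish.Codebook(
        {
            "gA": (1, 2, 3, 4),
            "gB": (2, 3, 4, 5),
            "gC": (5, 1, 4, 2),
            "gD": (3, 5, 1, 6),
        }
    )


def _spots(entries):
    return pd.DataFrame(
        entries, columns=["round", "pseudocolor", "x_px", "y_px", "z_px"]
    )


class TestCodebook:
    def test_min_round_distance_enforced(self):
        with pytest.raises(ValueError, match="differ"):
            fish.Codebook({"a": (1, 2, 3, 4), "b": (1, 2, 3, 5)})

    def test_pseudocolor_range(self):
        with pytest.raises(ValueError):
            fish.Codebook({"a": (0, 2, 3, 4)})

    def test_csv_roundtrip(self, tmp_path, codebook):
        rows = ["gene,ro1,ro2,ro3,ro4"]
        rows += [f"{g},{','.join(map(str, bc))}" for g, bc in codebook.barcodes.items()]
        p = tmp_path / "cb.csv"
        p.write_text("\n".join(rows) + "\n")
        back = fish.Codebook.from_csv(p)
        assert back.barcodes == codebook.barcodes


class TestDecodeCell:
    def test_full_barcode_decoded_at_true_position(self, codebook):
        spots = _spots([(r, codebook.barcodes["gA"][r], 10.0, 20.0, 5.0) for r in range(4)])
        calls = fish.decode_cell(spots, codebook, px_nm=100.0, cell_id="c")
        assert len(calls) == 1
        c = calls[0]
        assert c.gene == "gA" and c.n_rounds_matched == 4
        assert (c.x_nm, c.y_nm, c.z_nm) == (1_000.0, 2_000.0, 500.0)

    def test_one_round_dropout_still_decodes(self, codebook):
        spots = _spots(
            [(r, codebook.barcodes["gB"][r], 3.0, 3.0, 3.0) for r in (0, 2, 3)]
        )
        calls = fish.decode_cell(spots, codebook, cell_id="c")
        assert [c.gene for c in calls] == ["gB"]
        assert calls[0].n_rounds_matched == 3

    def test_two_missing_rounds_discarded(self, codebook):
        spots = _spots([(r, codebook.barcodes["gB"][r], 3.0, 3.0, 3.0) for r in (0, 1)])
        assert fish.decode_cell(spots, codebook) == []

    def test_colocalized_mixture_never_miscalls(self, codebook):
        """Two genes bursting at the same spot: mixed clusters must not
        decode to a gene that is not actually present."""
        entries = []
        for r in range(4):
            entries.append((r, codebook.barcodes["gA"][r], 0.0, 0.0, 0.0))
            entries.append((r, codebook.barcodes["gB"][r], 0.0, 0.0, 0.0))
        calls = fish.decode_cell(_spots(entries), codebook)
        assert {c.gene for c in calls} <= {"gA", "gB"}

    def test_spot_order_invariance(self, codebook, rng):
        entries = [
            (r, codebook.barcodes["gA"][r], 1.0, 1.0, 1.0) for r in range(4)
        ] + [(r, codebook.barcodes["gC"][r], 50.0, 50.0, 50.0) for r in range(4)]
        spots = _spots(entries)
        shuffled = spots.sample(frac=1.0, random_state=3)
        calls_a = fish.decode_cell(spots, codebook)
        calls_b = fish.decode_cell(shuffled, codebook)
        assert sorted(c.gene for c in calls_a) == sorted(c.gene for c in calls_b) == [
            "gA",
            "gC",
        ]

    def test_simulated_clean_recovery_is_complete(self, codebook):
        bursts, _ = sim.gen_burst_cells(
            [("gA", "gB")], {"gA": 0.8, "gB": 0.8}, co_burst_excess=1.0,
            n_cells=80, seed=5,
        )
        spots = sim.gen_readout_spots(bursts, codebook, seed=6)
        decoded = fish.decode_spots(spots, codebook)
        assert len(decoded) == len(bursts)
        pd.testing.assert_frame_equal(
            decoded.groupby("gene").size().to_frame("n"),
            bursts.groupby("gene").size().to_frame("n"),
        )

    def test_single_dropout_recovery_is_complete(self, codebook):
        bursts, _ = sim.gen_burst_cells(
            [("gA", "gB")], {"gA": 0.8, "gB": 0.8}, co_burst_excess=1.0,
            n_cells=80, seed=7,
        )
        spots = sim.gen_readout_spots(
            bursts, codebook, force_single_dropout=True, seed=8
        )
        decoded = fish.decode_spots(spots, codebook)
        assert len(decoded) == len(bursts)
        assert (decoded["n_rounds_matched"] == 3).all()

    def test_heavy_noise_degrades_recovery(self, codebook):
        bursts, _ = sim.gen_burst_cells(
            [("gA", "gB")], {"gA": 0.8, "gB": 0.8}, co_burst_excess=1.0,
            n_cells=80, seed=9,
        )
        spots = sim.gen_readout_spots(bursts, codebook, loc_noise_px=5.0, seed=10)
        decoded = fish.decode_spots(spots, codebook)
        assert len(decoded) < len(bursts)


class TestBurstStats:
    def test_bursting_frequency_arithmetic(self):
        calls = pd.DataFrame(
            {"cell_id": [f"c{i}" for i in range(37)], "gene": ["g"] * 37}
        )
        assert fish.bursting_frequency(calls, "g", 100) == pytest.approx(0.37)
        assert fish.bursting_frequency(calls, "absent", 100) == 0.0
        with pytest.raises(ValueError):
            fish.bursting_frequency(calls, "g", 0)

    def test_multi_allele_frequency_exceeds_one(self):
        calls = pd.DataFrame(
            {"cell_id": ["c0", "c0", "c1", "c1"], "gene": ["g"] * 4}
        )
        assert fish.bursting_frequency(calls, "g", 2) == pytest.approx(2.0)

    def _calls(self, rows):
        return pd.DataFrame(
            rows, columns=["cell_id", "gene", "x_nm", "y_nm", "z_nm"]
        )

    def test_gate_and_distance(self):
        calls = self._calls(
            [("c", "A", 0, 0, 0), ("c", "B", 500, 0, 0), ("c", "B", 3_000, 0, 0)]
        )
        n_co, dists = fish.co_burst_count(calls, "A", "B", cutoff_um=1.0)
        assert n_co == 1
        assert dists[0] == pytest.approx(0.5)

    def test_beyond_gate_not_counted(self):
        calls = self._calls([("c", "A", 0, 0, 0), ("c", "B", 3_000, 0, 0)])
        assert fish.co_burst_count(calls, "A", "B")[0] == 0

    def test_symmetry_and_no_double_use(self):
        calls = self._calls(
            [
                ("c", "A", 0, 0, 0),
                ("c", "B", 400, 0, 0),
                ("c", "B", 450, 0, 0),
            ]
        )
        n_ab, _ = fish.co_burst_count(calls, "A", "B")
        n_ba, _ = fish.co_burst_count(calls, "B", "A")
        assert n_ab == n_ba == 1  # single A site pairs once

    def test_normalized_co_burst_formula(self):
        assert fish.normalized_co_burst(10, 0.5, 0.4, 100) == pytest.approx(0.5)
        assert fish.normalized_co_burst(20, 0.5, 0.4, 100) == pytest.approx(1.0)
        assert fish.normalized_co_burst(0, 0.5, 0.4, 100) == 0.0
        assert np.isnan(fish.normalized_co_burst(3, 0.0, 0.4, 100))

    def test_independence_fixture_gives_unity(self):
        """psi = 1 burst geometry yields F_co within 3 SE of 1."""
        n_cells = 600
        bursts, _ = sim.gen_burst_cells(
            [("gA", "gB")], {"gA": 0.5, "gB": 0.4}, co_burst_excess=1.0,
            n_cells=n_cells, seed=13,
        )
        s = fish.burst_statistics(bursts, ["gA", "gB"], n_cells)[0]
        se = np.sqrt(max(s.n_co, 1)) / (s.f_a * s.f_b * n_cells)
        assert abs(s.f_co - 1.0) <= 3 * se

    def test_anticorrelated_fixture_has_no_coincidences(self):
        bursts, _ = sim.gen_burst_cells(
            [("gA", "gB")], {"gA": 0.5, "gB": 0.4}, co_burst_excess=0.0,
            n_cells=300, seed=14,
        )
        s = fish.burst_statistics(bursts, ["gA", "gB"], 300)[0]
        assert s.n_co == 0

    def test_infeasible_joint_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            sim.gen_burst_cells(
                [("gA", "gB")], {"gA": 1.0, "gB": 0.2}, co_burst_excess=6.0,
                n_cells=10, seed=1,
            )


class TestDifferentialMatrices:
    def test_identical_conditions_zero(self):
        bursts, _ = sim.gen_burst_cells(
            [("gA", "gB")], {"gA": 0.5, "gB": 0.5}, co_burst_excess=1.5,
            n_cells=150, seed=15,
        )
        stats = fish.burst_statistics(bursts, ["gA", "gB"], 150)
        dfco, ddist = fish.differential_matrices(stats, stats)
        assert dfco.loc["gA", "gB"] == 0.0
        assert ddist.loc["gA", "gB"] == 0.0

    def test_gene_set_mismatch_rejected(self):
        s = fish.CoBurstStat("gA", "gB", 1, 0.5, 0.5, 10, 0.4, 0.5)
        t = fish.CoBurstStat("gA", "gC", 1, 0.5, 0.5, 10, 0.4, 0.5)
        with pytest.raises(ValueError):
            fish.differential_matrices([s], [t])

    def test_raised_excess_and_shrunk_territory(self):
        """Higher psi with tighter territories: deltaF_co > 0, delta
        distance < 0 (the cohesin-loss direction)."""
        pairs = [("gA", "gB"), ("gC", "gD")]
        freqs = {"gA": 0.5, "gB": 0.5, "gC": 0.4, "gD": 0.6}
        n = 500
        b_ctrl, _ = sim.gen_burst_cells(
            pairs, freqs, co_burst_excess=1.0, n_cells=n,
            territory_radius_um=1.0, seed=16,
        )
        b_dep, _ = sim.gen_burst_cells(
            pairs, freqs, co_burst_excess=1.6, n_cells=n,
            territory_radius_um=0.6, seed=17,
        )
        genes = sorted(freqs)
        stats_c = fish.burst_statistics(b_ctrl, genes, n)
        stats_d = fish.burst_statistics(b_dep, genes, n)
        dfco, ddist = fish.differential_matrices(stats_c, stats_d)
        pair_vals = [dfco.loc[a, b] for a, b in pairs]
        dist_vals = [ddist.loc[a, b] for a, b in pairs]
        assert np.median(pair_vals) > 0
        assert np.median(dist_vals) < 0
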