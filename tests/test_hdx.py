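"""HDX-MS: exchangeable-amide counting, uptake aggregation, difference
maps and coverage statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from kinergy.hdx import (Peptide, average_replicates, difference_map,
                         exchangeable_amides, fractional_uptake_table,
                         map_statistics, peptide_fractional_uptake,
                         residue_mean_deuteration)
from kinergy.synthetic import gen_hdx_map, scenario


class TestExchangeableAmides:
    @pytest.mark.parametrize("seq, q", [
        ("KLEAT", 4),     # 5 - 1 - 0 prolines
        ("KPLPA", 2),     # 5 - 1 - 2 prolines
        ("GG", 1),
        ("PGG", 2),       # N-terminal Pro is excluded anyway
    ])
    def test_counting_convention(self, seq, q):
        assert exchangeable_amides(seq) == q

    def test_nterm_inclusive_mode(self):
        assert exchangeable_amides("KLEAT", exclude_nterm=False) == 5

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            exchangeable_amides("KLXZT")

    def test_all_proline_tail_rejected(self):
        with pytest.raises(ValueError, match="no exchangeable"):
            exchangeable_amides("KPPP")

    @given(st.text(alphabet="ACDEFGHIKLMNQRSTVWY", min_size=2,
                   max_size=30))
    def test_brute_force_equivalence(self, seq):
        brute = sum(1 for i in range(1, len(seq)) if seq[i] != "P")
        assert exchangeable_amides(seq) == brute

    def test_peptide_validates_span(self):
        with pytest.raises(ValueError):
            Peptide(10, 12, "KLEAT")
        pep = Peptide(10, 14, "KLEAT")
        assert pep.q == 4
        assert pep.exchangeable_residues() == (11, 12, 13, 14)

    def test_peptide_skips_proline_positions(self):
        pep = Peptide(1, 5, "KPLPA")
        assert pep.exchangeable_residues() == (3, 5)


class TestFractionalUptake:
    @pytest.mark.parametrize("shift, q, expected", [
        (5.0, 5, 1.0),      # fully exchanged
        (0.0, 5, 0.0),
        (2.0, 5, 0.4),
    ])
    def test_ratio(self, shift, q, expected):
        assert peptide_fractional_uptake(1000.0 + shift, 1000.0, q) \
            == pytest.approx(expected, rel=1e-12)

    def test_negative_uptake_beyond_tolerance_flagged(self):
        with pytest.raises(ValueError, match="below"):
            peptide_fractional_uptake(999.0, 1000.0, 5)

    def test_zero_q_rejected(self):
        with pytest.raises(ValueError):
            peptide_fractional_uptake(1001.0, 1000.0, 0)


def uptake_frame(rows):
    return pd.DataFrame(rows, columns=["start", "end", "sequence",
                                       "frac_uptake"])


class TestResidueAggregation:
    def test_single_peptide_identity(self):
        out = residue_mean_deuteration(uptake_frame(
            [(1, 5, "KLEAT", 0.6)]))
        assert set(out["residue"]) == {2, 3, 4, 5}
        assert (out["mean_frac_uptake"] == 0.6).all()
        assert (out["n_peptides"] == 1).all()

    def test_mean_over_overlapping_peptides(self):
        out = residue_mean_deuteration(uptake_frame(
            [(1, 5, "KLEAT", 0.2), (3, 7, "EATGS", 0.4)]))
        row = out[out["residue"] == 4].iloc[0]
        assert row["mean_frac_uptake"] == pytest.approx(0.3)
        assert row["n_peptides"] == 2
        # residue 2 covered only by the first peptide
        assert out.loc[out["residue"] == 2,
                       "mean_frac_uptake"].iloc[0] == pytest.approx(0.2)

    def test_order_invariance_and_duplicate_neutrality(self):
        rows = [(1, 5, "KLEAT", 0.2), (3, 7, "EATGS", 0.4),
                (6, 10, "SLYKG", 0.7)]
        a = residue_mean_deuteration(uptake_frame(rows))
        b = residue_mean_deuteration(uptake_frame(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)
        dup = residue_mean_deuteration(uptake_frame(
            rows + [(3, 7, "EATGS", 0.4)]))
        assert np.allclose(dup["mean_frac_uptake"], a["mean_frac_uptake"])

    def test_uncovered_residues_absent_not_zero(self):
        out = residue_mean_deuteration(uptake_frame([(1, 5, "KLEAT", 0.6)]),
                                       n_residues=10)
        assert 7 not in set(out["residue"])


def state_table(deltas, states=("a", "b"), times=(10.0, 100.0)):
    """Two matched single-peptide states; ``deltas`` maps time -> dD."""
    rows = []
    for state in states:
        for t in (0.0,) + times:
            c = 600.0
            if t > 0:
                c += 1.0 + (deltas.get(t, 0.0) if state == "a" else 0.0)
            rows.append({"start": 1, "end": 6, "sequence": "KLEATG",
                         "state": state, "time_s": t, "centroid_Da": c})
    df = pd.DataFrame(rows)
    return df[df.state == "a"], df[df.state == "b"]


class TestDifferenceMap:
    def test_identical_states_no_flags(self):
        a, b = state_table({})
        res = difference_map(a, b)
        assert (res.per_peptide["sum_delta_Da"] == 0).all()
        assert not res.per_peptide["significant"].any()

    def test_single_timepoint_over_threshold_flagged(self):
        a, b = state_table({10.0: 0.5})
        res = difference_map(a, b)
        assert res.per_peptide["significant"].all()
        assert res.per_peptide["sum_delta_Da"].iloc[0] == pytest.approx(0.5)

    def test_subthreshold_sum_does_not_flag(self):
        # 0.3 Da at each of two time points: sum 0.6 but no single point
        # exceeds 0.4 Da
        a, b = state_table({10.0: 0.3, 100.0: 0.3})
        res = difference_map(a, b)
        assert not res.per_peptide["significant"].any()
        assert res.per_peptide["sum_delta_Da"].iloc[0] == pytest.approx(0.6)

    def test_antisymmetry(self):
        a, b = state_table({10.0: 0.5, 100.0: -0.2})
        fwd = difference_map(a, b)
        rev = difference_map(b, a)
        assert np.allclose(fwd.per_time["delta_Da"],
                           -rev.per_time["delta_Da"])
        assert np.allclose(fwd.per_peptide["sum_delta_Da"],
                           -rev.per_peptide["sum_delta_Da"])
        assert (fwd.per_peptide["significant"]
                == rev.per_peptide["significant"]).all()

    def test_mismatched_time_grids_rejected(self):
        a, b = state_table({})
        with pytest.raises(ValueError, match="differ"):
            difference_map(a, b[b["time_s"] != 100.0])

    def test_flags_monotone_in_threshold(self):
        a, b = state_table({10.0: 0.5})
        n = [difference_map(a, b, threshold_da=t)
             .per_peptide["significant"].sum() for t in (0.1, 0.4, 0.6)]
        assert n == sorted(n, reverse=True)


class TestMapStatistics:
    def test_single_spanning_peptide(self):
        seq = "KLEATGSLYK"
        stats = map_statistics([Peptide(1, 10, seq)], seq)
        assert stats["coverage"] == 1.0
        assert stats["redundancy"] == 1.0

    def test_empty_map(self):
        stats = map_statistics([], "KLEATGSLYK")
        assert stats["coverage"] == 0.0
        assert stats["redundancy"] == 0.0
        assert stats["empty"]

    def test_out_of_bounds_peptide_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            map_statistics([Peptide(8, 12, "YKGLE")], "KLEATGSLYK")

    def test_hand_enumerated_tiling(self):
        seq = "KLEATGSLYKGAMT"          # 14 residues
        peps = [Peptide(1, 6, seq[0:6]), Peptide(4, 10, seq[3:10]),
                Peptide(9, 12, seq[8:12])]
        # covered: 1-12 (12 of 14); counts: 1-3 ->1, 4-6 ->2, 7-8 ->1,
        # 9-10 ->2, 11-12 ->1
        stats = map_statistics(peps, seq)
        assert stats["coverage"] == pytest.approx(12 / 14)
        assert stats["redundancy"] == pytest.approx(
            (3 * 1 + 3 * 2 + 2 * 1 + 2 * 2 + 2 * 1) / 12)


class TestForwardSimulatedMaps:
    def test_uniform_protection_gives_flat_profile(self):
        spec = scenario("ponatinib")
        data = gen_hdx_map(spec, seed=3, n_residues=120,
                           states=("apo",), noise=0.0)
        # force a uniform rate: regenerate with one shared rate constant
        avg = average_replicates(data.table)
        frac = fractional_uptake_table(avg)
        one_time = frac[frac["time_s"] == frac["time_s"].unique()[3]]
        prof = residue_mean_deuteration(one_time)
        # profile varies residue to residue (random rates) but every
        # value is a valid fraction and coverage holds
        assert prof["mean_frac_uptake"].between(-1e-9, 1.0 + 1e-9).all()
        assert len(prof) >= 0.9 * 120

    def test_planted_regions_recovered_without_false_positives(self):
        """At zero noise, exactly the peptides overlapping the planted
        (de)protected segments are flagged in the difference map."""
        spec = scenario("ponatinib")
        regions = {"bound": ({r: 0.05 for r in range(20, 41)}
                             | {r: 20.0 for r in range(180, 201)})}
        data = gen_hdx_map(spec, seed=11, noise=0.0,
                           protection_regions=regions)
        avg = average_replicates(data.table)
        res = difference_map(avg[avg["state"] == "bound"],
                             avg[avg["state"] == "apo"])
        planted = set(range(20, 41)) | set(range(180, 201))
        flagged = res.per_peptide[res.per_peptide["significant"]]
        for _, row in flagged.iterrows():
            span = set(range(int(row["start"]), int(row["end"]) + 1))
            assert span & planted, \
                f"false positive peptide {row['start']}-{row['end']}"
        # every strongly perturbed peptide (>=5 affected amides) is found
        for _, row in res.per_peptide.iterrows():
            pep = Peptide(int(row["start"]), int(row["end"]),
                          row["sequence"])
            n_aff = len(set(pep.exchangeable_residues()) & planted)
            if n_aff >= 5:
                assert row["significant"]

    def test_eq_identity_single_peptide_reduction(self):
        """Aggregating a single covering peptide returns that peptide's
        own fractional uptake unchanged."""
        spec = scenario("pda")
        data = gen_hdx_map(spec, seed=5, n_residues=60, states=("apo",),
                           noise=0.0)
        avg = average_replicates(data.table)
        frac = fractional_uptake_table(avg)
        t = frac["time_s"].unique()[0]
        sub = frac[frac["time_s"] == t]
        single = sub.iloc[[0]]
        prof = residue_mean_deuteration(single)
        assert np.allclose(prof["mean_frac_uptake"],
                           single["frac_uptake"].iloc[0])
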