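"""LLPS/disorder classifiers, GRAVY, charge, and the hub annotation table."""
import math
import random

import pytest
from scipy.optimize import brentq

from nbhub import (
    PTMAnnotation,
    ResidueTrack,
    ScoreTable,
    SyntheticSpec,
    annotate_hubs,
    charge_at_ph,
    gravy,
    llps_consensus,
    llps_role,
    ppidr,
)
from nbhub.annotate import CATGRANULE, FUZDROP_PLLPS, PSPHUNTER, PSPREDICTOR
from nbhub.hubs import HubRecord, HubTable
from nbhub.synthetic import gen_tracks_and_scores

EPS = 1e-9


class TestLLPSConsensusTruthTable:
    @pytest.mark.parametrize("score,label", [
        (0.5 + EPS, "LLPS"),
        (0.5, "non-LLPS"),       # strict >
        (0.5 - EPS, "non-LLPS"),
    ])
    def test_catgranule_strict_threshold(self, score, label):
        assert llps_consensus({CATGRANULE: score}).catgranule_label == label

    @pytest.mark.parametrize("score,label", [
        (0.61 + EPS, "likely"),
        (0.61, "unlikely"),      # endpoint falls in the middle band
        (0.36, "unlikely"),
        (0.36 - EPS, "non-LLPS"),
        (0.5, "unlikely"),
    ])
    def test_psphunter_bands(self, score, label):
        assert llps_consensus({PSPHUNTER: score}).psphunter_label == label

    @pytest.mark.parametrize("psp,fuz,label", [
        (0.7, 0.8, "LLPS"),
        (0.5 + EPS, 0.6 + EPS, "LLPS"),
        (0.5, 0.8, "controversial"),       # strict > on both
        (0.7, 0.6, "controversial"),
        (0.7, 0.3, "controversial"),
        (0.3, 0.9, "controversial"),
        (0.5, 0.6, "non-LLPS"),
        (0.2, 0.2, "non-LLPS"),
    ])
    def test_combined_scheme(self, psp, fuz, label):
        call = llps_consensus({PSPREDICTOR: psp, FUZDROP_PLLPS: fuz})
        assert call.combined_label == label

    def test_missing_scores_are_unknown_never_defaults(self):
        call = llps_consensus({})
        assert call.catgranule_label == "unknown"
        assert call.psphunter_label == "unknown"
        assert call.combined_label == "unknown"
        # one of the combined pair missing -> still unknown
        assert llps_consensus({PSPREDICTOR: 0.9}).combined_label == "unknown"


class TestLLPSRole:
    def track(self, values):
        return ResidueTrack("P1", "fuzdrop_pdp", values)

    def test_pllps_exactly_060_is_driver(self):
        assert llps_role(0.60, None) == "driver"  # inclusive >=

    def test_pllps_just_below_with_no_region_is_neither(self):
        assert llps_role(0.60 - EPS, self.track([0.0] * 20)) == "neither"

    def test_client_requires_contiguous_run(self):
        values = [0.0] * 5 + [0.7] * 12 + [0.0] * 5
        assert llps_role(0.4, self.track(values), min_region_length=10) == "client"

    def test_scattered_high_residues_do_not_make_a_client(self):
        values = ([0.7] * 5 + [0.0]) * 10  # runs of 5 only
        assert llps_role(0.4, self.track(values), min_region_length=10) == "neither"

    def test_pdp_boundary_inclusive(self):
        assert llps_role(0.4, self.track([0.60] * 10), min_region_length=10) == "client"
        assert llps_role(0.4, self.track([0.60 - EPS] * 10), min_region_length=10) == "neither"

    def test_missing_inputs_unknown(self):
        assert llps_role(None, self.track([0.9] * 20)) == "unknown"
        assert llps_role(0.4, None) == "unknown"


class TestPPIDR:
    def test_all_zero_highly_ordered(self):
        call = ppidr(ResidueTrack("P", "vsl2", [0.0] * 10))
        assert call.ppidr == 0.0 and call.disorder_class == "highly ordered"

    def test_exactly_half_scores_do_not_count(self):
        assert ppidr(ResidueTrack("P", "vsl2", [0.5] * 10)).ppidr == 0.0  # strict >

    def test_forty_percent_highly_disordered(self):
        call = ppidr(ResidueTrack("P", "vsl2", [0.9] * 4 + [0.1] * 6))
        assert call.ppidr == pytest.approx(40.0)
        assert call.disorder_class == "highly disordered"

    @pytest.mark.parametrize("n_high,cls", [
        (0, "highly ordered"),
        (1, "moderately disordered"),    # 10% -> boundary goes to the middle class
        (3, "moderately disordered"),    # 30%
        (4, "highly disordered"),
    ])
    def test_class_boundaries_on_length_ten(self, n_high, cls):
        track = ResidueTrack("P", "vsl2", [0.9] * n_high + [0.1] * (10 - n_high))
        assert ppidr(track).disorder_class == cls

    def test_invariant_under_score_permutation(self):
        rng = random.Random(0)
        values = [rng.random() for _ in range(50)]
        base = ppidr(ResidueTrack("P", "vsl2", values)).ppidr
        for _ in range(5):
            rng.shuffle(values)
            assert ppidr(ResidueTrack("P", "vsl2", values)).ppidr == base

    def test_role_depends_on_run_structure_unlike_ppidr(self):
        contiguous = [0.7] * 10 + [0.0] * 10
        scattered = [0.7, 0.0] * 10
        assert llps_role(0.4, ResidueTrack("P", "x", contiguous)) == "client"
        assert llps_role(0.4, ResidueTrack("P", "x", scattered)) == "neither"


class TestGravy:
    @pytest.mark.parametrize("seq,value", [
        ("GGGG", -0.4),
        ("III", 4.5),
        ("ACDE", (1.8 + 2.5 - 3.5 - 3.5) / 4),
    ])
    def test_closed_forms(self, seq, value):
        assert gravy(seq) == pytest.approx(value)

    def test_concatenation_is_length_weighted_mean(self):
        a, b = "ACDEFG", "KLMNPQRST"
        combined = gravy(a + b)
        expected = (gravy(a) * len(a) + gravy(b) * len(b)) / (len(a) + len(b))
        assert combined == pytest.approx(expected)

    def test_non_standard_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            gravy("ACXDE")

    def test_matches_biopython(self):
        ProtParam = pytest.importorskip("Bio.SeqUtils.ProtParam")
        for seq in ("MKTAYIAKQR", "GAVLIPFMW", "DDDDKKKK"):
            assert gravy(seq) == pytest.approx(
                ProtParam.ProteinAnalysis(seq).gravy(), abs=1e-9
            )


class TestChargeAtPH:
    def test_monotone_non_increasing_in_ph(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        charges = [charge_at_ph(seq, ph) for ph in [x / 2 for x in range(0, 29)]]
        assert all(a >= b for a, b in zip(charges, charges[1:]))

    def test_single_lysine_at_low_ph_near_plus_two(self):
        # N-terminus and side chain fully protonated, C-terminus mostly neutral
        assert charge_at_ph("K", 1.0) == pytest.approx(2.0, abs=0.01)

    def test_charge_at_isoelectric_point_is_zero(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        pi = brentq(lambda ph: charge_at_ph(seq, ph), 0.0, 14.0, xtol=1e-12)
        assert abs(charge_at_ph(seq, pi)) < 1e-6

    def test_ph_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            charge_at_ph("ACDE", 15.0)


class TestAnnotateHubs:
    def hub_table(self, proteins):
        return HubTable(records=[
            HubRecord(protein=p, qualifying_cores=["C1", "C2", "C3", "C4"], is_hub=True)
            for p in proteins
        ])

    def test_empty_hub_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            annotate_hubs(HubTable(records=[]), ScoreTable(), {}, PTMAnnotation())

    def test_hub_without_scores_is_all_unknown_and_uncounted(self):
        table, summary = annotate_hubs(
            self.hub_table(["P1"]), ScoreTable(), {}, PTMAnnotation()
        )
        row = table.iloc[0]
        assert row["catgranule_label"] == "unknown"
        assert row["combined_label"] == "unknown"
        assert row["role_label"] == "unknown"
        assert row["sumo"] is None
        assert math.isnan(row["ppidr"])
        assert all(v == 0 for v in summary.values())

    def test_summary_counts_match_generator_ledger(self):
        spec = SyntheticSpec(seed=11)
        proteins = [f"HUB{i:03d}" for i in range(1, 62)]
        scores, tracks, ptm, sequences, ledger = gen_tracks_and_scores(spec, proteins)
        _, summary = annotate_hubs(
            self.hub_table(proteins), scores, tracks, ptm, sequences=sequences,
            min_region_length=spec.min_region_length,
        )
        assert summary == ledger["annotation_counts"]

    def test_per_protein_labels_match_ledger(self):
        spec = SyntheticSpec(seed=13)
        proteins = [f"HUB{i:03d}" for i in range(1, 31)]
        scores, tracks, ptm, sequences, ledger = gen_tracks_and_scores(spec, proteins)
        table, _ = annotate_hubs(
            self.hub_table(proteins), scores, tracks, ptm, sequences=sequences,
            min_region_length=spec.min_region_length,
        )
        for _, row in table.iterrows():
            planted = ledger["labels"][row["protein"]]
            assert row["catgranule_label"] == planted["catgranule_label"]
            assert row["psphunter_label"] == planted["psphunter_label"]
            assert row["combined_label"] == planted["combined_label"]
            assert row["role_label"] == planted["role_label"]
            assert row["disorder_class"] == planted["disorder_class"]
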