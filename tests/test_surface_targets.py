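import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from archseek.surface_targets import (
    Loop,
    Topology,
    cascade_filter,
    extract_surface_loops,
    predict_signal_peptide,
    predict_signal_peptide_combined,
    predict_tmh,
)


class TestPredictTmh:
    def test_single_leucine_run_gives_one_helix(self):
        # hand hydropathy profile: windows with >= 10 of the 21 Leu pass 1.6
        seq = "S" * 20 + "L" * 21 + "S" * 20
        topo = predict_tmh(seq)
        assert topo.helices == [(21, 41)]  # the Leu run, within +-2

    def test_acidic_sequence_has_no_helix(self):
        topo = predict_tmh("DE" * 30)
        assert topo.helices == []

    def test_short_sequence_has_no_helix(self):
        assert predict_tmh("LLLLL").helices == []

    def test_positive_inside_rule_n_terminal_basic(self):
        # K/R only before the helix: N side is inside
        seq = "KKRKK" + "S" * 10 + "L" * 21 + "S" * 15
        topo = predict_tmh(seq)
        assert len(topo.helices) == 1
        assert topo.orientation == "N_in"

    def test_positive_inside_rule_c_terminal_basic(self):
        seq = "S" * 15 + "L" * 21 + "S" * 5 + "KKRKK" + "S" * 5
        topo = predict_tmh(seq)
        assert topo.orientation == "N_out"

    def test_tie_defaults_to_n_in(self):
        seq = "S" * 15 + "L" * 21 + "S" * 15
        assert predict_tmh(seq).orientation == "N_in"

    def test_loops_alternate_sides(self):
        seq = "S" * 20 + "L" * 21 + "S" * 25 + "L" * 21 + "S" * 20
        topo = predict_tmh(seq)
        assert len(topo.helices) == 2
        sides = [l.side for l in topo.loops if len(l) > 0]
        assert sides in (["inside", "outside", "inside"],
                         ["outside", "inside", "outside"])

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid residue"):
            predict_tmh("LLLLB" * 10)

    def test_deterministic(self):
        seq = "S" * 10 + "LIVFLIVFLIVFLIVFLIVF" + "KRKR" + "S" * 10
        t1, t2 = predict_tmh(seq), predict_tmh(seq)
        assert t1.helices == t2.helices
        assert t1.orientation == t2.orientation


class TestPredictSignalPeptide:
    def test_classic_tripartite_positive(self):
        seq = "MKK" + "L" * 10 + "ALA" + "S" * 30
        flag, cleavage = predict_signal_peptide(seq, "default")
        assert flag
        assert cleavage == 17  # residue after the A-x-A motif

    def test_no_h_region_negative(self):
        assert predict_signal_peptide("MKK" + "S" * 40, "default") == (False, None)

    def test_no_n_region_negative(self):
        assert predict_signal_peptide("MSS" + "L" * 10 + "ALA" + "S" * 30,
                                      "default") == (False, None)

    def test_short_sequence_negative(self):
        assert predict_signal_peptide("MKKLLLLL", "default") == (False, None)

    def test_combined_or_rule(self):
        # borderline h-region: 7xA + 1xS has mean KD (7*1.8 - 0.8)/8 = 1.475,
        # passing only the loose (1.2) preset
        seq = "MKK" + "AAASAAAA" + "SS" + "ALA" + "S" * 30
        assert not predict_signal_peptide(seq, "strict")[0]
        assert not predict_signal_peptide(seq, "default")[0]
        assert predict_signal_peptide(seq, "loose")[0]
        flag, cleavage = predict_signal_peptide_combined(seq)
        assert flag and cleavage == 17

    def test_unknown_stringency_rejected(self):
        with pytest.raises(ValueError, match="stringency"):
            predict_signal_peptide("M" * 30, "medium")


CASCADE_FIXTURE = pd.DataFrame(
    [
        # 2 soluble ORFs: removed at step 1
        dict(orf_id="sol1", tmh_count=0, sp_flag=False, top_hit_group="methanogen",
             is_transposase=False, is_adhesin=False, conservation_count=3),
        dict(orf_id="sol2", tmh_count=0, sp_flag=False, top_hit_group="methanogen",
             is_transposase=False, is_adhesin=False, conservation_count=3),
        # transposase, adhesin, non-methanogen top hit: removed at step 2
        dict(orf_id="tnp", tmh_count=2, sp_flag=False, top_hit_group="methanogen",
             is_transposase=True, is_adhesin=False, conservation_count=3),
        dict(orf_id="adh", tmh_count=1, sp_flag=True, top_hit_group="methanogen",
             is_transposase=False, is_adhesin=True, conservation_count=3),
        dict(orf_id="xen", tmh_count=3, sp_flag=False, top_hit_group="other",
             is_transposase=False, is_adhesin=False, conservation_count=3),
        # 3 qualifying ORFs with 2 / 4 / 6 TMH
        dict(orf_id="q2", tmh_count=2, sp_flag=False, top_hit_group="methanogen",
             is_transposase=False, is_adhesin=False, conservation_count=3),
        dict(orf_id="q4", tmh_count=4, sp_flag=True, top_hit_group="methanogen",
             is_transposase=False, is_adhesin=False, conservation_count=3),
        dict(orf_id="q6", tmh_count=6, sp_flag=False, top_hit_group="methanogen",
             is_transposase=False, is_adhesin=False, conservation_count=3),
    ]
)


class TestCascade:
    def test_hand_traced_fixture(self):
        report = cascade_filter(CASCADE_FIXTURE, min_conservation=2, panel_size=3)
        assert report.step_counts == [
            ("input", 8),
            ("membrane_or_sp", 6),
            ("specific", 3),
            ("conserved", 3),
        ]
        assert report.group_a == ["q2", "q4"]
        assert report.group_b == ["q6"]

    def test_five_tmh_survivor_lands_in_group_b(self):
        report = cascade_filter(CASCADE_FIXTURE.assign(
            tmh_count=CASCADE_FIXTURE["tmh_count"].replace({6: 5})
        ), min_conservation=2, panel_size=3)
        assert report.group_b == ["q6"]  # 5 TMH: more than 4

    def test_every_removed_orf_has_exactly_one_reason(self):
        report = cascade_filter(CASCADE_FIXTURE, min_conservation=2, panel_size=3)
        removed = report.audit[report.audit["status"] == "removed"]
        assert len(removed) == 5
        assert (removed["reason"] != "").all()
        assert removed["orf_id"].is_unique

    def test_negative_tmh_rejected(self):
        bad = CASCADE_FIXTURE.copy()
        bad.loc[0, "tmh_count"] = -1
        with pytest.raises(ValueError, match="negative tmh_count"):
            cascade_filter(bad, 1, 1)

    def test_conservation_threshold_bounded_by_panel(self):
        with pytest.raises(ValueError, match="panel_size"):
            cascade_filter(CASCADE_FIXTURE, min_conservation=5, panel_size=3)

    @given(data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_counts_monotone_and_groups_partition(self, data):
        n = data.draw(st.integers(min_value=1, max_value=25))
        rows = []
        for i in range(n):
            rows.append(
                dict(
                    orf_id=f"o{i}",
                    tmh_count=data.draw(st.integers(min_value=0, max_value=9)),
                    sp_flag=data.draw(st.booleans()),
                    top_hit_group=data.draw(
                        st.sampled_from(["methanogen", "other", "none"])
                    ),
                    is_transposase=data.draw(st.booleans()),
                    is_adhesin=data.draw(st.booleans()),
                    conservation_count=data.draw(st.integers(min_value=0, max_value=5)),
                )
            )
        report = cascade_filter(pd.DataFrame(rows), min_conservation=2, panel_size=5)
        counts = [c for _, c in report.step_counts]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        final = counts[-1]
        assert len(report.group_a) + len(report.group_b) == final
        assert not set(report.group_a) & set(report.group_b)
        removed = report.audit[report.audit["status"] == "removed"]
        assert len(removed) == counts[0] - final


class TestExtractLoops:
    def _topology(self, helices, loops, orientation="N_in"):
        return Topology(
            helices=helices,
            orientation=orientation,
            loops=[Loop(*l) for l in loops],
            n_residues=loops[-1][1],
        )

    def test_two_helix_n_in_returns_interhelix_loop(self):
        seq = "X" * 100
        topo = self._topology(
            [(11, 30), (51, 70)],
            [(1, 10, "inside"), (31, 50, "outside"), (71, 100, "inside")],
        )
        loops = extract_surface_loops(seq, topo)
        assert [(l.start, l.end) for l in loops] == [(31, 50)]

    def test_n_out_symmetry_returns_tails_only(self):
        seq = "X" * 100
        topo = self._topology(
            [(11, 30), (51, 70)],
            [(1, 10, "outside"), (31, 50, "inside"), (71, 100, "outside")],
            orientation="N_out",
        )
        loops = extract_surface_loops(seq, topo)
        assert [(l.start, l.end) for l in loops] == [(1, 10), (71, 100)]

    def test_length_bounds_select_single_loop(self):
        # outside loop lengths 5 / 20 / 50: only the 20-mer qualifies
        seq = "A" * 200
        topo = self._topology(
            [(6, 25), (31, 50), (71, 90), (141, 160)],
            [
                (1, 5, "outside"),
                (26, 30, "inside"),
                (51, 70, "outside"),
                (91, 140, "inside"),
                (161, 200, "outside"),  # 40 residues: at the bound
            ],
        )
        loops = extract_surface_loops(seq, topo, l_min=8, l_max=30)
        assert [(l.start, l.end) for l in loops] == [(51, 70)]

    def test_peptide_sequence_matches_coordinates(self):
        seq = "".join(chr(ord("A") + (i % 20)) for i in range(60))
        seq = "MKTLIVFAGSDE" * 5
        topo = self._topology(
            [(11, 30)], [(1, 10, "outside"), (31, 60, "inside")]
        )
        loops = extract_surface_loops(seq, topo)
        assert loops[0].sequence == seq[0:10]
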