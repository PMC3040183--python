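import numpy as np
import pytest

from mgcnet.network import (ConductanceSet, NetworkSpec, Cell, Synapse,
                            build_elementary, build_stacked, build_grouped,
                            TABLE1_CONDUCTANCES, E_REV_INH)
from mgcnet.synapses import SynapseParams

G = TABLE1_CONDUCTANCES[1000]


class TestElementary:
    def test_cell_and_synapse_counts(self):
        spec = build_elementary(G)
        assert spec.n_cells == 7            # 2 compound ORNs + 5 HH cells
        assert len(spec.synapses) == 12

    def test_zeroing_inter_ln_removes_six_weighted_edges(self):
        full = build_elementary(G)
        zeroed = build_elementary(ConductanceSet(G.g_orn_lnsp, G.g_orn_lngen,
                                                 0.0, 0.0, 0.0))
        assert (len(full.positive_weight_synapses())
                - len(zeroed.positive_weight_synapses())) == 6

    def test_compound_rate_is_rate_times_convergence(self):
        spec = build_elementary(G, convergence=1000)
        src = spec.orn_sources[0]
        assert src.n_orn * 0.01 == pytest.approx(10.0)

    def test_spontaneous_cells_are_lni_and_pn(self):
        spec = build_elementary(G)
        driven = {c.name for c in spec.cells if c.i_inj > 0}
        assert driven == {"LNi", "PN"}

    def test_synapse_sign_conventions(self):
        spec = build_elementary(G)
        for syn in spec.synapses:
            if syn.pre.startswith("ORN"):
                assert syn.params.e_rev == 0.0
            else:
                assert syn.params.e_rev == E_REV_INH

    def test_symmetry_of_specialist_drive(self):
        spec = build_elementary(G)
        g_by_edge = {(s.pre, s.post): s.params.g for s in spec.synapses}
        assert g_by_edge["ORNa", "LNa"] == g_by_edge["ORNb", "LNb"]
        assert g_by_edge["ORNa", "LNc"] == g_by_edge["ORNb", "LNc"]


class TestStacked:
    def test_single_unit_degenerates_to_elementary(self):
        assert build_stacked(1, G).arrangement == "elementary"

    def test_ten_units_share_one_lni_and_pn(self):
        spec = build_stacked(10, G)
        lns = [c for c in spec.cells if c.role == "LN"]
        assert len(lns) == 30
        assert sum(c.role == "LNi" for c in spec.cells) == 1
        assert sum(c.role == "PN" for c in spec.cells) == 1

    def test_units_are_mutually_isolated(self):
        spec = build_stacked(10, G)
        for syn in spec.synapses:
            if syn.pre.startswith("LN") and syn.post.startswith("LN") \
                    and syn.post != "LNi":
                assert syn.pre.rsplit("_", 1)[-1] == syn.post.rsplit("_", 1)[-1]

    def test_lnc_lni_conductance_downscaled_by_units(self):
        spec = build_stacked(10, G)
        g_edges = [s.params.g for s in spec.synapses if s.post == "LNi"]
        assert len(g_edges) == 10
        assert all(g == pytest.approx(G.g_lnc_lni / 10) for g in g_edges)


class TestGrouped:
    def test_single_ln_degenerates_to_elementary(self):
        assert build_grouped(1, G).arrangement == "elementary"

    def test_inter_glomerular_synapse_count(self):
        spec = build_grouped(10, G)
        inter = [s for s in spec.synapses
                 if s.pre.startswith("LN") and s.post.startswith("LN")
                 and s.post != "LNi"]
        assert len(inter) == 600   # 3 glomerulus pairs × 10×10 × 2 directions

    def test_no_within_glomerulus_inhibition_by_default(self):
        spec = build_grouped(10, G)
        for syn in spec.synapses:
            if syn.pre.startswith("LN") and syn.post.startswith("LN") \
                    and syn.post != "LNi":
                assert syn.pre[2] != syn.post[2]  # group letters differ

    def test_downscaling_conserves_total_rival_inhibition(self):
        """Total inhibitory conductance onto one LN from a rival glomerulus
        equals the elementary single-synapse value."""
        elem = build_elementary(G)
        g_elem = next(s.params.g for s in elem.synapses
                      if s.pre == "LNa" and s.post == "LNc")
        spec = build_grouped(10, G)
        total = sum(s.params.g for s in spec.synapses
                    if s.pre.startswith("LNa") and s.post == "LNc_0")
        assert total == pytest.approx(g_elem)

    def test_orn_drive_per_ln_kept_at_full_strength(self):
        spec = build_grouped(10, G)
        orn_edges = [s.params.g for s in spec.synapses if s.pre.startswith("ORN")]
        assert set(np.round(orn_edges, 6)) == {G.g_orn_lnsp, G.g_orn_lngen}

    def test_within_group_option_adds_edges(self):
        base = build_grouped(5, G)
        within = build_grouped(5, G, within_group_inhibition=True)
        assert len(within.synapses) - len(base.synapses) == 3 * 5 * 4


class TestValidation:
    def test_feedback_edge_rejected(self):
        spec = build_elementary(G)
        spec.synapses.append(Synapse("PN", "LNa",
                                     SynapseParams(e_rev=E_REV_INH)))
        with pytest.raises(ValueError, match="PN"):
            spec.validate()

    def test_excitatory_inter_ln_rejected(self):
        spec = build_elementary(G)
        spec.synapses.append(Synapse("LNa", "LNb", SynapseParams(e_rev=0.0)))
        with pytest.raises(ValueError, match="inhibitory"):
            spec.validate()

    def test_orn_to_pn_rejected(self):
        spec = build_elementary(G)
        spec.synapses.append(Synapse("ORNa", "PN", SynapseParams(e_rev=0.0)))
        with pytest.raises(ValueError, match="ORN"):
            spec.validate()

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            ConductanceSet(-0.1, 0.1, 0.1, 0.1, 0.1)

    def test_free_vector_round_trip(self):
        v = G.as_free_vector()
        assert ConductanceSet.from_free_vector(v).as_free_vector() == pytest.approx(v)


class TestSerialization:
    @pytest.mark.parametrize("builder", [
        lambda: build_elementary(G),
        lambda: build_stacked(3, G),
        lambda: build_grouped(3, G),
    ])
    def test_json_round_trip_lossless(self, builder):
        spec = builder()
        again = NetworkSpec.from_json(spec.to_json())
        assert again.arrangement == spec.arrangement
        assert again.orn_sources == spec.orn_sources
        assert again.cells == spec.cells
        assert again.synapses == spec.synapses
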