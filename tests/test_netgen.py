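"""Topology generation: probability rules, E/I assignment, serialization."""

import numpy as np
import pytest
from scipy import stats

from biosnn.hh_core import ConfigError
from biosnn.netgen import (
    MAX_NEURONS,
    SYNAPSE_CAPACITY,
    CapacityError,
    TopologySpec,
    apply_antagonist,
    export_adjacency_mtx,
    export_edge_list,
    generate,
    load_network,
    network_from_dict,
    network_to_dict,
    prob_external,
    prob_internal,
    save_network,
    synapse_capacity,
)


class TestProbabilityRules:
    def test_internal_at_zero_distance_is_p_max(self):
        assert prob_internal(0.0, r_org=2.0, p_max=0.1) == pytest.approx(0.1)

    def test_internal_at_radius_is_zero(self):
        assert prob_internal(2.0, r_org=2.0, p_max=0.1) == pytest.approx(0.0)

    def test_internal_midpoint_substitution(self):
        assert prob_internal(1.0, r_org=2.0, p_max=0.10) == pytest.approx(0.05)

    def test_internal_clamps_beyond_radius(self):
        assert prob_internal(5.0, r_org=2.0, p_max=0.1) == 0.0

    def test_external_at_centers_is_zero(self):
        assert prob_external(0.0, 2.0, 0.0, 2.0, p_max=0.02) == pytest.approx(0.0)

    def test_external_on_both_rims_is_p_max(self):
        assert prob_external(2.0, 2.0, 2.0, 2.0, p_max=0.02) == pytest.approx(0.02)

    def test_external_mixed_rim_center(self):
        assert prob_external(2.0, 2.0, 0.0, 2.0, p_max=0.02) == pytest.approx(0.01)


class TestGenerate:
    def test_zero_probability_gives_zero_synapses(self):
        spec = TopologySpec(
            variant="organoid_single", n_per_group=32, p_max_internal=0.0, seed=1
        )
        assert len(generate(spec).synapses) == 0

    def test_reproducible_from_seed(self):
        spec = TopologySpec(variant="organoid_connected", n_per_group=32, seed=9)
        a, b = generate(spec), generate(spec)
        assert network_to_dict(a) == network_to_dict(b)

    def test_exact_inhibitory_counts(self):
        spec = TopologySpec(variant="organoid_single", n_per_group=50, ei_ratio=0.2, seed=3)
        net = generate(spec)
        for g in (0, 1):
            members = [i for i, p in enumerate(net.placements) if p.group_id == g]
            n_fs = sum(1 for i in members if net.presets[i] == "FS")
            assert n_fs == round(0.2 * len(members))

    def test_inhibitory_sources_emit_gabaa_only(self):
        spec = TopologySpec(variant="organoid_connected", n_per_group=48, seed=5)
        net = generate(spec)
        for e in net.synapses.entries:
            expected = "GABA_A" if net.presets[e.pre] == "FS" else "AMPA"
            assert e.kind == expected

    def test_neuron_capacity_enforced(self):
        with pytest.raises(CapacityError):
            generate(TopologySpec(variant="organoid_single", n_per_group=600, seed=1))

    def test_connection_frequency_matches_distance_rule(self):
        # empirical frequencies over 40 seeds vs the linear rule, binned by
        # distance, within 3 Monte-Carlo standard errors
        n_hit = np.zeros(4)
        n_tot = np.zeros(4)
        edges = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        for seed in range(40):
            spec = TopologySpec(
                variant="organoid_single", n_per_group=64, n_groups=1, seed=seed
            )
            net = generate(spec)
            xy = net.positions()
            d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
            conn = np.zeros_like(d, dtype=bool)
            for e in net.synapses.entries:
                conn[e.pre, e.post] = True
            mask = ~np.eye(len(xy), dtype=bool)
            which = np.digitize(d[mask], edges) - 1
            ok = (which >= 0) & (which < 4)
            np.add.at(n_tot, which[ok], 1)
            np.add.at(n_hit, which[ok], conn[mask][ok])
        centers = (edges[:-1] + edges[1:]) / 2
        # expected probability at the bin center (rule is linear in d)
        for k in range(4):
            p_exp = 0.10 * (1 - centers[k] / 2.0)
            p_obs = n_hit[k] / n_tot[k]
            se = np.sqrt(p_exp * (1 - p_exp) / n_tot[k])
            assert abs(p_obs - p_exp) < 3 * se + 0.004  # + linearity-vs-binning slack


class TestClusteredVariant:
    def test_intra_cluster_density_exceeds_inter(self):
        spec = TopologySpec(
            variant="clustered",
            n_per_group=32,
            n_clusters=4,
            p_max_internal=0.3,
            p_max_external=0.01,
            seed=8,
        )
        net = generate(spec)
        groups = net.group_ids()
        intra = inter = 0
        for e in net.synapses.entries:
            if groups[e.pre] == groups[e.post]:
                intra += 1
            else:
                inter += 1
        n_per = 32
        intra_pairs = 4 * n_per * (n_per - 1)
        inter_pairs = (4 * n_per) ** 2 - intra_pairs - 4 * n_per
        assert intra / intra_pairs > inter / inter_pairs

class TestAntagonist:
    @pytest.fixture
    def net(self):
        return generate(TopologySpec(variant="organoid_connected", n_per_group=64, seed=11))

    def test_zero_fraction_is_identity(self, net):
        out = apply_antagonist(net, "AMPA", 0.0)
        assert len(out.synapses) == len(net.synapses)

    def test_full_ampa_block_leaves_gabaa_untouched(self, net):
        out = apply_antagonist(net, "AMPA", 1.0)
        assert len(out.synapses.by_kind("AMPA")) == 0
        assert len(out.synapses.by_kind("GABA_A")) == len(net.synapses.by_kind("GABA_A"))
        # original unmodified
        assert len(net.synapses.by_kind("AMPA")) > 0

    def test_half_block_within_binomial_interval(self, net):
        n0 = len(net.synapses.by_kind("AMPA"))
        removed = n0 - len(apply_antagonist(net, "AMPA", 0.5, seed=2).synapses.by_kind("AMPA"))
        lo, hi = stats.binom.ppf([0.005, 0.995], n0, 0.5)
        assert lo <= removed <= hi

    def test_unknown_kind_rejected(self, net):
        with pytest.raises(ConfigError):
            apply_antagonist(net, "DOPAMINE", 0.5)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        net = generate(TopologySpec(variant="organoid_connected", n_per_group=32, seed=4))
        path = tmp_path / "net.json"
        save_network(net, path)
        back = load_network(path)
        assert network_to_dict(back) == network_to_dict(net)

    def test_schema_version_checked(self):
        with pytest.raises(ConfigError):
            network_from_dict({"schema_version": 99})

    def test_exports_exist_and_parse(self, tmp_path):
        net = generate(TopologySpec(variant="organoid_single", n_per_group=32, seed=4))
        export_edge_list(net, tmp_path / "edges.csv")
        export_adjacency_mtx(net, tmp_path / "adj.mtx")
        lines = (tmp_path / "edges.csv").read_text().splitlines()
        assert lines[0] == "pre,post,kind,weight_code,weight"
        assert len(lines) - 1 == len(net.synapses)
        from scipy import io as spio

        mat = spio.mmread(tmp_path / "adj.mtx")
        assert mat.shape == (64, 64)
        assert mat.nnz == len(net.synapses)


def test_capacity_arithmetic():
    assert synapse_capacity(MAX_NEURONS) == SYNAPSE_CAPACITY == 2**20
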