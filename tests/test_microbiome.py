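"""Case/control enrichment, co-abundance networks and mapping ratios."""

import numpy as np
import pandas as pd
import pytest

from panprobio import microbiome as mb
from panprobio.simulate import BlockSpec, sim_abundance

from conftest import pearson_oracle


def small_table(rng, n=30, n_species=8, shift_species=None, fold=4.0):
    samples = [f"case_{i}" for i in range(n)] + [f"ctrl_{i}" for i in range(n)]
    groups = pd.Series(["case"] * n + ["control"] * n, index=samples)
    x = np.exp(rng.normal(0, 1, size=(2 * n, n_species)))
    if shift_species is not None:
        x[:n, shift_species] *= fold
    x = 100 * x / x.sum(axis=1, keepdims=True)
    data = pd.DataFrame(x, index=samples,
                        columns=[f"sp{i}" for i in range(n_species)])
    return mb.AbundanceTable(data, groups)


class TestDifferentialEnrichment:
    def test_planted_shift_detected_with_direction(self, rng):
        table = small_table(rng, n=50, shift_species=0)
        calls = {c.species: c for c in mb.differential_enrichment(table)}
        assert calls["sp0"].q < 0.05
        assert calls["sp0"].direction == "case_enriched"

    def test_identical_groups_all_ns(self, rng):
        data = pd.DataFrame(rng.uniform(0, 10, size=(20, 5)),
                            index=[f"s{i}" for i in range(20)],
                            columns=[f"sp{i}" for i in range(5)])
        data = 100 * data.div(data.sum(axis=1), axis=0)
        # mirrored samples: case i and control i share the same profile
        data.iloc[10:] = data.iloc[:10].to_numpy()
        groups = pd.Series(["case"] * 10 + ["control"] * 10, index=data.index)
        calls = mb.differential_enrichment(mb.AbundanceTable(data, groups))
        assert all(c.direction == "ns" for c in calls)

    def test_all_zero_species_skipped(self, rng):
        table = small_table(rng, n=10)
        table.data["ghost"] = 0.0
        calls = mb.differential_enrichment(table)
        assert "ghost" not in {c.species for c in calls}

    def test_label_permuted_null_yields_no_bh_calls(self, rng):
        """Null data, 200 species: ~5% raw p < 0.05 and ~no q < 0.05."""
        table = small_table(rng, n=40, n_species=200)
        calls = mb.differential_enrichment(table)
        raw_rate = np.mean([c.p < 0.05 for c in calls])
        assert raw_rate < 0.12
        assert sum(c.direction != "ns" for c in calls) <= 2

    def test_q_never_below_p(self, rng):
        calls = mb.differential_enrichment(small_table(rng, n=15))
        assert all(c.q >= c.p - 1e-12 for c in calls)


class TestNetworkRules:
    @pytest.mark.parametrize("cc, expected", [
        (0.75, "thick"), (0.7, "thick"), (0.5, "medium"), (0.4, "medium"),
        (-0.2, "thin"), (-0.11, "thin"), (0.39, "thin"), (-0.05, "none"),
    ])
    def test_edge_width_bins(self, cc, expected):
        assert mb.edge_width_category(cc) == expected

    @pytest.mark.parametrize("frac, expected", [
        (0.2, "1/10"), (0.1, "1/10"), (0.05, "1/100"), (0.002, "1/1000"),
        (1e-6, "1/10^6"), (9e-7, "<1/10^6"), (0.0, "<1/10^6"),
    ])
    def test_abundance_decade_bins(self, frac, expected):
        assert mb.abundance_decade_bin(frac) == expected

    def test_every_edge_satisfies_inclusion_rule(self, rng):
        table, truth = sim_abundance(n_case=60, n_control=60, n_species=60,
                                     n_enriched=10, seed=21)
        calls = mb.differential_enrichment(table)
        net = mb.build_coabundance_network(table, calls)
        for row in net.edges.itertuples():
            cc, p = mb.pearson(table.data[row.a], table.data[row.b])
            assert cc == pytest.approx(row.cc)
            assert p < 0.05
            assert cc > 0.4 or cc < -0.1
            assert mb.edge_width_category(cc) == row.width

    def test_network_invariant_to_sample_and_species_order(self, rng):
        table, _ = sim_abundance(n_case=40, n_control=40, n_species=40,
                                 n_enriched=8, block_spec=BlockSpec(4, 0.8),
                                 seed=22)
        calls = mb.differential_enrichment(table)
        net1 = mb.build_coabundance_network(table, calls)
        shuffled = mb.AbundanceTable(
            table.data.sample(frac=1, random_state=1).iloc[:, ::-1],
            table.groups, scale=table.scale)
        net2 = mb.build_coabundance_network(shuffled, calls)
        key = lambda df: sorted(map(tuple, df[["a", "b"]].to_numpy()))  # noqa: E731
        assert key(net1.edges) == key(net2.edges)

    def test_planted_block_recovery(self):
        """A planted 5-species correlated block (target cc 0.8) is fully
        recovered at 200 samples with few spurious edges."""
        table, truth = sim_abundance(n_case=100, n_control=100, seed=23,
                                     block_spec=BlockSpec(5, 0.8))
        calls = mb.differential_enrichment(table)
        net = mb.build_coabundance_network(table, calls)
        planted = {tuple(e) for e in truth.truth["expected_edges"]}
        found = {tuple(sorted((r.a, r.b))) for r in net.edges.itertuples()}
        assert len(planted & found) / len(planted) >= 0.95
        nodes = len(net.nodes)
        non_planted_pairs = nodes * (nodes - 1) // 2 - len(planted)
        assert len(found - planted) <= 0.05 * non_planted_pairs

    def test_top10_flags_stable_sorted(self, rng):
        table, _ = sim_abundance(n_case=60, n_control=60, n_species=80,
                                 n_enriched=16, seed=24)
        calls = mb.differential_enrichment(table)
        net = mb.build_coabundance_network(table, calls)
        nodes = net.nodes.set_index("species")
        by_deg = sorted(nodes.index, key=lambda s: (-nodes.loc[s, "degree"], s))
        assert set(nodes.index[nodes["top10_degree"]]) == set(by_deg[:10])


class TestMappingRatio:
    def test_ratio_definition(self):
        mapped = pd.DataFrame({"spX": [500, 250]}, index=["s1", "s2"])
        totals = pd.Series([1000, 1000], index=["s1", "s2"])
        groups = pd.Series(["case", "control"], index=["s1", "s2"])
        out = mb.mapping_ratio_compare(mapped, totals, groups)
        assert out.iloc[0]["mean_case"] == pytest.approx(0.5)
        assert out.iloc[0]["mean_control"] == pytest.approx(0.25)

    def test_planted_shift_significant(self, rng):
        n = 30
        idx = [f"s{i}" for i in range(2 * n)]
        groups = pd.Series(["case"] * n + ["control"] * n, index=idx)
        totals = pd.Series(1_000_000, index=idx)
        base = rng.normal(0.10, 0.01, 2 * n)
        base[:n] *= 2  # cases map twice as well
        mapped = pd.DataFrame({"spX": (base * totals).astype(int)}, index=idx)
        out = mb.mapping_ratio_compare(mapped, totals, groups)
        assert out.iloc[0]["q"] < 0.05 and out.iloc[0]["direction"] == "case"

    def test_identical_ratios_ns(self):
        idx = ["a", "b", "c", "d"]
        out = mb.mapping_ratio_compare(
            pd.DataFrame({"spX": [100, 100, 100, 100]}, index=idx),
            pd.Series([1000] * 4, index=idx),
            pd.Series(["case", "case", "control", "control"], index=idx))
        assert out.iloc[0]["direction"] == "ns"

    def test_mapped_exceeding_total_rejected(self):
        idx = ["a", "b"]
        with pytest.raises(ValueError):
            mb.mapping_ratio_compare(
                pd.DataFrame({"spX": [2000, 10]}, index=idx),
                pd.Series([1000, 1000], index=idx),
                pd.Series(["case", "control"], index=idx))


class TestMetaphlanParser:
    def test_species_rows_selected(self):
        profiles = pd.DataFrame(
            {"s1": [90.0, 60.0, 30.0, 60.0], "s2": [80.0, 50.0, 30.0, 50.0]},
            index=["k__Bacteria",
                   "k__Bacteria|g__Lacto",
                   "k__Bacteria|g__Lacto|s__Lacto_casei",
                   "k__Bacteria|g__Lacto|s__Lacto_casei|t__GCF_1"])
        meta = pd.DataFrame({"sample_id": ["s1", "s2"],
                             "group": ["case", "control"]})
        table = mb.read_metaphlan_profiles(profiles, meta)
        assert list(table.data.columns) == ["Lacto_casei"]
        assert table.data.loc["s1", "Lacto_casei"] == 30.0
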