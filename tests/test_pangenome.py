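"""Pan-genome clustering, partition, rarefaction, PI and its correlates."""

import numpy as np
import pytest

from panprobio import pangenome as pg
from panprobio.simulate import _mutate_protein, _random_protein, sim_pangenome

from conftest import pearson_oracle


def greedy_oracle(proteins, identity=0.95, coverage=0.90):
    """Independent greedy clustering: same contract, naive all-pairs loop
    (no prefilter), reusing only the public threshold predicate."""
    items = [(g, gene, seq) for g in proteins for gene, seq in proteins[g].items()]
    items.sort(key=lambda t: (-len(t[2]), t[0], t[1]))
    reps, assign = [], []
    for g, gene, seq in items:
        for fi, rep in enumerate(reps):
            if pg.meets_family_thresholds(seq, rep, identity, coverage):
                assign.append((fi, (g, gene)))
                break
        else:
            reps.append(seq)
            assign.append((len(reps) - 1, (g, gene)))
    out = {}
    for fi, member in assign:
        out.setdefault(fi, set()).add(member)
    return {frozenset(m) for m in out.values()}


def family_partition(families):
    return {frozenset(f.members) for f in families}


class TestClustering:
    def test_identical_proteins_one_family(self, rng):
        seq = _random_protein(rng, 120)
        fams = pg.cluster_gene_families({"a": {"g1": seq}, "b": {"g1": seq}})
        assert len(fams) == 1 and len(fams[0].members) == 2

    def test_distant_proteins_separate_families(self, rng):
        fams = pg.cluster_gene_families(
            {"a": {"g1": _random_protein(rng, 120)},
             "b": {"g1": _random_protein(rng, 120)}})
        assert len(fams) == 2

    def test_coverage_rule_prefix_match(self, rng):
        """A 100-aa protein identical to the first 80 aa of a 200-aa
        representative fails the 90%-of-shorter coverage rule."""
        rep = _random_protein(rng, 200)
        short = rep[:80] + _random_protein(rng, 20)
        fams = pg.cluster_gene_families({"a": {"long": rep}, "b": {"short": short}})
        assert len(fams) == 2

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        """Greedy result with the k-mer prefilter equals the naive all-pairs
        greedy oracle."""
        for _ in range(15):
            n = int(rng.integers(5, 30))
            base = [_random_protein(rng, int(rng.integers(60, 140)))
                    for _ in range(max(2, n // 3))]
            proteins = {"g0": {}, "g1": {}, "g2": {}}
            for i in range(n):
                src = base[int(rng.integers(len(base)))]
                seq = _mutate_protein(rng, src, 0.01, 0.02)
                proteins[f"g{int(rng.integers(3))}"][f"gene{i:03d}"] = seq
            proteins = {g: d for g, d in proteins.items() if d}
            fams = pg.cluster_gene_families(proteins)
            assert family_partition(fams) == greedy_oracle(proteins)

    def test_every_gene_in_exactly_one_family(self, rng):
        proteins, _ = sim_pangenome(n_genomes=4, core_size=15,
                                    accessory_pool=20, accessory_rate=0.4, seed=9)
        fams = pg.cluster_gene_families(proteins)
        members = [m for f in fams for m in f.members]
        assert len(members) == len(set(members)) == sum(len(d) for d in proteins.values())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pg.cluster_gene_families({})


class TestPartition:
    def test_three_way_partition(self):
        pan = pg.build_pangenome(family_sets={"A": {"f1", "f2"}, "B": {"f1", "f3"}})
        core, accessory, specific = pg.partition_families(pan)
        assert core == ["f1"]
        assert sorted(specific) == ["f2", "f3"]
        assert accessory == []

    def test_partition_is_disjoint_cover(self, rng):
        sets = {f"g{i}": set(rng.choice(50, size=20, replace=False).astype(str))
                for i in range(5)}
        pan = pg.build_pangenome(family_sets=sets)
        core, accessory, specific = pg.partition_families(pan)
        all_ids = set(core) | set(accessory) | set(specific)
        assert all_ids == set(pan.membership.columns)
        assert len(core) + len(accessory) + len(specific) == len(all_ids)


class TestRarefaction:
    def test_identical_genomes_flat_curves(self):
        sets = {f"g{i}": {"f1", "f2", "f3"} for i in range(4)}
        pan = pg.build_pangenome(family_sets=sets)
        df = pg.rarefaction_curves(pan, n_permutations=10, seed=0)
        assert (df["pan_mean"] == 3).all() and (df["core_mean"] == 3).all()

    def test_disjoint_genomes_linear_pan(self):
        sets = {f"g{i}": {f"g{i}_f{j}" for j in range(5)} for i in range(4)}
        pan = pg.build_pangenome(family_sets=sets)
        df = pg.rarefaction_curves(pan, n_permutations=5, seed=0)
        np.testing.assert_allclose(df["pan_mean"], 5 * df["k"])

    def test_monotonicity(self, rng):
        sets = {f"g{i}": set(rng.choice(40, size=15, replace=False).astype(str))
                for i in range(6)}
        pan = pg.build_pangenome(family_sets=sets)
        df = pg.rarefaction_curves(pan, n_permutations=20, seed=1)
        assert (np.diff(df["pan_mean"]) >= 0).all()
        assert (np.diff(df["core_mean"]) <= 0).all()


class TestPanIndex:
    def test_identical_genomes_pi_one(self):
        pan = pg.build_pangenome(family_sets={"a": {"f1", "f2"}, "b": {"f1", "f2"}})
        idx = pg.pan_genome_index(pan)
        assert idx.pi == pytest.approx(1.0) and idx.level == "A"

    def test_forced_by_definition(self):
        pan = pg.build_pangenome(
            family_sets={"A": {"a", "b", "c"}, "B": {"a", "b", "d"}})
        idx = pg.pan_genome_index(pan)
        assert idx.pi == pytest.approx(4 / 3)
        assert idx.level == "A"

    @pytest.mark.parametrize("pi, level", [
        (1.5, "A"), (1.51, "B"), (3.0, "B"), (3.01, "C"), (4.19, "C"),
    ])
    def test_level_bins(self, pi, level):
        assert pg._pi_level(pi) == level

    def test_empty_genome_rejected(self):
        pan = pg.build_pangenome(family_sets={"a": {"f1"}, "b": set()})
        with pytest.raises(ValueError):
            pg.pan_genome_index(pan)

    def test_subset_monotone_under_pure_family_addition(self):
        """Adding a genome that only adds new families cannot lower PI."""
        base = {"a": {"f1", "f2"}, "b": {"f1", "f2", "f3"}}
        extended = dict(base, c={"f1", "f2", "f3", "f4", "f5"})
        pi_base = pg.pan_genome_index(pg.build_pangenome(family_sets=base)).pi
        pi_ext = pg.pan_genome_index(pg.build_pangenome(family_sets=extended)).pi
        assert pi_ext >= pi_base


class TestOpennessCorrelates:
    def test_perfect_linear_factor(self):
        pi = {f"s{i}": 1.0 + 0.5 * i for i in range(6)}
        src = {f"s{i}": float(i) for i in range(6)}
        gen = {f"s{i}": 10.0 for i in range(6)}  # constant -> excluded
        sd = {f"s{i}": float(i % 3) for i in range(6)}
        out = pg.openness_correlates(pi, src, gen, sd)
        assert out["per_factor"]["source_count"]["r2"] == pytest.approx(1.0)
        assert out["per_factor"]["genome_count"]["constant"]
        assert "genome_count" not in out["combined"]["factors"]
        assert out["combined"]["r2"] == pytest.approx(1.0)

    def test_single_factor_r2_equals_squared_pearson(self):
        pi = {"a": 1.2, "b": 2.0, "c": 2.8, "d": 4.1, "e": 1.9}
        sd = {"a": 0.5, "b": 1.1, "c": 1.0, "d": 2.2, "e": 0.8}
        src = {k: 1.0 for k in pi}
        gen = {k: 1.0 for k in pi}
        out = pg.openness_correlates(pi, src, gen, sd)
        keys = sorted(pi)
        cc = pearson_oracle([sd[k] for k in keys], [pi[k] for k in keys])
        assert out["per_factor"]["aai_sd"]["cc"] == pytest.approx(cc)
        assert out["per_factor"]["aai_sd"]["r2"] == pytest.approx(cc ** 2)
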