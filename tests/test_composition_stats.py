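import math

import numpy as np
import pytest
from scipy import stats as sps

from protexp import composition_stats as cs
from protexp.io_formats import STANDARD_AA, CostTable, PropertyIndex, read_cost_table
from protexp.synthetic_fixtures import PlantedExpressionSpec, gen_expression_dataset

from conftest import make_labeled_dataset


def uniform_aei(value=1.0, species="sp"):
    return cs.AEITable(species_id=species, aei={aa: value for aa in STANDARD_AA})


class TestFrequencies:
    def test_simple_counting(self):
        f = cs.aa_frequencies("AAG")
        assert f[STANDARD_AA.index("A")] == pytest.approx(2 / 3)
        assert f[STANDARD_AA.index("G")] == pytest.approx(1 / 3)
        assert f.sum() == pytest.approx(1.0)

    def test_nonstandard_excluded_from_denominator(self):
        f = cs.aa_frequencies("AXA")
        assert f[STANDARD_AA.index("A")] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.aa_frequencies("")
        with pytest.raises(ValueError):
            cs.aa_frequencies("XXX")


class TestAEI:
    def test_identical_classes_give_unity(self):
        seqs = ["ACDEFGHIKLMNPQRSTVWY"] * 3
        ds = make_labeled_dataset(seqs, seqs)
        table = cs.compute_aei(ds)
        for aa in STANDARD_AA:
            assert table[aa] == pytest.approx(1.0)

    def test_hand_counted_example(self):
        # high mean freq: A=2/3, G=1/3 ; low: A=1/3, G=2/3
        ds = make_labeled_dataset(["AAG", "AAG"], ["AGG"])
        table = cs.compute_aei(ds)
        assert table["A"] == pytest.approx(2.0)
        assert table["G"] == pytest.approx(0.5)

    def test_zero_denominator_names_residue(self):
        ds = make_labeled_dataset(["ACDEFGHIKLMNPQRSTVWY"], ["ACDEFGHIKLMNPQRSTVY"])
        with pytest.raises(ValueError, match="W"):
            cs.compute_aei(ds)

    def test_class_swap_gives_reciprocal(self, planted_dataset):
        ds, _ = planted_dataset
        swapped = make_labeled_dataset(
            [e.sequence for e in ds.entries if e.expr_class == "low"],
            [e.sequence for e in ds.entries if e.expr_class == "high"],
        )
        t1 = cs.compute_aei(ds)
        t2 = cs.compute_aei(swapped)
        for aa in STANDARD_AA:
            assert t2[aa] == pytest.approx(1.0 / t1[aa])

    def test_planted_ratio_recovery(self):
        spec = PlantedExpressionSpec(n_per_class=1000, length_range=(80, 120), seed=21)
        ds, truth = gen_expression_dataset(spec)
        table = cs.compute_aei(ds)
        # 3-standard-error bound via per-sequence frequency variances
        high = np.array([cs.aa_frequencies(e.sequence) for e in ds.entries
                         if e.expr_class == "high"])
        low = np.array([cs.aa_frequencies(e.sequence) for e in ds.entries
                        if e.expr_class == "low"])
        for i, aa in enumerate(STANDARD_AA):
            mh, ml = high[:, i].mean(), low[:, i].mean()
            se = math.hypot(high[:, i].std() / math.sqrt(len(high)) / ml,
                            mh / ml**2 * low[:, i].std() / math.sqrt(len(low)))
            assert abs(table[aa] - truth[aa]) < 3 * se + 1e-12


class TestSRAB:
    def test_all_equal_table_closed_form(self):
        table = uniform_aei(1.0)
        res = cs.compute_srab("ACD", table)
        assert res.value == pytest.approx(2 ** 1.5)
        assert res.n_residues == 3
        # general closed form exp(n*log(1+c)/(n-1))
        for c, seq in ((0.5, "AAAA"), (3.0, "ACDEFG")):
            n = len(seq)
            expected = math.exp(n * math.log(1 + c) / (n - 1))
            assert cs.compute_srab(seq, uniform_aei(c)).value == pytest.approx(expected)

    def test_homopolymer_limit(self):
        table = uniform_aei(1.0)
        table = cs.AEITable("sp", {**table.aei, "A": 0.8})
        vals = [cs.compute_srab("A" * n, table).value for n in (10, 100, 1000)]
        errors = [abs(v - 1.8) for v in vals]
        assert errors == sorted(errors, reverse=True)
        assert vals[-1] == pytest.approx(1.8, abs=1e-2)

    def test_monotone_under_residue_upgrade(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            aei = {aa: float(rng.uniform(0.2, 3.0)) for aa in STANDARD_AA}
            table = cs.AEITable("sp", aei)
            seq = "".join(rng.choice(list(STANDARD_AA), size=20))
            i = int(rng.integers(0, 20))
            better = [aa for aa in STANDARD_AA if aei[aa] > aei[seq[i]]]
            if not better:
                continue
            upgraded = seq[:i] + str(rng.choice(better)) + seq[i + 1:]
            assert cs.compute_srab(upgraded, table).value > cs.compute_srab(seq, table).value

    def test_nonstandard_skipped(self):
        table = uniform_aei(1.0)
        assert cs.compute_srab("ACXD", table).n_residues == 3

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cs.compute_srab("A", uniform_aei())


class TestCost:
    def test_tryptophan_dipeptide(self):
        table = read_cost_table()
        assert cs.mean_biosynthetic_cost("WW", table) == pytest.approx(75.5)

    def test_toy_arithmetic(self):
        costs = {aa: 1.0 for aa in STANDARD_AA}
        costs["W"], costs["A"] = 10.0, 2.0
        table = CostTable(costs)
        assert cs.mean_biosynthetic_cost("WA", table) == pytest.approx(6.0)

    def test_all_ones(self):
        table = CostTable({aa: 1.0 for aa in STANDARD_AA})
        assert cs.mean_biosynthetic_cost("MKVL", table) == 1.0

    def test_constructed_anticorrelation(self):
        # abundance built as a decreasing function of mean cost
        table = read_cost_table()
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list(STANDARD_AA), size=60)) for _ in range(60)]
        costs = [cs.mean_biosynthetic_cost(s, table) for s in seqs]
        order = np.argsort(costs)
        ds = make_labeled_dataset(
            [seqs[i] for i in order[:30]], [seqs[i] for i in order[30:]]
        )
        # abundances in make_labeled_dataset decrease with index, so low-cost
        # sequences got the highest abundances
        result = cs.cost_expression_analysis(ds, table)
        assert result["spearman_r"] < -0.9

    def test_identical_class_compositions_equal_means(self):
        table = read_cost_table()
        ds = make_labeled_dataset(["MKVL", "MKVL"], ["MKVL"])
        result = cs.cost_expression_analysis(ds, table)
        assert result["mean_cost_high"] == pytest.approx(result["mean_cost_low"])

    def test_constant_cost_reported_missing(self):
        table = CostTable({aa: 1.0 for aa in STANDARD_AA})
        ds = make_labeled_dataset(["MK", "VL"], ["AC"])
        result = cs.cost_expression_analysis(ds, table)
        assert result["spearman_r"] is None


def _index(accession, values):
    return PropertyIndex(accession, "test", dict(zip(STANDARD_AA, values)))


class TestProperties:
    def test_zscore_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        ix = _index("P1", rng.uniform(-5, 5, 20))
        m = cs.standardize_properties([ix])
        assert m.z[0].mean() == pytest.approx(0, abs=1e-9)
        assert m.z[0].std() == pytest.approx(1, abs=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 1, 20)
        m1 = cs.standardize_properties([_index("P1", vals)])
        m2 = cs.standardize_properties([_index("P1", vals * 5 + 3)])
        np.testing.assert_allclose(m1.z, m2.z)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="P1"):
            cs.standardize_properties([_index("P1", np.ones(20))])

    def test_planted_property_recovered(self):
        # abundance increases with A content; property scores A highest
        rng = np.random.default_rng(3)
        seqs, abunds = [], []
        for i in range(50):
            n_a = rng.integers(1, 40)
            seq = "A" * n_a + "".join(rng.choice(list("CDEFG"), size=40 - n_a))
            seqs.append("".join(rng.permutation(list(seq))))
            abunds.append(float(n_a) + rng.normal(0, 0.01))
        ds = make_labeled_dataset(seqs[:25], seqs[25:])
        # overwrite abundances to the planted signal
        for e, a in zip(ds.entries, abunds):
            object.__setattr__(e, "abundance", a)
        vals = np.where(np.array(STANDARD_AA) == "A", 1.0, 0.0)
        ix = _index("PLANT", vals + np.linspace(0, 0.01, 20))
        results = cs.property_expression_correlations([ds], [ix])
        assert results[0].mean_r > 0.9

    def test_sign_flip_negates_exactly(self):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list(STANDARD_AA), size=30)) for _ in range(30)]
        ds = make_labeled_dataset(seqs[:15], seqs[15:])
        vals = rng.uniform(-1, 1, 20)
        r1 = cs.property_expression_correlations([ds], [_index("P1", vals)])
        r2 = cs.property_expression_correlations([ds], [_index("P1", -vals)])
        assert r2[0].mean_r == pytest.approx(-r1[0].mean_r)

    def test_constant_property_skipped(self):
        ds = make_labeled_dataset(["MK", "VL"], ["AC"])
        results = cs.property_expression_correlations([ds], [_index("P1", np.ones(20))])
        assert results == []

    def test_select_key_properties(self):
        results = [
            cs.PropertyCorrelationResult("A1", {}, {}, 0.25),
            cs.PropertyCorrelationResult("A2", {}, {}, -0.21),
            cs.PropertyCorrelationResult("A3", {}, {}, 0.1),
        ]
        sel = cs.select_key_properties(results, threshold=0.2)
        assert len(sel["kept"]) == 2
        assert sel["n_positive"] == 1 and sel["n_negative"] == 1
        assert cs.select_key_properties(results, threshold=1.0)["kept"] == []

    def test_pipeline_matches_bruteforce(self):
        # direct-loop reimplementation as an independent oracle
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list(STANDARD_AA), size=25)) for _ in range(20)]
        ds = make_labeled_dataset(seqs[:10], seqs[10:])
        vals = rng.uniform(0, 1, 20)
        ix = _index("P1", vals)
        res = cs.property_expression_correlations([ds], [ix])[0]
        by_aa = dict(zip(STANDARD_AA, vals))
        means, abunds = [], []
        for e in ds.entries:
            total, count = 0.0, 0
            for ch in e.sequence:
                total += by_aa[ch]
                count += 1
            means.append(total / count)
            abunds.append(e.abundance)
        r, _ = sps.spearmanr(abunds, means)
        assert res.mean_r == pytest.approx(r)


class TestPropertyClustering:
    def test_identical_rows_merge_first(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(0, 1, 20)
        w = rng.uniform(0, 1, 20)
        m = cs.standardize_properties(
            [_index("A", v), _index("B", v * 2 + 1), _index("C", w)]
        )
        newick = cs.cluster_property_matrix(m)["properties"]
        # A and B standardize identically -> distance ~0 -> sister leaves
        import re

        stripped = re.sub(r":[0-9.e+-]+", "", newick.replace(" ", ""))
        assert "(A,B)" in stripped

    def test_row_permutation_invariant_topology(self):
        rng = np.random.default_rng(8)
        rows = [_index(f"P{i}", rng.uniform(0, 1, 20)) for i in range(5)]
        n1 = cs.cluster_property_matrix(cs.standardize_properties(rows))
        n2 = cs.cluster_property_matrix(cs.standardize_properties(rows[::-1]))
        assert n1["properties"] == n2["properties"]

    def test_single_row_rejected(self):
        rng = np.random.default_rng(9)
        m = cs.standardize_properties([_index("A", rng.uniform(0, 1, 20))])
        with pytest.raises(ValueError):
            cs.cluster_property_matrix(m)
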