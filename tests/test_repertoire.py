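import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucosa import repertoire as rep
from mucosa import synth


def make_table(rows):
    df = pd.DataFrame(rows)
    for col, default in (("condition", "HC"), ("cluster", pd.NA),
                         ("cdr3_nt", "TGT"), ("count", 1), ("j_call", "TRBJ1")):
        if col not in df.columns:
            df[col] = default
    return df


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = math.comb(n, c1)
    support = range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = {k: math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom
           for k in support}
    cutoff = pmf[a] * (1 + 1e-7)
    return sum(v for v in pmf.values() if v <= cutoff)


clonotype_vectors = st.dictionaries(
    st.integers(min_value=0, max_value=30).map(lambda i: (f"k{i}",)),
    st.integers(min_value=1, max_value=500), min_size=1, max_size=20)


class TestAggregate:
    def test_duplicates_merged(self):
        table = make_table([
            {"sample_id": "s1", "v_call": "V1", "cdr3_aa": "CASSL",
             "cdr3_nt": "TGTGCAAGTAGTTTA", "count": 2},
            {"sample_id": "s1", "v_call": "V1", "cdr3_aa": "CASSL",
             "cdr3_nt": "TGTGCAAGTAGTTTA", "count": 3}])
        vec = rep.aggregate(table, key_mode="nt")["s1"]
        assert vec.counts == {("V1", "TGTGCAAGTAGTTTA"): 5}

    def test_aa_mode_merges_nt_synonyms(self):
        table = make_table([
            {"sample_id": "s1", "v_call": "V1", "cdr3_aa": "CASSL",
             "cdr3_nt": "TGTGCAAGTAGTCTA", "count": 1},
            {"sample_id": "s1", "v_call": "V1", "cdr3_aa": "CASSL",
             "cdr3_nt": "TGTGCAAGTAGTTTG", "count": 1}])
        assert rep.aggregate(table, key_mode="nt")["s1"].n_unique == 2
        assert rep.aggregate(table, key_mode="aa")["s1"].n_unique == 1

    def test_totals_conserved(self, repertoire_bundle):
        _, table, _ = repertoire_bundle
        vectors = rep.aggregate(table)
        assert sum(v.total for v in vectors.values()) == table["count"].sum()

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rep.aggregate(make_table([]).iloc[:0])


class TestMorisitaHorn:
    def test_identity_is_one(self):
        v = rep.ClonotypeVector({("a",): 5, ("b",): 2, ("c",): 9}, "nt")
        assert rep.morisita_horn(v, v) == pytest.approx(1.0, abs=1e-15)

    def test_disjoint_is_zero(self):
        a = rep.ClonotypeVector({("a",): 5}, "nt")
        b = rep.ClonotypeVector({("b",): 7}, "nt")
        assert rep.morisita_horn(a, b) == 0.0

    def test_hand_derived_example(self):
        # X=3, Y=2, sum xy = 3, sum x^2/X^2 = 5/9, sum y^2/Y^2 = 1/2
        # MH = 2*3 / ((5/9 + 1/2) * 3 * 2) = 18/19
        a = rep.ClonotypeVector({("c1",): 2, ("c2",): 1}, "nt")
        b = rep.ClonotypeVector({("c1",): 1, ("c2",): 1}, "nt")
        assert rep.morisita_horn(a, b) == pytest.approx(18 / 19, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(clonotype_vectors, clonotype_vectors)
    def test_symmetry_and_bounds(self, da, db):
        a = rep.ClonotypeVector(da, "nt")
        b = rep.ClonotypeVector(db, "nt")
        mh_ab = rep.morisita_horn(a, b)
        assert mh_ab == pytest.approx(rep.morisita_horn(b, a), abs=1e-12)
        assert -1e-12 <= mh_ab <= 1.0 + 1e-12

    @settings(max_examples=100, deadline=None)
    @given(clonotype_vectors, clonotype_vectors,
           st.integers(min_value=2, max_value=50))
    def test_scale_invariance(self, da, db, c):
        a = rep.ClonotypeVector(da, "nt")
        b = rep.ClonotypeVector(db, "nt")
        scaled = rep.ClonotypeVector({k: v * c for k, v in da.items()}, "nt")
        assert rep.morisita_horn(a, b) == pytest.approx(
            rep.morisita_horn(scaled, b), rel=1e-9)

    def test_overlap_matrix_symmetric(self, repertoire_bundle):
        _, table, _ = repertoire_bundle
        M = rep.overlap_matrix(rep.aggregate(table))
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)


class TestVUsage:
    def test_identical_counts_null(self):
        rows = []
        for s, cond in (("a1", "ACD"), ("a2", "ACD"), ("h1", "HC"), ("h2", "HC")):
            for v in ("V1", "V2"):
                for i in range(5):
                    rows.append({"sample_id": s, "condition": cond, "v_call": v,
                                 "cdr3_aa": f"CASS{i}X", "cdr3_nt": f"nt{i}{v}",
                                 "count": 1})
        res = rep.v_usage_test(make_table(rows)).set_index("segment")
        assert res.loc["V1", "lfc"] == pytest.approx(0.0, abs=1e-6)
        assert res.loc["V1", "p"] > 0.99

    def test_shift_detected(self):
        cfg = synth.RepertoireSimConfig(
            n_clones=3000, samples_per_condition={"HC": 4, "ACD": 4},
            v_probs={"HC": [0.02] + [0.98 / 9] * 9,
                     "ACD": [0.10] + [0.90 / 9] * 9}, seed=0)
        table, _ = synth.simulate_repertoire(cfg)
        res = rep.v_usage_test(table).set_index("segment")
        assert res.loc["TRBV1", "q"] < 0.05
        assert res.loc["TRBV1", "lfc"] > 0
        high = res[res["frequency_class"] == "high"]
        assert high["lfc"].idxmax() == "TRBV1"

    def test_small_group_rejected(self, repertoire_bundle):
        _, table, _ = repertoire_bundle
        sub = table[table["sample_id"].isin(["HC1", "ACD1", "ACD2"])]
        with pytest.raises(ValueError, match="fewer than 2"):
            rep.v_usage_test(sub)

    def test_frequency_class_threshold(self, repertoire_bundle):
        _, table, _ = repertoire_bundle
        res = rep.v_usage_test(table)
        pooled = table.drop_duplicates(["sample_id", "v_call", "cdr3_nt"])
        fracs = pooled["v_call"].value_counts(normalize=True)
        for _, row in res.iterrows():
            expected = "high" if fracs[row["segment"]] > 0.01 else "low"
            assert row["frequency_class"] == expected


class TestExpansionStats:
    def test_unique_fraction_arithmetic(self):
        rows = [{"sample_id": "s1", "v_call": v, "cdr3_aa": f"CASS{i}",
                 "cdr3_nt": f"nt{i}", "count": 1}
                for i, v in enumerate(["V1", "V1", "V2", "V2", "V2"])]
        frac = rep.unique_v_fraction(make_table(rows), "V1")
        assert frac["s1"] == pytest.approx(0.4)

    def test_top_n_larger_than_repertoire_flagged(self):
        rows = [{"sample_id": "s1", "v_call": "V1", "cdr3_aa": f"CASS{i}",
                 "cdr3_nt": f"nt{i}", "count": i + 1} for i in range(5)]
        res = rep.top_expanded_v_fraction(make_table(rows), "V1", n=100)
        assert res["truncated"].iloc[0]
        assert res["n_used"].iloc[0] == 5
        assert res["fraction"].iloc[0] == 1.0

    def test_simulated_fraction_within_ci(self):
        cfg = synth.RepertoireSimConfig(
            n_clones=5000, samples_per_condition={"ACD": 1},
            v_probs={"ACD": [0.10] + [0.90 / 9] * 9}, seed=12)
        table, _ = synth.simulate_repertoire(cfg)
        frac = rep.unique_v_fraction(table, "TRBV1").iloc[0]
        assert 0.085 <= frac <= 0.115

    def test_quintile_fisher_matches_oracle(self):
        # engineered sample: 50 clonotypes, top 10 ranks hold 8 with segment
        rows = []
        for i in range(50):
            has = (i < 8) or (38 <= i < 50)
            rows.append({"sample_id": "s1",
                         "v_call": "V1" if has else "V2",
                         "cdr3_aa": f"CASS{i:02d}", "cdr3_nt": f"nt{i:02d}",
                         "count": 50 - i})
        res = rep.quintile_enrichment(make_table(rows), "V1")
        a, b, c, d = 8, 2, 12, 28
        assert res["top_with_segment"].iloc[0] == a
        assert res["p"].iloc[0] == pytest.approx(
            fisher_two_sided_oracle(a, b, c, d), rel=1e-9)

    def test_spec_table_or_six(self):
        # [[8,2],[12,18]] -> OR = (8*18)/(2*12) = 6.0
        from scipy.stats import fisher_exact
        odds, p = fisher_exact([[8, 2], [12, 18]])
        assert odds == pytest.approx(6.0)
        assert p == pytest.approx(fisher_two_sided_oracle(8, 2, 12, 18),
                                  rel=1e-9)

    def test_all_segment_or_undefined(self):
        rows = [{"sample_id": "s1", "v_call": "V1", "cdr3_aa": f"CASS{i}",
                 "cdr3_nt": f"nt{i}", "count": i + 1} for i in range(10)]
        res = rep.quintile_enrichment(make_table(rows), "V1")
        assert np.isnan(res["odds_ratio"].iloc[0])
        assert "undefined" in res["note"].iloc[0]


class TestCdr3Composition:
    def test_global_frequency_arithmetic(self):
        rows = [{"sample_id": "s1", "condition": "HC", "v_call": "V1",
                 "cdr3_aa": aa, "cdr3_nt": f"nt{aa}", "count": 1}
                for aa in ("CASSLG", "CASSFG")]
        res = rep.cdr3_aa_usage(make_table(rows))
        l_freq = res[(res["group"] == "HC") & (res["residue"] == "L")]
        assert l_freq["global_freq"].iloc[0] == pytest.approx(1 / 12)

    def test_germline_mask(self):
        rows = [{"sample_id": "s1", "condition": "HC", "v_call": "V1",
                 "cdr3_aa": "CASL", "cdr3_nt": "ntx", "count": 1}]
        res = rep.cdr3_aa_usage(make_table(rows), germline_prefix_len=3,
                                germline_suffix_len=0)
        row = res[(res["group"] == "HC") & (res["residue"] == "L")]
        assert row["nongermline_freq"].iloc[0] == 1.0

    def test_invalid_character_rejected(self):
        rows = [{"sample_id": "s1", "condition": "HC", "v_call": "V1",
                 "cdr3_aa": "CASS*", "cdr3_nt": "nt", "count": 1}]
        with pytest.raises(ValueError, match="non-amino-acid"):
            rep.cdr3_aa_usage(make_table(rows))

    def test_leucine_bias_recovered(self):
        rng = np.random.default_rng(0)
        rows = []
        for cond, l_prob in (("ACD", 0.35), ("HC", 0.05)):
            for i in range(400):
                core = "".join(rng.choice(["L", "G", "S", "T"],
                                          p=[l_prob, (1 - l_prob) / 3,
                                             (1 - l_prob) / 3, (1 - l_prob) / 3])
                               for _ in range(8))
                rows.append({"sample_id": f"{cond}1", "condition": cond,
                             "v_call": "V1", "cdr3_aa": "CAS" + core + "F",
                             "cdr3_nt": f"nt{cond}{i}", "count": 1})
        res = rep.cdr3_aa_usage(make_table(rows), groups=("ACD", "HC"))
        row = res[(res["residue"] == "L") & (res["group"] == "ACD")]
        assert row["q"].iloc[0] < 1e-6


class TestMotifs:
    def test_match_all(self):
        rows = [{"sample_id": "s1", "v_call": "V1", "cdr3_aa": "CASSLG",
                 "cdr3_nt": "nt1", "count": 1}]
        assert rep.motif_frequency(make_table(rows), "CASS")["s1"] == 1.0

    def test_half_match(self):
        rows = [{"sample_id": "s1", "v_call": "V1", "cdr3_aa": aa,
                 "cdr3_nt": f"nt{aa}", "count": 1}
                for aa in ("CASSLG", "CASSFG")]
        assert rep.motif_frequency(make_table(rows), "L")["s1"] == 0.5

    def test_invalid_pattern_rejected(self):
        rows = [{"sample_id": "s1", "v_call": "V1", "cdr3_aa": "CASSF",
                 "cdr3_nt": "nt", "count": 1}]
        with pytest.raises(ValueError, match="invalid motif"):
            rep.motif_frequency(make_table(rows), "[")

    def test_injected_motif_rate_recovered(self):
        rng = np.random.default_rng(3)
        rate = 0.2
        rows = []
        for i in range(2000):
            core = "LQGL" if rng.uniform() < rate else "GGST"
            rows.append({"sample_id": "s1", "v_call": "V1",
                         "cdr3_aa": "CAS" + core + str(i % 10) * 0 + "F",
                         "cdr3_nt": f"nt{i}", "count": 1})
        freq = rep.motif_frequency(make_table(rows), "LQGL")["s1"]
        assert abs(freq - rate) < 0.03


class TestSharing:
    def test_identical_repertoires(self):
        rows = []
        for s in ("s1", "s2"):
            for i in range(5):
                rows.append({"sample_id": s, "condition": "HC", "v_call": "V1",
                             "cdr3_aa": f"CASS{i}", "cdr3_nt": f"nt{i}",
                             "count": 1})
        res = rep.sharing(make_table(rows))
        assert res["jaccard"].iloc[0] == 1.0

    def test_disjoint(self):
        rows = []
        for s, off in (("s1", 0), ("s2", 100)):
            for i in range(5):
                rows.append({"sample_id": s, "condition": "HC", "v_call": "V1",
                             "cdr3_aa": f"CASS{i + off}",
                             "cdr3_nt": f"nt{i + off}", "count": 1})
        res = rep.sharing(make_table(rows))
        assert res["shared"].iloc[0] == 0
        assert np.isnan(res["mean_shared_length"].iloc[0])

    def test_within_condition_sharing_exceeds_between(self):
        from scipy.stats import mannwhitneyu
        cfg = synth.RepertoireSimConfig(
            n_clones=1000, samples_per_condition={"HC": 3, "ACD": 3},
            public_pool_fraction=0.10, seed=4)
        table, _ = synth.simulate_repertoire(cfg)
        res = rep.sharing(table)
        within = res[res["pair_class"].str.startswith("within")]["shared"]
        between = res[res["pair_class"] == "between"]["shared"]
        p = mannwhitneyu(within, between, alternative="greater").pvalue
        assert p < 0.05


class TestSegmentUsageSummary:
    def test_fractions_sum_to_one(self, repertoire_bundle):
        _, table, _ = repertoire_bundle
        res = rep.segment_usage_summary(table, "TRBV")
        sums = res.groupby("sample_id")["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_injected_excess_recovered(self):
        cfg = synth.RepertoireSimConfig(
            v_vocabulary=[f"TRGV{i}" for i in range(1, 6)],
            n_clones=2000, samples_per_condition={"HC": 2, "ACD": 2},
            v_probs={"HC": [0.1, 0.1, 0.2, 0.3, 0.3],
                     "ACD": [0.1, 0.1, 0.5, 0.1, 0.2]}, seed=5)
        table, _ = synth.simulate_repertoire(cfg)
        res = rep.segment_usage_summary(table, "TRGV")
        mean = res.groupby(["condition", "segment"])["fraction"].mean()
        assert mean["ACD", "TRGV3"] > mean["HC", "TRGV3"] + 0.2

    def test_empty_locus_rejected(self, repertoire_bundle):
        _, table, _ = repertoire_bundle
        with pytest.raises(ValueError, match="TRDV"):
            rep.segment_usage_summary(table, "TRDV")
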