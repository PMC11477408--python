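import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allergoscope.profiling import (
    AllergenExpressionMatrix,
    aggregate_allergen_expression,
    cluster_fish,
    filter_true_allergens,
    fish_means,
    rank_isoforms,
    top_allergens,
)
from allergoscope.scan import AlignmentHit, ScanResult


def _hit(tid, allergen, name, identity=85.0, primary=True):
    return AlignmentHit(
        transcript_id=tid, allergen_id=allergen, allergen_name=name,
        organism="fish", frame=1, raw_score=100.0, bit_score=40.0,
        e_value=1e-20, identity_pct=identity, subject_coverage_pct=100.0,
        query_span=(1, 100), subject_span=(1, 100), tier="high", is_primary=primary,
    )


def _scan(hits):
    result = ScanResult(hits=hits)
    for h in hits:
        if h.is_primary:
            result.primary[h.transcript_id] = h.allergen_id
    return result


@pytest.fixture()
def simple_scan():
    return _scan([
        _hit("t1", "PV_m1", "PV"),
        _hit("t2", "PV_m2", "PV"),
        _hit("t3", "GAPDH_m1", "GAPDH", identity=72.0),
        _hit("t4", "ENO_m1", "enolase", identity=65.0),
    ])


@pytest.fixture()
def simple_tpm():
    return pd.DataFrame(
        {"s1": [10.0, 30.0, 20.0, 10.0], "s2": [5.0, 5.0, 80.0, 10.0]},
        index=["t1", "t2", "t3", "t4"],
    )


class TestAggregate:
    def test_tpm_sums_pool_by_allergen_name(self, simple_scan, simple_tpm):
        m = aggregate_allergen_expression(simple_scan, simple_tpm)
        assert m.tpm_sum.loc["PV", "s1"] == 40.0
        assert m.rel_abundance.loc["PV", "s1"] == pytest.approx(40 / 70)

    def test_rel_abundance_normalised_per_sample(self, simple_scan, simple_tpm):
        m = aggregate_allergen_expression(simple_scan, simple_tpm)
        assert m.rel_abundance.sum(axis=0).to_numpy() == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_allergen_total_bounded_by_transcriptome_total(self, simple_scan, simple_tpm):
        extra = simple_tpm.copy()
        extra.loc["decoy"] = [100.0, 100.0]
        m = aggregate_allergen_expression(simple_scan, extra)
        assert (m.tpm_sum.sum(axis=0) <= extra.sum(axis=0) + 1e-9).all()

    def test_missing_transcript_is_named(self, simple_scan, simple_tpm):
        with pytest.raises(KeyError, match="t4"):
            aggregate_allergen_expression(simple_scan, simple_tpm.drop(index="t4"))

    def test_zero_allergen_sample_flagged(self, simple_scan, simple_tpm):
        tpm = simple_tpm.copy()
        tpm["s3"] = 0.0
        m = aggregate_allergen_expression(simple_scan, tpm)
        assert m.flagged_samples == ["s3"]
        assert m.rel_abundance["s3"].isna().all()


class TestIsoformRanking:
    def test_descending_order_and_top_share(self):
        scan = _scan([_hit(t, "PV_m1", "PV") for t in ("a", "b", "c")])
        tpm = pd.DataFrame({"s1": [5.0, 20.0, 1.0]}, index=["a", "b", "c"])
        r = rank_isoforms(scan, tpm, "PV", "s1")
        assert r.transcript_ids == ["b", "a", "c"]
        assert r.top_share == pytest.approx(20 / 26)

    def test_single_isoform(self):
        scan = _scan([_hit("a", "PV_m1", "PV")])
        tpm = pd.DataFrame({"s1": [7.0]}, index=["a"])
        r = rank_isoforms(scan, tpm, "PV", "s1")
        assert r.transcript_ids == ["a"] and r.top_share == 1.0

    def test_tpm_tie_broken_by_transcript_id(self):
        scan = _scan([_hit("y", "PV_m1", "PV"), _hit("x", "PV_m1", "PV")])
        tpm = pd.DataFrame({"s1": [10.0, 10.0]}, index=["y", "x"])
        assert rank_isoforms(scan, tpm, "PV", "s1").transcript_ids == ["x", "y"]

    def test_unknown_allergen_rejected(self):
        scan = _scan([_hit("a", "PV_m1", "PV")])
        tpm = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            rank_isoforms(scan, tpm, "GAPDH", "s1")


def _matrix(rel, identity):
    rel = pd.DataFrame(rel)
    tpm = rel * 1000
    ident = pd.DataFrame(
        {s: np.asarray(identity, dtype=float) for s in rel.columns}, index=rel.index
    )
    return AllergenExpressionMatrix(
        tpm_sum=tpm, rel_abundance=rel, best_identity=ident
    )


class TestTrueAllergenFilter:
    samples = ["s1", "s2", "s3", "s4"]

    def _m(self, rows, identities):
        rel = {s: [rows[a][i] for a in rows] for i, s in enumerate(self.samples)}
        rel = pd.DataFrame(rel, index=list(rows))
        return _matrix(rel, pd.Series(identities))

    def test_rule_application(self):
        rows = {
            "keep": [0.02, 0.02, 0.02, 0.02],       # 75% identity, 4 supporting samples
            "low_identity": [0.05, 0.05, 0.05, 0.05],  # 65% identity
            "low_support": [0.02, 0.02, 0.005, 0.005],  # only 2 supporting samples
        }
        m = self._m(rows, [75.0, 65.0, 80.0])
        assert filter_true_allergens(m) == ["keep"]

    def test_identity_uses_maximum_anywhere(self):
        rel = pd.DataFrame({"s1": [0.5], "s2": [0.5], "s3": [0.5]}, index=["a"])
        ident = pd.DataFrame(
            {"s1": [60.0], "s2": [np.nan], "s3": [71.0]}, index=["a"]
        )
        m = AllergenExpressionMatrix(rel * 100, rel, ident)
        assert filter_true_allergens(m) == ["a"]

    def test_too_few_samples_rejected(self):
        rel = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["a"])
        m = _matrix(rel, pd.Series([90.0]))
        with pytest.raises(ValueError):
            filter_true_allergens(m)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        id_lo=st.floats(50, 69), id_hi=st.floats(70, 95),
        ab_lo=st.floats(0.001, 0.01), ab_hi=st.floats(0.011, 0.2),
    )
    def test_monotone_in_both_thresholds(self, id_lo, id_hi, ab_lo, ab_hi):
        rng = np.random.default_rng(42)
        rel = pd.DataFrame(
            rng.dirichlet(np.ones(6), size=5).T,
            index=list("abcdef"), columns=[f"s{i}" for i in range(5)],
        )
        m = _matrix(rel, pd.Series(rng.uniform(55, 95, size=6)))
        loose = set(filter_true_allergens(m, id_thresh=id_lo, abund_thresh=ab_lo))
        strict = set(filter_true_allergens(m, id_thresh=id_hi, abund_thresh=ab_hi))
        assert strict <= loose


class TestTopAllergens:
    def test_dominant_allergen_ranks_first(self):
        rel = pd.DataFrame(
            {"s1": [0.9, 0.05, 0.05], "s2": [0.9, 0.08, 0.02]},
            index=["PV", "a", "b"],
        )
        order, cum = top_allergens(_matrix(rel, pd.Series([90.0] * 3)), k=1)
        assert order[0] == "PV" and (cum >= 0.9).all()

    def test_uniform_matrix_top6_share(self):
        rel = pd.DataFrame(0.1, index=[f"a{i}" for i in range(10)], columns=["s1", "s2"])
        _, cum = top_allergens(_matrix(rel, pd.Series([90.0] * 10)), k=6)
        assert cum.to_numpy() == pytest.approx([0.6, 0.6])


class TestClusterFish:
    def _two_block(self, seed, n_per_block=4, n_allergens=8):
        rng = np.random.default_rng(seed)
        high = np.r_[0.6, rng.dirichlet(np.ones(n_allergens - 1)) * 0.4]
        low = np.r_[0.05, rng.dirichlet(np.ones(n_allergens - 1)) * 0.95]
        cols = {}
        truth = {}
        for i in range(n_per_block):
            for base, grp in ((high, "PV-high"), (low, "PV-low")):
                noisy = base * np.exp(rng.normal(0, 0.15, n_allergens))
                name = f"{grp[3:]}{i}"
                cols[name] = noisy / noisy.sum()
                truth[name] = grp
        rel = pd.DataFrame(cols, index=["PV"] + [f"a{j}" for j in range(n_allergens - 1)])
        return rel, truth

    def test_identical_profiles_cluster_together(self):
        rel = pd.DataFrame(
            {"f1": [0.7, 0.3], "f2": [0.7, 0.3], "f3": [0.1, 0.9]},
            index=["PV", "a"],
        )
        # add a third allergen to get non-degenerate correlations
        rel.loc["b"] = [0.0, 0.0, 0.0]
        rel = rel + 1e-6
        g = cluster_fish(rel.div(rel.sum(axis=0), axis=1))
        assert g.labels["f1"] == g.labels["f2"] == "PV-high"
        assert g.labels["f3"] == "PV-low"
        assert g.correlation.loc["f1", "f2"] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_block_design_recovered(self, seed):
        rel, truth = self._two_block(seed)
        g = cluster_fish(rel)
        assert g.labels == truth

    def test_invariant_to_sample_order_and_scaling(self):
        rel, _ = self._two_block(99)
        g1 = cluster_fish(rel)
        g2 = cluster_fish(rel[list(rel.columns)[::-1]] * 7.0)
        assert g1.labels == g2.labels

    def test_label_follows_pv_abundance(self):
        rel, truth = self._two_block(3)
        g = cluster_fish(rel)
        pv_high_mean = np.mean([rel.loc["PV", s] for s, lab in g.labels.items() if lab == "PV-high"])
        pv_low_mean = np.mean([rel.loc["PV", s] for s, lab in g.labels.items() if lab == "PV-low"])
        assert pv_high_mean > pv_low_mean


class TestFishMeans:
    def test_replicates_averaged(self):
        t = pd.DataFrame({"cod_1": [1.0, 3.0], "cod_2": [3.0, 5.0], "tuna_1": [2.0, 2.0]})
        out = fish_means(t)
        assert list(out.columns) == ["cod", "tuna"]
        assert out["cod"].tolist() == [2.0, 4.0]
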