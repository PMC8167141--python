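"""Age EWAS statistics, top-CpG selection and annotation summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oeac.ewas import (
    EwasResult,
    TopSet,
    ewas_age,
    fisher_z,
    island_contrast,
    overlap_counts,
    region_distribution,
    select_top,
    top_loci,
)


def _result(z, p, species="dolphin_a", tissue="blood", probes=None):
    z = np.asarray(z, dtype=float)
    probes = probes or [f"cg{j:03d}" for j in range(len(z))]
    table = pd.DataFrame(
        {
            "n": 30,
            "r": np.tanh(z / np.sqrt(27)),
            "z": z,
            "p": p,
            "direction": np.sign(z).astype(int),
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return EwasResult(species=species, tissue=tissue, table=table)


class TestFisherZ:
    def test_closed_form(self):
        # r = 0.5, n = 28: atanh(0.5) * 5
        assert fisher_z(0.5, 28) == pytest.approx(2.74654, abs=1e-4)

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(-0.99, 0.99, 1000)
        n = rng.integers(4, 200, 1000)
        expected = 0.5 * np.log((1 + r) / (1 - r)) * np.sqrt(n - 3)
        assert np.max(np.abs(fisher_z(r, n) - expected)) < 1e-10

    def test_perfect_correlation_capped(self):
        assert fisher_z(1.0, 30) == 40.0
        assert fisher_z(-1.0, 30) == -40.0


class TestEwasAge:
    def test_linear_probe_and_null_probe(self, tiny_cohort_builder):
        ages = [1.0, 2.0, 3.0, 4.0]
        linear = [0.1, 0.2, 0.3, 0.4]
        balanced = [0.4, 0.5, 0.5, 0.4]  # exactly orthogonal to age
        constant = [0.5, 0.5, 0.5, 0.5]
        cohort = tiny_cohort_builder(
            [linear, balanced, constant], {"age_years": ages}
        )
        res = ewas_age(cohort, "dolphin_a", "blood")
        t = res.table
        assert t.loc["cg000", "r"] == pytest.approx(1.0)
        assert t.loc["cg000", "z"] == 40.0  # capped
        assert t.loc["cg001", "r"] == pytest.approx(0.0, abs=1e-12)
        assert t.loc["cg001", "p"] == pytest.approx(1.0)
        assert np.isnan(t.loc["cg002", "r"])  # constant probe flagged

    def test_r_matches_pearson_oracle(self, small_cohort):
        cohort, _ = small_cohort
        res = ewas_age(cohort, "dolphin_a", "blood")
        ids = cohort.sheet.query("species == 'dolphin_a' and tissue == 'blood'")[
            "sample_id"
        ]
        ages = cohort.sheet.set_index("sample_id").loc[ids, "age_years"]
        for probe in cohort.beta.index[:25]:
            r_ref = stats.pearsonr(cohort.beta.loc[probe, ids], ages).statistic
            assert res.table.loc[probe, "r"] == pytest.approx(r_ref, abs=1e-10)

    def test_pairwise_complete_missing(self, tiny_cohort_builder):
        ages = [1.0, 2.0, 3.0, 4.0, 5.0]
        probe = [0.1, 0.2, np.nan, 0.4, 0.5]
        cohort = tiny_cohort_builder([probe], {"age_years": ages})
        res = ewas_age(cohort, "dolphin_a", "blood")
        assert res.table.loc["cg000", "n"] == 4
        assert res.table.loc["cg000", "r"] == pytest.approx(1.0)

    def test_too_few_samples(self, tiny_cohort_builder):
        cohort = tiny_cohort_builder([[0.1, 0.2, 0.3]], {"age_years": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="4"):
            ewas_age(cohort, "dolphin_a", "blood")


class TestSelectTop:
    def test_nothing_significant(self):
        res = _result(np.linspace(-1, 1, 10), np.full(10, 0.5))
        assert len(select_top(res)) == 0

    def test_per_direction_cap(self):
        z = np.concatenate([np.linspace(5, 10, 700), np.linspace(-10, -5, 100)])
        p = np.full(800, 1e-6)
        res = _result(z, p)
        top = select_top(res, cap=500)
        signs = np.sign(res.table.loc[top.probe_ids, "z"])
        assert (signs > 0).sum() == 500
        assert (signs < 0).sum() == 100

    def test_matches_sort_and_filter_oracle(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0, 4, 400)
        p = 2 * stats.norm.sf(np.abs(z))
        res = _result(z, p)
        top = select_top(res, p_thresh=1e-2, cap=30)
        # brute-force oracle
        t = res.table[res.table["p"] < 1e-2]
        expected = []
        for sign in (1, -1):
            d = t[np.sign(t["z"]) == sign]
            ranked = sorted(d.index, key=lambda pid: (-abs(d.at[pid, "z"]), pid))
            expected.extend(ranked[:30])
        assert sorted(top.probe_ids) == sorted(expected)

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 4, 200)
        p = 2 * stats.norm.sf(np.abs(z))
        res = _result(z, p)
        top1 = select_top(res, p_thresh=1e-2, cap=20)
        perm = rng.permutation(len(z))
        res_perm = EwasResult(res.species, res.tissue, res.table.iloc[perm])
        top2 = select_top(res_perm, p_thresh=1e-2, cap=20)
        assert top1.probe_ids == top2.probe_ids


class TestOverlapCounts:
    @staticmethod
    def _ts(name, probes):
        return TopSet("sp", name, list(probes), 1e-4, 500)

    def test_disjoint(self):
        out = overlap_counts([self._ts("a", "xyz"), self._ts("b", "pqrs")])
        c = out.set_index("region")["count"]
        assert c["sp/a"] == 3 and c["sp/b"] == 4 and c["sp/a&sp/b"] == 0

    def test_identical(self):
        out = overlap_counts([self._ts("a", "abcde"), self._ts("b", "abcde")])
        c = out.set_index("region")["count"]
        assert c["sp/a&sp/b"] == 5 and c["sp/a"] == 0 and c["sp/b"] == 0

    def test_counts_sum_to_union_and_match_enumeration(self):
        rng = np.random.default_rng(8)
        universe = [f"cg{j}" for j in range(60)]
        sets = [
            self._ts(f"t{i}", rng.choice(universe, rng.integers(5, 40), replace=False))
            for i in range(4)
        ]
        out = overlap_counts(sets)
        union = set().union(*(s.probe_ids for s in sets))
        assert out["count"].sum() == len(union)
        # brute-force membership enumeration
        for _, row in out.iterrows():
            labels = set(row["region"].split("&"))
            expected = sum(
                1
                for probe in universe
                if {s.label for s in sets if probe in s.probe_ids} == labels
            )
            assert row["count"] == expected


class TestRegionDistribution:
    def test_all_promoter(self, small_cohort):
        cohort, _ = small_cohort
        ann = cohort.annotation.copy()
        ann["region_class"] = "promoter"
        top = TopSet("sp", "blood", list(cohort.beta.index[:10]), 1e-4, 500)
        dist = region_distribution(top, ann)
        assert dist["promoter"] == 1.0
        assert dist.sum() == pytest.approx(1.0)

    def test_uniform_annotation_near_uniform(self, default_cohort):
        cohort, _ = default_cohort
        top = TopSet("sp", "blood", list(cohort.beta.index[:1000]), 1e-4, 2000)
        dist = region_distribution(top, cohort.annotation)
        assert dist.sum() == pytest.approx(1.0)
        # binomial error band around 1/8 at n = 1000
        assert np.all(np.abs(dist - 1 / 8) < 4 * np.sqrt((1 / 8) * (7 / 8) / 1000))

    def test_empty_topset_warns(self, small_cohort):
        cohort, _ = small_cohort
        top = TopSet("sp", "blood", [], 1e-4, 500)
        with pytest.warns(UserWarning, match="empty"):
            dist = region_distribution(top, cohort.annotation)
        assert dist.empty

    def test_unannotated_probe_named(self, small_cohort):
        cohort, _ = small_cohort
        top = TopSet("sp", "blood", ["not_a_probe"], 1e-4, 500)
        with pytest.raises(ValueError, match="not_a_probe"):
            region_distribution(top, cohort.annotation)


class TestIslandContrast:
    @staticmethod
    def _ann(probes, statuses):
        return pd.DataFrame(
            {
                "probe_id": probes,
                "chrom": "chr1",
                "pos": 1,
                "nearest_gene": "G",
                "region_class": "exon",
                "dist_to_tss": 0,
                "island_status": statuses,
            }
        )

    def test_identical_distributions(self):
        z = np.tile(np.linspace(-2, 2, 50), 2)
        probes = [f"cg{j:03d}" for j in range(100)]
        res = _result(z, np.full(100, 0.5), probes=probes)
        ann = self._ann(probes, ["island"] * 50 + ["non-island"] * 50)
        out = island_contrast(res, ann)
        assert out["percent_difference"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"] == pytest.approx(1.0, abs=0.05)

    def test_shift_alternative_detected(self):
        rng = np.random.default_rng(0)
        z_non = rng.normal(2.0, 1.0, 300)
        z_isl = z_non + 1.0
        probes = [f"cg{j:04d}" for j in range(600)]
        res = _result(
            np.concatenate([z_isl, z_non]), np.full(600, 0.5), probes=probes
        )
        ann = self._ann(probes, ["island"] * 300 + ["non-island"] * 300)
        out = island_contrast(res, ann)
        assert out["percent_difference"] > 0
        assert out["p_value"] < 1e-3

    def test_medians_match_sort_oracle(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 3, 101)
        probes = [f"cg{j:04d}" for j in range(101)]
        status = ["island" if i % 2 else "non-island" for i in range(101)]
        res = _result(z, np.full(101, 0.5), probes=probes)
        out = island_contrast(res, self._ann(probes, status))

        def median_by_sort(values):
            v = sorted(values)
            k = len(v)
            return v[k // 2] if k % 2 else (v[k // 2 - 1] + v[k // 2]) / 2

        isl = [zi for zi, s in zip(z, status) if s == "island"]
        non = [zi for zi, s in zip(z, status) if s == "non-island"]
        assert out["median_z_island"] == pytest.approx(median_by_sort(isl), abs=1e-12)
        assert out["median_z_nonisland"] == pytest.approx(median_by_sort(non), abs=1e-12)

    def test_empty_stratum_rejected(self):
        probes = [f"cg{j}" for j in range(10)]
        res = _result(np.ones(10), np.full(10, 0.5), probes=probes)
        with pytest.raises(ValueError, match="non-empty"):
            island_contrast(res, self._ann(probes, ["island"] * 10))


class TestTopLoci:
    def _ann(self, probes):
        return pd.DataFrame(
            {
                "probe_id": probes,
                "chrom": "chr1",
                "pos": np.arange(1, len(probes) + 1),
                "nearest_gene": [f"GENE{j}" for j in range(len(probes))],
                "region_class": "exon",
                "dist_to_tss": 0,
                "island_status": "island",
            }
        )

    def test_strongest_probe_first(self, default_cohort):
        cohort, truth = default_cohort
        from oeac.ewas import ewas_age

        res = ewas_age(cohort, "bottlenose_dolphin", "blood")
        out = top_loci(res, cohort.annotation, k=10)
        planted = truth.planted(("shared_aging", "private_aging"))
        assert out["probe_id"].iloc[0] in planted
        assert set(out["probe_id"]) <= planted

    def test_shorter_when_few_pass(self):
        z = np.array([10.0, 0.1, 0.2])
        p = np.array([1e-8, 0.9, 0.8])
        res = _result(z, p)
        out = top_loci(res, self._ann(list(res.table.index)), k=10)
        assert len(out) == 1

    def test_tie_break_lexicographic(self):
        z = np.array([5.0, -5.0, 5.0])
        p = np.full(3, 1e-6)
        res = _result(z, p, probes=["cgB", "cgA", "cgC"])
        out = top_loci(res, self._ann(["cgB", "cgA", "cgC"]), k=3)
        assert out["probe_id"].tolist() == ["cgA", "cgB", "cgC"]
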