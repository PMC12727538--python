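"""Amplicon landscape analyses: annotation and density against brute-force
oracles, co-amplification counting rules, oncogene-window enrichment,
correlation comparison, and generic interval-set enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from retainkit.amplicon import (
    amplicon_summaries,
    annotate_intervals,
    coamplification_rates,
    density_size_correlation,
    interval_set_enrichment,
    local_re_density,
    oncogene_re_enrichment,
)
from retainkit.intervals import GenomeLayout, IntervalSet, bin_genome

from conftest import random_interval_set
from test_stats import hypergeom_tail_oracle


def catalog_from_records(records):
    """records: (sample, amplicon_id, class, chrom, start, end)"""
    return pd.DataFrame(
        records, columns=["sample", "amplicon_id", "class", "chrom", "start", "end"]
    )


class TestAnnotate:
    def test_contained_and_straddling_elements_counted_once(self):
        cat = catalog_from_records([("s1", "a1", "ecDNA", "chr1", 1000, 5000)])
        res = IntervalSet.from_records(
            [("chr1", 2000, 2500), ("chr1", 3000, 3100), ("chr1", 4900, 5500)]
        )
        ann = annotate_intervals(cat, res)
        assert ann["n_re"].tolist() == [3]
        assert ann["width"].tolist() == [4000]

    def test_matches_brute_force_on_random_catalog(self, rng, small_layout):
        ivals = random_interval_set(rng, small_layout, 30, max_width=2000)
        cat = ivals.df.copy()
        cat["sample"] = "s"
        cat["amplicon_id"] = [f"a{i}" for i in range(len(cat))]
        cat["class"] = "ecDNA"
        res = random_interval_set(rng, small_layout, 50, max_width=300)
        ann = annotate_intervals(cat, res)
        brute = [
            sum((rc == c) and (rs < e) and (re_ > s)
                for rc, rs, re_ in zip(res.chroms, res.starts, res.ends))
            for c, s, e in zip(cat["chrom"], cat["start"], cat["end"])
        ]
        assert ann["n_re"].tolist() == brute

    def test_unknown_chromosome_rejected(self, small_layout):
        cat = catalog_from_records([("s", "a", "ecDNA", "chrZ", 0, 100)])
        with pytest.raises(KeyError):
            annotate_intervals(cat, IntervalSet.empty(), layout=small_layout)


class TestLocalDensity:
    def test_ten_elements_in_window_is_two_per_mb(self):
        cat = catalog_from_records([("s", "a", "ecDNA", "chr1", 5_000_000, 5_010_000)])
        mid = 5_005_000
        res = IntervalSet.from_records(
            [("chr1", mid + i * 100_000, mid + i * 100_000 + 1000) for i in range(10)]
        )
        out = local_re_density(cat, res)
        assert out["local_density"].iloc[0] == pytest.approx(2.0)

    def test_no_elements_gives_zero(self):
        cat = catalog_from_records([("s", "a", "ecDNA", "chr1", 0, 10_000)])
        assert local_re_density(cat, IntervalSet.empty())["local_density"].iloc[0] == 0.0

    def test_weighted_amplicon_density(self):
        # two intervals of widths 1 and 3 Mb with densities 2 and 4 -> 3.5
        ann = pd.DataFrame(
            {
                "sample": ["s", "s"],
                "amplicon_id": ["a", "a"],
                "class": ["ecDNA", "ecDNA"],
                "width": [1e6, 3e6],
                "n_re": [1, 1],
                "local_density": [2.0, 4.0],
            }
        )
        summ = amplicon_summaries(ann)
        assert summ["weighted_density"].iloc[0] == pytest.approx(3.5)


class TestCoamplification:
    def make_summaries(self, spec):
        """spec: {class: list of per-amplicon interval n_re lists}"""
        rows = []
        i = 0
        for klass, amps in spec.items():
            for n_res in amps:
                i += 1
                for j, nre in enumerate(n_res):
                    rows.append(
                        {"sample": f"s{i}", "amplicon_id": f"a{i}", "class": klass,
                         "width": 1e6, "n_re": nre, "local_density": 0.0}
                    )
        return amplicon_summaries(pd.DataFrame(rows))

    def test_counting_rules(self):
        summ = self.make_summaries(
            {"ecDNA": [[0, 2], [0, 0, 3], [1, 2], [0]], "linear": [[0], [0, 1]]}
        )
        rates, _ = coamplification_rates(summ)
        ec = rates.set_index("class").loc["ecDNA"]
        # [1,2] has no element-negative interval -> excluded from denominator;
        # [0,2] and [0,0,3] co-amplified; [0] eligible but not co-amplified
        assert (ec["n_coamplified"], ec["n_eligible"]) == (2, 3)

    def test_proportion_test_equals_hand_z(self):
        summ = self.make_summaries(
            {"ecDNA": [[0, 1]] * 45 + [[0]] * 5, "linear": [[0, 1]] * 20 + [[0]] * 30}
        )
        _, tests = coamplification_rates(summ, pairs=[("ecDNA", "linear")])
        z_hand = (0.9 - 0.4) / math.sqrt(0.65 * 0.35 * (2 / 50))
        assert tests["z"].iloc[0] == pytest.approx(z_hand)


class TestOncogeneEnrichment:
    layout = GenomeLayout.from_dict({"chr8": 10_000_000})
    oncogene = ("chr8", 5_000_000, 5_050_000)

    def test_element_inside_oncogene_has_fold_change_one(self):
        obs = pd.DataFrame({"chrom": "chr8",
                            "start": [4_900_000, 4_800_000, 4_950_000],
                            "end": [5_200_000, 5_100_000, 5_300_000]})
        res = IntervalSet.from_records([("chr8", 5_010_000, 5_012_000)])
        out = oncogene_re_enrichment(obs, self.oncogene, res, self.layout, seed=0)
        row = out.iloc[0]
        assert row["obs_freq"] == 1.0 and row["exp_freq"] == 1.0
        assert row["fold_change"] == pytest.approx(1.0)
        assert row["p"] == 1.0

    def test_unreachable_element_not_estimable(self):
        obs = pd.DataFrame({"chrom": ["chr8"], "start": [4_990_000], "end": [5_060_000]})
        res = IntervalSet.from_records([("chr8", 5_400_000, 5_401_000)])
        out = oncogene_re_enrichment(obs, self.oncogene, res, self.layout, seed=0)
        assert not out["estimable"].iloc[0]
        assert np.isnan(out["fold_change"].iloc[0])

    def test_interval_narrower_than_oncogene_rejected(self):
        obs = pd.DataFrame({"chrom": ["chr8"], "start": [5_000_000], "end": [5_020_000]})
        with pytest.raises(ValueError):
            oncogene_re_enrichment(obs, self.oncogene, IntervalSet.empty(), self.layout)

    def test_random_placements_always_contain_oncogene(self):
        obs = pd.DataFrame({"chrom": "chr8", "start": [4_000_000], "end": [6_000_000]})
        # an element overlapping the oncogene span itself must be included in
        # every random placement too
        res = IntervalSet.from_records([("chr8", 5_000_000, 5_050_000)])
        out = oncogene_re_enrichment(obs, self.oncogene, res, self.layout,
                                     n_random=200, seed=5)
        assert out["exp_freq"].iloc[0] == 1.0


class TestDensitySizeCorrelation:
    def test_identical_classes_give_z_zero(self, rng):
        d = rng.normal(size=50)
        s = 10 ** (6 + 0.3 * rng.normal(size=50))
        rows = []
        for klass in ("ecDNA", "linear"):
            for di, si in zip(d, s):
                rows.append({"class": klass, "weighted_density": di, "total_size": si})
        per, pairs = density_size_correlation(pd.DataFrame(rows),
                                              classes=("ecDNA", "linear"))
        pair = pairs.iloc[0]
        assert pair["z"] == pytest.approx(0.0)
        assert pair["p"] == pytest.approx(1.0)

    def test_perfect_linear_relation_hits_the_bound(self):
        d = np.arange(10.0)
        rows = [{"class": "ecDNA", "weighted_density": di, "total_size": 10 ** (7 - 0.2 * di)}
                for di in d]
        per, _ = density_size_correlation(pd.DataFrame(rows), classes=("ecDNA",))
        assert per["r"].iloc[0] == pytest.approx(-1.0)
        assert per["ci_low"].iloc[0] == per["ci_high"].iloc[0] == pytest.approx(-1.0)

    def test_too_few_amplicons_rejected(self):
        rows = [{"class": "ecDNA", "weighted_density": i, "total_size": 10 ** (6 + i)}
                for i in range(3)]
        with pytest.raises(ValueError):
            density_size_correlation(pd.DataFrame(rows), classes=("ecDNA",))


class TestIntervalSetEnrichment:
    def test_log2fc_zero_when_fractions_match(self):
        q = IntervalSet.from_records([("c", i * 1000, i * 1000 + 500) for i in range(10)])
        ann = IntervalSet.from_records([("c", i * 1000, i * 1000 + 500) for i in range(0, 10, 2)])
        bg = q  # background identical to query
        res = interval_set_enrichment(q, ann, 0.5, test="log2fc", background=bg)
        assert res.log2fc == pytest.approx(0.0)
        assert res.p is None

    def test_genome_wide_annotation_gives_hypergeom_p_one(self, small_layout):
        bins = bin_genome(small_layout, 1000)
        q = IntervalSet.from_records([("chr1", 0, 1000), ("chr1", 2000, 3000)])
        ann = IntervalSet.from_records(
            [(c, 0, l) for c, l in small_layout.sizes.items()]
        )
        res = interval_set_enrichment(q, ann, 0.25, test="hypergeometric", genome_bins=bins)
        assert res.p == pytest.approx(1.0)
        assert res.fold_change == pytest.approx(1.0)

    def test_fisher_mode_p_matches_enumeration(self):
        # observed table [[8,2],[2,8]]
        q = IntervalSet.from_records([("c", i * 100, i * 100 + 10) for i in range(10)])
        ann = IntervalSet.from_records([("c", i * 100, i * 100 + 10) for i in range(8)])
        bg = IntervalSet.from_records([("c", 10_000 + i * 100, 10_000 + i * 100 + 10)
                                       for i in range(10)])
        ann_bg = IntervalSet.from_records(
            [("c", 10_000 + i * 100, 10_000 + i * 100 + 10) for i in range(2)]
        )
        ann_all = IntervalSet(pd.concat([ann.df, ann_bg.df], ignore_index=True))
        res = interval_set_enrichment(q, ann_all, 0.5, test="fisher", background=bg)
        # two-sided Fisher by enumeration over the fixed margins
        N, K, n, k = 20, 10, 10, 8
        pmf = [math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
               for x in range(max(0, n - (N - K)), min(K, n) + 1)]
        xs = list(range(max(0, n - (N - K)), min(K, n) + 1))
        p_obs = pmf[xs.index(k)]
        expected = sum(p for p in pmf if p <= p_obs * (1 + 1e-9))
        assert res.p == pytest.approx(expected, rel=1e-6)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            interval_set_enrichment(IntervalSet.empty(), IntervalSet.empty(), 0.5)
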