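"""Clone construction, diversity, overlap, public clones, SHM statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import pclong as pl
from conftest import build_all_samples


def rows_from(specs):
    """Build rearrangement rows from (v_call, cdr3, count[, locus]) tuples."""
    recs = []
    for i, s in enumerate(specs):
        v_call, cdr3, count = s[:3]
        locus = s[3] if len(s) > 3 else "IGH"
        recs.append(
            {
                "sequence_id": f"s{i:03d}", "v_call": v_call, "c_call": "IGHG1",
                "junction_aa": cdr3, "duplicate_count": count, "locus": locus,
                "mutation_count": 0, "v_sequence_length": 300,
            }
        )
    columns = ["sequence_id", "v_call", "c_call", "junction_aa",
               "duplicate_count", "locus", "mutation_count", "v_sequence_length"]
    return pd.DataFrame(recs, columns=columns)


def sample_with_sizes(sizes, sample_id="s", mouse_id="m1", **kw):
    rows = rows_from(
        [(f"IGHV1-{i}*01", "CARW" + "A" * (i % 5), size) for i, size in enumerate(sizes)]
    )
    return pl.build_clones(rows, sample_id, mouse_id, min_size=1, **kw)


class TestBuildClones:
    def test_empty_input(self):
        s = pl.build_clones(rows_from([]), "s", "m1")
        assert s.clones == []

    def test_size_filter_keeps_only_large_clones(self):
        # summed sizes {12, 9, 4} -> one clone survives the <10 filter
        rows = rows_from([
            ("IGHV1-1*01", "CARAAA", 7), ("IGHV1-1*01", "CARAAA", 5),
            ("IGHV2-2*01", "CARCCC", 9), ("IGHV3-3*01", "CARGGG", 4),
        ])
        s = pl.build_clones(rows, "s", "m1", min_size=10)
        assert len(s.clones) == 1
        assert s.clones[0].key == ("IGHV1-1", "CARAAA") and s.clones[0].size == 12

    def test_allele_suffixes_merge_to_gene_level_key(self):
        rows = rows_from([
            ("IGHV8-9*01", "CARDDD", 6), ("IGHV8-9*02", "CARDDD", 6),
        ])
        s = pl.build_clones(rows, "s", "m1", min_size=1)
        assert len(s.clones) == 1
        assert s.clones[0].size == 12
        assert set(s.clones[0].member_alleles) == {"IGHV8-9*01", "IGHV8-9*02"}

    def test_missing_cdr3_and_other_locus_dropped_with_counts(self):
        rows = rows_from([
            ("IGHV1-1*01", "CARAAA", 12),
            ("IGKV1-1*01", "CQQAAA", 12, "IGK"),
        ])
        rows.loc[len(rows)] = {"sequence_id": "x", "v_call": "IGHV1-2*01",
                               "c_call": "IGHG1", "junction_aa": None,
                               "duplicate_count": 5, "locus": "IGH",
                               "mutation_count": 0, "v_sequence_length": 300}
        s = pl.build_clones(rows, "s", "m1", min_size=1)
        assert len(s.clones) == 1
        assert s.dropped_rows == {"missing_cdr3": 1, "other_locus": 1}

    def test_idempotent_on_own_output(self):
        s = sample_with_sizes([12, 15, 20])
        again = pl.build_clones(
            s.to_frame().rename(columns={"v_gene": "v_call", "size": "duplicate_count",
                                         "v_length": "v_sequence_length"}),
            "s", "m1", min_size=10,
        )
        assert again.keys == s.keys
        assert sorted(c.size for c in again.clones) == sorted(c.size for c in s.clones)


class TestChao1:
    @pytest.mark.parametrize(
        "sizes, expected",
        [
            ([3, 4, 5, 6], 4.0),             # f1 = f2 = 0 -> S_obs
            ([1, 1, 1, 2, 2, 3], 8.25),      # 6 + 9/4
            ([1, 2, 3], 3.5),                # 3 + 1/2
            ([1, 1, 5], 3 + 1.0),            # f2 = 0 bias-corrected branch
        ],
    )
    def test_known_values(self, sizes, expected):
        assert pl.chao1(sample_with_sizes(sizes)) == pytest.approx(expected)

    def test_never_below_observed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sizes = rng.integers(1, 6, size=rng.integers(1, 30)).tolist()
            assert pl.chao1(sample_with_sizes(sizes)) >= len(sizes)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            pl.chao1(pl.RepertoireSample("s", "m1", clones=[]))


class TestOverlapFraction:
    def _pair(self, n_a, n_b, n_shared):
        shared = [(f"IGHV1-1*01", f"CARS{i}", 10) for i in range(n_shared)]
        a = pl.build_clones(
            rows_from(shared + [("IGHV2-2*01", f"CARA{i}", 10)
                                for i in range(n_a - n_shared)]),
            "a", "m1", min_size=1)
        b = pl.build_clones(
            rows_from(shared + [("IGHV3-3*01", f"CARB{i}", 10)
                                for i in range(n_b - n_shared)]),
            "b", "m2", min_size=1)
        return a, b

    def test_identical_sets_are_100_percent_everywhere(self):
        a, b = self._pair(5, 5, 5)
        for mode in ("jaccard", "relative_to_first", "relative_to_min"):
            assert pl.overlap_fraction(a, b, mode) == pytest.approx(100.0)

    def test_disjoint_sets_are_zero(self):
        a, b = self._pair(5, 4, 0)
        assert pl.overlap_fraction(a, b) == 0.0

    def test_hand_computed_example(self):
        a, b = self._pair(10, 8, 4)
        assert pl.overlap_fraction(a, b, "jaccard") == pytest.approx(100 * 4 / 14)
        assert pl.overlap_fraction(a, b, "relative_to_first") == pytest.approx(40.0)

    def test_symmetry_of_jaccard_and_min_modes(self):
        a, b = self._pair(10, 6, 3)
        for mode in ("jaccard", "relative_to_min"):
            assert pl.overlap_fraction(a, b, mode) == pl.overlap_fraction(b, a, mode)


class TestPublicClones:
    def test_single_mouse_yields_empty_catalog(self):
        samples = [sample_with_sizes([10, 12], sample_id=f"s{i}", mouse_id="m1")
                   for i in range(3)]
        assert len(pl.find_public_clones(samples)) == 0

    def test_same_mouse_sharing_excluded(self):
        shared = rows_from([("IGHV1-1*01", "CARSHARED", 10)])
        s1 = pl.build_clones(shared, "s1", "m1", min_size=1)
        s2 = pl.build_clones(shared, "s2", "m1", min_size=1)
        s3 = pl.build_clones(rows_from([("IGHV9-9*01", "CAROTHER", 10)]),
                             "s3", "m2", min_size=1)
        assert len(pl.find_public_clones([s1, s2, s3])) == 0

    def test_recovers_spiked_cross_mouse_clones(self, demo_repertoire, demo_samples):
        _, _, public_keys = demo_repertoire
        catalog = pl.find_public_clones(demo_samples)
        assert catalog.keys == set(public_keys)

    def test_monotone_under_mouse_removal(self, demo_samples):
        full = pl.find_public_clones(demo_samples).keys
        mice = {s.mouse_id for s in demo_samples}
        for drop in mice:
            reduced = pl.find_public_clones(
                [s for s in demo_samples if s.mouse_id != drop]
            ).keys
            assert reduced <= full

    def test_missing_mouse_id_rejected(self):
        s = sample_with_sizes([10], mouse_id="")
        with pytest.raises(ValueError, match="mouse_id"):
            pl.find_public_clones([s])


class TestTopPublicEnrichment:
    def test_all_target_only_gives_one(self, demo_samples):
        only_llpc = [s for s in demo_samples if s.subset == "llpc"]
        catalog = pl.find_public_clones(only_llpc)
        assert len(catalog) > 0
        res = pl.top_public_enrichment(catalog, only_llpc, n_top=100)
        assert res["top_fraction_in_target"] == 1.0

    def test_constructed_fraction(self):
        # 10 public clones, exactly 4 occur in a target-subset sample
        samples = []
        for i in range(10):
            subset = "llpc" if i < 4 else "bulk"
            for mouse in ("m1", "m2"):
                samples.append(pl.build_clones(
                    rows_from([(f"IGHV1-1*01", f"CARPUB{i}", 10 + i)]),
                    f"s{i}_{mouse}", mouse, min_size=1, subset=subset,
                ))
        catalog = pl.find_public_clones(samples)
        res = pl.top_public_enrichment(catalog, samples, n_top=10)
        assert res["top_fraction_in_target"] == pytest.approx(0.4)

    def test_invalid_n_top(self):
        with pytest.raises(ValueError):
            pl.top_public_enrichment(
                pl.PublicCloneCatalog({("v", "c"): [("s", "m", None)]},
                                      {("v", "c"): 5}),
                [], n_top=0)


class TestIsotypeComposition:
    def _mixed(self):
        recs = rows_from([("IGHV1-1*01", f"CAR{i}", 1) for i in range(10)])
        recs["c_call"] = ["IGHM"] * 2 + ["IGHA"] * 6 + ["IGHG2"] * 2
        return pl.build_clones(recs, "s", "m1", min_size=1)

    def test_single_isotype(self):
        recs = rows_from([("IGHV1-1*01", "CARAAA", 5)])
        recs["c_call"] = "IGHA"
        s = pl.build_clones(recs, "s", "m1", min_size=1)
        assert pl.isotype_composition(s) == {"IgA": 1.0}

    def test_clone_weighted_fractions(self):
        comp = pl.isotype_composition(self._mixed())
        assert comp == pytest.approx({"IgM": 0.2, "IgA": 0.6, "IgG": 0.2})

    def test_read_weighting_shifts_toward_large_clones(self):
        recs = rows_from([("IGHV1-1*01", "CARBIG", 90),
                          ("IGHV2-2*01", "CARS1", 5),
                          ("IGHV3-3*01", "CARS2", 5)])
        recs["c_call"] = ["IGHM", "IGHA", "IGHA"]
        s = pl.build_clones(recs, "s", "m1", min_size=1)
        by_clone = pl.isotype_composition(s, weight="clones")["IgM"]
        by_reads = pl.isotype_composition(s, weight="reads")["IgM"]
        assert by_reads > by_clone


class TestShmPerAllele:
    def _sample(self, entries):
        recs = []
        for i, (allele, mut, vlen) in enumerate(entries):
            recs.append({"sequence_id": f"s{i}", "v_call": allele,
                         "c_call": "IGHG1", "junction_aa": f"CAR{i}",
                         "duplicate_count": 1, "locus": "IGH",
                         "mutation_count": mut, "v_sequence_length": vlen})
        return pl.build_clones(pd.DataFrame(recs), "s", "m1", min_size=1)

    def test_zero_mutations_everywhere(self):
        s = self._sample([("IGHV1-1*01", 0, 300), ("IGHV2-2*01", 0, 300)])
        assert all(v == 0.0 for v in pl.shm_per_allele(s, seed=0).values())

    def test_direct_frequency(self):
        s = self._sample([("IGHV8-9*01", 6, 300)])
        assert pl.shm_per_allele(s, seed=0) == {"IGHV8-9*01": pytest.approx(0.02)}

    def test_mean_over_clones_on_one_allele(self):
        s = self._sample([("IGHV8-9*01", 6, 300), ("IGHV8-9*01", 12, 300)])
        assert pl.shm_per_allele(s, seed=0)["IGHV8-9*01"] == pytest.approx(0.03)

    def test_seeded_reproducibility_and_unbiasedness(self):
        # a clone with two member sequences: expectation over seeds equals
        # the mean of the member frequencies
        rows = pd.DataFrame([
            {"sequence_id": "a", "v_call": "IGHV1-1*01", "c_call": "IGHG1",
             "junction_aa": "CARX", "duplicate_count": 1, "locus": "IGH",
             "mutation_count": 3, "v_sequence_length": 300},
            {"sequence_id": "b", "v_call": "IGHV1-1*01", "c_call": "IGHG1",
             "junction_aa": "CARX", "duplicate_count": 1, "locus": "IGH",
             "mutation_count": 9, "v_sequence_length": 300},
        ])
        s = pl.build_clones(rows, "s", "m1", min_size=1)
        assert pl.shm_per_allele(s, seed=5) == pl.shm_per_allele(s, seed=5)
        draws = [pl.shm_per_allele(s, seed=k)["IGHV1-1*01"] for k in range(400)]
        assert np.mean(draws) == pytest.approx((3 + 9) / 2 / 300, rel=0.05)

    def test_zero_v_length_rejected(self):
        s = self._sample([("IGHV1-1*01", 0, 0)])
        with pytest.raises(ValueError, match="V length"):
            pl.shm_per_allele(s, seed=0)

    def test_subset_mutation_contrast_in_generated_data(self, demo_repertoire):
        rows, meta, _ = demo_repertoire
        freqs = {"llpc": [], "bulk": []}
        for m in meta.itertuples():
            sub = rows[rows["sample_id"] == m.sample_id]
            freqs[m.subset].append(
                (sub["mutation_count"] / sub["v_sequence_length"]).mean()
            )
        assert np.mean(freqs["llpc"]) < np.mean(freqs["bulk"])


class TestPairedAlleleTests:
    def test_identical_tables_give_t_zero_p_one(self):
        tab = {"IGHV1-1*01": 0.02, "IGHV2-2*01": 0.03, "IGHV3-3*01": 0.04}
        res = pl.paired_allele_t(tab, dict(tab))
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_known_t_statistic(self):
        # differences {0.01, 0.02, 0.03}: t = 0.02 / (0.01/sqrt(3)) = 3.464
        a = {"x": 0.03, "y": 0.05, "z": 0.07}
        b = {"x": 0.02, "y": 0.03, "z": 0.04}
        res = pl.paired_allele_t(a, b)
        assert res["t"] == pytest.approx(3.464, abs=1e-3)
        assert res["df"] == 2
        assert res["p"] == pytest.approx(2 * sps.t.sf(3.4641016, 2), rel=1e-4)

    def test_unmatched_alleles_ignored(self):
        a = {"x": 0.03, "y": 0.05, "z": 0.07, "only_a": 0.5}
        b = {"x": 0.02, "y": 0.03, "z": 0.04, "only_b": 0.5}
        assert pl.paired_allele_t(a, b)["n_matched"] == 3

    def test_too_few_matched_skipped(self):
        res = pl.paired_allele_t({"x": 0.1}, {"x": 0.2})
        assert res["status"] == "skipped_too_few_alleles"
        assert np.isnan(res["p"])

    def test_constant_nonzero_difference_is_degenerate(self):
        res = pl.paired_allele_t({"x": 0.2, "y": 0.3}, {"x": 0.1, "y": 0.2})
        assert res["status"] == "degenerate_zero_variance"
        assert np.isnan(res["p"])

    def test_bh_adjustment_hand_stepped(self):
        # raw {0.01, 0.02, 0.04} -> adjusted {0.03, 0.03, 0.04}
        comps = {}
        rng = np.random.default_rng(0)
        for name, target_p in [("c1", 0.01), ("c2", 0.02), ("c3", 0.04)]:
            # build a pair with the exact desired p by inverting the t CDF
            n = 4
            t_target = sps.t.isf(target_p / 2, n - 1)
            base = rng.normal(0, 1, n)
            d = base - base.mean()
            d = d / d.std(ddof=1)          # mean 0, sd 1
            shift = t_target / np.sqrt(n)  # gives t = t_target
            vals = d + shift
            a = {f"al{i}": v for i, v in enumerate(vals)}
            b = {f"al{i}": 0.0 for i in range(n)}
            comps[name] = (a, b)
        df = pl.paired_allele_tests(comps)
        assert df["p"].to_numpy() == pytest.approx([0.01, 0.02, 0.04], rel=1e-6)
        assert df["p_adj"].to_numpy() == pytest.approx([0.03, 0.03, 0.04], rel=1e-6)

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        comps = {}
        for i in range(8):
            a = {f"al{j}": rng.normal(0.03, 0.01) for j in range(5)}
            b = {f"al{j}": rng.normal(0.03, 0.01) for j in range(5)}
            comps[f"c{i}"] = (a, b)
        df = pl.paired_allele_tests(comps).sort_values("p")
        padj = df["p_adj"].to_numpy()
        assert (np.diff(padj) >= -1e-12).all()
        assert (padj <= 1.0 + 1e-12).all()
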