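"""Cohort set-algebra: spectra, genome bins, Venn cells, sharing, top tables."""

import numpy as np
import pandas as pd
import pytest

from cfmito.cohort import (
    CohortTable,
    frequency_spectrum,
    genome_bins,
    load_ancestral_variants,
    normalize_variant_count,
    region_intersection,
    shared_variants,
    spectrum_bins,
    top_variants,
)
from cfmito.variants import DEL, SNV, VariantKey, parse_hgvs


def key(pos, alt="G"):
    return VariantKey(pos, "A", alt, SNV)


def random_cohort(rng, n_samples=8, n_variants=15, regions=("R1", "R2", "R3", "R4")):
    keys = [key(int(p)) for p in rng.choice(16_000, size=n_variants, replace=False) + 1]
    calls = {
        f"s{i}": [k for k in keys if rng.random() < 0.4] for i in range(n_samples)
    }
    meta = pd.DataFrame(
        {"region": [regions[i % len(regions)] for i in range(n_samples)],
         "mt_content": rng.uniform(1e-5, 1e-3, size=n_samples)},
        index=list(calls),
    )
    return CohortTable.from_calls(calls, meta)


class TestFrequencySpectrum:
    def test_simple_fractions(self):
        cohort = CohortTable.from_calls(
            {"a": [key(10)], "b": [], "c": []}
        )
        freqs = frequency_spectrum(cohort)
        assert freqs[key(10)] == pytest.approx(1 / 3)

    def test_universal_variant(self):
        cohort = CohortTable.from_calls({s: [key(5)] for s in "abc"})
        assert frequency_spectrum(cohort)[key(5)] == pytest.approx(1.0)

    def test_matches_column_means(self):
        rng = np.random.default_rng(21)
        cohort = random_cohort(rng)
        freqs = frequency_spectrum(cohort)
        for k in cohort.presence.columns:
            assert freqs[k] == pytest.approx(cohort.presence[k].mean())

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(22)
        cohort = random_cohort(rng)
        freqs = frequency_spectrum(cohort)
        assert ((freqs > 0) & (freqs <= 1)).all()

    def test_spectrum_bins_conserve_total(self):
        rng = np.random.default_rng(23)
        cohort = random_cohort(rng)
        freqs = frequency_spectrum(cohort)
        assert spectrum_bins(freqs).sum() == len(freqs)


class TestGenomeBins:
    @pytest.mark.parametrize("pos,expected_bin", [(1, 1), (1000, 1), (1001, 2),
                                                  (15_000, 15), (16_100, 16),
                                                  (16_569, 16)])
    def test_bin_boundaries(self, pos, expected_bin):
        counts = genome_bins([key(pos)])
        assert counts[expected_bin] == 1 and counts.sum() == 1

    def test_totals_conserved(self):
        rng = np.random.default_rng(24)
        keys = [key(int(p)) for p in rng.integers(1, 16_570, size=60)]
        assert genome_bins(keys).sum() == len(set(keys))

    def test_simulated_cohort_concentrates_in_hotspot_bins(self, ref, tree):
        """Hot-spot weighting of variant positions shows up in the 3-5, 11-13
        and 15-16 kb genome sections, which jointly exceed their uniform
        expectation (their share of the genome)."""
        from cfmito.simulate import SimConfig, simulate_cohort

        cohort = simulate_cohort(SimConfig(n_samples=12, seed=27), ref, tree)
        keys = sorted({
            v for s in cohort.samples
            for v in s.truth.maternal_variants | s.truth.leukocyte_private
            | s.truth.cf_private
        })
        bins = genome_bins(keys)
        hot = bins[[3, 4, 5, 11, 12, 13, 15, 16]].sum()
        uniform_share = (3000 + 3000 + 2569) / 16_569
        assert hot / bins.sum() > uniform_share


class TestVenn:
    def test_identical_region_sets(self):
        calls = {"a": [key(1), key(2)], "b": [key(1), key(2)]}
        meta = pd.DataFrame({"region": ["R1", "R2"]}, index=["a", "b"])
        venn = region_intersection(CohortTable.from_calls(calls, meta), ["R1", "R2"])
        assert venn.cell("R1", "R2") == 2
        assert venn.cell("R1") == 0 and venn.total_distinct == 2

    def test_disjoint_region_sets(self):
        calls = {"a": [key(1)], "b": [key(2)]}
        meta = pd.DataFrame({"region": ["R1", "R2"]}, index=["a", "b"])
        venn = region_intersection(CohortTable.from_calls(calls, meta), ["R1", "R2"])
        assert venn.cell("R1", "R2") == 0
        assert venn.cell("R1") == 1 and venn.cell("R2") == 1

    def test_cells_match_brute_force_and_conserve(self):
        rng = np.random.default_rng(25)
        for _ in range(20):
            cohort = random_cohort(rng)
            regions = ["R1", "R2", "R3", "R4"]
            venn = region_intersection(cohort, regions)
            # brute-force membership-vector tally
            sets = {
                r: set().union(*(cohort.sample_variants(s)
                                 for s in cohort.metadata.index[
                                     cohort.metadata["region"] == r]))
                for r in regions
            }
            universe = set().union(*sets.values())
            for k in universe:
                members = frozenset(r for r in regions if k in sets[r])
                assert venn.cells[members] >= 1
            assert sum(venn.cells.values()) == venn.total_distinct == len(universe)

    def test_empty_region_rejected(self):
        calls = {"a": [key(1)]}
        meta = pd.DataFrame({"region": ["R1"]}, index=["a"])
        with pytest.raises(ValueError, match="no samples"):
            region_intersection(CohortTable.from_calls(calls, meta), ["R1", "R9"])


class TestNormalisation:
    def test_zero_variants(self):
        assert normalize_variant_count(0, 1e-4) == 0

    def test_arithmetic(self):
        assert normalize_variant_count(10, 2e-4) == pytest.approx(50_000)

    def test_doubling_content_halves_count(self):
        assert normalize_variant_count(10, 2e-4) == pytest.approx(
            2 * normalize_variant_count(10, 4e-4)
        )

    def test_zero_content_rejected(self):
        with pytest.raises(ValueError):
            normalize_variant_count(5, 0.0)


class TestSharedVariants:
    def test_identical_sets(self):
        ks = [key(i) for i in range(1, 8)]
        assert shared_variants(ks, list(ks)) == 7

    def test_disjoint_sets(self):
        assert shared_variants([key(1)], [key(2)]) == 0


class TestTopVariants:
    def test_packaged_ancestral_list(self):
        ancestral = load_ancestral_variants()
        for name in ("m.750A>G", "m.2706A>G", "m.263A>G", "m.15326A>G",
                     "m.9769delT", "m.12272delA"):
            assert parse_hgvs(name) in ancestral

    def test_ancestral_only_cohort_empties_table(self):
        ks = [parse_hgvs("m.750A>G"), parse_hgvs("m.263A>G")]
        cohort = CohortTable.from_calls({"a": ks, "b": ks})
        out = top_variants(cohort, k=5, exclude_ancestral=True)
        assert out.empty

    def test_ranking_matches_sorted_spectrum(self):
        rng = np.random.default_rng(26)
        cohort = random_cohort(rng)
        out = top_variants(cohort, k=5)
        freqs = frequency_spectrum(cohort).sort_values(ascending=False)
        assert out["frequency"].tolist() == sorted(
            out["frequency"], reverse=True
        )
        assert out["frequency"].iloc[0] == pytest.approx(freqs.iloc[0])

    def test_per_region_frequencies(self):
        calls = {"a": [key(1)], "b": [key(1)], "c": []}
        meta = pd.DataFrame({"region": ["R1", "R2", "R2"]}, index=["a", "b", "c"])
        out = top_variants(CohortTable.from_calls(calls, meta), k=1, per_region=True)
        assert out["freq_R1"].iloc[0] == pytest.approx(1.0)
        assert out["freq_R2"].iloc[0] == pytest.approx(0.5)

    def test_type_restriction(self):
        ks = [VariantKey(5, "A", "", DEL), key(9)]
        cohort = CohortTable.from_calls({"a": ks})
        out = top_variants(cohort, k=5, variant_types=[DEL])
        assert out["variant"].tolist() == ["m.5delA"]
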