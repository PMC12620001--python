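"""Marker maps, founder synthesis, traits, genotypic values and text formats."""

import numpy as np
import pytest

from softbreed import (
    MarkerMap,
    Population,
    TraitArchitecture,
    build_marker_map,
    genotypic_values,
    haldane,
    sample_trait,
    simulate_founders,
)
from softbreed.genome import (
    read_effects,
    read_haplotypes,
    read_marker_map,
    write_effects,
    write_haplotypes,
    write_marker_map,
    write_vcf,
)


class TestMarkerMap:
    def test_cross_chromosome_pairs_recombine_freely(self):
        gmap = build_marker_map([1, 1], spacing_cM=1.0)
        assert gmap.r_pair()[0, 1] == 0.5

    def test_cosited_markers_never_recombine(self):
        gmap = build_marker_map([2], positions=[np.array([5.0, 5.0])])
        assert gmap.r_pair()[0, 1] == 0.0

    def test_haldane_at_50_cM(self):
        gmap = build_marker_map([2], positions=[np.array([0.0, 50.0])])
        expected = 0.5 * (1 - np.exp(-1.0))
        assert gmap.r_pair()[0, 1] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3161, abs=5e-5)

    def test_r_pair_symmetric_zero_diag_bounded(self):
        gmap = build_marker_map([4, 3], spacing_cM=7.0)
        r = gmap.r_pair()
        np.testing.assert_allclose(r, r.T)
        np.testing.assert_allclose(np.diag(r), 0.0)
        assert np.all((r >= 0) & (r <= 0.5))
        assert np.all((gmap.r_adj >= 0) & (gmap.r_adj <= 0.5))

    def test_chromosome_starts_carry_virtual_half(self):
        gmap = build_marker_map([3, 2], spacing_cM=10.0)
        assert gmap.r_adj[0] == 0.5
        assert gmap.r_adj[3] == 0.5

    @pytest.mark.parametrize("bad", [lambda: build_marker_map([0, 2], spacing_cM=1.0),
                                     lambda: build_marker_map([2], spacing_cM=-1.0)])
    def test_rejects_degenerate_layouts(self, bad):
        with pytest.raises(ValueError):
            bad()

    def test_rejects_unsorted_positions(self):
        with pytest.raises(ValueError):
            MarkerMap(["a", "b"], np.array([1, 1]), np.array([2.0, 1.0]))


class TestFounders:
    def test_shape_and_binarity_scenario2_scale(self):
        gmap = build_marker_map([50] * 10, spacing_cM=2.0)
        pop = simulate_founders(gmap, 250, seed=3)
        assert pop.w.shape == (250, 1000)
        assert set(np.unique(pop.w)) <= {0, 1}

    def test_seed_reproducibility(self, tiny_map):
        a = simulate_founders(tiny_map, 30, seed=5)
        b = simulate_founders(tiny_map, 30, seed=5)
        np.testing.assert_array_equal(a.w, b.w)
        c = simulate_founders(tiny_map, 30, seed=6)
        assert not np.array_equal(a.w, c.w)

    def test_degenerate_frequency_target_is_hit(self):
        # maf fixed at 0.5 and no LD -> every marker near 0.5 within binomial error
        gmap = build_marker_map([40], spacing_cM=5.0)
        pop = simulate_founders(gmap, 2000, seed=7, maf_range=(0.5, 0.5),
                                ld_decay=100.0)
        freq = pop.w.reshape(-1, 40).mean()  # pooled over markers and haplotypes
        n_draws = 2 * 2000 * 40
        assert abs(freq - 0.5) < 4 * np.sqrt(0.25 / n_draws)

    def test_ld_decays_with_distance(self):
        gmap = build_marker_map([30], spacing_cM=2.0)
        pop = simulate_founders(gmap, 800, seed=8, maf_range=(0.3, 0.5), ld_decay=0.05)
        hap = np.concatenate([pop.w[:, :30], pop.w[:, 30:]], axis=0).astype(float)
        corr = np.corrcoef(hap.T)
        adjacent = np.mean([corr[j, j + 1] for j in range(29)])
        distant = np.mean([corr[j, j + 15] for j in range(15)])
        assert adjacent > distant + 0.1

    def test_invalid_maf_range_rejected(self, tiny_map):
        with pytest.raises(ValueError):
            simulate_founders(tiny_map, 10, seed=1, maf_range=(0.0, 0.5))


class TestTrait:
    def test_alpha_duplicates_beta(self, tiny_map):
        trait = sample_trait(tiny_map, seed=1)
        m = tiny_map.m
        assert len(trait.beta) == m and len(trait.alpha) == 2 * m
        np.testing.assert_array_equal(trait.alpha[:m], trait.alpha[m:])

    def test_seeded_and_mean_zero(self):
        gmap = build_marker_map([10000], spacing_cM=0.01)
        a = sample_trait(gmap, seed=4, effect_sd=1.0)
        b = sample_trait(gmap, seed=4, effect_sd=1.0)
        np.testing.assert_array_equal(a.beta, b.beta)
        assert abs(a.beta.mean()) < 3.0 / np.sqrt(10000)

    def test_rejects_nonpositive_sd(self, tiny_map):
        with pytest.raises(ValueError):
            sample_trait(tiny_map, seed=1, effect_sd=0.0)


class TestGenotypicValues:
    def test_matches_elementwise_oracle(self, rng):
        w = rng.integers(0, 2, size=(5, 6))
        trait = TraitArchitecture(rng.normal(size=3))
        vals = genotypic_values(Population(w), trait)
        oracle = np.array(
            [sum(trait.alpha[j] * w[i, j] for j in range(6)) for i in range(5)]
        )
        np.testing.assert_allclose(vals, oracle)

    def test_zero_genotype_and_single_marker(self):
        trait = TraitArchitecture([0.5])
        assert genotypic_values(Population(np.zeros((1, 2))), trait)[0] == 0.0
        assert genotypic_values(Population(np.ones((1, 2))), trait)[0] == pytest.approx(1.0)

    def test_linearity_in_effects(self, tiny_founders, tiny_trait):
        doubled = TraitArchitecture(2.0 * tiny_trait.beta)
        np.testing.assert_allclose(
            genotypic_values(tiny_founders, doubled),
            2.0 * genotypic_values(tiny_founders, tiny_trait),
        )

    def test_dimension_mismatch_rejected(self, tiny_founders):
        with pytest.raises(ValueError):
            genotypic_values(tiny_founders, TraitArchitecture(np.ones(5)))


class TestFormats:
    def test_round_trips(self, tmp_path, tiny_map, tiny_founders, tiny_trait):
        mp, hp, ep = tmp_path / "map.tsv", tmp_path / "hap.tsv", tmp_path / "eff.tsv"
        write_marker_map(tiny_map, mp)
        gmap2 = read_marker_map(mp)
        assert gmap2.marker_id == tiny_map.marker_id
        np.testing.assert_allclose(gmap2.pos_cM, tiny_map.pos_cM)
        write_haplotypes(tiny_founders, tiny_map, hp)
        pop2 = read_haplotypes(hp)
        np.testing.assert_array_equal(pop2.w, tiny_founders.w)
        write_effects(tiny_trait, tiny_map, ep)
        trait2 = read_effects(ep, tiny_map)
        np.testing.assert_allclose(trait2.beta, tiny_trait.beta)

    def test_nonbinary_haplotype_entry_reports_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\n0\t1\n0\t2\n")
        with pytest.raises(ValueError, match="row 3"):
            read_haplotypes(path)

    def test_unknown_marker_in_effects_rejected(self, tmp_path, tiny_map):
        path = tmp_path / "eff.tsv"
        path.write_text("marker_id\teffect\nNOPE\t1.0\n")
        with pytest.raises(ValueError, match="unknown|missing"):
            read_effects(path, tiny_map)

    def test_vcf_export_is_phased(self, tmp_path, tiny_map, tiny_founders):
        path = tmp_path / "out.vcf"
        write_vcf(tiny_founders, tiny_map, path)
        lines = path.read_text().splitlines()
        body = [l for l in lines if not l.startswith("#")]
        assert len(body) == tiny_map.m
        assert "|" in body[0].split("\t")[9]
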