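"""Fill-in imputation, multipoint genotype probabilities, dense projection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nampanel import codes, impute, simulate
from nampanel.types import Chromosome, GeneticMap, GenotypeMatrix

R, A, H, M = codes.REF, codes.ALT, codes.HET, codes.MISSING


def _single_line(calls, cm=None):
    calls = np.asarray([calls], dtype=np.int8)
    n = calls.shape[1]
    markers = np.array([f"m{j}" for j in range(n)], dtype=object)
    gmap = GeneticMap(pd.DataFrame({
        "chrom": "c1", "marker": markers,
        "bp": np.arange(1, n + 1) * 1000,
        "cM": np.arange(n, dtype=float) if cm is None else np.asarray(cm)}))
    return GenotypeMatrix(np.array(["L1"], dtype=object), markers, calls), gmap


class TestFillIn:
    @pytest.mark.parametrize("calls,expected", [
        ([R, M, R], [R, R, R]),                  # like flanks: filled
        ([R, M, A], [R, M, A]),                  # breakpoint region: untouched
        ([M, A, A], [M, A, A]),                  # chromosome end: untouched
        ([A, M, M, A, M], [A, A, A, A, M]),      # run fill + trailing end
        ([R, M, H], [R, M, H]),                  # HET flank: untouched
        ([H, M, H], [H, M, H]),                  # HET is not a homozygous anchor
    ])
    def test_run_rules(self, calls, expected):
        g, gmap = _single_line(calls)
        out, _ = impute.fill_in_missing(g, gmap)
        assert out.geno[0].tolist() == expected

    def test_origin_flags_and_report(self):
        g, gmap = _single_line([R, M, M, R, A])
        out, rep = impute.fill_in_missing(g, gmap)
        assert out.origin[0].tolist() == [0, 1, 1, 0, 0]
        assert rep.n_filled == 2
        assert rep.missing_fraction_after <= rep.missing_fraction_before

    @given(st.lists(st.sampled_from([R, A, H, M]), min_size=2, max_size=30))
    @settings(deadline=None, max_examples=100)
    def test_never_alters_observed_calls(self, calls):
        g, gmap = _single_line(calls)
        out, _ = impute.fill_in_missing(g, gmap)
        obs = g.geno != M
        assert np.array_equal(out.geno[obs], g.geno[obs])
        # missing fraction never increases
        assert (out.geno == M).sum() <= (g.geno == M).sum()


class TestGenotypeProbabilities:
    def test_single_marker_certain_call(self):
        g, gmap = _single_line([R])
        gp = impute.genotype_probabilities(g, gmap, epsilon=0.0)
        assert gp.probs[0, 0, 0] == pytest.approx(1.0)

    def test_all_missing_gives_stationary(self):
        g, gmap = _single_line([M, M, M, M])
        gp = impute.genotype_probabilities(g, gmap, epsilon=0.01)
        h = 0.5**7
        expected = np.array([(1 - h) / 2, (1 - h) / 2, h])
        assert np.allclose(gp.probs[0], expected[None, :], atol=1e-12)

    def test_rejects_unknown_code(self):
        g, gmap = _single_line([R, A])
        g.geno[0, 0] = 5
        with pytest.raises(ValueError):
            impute.genotype_probabilities(g, gmap)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_exhaustive_enumeration(self, trial):
        # forward-backward equals brute force over all 3^5 paths
        rng = np.random.default_rng(100 + trial)
        n_m = 5
        cm = np.concatenate([[0.0], np.sort(rng.uniform(0, 40, n_m - 1))])
        calls = rng.choice([R, A, H, M], size=n_m, p=[0.4, 0.4, 0.1, 0.1])
        g, gmap = _single_line(calls.tolist(), cm=cm)
        eps = 0.01
        gp = impute.genotype_probabilities(g, gmap, eps)
        h = 0.5**7
        pi = np.array([(1 - h) / 2, (1 - h) / 2, h])
        Ts = [impute._transition_matrix(cm[j + 1] - cm[j], h, "kosambi")
              for j in range(n_m - 1)]
        E = impute._emissions(g.geno, eps)[0]
        post = np.zeros((n_m, 3))
        tot = 0.0
        for path in itertools.product(range(3), repeat=n_m):
            p = pi[path[0]] * E[0, path[0]]
            for j in range(1, n_m):
                p *= Ts[j - 1][path[j - 1], path[j]] * E[j, path[j]]
            tot += p
            for j in range(n_m):
                post[j, path[j]] += p
        post /= tot
        assert np.abs(gp.probs[0] - post).max() < 1e-10


class TestFilterLowConfidence:
    def test_threshold_rules(self):
        g, gmap = _single_line([R, M, R])
        filled, _ = impute.fill_in_missing(g, gmap)
        probs = impute.genotype_probabilities(filled, gmap, epsilon=0.01)
        # confident fill survives
        kept, n_rm = impute.filter_low_confidence(filled, probs, 0.99)
        assert kept.geno[0, 1] == R and n_rm == 0
        # threshold 1.0 with eps > 0 reverts every filled call
        kept, n_rm = impute.filter_low_confidence(filled, probs, 1.0)
        assert kept.geno[0, 1] == M and n_rm == 1
        # observed calls untouched either way
        assert kept.geno[0, 0] == R and kept.geno[0, 2] == R

    def test_rejects_bad_threshold(self):
        g, gmap = _single_line([R, M, R])
        filled, _ = impute.fill_in_missing(g, gmap)
        probs = impute.genotype_probabilities(filled, gmap)
        with pytest.raises(ValueError):
            impute.filter_low_confidence(filled, probs, 0.4)


class TestConservativeImputePipeline:
    def test_drives_missingness_down(self, ril150_gbs, ril150_imputed):
        pop, report = ril150_imputed
        before = ril150_gbs.genotypes.missing_fraction()
        assert before == pytest.approx(0.216, abs=0.01)
        assert report.missing_fraction_after <= 0.03
        # observed calls preserved
        obs = ril150_gbs.genotypes.geno != M
        assert np.array_equal(pop.genotypes.geno[obs],
                              ril150_gbs.genotypes.geno[obs])


class TestDenseProjection:
    def _toy(self):
        # one chromosome, alternate parent REF at snp 2500 and ALT elsewhere
        chrom = Chromosome("c1", 10_000, 10.0)
        panel_pos = np.array([500, 1500, 2500, 3500, 4500], dtype=np.int64)
        alleles = np.array([[0, 0, 0, 0, 0],
                            [1, 1, 0, 1, 1]], dtype=np.uint8)
        from nampanel.types import FounderPanel
        panel = FounderPanel(["recurrent", "alt01"], [chrom],
                             {"c1": panel_pos}, {"c1": alleles})
        return panel

    def _pop(self, calls, bps):
        from nampanel.types import RILPopulation
        markers = np.array([f"c1_{b}" for b in bps], dtype=object)
        g = GenotypeMatrix(np.array(["L1"], dtype=object), markers,
                           np.asarray([calls], dtype=np.int8))
        gmap = GeneticMap(pd.DataFrame({
            "chrom": "c1", "marker": markers, "bp": bps,
            "cM": np.linspace(0, 5, len(bps))}))
        return RILPopulation("p", "alt01", 8, g, gmap)

    def test_alt_anchored_interval(self):
        panel = self._toy()
        pop = self._pop([A, A], [500, 4500])
        dense = impute.impute_parental_snps(pop, panel)
        # interior SNPs inherit the alternate parent's alleles: ALT at 1500
        # and 3500, REF at 2500 where the alternate carries the reference
        assert dense.geno[0].tolist() == [A, A, R, A, A]

    def test_unlike_anchors_stay_missing(self):
        panel = self._toy()
        pop = self._pop([R, A], [500, 4500])
        dense = impute.impute_parental_snps(pop, panel)
        assert dense.geno[0].tolist() == [R, M, M, M, A]

    def test_chromosome_ends_missing(self):
        panel = self._toy()
        pop = self._pop([A, A], [1500, 3500])
        dense = impute.impute_parental_snps(pop, panel)
        assert dense.geno[0].tolist() == [M, A, R, A, M]

    def test_het_anchor_not_anchoring(self):
        panel = self._toy()
        pop = self._pop([A, H, A], [500, 2500, 4500])
        dense = impute.impute_parental_snps(pop, panel)
        # HET call is skipped; interval (500, 4500) still like-anchored
        assert dense.geno[0].tolist() == [A, A, R, A, A]

    def test_error_rate_bounded_by_double_crossover_model(
            self, ril150_panel, ril150_raw, ril150_imputed):
        pop, _ = ril150_imputed
        dense = impute.impute_parental_snps(pop, ril150_panel)
        alt_row = ril150_panel.founder_row(pop.alt_parent)
        n_proj, n_err, bound_sum = 0, 0, 0.0
        for chrom in ril150_panel.snp_positions:
            cmask = np.array([m.startswith(chrom + "_")
                              for m in dense.marker_ids])
            pos = ril150_panel.snp_positions[chrom]
            truth = ril150_raw.truth_genotypes(chrom, pos)
            alt_al = ril150_panel.snp_alleles[chrom][alt_row]
            expected = np.where(truth == A, alt_al[None, :],
                                np.where(truth == R, 0, -9))
            block = dense.geno[:, cmask]
            proj = ((dense.origin[:, cmask] == codes.ORIGIN_PROJECTED)
                    & (block != M) & (expected != -9))
            n_proj += int(proj.sum())
            n_err += int((block[proj] != expected[proj]).sum())
        # bound: (d/100)^2 of the largest anchored interval in the map
        gmap = pop.genetic_map
        rate_bound = impute.double_crossover_error_rate(
            float(np.max([np.diff(gmap.chrom_table(c)["cM"].to_numpy()).max()
                          for c in gmap.chromosomes()])))
        assert n_proj > 10_000
        err_rate = n_err / n_proj
        assert err_rate <= rate_bound + 3 * np.sqrt(
            rate_bound * (1 - rate_bound) / n_proj)
        assert err_rate < 0.001  # < 0.1% overall at study-like density


class TestDoubleCrossoverModel:
    def test_printed_values(self):
        assert impute.double_crossover_error_rate(0.4) * 100 == \
            pytest.approx(0.0016)
        assert impute.double_crossover_error_rate(13.9) * 100 == \
            pytest.approx(1.93, abs=0.005)
        assert impute.double_crossover_error_rate(0.0) == 0.0

    def test_kosambi_variant_smaller(self):
        d = 13.9
        assert impute.double_crossover_error_rate(d, "kosambi") < \
            impute.double_crossover_error_rate(d)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            impute.double_crossover_error_rate(-1.0)
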