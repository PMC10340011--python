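"""Screening strategies: Fisher oracle, pattern filters, verdict logic."""

import math

import numpy as np
import pytest
from scipy import stats

from sexscan.model import (
    GenotypeMatrix,
    LocusRecord,
    Pattern,
    Sex,
    SexRegistry,
    Strategy,
    TagCatalog,
    TagRecord,
)
from sexscan.scan import (
    ScreenConfig,
    classify_system,
    scan_all,
    screen_allele_freq,
    screen_heterozygosity,
    screen_sex_limited,
)


def fisher_two_sided_oracle(a, b, c, d) -> float:
    """Independent oracle: enumerate all 2x2 tables with the observed margins
    and sum hypergeometric point probabilities <= the observed one."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, k - r2), min(r1, k)

    def point(x):
        return (math.comb(r1, x) * math.comb(r2, k - x)) / math.comb(n, k)

    p_obs = point(a)
    return min(1.0, sum(point(x) for x in range(lo, hi + 1)
                        if point(x) <= p_obs * (1 + 1e-9)))


def _matrix_from_genotypes(per_locus, samples):
    """per_locus: list of dicts sample -> (a, b) allele index pairs."""
    loci = [LocusRecord(f"t{i}:{0}", f"t{i}", 0, "A", ("T",))
            for i in range(len(per_locus))]
    gt = np.array([[row.get(s, (-1, -1)) for s in samples] for row in per_locus],
                  dtype=np.int16)
    return GenotypeMatrix(loci, samples, gt)


def _registry(n_f, n_m):
    return SexRegistry({**{f"F{i}": Sex.F for i in range(n_f)},
                        **{f"M{i}": Sex.M for i in range(n_m)}})


class TestAlleleFreqScreen:
    def _one_locus_matrix(self, f_genos, m_genos):
        reg = _registry(len(f_genos), len(m_genos))
        row = {f"F{i}": g for i, g in enumerate(f_genos)}
        row.update({f"M{i}": g for i, g in enumerate(m_genos)})
        return _matrix_from_genotypes([row], reg.samples), reg

    def test_female_limited_alt_is_zw_candidate(self):
        # F alleles ref=10/alt=10 (10 hets), M alleles ref=20/alt=0
        gm, reg = self._one_locus_matrix([(0, 1)] * 10, [(0, 0)] * 10)
        cands = screen_allele_freq(gm, reg, ScreenConfig())
        assert len(cands) == 1 and cands[0].pattern is Pattern.ZW
        assert cands[0].p_raw == pytest.approx(
            fisher_two_sided_oracle(10, 10, 20, 0), abs=1e-12)

    def test_mirrored_table_same_p_pattern_xy(self):
        gm_zw, reg = self._one_locus_matrix([(0, 1)] * 10, [(0, 0)] * 10)
        gm_xy, _ = self._one_locus_matrix([(0, 0)] * 10, [(0, 1)] * 10)
        zw = screen_allele_freq(gm_zw, reg, ScreenConfig())
        xy = screen_allele_freq(gm_xy, reg, ScreenConfig())
        assert xy[0].pattern is Pattern.XY
        assert zw[0].p_raw == pytest.approx(xy[0].p_raw, abs=1e-15)

    def test_identical_counts_not_candidate(self):
        gm, reg = self._one_locus_matrix([(0, 1)] * 10, [(0, 1)] * 10)
        assert screen_allele_freq(gm, reg, ScreenConfig()) == []

    def test_low_call_rate_locus_skipped(self):
        f = [(0, 1)] * 7 + [(-1, -1)] * 3
        m = [(0, 0)] * 10
        gm, reg = self._one_locus_matrix(f, m)
        assert screen_allele_freq(gm, reg, ScreenConfig(min_call_frac=0.8)) == []

    @pytest.mark.parametrize("table", [(5, 5, 10, 0), (2, 8, 9, 1), (0, 10, 10, 0),
                                       (7, 3, 3, 7), (1, 1, 1, 1), (12, 0, 0, 12)])
    def test_fisher_matches_enumeration(self, table):
        a, b, c, d = table
        p_scipy = stats.fisher_exact([[a, b], [c, d]], "two-sided")[1]
        assert p_scipy == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-12)


class TestHeterozygosityScreen:
    def _matrix(self, f_genos, m_genos):
        reg = _registry(len(f_genos), len(m_genos))
        row = {f"F{i}": g for i, g in enumerate(f_genos)}
        row.update({f"M{i}": g for i, g in enumerate(m_genos)})
        return _matrix_from_genotypes([row], reg.samples), reg

    def test_all_f_het_all_m_hom_is_zw(self):
        gm, reg = self._matrix([(0, 1)] * 10, [(0, 0)] * 5 + [(1, 1)] * 5)
        cands = screen_heterozygosity(gm, reg, ScreenConfig())
        assert len(cands) == 1
        assert cands[0].pattern is Pattern.ZW
        assert cands[0].strategy is Strategy.HETEROZYGOSITY

    def test_mirror_is_xy(self):
        gm, reg = self._matrix([(0, 0)] * 10, [(0, 1)] * 10)
        cands = screen_heterozygosity(gm, reg, ScreenConfig())
        assert [c.pattern for c in cands] == [Pattern.XY]

    def test_one_discordant_female_fails_strict_rule(self):
        gm, reg = self._matrix([(0, 1)] * 9 + [(0, 0)], [(0, 0)] * 10)
        assert screen_heterozygosity(gm, reg, ScreenConfig()) == []

    def test_false_positive_rate_matches_closed_form(self):
        """Autosomal HWE locus at MAF 0.5, 10F+10M: P(strict ZW rule) =
        (1/2)^20; Monte-Carlo agreement within 3 binomial SEs."""
        rng = np.random.default_rng(0)
        n_loci, n = 100_000, 20
        hap = rng.random((n_loci, n, 2)) < 0.5
        het = hap[..., 0] != hap[..., 1]
        passes = het[:, :10].all(axis=1) & (~het[:, 10:]).all(axis=1)
        p = 0.5 ** 20
        se = math.sqrt(n_loci * p * (1 - p))
        assert abs(passes.sum() - n_loci * p) <= 3 * se


class TestSexLimitedScreen:
    def _catalog(self, present_f, present_m, n_f=5, n_m=5):
        tc = TagCatalog()
        seqs = {}
        seqs.update({f"F{i}": ["ACGTACGTAC"] for i in range(present_f)})
        seqs.update({f"M{i}": ["ACGTACGTAC"] for i in range(present_m)})
        tc.tags["CLocus_1"] = TagRecord("CLocus_1", "ACGTACGTAC", seqs)
        return tc, _registry(n_f, n_m)

    def test_female_only_tag_is_zw(self):
        tc, reg = self._catalog(present_f=5, present_m=0)
        cands = screen_sex_limited(tc, reg, ScreenConfig())
        assert len(cands) == 1 and cands[0].pattern is Pattern.ZW
        assert (cands[0].n_present_f, cands[0].n_present_m) == (5, 0)

    def test_ubiquitous_tag_not_candidate(self):
        tc, reg = self._catalog(present_f=5, present_m=5)
        assert screen_sex_limited(tc, reg, ScreenConfig()) == []

    def test_leak_budget(self):
        tc, reg = self._catalog(present_f=5, present_m=1)
        assert screen_sex_limited(tc, reg, ScreenConfig(max_leak=0)) == []
        cands = screen_sex_limited(tc, reg, ScreenConfig(max_leak=1))
        assert [c.pattern for c in cands] == [Pattern.ZW]

    def test_monotonicity_in_thresholds(self, noisy_zw):
        """Lowering the presence fraction or raising max_leak never shrinks
        the candidate set."""
        ds = noisy_zw
        base = {c.tag_id for c in screen_sex_limited(
            ds.catalog, ds.registry, ScreenConfig(presence_frac=1.0, max_leak=0))}
        looser = {c.tag_id for c in screen_sex_limited(
            ds.catalog, ds.registry, ScreenConfig(presence_frac=0.7, max_leak=1))}
        assert base <= looser


class TestClassify:
    def test_study_shaped_tally_is_zw(self):
        snps = ([_snp(Pattern.ZW)] * 164) + ([_snp(Pattern.XY)] * 3)
        v = classify_system(snps, [])
        assert v.verdict == "ZW"
        assert v.dominance_ratio == pytest.approx(164 / 167)

    def test_zero_candidates_inconclusive(self):
        v = classify_system([], [])
        assert v.verdict == "inconclusive" and v.dominance_ratio is None

    def test_tie_inconclusive(self):
        snps = [_snp(Pattern.ZW)] * 5 + [_snp(Pattern.XY)] * 5
        assert classify_system(snps, []).verdict == "inconclusive"


def _snp(pattern):
    from sexscan.scan import CandidateSNP, SexCounts

    return CandidateSNP("x:0", "x", Strategy.ALLELE_FREQ, pattern, 0.001, 0.01,
                        SexCounts(0, 10, 0, 0), SexCounts(10, 0, 0, 0))


class TestOnSimulation:
    def test_clean_data_pattern_screens_are_exact(self, clean_zw):
        """Strategies (ii)+(iii) jointly recover every planted tag and no
        autosomal tag on noiseless data at strict thresholds."""
        ds = clean_zw
        cfg = ScreenConfig(het_presence_frac=1.0, hom_presence_frac=1.0,
                           presence_frac=1.0, max_leak=0)
        het = screen_heterozygosity(ds.genotypes, ds.registry, cfg)
        lim = screen_sex_limited(ds.catalog, ds.registry, cfg)
        found = {c.tag_id for c in het} | {c.tag_id for c in lim}
        from sexscan.simulate import TagClass

        assert found == ds.truth.sex_linked
        assert {c.tag_id for c in lim} == set(ds.truth.of_class(TagClass.W_LIMITED))

    def test_sex_swap_antisymmetry(self, clean_zw):
        """Relabeling F<->M maps every ZW candidate to an XY candidate with
        identical statistics and flips the verdict."""
        ds = clean_zw
        snps, tags, v = scan_all(ds.genotypes, ds.catalog, ds.registry)
        s_snps, s_tags, s_v = scan_all(ds.genotypes, ds.catalog,
                                       ds.registry.swapped())
        flip = {Pattern.ZW: Pattern.XY, Pattern.XY: Pattern.ZW}
        assert {(c.locus_id, c.strategy, flip[c.pattern], c.p_raw) for c in snps} \
            == {(c.locus_id, c.strategy, c.pattern, c.p_raw) for c in s_snps}
        assert {(c.tag_id, flip[c.pattern]) for c in tags} \
            == {(c.tag_id, c.pattern) for c in s_tags}
        assert (v.verdict, s_v.verdict) == ("ZW", "XY")
        assert v.dominance_ratio == s_v.dominance_ratio
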