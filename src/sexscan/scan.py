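"""Sex-linked locus screening and sex-determination system classification.

Three strategies, symmetric in the two heterogamety systems:

(i)   allele-frequency screen — per biallelic SNP, a two-sided Fisher's exact
      test on the 2x2 table of allele counts (females vs males x ref vs alt),
      Benjamini-Hochberg corrected within the strategy; the pattern (ZW vs XY)
      follows the sex toward which the minor allele is biased;
(ii)  heterozygosity screen — deterministic pattern filter: all (or a
      configured fraction of) genotyped heterogametic-sex samples are
      heterozygous while the homogametic sex is homozygous;
(iii) sex-limited screen — tag presence/absence: a tag observed in (a
      fraction of) one sex and in at most ``max_leak`` samples of the other.

A ZW candidate under (i)/(ii) is a SNP with female-specific variation, under
(iii) a whole tag restricted to females (a W-borne fragment). XY is the exact
mirror. The pooled ZW-vs-XY tally yields the system verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import GenotypeMatrix, Pattern, Sex, SexRegistry, Strategy, TagCatalog


@dataclass
class ScreenConfig:
    """Screening thresholds. The source screening protocol states none, so
    every choice is explicit and overridable here."""

    min_call_frac: float = 0.8  # fraction of each sex that must be genotyped
    het_presence_frac: float = 1.0  # het-sex fraction matching the SNP pattern
    hom_presence_frac: float = 1.0  # hom-sex fraction matching the SNP pattern
    presence_frac: float = 0.9  # sex fraction carrying a sex-limited tag
    max_leak: int = 0  # opposite-sex samples allowed to carry a sex-limited tag
    alpha: float = 0.05
    mt_method: str = "fdr_bh"
    min_mac: int = 2  # pooled minor-allele-count floor for strategy (i)
    # polarization of significant loci: the minor allele must be near-absent
    # in one sex and appreciably carried by the other, else no pattern is
    # assigned and the locus is dropped
    pattern_absence_frac: float = 0.05
    pattern_presence_frac: float = 0.25
    min_samples_per_sex: int = 2
    confirm_max_leak_alleles: int = 1  # error tolerance in the confirmation step
    decision_threshold: float = 0.9

    def __post_init__(self):
        for f in (self.min_call_frac, self.het_presence_frac,
                  self.hom_presence_frac, self.presence_frac,
                  self.decision_threshold):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class SexCounts:
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int


@dataclass
class CandidateSNP:
    locus_id: str
    tag_id: str
    strategy: Strategy
    pattern: Pattern
    p_raw: float | None
    p_adj: float | None
    counts_f: SexCounts
    counts_m: SexCounts


@dataclass
class CandidateTag:
    tag_id: str
    pattern: Pattern
    n_present_f: int
    n_present_m: int
    n_total_f: int
    n_total_m: int
    strategy: Strategy = Strategy.SEX_LIMITED


@dataclass
class SystemVerdict:
    verdict: str  # "ZW" | "XY" | "inconclusive"
    n_zw_snps: int
    n_xy_snps: int
    n_zw_tags: int
    n_xy_tags: int
    dominance_ratio: float | None

    @property
    def n_zw(self) -> int:
        return self.n_zw_snps + self.n_zw_tags

    @property
    def n_xy(self) -> int:
        return self.n_xy_snps + self.n_xy_tags


def fisher_two_sided(f_ref: int, f_alt: int, m_ref: int, m_alt: int) -> float:
    """Two-sided Fisher's exact p for the per-sex allele-count table."""
    return float(stats.fisher_exact([[f_ref, f_alt], [m_ref, m_alt]],
                                    alternative="two-sided")[1])


def _sex_masks(gm: GenotypeMatrix, reg: SexRegistry):
    reg.require_both_sexes()
    in_matrix = set(gm.samples)
    f_idx = gm.sample_index([s for s in reg.females if s in in_matrix])
    m_idx = gm.sample_index([s for s in reg.males if s in in_matrix])
    if len(f_idx) < 1 or len(m_idx) < 1:
        raise ValueError("genotype matrix lacks samples of one sex")
    return f_idx, m_idx


def _callrate_ok(missing, f_idx, m_idx, cfg):
    """Per-locus boolean: both sexes genotyped densely enough to screen."""
    ok = np.ones(missing.shape[0], dtype=bool)
    for idx in (f_idx, m_idx):
        n_called = (~missing[:, idx]).sum(axis=1)
        ok &= n_called >= max(cfg.min_samples_per_sex,
                              int(np.ceil(cfg.min_call_frac * len(idx))))
    return ok


def _counts(cls, idx) -> np.ndarray:
    return np.stack([cls[k][:, idx].sum(axis=1)
                     for k in ("hom_ref", "het", "hom_alt", "missing")], axis=1)


def screen_allele_freq(gm: GenotypeMatrix, reg: SexRegistry,
                       cfg: ScreenConfig | None = None) -> list[CandidateSNP]:
    """Strategy (i): Fisher's exact test on per-sex allele counts.

    Exact at the study's sample sizes (10+10); monomorphic, multi-allelic,
    low-call-rate and minor-allele-count < ``min_mac`` loci are skipped.
    """
    cfg = cfg or ScreenConfig()
    if gm.n_loci == 0:
        return []
    f_idx, m_idx = _sex_masks(gm, reg)
    cls = gm.genotype_classes()
    ok = _callrate_ok(cls["missing"], f_idx, m_idx, cfg)

    a, b = gm.gt[..., 0], gm.gt[..., 1]
    biallelic = np.array([len(loc.alt_alleles) == 1 for loc in gm.loci])
    # multi-allelic sites are retained in the matrix but only indices {0,1}
    # form a 2x2 allele table
    ok &= biallelic

    def allele_counts(idx):
        sub_a, sub_b = a[:, idx], b[:, idx]
        called = (sub_a >= 0)
        ref = ((sub_a == 0) & called).sum(axis=1) + ((sub_b == 0) & called).sum(axis=1)
        alt = ((sub_a == 1) & called).sum(axis=1) + ((sub_b == 1) & called).sum(axis=1)
        return ref, alt

    f_ref, f_alt = allele_counts(f_idx)
    m_ref, m_alt = allele_counts(m_idx)
    mac = np.minimum(f_ref + m_ref, f_alt + m_alt)
    ok &= mac >= cfg.min_mac  # also drops monomorphic loci (mac 0)

    tested = np.flatnonzero(ok)
    if tested.size == 0:
        return []
    pvals = np.array([
        fisher_two_sided(f_ref[i], f_alt[i], m_ref[i], m_alt[i]) for i in tested
    ])
    _, p_adj, _, _ = multipletests(pvals, alpha=cfg.alpha, method=cfg.mt_method)

    counts_f = _counts(cls, f_idx)
    counts_m = _counts(cls, m_idx)
    out: list[CandidateSNP] = []
    for j, i in enumerate(tested):
        if p_adj[j] >= cfg.alpha:
            continue
        pattern = _freq_pattern(f_ref[i], f_alt[i], m_ref[i], m_alt[i], cfg)
        if pattern is None:
            continue  # minor allele not polarized by sex: dropped
        loc = gm.loci[i]
        out.append(CandidateSNP(loc.locus_id, loc.tag_id, Strategy.ALLELE_FREQ,
                                pattern, float(pvals[j]), float(p_adj[j]),
                                SexCounts(*counts_f[i]), SexCounts(*counts_m[i])))
    return out


def _freq_pattern(f_ref, f_alt, m_ref, m_alt, cfg: ScreenConfig) -> Pattern | None:
    """ZW if the pooled minor allele is carried by females and near-absent in
    males, XY for the mirror; unpolarized loci get no pattern."""
    minor_is_alt = (f_alt + m_alt) <= (f_ref + m_ref)
    f_minor, f_tot = (f_alt, f_ref + f_alt) if minor_is_alt else (f_ref, f_ref + f_alt)
    m_minor, m_tot = (m_alt, m_ref + m_alt) if minor_is_alt else (m_ref, m_ref + m_alt)
    if f_tot == 0 or m_tot == 0:
        return None
    f_frac, m_frac = f_minor / f_tot, m_minor / m_tot
    tol = 1e-12
    zw = (m_frac <= cfg.pattern_absence_frac + tol
          and f_frac >= cfg.pattern_presence_frac - tol)
    xy = (f_frac <= cfg.pattern_absence_frac + tol
          and m_frac >= cfg.pattern_presence_frac - tol)
    if zw and not xy:
        return Pattern.ZW
    if xy and not zw:
        return Pattern.XY
    return None


def screen_heterozygosity(gm: GenotypeMatrix, reg: SexRegistry,
                          cfg: ScreenConfig | None = None) -> list[CandidateSNP]:
    """Strategy (ii): female-het / male-hom pattern filter (ZW), and mirror."""
    cfg = cfg or ScreenConfig()
    if gm.n_loci == 0:
        return []
    f_idx, m_idx = _sex_masks(gm, reg)
    cls = gm.genotype_classes()
    ok = _callrate_ok(cls["missing"], f_idx, m_idx, cfg)

    def fracs(idx):
        called = (~cls["missing"][:, idx]).sum(axis=1)
        het = cls["het"][:, idx].sum(axis=1)
        hom = cls["hom_ref"][:, idx].sum(axis=1) + cls["hom_alt"][:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return het / called, hom / called

    f_het, f_hom = fracs(f_idx)
    m_het, m_hom = fracs(m_idx)
    tol = 1e-12
    zw = ok & (f_het >= cfg.het_presence_frac - tol) & (m_hom >= cfg.hom_presence_frac - tol)
    xy = ok & (m_het >= cfg.het_presence_frac - tol) & (f_hom >= cfg.hom_presence_frac - tol)
    both = zw & xy
    if both.any() and cfg.het_presence_frac + cfg.hom_presence_frac > 1.0:
        raise AssertionError("locus matched both ZW and XY heterozygosity patterns")
    xy &= ~zw  # permissive thresholds: first-match precedence, documented

    counts_f = _counts(cls, f_idx)
    counts_m = _counts(cls, m_idx)
    out: list[CandidateSNP] = []
    for i in np.flatnonzero(zw | xy):
        loc = gm.loci[i]
        out.append(CandidateSNP(loc.locus_id, loc.tag_id, Strategy.HETEROZYGOSITY,
                                Pattern.ZW if zw[i] else Pattern.XY, None, None,
                                SexCounts(*counts_f[i]), SexCounts(*counts_m[i])))
    return out


def screen_sex_limited(tc: TagCatalog, reg: SexRegistry,
                       cfg: ScreenConfig | None = None) -> list[CandidateTag]:
    """Strategy (iii): tags observed in one sex only (up to ``max_leak``)."""
    cfg = cfg or ScreenConfig()
    reg.require_both_sexes()
    females, males = reg.females, reg.males
    out: list[CandidateTag] = []
    for rec in tc:
        n_f = sum(rec.present(s) for s in females)
        n_m = sum(rec.present(s) for s in males)
        zw = n_f >= np.ceil(cfg.presence_frac * len(females)) and n_m <= cfg.max_leak
        xy = n_m >= np.ceil(cfg.presence_frac * len(males)) and n_f <= cfg.max_leak
        if zw == xy:  # both (degenerate thresholds) or neither
            continue
        out.append(CandidateTag(rec.tag_id, Pattern.ZW if zw else Pattern.XY,
                                n_f, n_m, len(females), len(males)))
    return out


def classify_system(snps: list[CandidateSNP], tags: list[CandidateTag],
                    decision_threshold: float = 0.9) -> SystemVerdict:
    """Pooled ZW-vs-XY tally; majority pattern wins if dominant enough."""
    n_zw_snps = sum(1 for c in snps if c.pattern is Pattern.ZW)
    n_xy_snps = sum(1 for c in snps if c.pattern is Pattern.XY)
    n_zw_tags = sum(1 for c in tags if c.pattern is Pattern.ZW)
    n_xy_tags = sum(1 for c in tags if c.pattern is Pattern.XY)
    zw, xy = n_zw_snps + n_zw_tags, n_xy_snps + n_xy_tags
    total = zw + xy
    if total == 0:
        return SystemVerdict("inconclusive", 0, 0, 0, 0, None)
    dominance = max(zw, xy) / total
    if dominance >= decision_threshold:
        verdict = "ZW" if zw >= xy else "XY"
    else:
        verdict = "inconclusive"
    return SystemVerdict(verdict, n_zw_snps, n_xy_snps, n_zw_tags, n_xy_tags,
                         dominance)


def scan_all(gm: GenotypeMatrix, tc: TagCatalog, reg: SexRegistry,
             cfg: ScreenConfig | None = None):
    """Run all three strategies; returns (snp candidates, tag candidates, verdict)."""
    cfg = cfg or ScreenConfig()
    snps = screen_allele_freq(gm, reg, cfg) + screen_heterozygosity(gm, reg, cfg)
    tags = screen_sex_limited(tc, reg, cfg)
    verdict = classify_system(snps, tags, cfg.decision_threshold)
    return snps, tags, verdict
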