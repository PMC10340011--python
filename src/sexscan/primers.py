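"""PCR primer design for confirmed sex-linked markers, plus an in-silico gel.

Two validation modes mirror the wet-lab designs for a ZW marker:

* ``sex_specific`` — one primer's 3' terminal base sits exactly on a
  diagnostic site and equals the female-specific (W) base, so only W-bearing
  templates amplify: the expected gel shows bands in females and none in
  males;
* ``conserved`` — both primers sit in regions identical across sexes and the
  product spans at least one diagnostic site, so everyone amplifies and
  Sanger-style readout of the product shows heterozygous females and
  homozygous males.

The picker is a minimal deterministic search (no dimer/hairpin
thermodynamics): among all pairs satisfying the length, Tm, GC, homopolymer
and product-size constraints it returns the one minimizing
``|Tm_f - Tm_r| + |product_len - midpoint| / 100``, ties broken toward a
forward-anchored, leftmost, lexicographically smallest pair.
"""

from __future__ import annotations

import enum
import logging
from bisect import bisect_left
from dataclasses import dataclass

from .confirm import ConfirmedMarker
from .model import SexRegistry, TagCatalog, revcomp

log = logging.getLogger(__name__)


class PrimerMode(str, enum.Enum):
    SEX_SPECIFIC = "sex_specific"
    CONSERVED = "conserved"


@dataclass
class PrimerConfig:
    len_range: tuple[int, int] = (18, 24)
    product_range: tuple[int, int] = (250, 350)
    tm_target: float = 55.0  # deg C
    tm_window: float = 3.0
    gc_range: tuple[float, float] = (0.35, 0.65)
    max_homopolymer: int = 4

    def __post_init__(self):
        for lo, hi in (self.len_range, self.product_range, self.gc_range):
            if lo > hi:
                raise ValueError("degenerate range")


@dataclass
class PrimerPair:
    marker_id: str
    mode: PrimerMode
    fwd_seq: str  # 5'->3' on the plus strand of the tag
    rev_seq: str  # 5'->3' on the minus strand
    fwd_start: int  # 0-based tag coordinate of the forward primer's 5' end
    rev_end: int  # 0-based half-open end of the product
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float

    @property
    def product_len(self) -> int:
        return self.rev_end - self.fwd_start


@dataclass
class DesignResult:
    pair: PrimerPair | None
    reason: str | None = None  # machine-readable constraint that failed

    def __bool__(self) -> bool:
        return self.pair is not None


def gc_content(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT base in {seq!r}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temp(seq: str) -> float:
    """Wallace rule below 14 nt, GC-fraction formula otherwise."""
    n = len(seq)
    if not 10 <= n <= 36:
        raise ValueError(f"primer length {n} outside 10-36 nt")
    gc = seq.count("G") + seq.count("C")
    if n < 14:
        return 2.0 * (n - gc) + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / n


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _primer_ok(seq: str, cfg: PrimerConfig) -> bool:
    if set(seq) - set("ACGT"):
        return False
    tm = melting_temp(seq)
    gc = gc_content(seq)
    return (abs(tm - cfg.tm_target) <= cfg.tm_window
            and cfg.gc_range[0] <= gc <= cfg.gc_range[1]
            and _max_homopolymer(seq) <= cfg.max_homopolymer)


# a design candidate is the tuple
#   (score, orientation 0=fwd-anchored, fwd_start, fwd_seq, rev_end, rev_seq)
# whose natural ordering implements every documented tie-break


def _overlaps(sorted_pos: list[int], start: int, end: int) -> bool:
    i = bisect_left(sorted_pos, start)
    return i < len(sorted_pos) and sorted_pos[i] < end


def _feasible_windows(template: str, cfg: PrimerConfig, avoid: list[int]):
    """All (start, end, seq, tm) primer windows passing constraints, off `avoid`."""
    L = len(template)
    out = []
    for start in range(L):
        for plen in range(cfg.len_range[0], cfg.len_range[1] + 1):
            end = start + plen
            if end > L:
                break
            if _overlaps(avoid, start, end):
                continue
            seq = template[start:end]
            if _primer_ok(seq, cfg):
                out.append((start, end, seq, melting_temp(seq)))
    return out


def _pair_search(fwd_windows, rev_windows, pmin, pmax, cfg,
                 orient: int, span_diag: list[int] | None = None):
    """Best-scoring compatible (fwd, rev) placement, or None."""
    by_rend = sorted(rev_windows, key=lambda w: w[1])
    rends = [w[1] for w in by_rend]
    mid = (cfg.product_range[0] + cfg.product_range[1]) / 2
    best = None
    for fstart, fend, fwd, ftm in fwd_windows:
        lo = bisect_left(rends, fstart + pmin)
        for rstart, rend, rseq, rtm in by_rend[lo:]:
            if rend > fstart + pmax:
                break
            if rstart < fend:
                continue
            if span_diag is not None and not _overlaps(span_diag, fend, rstart):
                continue
            score = abs(ftm - rtm) + abs(rend - fstart - mid) / 100.0
            cand = (score, orient, fstart, fwd, rend, revcomp(rseq))
            if best is None or cand < best:
                best = cand
    return best


def _sex_specific_template(marker: ConfirmedMarker, consensus: str) -> str:
    """Tag sequence carrying the sex-specific base at every diagnostic site."""
    seq = list(consensus)
    for p, _shared, specific in marker.diag_sites:
        seq[p] = specific
    return "".join(seq)


def design_sex_specific_pair(marker: ConfirmedMarker, tc: TagCatalog,
                             cfg: PrimerConfig | None = None) -> DesignResult:
    """Anchor one primer's 3' terminus on a diagnostic site (allele-specific PCR).

    For whole-tag sex-limited markers any placement is sex-specific (the
    template itself is absent from the other sex), so the anchor and the
    partner's avoid-constraint are vacuous and the search reduces to the best
    pair anywhere on the tag.
    """
    cfg = cfg or PrimerConfig()
    err = _design_preconditions(marker, tc)
    if err:
        return err
    rec = tc[marker.tag_id]
    template = _sex_specific_template(marker, rec.consensus)
    L = len(template)
    pmin, pmax = _effective_product_range(L, cfg, marker.tag_id)
    diag = sorted(p for p, _, _ in marker.diag_sites)
    partner_avoid = [] if marker.sex_limited else diag

    partner = _feasible_windows(template, cfg, partner_avoid)
    if marker.sex_limited:
        best = _pair_search(partner, partner, pmin, pmax, cfg, orient=0)
    else:
        anchored_f, anchored_r = [], []
        for p in diag:
            for plen in range(cfg.len_range[0], cfg.len_range[1] + 1):
                if p - plen + 1 >= 0:
                    seq = template[p - plen + 1:p + 1]
                    if _primer_ok(seq, cfg):
                        anchored_f.append((p - plen + 1, p + 1, seq, melting_temp(seq)))
                if p + plen <= L:
                    seq = template[p:p + plen]
                    if _primer_ok(seq, cfg):
                        anchored_r.append((p, p + plen, seq, melting_temp(seq)))
        best = _min_cand(
            _pair_search(anchored_f, partner, pmin, pmax, cfg, orient=0),
            _pair_search(partner, anchored_r, pmin, pmax, cfg, orient=1),
        )
    if best is None:
        return DesignResult(None, "no_feasible_pair")
    return DesignResult(_mk_pair(marker.tag_id, PrimerMode.SEX_SPECIFIC, best))


def design_conserved_pair(marker: ConfirmedMarker, tc: TagCatalog,
                          cfg: PrimerConfig | None = None) -> DesignResult:
    """Both primers avoid diagnostic sites; the product must span one."""
    cfg = cfg or PrimerConfig()
    err = _design_preconditions(marker, tc)
    if err:
        return err
    rec = tc[marker.tag_id]
    template = rec.consensus
    pmin, pmax = _effective_product_range(len(template), cfg, marker.tag_id)
    diag = sorted(p for p, _, _ in marker.diag_sites)
    windows = _feasible_windows(template, cfg, diag)
    best = _pair_search(windows, windows, pmin, pmax, cfg, orient=0,
                        span_diag=diag)
    if best is None:
        return DesignResult(None, "no_feasible_pair")
    return DesignResult(_mk_pair(marker.tag_id, PrimerMode.CONSERVED, best))


def _design_preconditions(marker, tc) -> DesignResult | None:
    if not marker.confirmed:
        raise ValueError(f"marker {marker.tag_id} is not confirmed "
                         f"(status {marker.status.value})")
    if not marker.diag_sites:
        raise ValueError(f"marker {marker.tag_id} has no diagnostic sites")
    if marker.tag_id not in tc:
        return DesignResult(None, "tag_absent_from_catalog")
    return None


def _effective_product_range(L: int, cfg: PrimerConfig, tag_id: str):
    pmin, pmax = cfg.product_range
    if L < pmin:
        log.info("tag %s shorter than product minimum; relaxing range to tag length",
                 tag_id)
        pmin = 2 * cfg.len_range[0]
    return pmin, min(pmax, L)


def _min_cand(a, b):
    if a is None:
        return b
    if b is None:
        return a
    return min(a, b)


def _mk_pair(marker_id, mode, cand) -> PrimerPair:
    _score_, _orient, fstart, fwd, rend, rev = cand
    return PrimerPair(marker_id, mode, fwd, rev, fstart, rend,
                      melting_temp(fwd), melting_temp(rev),
                      gc_content(fwd), gc_content(rev))


# ---------------------------------------------------------------------------
# in-silico PCR / gel


def insilico_pcr(pair: PrimerPair, tc: TagCatalog, reg: SexRegistry,
                 max_5p_mismatches: int = 1) -> dict[str, bool]:
    """Band per sample: both primers must anneal on at least one allele.

    The 3' half of each primer (including the terminal base) must match
    exactly; up to ``max_5p_mismatches`` mismatches are tolerated in the
    5' half, mimicking permissive annealing away from the extension end.
    """
    if pair.marker_id not in tc:
        raise ValueError(f"tag {pair.marker_id} absent from catalog")
    rec = tc[pair.marker_id]
    f0, f1 = pair.fwd_start, pair.fwd_start + len(pair.fwd_seq)
    r0, r1 = pair.rev_end - len(pair.rev_seq), pair.rev_end
    rev_on_plus = revcomp(pair.rev_seq)

    bands: dict[str, bool] = {}
    for sample in reg.samples:
        alleles = rec.sample_alleles.get(sample) or []
        bands[sample] = any(
            _anneals(pair.fwd_seq, a[f0:f1], max_5p_mismatches, three_prime_right=True)
            and _anneals(rev_on_plus, a[r0:r1], max_5p_mismatches,
                         three_prime_right=False)
            for a in alleles
        )
    return bands


def _anneals(primer_on_plus: str, site: str, max_5p: int,
             three_prime_right: bool) -> bool:
    if len(site) != len(primer_on_plus):
        return False
    n = len(primer_on_plus)
    half = n // 2
    mism = [i for i in range(n) if primer_on_plus[i] != site[i]]
    if three_prime_right:
        three_p = [i for i in mism if i >= half]
        five_p = [i for i in mism if i < half]
    else:  # the primer's 3' end maps to the left edge of the plus-strand site
        three_p = [i for i in mism if i < n - half]
        five_p = [i for i in mism if i >= n - half]
    return not three_p and len(five_p) <= max_5p
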