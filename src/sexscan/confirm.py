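"""False-positive elimination against per-sample allele sequences.

A ZW candidate tag is confirmed when the per-sample sequences reproduce the
expected gametolog structure: males are sequence-homozygous, (a configured
fraction of) females are sequence-heterozygous, and at one or more positions
the females carry a W-specific base that is (up to a small error tolerance)
absent from every male allele. Those positions are the diagnostic sites that
primer design anchors on. Tags with no male sequence at all are W-limited
fragments and confirm as whole-tag sex-specific markers. XY is the mirror.

The catalog's alleles are column-aligned by construction (equal-length,
SNP-only model), so "homozygous / heterozygous by alignment" reduces to exact
column comparison. Because consensus alleles carry miscalls, tolerance is
applied per column: a diagnostic site may show the sex-specific base in at
most ``confirm_max_leak_alleles`` opposite-sex alleles (default 1, roughly
the expectation under a 0.5% per-base miscall rate over 20 alleles).
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass, field

from .model import Pattern, Sex, SexRegistry, TagCatalog
from .scan import CandidateSNP, CandidateTag, ScreenConfig


class ConfirmStatus(str, enum.Enum):
    CONFIRMED = "confirmed"
    REJECTED_MALE_HET = "rejected_male_het"
    REJECTED_FEMALE_HOM = "rejected_female_hom"
    REJECTED_VARIANT_LEAK = "rejected_variant_leak"
    INSUFFICIENT_DATA = "insufficient_data"


@dataclass
class ConfirmedMarker:
    tag_id: str
    pattern: Pattern
    status: ConfirmStatus
    diag_sites: list[tuple[int, str, str]] = field(default_factory=list)
    n_support_het: int = 0  # heterogametic-sex samples with data
    n_support_hom: int = 0  # homogametic-sex samples with data
    sex_limited: bool = False

    @property
    def confirmed(self) -> bool:
        return self.status is ConfirmStatus.CONFIRMED


def confirm_candidates(cands: list[CandidateSNP | CandidateTag], tc: TagCatalog,
                       reg: SexRegistry, cfg: ScreenConfig | None = None
                       ) -> list[ConfirmedMarker]:
    """Evaluate candidates tag by tag; SNP candidates collapse to their tag.

    One ConfirmedMarker per (tag, pattern); output ordered by tag id.
    """
    cfg = cfg or ScreenConfig()
    reg.require_both_sexes()
    seen: dict[tuple[str, Pattern], None] = {}
    for c in cands:
        seen.setdefault((c.tag_id, c.pattern), None)

    out = []
    for tag_id, pattern in sorted(seen, key=lambda k: (_tag_key(k[0]), k[1].value)):
        out.append(confirm_tag(tag_id, pattern, tc, reg, cfg))
    return out


def _tag_key(tag_id: str):
    head, _, tail = tag_id.partition("_")
    return (head, int(tail)) if tail.isdigit() else (tag_id, 0)


def confirm_tag(tag_id: str, pattern: Pattern, tc: TagCatalog, reg: SexRegistry,
                cfg: ScreenConfig) -> ConfirmedMarker:
    """Confirm or reject one candidate tag under the given pattern."""
    if tag_id not in tc:
        return ConfirmedMarker(tag_id, pattern, ConfirmStatus.INSUFFICIENT_DATA)
    rec = tc[tag_id]
    # the heterogametic sex carries the private (W or Y) variant
    het_ids, hom_ids = ((reg.females, reg.males) if pattern is Pattern.ZW
                        else (reg.males, reg.females))
    het_alleles = {s: rec.sample_alleles[s] for s in het_ids if rec.present(s)}
    hom_alleles = [a for s in hom_ids if rec.present(s) for a in rec.sample_alleles[s]]
    marker = ConfirmedMarker(tag_id, pattern, ConfirmStatus.INSUFFICIENT_DATA,
                             n_support_het=len(het_alleles),
                             n_support_hom=sum(rec.present(s) for s in hom_ids))
    if not het_alleles:
        return marker

    need_het = math.ceil(cfg.het_presence_frac * len(het_alleles))

    if not hom_alleles:
        # sex-limited fragment: every position is (trivially) sex-specific
        marker.status = ConfirmStatus.CONFIRMED
        marker.sex_limited = True
        marker.diag_sites = [(p, b, b) for p, b in enumerate(rec.consensus)]
        return marker

    # (b) enough heterogametic-sex samples must be sequence-heterozygous
    n_het = sum(1 for seqs in het_alleles.values() if len(set(seqs)) >= 2)
    if n_het < need_het:
        marker.status = ConfirmStatus.REJECTED_FEMALE_HOM
        return marker

    # shared-copy (Z) base = column majority over homogametic-sex alleles
    L = len(rec)
    shared = _column_consensus(hom_alleles, L)

    diag: list[tuple[int, str, str]] = []
    leaked = False
    leak_from_het_carrier = False
    e = cfg.confirm_max_leak_alleles
    for p in range(L):
        carrier_counts = Counter(seqs_base for seqs in het_alleles.values()
                                 for seqs_base in {a[p] for a in seqs})
        for b, n_carriers in sorted(carrier_counts.items()):
            if b == shared[p] or n_carriers < need_het:
                continue
            leak = sum(1 for a in hom_alleles if a[p] == b)
            if leak <= e:
                diag.append((p, shared[p], b))
            else:
                leaked = True
                # a homogametic-sex sample heterozygous for the sex-specific
                # base is direct evidence against sex linkage
                for s in hom_ids:
                    seqs = rec.sample_alleles.get(s) or []
                    if len(set(seqs)) >= 2 and any(a[p] == b for a in seqs):
                        leak_from_het_carrier = True

    if diag:
        marker.status = ConfirmStatus.CONFIRMED
        marker.diag_sites = diag
    elif leak_from_het_carrier:
        marker.status = ConfirmStatus.REJECTED_MALE_HET
    elif leaked:
        marker.status = ConfirmStatus.REJECTED_VARIANT_LEAK
    else:
        marker.status = ConfirmStatus.REJECTED_FEMALE_HOM
    return marker


def _column_consensus(alleles: list[str], L: int) -> str:
    out = []
    for p in range(L):
        counts = Counter(a[p] for a in alleles)
        out.append(max(sorted(counts), key=counts.get))
    return "".join(out)
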