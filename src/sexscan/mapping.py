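"""K-mer seed-and-extend marker-to-chromosome alignment with e-value filtering.

Confirmed markers are short (~300 bp) high-identity queries against a
chromosome-scale reference, so ungapped extension suffices: exact k-mer
seeds (default k=16) are extended in both directions under an x-drop rule
with +1/-2 match/mismatch scores, and each hit is assigned a BLAST-like
Karlin-Altschul e-value, E = K * m * n * exp(-lambda * S), with m the query
length and n the total reference length. Constants lambda and K are fixed
for the +1/-2 scheme, so e-values are BLAST-like rather than BLAST-identical;
they are used, as in the source protocol, only as a retention filter
(default E <= 1e-25). Per marker only the top-scoring hit is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ReferenceAssembly, revcomp


@dataclass
class MappingConfig:
    k: int = 16
    match: int = 1
    mismatch: int = -2
    xdrop: int = 20
    evalue_max: float = 1e-25
    karlin_lambda: float = 1.28  # for the +1/-2 scheme
    karlin_k: float = 0.46
    keep_all_hits: bool = False  # report every passing hit, not just the top

    def __post_init__(self):
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")


@dataclass
class AlignmentHit:
    marker_id: str
    chrom: str
    start: int  # 0-based half-open reference coords
    end: int
    strand: str  # "+" | "-"
    n_matches: int
    n_mismatches: int
    score: int
    evalue: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("hit start must be < end")


_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(vals: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-window (2 bits/base); -1 where a window
    contains a non-ACGT base."""
    n = len(vals) - k + 1
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        win = vals[i:i + n]
        codes = codes * 4 + np.maximum(win, 0)
        bad |= win < 0
    codes[bad] = -1
    return codes


@dataclass
class KmerIndex:
    """Sorted-array exact-match index of all plus-strand reference k-mers.

    Minus-strand matches are found by looking up the query's reverse
    complement, which is equivalent to indexing both strands.
    """

    k: int
    ref: ReferenceAssembly
    chrom_names: list[str]
    chrom_offsets: np.ndarray  # concatenated-coordinate start of each chrom
    sorted_codes: np.ndarray
    sorted_pos: np.ndarray  # concatenated coordinates, same order

    @classmethod
    def build(cls, ref: ReferenceAssembly, cfg: MappingConfig) -> "KmerIndex":
        shortest = min(len(s) for s in ref.chroms.values())
        if cfg.k > shortest:
            raise ValueError(f"k={cfg.k} exceeds shortest chromosome ({shortest} bp)")
        names = list(ref.chroms)
        offsets = np.cumsum([0] + [len(ref.chroms[c]) for c in names])
        codes_parts, pos_parts = [], []
        for name, off in zip(names, offsets):
            vals = _encode(ref.chroms[name])
            codes = _kmer_codes(vals, cfg.k)
            keep = codes >= 0
            codes_parts.append(codes[keep])
            pos_parts.append(np.flatnonzero(keep) + off)
        codes = np.concatenate(codes_parts)
        pos = np.concatenate(pos_parts)
        order = np.argsort(codes, kind="stable")
        return cls(cfg.k, ref, names, offsets, codes[order], pos[order])

    def _decode_pos(self, cat_pos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.chrom_offsets, cat_pos, side="right")) - 1
        return self.chrom_names[ci], int(cat_pos - self.chrom_offsets[ci])

    def lookup_code(self, code: int) -> list[tuple[str, int]]:
        lo = np.searchsorted(self.sorted_codes, code, side="left")
        hi = np.searchsorted(self.sorted_codes, code, side="right")
        return [self._decode_pos(p) for p in self.sorted_pos[lo:hi]]

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """Seed positions of a k-mer on either strand (plus-strand coords)."""
        vals = _encode(kmer)
        if len(vals) != self.k or (vals < 0).any():
            return []
        code = int(_kmer_codes(vals, self.k)[0])
        hits = self.lookup_code(code)
        rc = int(_kmer_codes(_encode(revcomp(kmer)), self.k)[0])
        if rc != code:
            hits += self.lookup_code(rc)
        return hits


def build_index(ref: ReferenceAssembly, cfg: MappingConfig | None = None) -> KmerIndex:
    return KmerIndex.build(ref, cfg or MappingConfig())


def evalue(score: float, m: int, n: int, cfg: MappingConfig) -> float:
    return cfg.karlin_k * m * n * float(np.exp(-cfg.karlin_lambda * score))


def map_markers(markers: dict[str, str], ref: ReferenceAssembly,
                cfg: MappingConfig | None = None,
                index: KmerIndex | None = None) -> list[AlignmentHit]:
    """Map marker sequences (id -> DNA) onto the reference.

    Returns the top-scoring passing hit per marker (ties broken by chrom
    name, then start), or every passing hit when ``keep_all_hits`` is set.
    """
    cfg = cfg or MappingConfig()
    if not ref.chroms:
        raise ValueError("empty reference")
    index = index or KmerIndex.build(ref, cfg)
    n_total = ref.total_length

    out: list[AlignmentHit] = []
    for marker_id in sorted(markers):
        qseq = markers[marker_id]
        if len(qseq) < cfg.k:
            raise ValueError(f"marker {marker_id} shorter than seed length")
        hits = _map_one(marker_id, qseq, index, cfg, n_total)
        hits = [h for h in hits if h.evalue <= cfg.evalue_max]
        if not hits:
            continue
        hits.sort(key=lambda h: (-h.score, h.chrom, h.start, h.strand))
        out.extend(hits if cfg.keep_all_hits else hits[:1])
    return out


def _map_one(marker_id, qseq, index, cfg, n_total) -> list[AlignmentHit]:
    m = len(qseq)
    best: dict[tuple[str, str, int], AlignmentHit] = {}
    for strand in "+-":
        q = qseq if strand == "+" else revcomp(qseq)
        qcodes = _kmer_codes(_encode(q), cfg.k)
        seen_diag: dict[tuple[str, int], int] = {}
        for qpos in range(m - cfg.k + 1):
            if qcodes[qpos] < 0:
                continue
            for chrom, rpos in index.lookup_code(int(qcodes[qpos])):
                diag = rpos - qpos
                # one extension per diagonal: seeds on the same gapless
                # alignment reproduce the same extension
                if seen_diag.get((chrom, diag)) is not None:
                    continue
                seen_diag[(chrom, diag)] = qpos
                hit = _extend(marker_id, q, index.ref.chroms[chrom], chrom,
                              qpos, rpos, strand, cfg, m, n_total)
                key = (chrom, strand, diag)
                if key not in best or hit.score > best[key].score:
                    best[key] = hit
    return list(best.values())


def _extend(marker_id, q, rseq, chrom, qpos, rpos, strand, cfg, m, n_total):
    """Ungapped x-drop extension from an exact seed."""
    k = cfg.k
    # right extension
    best_right, run = 0, 0
    qi, ri = qpos + k, rpos + k
    right_len = 0
    while qi + right_len < len(q) and ri + right_len < len(rseq):
        run += cfg.match if q[qi + right_len] == rseq[ri + right_len] else cfg.mismatch
        right_len += 1
        if run > best_right:
            best_right, best_right_len = run, right_len
        if best_right - run > cfg.xdrop:
            break
    right_len = best_right_len if best_right > 0 else 0
    # left extension
    best_left, run = 0, 0
    left_len = 0
    while qpos - left_len > 0 and rpos - left_len > 0:
        run += (cfg.match if q[qpos - left_len - 1] == rseq[rpos - left_len - 1]
                else cfg.mismatch)
        left_len += 1
        if run > best_left:
            best_left, best_left_len = run, left_len
        if best_left - run > cfg.xdrop:
            break
    left_len = best_left_len if best_left > 0 else 0

    a0, a1 = qpos - left_len, qpos + k + right_len
    r0, r1 = rpos - left_len, rpos + k + right_len
    n_match = sum(1 for x, y in zip(q[a0:a1], rseq[r0:r1]) if x == y)
    n_mm = (a1 - a0) - n_match
    score = cfg.match * n_match + cfg.mismatch * n_mm
    return AlignmentHit(marker_id, chrom, r0, r1, strand, n_match, n_mm, score,
                        evalue(score, m, n_total, cfg))


@dataclass
class ChromosomeTrack:
    chrom: str
    length: int
    hits: list[AlignmentHit]

    @property
    def count(self) -> int:
        return len(self.hits)


def chromosome_map(hits: list[AlignmentHit], ref: ReferenceAssembly
                   ) -> dict[str, ChromosomeTrack]:
    """Per-chromosome ordered marker track (the Fig-3-style ideogram)."""
    for h in hits:
        if h.chrom not in ref.chroms:
            raise ValueError(f"hit chromosome {h.chrom} not in reference")
    tracks = {chrom: ChromosomeTrack(chrom, len(seq), [])
              for chrom, seq in ref.chroms.items()}
    for h in sorted(hits, key=lambda h: (h.chrom, h.start, h.marker_id)):
        tracks[h.chrom].hits.append(h)
    return tracks


def ideogram_text(tracks: dict[str, ChromosomeTrack]) -> str:
    lines = []
    for chrom in sorted(tracks):
        t = tracks[chrom]
        lines.append(f"{chrom} ({t.length} bp): {t.count} marker(s)")
        for h in t.hits:
            lines.append(f"  {h.start:>10}-{h.end:<10} {h.strand} {h.marker_id}")
    return "\n".join(lines) + "\n"
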