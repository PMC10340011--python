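"""Readers and writers for every on-disk format the pipeline touches.

TSV sex tables, Stacks-style VCF genotypes (CHROM = tag id, POS = 1-based
position within the tag), tag FASTA with per-sample allele sequences,
reference FASTA, BED6 marker maps and newick trees. All writers emit LF
line endings and deterministic ordering.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .model import (
    MISSING,
    GenotypeMatrix,
    LocusRecord,
    ReferenceAssembly,
    Sex,
    SexRegistry,
    TagCatalog,
    TagRecord,
)

log = logging.getLogger(__name__)

_SEX_CODES = {"f": Sex.F, "female": Sex.F, "m": Sex.M, "male": Sex.M}

#: Stacks-like header dialect for per-sample tag alleles. The field study's
#: population.sample.fa grammar is undocumented upstream; this dialect is an
#: explicit assumption and can be overridden with any regex exposing named
#: groups ``tag``, ``sample`` and ``allele``.
TAG_HEADER_RE = re.compile(r"^CLocus_(?P<tag>\d+)_Sample_(?P<sample>.+)_Allele_(?P<allele>\d+)$")


# ---------------------------------------------------------------------------
# sex table


def read_sex_table(path: str | Path) -> SexRegistry:
    """Parse a 2-column TSV (sample_id, sex); header optional.

    Sex codes F/M/female/male are accepted case-insensitively; anything else
    is an error, not a guess.
    """
    entries: dict[str, Sex] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, code = parts[0].strip(), parts[1].strip()
            if lineno == 1 and code.lower() not in _SEX_CODES:
                # tolerate a header row
                continue
            if code.lower() not in _SEX_CODES:
                raise ValueError(f"{path}:{lineno}: unrecognized sex code {code!r}")
            if sid in entries:
                raise ValueError(f"duplicate sample_id {sid}")
            entries[sid] = _SEX_CODES[code.lower()]
    return SexRegistry(entries)


def write_sex_table(reg: SexRegistry, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("sample_id\tsex\n")
        for sid, sex in reg.entries.items():
            fh.write(f"{sid}\t{sex.value}\n")


# ---------------------------------------------------------------------------
# VCF


def _locus_id(tag_id: str, pos_in_tag: int) -> str:
    return f"{tag_id}:{pos_in_tag}"


def read_vcf(path: str | Path, registry: SexRegistry) -> GenotypeMatrix:
    """Read a Stacks-dialect VCF into a genotype matrix.

    CHROM carries the tag id and the 1-based POS is converted to a 0-based
    position within the tag. Samples absent from the registry are dropped
    with a warning; genotypes containing "." (including half-missing calls)
    are treated as missing.
    """
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    keep = [j for j, s in enumerate(vcf_samples) if s in registry.entries]
    dropped = [s for s in vcf_samples if s not in registry.entries]
    if dropped:
        log.warning("dropping %d VCF sample(s) absent from sex table: %s",
                    len(dropped), ", ".join(dropped))
    samples = [vcf_samples[j] for j in keep]

    loci: list[LocusRecord] = []
    rows = []
    for v in vcf:
        pos_in_tag = v.POS - 1
        alts = tuple(a for a in v.ALT if a not in (".", ""))
        loc = LocusRecord(_locus_id(v.CHROM, pos_in_tag), v.CHROM, pos_in_tag,
                          v.REF, alts)
        row = []
        for j in keep:
            g = v.genotypes[j]
            a, b = int(g[0]), int(g[1]) if len(g) > 2 else int(g[0])
            if a < 0 or b < 0:
                a = b = MISSING
            if max(a, b) > len(alts):
                raise ValueError(
                    f"malformed GT at {v.CHROM}:{v.POS} sample {vcf_samples[j]}: "
                    f"allele index exceeds ALT count")
            row.append((a, b))
        loci.append(loc)
        rows.append(row)
    vcf.close()
    gt = np.array(rows, dtype=np.int16) if rows else np.empty((0, len(samples), 2), np.int16)
    return GenotypeMatrix(loci, samples, gt)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix back out in the same Stacks VCF dialect."""
    order = sorted(range(gm.n_loci), key=lambda i: (gm.loci[i].tag_id, gm.loci[i].pos_in_tag))
    tags = sorted({loc.tag_id for loc in gm.loci})
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sexscan\n")
        for t in tags:
            fh.write(f"##contig=<ID={t}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for i in order:
            loc = gm.loci[i]
            alt = ",".join(loc.alt_alleles) if loc.alt_alleles else "."
            cells = []
            for a, b in gm.gt[i]:
                cells.append("./." if a < 0 or b < 0 else f"{a}/{b}")
            fh.write(f"{loc.tag_id}\t{loc.pos_in_tag + 1}\t{loc.locus_id}\t"
                     f"{loc.ref_allele}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# tag FASTA


def read_tag_fasta(path: str | Path, header_re: re.Pattern = TAG_HEADER_RE) -> TagCatalog:
    """Group per-sample allele sequences by tag; consensus = majority base.

    Headers must match ``header_re`` (default ``CLocus_<id>_Sample_<sid>_Allele_<k>``).
    """
    per_tag: dict[str, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    for rec in SeqIO.parse(str(path), "fasta"):
        m = header_re.match(rec.id)
        if not m:
            raise ValueError(f"unparseable tag FASTA header: {rec.id!r}")
        tag_id = f"CLocus_{m.group('tag')}"
        per_tag[tag_id][m.group("sample")].append(str(rec.seq).upper())

    catalog = TagCatalog()
    for tag_id, sample_alleles in per_tag.items():
        lengths = {len(s) for seqs in sample_alleles.values() for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"tag {tag_id}: allele sequences of unequal length")
        catalog.tags[tag_id] = TagRecord(
            tag_id, _majority_consensus(sample_alleles), dict(sample_alleles)
        )
    return catalog


def _majority_consensus(sample_alleles: dict[str, list[str]]) -> str:
    seqs = [s for alleles in sample_alleles.values() for s in alleles]
    out = []
    for col in zip(*seqs):
        counts: dict[str, int] = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        # highest count, alphabetical tie-break: deterministic consensus
        out.append(max(sorted(counts), key=counts.get))
    return "".join(out)


def write_tag_fasta(tc: TagCatalog, path: str | Path) -> None:
    recs = []
    for tag_id in sorted(tc.tags, key=_tag_sort_key):
        rec = tc[tag_id]
        num = tag_id.split("_", 1)[1]
        for sid in sorted(rec.sample_alleles):
            for k, seq in enumerate(rec.sample_alleles[sid]):
                recs.append(SeqRecord(Seq(seq), id=f"CLocus_{num}_Sample_{sid}_Allele_{k}",
                                      description=""))
    SeqIO.write(recs, str(path), "fasta-2line")


def _tag_sort_key(tag_id: str):
    head, _, tail = tag_id.partition("_")
    return (head, int(tail)) if tail.isdigit() else (tag_id, 0)


# ---------------------------------------------------------------------------
# reference FASTA


def read_reference(path: str | Path, metadata: str = "") -> ReferenceAssembly:
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome name {rec.id}")
        chroms[rec.id] = str(rec.seq).upper()
    if not chroms:
        raise ValueError(f"no sequences in {path}")
    return ReferenceAssembly(chroms, metadata or str(path))


def write_reference(ref: ReferenceAssembly, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in ref.chroms.items()]
    SeqIO.write(recs, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# BED


def write_bed(hits, path: str | Path) -> None:
    """BED6, 0-based half-open, score column = round(alignment score)."""
    for h in hits:
        if h.start >= h.end:
            raise ValueError(f"hit {h.marker_id}: start {h.start} >= end {h.end}")
    ordered = sorted(hits, key=lambda h: (h.chrom, h.start, h.marker_id))
    with open(path, "w", newline="\n") as fh:
        for h in ordered:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.marker_id}\t"
                     f"{round(h.score)}\t{h.strand}\n")


# ---------------------------------------------------------------------------
# newick


def write_newick(tree, path: str | Path) -> None:
    """Serialize a TreeNode with >= 6 significant digits on branch lengths."""
    tips = [t.name for t in tree.tips()]
    dup = {n for n in tips if tips.count(n) > 1}
    if dup:
        raise ValueError(f"duplicate tip labels: {sorted(dup)}")
    with open(path, "w", newline="\n") as fh:
        fh.write(newick_string(tree))
        fh.write("\n")


def newick_string(tree) -> str:
    def fmt(node) -> str:
        if node.is_tip():
            body = node.name or ""
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += node.name
        if node.length is not None:
            body += f":{node.length:.10g}"
        return body

    return fmt(tree) + ";"


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")
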