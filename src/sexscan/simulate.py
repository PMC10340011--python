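"""Synthetic Stacks-shaped GBS datasets with planted sex-linked structure.

The generator emulates the outputs of a RAD-locus caller on a female-
heterogametic (ZW) lizard screening design: 10 females + 10 males, 300-350 bp
tags, a background of autosomal tags segregating under Hardy-Weinberg,
W-limited tags present only in females, and Z/W gametolog tags carrying fixed
sex-diagnostic SNPs (females Z/W heterozygous, males Z/Z homozygous). Whole-
tag allelic dropout and per-base miscalls are applied after genotype
assignment, so error can create spurious heterozygotes. Sex-linked tag
sequences are planted verbatim into a synthetic reference (W-limited tags on
chrW, the Z haplotype of gametolog tags on chrZ) with recorded coordinates,
giving every downstream stage a ground truth to be scored against.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    DNA_ALPHABET,
    MISSING,
    GenotypeMatrix,
    LocusRecord,
    ReferenceAssembly,
    Sex,
    SexRegistry,
    TagCatalog,
    TagRecord,
    revcomp,
)

_BASES = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)


class TagClass(str, enum.Enum):
    AUTOSOMAL = "autosomal"
    W_LIMITED = "w_limited"
    ZW_SNP = "zw_snp"
    Z_LINKED = "z_linked"


class System(str, enum.Enum):
    ZW = "ZW"
    XY = "XY"
    NONE = "none"


@dataclass
class SimConfig:
    """Study conditions of the emulated screening design.

    Defaults follow the screening cohort (10 F + 10 M), the 300-350 bp GBS
    fragment window, and a 38 = 11 + 27 sex-linked tag accounting (11 of which
    are plantable on the W) so that pipeline outputs have a readable shape.
    """

    n_females: int = 10
    n_males: int = 10
    n_autosomal_tags: int = 200
    n_w_tags: int = 11
    n_zw_snp_tags: int = 27
    n_z_tags: int = 0
    tag_len_range: tuple[int, int] = (300, 350)
    snps_per_autosomal_tag: float = 1.5  # Poisson mean
    zw_snps_per_tag: float = 2.1  # Poisson mean on top of a guaranteed 1
    maf_range: tuple[float, float] = (0.05, 0.5)
    dropout: float = 0.05  # per-sample per-tag missing probability
    error: float = 0.005  # per-base miscall probability
    system: System = System.ZW
    ref_len: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        self.system = System(self.system)
        for p in (self.dropout, self.error):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for n in (self.n_females, self.n_males, self.n_autosomal_tags,
                  self.n_w_tags, self.n_zw_snp_tags, self.n_z_tags):
            if n < 0:
                raise ValueError("counts must be >= 0")


@dataclass
class TagTruth:
    tag_id: str
    tag_class: TagClass
    diag_sites: list[tuple[int, str, str]] = field(default_factory=list)
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None


@dataclass
class SimTruth:
    tags: dict[str, TagTruth]

    def of_class(self, cls: TagClass) -> list[str]:
        return [t for t, rec in self.tags.items() if rec.tag_class is cls]

    @property
    def sex_linked(self) -> set[str]:
        return {t for t, rec in self.tags.items()
                if rec.tag_class in (TagClass.W_LIMITED, TagClass.ZW_SNP)}


@dataclass
class SimDataset:
    cfg: SimConfig
    registry: SexRegistry
    genotypes: GenotypeMatrix
    catalog: TagCatalog
    reference: ReferenceAssembly
    truth: SimTruth


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Generate one dataset; byte-reproducible from (cfg, seed)."""
    rng = np.random.default_rng(cfg.seed)
    het_sex, hom_sex = (Sex.F, Sex.M) if cfg.system is not System.XY else (Sex.M, Sex.F)

    females = [f"F{i + 1:02d}" for i in range(cfg.n_females)]
    males = [f"M{i + 1:02d}" for i in range(cfg.n_males)]
    registry = SexRegistry({**{s: Sex.F for s in females}, **{s: Sex.M for s in males}})
    het_samples = females if het_sex is Sex.F else males
    hom_samples = males if het_sex is Sex.F else females
    all_samples = registry.samples

    plant = cfg.system is not System.NONE
    # private chromosome of the heterogametic sex, shared sex chromosome
    priv_chrom, shared_chrom = ("chrW", "chrZ") if cfg.system is not System.XY else ("chrY", "chrX")
    classes: list[TagClass] = []
    if plant:
        classes += [TagClass.ZW_SNP] * cfg.n_zw_snp_tags
        classes += [TagClass.W_LIMITED] * cfg.n_w_tags
        classes += [TagClass.Z_LINKED] * cfg.n_z_tags
    classes += [TagClass.AUTOSOMAL] * cfg.n_autosomal_tags

    truth: dict[str, TagTruth] = {}
    catalog = TagCatalog()
    plantings: list[tuple[str, str, np.ndarray]] = []  # (tag_id, chrom, seq)
    loci: list[LocusRecord] = []
    gt_rows: list[list[tuple[int, int]]] = []

    for idx, cls in enumerate(classes, start=1):
        tag_id = f"CLocus_{idx}"
        L = int(rng.integers(cfg.tag_len_range[0], cfg.tag_len_range[1] + 1))
        cons = rng.choice(_BASES, size=L)
        tt = TagTruth(tag_id, cls)

        # haplotype pair per sample (None = tag absent on that haplotype/sample)
        haps: dict[str, list[np.ndarray]] = {}
        if cls is TagClass.AUTOSOMAL:
            sites = _draw_sites(rng, L, rng.poisson(cfg.snps_per_autosomal_tag))
            alts = _draw_alts(rng, cons, sites)
            mafs = rng.uniform(*cfg.maf_range, size=len(sites))
            for s in all_samples:
                pair = []
                for _ in range(2):
                    h = cons.copy()
                    carry = rng.random(len(sites)) < mafs
                    h[sites[carry]] = alts[carry]
                    pair.append(h)
                haps[s] = pair
        elif cls is TagClass.ZW_SNP:
            n_diag = 1 + int(rng.poisson(cfg.zw_snps_per_tag))
            sites = _draw_sites(rng, L, n_diag)
            alts = _draw_alts(rng, cons, sites)
            w_hap = cons.copy()
            w_hap[sites] = alts
            for s in het_samples:
                haps[s] = [cons.copy(), w_hap.copy()]
            for s in hom_samples:
                haps[s] = [cons.copy(), cons.copy()]
            tt.diag_sites = [(int(p), chr(cons[p]), chr(a)) for p, a in zip(sites, alts)]
            plantings.append((tag_id, shared_chrom, cons.copy()))
        elif cls is TagClass.W_LIMITED:
            for s in het_samples:
                haps[s] = [cons.copy()]
            tt.diag_sites = [(p, chr(b), chr(b)) for p, b in enumerate(cons)]
            plantings.append((tag_id, priv_chrom, cons.copy()))
        else:  # Z_LINKED: diploid in the homogametic sex, hemizygous otherwise
            sites = _draw_sites(rng, L, rng.poisson(cfg.snps_per_autosomal_tag))
            alts = _draw_alts(rng, cons, sites)
            mafs = rng.uniform(*cfg.maf_range, size=len(sites))
            for s in all_samples:
                n_copies = 2 if s in hom_samples else 1
                pair = []
                for _ in range(n_copies):
                    h = cons.copy()
                    carry = rng.random(len(sites)) < mafs
                    h[sites[carry]] = alts[carry]
                    pair.append(h)
                haps[s] = pair

        # whole-tag dropout, then per-base miscalls
        for s in list(haps):
            if rng.random() < cfg.dropout:
                del haps[s]
                continue
            if cfg.error > 0:
                for h in haps[s]:
                    hits = np.flatnonzero(rng.random(L) < cfg.error)
                    for p in hits:
                        h[p] = _other_base(rng, h[p])

        tag_loci, tag_gt = _call_tag(tag_id, cons, haps, all_samples)
        loci.extend(tag_loci)
        gt_rows.extend(tag_gt)
        catalog.tags[tag_id] = TagRecord(
            tag_id,
            consensus="".join(map(chr, cons)),
            sample_alleles={
                s: sorted({h.tobytes().decode() for h in pair})
                for s, pair in haps.items()
            },
        )
        truth[tag_id] = tt

    gm = GenotypeMatrix(
        loci,
        all_samples,
        np.array(gt_rows, dtype=np.int16).reshape(len(loci), len(all_samples), 2),
    )
    reference = _build_reference(rng, cfg, plantings, truth,
                                 (priv_chrom, shared_chrom))
    return SimDataset(cfg, registry, gm, catalog, reference, SimTruth(truth))


def _draw_sites(rng, L: int, n: int) -> np.ndarray:
    n = int(min(n, L))
    return np.sort(rng.choice(L, size=n, replace=False)).astype(int)


def _draw_alts(rng, cons: np.ndarray, sites: np.ndarray) -> np.ndarray:
    return np.array([_other_base(rng, cons[p]) for p in sites], dtype=np.uint8)


def _other_base(rng, base: int) -> int:
    choices = _BASES[_BASES != base]
    return int(choices[rng.integers(len(choices))])


def _call_tag(tag_id, cons, haps, all_samples):
    """Emit one VCF-style locus per polymorphic column, like a RAD caller."""
    present = [s for s in all_samples if s in haps]
    if not present:
        return [], []
    mat = np.stack([h for s in present for h in haps[s]])
    poly = np.flatnonzero((mat != mat[0]).any(axis=0))
    loci, rows = [], []
    for p in poly:
        col = mat[:, p]
        bases, counts = np.unique(col, return_counts=True)
        # ref = majority base (alphabetical tie-break), alts by count then base
        order = sorted(range(len(bases)), key=lambda i: (-counts[i], bases[i]))
        ref = int(bases[order[0]])
        alts = [int(bases[i]) for i in order[1:]]
        index = {b: i for i, b in enumerate([ref] + alts)}
        loci.append(LocusRecord(f"{tag_id}:{p}", tag_id, int(p), chr(ref),
                                tuple(chr(b) for b in alts)))
        row = []
        for s in all_samples:
            if s not in haps:
                row.append((MISSING, MISSING))
            else:
                pair = haps[s]
                a = index[int(pair[0][p])]
                b = index[int(pair[-1][p])]
                row.append((min(a, b), max(a, b)))
        rows.append(row)
    return loci, rows


def _build_reference(rng, cfg, plantings, truth, chrom_names) -> ReferenceAssembly:
    chroms: dict[str, str] = {}
    by_chrom: dict[str, list[tuple[str, np.ndarray]]] = {}
    for tag_id, chrom, seq in plantings:
        by_chrom.setdefault(chrom, []).append((tag_id, seq))
    for chrom in chrom_names:
        seq = rng.choice(_BASES, size=cfg.ref_len)
        occupied: list[tuple[int, int]] = []
        for tag_id, tag_seq in by_chrom.get(chrom, []):
            L = len(tag_seq)
            start = _place_nonoverlapping(rng, cfg.ref_len, L, occupied)
            occupied.append((start, start + L))
            strand = "+" if rng.random() < 0.5 else "-"
            ins = tag_seq if strand == "+" else np.frombuffer(
                revcomp(tag_seq.tobytes().decode()).encode(), dtype=np.uint8)
            seq[start:start + L] = ins
            tt = truth[tag_id]
            tt.chrom, tt.start, tt.end, tt.strand = chrom, start, start + L, strand
        chroms[chrom] = seq.tobytes().decode()
    return ReferenceAssembly(chroms, metadata=f"synthetic seed={cfg.seed}")


def _place_nonoverlapping(rng, ref_len: int, L: int, occupied) -> int:
    for _ in range(10_000):
        start = int(rng.integers(0, ref_len - L))
        if all(start + L <= s or start >= e for s, e in occupied):
            return start
    raise RuntimeError("could not place tag without overlap; reference too short")


# ---------------------------------------------------------------------------
# gametolog sequence simulation


@dataclass
class SeqSet:
    """Labeled Z/W sequences across species for the gene-genealogy test."""

    records: list[tuple[str, str, str]]  # (label, seq, class "Z"|"W")

    @property
    def classes(self) -> dict[str, str]:
        return {label: cls for label, _, cls in self.records}


def simulate_gametologs(
    n_species: int,
    t_zw_split: float = 0.15,
    t_speciation_max: float = 0.05,
    seq_len: int = 300,
    seed: int = 0,
    enforce_history: bool = True,
) -> SeqSet:
    """Simulate Z and W gametologs under recombination-suppression-first history.

    One ancestral locus splits into a Z and a W copy diverged by
    ``2 * t_zw_split`` expected substitutions/site under Jukes-Cantor; each
    copy then evolves down one shared random ultrametric species tree of depth
    <= ``t_speciation_max``. With suppression predating speciation the gene
    genealogy clusters by gametolog, which is what the downstream test checks.
    """
    if enforce_history and t_zw_split <= t_speciation_max:
        raise ValueError(
            "t_zw_split must exceed t_speciation_max: a Z/W split younger than "
            "the speciations would not predict gametolog clustering")
    if n_species < 2:
        raise ValueError("need >= 2 species (>= 2 tips per gametolog class)")
    rng = np.random.default_rng(seed)
    root = rng.choice(_BASES, size=seq_len)
    z_root = _jc_evolve(rng, root, t_zw_split)
    w_root = _jc_evolve(rng, root, t_zw_split)

    depth = float(rng.uniform(0.5, 1.0) * t_speciation_max)
    topo = _random_coalescent(rng, n_species, depth)
    records = []
    for cls, seq0 in (("Z", z_root), ("W", w_root)):
        tips = _evolve_down(rng, topo, seq0)
        for sp, seq in sorted(tips.items()):
            records.append((f"{sp}_{cls}", seq.tobytes().decode(), cls))
    return SeqSet(records)


def _jc_evolve(rng, seq: np.ndarray, t: float) -> np.ndarray:
    """Jukes-Cantor: per-site substitution probability 3/4 (1 - exp(-4t/3))."""
    if t <= 0:
        return seq.copy()
    p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    out = seq.copy()
    for i in np.flatnonzero(rng.random(len(seq)) < p):
        out[i] = _other_base(rng, out[i])
    return out


def _random_coalescent(rng, n: int, depth: float):
    """Random ultrametric species tree as nested (child, branch_len) tuples."""
    times = np.sort(rng.uniform(0.0, depth, size=n - 1))
    times[-1] = depth  # root at the stated depth
    nodes = [(f"sp{i + 1}", 0.0) for i in range(n)]  # (subtree, height)
    for t in times:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (a, ha), (b, hb) = nodes[i], nodes[j]
        merged = (("node", (a, t - ha), (b, t - hb)), t)
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0][0]


def _evolve_down(rng, node, seq: np.ndarray) -> dict[str, np.ndarray]:
    if isinstance(node, str):
        return {node: seq}
    _, (left, bl), (right, br) = node
    out = {}
    out.update(_evolve_down(rng, left, _jc_evolve(rng, seq, bl)))
    out.update(_evolve_down(rng, right, _jc_evolve(rng, seq, br)))
    return out


# ---------------------------------------------------------------------------
# on-disk output


def write_dataset(ds: SimDataset, outdir: str | Path) -> dict[str, str]:
    """Write the five pipeline inputs plus a manifest; returns file paths."""
    from . import io as gio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sex_table": outdir / "sex.tsv",
        "vcf": outdir / "genotypes.vcf",
        "tag_fasta": outdir / "tags.fa",
        "reference": outdir / "reference.fa",
        "truth": outdir / "truth.tsv",
    }
    gio.write_sex_table(ds.registry, paths["sex_table"])
    gio.write_vcf(ds.genotypes, paths["vcf"])
    gio.write_tag_fasta(ds.catalog, paths["tag_fasta"])
    gio.write_reference(ds.reference, paths["reference"])
    write_truth(ds.truth, paths["truth"])

    manifest = {
        "config": {k: (v.value if isinstance(v, enum.Enum) else v)
                   for k, v in asdict(ds.cfg).items()},
        "seed": ds.cfg.seed,
        "files": {k: _sha256(p) for k, p in paths.items()},
    }
    with open(outdir / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(p) for k, p in paths.items()}


def write_truth(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("tag_id\tclass\tdiag_sites\tchrom\tstart\tend\tstrand\n")
        for tag_id in sorted(truth.tags, key=lambda t: int(t.split("_")[1])):
            tt = truth.tags[tag_id]
            sites = ";".join(f"{p}:{a}>{b}" for p, a, b in tt.diag_sites)
            fh.write(f"{tag_id}\t{tt.tag_class.value}\t{sites}\t"
                     f"{tt.chrom or '.'}\t{tt.start if tt.start is not None else '.'}\t"
                     f"{tt.end if tt.end is not None else '.'}\t{tt.strand or '.'}\n")


def read_truth(path: str | Path) -> SimTruth:
    tags: dict[str, TagTruth] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            tag_id, cls, sites, chrom, start, end, strand = line.rstrip("\n").split("\t")
            diag = []
            if sites:
                for item in sites.split(";"):
                    pos, change = item.split(":")
                    a, b = change.split(">")
                    diag.append((int(pos), a, b))
            tags[tag_id] = TagTruth(
                tag_id, TagClass(cls), diag,
                None if chrom == "." else chrom,
                None if start == "." else int(start),
                None if end == "." else int(end),
                None if strand == "." else strand,
            )
    return SimTruth(tags)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
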