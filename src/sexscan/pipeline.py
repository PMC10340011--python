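"""End-to-end orchestration: simulate/load -> scan -> confirm -> primers ->
map -> tree, with a machine-readable run report.

Every stage is a pure function of (inputs, config, seed); the report carries
the per-stage summary counts and the output manifest hashes verify reruns.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as gio
from .confirm import ConfirmedMarker, confirm_candidates
from .mapping import MappingConfig, chromosome_map, ideogram_text, map_markers
from .model import GenotypeMatrix, ReferenceAssembly, SexRegistry, TagCatalog
from .phylo import DistanceMatrix, gametolog_cluster_test, nj_build
from .primers import (
    DesignResult,
    PrimerConfig,
    design_conserved_pair,
    design_sex_specific_pair,
)
from .scan import ScreenConfig, scan_all
from .simulate import SimConfig, simulate_dataset, simulate_gametologs, write_dataset

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    primers: PrimerConfig = field(default_factory=PrimerConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    sim: SimConfig | None = field(default_factory=SimConfig)
    # input paths, used when sim is None
    sex_table: str | None = None
    vcf: str | None = None
    tag_fasta: str | None = None
    reference: str | None = None
    out_dir: str | None = None
    seed: int = 0
    run_tree_demo: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub_cls in (("screen", ScreenConfig), ("primers", PrimerConfig),
                             ("mapping", MappingConfig), ("sim", SimConfig)):
            if key in raw:
                val = raw.pop(key)
                kwargs[key] = None if val is None else _build(sub_cls, val)
        kwargs.update(raw)
        return cls(**kwargs)


def _build(cls, mapping: dict):
    mapping = {k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()}
    return cls(**mapping)


@dataclass
class RunReport:
    verdict: str
    dominance_ratio: float | None
    n_zw_snps: int
    n_xy_snps: int
    n_zw_tags: int
    n_xy_tags: int
    n_candidate_tags: int
    n_confirmed: int
    n_rejected: int
    n_primer_pairs: int
    mapped_per_chrom: dict[str, int]
    tree_verdict: str | None
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class RunResult:
    report: RunReport
    registry: SexRegistry
    genotypes: GenotypeMatrix
    catalog: TagCatalog
    reference: ReferenceAssembly | None
    snp_candidates: list
    tag_candidates: list
    markers: list[ConfirmedMarker]
    primer_designs: dict[str, DesignResult]
    hits: list
    truth: object | None = None


def run_all(cfg: RunConfig) -> RunResult:
    """Execute every stage in order; returns the report plus stage outputs."""
    truth = None
    if cfg.sim is not None:
        ds = simulate_dataset(cfg.sim)
        registry, gm, tc, ref, truth = (ds.registry, ds.genotypes, ds.catalog,
                                        ds.reference, ds.truth)
        if cfg.out_dir:
            write_dataset(ds, Path(cfg.out_dir) / "simulated")
    else:
        for name in ("sex_table", "vcf", "tag_fasta"):
            if getattr(cfg, name) is None:
                raise ValueError(f"stage scan: missing input {name}")
        registry = gio.read_sex_table(cfg.sex_table)
        gm = gio.read_vcf(cfg.vcf, registry)
        tc = gio.read_tag_fasta(cfg.tag_fasta)
        ref = gio.read_reference(cfg.reference) if cfg.reference else None

    snps, tags, verdict = scan_all(gm, tc, registry, cfg.screen)
    markers = confirm_candidates(snps + tags, tc, registry, cfg.screen)
    confirmed = [m for m in markers if m.confirmed]

    designs: dict[str, DesignResult] = {}
    for m in confirmed:
        res = design_sex_specific_pair(m, tc, cfg.primers)
        if not res:
            res = design_conserved_pair(m, tc, cfg.primers)
        designs[m.tag_id] = res

    hits = []
    mapped_per_chrom: dict[str, int] = {}
    if ref is not None and confirmed:
        marker_seqs = {m.tag_id: tc[m.tag_id].consensus for m in confirmed
                       if m.tag_id in tc}
        hits = map_markers(marker_seqs, ref, cfg.mapping)
        tracks = chromosome_map(hits, ref)
        mapped_per_chrom = {c: t.count for c, t in tracks.items()}

    tree_verdict = None
    if cfg.run_tree_demo:
        seqset = simulate_gametologs(n_species=4, seed=cfg.seed)
        tree = nj_build(DistanceMatrix.from_seqset(seqset))
        tree_verdict = gametolog_cluster_test(tree, seqset.classes).value

    report = RunReport(
        verdict=verdict.verdict,
        dominance_ratio=verdict.dominance_ratio,
        n_zw_snps=verdict.n_zw_snps,
        n_xy_snps=verdict.n_xy_snps,
        n_zw_tags=verdict.n_zw_tags,
        n_xy_tags=verdict.n_xy_tags,
        n_candidate_tags=len(markers),
        n_confirmed=len(confirmed),
        n_rejected=sum(1 for m in markers
                       if not m.confirmed and m.status.value != "insufficient_data"),
        n_primer_pairs=sum(1 for r in designs.values() if r),
        mapped_per_chrom=mapped_per_chrom,
        tree_verdict=tree_verdict,
        seed=cfg.seed,
    )
    result = RunResult(report, registry, gm, tc, ref, snps, tags, markers,
                       designs, hits, truth)
    if cfg.out_dir:
        write_outputs(result, cfg.out_dir)
    return result


# ---------------------------------------------------------------------------
# tabular writers


def write_candidates_tsv(snps, tags, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("id\ttag_id\tstrategy\tpattern\tp_raw\tp_adj\t"
                 "F_hom_ref\tF_het\tF_hom_alt\tF_missing\t"
                 "M_hom_ref\tM_het\tM_hom_alt\tM_missing\t"
                 "n_present_F\tn_present_M\n")
        for c in snps:
            cf, cm = c.counts_f, c.counts_m
            fh.write(f"{c.locus_id}\t{c.tag_id}\t{c.strategy.value}\t{c.pattern.value}\t"
                     f"{_fmt(c.p_raw)}\t{_fmt(c.p_adj)}\t"
                     f"{cf.n_hom_ref}\t{cf.n_het}\t{cf.n_hom_alt}\t{cf.n_missing}\t"
                     f"{cm.n_hom_ref}\t{cm.n_het}\t{cm.n_hom_alt}\t{cm.n_missing}\t"
                     ".\t.\n")
        for t in tags:
            fh.write(f"{t.tag_id}\t{t.tag_id}\t{t.strategy.value}\t{t.pattern.value}\t"
                     f".\t.\t.\t.\t.\t.\t.\t.\t.\t.\t{t.n_present_f}\t{t.n_present_m}\n")


def write_markers_tsv(markers: list[ConfirmedMarker], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("tag_id\tpattern\tstatus\tsex_limited\tn_diag_sites\tdiag_sites\n")
        for m in markers:
            sites = ";".join(f"{p}:{a}>{b}" for p, a, b in m.diag_sites)
            fh.write(f"{m.tag_id}\t{m.pattern.value}\t{m.status.value}\t"
                     f"{int(m.sex_limited)}\t{len(m.diag_sites)}\t{sites}\n")


def write_primers_tsv(designs: dict[str, DesignResult], path) -> None:
    """Table mirroring a wet-lab primer sheet: locus, sequences, Tm, product."""
    with open(path, "w", newline="\n") as fh:
        fh.write("locus\tmode\tforward_5p3p\treverse_5p3p\tannealing_C\t"
                 "product_bp\tstatus\n")
        for tag_id in sorted(designs):
            res = designs[tag_id]
            if res.pair is None:
                fh.write(f"{tag_id}\t.\t.\t.\t.\t.\t{res.reason}\n")
            else:
                p = res.pair
                anneal = round(min(p.fwd_tm, p.rev_tm), 1)
                fh.write(f"{tag_id}\t{p.mode.value}\t{p.fwd_seq}\t{p.rev_seq}\t"
                         f"{anneal}\t{p.product_len}\tok\n")


def _fmt(x) -> str:
    return "." if x is None else f"{x:.6g}"


def write_outputs(result: RunResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_candidates_tsv(result.snp_candidates, result.tag_candidates,
                         out / "candidates.tsv")
    write_markers_tsv(result.markers, out / "markers.tsv")
    write_primers_tsv(result.primer_designs, out / "primers.tsv")
    if result.hits and result.reference is not None:
        gio.write_bed(result.hits, out / "hits.bed")
        tracks = chromosome_map(result.hits, result.reference)
        (out / "chromosome_map.txt").write_text(ideogram_text(tracks))
    (out / "report.json").write_text(result.report.to_json() + "\n")
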