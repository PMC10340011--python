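"""Core data model shared by all pipeline stages.

Coordinates are 0-based half-open everywhere inside the package; VCF
(1-based) and BED (0-based) are converted at the I/O boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

DNA_ALPHABET = "ACGT"

MISSING = -1  # allele index for a missing call


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class Pattern(str, enum.Enum):
    """Heterogamety pattern a candidate supports."""

    ZW = "ZW"
    XY = "XY"


class Strategy(str, enum.Enum):
    ALLELE_FREQ = "allele_freq"
    HETEROZYGOSITY = "heterozygosity"
    SEX_LIMITED = "sex_limited"


@dataclass(frozen=True)
class SexRegistry:
    """Sample -> sex map anchoring every per-sex partition.

    Sample order is preserved from the source table for reporting.
    """

    entries: dict[str, Sex]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("sex registry is empty")
        for sid in self.entries:
            if not sid:
                raise ValueError("empty sample_id in sex registry")

    @property
    def samples(self) -> list[str]:
        return list(self.entries)

    def of_sex(self, sex: Sex) -> list[str]:
        return [s for s, x in self.entries.items() if x is sex]

    @property
    def females(self) -> list[str]:
        return self.of_sex(Sex.F)

    @property
    def males(self) -> list[str]:
        return self.of_sex(Sex.M)

    @property
    def n_f(self) -> int:
        return len(self.females)

    @property
    def n_m(self) -> int:
        return len(self.males)

    def require_both_sexes(self) -> None:
        if self.n_f < 1 or self.n_m < 1:
            raise ValueError(
                f"screening needs at least 1 female and 1 male "
                f"(got {self.n_f} F, {self.n_m} M)"
            )

    def swapped(self) -> "SexRegistry":
        """Relabel every F as M and vice versa (antisymmetry checks)."""
        flip = {Sex.F: Sex.M, Sex.M: Sex.F}
        return SexRegistry({s: flip[x] for s, x in self.entries.items()})


@dataclass(frozen=True)
class LocusRecord:
    locus_id: str
    tag_id: str
    pos_in_tag: int  # 0-based
    ref_allele: str
    alt_alleles: tuple[str, ...]

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele, *self.alt_alleles)


@dataclass
class GenotypeMatrix:
    """Loci x samples diploid genotypes with missing data.

    ``gt`` has shape (n_loci, n_samples, 2) holding allele indices into
    ``loci[i].alleles``; MISSING (-1) marks a missing call. Any genotype
    containing "." is treated as entirely missing.
    """

    loci: list[LocusRecord]
    samples: list[str]
    gt: np.ndarray

    def __post_init__(self):
        self.gt = np.asarray(self.gt, dtype=np.int16)
        if self.gt.shape != (len(self.loci), len(self.samples), 2):
            raise ValueError(
                f"gt shape {self.gt.shape} inconsistent with "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        n_alleles = np.fromiter((len(loc.alleles) for loc in self.loci),
                                dtype=np.int16, count=len(self.loci))
        bad = (self.gt >= n_alleles[:, None, None]).any(axis=(1, 2))
        if bad.any():
            loc = self.loci[int(np.flatnonzero(bad)[0])]
            raise ValueError(f"allele index out of range at locus {loc.locus_id}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_index(self, sample_ids: list[str]) -> np.ndarray:
        pos = {s: j for j, s in enumerate(self.samples)}
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def genotype_classes(self) -> dict[str, np.ndarray]:
        """Boolean (n_loci, n_samples) masks: missing / het / hom_ref / hom_alt."""
        a, b = self.gt[..., 0], self.gt[..., 1]
        missing = (a < 0) | (b < 0)
        het = ~missing & (a != b)
        hom_ref = ~missing & (a == 0) & (b == 0)
        hom_alt = ~missing & (a == b) & (a > 0)
        return {"missing": missing, "het": het, "hom_ref": hom_ref, "hom_alt": hom_alt}


@dataclass
class TagRecord:
    """One GBS tag: consensus plus the per-sample distinct allele sequences.

    One sequence = the sample looks homozygous at this tag, two = heterozygous.
    All sequences share the consensus length (alignment-free SNP-only model).
    """

    tag_id: str
    consensus: str
    sample_alleles: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        L = len(self.consensus)
        for sid, seqs in self.sample_alleles.items():
            for s in seqs:
                if len(s) != L:
                    raise ValueError(
                        f"tag {self.tag_id}: allele of sample {sid} has length "
                        f"{len(s)} != consensus length {L}"
                    )

    def __len__(self) -> int:
        return len(self.consensus)

    def present(self, sample_id: str) -> bool:
        return bool(self.sample_alleles.get(sample_id))


@dataclass
class TagCatalog:
    tags: dict[str, TagRecord] = field(default_factory=dict)

    def __contains__(self, tag_id: str) -> bool:
        return tag_id in self.tags

    def __getitem__(self, tag_id: str) -> TagRecord:
        return self.tags[tag_id]

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags.values())


@dataclass
class ReferenceAssembly:
    chroms: dict[str, str]
    metadata: str = ""

    def __post_init__(self):
        for name, seq in self.chroms.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")
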