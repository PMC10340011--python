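# Methods

`sexscan` implements a sex-linked-marker discovery pipeline for reduced-
representation (GBS/RAD) genotype data, of the kind produced by Stacks on a
screening panel of known-sex individuals. This note documents the model
behind each stage, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices that were genuinely open.

## Screening model

Let a panel contain $n_F$ females and $n_M$ males genotyped at thousands of
short tags (restriction-associated loci of 300–350 bp, each carrying zero or
more SNPs). Under female heterogamety (ZW), loci in the non-recombining
region of the sex chromosomes show one of two signatures:

* **Z/W gametolog SNPs** — a site where the W-borne copy carries a base
  absent from Z: every female (Z/W) is heterozygous, every male (Z/Z) is
  homozygous;
* **W-limited tags** — fragments private to the W: present in females,
  absent from males (e.g. because the restriction site or the whole locus
  does not exist on Z).

Male heterogamety (XY) produces the exact mirror. Three screens target these
signatures:

1. **Allele-frequency screen.** For each biallelic SNP the 2×2 table of
   allele counts (sex × allele) is tested with a two-sided Fisher's exact
   test — exact at these sample sizes (10+10), unlike a chi-square —
   followed by Benjamini–Hochberg correction *within this strategy* (the
   other two screens are deterministic pattern filters, not tests).
   Significant loci (`alpha` 0.05 on the adjusted p) are kept only when the
   pooled minor allele is *polarized by sex*: carried by at least
   `pattern_presence_frac` (0.25) of one sex's alleles and at most
   `pattern_absence_frac` (0.05) of the other's. A fully sex-linked site has
   minor-allele frequency ≈ 0.5 in the heterogametic sex and ≈ 0 in the
   other, so true signals pass easily; polarization exists because BH at a
   5% false-discovery rate otherwise admits a handful of ride-along
   discoveries whose minor allele is merely skewed between the sexes. Loci
   with pooled minor-allele count below `min_mac` (2) are untestable at
   these sample sizes and are skipped; this also removes the singleton
   columns that per-base miscalls create in a Stacks-style VCF, which would
   otherwise dilute the multiple-testing correction by an order of
   magnitude.
2. **Heterozygosity screen.** A SNP is a ZW candidate when at least
   `het_presence_frac` (1.0) of genotyped females are heterozygous *and* at
   least `hom_presence_frac` (1.0) of genotyped males are homozygous (either
   homozygote). Under Hardy–Weinberg at allele frequency 0.5 an autosomal
   locus passes the strict rule with probability $(1/2)^{20}\approx10^{-6}$
   for 10+10 samples, so no correction is needed. Loci where fewer than
   `min_call_frac` (0.8) of either sex is genotyped are skipped.
3. **Sex-limited screen.** A tag is a ZW candidate when present (≥ 1 allele
   sequence) in at least `presence_frac` (0.9) of females and in at most
   `max_leak` (0) males. Presence — unlike genotype heterozygosity — is
   directly exposed to whole-tag allelic dropout: at a 5% dropout rate the
   probability that all 10 females retain a W tag is only $0.95^{10}\approx
   0.60$, so the presence threshold tolerates one missing female by default
   while the genotype thresholds stay strict.

**Verdict.** ZW- and XY-patterned candidates from all three screens are
pooled; the system is called for the majority pattern when its share
(`decision_threshold`, 0.9) is reached, otherwise `inconclusive`. Every
screen is exactly symmetric under swapping the sex labels, which flips every
candidate's pattern and the verdict — a property the tests assert exactly.

## False-positive elimination

Candidates are re-examined at the sequence level against the per-sample
allele sequences of their tag (the Stacks `population.sample.fa` analog).
The catalog's alleles are column-aligned by construction (equal-length,
SNP-only model), so "homozygous/heterozygous by alignment" reduces to column
comparison; no external aligner is needed. For a ZW candidate tag:

* at least `het_presence_frac` of females-with-data must carry two distinct
  allele sequences;
* a **diagnostic site** is a column where a base differing from the male
  column consensus is carried by at least `het_presence_frac` of
  females-with-data and appears in at most `confirm_max_leak_alleles` male
  alleles; confirmation requires at least one;
* tags with *no* male sequence at all are W-limited fragments and confirm
  as whole-tag sex-specific markers;
* rejections are typed: the putative female variant found in male
  heterozygotes (`rejected_male_het`), fixed or segregating among males
  (`rejected_variant_leak`), or no consistent female variant at all
  (`rejected_female_hom`) — a finer taxonomy than the upstream protocols
  report, useful for diagnosing screens.

The error tolerance is deliberately *column-wise*, not per-sequence: at a
0.5% per-base miscall rate a 300–350 bp consensus allele carries ~1.6 errors
in expectation, so any whole-sequence Hamming criterion would call nearly
every male "heterozygous". Per column, 20 male alleles carry only 0.1
expected miscalls, so tolerating one stray allele
(`confirm_max_leak_alleles` = 1) absorbs sequencing error while still
rejecting genuine polymorphism, which concentrates many deviant alleles on
one column. SNP-level candidates collapse to one marker per tag, matching
the tag-level accounting used for reporting.

## Primer design and in-silico PCR

Two validation designs are produced for each confirmed marker:

* **sex-specific** (allele-specific PCR): one primer's 3′ terminal base
  sits exactly on a diagnostic site and equals the sex-specific base, so
  only W-bearing templates amplify — the expected gel is bands in females,
  none in males. For whole-tag W-limited markers any pair is sex-specific
  and the anchor constraint is vacuous.
* **conserved**: both primers avoid diagnostic sites and the product spans
  at least one, so all samples amplify and sequencing the product shows
  het females / hom males.

Constraints: length 18–24 nt, product 250–350 bp (the GBS insert window; the
range is relaxed for shorter tags and logged), Tm 55 ± 3 °C, GC 0.35–0.65,
homopolymers ≤ 4. Tm is the Wallace rule below 14 nt and
$64.9 + 41\,(\mathrm{GC} - 16.4)/L$ otherwise. Among feasible pairs the
search minimizes $|T_f - T_r| + |L_\text{prod} - 300|/100$ with
deterministic tie-breaks (forward-anchored, then leftmost, then
lexicographic), and performs no dimer/hairpin thermodynamics — it is a
minimal deterministic stand-in for a full primer-design suite, sufficient to
encode the two validation logics. The in-silico gel calls a band when both
primers match an allele exactly over their 3′ half (terminal base included)
with ≤ 1 mismatch tolerated in the 5′ half.

## Marker-to-chromosome mapping

Markers are placed on a reference assembly with exact k-mer seeding
(k = 16, both strands) and ungapped x-drop extension (+1/−2 scores, x-drop
20) — appropriate because the queries are short, high-identity tags, for
which gapped alignment adds nothing. Each hit gets a Karlin–Altschul
e-value $E = K m n e^{-\lambda S}$ with λ = 1.28, K = 0.46 for the +1/−2
scheme; these constants make e-values BLAST-like rather than
BLAST-identical, acceptable because the e-value is used only as a retention
filter (default $E \le 10^{-25}$). Per marker only the top-scoring passing
hit is kept (ties: chromosome name, then start); a flag reports all passing
hits instead. A 300 bp exact match scores 300, giving $E \sim 10^{-160}$ on
a megabase reference, while a chance seed extends to scores far below the
~60 needed to pass the threshold — hence the clean separation the mapping
oracle tests measure.

## Gametolog genealogies

If Z–W recombination stopped before the sampled species split, the W copies
of a locus across species form a clade, as do the Z copies. The pipeline
computes pairwise distances (p-distance or Kimura two-parameter,
$d = -\tfrac12\ln(1-2P-Q) - \tfrac14\ln(1-2Q)$; default K2P, since the
distance model used upstream is unstated), builds a Saitou–Nei
neighbor-joining tree (deterministic lexicographic tie-break on the
Q-criterion; negative branch estimates clamped to zero with a warning), and
reports `by_gametolog` when some edge bipartitions the tips exactly into the
Z and W sets, `by_species` when every species is monophyletic instead, and
`mixed` otherwise. Sequences are assumed pre-aligned and gapless; unequal
lengths are end-trimmed to the shared window (≥ 20 comparable sites
required; a saturated K2P log argument is an error, not infinity). NJ is
exact on additive matrices, which the test suite exploits as an oracle, and
is cross-checked against an independent implementation. Bayesian tree
inference is intentionally out of scope: on these data it is a confirmatory
duplicate of the NJ topology.

## Synthetic data

`simulate_dataset` emulates the *outputs* of a Stacks-style pipeline — not
reads, coverage, or assembly. Defaults define the study conditions: 10
females + 10 males; 200 autosomal tags (Poisson(1.5) SNPs each, minor
allele frequency U(0.05, 0.5), Hardy–Weinberg, unlinked); 27 Z/W gametolog
tags (1 + Poisson(2.1) diagnostic sites each, echoing the ~3 SNPs/tag ratio
of the motivating screen); 11 W-limited tags; tag lengths U(300, 350) bp;
whole-tag dropout 5% per sample; per-base miscall 0.5% applied to allele
sequences *after* genotype assignment, so error creates spurious
heterozygotes and stresses the confirmation tolerance. The VCF emits one
record per polymorphic column, like a RAD caller, so miscalls surface as
low-MAC singleton loci exactly where a real Stacks VCF would have them. Sex-
linked tag sequences are planted verbatim (random strand, non-overlapping)
into a synthetic two-chromosome reference — W-limited tags on `chrW`, the Z
haplotype of gametolog tags on `chrZ` — and every planting is recorded in a
truth table that the tests and the acceptance script score against. XY mode
mirrors the construction with the sexes swapped (`chrY`/`chrX`); `none`
plants nothing.

What this does *not* model: read-level noise and coverage, linkage and
population structure, single-allele (as opposed to whole-tag) dropout,
indels and length variation within tags, paralogous tag collapse, and
recombining pseudoautosomal regions. Passing tests therefore demonstrate
the pipeline's statistical behavior under its stated locus-level model, not
robustness to assembly artifacts upstream of it.

`simulate_gametologs` generates one Z and one W ancestor diverged by
2 × `t_zw_split` (default 0.15) expected substitutions/site under
Jukes–Cantor, then evolves each down one shared random ultrametric species
tree of depth ≤ `t_speciation_max` (default 0.05). The precondition
`t_zw_split > t_speciation_max` encodes the suppression-first history this
simulation is about; it can be lifted explicitly (`enforce_history=False`)
to study the degenerate limit, where the gametolog edge has length zero and
the verdict is decided by sampling noise.

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere internally; VCF (1-based)
  and BED (0-based) convert at the I/O boundary. Any genotype containing
  "." (including half-calls like `0/.`) is missing.
* The tag-FASTA header dialect is fixed as
  `CLocus_<tag>_Sample_<sid>_Allele_<k>` (Stacks-like); the upstream
  grammar is undocumented, so the regex is a config override.
* Consensus sequences are per-column majorities with an alphabetical
  tie-break; candidate, marker, and hit orderings are all deterministic, and
  rerunning any stage with the same config and seed reproduces its outputs
  byte for byte (the dataset manifest records file hashes for this).
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`.

## Problem sizes used in validation

The shipped test suite and `scripts/acceptance.py` run the full design at
its native size (238 tags × 20 samples, megabase references), 20-seed
replicate batteries per heterogamety system, a full Fisher oracle sweep over
all 2×2 tables with row margins ≤ 30, a 10⁵-locus Monte-Carlo check of the
heterozygosity screen's false-positive rate, 200 planted/200 null mapping
queries on a 1 Mb chromosome, 100 random 4–12-taxon NJ oracle trees, and
100 gametolog-history replicates.

## Known limitations

* E-values are calibrated for the default +1/−2 scheme only; other scoring
  schemes need their own Karlin–Altschul constants.
* The confirmation step assumes tags align column-to-column; catalogs with
  indel variation within tags are out of scope.
* The allele-frequency screen tests the first two alleles of multi-allelic
  sites only; the heterozygosity screen uses all alleles.
* With fewer than ~8 samples per sex the Fisher screen has little power and
  the deterministic screens dominate; thresholds were chosen for panels
  near the 10+10 design.
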