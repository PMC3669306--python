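# Methods

This note records the models, conventions and design choices behind
`quartet-phase`, in the order the pipeline applies them.

## Data model and coordinates

Alleles are coded `REF = 0`, `ALT = 1`, with `MISSING` for uncalled alleles
and `DEL` for a deleted homolog (which appears only after hemizygous
correction). Only biallelic SNP/indel records enter the model;
multi-allelic and symbolic-ALT records are counted and logged at load time,
never silently dropped. VCF positions are 1-based; every interval (BED
masks, inheritance blocks, SV calls, haplotype blocks) is 0-based
half-open. The two conventions meet only in `vcf_io`.

The pedigree is always supplied explicitly (file or constructor); sample
order in the VCF carries no meaning.

## Transmission phasing

Each site is phased independently within the two father–mother–child
trios. A trio is phasable exactly when the gamete assignment is unique,
which happens iff at least one member is homozygous; homozygous genotypes
are the trivially phased seeds. Orderings: children `Maternal|Paternal`;
parents `Transmitted-to-child-1|Other`. The parent anchor is fixed to
child 1 (rather than per-trio arbitrary) so quartet output is
deterministic; within an inheritance block the anchor is constant, and it
may switch physical homolog only at crossovers in child 1's gametes —
downstream consumers (physical phasing of parents, parent-block
orientation) account for this per block.

Sites with any missing genotype are excluded from transmission phasing but
kept for later imputation. Mendel-inconsistent sites are left unphased for
error analysis. Triple-heterozygous sites (one trio all-het, the other
phasable) are resolved by propagating the phasable child's transmitted
alleles through the block states; a propagation that contradicts the
observed genotype flags the site as an SCE candidate instead (annotation
only — see error classification). Sites inside crossover junctions are left
unresolved.

## Inheritance blocks

An informative marker requires the parent heterozygous and both children
transmission-phased; the marker is +1 when the children's inherited alleles
from that parent agree (same homolog), −1 otherwise. Segmentation of a
marker sequence minimizes

    (# discordant markers) + r · (# state switches)

by an exact two-state dynamic program (`r = min_opposite_run`, default 10).
This makes an isolated discordant marker (an SCE candidate) cheaper to
absorb than to segment around, while ≥ r sustained opposite markers open a
new block. Ties prefer staying in the current state and, for the final
state, agreeing with the last marker. Runs shorter than `min_markers`
(default 20) are then absorbed into their neighbors, shortest first; a
run's discordant fraction above `max_discordant_fraction` (default 0.1)
sets a QC flag rather than forcing a further split (there is no principled
unique split for a noisy run). Two reciprocal crossovers closer than the
segmentation resolution are, by construction, indistinguishable from an
SCE; this is a stated detection limit, not a defect.

Blocks cover `[first marker, last marker]` of their run; chromosome ends
stay open. The crossover junction is the open interval between the last
marker of the upstream block and the first marker of the downstream block;
`gap_bp` is the distance between those two markers. The per-chromosome
per-gamete crossover mean divides the count by (2 gametes × number of
chromosomes analyzed).

## Error classification

`classify_mie` declares an MIE when no assignment of one allele from each
parent to each child reproduces both children (brute-force over ≤ 16
assignments). `classify_sce` is *marker-based*: a Mendel-consistent site is
an SCE iff, for some heterozygous parent whose transmitted alleles to both
children are uniquely determined by the genotypes, the implied same/different
marker contradicts the block state at that position. Sites whose
transmission is ambiguous (observed triple/quadruple heterozygous) and
sites inside junctions are not classifiable — this mirrors what the ±1
comparison track can actually see, and keeps the classifier consistent with
the detectability enumeration below. MIE and SCE are mutually exclusive;
triple-het propagation conflicts are annotated `sce_candidate` but not
counted as SCE proper.

## Error-rate estimators

With `GDE = MIE + SCE` and detectable fraction `d` (default 0.75):
`undetected = GDE·(1−d)/d`; `FP% = 100·undetected/(called − GDE)`;
`true variants = called − GDE − round(undetected)`;
`FN% = 100·(corrected₀ − corrected)/corrected` against the unfiltered
baseline. The undetected multiplier uses the exact fraction `(1−d)/d`
(= 1/3 at d = 0.75) rather than a rounded 0.33; the true-variant count uses
the rounded integer so printed worked examples reproduce exactly.

## Detectability enumeration

The enumeration answers: what fraction of genotype miscalls at a variant
site does transmission analysis catch? The space is every ordered parental
haplotype pair over {REF, ALT} × the four inheritance states (child 1
takes each parent's first-listed homolog; the all-REF configuration is
excluded since no variant would be called) — 60 configurations. For each,
the unit of corruption is a *wrong genotype in one member*: every distinct
erroneous unordered genotype is applied (a hom→opposite-hom miscall is one
genotype error), the corrupted quartet is classified with the same
marker-based rule as the pipeline, and corruptions that erase the variant
entirely (all members hom-REF — such a site never enters a call set) are
excluded from the denominator. Detection fractions are averaged uniformly
over configurations, separately for errors in children (83.3%) and parents
(66.4%); the overall fraction is their mean (74.9%), the source of the
`d = 0.75` default.

Two scheme choices deserve emphasis. First, the SCE side of the classifier
is deliberately the marker rule, not "no state-consistent assignment
exists": the latter would credit detection at unphasable (ambiguous)
observations, which the comparison track cannot flag, and would claim 100%
child-side detection — inconsistent with the ~80% that ambiguity actually
permits. Second, `enumerate_detectability` also accepts an `"allele"` error
model (single-allele flips) and per-configuration weights; tests use this
to predict the flagged fraction for the simulator's own configuration mix,
where the realized detectable fraction (~61%) is lower than 0.75 because
the simulator only places errors at variant sites, whose configuration mix
is more parent-opaque than the uniform average. Injected-error recovery in
the acceptance tests therefore divides GDE by that predicted fraction
rather than by the fixed 0.75.

The non-sporadic mode applies every pair of single-allele flips hitting two
different members; pairs within the children (resp. parents) populate the
two reported fractions.

## Filters

Read-depth mask: per-sample "normal" depth is the genome-wide median of
fixed-width coverage bins (default 500 bp); a bin is masked when **all
four** members are at ≥ `multiplier` (default 2.0) × their own median, and
flagged bins within one bin of each other merge. The recalibration filter
is a pass-through of the caller's FILTER column. The PL filter removes a
site when any member's genotype confidence margin — the second-smallest PL
entry, i.e. how much less likely the best alternative genotype is — falls
below `min_pl` (default 20), and also removes partially called sites.
Members without PL values are exempt from the margin test. Filter
efficiency is errors removed per site removed.

## Structural variants and hemizygous correction

Consensus SVs require ≥ 2 distinct callers reporting overlapping (≥ 1 bp,
any reciprocal fraction) calls of the same type, each longer than 100 bp;
the representative call is the primary caller's (default `pindel`) when
present, else the largest. Hemizygous correction re-evaluates each MIE site
inside a deletion heterozygous in ≥ 1 member: the deleted homolog's allele
becomes `DEL`, which transmits like any allele (so a child's DEL must come
from a deletion-carrying parent), and consistency is checked against the
block states when available. Consistent sites have their error class
cleared and the affected genotypes marked hemizygous; the operation never
touches non-MIE sites and never increases the MIE count. Regions with
multiple overlapping deletions are out of scope (flag-only in the real
workflow, not generated by the simulator).

## Phase merging

Fragments (pairs/mates) observing ≥ 2 heterozygous sites vote on the
relative orientation of adjacent site pairs; ties drop the edge, cycle
conflicts split the component at the conflicting edge. Phase sets are the
resulting connected components. Integration order and precedence are
strict: transmission > physical > population; a later tier never reorients
an earlier one, and disagreements are counted as divergences while the
earlier tier's phase stands. For parents, phase-set orientation is voted
within each inheritance block (the transmission anchor flips at child-1
crossovers). Population evidence (external per-trio phased calls) is used
only where the two trios agree on the parents' phase; agreeing evidence
phases remaining quadruple-het sites and imputes genotypes at MIE/SCE/
uncalled positions, which keep their error provenance. Parent-block pairs
across a junction are oriented by a spanning phase set (high confidence) or
by population haplotypes on the two flanks (high confidence only when both
flanks have ≥ 5 informative markers agreeing at ≥ 90%, else low). N10/N50
are the span at which the cumulative span of sets, largest first, reaches
10%/50% of the total.

## Haplotype blocks

Per sample, phased variants map to three tracks (hom 1|1, het 0|1, het
1|0); unphased heterozygotes are excluded and counted. Islands per track
are windows (default 10 kb) holding ≥ 5 SNPs, merged across gaps ≤ 20 kb —
defaults calibrated so that simulated genomes with the observed class
densities (0.36 / ~1.35 / 2.15 SNP per kb) yield a mean block length near
58.5 kb. Region classes: exactly one track's islands → that class; two or
more → mixed; none → SNP-poor. Classes tile each chromosome; every SNP is
counted in exactly one block.

## The synthetic quartet generator

What it emulates: parental haplotypes as mosaics of ancestry-density
segments (exponential lengths, mean 58,500 bp; genome fractions 36% /
45.65% / 18.35%; densities 0.36 / 1.35 / 2.15 SNP per kb); meiosis with
Poisson crossovers at uniform positions (maternal 1.85, paternal 1.27 per
chromosome per gamete; no interference); a configurable
quadruple-heterozygous fraction (default 4% of sites, applied where the
local inheritance states admit a quad-het, i.e. outside mixed-state
regions); per-allele genotype miscalls (default 10⁻³) and per-member-site
missingness (default 5·10⁻³), both recorded in a registry that is a
bijection with the observed-vs-truth differences; depth-scaled PL margins
with a heavy lower tail, and systematically low margins at miscalled and
hemizygous genotypes so PL filtration has realistic efficiency;
non-overlapping heterozygous deletions placed away from crossover
breakpoints, whose carriers' calls collapse to the remaining homolog;
shared high-read-depth regions at 4× in all members; fragment libraries at
the three insert sizes (300/600/2500 bp) or an exhaustive adjacent-het
mode; and a population-phasing surrogate applying independent per-trio
Markov switch errors to the truth phases.

What it does not emulate — and hence what passing tests do not show about
real data: reference alignment artifacts, clustered (coverage-driven)
errors at the same position, error processes at invariant positions
(simulated errors occur only at variant sites), de novo mutations,
multi-allelic sites, sex chromosomes, recombination interference or
hotspots, and linkage-disequilibrium structure within haplotype classes
(alleles are drawn independently per site given the class). Per-class
per-haplotype ALT probabilities (0.15 / 0.35 / 0.5) were chosen once to
give realistic heterozygosity gradients across classes.

All randomness flows from one integer seed through numpy's default
generator; a fixed seed reproduces sites, registries and coverage exactly.

## Problem sizes and tolerances in the test suite

Acceptance-style simulations use: ~10⁵ sites (4 × 22 Mb) for error-free
phasing exactness and full-het physical phasing; 6 × 30 Mb (~2·10⁵ sites,
~1,700 injected errors) for flag-rate agreement (±3 pp) and injected-count
recovery (±10%); 8 × 50 Mb for crossover recall/precision ≥ 0.95 with
10 kb junction-matching slack (one miscalled boundary marker can shift a
junction by one marker spacing; exact containment is asserted separately on
error-free data); 50 deletions on 20 Mb for hemizygous correction; 30 Mb of
track simulation for ≥ 90% haplotype-block base recovery. Oracle tests
compare the segmentation DP against exhaustive enumeration (n ≤ 14) and an
independent quadratic DP (n ≤ 200), and the MIE/SCE classifiers against
brute-force gamete enumeration on the full 3⁴ genotype grid × 4 states.

## Known limitations

Parent-block orientation confidence is a heuristic proxy (marker counts and
consistency) for "the flanking haplotypes differ". The island finder's
`max_discordant_fraction` is a QC flag, not a hard guarantee. The
detectability enumeration's averaging scheme (uniform over configurations,
genotype-level miscall units, vanished corruptions excluded) is one
defensible choice among several; the `weights`/`error_model` parameters
expose the alternatives. X/Y and mitochondrial chromosomes are treated as
autosomal only if included by the caller; no special hemizygous-male logic
exists.
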