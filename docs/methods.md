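# Methods

This note documents the models and decision rules implemented in
`stratovir`, the defaults they ship with, and what the synthetic-data
tests do and do not demonstrate about real data.

## Study design being modelled

A monomictic lake sampled monthly over one year at two depths — the
epilimnion (surface mixed layer, 5 m) and the hypolimnion (deep layer,
65 m) — for 24 samples in total. Thermal stratification lasts from May to
December; from January to April the water column mixes and the two
layers' communities converge. All habitat statistics are restricted to
the eight stratified months, because only then are the two layers
distinct habitats.

## Screening rules

A sequence or bin is a giant-virus candidate iff its length exceeds
50 kb **and** it shows a giant-virus signal: at least one hit among the
seven nucleocytovirus hallmark genes (MCP, PolB, TFIIB, TopoII, A32,
SFII, VLTF3), or an HK97-fold major capsid protein hit with bit score
strictly above 100 (the diagnostic mirusvirus marker). Bins with
bacterial completeness above 15 or archaeal completeness above 20
(CheckM-style estimates, strict inequalities) are treated as prokaryotes
and removed. Marker hits arrive as a table (sequence id, gene, bit
score); running the profile-HMM searches that produce such tables is out
of scope.

The core-gene density index is defined here as the number of *distinct*
nucleocytovirus core genes (of a panel of 20) per 100 kb of genome, with
a default acceptance threshold of 0.5. The index is cited but not
formally defined in the literature this package operationalises; our
definition is a documented proxy chosen because it separates
marker-dense viral genomes (typically ≥1 distinct core gene per 100 kb)
from megabase-scale cellular sequences with sporadic hits. The threshold
is fully configurable.

POA90 is likewise accepted as an operational proxy: the percentage of a
genome's predicted proteins whose best alignment to a reference covers
at least 90% of the protein. Frameshifts from unpolished indels truncate
predicted proteins and drag this score down. The ORF prediction and
reference search that produce per-protein coverages are inputs, not part
of this package; an empty coverage list yields a missing value, never 0.

Completeness tiers: "high" requires completeness strictly above 90;
"medium" (≥50) and "low" follow the MIMAG convention, since only the
high tier is defined by the source analysis. A marker-based fallback
completeness (7-marker tally / 7 × 100) exists but is never silently
substituted for an externally estimated value.

### Terminal inverted repeats

`find_tir` returns the longest prefix length L (bounded by a 5 kb window,
truncated to half the sequence) whose first L bases match the reverse
complement of the last L bases with mismatch fraction ≤ 5% and L ≥ 20.
The scan exploits the identity revcomp(suffix of length L)[i] =
complement(base n−1−i), so one complement-mismatch profile over the
window serves every L in O(window) after an O(window) setup. Sequences
must be uppercase ACGT; anything else is rejected rather than guessed.

### Fragmentation comparison

Contig-count (or N50) distributions of two catalogues are compared by a
two-sided Mann–Whitney U test; the source analysis reports P values
without naming the test, and a rank test is the standard choice for
skewed count data. The exact U distribution is used whenever the data
are tie-free and both groups have ≤25 observations, the normal
approximation otherwise.

## Dereplication

Species clusters are formed at ANI ≥95% by greedy centroid clustering on
a supplied pairwise ANI table: genomes are visited in order of
decreasing quality score (default: completeness + 10·log10(N50),
following common dereplication practice) and join the first existing
representative they match, otherwise found a new cluster. Missing table
entries mean "below threshold", so sparse tables are valid. This
replaces the two-stage Mash/ANIm pipeline of dRep because the decision
rule — the 95% boundary applied to an ANI estimate — is what matters
downstream, not the estimator. Serial IDs (0001, 0002, …) order
representatives by maximum per-sample coverage depth, ties broken
lexicographically.

polB diversity capture uses an exact global (Needleman–Wunsch) aligner
with match +1 / mismatch −1 / gap −2; identity is matches over all
alignment columns and aligned length counts columns where both sequences
have a residue. A cluster is captured when any catalogue polB exceeds
96% identity over more than 60% of the shorter sequence. The aligner is
intended for gene-scale fixtures (≤ a few kb), not genomes; precomputed
alignment tables are accepted for anything larger.

## Abundance and community structure

RPKM = count / ((genome length / 10³) × (total mapped reads / 10⁶)).
Samples with zero mapped reads are reported with a warning and zero
profiles rather than NaN. Bray–Curtis dissimilarity is Σ|x−y| / Σ(x+y),
defined as 0 for two all-zero profiles (logged when triggered).

NMDS minimizes Kruskal stress-1 by alternating a weighted isotonic
regression of configuration distances on dissimilarity ranks (ties are
handled by the secondary approach — tied dissimilarities share one
disparity, so e.g. three equidistant samples embed as an equilateral
triangle) with a Guttman transform update. Defaults: k = 2 dimensions,
10 random restarts, 500 iterations, tolerance 1e-6 on the stress
decrease, all seed-controlled. A run stops at the first non-improving
iteration, so the recorded stress history is non-increasing by
construction; the returned solution is the best restart.

The toy read mapper exists so end-to-end fixture tests can exercise the
counts → RPKM path with sequence-level inputs: exact k-mer seeding
(k = 15), ungapped extension over the full read, both strands, reads
below 92% identity discarded, ties broken uniformly at random under the
seed. It is not a general-purpose mapper; real studies use external
mappers and enter via count tables.

## Habitat preference and persistence

P_epi is the cumulative epilimnion RPKM divided by the cumulative RPKM
of both layers over the stratified months; it is undefined (label
"unclassified") when a genome is never detected during stratification.
P_epi > 0.95 → epilimnion-specific, < 0.05 → hypolimnion-specific,
otherwise generalist (strict inequalities; P_epi = 0.95 is a
generalist). Percentage denominators include unclassified genomes by
default; an option excludes them.

Persistence is the longest run of consecutive stratified months with
covered fraction strictly above 20%, with no wrap-around, computed for
each specialist in its own layer only. Generalist persistence is
available behind a flag (using the layer with the larger cumulative
signal) but excluded by default, matching the specialist-only design of
the comparison. Group mean persistence is compared with Welch's
unequal-variance t-test (Welch–Satterthwaite degrees of freedom, p from
the t survival function). Degenerate zero-variance groups return p = 1
for equal means and a floored minimal p (1e-300) otherwise.

Gene-sharing partition: a KEGG-Orthology-style term is *exclusive* to a
habitat class when absent from every other class; *shared* counts terms
present both in the union of the two specialist classes and in the
generalist class — i.e. in use by genomes with and without a habitat
preference. The "shared" notion is ambiguous in prose descriptions of
such partitions; this set-algebra definition is isolated in one function
so alternatives are a one-line change.

Report percentages are rounded half-up to one decimal (via exact decimal
arithmetic, not binary floats), matching how such catalogue statistics
are conventionally printed.

## Synthetic community generator

The generator's defaults describe the study conditions the statistics
were designed for: 60 epilimnion specialists, 30 hypolimnion
specialists, 30 generalists, 10 cellular decoys; 12 months (May–April)
with May–December stratified.

* **Epilimnion specialists** get one contiguous abundance peak of 2
  months (uniformly placed within stratification) at amplitude 3.0 —
  short, intense blooms.
* **Hypolimnion specialists** occupy the hypolimnion each stratified
  month independently with probability 0.95 at amplitude 1.0 —
  persistent, lower-contrast presence.
* **Generalists** sit in both layers all year at amplitude 0.3.
* A fixed fraction (0.002) of each home-layer signal leaks into the
  other layer, so specialist P_epi is extreme but not degenerate.
* During the mixing months the two layers are linearly interpolated
  toward their mean, reaching complete mixing in the final month.
* Multiplicative lognormal noise (σ = 0.5, mean normalised to 1) is
  applied last; σ = 0 reproduces the deterministic template exactly.

Abundances are not specified by any source at this level of detail; the
amplitudes, leakage and lognormal dispersion are this package's choices,
picked to be ecologically plausible (blooms an order of magnitude above
background, ~2-fold typical month-to-month noise) and fixed once.
Lognormal abundance is an assumption — the true abundance distribution
of freshwater giant viruses is unknown.

Read sampling is Poisson with per-genome mean proportional to
abundance × genome length, normalised to 100 000 reads of 150 bp per
sample (fixture scale; real samples are orders of magnitude deeper, but
the statistics under test are scale-free or depend only on relative
depth). Coverage depth is count × read length / genome length and the
covered fraction follows the Lander–Waterman approximation 1 − e^(−d).
Poisson rather than negative-binomial sampling keeps the count law
analytically checkable; overdispersion is already supplied by the
lognormal abundance noise. Genome lengths are uniform on 60–400 kb;
sequences are uniform-random ACGT (uppercase only, no ambiguity codes)
with planted features: marker-gene tables, TIRs (prefix = reverse
complement of suffix up to a planted mismatch count) on a configurable
fraction of single-contig linear genomes, and substitution-only polB
variants whose identities are exact by construction.

What passing tests therefore show: the decision rules, statistics and
their implementations recover planted truth under guild-structured
dynamics with realistic sampling noise. What they do not show: behaviour
under real sequence evolution (indels, repeats, strain mixtures),
read-error models, assembly artefacts, or abundance distributions unlike
the lognormal assumption.

## Numerical and degenerate-input choices

* Strict vs non-strict inequalities follow the printed rules everywhere:
  length >50 kb, bit score >100, completeness >15/>20, identity >96%,
  coverage >60%, P_epi >0.95/<0.05, covered fraction >20%,
  completeness >90; the ANI species boundary is inclusive (≥95%).
* TIR mismatch tolerance is inclusive (mismatch fraction ≤ 5%): a 40 bp
  repeat with 2 mismatches (exactly 5%) is a hit.
* N50 is the largest L such that contigs of length ≥L sum to at least
  half the total; verified exhaustively against the definition for all
  small contig multisets.
* Empty POA90 input and sub-minimal statistical groups report *missing*,
  never 0 — absence of evidence is not a score.
* All randomness flows from `numpy.random.default_rng` with explicit
  seeds; identical configuration and seed give byte-identical outputs,
  including FASTA files.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the default community
(120 giant-virus genomes + 10 decoys, 24 samples, 10⁵ reads/sample) for
recovery statistics, gene-scale fixtures (≤ 600 bp, ≤ 29 clusters) for
alignment-based capture, and ≤ 5 kb sequences for TIR oracle
comparisons. These sizes exercise every code path at full fidelity; the
package's own statistics are either scale-free or improve with depth, so
conclusions about correctness do not depend on fixture scale.

## Known limitations

* Marker hits, ANI values, completeness estimates and (at study scale)
  read counts are inputs; this package deliberately does not re-implement
  hmmsearch, CheckM, fastANI/dRep's estimators, or a production mapper.
* The core-gene-density index and POA90 are documented proxies for
  metrics whose original definitions live in tool-specific supplements.
* The NMDS implementation targets the 24-sample scale of this design;
  it is O(n²) per iteration and not tuned for hundreds of samples.
* The toy aligner is quadratic and intended for gene-length sequences.
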