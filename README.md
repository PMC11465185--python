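# stratovir

Giant viruses (nucleocytoviruses and mirusviruses) structure plankton
communities in lakes, but their genomes arrive from metagenomes as mixed,
fragmented bins. `stratovir` is a Python toolkit for the analysis that
turns such bins into ecology: it screens candidate giant-virus
metagenome-assembled genomes (MAGs), collapses them into species, profiles
their abundance across a seasonally stratified water column, and
quantifies habitat preference and persistence. It is aimed at microbial
ecologists working with time-series metagenomes from stratified lakes
(monthly samples from the sunlit epilimnion and the dark hypolimnion).

## What it computes

**Screening.** A bin is a giant-virus candidate when it exceeds 50 kb and
carries ≥1 of the seven nucleocytovirus marker genes (MCP, PolB, TFIIB,
TopoII, A32, SFII, VLTF3) or a mirusvirus HK97 MCP hit with bit score
>100. Bins with CheckM-style bacterial completeness >15 or archaeal >20
are excluded as prokaryotes. A core-gene density index (distinct hits
among 20 nucleocytovirus core genes per 100 kb) guards against large
cellular sequences with sporadic hits. Quality metrics include N50,
completeness tiers (>90% = high quality), terminal-inverted-repeat (TIR)
detection for complete linear genomes, and POA90.

**Dereplication.** Greedy centroid clustering on a pairwise ANI table at
the 95% species boundary; representatives get four-digit serial IDs
ordered by maximum per-sample coverage. Diversity capture asks what
fraction of environmental polB gene clusters is represented in the
catalogue (match rule: >96% identity over >60% of the shorter gene).

**Community structure.** RPKM per MAG and sample, Bray–Curtis
dissimilarities, nonmetric multidimensional scaling (NMDS, Kruskal
stress-1 by iterative majorization), and within-layer dispersion during
stratification.

**Habitat preference.** For each genome, over the stratified months
(May–December),

    P_epi = Σ RPKM_epilimnion / (Σ RPKM_epilimnion + Σ RPKM_hypolimnion)

with P_epi > 0.95 defining epilimnion specialists and P_epi < 0.05
hypolimnion specialists. Persistence is the longest run of consecutive
stratified months with genome covered fraction >20%, scored in the
specialist's own layer; group means are compared with Welch's t-test.

A synthetic community generator produces all inputs with known ground
truth — guild-structured dynamics (transient epilimnion specialists,
persistent hypolimnion specialists, generalists), Poisson read sampling,
planted marker genes, TIRs and polB variants — so the whole pipeline is
testable without any download.

## Worked example

```python
from stratovir import CommunityConfig
from stratovir.synthetic import generate_genomes, simulate_dynamics, abundance_to_reads
from stratovir.abundance import rpkm_table
from stratovir.habitat import classify_community, persistence_cohort
from stratovir.config import STRATIFIED_MONTHS

cfg = CommunityConfig(seed=1)                      # 60 epi / 30 hypo / 30 generalist
community = generate_genomes(cfg, with_sequences=False)
abundance, samples = simulate_dynamics(cfg)
counts, depth, covfrac = abundance_to_reads(abundance, community.genome_lengths, cfg)

rpkm = rpkm_table(counts, community.genome_lengths)
calls = classify_community(rpkm, STRATIFIED_MONTHS)
cohort = persistence_cohort(calls, covfrac, STRATIFIED_MONTHS)
```

Output:

```
habitat labels: {'epilimnion-specific': 60, 'hypolimnion-specific': 30, 'generalist': 30}
median persistence (months): {'epilimnion-specific': 2.0, 'hypolimnion-specific': 8.0}
Welch t = -19.01, p = 6.43e-18
```

Every planted specialist is recovered by the P_epi classifier; epilimnion
specialists persist for their short planted peaks (median 2 months) while
hypolimnion specialists occupy the deep layer through most of the
stratified period (median 8 of 8 months), and the difference in mean
persistence is highly significant.

The same run is available from the shell:

```
stratovir all --seed 1 --out run/
```

which writes fixtures, per-stage tables (`mags_screened.tsv`, `rpkm.tsv`,
`beta.tsv`, `nmds.tsv`, `clusters.tsv`, `habitat_calls.tsv`) and a
`report.json` with the headline statistics, plus a manifest recording the
seed and every threshold.

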