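# Methods

This note documents the models and conventions implemented in `cosymbio`,
the parameters that matter, and what the synthetic-data generator does and
does not emulate.

## Infection calling and prevalence

Each host individual is assayed by one PCR per symbiont plus a universal
host 18S rRNA PCR as an extraction/inhibition control. The calling rule
(`infection_stats.call_individual`):

* positive symbiont PCR → **infected**, regardless of the control (a
  successful amplification is its own evidence of amplifiable DNA);
* negative or missing symbiont PCR with a positive host control →
  **uninfected** (a validated negative);
* negative or missing symbiont PCR with a failed host control →
  **invalid**; invalid individuals are excluded from prevalence
  denominators and the exclusion count is logged.

Prevalence is `n_positive / n_valid` with a Wilson score interval by
default (Clopper–Pearson available; both via statsmodels, cross-checked in
the tests against an independently coded closed form). Wilson is the
default because it behaves well at the extreme proportions typical of
endosymbiont surveys (e.g. 123/127).

Coinfection is summarised as the 2×2 table over individuals valid for both
symbionts, a **nestedness** flag (true iff the second-symbiont-only cell is
empty — every *Wolbachia* carrier is also a *Cardinium* carrier), and a
two-sided Fisher exact p-value (scipy; verified in the tests against
exhaustive hypergeometric enumeration for all tables with margins ≤ 15).

## Titer ("intensity") estimation

Pooled sequencing depth is converted to cells per infected host. With
symbiont mean depth `d_s`, single-copy host gene depth `d_h`, prevalence
`p` and `N` assumed host cells per individual (default 1000, by analogy to
the ~1000 somatic cells of a free-living nematode; treated as a free
parameter):

* `as_printed` (default): `cells = (d_s * p) / (d_h / N)`
* `per_infected_alternative`: `cells = (d_s / p) / (d_h / N)`

The default reproduces the source analyses' arithmetic verbatim (437 and
243 cells from the worked example). Note its multiplication by `p` while
describing the result "per infected host"; the alternative variant, which
treats prevalence as diluting the pooled symbiont signal, is exposed
explicitly and never silently substituted. The estimate is linear in
`d_s`, in `p` (as printed), and in `N`.

## Percent display conventions

All percentages are computed with exact rational arithmetic; three display
conventions coexist, each matching the reporting style of the table it
serves:

* **prevalence**: whole percent, truncated toward zero (123/127 → 96%) — a
  prevalence report never overstates the whole percent attained;
* **functional breakdowns**: half-up at the printed precision — whole
  percent at or above 20%, one decimal below (40/154 → 26%, 7/154 → 4.5%);
* **pangenome overlaps**: one decimal, half-up, but never carrying into the
  units digit (178/7175 → 2.5%, 350/361 → 96.9% rather than 97.0%), keeping
  the integer part a floor.

## Ortholog set algebra

The substrate is a cluster × taxon copy-count matrix built from an
OrthoMCL-style groups file. **Presence means copy count ≥ 1** everywhere;
copy number matters only to expansion profiling. Definitions:

* *universal core*: clusters present in every ingroup and every outgroup
  taxon;
* *ingroup-specific core*: present in every ingroup taxon but absent from
  at least one outgroup taxon (default; a strict mode requires absence from
  all outgroups — the default matches the "not universally shared" notion,
  the flag the stronger claim);
* *pangenome overlap*: clusters touching only group 1, only group 2, or
  both, with percents over clusters touching either group;
* *expansion profile*: a gene family is an expansion candidate iff its
  maximum per-taxon copy count is ≥ 3 (the conventional floor below which
  "expansion" is noise); normalisation is copies per Mbp of genome, so
  `copies_per_mbp × size_mbp` inverts exactly;
* *functional category of a cluster*: majority vote over member genes'
  categories, ties resolved to `unknown_function` (the conservative sink).

Genome features: GC% excludes ambiguity codes from numerator and
denominator; coding fraction merges overlapping gene intervals before
summing (so nested genes are not double-counted); the ortholog length sum
is over a caller-designated gene set (e.g. single-copy phylogenomic
markers).

## HGT classification

Candidates are focal-genome genes whose ortholog cluster has no member in
any outgroup, plus singletons. Each candidate is classified from the ranked
lineages of its blast hits and of its flanking genes' hits (the flanks
estimate the genomic background's expected taxonomy). Self-strain hits must
be removed first (`drop_self_hits`), else every gene is trivially non-HGT.
Rules, applied in order, with self-clade rank *genus* and mismatch rank
*phylum* by default (both configurable):

1. no hits → `ambiguous` (no_evidence);
2. bit-score ties at the top that disagree at the phylum rank →
   `ambiguous` (tied_top);
3. `non_hgt`: top hit in the expected phylum, majority of the top-k hits
   (k = 10 by default) in the expected phylum, flanking best-hits majority
   likewise — and, when a gene tree is supplied, the query's sister group
   majority-matches the expected phylum (a discordant tree demotes the call
   to `ambiguous`);
4. `recent_hgt`: top hit outside the expected phylum while flanking
   best-hits match it;
5. `older_hgt`: top hit within the self-clade (the transferred copy has
   since diversified within the recipient clade), and after removing
   self-clade hits every remaining hit up to k is outside the expected
   phylum;
6. anything else → `ambiguous` with the reason recorded (e.g. flanks also
   pointing outside the phylum, which suggests contamination rather than
   transfer).

Missing flanking evidence is treated as vacuously consistent for rule 3
(absence of evidence about the background is not evidence of transfer) but
cannot *confirm* rule 4, whose whole point is the gene/background contrast.
The `donor_guess` is the deepest rank at which all top-k hits **outside the
expected phylum** agree — self-phylum non-genus hits carry no information
about a donor, so they are excluded from the guess.

`bitscore_ratio` (gene best bit score over the median self-phylum bit score
of the flanks) is recorded on every call as supporting evidence and never
gates a category: the underlying observation — transferred genes score
higher against their donor lineage than the background does against its own
phylum — is descriptive, not a threshold.

Box statistics (for bit-score divergence plots) use linear-interpolation
quartiles, whiskers at the most extreme observations within 1.5×IQR of the
box, and outliers beyond.

k = 10 balances robustness to isolated stray hits against sensitivity when
few informative hits exist; raising k can only make `non_hgt` harder to
call, never flip a uniform-phylum gene to `recent_hgt` (property-tested).

## Assembly metrics

N50 is the length of the scaffold at which the descending cumulative length
sum first reaches half the assembly total (so N50 is always one of the
scaffold lengths and ≥ the median length). Runs of N count toward total
length (gap-filled drafts contain them) but never toward GC. rRNA/tRNA
genes are counted by configurable regular expressions over gene products.

## Synthetic data generator

The generator emulates the *structure* of the study's data, not its
sequences: random-composition scaffolds at a chosen GC (default 35.8%),
gene lengths uniform on 300–1500 bp with 50–200 bp intergenic gaps
(arbitrary but echoed in the `config.json` written beside the outputs), a
pangenome of universal-core / ingroup-core / taxon-unique / expansion
clusters, and planted HGT genes as focal singletons. Defaults are the study
conditions: 127 assayed individuals, prevalences 123/127 and 62/127 with
nested coinfection, 32.97X host depth and 1,000 cells per host (coverage is
derived by inverting the titer formula, so the estimator recovers the
configured cell counts exactly), and a planted panel of 50 recent / 25
older / 125 non-HGT genes.

Hit tables follow the category patterns: background and non-HGT genes draw
self-phylum hits ~ Normal(150, 20) truncated at zero; recent transfers get
donor-lineage hits placed strictly above the gene's self-phylum scores
(offset |Normal(75, 20)|, i.e. a ~1.5× ratio); older transfers get
self-genus top hits above donor-lineage hits and no other self-phylum hits.
Focal genes are laid out so every planted candidate has at least two
non-planted neighbours per side, guaranteeing a background-like flanking
context. All draws come from one seeded generator threaded through the run;
identical (seed, config) pairs produce byte-identical files.

What passing tests on this generator show: the pipeline's bookkeeping, set
algebra, estimators and classification rules are correct against planted
truth. What they do not show: robustness to real-data pathologies —
homology detection noise, chimeric assemblies, incomplete lineages in
taxonomy databases, compositional HGT signals, or hit patterns intermediate
between the planted archetypes. The classifier's ≥95% planted recovery is a
correctness check of the rules, not an accuracy claim on real genomes.

## Problem sizes and numerical choices

The default simulation plants 200 classified genes among ~600 focal genes
across five taxa (~420 clusters, ~0.6 Mbp of focal sequence), sized so a
full generate-analyse cycle runs in seconds. Oracle-equivalence tests use
1,000 random length multisets (N50), every 2×2 table with margins ≤ 15
(Fisher), and 1,000 simulated replicates at n = 127 (Wilson coverage).
Quartiles use linear interpolation between closest ranks. Percent display
never passes through binary floating point. Rounding of intensity displays
is half-up to the nearest integer. Degenerate inputs (empty panels, empty
assemblies, empty cluster sets, pathways with empty gene sets) raise typed
errors rather than returning defaults.

## Known limitations

* The classifier consumes hit taxonomies at six fixed ranks; finer
  structure (species, strain) is out of scope except through the self-hit
  prefix filter.
* Gene trees are consumed, never inferred; concordance evaluation uses a
  midpoint-rooted sister-group majority, which can be misled by sparse or
  unbalanced taxon sampling.
* The titer model assumes uniform depth within each genome and equal
  extraction efficiency across taxa.
* Synteny-level comparisons beyond flanking-gene taxonomy (e.g. block-level
  rearrangement maps) are not implemented.
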