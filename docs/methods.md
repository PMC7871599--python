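# Methods

This note documents the models, conventions and design choices behind
`youngdup`, in the order the pipeline runs them.

## Synthetic genomes and planted duplications

The simulator (`youngdup.simulate`) is first-class, tested code: it
defines the conditions under which the rest of the pipeline is verified.

**Substitution model.** Sequences evolve by Jukes–Cantor: on a branch of
length *t* (expected substitutions/site) each site substitutes with
probability `p = 3/4 (1 − e^{−4t/3})`, uniformly to one of the three other
bases. JC was chosen because it lets identity and Ks targets be set
analytically; the analysis itself makes no model assumption beyond its JC
distance correction. Substitutions that would create a stop codon are
redrawn (new target base at the same site), so every emitted CDS
translates cleanly and protein-guided alignment is always possible. The
redraw slightly depletes stop-adjacent codons; at the divergences used
(< 0.1) the effect on realized p-distance is far below the binomial noise
the tests allow for.

**Events.** A duplication event on a branch is applied at the end of that
branch, after background mutation. The configured divergence *d* is split
evenly: template and copy each receive an independent *d*/2 of JC
mutation, so their expected pairwise divergence at the event is *d*; genes
then continue to diverge by twice the remaining path to each leaf. Tandem
copies are inserted immediately adjacent to their template; transposed
copies at a uniformly random locus on a random chromosome; WGD segments
duplicate a contiguous run of ≥ 6 genes, preserving order, appended at the
end of a random chromosome. Each event draws a previously unused ancestral
family, so planted families are disjoint and the truth ledger is exact.

**Layout.** All species share the ancestral gene order (events aside);
genes are spaced by a fixed 10 kb so chromosome windowing is exercisable
at small gene counts. Coordinates are 0-based half-open internally and
1-based inclusive in GFF3; the conversion happens only in the reader and
writer.

**The standard study clade** (`make_demo_config`) is six species on a
shallow asymmetric tree (terminal branches 0.01–0.035), 200 ancestral
genes on 4 chromosomes, gene length 900 nt, and 60 events — per terminal
branch 4 tandem + 3 transposed + 1 WGD segment, plus 2 of each type on two
internal branches — with divergences drawn uniformly from [0.005, 0.05] so
duplicate pairs stay above 90% identity. These sizes keep a full pipeline
run within a few minutes on one CPU while leaving every class populated
well enough for per-class recall to be meaningful.

**What the simulator does not emulate:** indels, introns and isoforms,
codon-usage bias, selection, gene loss, and genome rearrangement beyond
the planted events. Passing tests therefore demonstrate that the pipeline
recovers what its rules define on clean data of realistic scale — not that
those rules are robust to annotation noise or deep divergence in real
genomes.

## Similarity search

Local alignment with BLASTN-like scoring (match +2, mismatch −3, gap of
length L costs 5 + 2L), both strands searched, best orientation reported.
Identity is matching columns over aligned columns; coverage is the aligned
span of the shorter sequence over its length (switchable to query length
in the config). A raw score threshold (default 100) replaces an e-value
cutoff: for young duplicates (identity > 90%, length ≥ 300) any sensible
threshold is far from the decision boundary, so family membership does not
depend on the proxy. The all-vs-all pass prefilters pairs by shared exact
12-mers; because two unrelated ~1 kb CDSs share a single 12-mer with
appreciable probability, the prefilter requires a minimum shared-k-mer
count (default 3). At identity ≥ 0.85 and length ≥ 300 the expected count
is in the tens, and the suite checks the prefiltered hit set equals the
brute-force all-pairs set on small fixtures. An adapter can import an
external BLAST outfmt-6 file as the hit list for fidelity runs.

## Families, young flags, expansions

Families are single-linkage connected components over hits with coverage
strictly above 0.60; components of size 1 are not families. Thresholds are
strict inequalities throughout ("exceeds", "more than"). A family is young
when (a) some species contributes ≥ 2 members and (b) the maximum
identity over same-species member pairs strictly exceeds 0.90. The
identity scope is intra-species by default (the young-duplication
criterion concerns within-species duplicates) and can be widened to the
whole family. Expansion labels come from per-species member counts:
exactly one species with ≥ 2 members → species-specific; two or more →
lineage-specific of that species set (which may be the entire clade).

## Orthogroups

Young families are split into orthogroups with a length-normalised
best-hit surrogate rather than a full orthology-inference run: scores are
normalised by the geometric mean of sequence lengths; an inter-species
edge is kept when its normalised score is within a factor (default 0.5) of
either endpoint's best inter-species score; intra-species edges are kept
above the young-identity threshold; orthogroups are the connected
components of the kept subgraph. For young families — small, high
identity — this reduces to the same components a cluster-based tool
produces, and an adapter can import an external orthogroups TSV. All
member pairs are enumerated (not only best pairs), since the downstream
statistics average Ks, π and Ka/Ks over all paralog and ortholog pairs.

## Codon alignment and evolutionary statistics

CDSs are translated and the proteins multiply aligned with MAFFT (the
standard tool for this step); codons are threaded back through the protein
alignment, so gaps always occupy whole codon columns and ungapping any row
recovers its input CDS.

**Ka/Ks** uses Nei–Gojobori (1986) counting. Synonymous site fractions
per codon take the three possible changes at each position, with changes
to stop codons counted as nonsynonymous; differences in multi-hit codons
are averaged over all mutational pathways that avoid stop codons (over all
pathways when every one is blocked). Both proportions receive the JC
correction `d = −3/4 ln(1 − 4/3 p)`; a pair with `p ≥ 3/4` is saturated
and dropped with a log message. Gapped codon columns are excluded per pair
(pairwise deletion). Ka/Ks is undefined at Ks = 0 and such pairs are
excluded from ratio averages, avoiding infinities in group means. Ks
values ≥ 1 are not "retained" (synonymous saturation makes the clock
unreliable); histograms bin retained values in [0, 1) at width 0.1, with
each value assigned to `floor(Ks/0.1)`.

**π** is the mean pairwise difference proportion over columns where
neither row of the pair is gapped, `π = 2/(n(n−1)) Σ_{i<j} d_ij/L_ij`.

**Group comparisons** (paralog vs ortholog π and Ka/Ks) use Welch's
two-sample *t*-test; the degenerate case (both groups constant and equal)
reports p = 1 by convention. In per-species summaries a cross-species
ortholog pair contributes to both member species, since no principled
single assignment exists.

## Collinearity and duplication types

Anchors are homologous pairs placed in gene-rank space (rank = 0-based
order by start along the chromosome, strand-ignored). Per chromosome pair,
blocks are longest chains of anchors strictly monotone on both sides (same
or inverted orientation) with rank gaps ≤ 25, of ≥ 5 anchors;
non-overlapping top chains are extracted greedily. On instances of ≤ 12
anchors the DP is tested against exhaustive chain enumeration.

Each young intra-species paralog pair is typed with priority
**WGD > tandem > transposed > other**:

* WGD — the pair itself is an anchor inside an intra-species block (block
  evidence is the most specific, hence highest priority);
* tandem — same chromosome with at most `tandem_max_gap` (default 0:
  strict adjacency) intervening genes; a proximal category (gap ≤ 10) can
  optionally be folded into tandem, otherwise it falls to "other";
* transposed — the two genes have *unequal cross-species block support*
  (the number of partner species a gene is block-collinear with); the
  better-supported gene is the ancestral locus. This generalises the
  simpler "exactly one gene sits in a block" test, which fails for copies
  transposed on internal branches: such a copy is inherited at the same
  locus by every descendant species and is therefore collinear with its
  sister lineages while remaining non-collinear with the outgroup —
  support asymmetry captures exactly that without requiring a designated
  outgroup genome;
* other — everything else, including unpaired genes, so per class
  tandem + transposed + WGD + other equals the class total.

Gene-level summaries type each gene once by its highest-priority pair
call; percentages divide by the number of young duplicate genes of that
species and expansion class (genes of species inside the family's
expanded-species set).

## Windows

A gene belongs to the window of its start coordinate (windows default to
1 Mb). Density is young genes over all annotated genes per window — the
definition that reproduces "fewer genes but higher density" telomeric
signals — with genes-per-Mb available as an alternative. The
species-specific vs lineage-specific location relationship is Pearson's r
between per-window count vectors on the same chromosome, undefined (and
reported missing) when a vector is constant.

## Trees and duplication events

Family trees use Saitou–Nei neighbor joining on nucleotide p-distances
(pairwise deletion of gapped sites) with deterministic lexicographic
tie-breaking; branch lengths are the standard NJ estimates and may be
slightly negative on non-additive input. Bootstrap resamples codon
columns (preserving frame) and reports, per original internal bipartition,
the percentage of replicates containing it. Trees are unrooted: a "clade"
is a bipartition side. A species-specific duplication event is a maximal
single-species side with ≥ 2 genes and support strictly above 50;
maximal-first greedy selection keeps only disjoint clades, so nested
duplications are counted once and each gene contributes to one event. The
pipeline builds trees for young families in which every species has ≥ 2
members (the families where cross-species event counting is informative).

## Reports

Displayed percentages are count ratios rounded half-up to 2 decimals; TSVs
keep full precision. Domain preference consumes a precomputed
gene-to-domain table (running an HMM scan is out of scope); counts are per
gene occurrence, a domain's species occurrence is the number of species
whose young duplicates of the given expansion kind carry it, and the
spectrum gives the share of domains at each occurrence level. The
simulator ships a synthetic domain table generator for exercising these
summaries.

## Numerical and degenerate-input conventions

* Seeds: every stochastic component (simulation, bootstrap, power
  estimation) takes an explicit seed; identical configuration and seed
  give byte-identical outputs.
* Genes failing CDS validation (length not a multiple of 3, internal stop)
  are dropped with a logged count rather than aborting — real annotations
  contain such models.
* Equal-distance NJ ties, equal-scoring chains and component orderings all
  break deterministically (lexicographic by identifier).
* Known limitations: the score-threshold proxy is not an e-value and is
  not calibrated for remote homology; the orthogroup surrogate is not a
  substitute for full orthology inference on old families; transposed
  detection needs enough genome-wide collinearity for block support to be
  informative and will under-call in heavily rearranged genomes; p-distance
  NJ is appropriate for the young (low-divergence) families it is applied
  to, not for deep phylogenies.
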