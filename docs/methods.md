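# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Replication origin/terminus from GC skew

On most bacterial chromosomes the leading replication strand accumulates
an excess of G over C, so the windowed skew S_w = (G−C)/(G+C) changes
sign at the origin and terminus and the cumulative per-base skew
c[i] = Σ_{j≤i} (+1 for G, −1 for C) is V-shaped with its minimum at ori
and maximum at ter (under the G-rich-leading-strand convention; the sign
convention is a documented choice, configurable in principle by
complementing the input).

Because a deposited circular sequence starts at an arbitrary rotation,
c carries a linear trend equal to its net slope over one full circle;
we subtract that trend before taking extrema. This makes the call
exactly rotation-equivariant: rotating the sequence by k shifts both
calls by k mod L, with no dependence on the deposited start coordinate.

* Window 2000 bp, step = window (non-overlapping) by default — the
  display convention for genome-atlas rings; both configurable.
* N bases contribute 0 to skew and are excluded from the GC-content
  denominator (neutrality).
* Confidence: a profile whose detrended range is below 2·√L — the
  scale of the fluctuation of an unbiased ±1 random walk of length L —
  yields a flagged low-confidence call rather than an exception.
* DnaA-box refinement: biological origins are marked by clusters of
  DnaA boxes. If a cluster of ≥ 3 boxes lies within 20 kb of the skew
  minimum, the ori coordinate snaps to the cluster midpoint. The 20 kb
  radius reflects how far skew extrema typically wander from the true
  origin on real chromosomes (the CH34 paper-scale case has the box
  cluster ~90 kb from the *dnaA* gene but immediately adjacent to the
  skew transition). The skew extremum and the cluster positions are both
  reported; the tool does not adjudicate between them beyond the snap.

## Degenerate motif scanning

A consensus is an ordered list of allowed-base sets, parsed from plain
bases, IUPAC codes, or `(X/Y)` alternation. Mismatch counting: a base in
the allowed set costs 0 (degenerate positions are free by construction —
mismatches are counted against the consensus, not against one
expansion); an N in the subject never matches (conservative on
ambiguous sequence). Circular scans wrap across the origin; minus-strand
hits are matches of the reverse-complemented motif reported in forward
coordinates. All overlapping hits are reported (box clusters genuinely
overlap); clustering of hits is single-linkage on start-position gaps
with a configurable maximum gap, merging across the circular origin.
Default budgets follow usage: ≤ 2 mismatches for the DnaA box, 0 for
the RepA repeat.

## Orthology

Protein pairs between species are orthologs iff (i) percent identity
≥ 35, (ii) reciprocal best hit by alignment score, (iii) alignment
covering ≥ 80 % of the smaller protein. Identity is computed over
aligned columns (the BLAST convention); coverage is the aligned span on
the shorter protein over its length. Criterion (iii) is a coverage
requirement, not a second identity computation.

The aligner is Smith–Waterman with affine gaps via Biopython's
`PairwiseAligner` (BLOSUM62, open 11, extend 1 — BLAST protein
defaults). Traceback ties are resolved by the aligner's deterministic
first-optimal-alignment enumeration. A best-score tie between two
subjects breaks toward the lexicographically smaller id, making the
whole search order-independent. No E-value statistics are computed; the
identity/coverage criteria are the operative filter.

The all-vs-all search screens candidates by shared k-mers (k = 4,
≥ 2 shared words by default). The screen is a pure speed device: with it
disabled the search is exhaustive, and that exhaustive mode is the
reference the screened mode is tested against. On substitution-only
synthetic data the screen loses essentially nothing at the identities of
interest (a planted ortholog at ≥ 60 % identity shares far more than two
4-mers); on real proteomes, as with BLAST word seeding, very weak
homologies below the ortholog criteria could be screened out.

Ortholog groups across ≥ 2 species are connected components of the RBH
graph (single linkage over pairs); the Venn partition counts, per
species subset, the groups whose species set equals that subset — both
group counts and member-protein counts are emitted, since either may be
the quantity of interest. Singleton regions count proteins in no
multi-species group.

Syntons are maximal runs of ortholog pairs whose order indices on the
two replicons move co-monotonically (same or inverted orientation),
tolerating up to `max_gap` intervening unmatched genes on either
replicon (default 1); runs shorter than `min_synton_size` (default 3)
are discarded. The walk is greedy from each unconsumed anchor, taking
the longer of the two orientations; on the hand-checkable fixtures it
matches exhaustive enumeration of co-monotone runs.

## Replicon and protein distances; single linkage

Replicon distance: d = 1 − n_orthologs / min(N_a, N_b) with N the
protein counts — the normalisation is by the smaller *proteome* (the
numerator is a protein count, so a base-pair denominator would be
dimensionally wrong). d ∈ [0,1], monotone in shared orthologs.

Protein distance (sigma-factor survey style): d = 100 − % similarity,
where the percentage is normalised by the shorter protein's length
rather than by aligned columns. This is deliberate: a whole-protein
distance must not reward the short, ~40–50 %-identity local hits that
any two unrelated proteins produce; with length normalisation unrelated
200-residue pairs land at d > 60 while identical sequences are d = 0.
A flag switches the numerator from identical columns to BLOSUM-positive
(similar) columns.

Single linkage is implemented directly (naive agglomeration) because
determinism requires a tie rule — equal minimum distances break toward
the lexicographically smallest cluster-label pair — which library
implementations do not expose. Merge heights are verified against an
independent library implementation in the tests. The dendrogram is
exported as an ultrametric Newick (a cluster merged at height h sits at
h/2 above the leaves, so cophenetic leaf-leaf distances equal merge
heights).

## Paralog families

Within one proteome: (1) mask low-complexity segments; (2) build a
directed graph of above-threshold all-vs-all hits; (3) re-check every
asymmetric edge with a fresh full alignment and keep it only if it
passes the threshold (symmetrification); (4) flag and exclude putative
multi-domain fusion proteins; (5) families are connected components
(size ≥ 2) of the symmetrified graph; everything else is a singleton.

Numerical choices, all configurable:

* Edge threshold: identity ≥ 30 % with coverage ≥ 50 % of the smaller
  protein — a deliberate proxy for a stringent E-value cutoff, since no
  E-value statistics are implemented.
* Low-complexity mask: sliding 12-residue window, Shannon entropy
  < 2.2 bits → masked to X. A uniform-random 12-mer has entropy
  ~3.4 bits, so ordinary sequence is untouched while homopolymeric and
  short-period runs are masked. Windows containing X are not
  re-evaluated, which makes the mask idempotent by construction. This is
  a simplification of dedicated complexity filters (CAST/SEG): it
  catches compositional runs but not subtler period-k bias.
* Multi-domain flag: a protein with two neighbours whose aligned spans
  on it overlap by < 20 % of the shorter span, the neighbours themselves
  being unconnected, is treated as a domain fusion and excluded before
  closure (otherwise one fusion glues two unrelated families). The 20 %
  cutoff separates clean fusions from alignment jitter on the fixtures;
  no principled value exists without domain decomposition.

## Genome reports

The general-features summary counts CDS per category (assigned /
conserved hypothetical / hypothetical / unclassified — finished-genome
tables leave a remainder of CDS in no narrative category, so the
categories are not forced to sum without it), RNA genes and mobile
elements per replicon, with percentages computed from the counts and
rounded half-up to one decimal (so printed values like 9.1 % are
reproduced exactly). The COG ratio r = (n₂/N₂)/(n₁/N₁) defaults to
second-replicon-over-first with N = COG-assigned CDS; both the
direction and the denominator (total CDS instead) are flags, since
either convention is defensible and published figures rarely state
which was used. A class absent from replicon 1 yields a flagged
infinite ratio rather than an error.

## Synthetic data: what it emulates and what it does not

Replicons: i.i.d. background with P(G) = gc/2 + δ/2 on the leading
replichore (reversed on the lagging one), planted motif instances
overwriting the background. This reproduces the *signal* the skew
analysis detects — a sign-switching compositional bias — with known
truth, but none of the local structure of real chromosomes (genes,
codon bias, repeats, GC gradients). Passing recovery tests therefore
shows the estimator is correct for the bias model, not that real
chromosomes always carry a detectable bias.

Proteomes: ancestral sequences i.i.d. uniform over 20 residues
(length ~ N(300, 60²), floored at 60); core genes are per-species
mutants of a common ancestor; accessory genes are private random
sequences; paralog families are diverged duplicates within one species.
Divergence is substitution-only — positions uniform without
replacement, replacement residue ≠ original — so `mutate_to_identity`
hits its target exactly (±1 point from rounding) and planted ortholog
alignments are full-length (coverage 1.0 up to the occasional clipped
terminal mismatch: an optimal local alignment drops a negative-scoring
substituted end residue). Pairwise targets are met on a star topology
by non-negative least squares over per-species divergences
(d_a + d_b = 100 − t_ab); realized pairwise identity is then accurate
to a point or two for targets ≥ 60 % (mutation-position overlap adds a
small positive bias). Real protein families violate most of this —
indels, domain shuffling, rate heterogeneity, biased composition — so
recovery results bound performance under the clean model only. An indel
mode is deliberately not the default because it would destroy the exact
coverage control.

Default study conditions: 4 species × 150 genes, core fraction 0.62
(the chromosome-1 compartment of a four-species *Cupriavidus*-style
comparison), pairwise identity 80 %, gene order fully conserved. All
randomness flows from explicit seeds; a global seed derives independent
per-component streams via fixed offsets, and identical spec + seed
yields byte-identical output files.

## Problem sizes and determinism

The test and acceptance workloads run at desk scale by design: ori/ter
recovery on 100 kb replicons (20–100 seeded runs), orthology on
4 × 150-gene proteomes, paralog recovery on 20-member planted families
over 10–20 seeds, oracle equivalence on 10 kb scans and ≤ 30-residue
alignment pairs. These sizes give stable statistics (recovery rates are
at their ceiling well before these n) while keeping a full run in the
low minutes. Every pipeline stage is deterministic given its
parameters; the pipeline manifest records seeds, effective thresholds
and output checksums, and a rerun of a seeded config reproduces the
checksums bit for bit.

## Known limitations

* No E-value model; thresholds are identity/coverage proxies.
* No indel-aware truth bookkeeping in the generator (substitution-only
  by default).
* The ori/ter caller assumes a single bias switch per replichore pair;
  heavily rearranged replicons with multiple skew sign changes yield a
  single call plus a confidence flag, not a segmentation.
* Multi-domain detection is span-overlap heuristics, not domain
  decomposition.
* The Venn partition's "group vs protein" counting ambiguity is handled
  by emitting both counts, labelled.
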