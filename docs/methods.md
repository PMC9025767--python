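# Methods

This note documents the models, decision rules and numerical choices
behind `repliconkit`, and what the synthetic-data tests do and do not
demonstrate about real genomes.

## Scope and assumptions

The toolkit operates on *closed* multipartite genomes: one declared
chromosome (typically the DnaA-bearing largest replicon; chromosome
identity is an input, not an inference) plus extrachromosomal replicons
(ECRs). It consumes final assemblies, annotations and per-base depth;
read mapping, assembly, assembly polishing and HMM-based protein domain
annotation are upstream of this package. Coordinates are 1-based and
inclusive throughout (GFF3 convention).

## Copy number

The copy number of an ECR is the ratio of its median per-base coverage
to the chromosome's median per-base coverage, so the chromosome is 1.0
by definition. The median — not the mean — is used because it is robust
to repeat-induced coverage spikes and origin/terminus gradients.
Even-length medians are midpoint-averaged. Zero-depth positions are
included: they are genuine observations of the replicon's coverage.
No GC-bias correction is applied to the depth. The chromosome median
must be positive; a zero median is a degenerate input and an error.

Under the Poisson coverage model of the simulator, the median-ratio
estimator recovers true ratios in {0.5 … 124.3} with median relative
error well under 5% (chromosome ≥ 50 kb at 100×); the residual error is
dominated by the discreteness of the Poisson median.

## Circularity

A linear contig representing a closed circle carries its 5′ prefix
verbatim as its 3′ suffix. The detector finds the longest k ≤ L/2 with
`seq[:k] == seq[-k:]` at 100% identity (N matches nothing — each N is
internally mapped to a unique symbol) via the Knuth–Morris–Pratt border
array, so detection is exact and linear-time; a quadratic brute-force
comparator serves as the oracle in tests. A contig is circular when
k ≥ 50 nt (configurable), and circularization removes the suffix copy.
Choices worth noting:

* Only strictly terminal, forward-orientation overlap is tested. A
  reverse-complement end join would indicate misassembly, not a circle;
  a near-terminal (not flush) repeat, which an alignment-based scan
  could report, is likewise not accepted.
* The search is capped at half the contig length: a longer
  "self-overlap" implies a collapsed tandem repeat.
* Rotating the circularized sequence to start at the replication locus
  requires the replicase coordinate and is offered only as a manual
  operation (`rotate_to_start`).

## Genomic imprints

Two compositional signatures are computed per replicon:

* **RSCU** — for codon c in synonymous family F,
  RSCU(c) = |F| · n_c / Σ_{c′∈F} n_{c′}. Methionine, tryptophan and
  stop codons have no synonymous choice and are excluded (59 codons).
  Codon counts are pooled over all CDS of the replicon (concatenation,
  not per-gene weighting); minus-strand CDS are counted in coding
  orientation; incomplete trailing codons are trimmed and codons
  containing N skipped. Families unobserved on a replicon yield missing
  values, imputed as the neutral 1.0 for distance computation only.
* **Tetranucleotide frequency** — overlapping 4-mer counts accumulated
  from the sequence and its reverse complement (strand-convention-free)
  and normalized; windows containing N are skipped.

Profiles are compared with the correlation distance 1 − *r* (Pearson),
which is scale-free and standard for compositional signatures. An ECR
is *chromosome-like* under a signature when its distance to the host
chromosome is smaller than its distance to **every** replicon of an
internal reference genome — an unrelated, well-characterized genome
that acts as an outgroup and calibrates how far "foreign" lies. The
imprint criterion passes only when the CU and tetra verdicts agree.
This nearest-profile rule replaces dendrogram-membership reading, which
is not reproducible without an explicit cut height; an average-linkage
dendrogram over all profiles is still emitted (newick) for inspection.
An ECR with no usable CDS fails the CU criterion explicitly (reason
flag), never silently.

## The four-criterion chromid rule

A non-chromosome replicon is a **chromid** iff all four hold, else a
**plasmid**:

1. a *parAB* partitioning system (≥ 1 parA-labeled and ≥ 1 parB-labeled
   CDS; co-presence anywhere on the replicon by default, an operon-like
   maximum distance is configurable);
2. copy number strictly < 2;
3. |GC_replicon − GC_chromosome| strictly < 2.5 percentage points,
   applied to full-precision GC (display rounds to 1 d.p.);
4. chromosome-like imprint under both signatures.

Both thresholds are configurable. GC is computed over determined bases
(N excluded from the denominator). Missing evidence fails the affected
criterion closed, with an "insufficient evidence" flag in the report.
One published boundary case is worth recording: a replicon whose
rounded GC sits exactly 2.5 points from its chromosome is classified
chromid in the packaged reference table although strict `< 2.5` on the
rounded values would exclude it — consistent with unrounded GC values
differing from the displayed ones; the packaged table stores the
published class labels verbatim and the strict rule is applied only to
full-precision inputs.

## Mobility screening

Annotation labels (tokens from `gene=`/`product=` strings) are matched
against a JSON vocabulary. A replicon is **conjugative** when it
carries both universal T4SS core components — a VirB4-like ATPase and a
VirD4-like coupling protein; it is **mobilizable** when it carries a
MOB-family relaxase without a T4SS. When several relaxase tokens occur,
the family is taken from a fixed priority order (MOBF > MOBH > MOBP >
MOBQ > MOBC > MOBV). Token matching is a deliberate stand-in for
HMM-based relaxase/T4SS scans, which are upstream tools; a precomputed
relaxase-scan TSV can override the token-derived families
(`apply_mob_override`).

## Replicase typing and homolog trees

A query replicase is globally aligned (Needleman–Wunsch/Gotoh affine
gaps, BLOSUM62, open −11 / extend −1, via Biopython) against each panel
exemplar; identity = identical columns / aligned columns. The query
receives the type of its best exemplar when identity ≥ 0.30 — the
conventional homology floor for replication proteins — else
"unclassified". Ties break by alignment score, then exemplar id, so
typing is independent of panel order. The bundled panel is **synthetic**
(seeded random exemplars, two per type family, 15% within-family
divergence); it exercises the machinery and the packaged tests, and a
curated protein panel can be supplied in the same `|type=`-tagged FASTA
format.

Trees of replicase homologs are built by: (1) center-star progressive
multiple alignment (the sequence with the highest summed pairwise score
is the scaffold; "once a gap, always a gap"), or a user-supplied
alignment; (2) elimination of every column containing a gap or missing
data; (3) Kimura-style corrected distances d = −ln(1 − p − 0.2 p²),
capped at 10 for saturated pairs; (4) neighbor joining (scikit-bio),
negative branch lengths clamped to zero; (5) bootstrap by resampling
alignment columns with replacement (default 100 replicates), supports
attached as percentages on internal bipartitions. Full maximum
likelihood search is out of scope; distance NJ is sufficient for
type-level grouping and is deterministic given the seed. The
Kimura-style correction is used for all pairs rather than a
rate-matrix ML distance: at the within-family divergences these trees
are built for, the two are nearly proportional, and the correction
needs no model constants. Note the center-star alignment (and hence the
gap-free column count) is only meaningful for sets of actual homologs —
one family per tree, as in per-type replicase trees; mixing unrelated
families saturates all distances.

## Synthetic genomes

The simulator defines the study conditions under which the pipeline is
validated:

* **Background composition**: a 3rd-order Markov model (64 contexts ×
  4 bases). Every context row emits G+C with probability exactly equal
  to the GC target, while the C/G and A/T splits are context-specific
  seeded Beta(4,4) draws — so realized GC concentrates on the target
  (±0.5 points at 100 kb is asserted over 20 seeds) while each profile
  retains a distinctive tetranucleotide signature.
* **Codon model**: a seeded Dirichlet draw over the 61 sense codons,
  exponentially tilted so the expected CDS GC matches the target (the
  tilt target is nudged by (6·GC − 1)/600 to offset the fixed ATG/TAA
  start and stop of each simulated gene). Filler genes sample codons
  iid from this distribution; marker genes carry real product strings
  (ParA/ParB, VirB4/VirD4, Mob-family relaxases); the replicase gene is
  a back-translated, substitution-diverged copy of a panel exemplar.
* **Bias sources**: an ECR inherits the host profile (chromid-like
  imprint), the reference profile (foreign imprint at GC 66% vs host
  60% by default) or a custom one. The internal-reference genome
  (chromosome + 2 ECRs) shares the reference profile.
* **Coverage**: independent per-base Poisson(copy_number × chromosome
  median depth); no overdispersion (a negative-binomial hook is left
  out deliberately — the validated estimator is median-based and
  insensitive to mild overdispersion).
* **Circularity**: a circular replicon is emitted with its first
  `overlap` bases duplicated at the end.
* Identical seeds give byte-identical output (all randomness flows
  from `numpy.random.default_rng` seeded with the spec seed).

The default study condition (`default_simulation`) is a 100 kb
chromosome at GC 60%, reference at 66%, with a 25 kb host-imprinted
chromid (0.9 copies, parAB, 60 nt terminal overlap), a 25 kb
foreign-imprinted conjugative plasmid and a 6,732 bp 20-copy
mobilizable plasmid. The problem sizes (100 kb chromosomes, 20 seeds;
300 kb–3 Mb coverage-only stand-ins for copy-number recovery) are the
package's chosen desk-scale conditions: large enough that composition
and median statistics concentrate, small enough to iterate quickly.

**What passing tests show — and don't.** The generative separation
between host and reference profiles (6 GC points plus independent codon
preferences) is stronger than between a real chromosome and a
long-ameliorated chromid; the ≥ 95% label-recovery results therefore
validate the machinery and the decision rule, not the difficulty of
borderline real replicons. Real annotations are noisier than the
simulator's clean product strings, so token-based screening on real
genomes benefits from the relaxase-scan override. The Poisson coverage
model omits mappability and GC-coverage artifacts of real libraries.

## Numerical details and degenerate inputs

* GC of a sequence with no determined bases is 0; empty replicons are
  rejected at construction.
* Depth TSVs are dense-filled with 0 at absent positions; duplicate
  positions and positions beyond the replicon length are errors.
* `imprint_distance` requires non-constant vectors (zero variance is an
  error, not a silent NaN).
* Alignment identity counts matches over aligned columns; pairwise
  global alignments contain no dual-gap columns.
* NJ requires ≥ 3 taxa; alignments with zero gap-free columns are an
  error; bootstrap supports are rounded to integer percentages.
* All report rounding (GC, ΔGC, copy number to 1 d.p.) happens at
  display time; thresholds always see full precision.

## Known limitations

* The chromosome must be declared; the package does not locate *dnaA*.
* Chromid criterion iv depends on the chosen reference genome; a
  reference compositionally close to the host weakens the contrast.
* The token vocabulary is intentionally small and curated; exotic
  T4SS nomenclatures require extending the JSON config.
* The bundled replicase panel is synthetic; typing real proteins
  requires a curated panel of real exemplars.
* Terminal-overlap detection assumes polished assemblies: a single
  sequencing error in the overlap defeats the 100%-identity rule, by
  design.
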