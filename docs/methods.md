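# Methods

This note documents the models and procedures implemented in `glutannot`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Gene model and translation policy

A HMW-GS gene is treated as one intronless ORF plus an optional 5'-flanking
promoter supplied in the same FASTA under the `<id>_prom` naming convention.
Translation uses the standard genetic code with three conventions specific
to these genes: up to two trailing in-frame stop codons are consumed and
counted (HMW-GS ORFs conventionally terminate in a tandem stop pair, and the
3' cloning primers for these genes encode TGA TAG); a codon containing `N`
translates to `X`; an internal stop followed by further coding sequence
marks the record as pseudogene-like, and translation is returned up to that
stop with a warning rather than an error. Reports carry both the raw codon
count of the ORF and the mature-subunit length, because the two accountings
(ORF bp vs signal + mature + stops) are the quantities practitioners quote
and they cannot always be reconciled from published tables alone.

## Subunit anatomy

The mature subunit starts at the leftmost occurrence of the conserved
pentapeptide **EGEAS** within the first 40 residues; everything before it is
the signal peptide. No SignalP-style prediction is attempted — the anchor is
diagnostic in this family. Typing uses residue 6 of the mature sequence
(G/E → x-type, R/K → y-type); if that residue is uninformative (e.g. `X`),
the N-terminal domain length is used instead (75–95 → x, 96–112 → y,
otherwise unknown).

Domain partitioning fixes the C-terminal domain at the final 42 residues
(constant across known alleles; deviations would be reported, not forced)
and defines the repetitive domain as the maximal region starting at the
first position from which at least three consecutive repeat motifs can be
chained. The three-in-a-row onset rule is our operationalization of a
boundary that the literature reports but never algorithmically defines; it
is robust to single spurious motif-like words inside the N-terminal domain
(the N-terminal consensus itself contains one near-tripeptide at residues
6–8). All residue numbering is 1-based.

The cysteine census counts `C` per domain and flags conformance with the
conserved patterns x = (3, 0, 1) and y = (5, 1, 1); the known x-type variant
(3, 1, 1) with an extra repetitive-domain cysteine (as in subunit 1Dx5) is
accepted as conforming.

## Repeat grammar

The default motif lexicon is the canonical HMW-GS set: tripeptide `GQQ`
(≤ 1 mismatch), hexapeptide `PGQGQQ` (≤ 2), nonapeptides `GYYPTSPQQ` and
`GYYPTSLQQ` (≤ 2). The published repeat classes do not come with fixed
consensus strings, so the lexicon is a plain config file (`class consensus
max_mismatch` per line) and every entry point accepts a replacement;
reproducing motif counts on particular real accessions may require tuning
it.

Segmentation is an exact dynamic program over the domain that minimizes,
lexicographically, (1) unassigned residues and (2) total Hamming mismatches
against the consensus, with a deterministic reconstruction that prefers a
motif over a skip and a longer motif over a shorter one at equal cost.
Mismatches are substitutions only; indels are absorbed by unassigned spans,
which keeps the parse quadratic and reproducible. The DP optimum is verified
against exhaustive tiling enumeration in the test suite. Every census
satisfies the identity `3a + 6b + 9c + unassigned = domain length`, which is
asserted at run time.

## Insertion blocks and tandem duplication

Query and reference subunits (same type) are globally aligned with affine
gaps via `Bio.Align.PairwiseAligner`. Defaults: match +2, mismatch −1, gap
open −10, gap extend −0.2, where a gap of length k costs `open + k·extend`.
The long-gap-friendly setting makes a 141-residue duplication align as one
contiguous block rather than scattered gaps. Runs of reference-gap columns
of at least `min_block = 30` residues become insertion blocks; the threshold
separates block duplications from the single-repeat-scale changes (point
substitutions, single-motif indels) that show up as short gaps and
mismatches instead.

Within a tandem repeat the placement of an indel is ambiguous — excising
either copy of a perfect duplication yields the same sequence — so each gap
run is normalized to its 3'-most equivalent position (the indel-
normalization convention of variant calling). A detected duplication block
is therefore reported as the downstream copy with its donor window
immediately upstream, and the planted-truth tests recover block boundaries
exactly. Duplication evidence compares the block with its equal-length
upstream and downstream windows by global alignment, reporting the better
flank, percent identity over alignment columns, and 1-based variant
positions; a block touching the sequence edge is compared on its single
available flank. The comparison window is defined as the equal-length
immediately adjacent window; published figures of repeated-vs-inserted
regions do not specify their window placement numerically, so this is the
package's own convention.

## Promoter elements

The six regulatory elements are scanned in their canonical 5'→3' order with
per-element mismatch budgets: 2 for the 8–9-bp elements, 3 for the 38-bp
enhancer, 1 for the 6-bp start motif. Known alleles carry up to two
substitutions in the short elements and up to three changes in the enhancer,
so stricter budgets would misclassify real promoters as deleted.

Assignment is a joint optimization over all six elements rather than a
greedy per-element scan: elements must occur in order without overlap, and
the annotation minimizes, lexicographically, deleted elements, unmatched
element length, substitutions, gapped hits, and finally prefers leftmost
placements. The joint criterion is load-bearing because the partial enhancer
(`TTTGCAAA`) is an exact substring of the complete enhancer: when the true
partial copy has been deleted (the case of promoters carrying the 85-bp
deletion), a greedy scan would claim the enhancer's internal copy for the
partial element and then mis-report the enhancer itself as lost. Preferring
smaller unmatched length resolves the tie in favour of keeping the 38-bp
enhancer.

A single-base deletion inside the enhancer (seen in one known x-type allele)
is handled by also scoring windows of length L−1 against the consensus with
one base removed; the gap counts as one edit against the budget and the hit
is reported as found with a deletion flag. Gapped windows are only
considered for elements of ≥ 20 bp — on an 8-bp element a gapped match
carries no statistical signal. Scanning is on the given strand only;
promoters are supplied in gene orientation.

## Phylogeny

The phylogenetically informative region is the promoter followed by the CDS
of the signal peptide and the N-terminal domain; the repetitive domain is
excluded as unalignable. Distances are p-distances (proportion of differing
sites) with pairwise deletion of gapped sites; a Jukes–Cantor correction is
available. The original analyses of such data used MEGA's Maximum Composite
Likelihood model; we deliberately substitute the p-distance because exact
MCL replication is out of scope and, on sequences this similar, topology is
insensitive to the model choice — a claim the test suite itself checks by
comparing p-distance and Jukes–Cantor NJ topologies on synthetic families.

Neighbor joining is the Saitou–Nei algorithm with two determinism/sanity
conventions: minimum-Q ties break lexicographically by the smallest leaf id
under each cluster, and a negative branch length is clamped to zero with the
deficit transferred to its sibling so pairwise path lengths are preserved.
Trees are written as newick with bootstrap supports as internal-node labels.
Bootstrap resamples alignment columns with replacement under an explicit
seed; support is the percentage of replicate NJ trees containing each
internal bipartition.

The median-joining network follows Bandelt's construction: invariant sites
are dropped, identical haplotypes collapse into one node, a minimum-spanning
network is built over distance classes in ascending order (with tolerance
epsilon, default 0), median (Steiner) vectors of connected triplets are
added iteratively, and a median is retained only if removing it would
lengthen the minimum spanning tree over the remaining nodes — a simplified
but deterministic form of obsolete-median pruning that reproduces the
hand-enumerable cases. `weights` (default 10, the convention of the Network
program) is a uniform per-site weight recorded in the output; with uniform
weights it cannot change the topology. Edge labels are counts of differing
variable sites.

## Synthetic data: what it does and does not emulate

The generator emits genes whose truth record fully determines every
downstream result at substitution rate 0. Architecture: 21-residue signal
peptide, x-type 86-residue or y-type 104-residue N-terminal domain starting
`EGEAS(G|R)QLQCER`, a repetitive domain concatenated from canonical motifs
in a seeded order, and a 42-residue C-terminal domain, with the conserved
cysteine placements (the y-type repetitive cysteine is planted inside one
hexapeptide token, within its mismatch budget). Proteins are
reverse-translated with uniform seeded choice among synonymous codons (no
codon-usage model — nothing tested depends on one) and terminated with the
tandem stop pair.

Deliberate identifiability choices, without which "recover the planted
truth" would be ill-posed rather than merely hard:

- N- and C-terminal filler sequences avoid G and Q entirely, so no repeat
  motif can match outside the repetitive domain and the domain onset is
  unambiguous.
- The token immediately following a planted duplication starts with a
  different residue than the duplicated block, so the block's 3' boundary
  cannot slide.
- Promoter background spacers are rejection-sampled to contain no window
  within any element's mismatch budget (a uniform-random 900-bp background
  would contain ~0.4%-per-window spurious matches for an 8-bp element,
  making planted deletions undetectable in principle).
- `sub_rate` substitutions spare the signal peptide and the 12-codon
  N-terminal consensus and are redrawn if they would create an in-frame
  stop.

In `generate_insertion_pair` the reference allele is derived from the query
by excising the inserted copy's codons, so the two alleles share their
`sub_rate` divergence by inheritance — as real allele pairs related by a
recent duplication do. Post-duplication divergence of the copy is modelled
separately by `n_substitutions`, which mutates one residue in each of that
many motif tokens of the inserted copy. Under independent noise on the two
alleles, the placement of a block inside a periodic repeat region is
unidentifiable (many rotations are near-co-optimal), so planted-boundary
recovery is a property of the shared-ancestry model, not of arbitrary noise.

Consequently, passing tests demonstrate correct recovery of planted
structure under the generator's conditions; they do not demonstrate that the
default lexicon or alignment parameters reproduce motif counts on arbitrary
real accessions, which may need lexicon tuning (see above), nor do they
bear on expression-level biology.

Family generation evolves a random root along a stated topology with an
exact per-branch substitution count, placing mutations at distinct alignment
sites while unused sites remain so that leaf-to-leaf distances stay additive
on the true tree. No indels are generated, so alignment is the identity.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale inputs chosen to exercise every code
path: repetitive domains of a few hundred residues (real domains are
480–870), segmentation-oracle domains of ≤ 30 residues (exhaustive tiling
enumeration is exponential), alignment-oracle sequences of ≤ 12 residues,
6-leaf families with 5 substitutions per branch, and 100–200 bootstrap
replicates in tests (the pipeline default is 1000, the conventional
published setting). All reported coordinates are 1-based inclusive; all
randomness flows through explicitly seeded numpy generators; report files
embed the package version, a configuration hash and the seed, and identical
configurations produce byte-identical outputs.

## Known limitations

- The motif lexicon is a heuristic consensus set; exact repeat censuses on
  real accessions are lexicon-dependent.
- Published tables of domain sizes contain two internally inconsistent rows
  (an x-type allele listed as 89 + 984 + 42 = 815 and a y-type allele as
  104 + 583 + 42 = 732); such rows cannot be used as checks and are
  excluded from validation.
- Alignment is pairwise only; the multiple-alignment step of the original
  workflow is replaced by accepting pre-aligned FASTA for phylogeny input.
- The median-joining pruning rule is a simplification of the full
  obsolete-vector criterion; on large haplotype sets it may retain slightly
  different median sets than the Network program, though observed haplotypes
  and connectivity are always preserved.
- Breakpoints are reported at the protein level; reconstructing unequal-
  crossover breakpoints at the DNA level is out of scope.
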