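# glutannot

Structural and evolutionary annotation of high molecular weight glutenin
subunit (HMW-GS) genes.

HMW glutenin subunits are the seed storage proteins of wheat and its wild
relatives that largely determine dough elasticity and bread-making quality.
Each *Glu-1* locus encodes one x-type and one y-type subunit; a mature
subunit consists of a conserved N-terminal domain (~81–89 residues in x-type,
~104 in y-type, starting with the signature E-G-E-A-S), a central
low-complexity repetitive domain built from tripeptide (GQQ), hexapeptide
(PGQGQQ) and nonapeptide (GYYPTSPQQ) repeat motifs, and a conserved
42-residue C-terminal domain. Unusually large alleles — including those
found in *Aegilops* section *Sitopsis* (S-genome) species — arise by unequal
crossover, which inserts a tandem duplicate of a whole repeat block into the
repetitive domain.

`glutannot` is a toolkit for characterizing such genes from plain FASTA
input, plus a synthetic-data generator so the entire pipeline is testable
with known ground truth and no downloads:

- **Translation** with the HMW-GS conventions: tandem trailing stop codons
  consumed and counted, `N` codons → `X`, premature internal stops flagged
  as pseudogene-like.
- **Subunit anatomy**: signal-peptide removal at the EGEAS anchor, x/y
  typing from residue 6 of the mature N-terminus (G/E → x, R/K → y, with an
  N-terminal-length fallback), domain partitioning, per-domain cysteine
  census checked against the conserved patterns x = (3, 0, 1) and
  y = (5, 1, 1).
- **Repeat grammar**: an exact dynamic program tiles the repetitive domain
  with motif tokens, minimizing unassigned residues and then mismatches.
  The census obeys the length accounting `3a + 6b + 9c + unassigned = L`
  for `a` tripeptides, `b` hexapeptides and `c` nonapeptides.
- **Insertion finder**: affine-gap global alignment of a query subunit
  against a same-type reference; runs of ≥ 30 reference-gap columns become
  insertion blocks, each given a motif census and tested for tandem
  duplication against its equal-length flanking windows (percent identity
  and variant positions).
- **Promoter scan**: joint annotation of the six *Glu-1* regulatory elements
  (E motif `TGTAACCC`, N motif `TGAGTCAT`, partial HMW enhancer `TTTGCAAA`,
  the 38-bp complete enhancer, TATA box `CTATAAAAG`, start motif `TTATCA`)
  with per-element mismatch budgets, substitution lists and deletion calls.
- **Phylogeny**: p-distances with pairwise gap deletion, Saitou–Nei
  neighbor joining with seeded site-resampling bootstrap, and a Bandelt
  median-joining haplotype network — computed from the conserved region
  (promoter + signal-peptide CDS + N-terminal CDS).

## Worked example

Generate a synthetic x-type gene pair in which the query carries a planted
tandem duplication of 5 tripeptides + 15 hexapeptides + 4 nonapeptides
(5·3 + 15·6 + 4·9 = 141 residues), then annotate and compare:

```python
from glutannot import seq_io
from glutannot.synth import generate_insertion_pair

ref, query, truth = generate_insertion_pair(
    seed=1, subunit_type="x", n_tri=10, n_hexa=40, n_nona=20,
    composition=(5, 15, 4),
)
seq_io.write_fasta([query], "query.fa")
seq_io.write_fasta([ref], "ref.fa")
```

```sh
glutannot annotate query.fa --out annot.tsv
glutannot compare query.fa ref.fa --out blocks.tsv
```

`annot.tsv` contains (header comments omitted):

```
id             subunit_type  ...  signal_len  nterm_len  rep_len  cterm_len  mature_len  ...  cys_nterm  cys_rep  cys_cterm  cys_total  cys_conforms
syn_x_1_query  x                  21          86         591      42         719              3          0        1          4          True
```

i.e. the 21-residue signal peptide was stripped, the mature subunit
partitions into 86 + 591 + 42 = 719 residues, and the cysteine pattern is
the conserved x-type (3, 0, 1). `blocks.tsv` contains:

```
query_id       ref_id       start  end  length  n_tri  n_hexa  n_nona  unassigned  flank     identity_pct  n_variants
syn_x_1_query  syn_x_1_ref  378    518  141     5      15      4       0           upstream  100.0         0
```

one insertion block of exactly 141 residues at mature positions 378–518,
whose motif census matches the planted composition and which is a perfect
(100% identity) copy of the adjacent upstream window — the signature of a
tandem block duplication.

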