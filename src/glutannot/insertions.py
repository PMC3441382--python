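"""Detection of large duplicated blocks in HMW-GS repetitive domains.

The large S-genome glutenin subunits differ from their D-genome relatives by
insertions of whole repeat blocks (tens to hundreds of residues) that are
near-perfect copies of the adjacent repetitive-domain region -- the protein
signature of unequal crossover.  This module finds such blocks by global
pairwise alignment of a query subunit against a same-type reference: maximal
runs of reference-gap columns of at least ``min_block`` residues become
insertion blocks, each is given a repeat-motif census, and its tandem-
duplication origin is tested by comparing it with the equal-length windows
immediately upstream and downstream in the query.

Alignment is affine-gap global alignment (Needleman-Wunsch/Gotoh as provided
by Bio.Align.PairwiseAligner).  The default parameters (match +2, mismatch
-1, gap open -10, gap extend -0.2) are deliberately long-gap friendly so a
141-residue duplication aligns as one contiguous block rather than scattered
gaps.  A gap of length k costs gap_open + k * gap_extend.

Coordinates are reported in query space, 1-based inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .anatomy import MatureSubunit
from .repeats import DEFAULT_LEXICON, MotifCensus, MotifLexicon, motif_census, segment_repeats


class InsertionTypeError(ValueError):
    """Query and reference subunit types differ (or are unknown)."""


@dataclass(frozen=True)
class AlignParams:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.2


@dataclass
class AlignmentResult:
    aligned_query: str
    aligned_ref: str
    score: float
    params: AlignParams


@dataclass
class DuplicationEvidence:
    flank: str                      # "upstream" | "downstream"
    identity_pct: float             # 0-100
    variant_positions: list[int]    # 1-based within the block
    note: str = ""


@dataclass
class InsertionBlock:
    query_span: tuple[int, int]     # 1-based inclusive, query coordinates
    length: int
    sequence: str
    motif_census: MotifCensus
    duplication_evidence: DuplicationEvidence | None = None


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    # our convention: gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def global_align(query: str, ref: str, params: AlignParams | None = None) -> AlignmentResult:
    """Optimal affine-gap global alignment of two protein strings.

    Deterministic: among co-optimal alignments the aligner's first traceback
    is returned, which is stable for fixed inputs and parameters.
    """
    if not query or not ref:
        raise ValueError("global_align requires non-empty sequences")
    params = params or AlignParams()
    aln = _aligner(params).align(query, ref)
    best = aln[0]
    aq, ar = str(best[0]), str(best[1])
    assert aq.replace("-", "") == query and ar.replace("-", "") == ref
    return AlignmentResult(aq, ar, float(best.score), params)


def gap_runs(
    result: AlignmentResult, row: str = "ref", normalize: bool = True
) -> list[tuple[int, int, str]]:
    """Maximal gap runs in one alignment row.

    For ``row="ref"`` returns (start, end, inserted_seq) with coordinates in
    the query (sequence present in those columns); for ``row="query"`` the
    coordinates are in the reference.  1-based inclusive.

    Inside a tandem repeat the placement of an indel is ambiguous (excising
    either copy of a perfect duplication yields the same sequence), so with
    ``normalize`` each run is shifted to its 3'-most equivalent position.
    This makes a detected tandem-duplication block the downstream copy, with
    the donor window immediately upstream.
    """
    gapped, other = (
        (result.aligned_ref, result.aligned_query)
        if row == "ref"
        else (result.aligned_query, result.aligned_ref)
    )
    runs = []
    pos = 0          # 1-based position in `other` of the last consumed residue
    run_start = None
    run_seq = []
    for g, o in zip(gapped, other):
        if o != "-":
            pos += 1
        if g == "-" and o != "-":
            if run_start is None:
                run_start = pos
                run_seq = []
            run_seq.append(o)
        else:
            if run_start is not None:
                runs.append((run_start, pos - 1 if o != "-" else pos, "".join(run_seq)))
                run_start = None
    if run_start is not None:
        runs.append((run_start, pos, "".join(run_seq)))
    if normalize:
        seq = other.replace("-", "")
        shifted = []
        for start, end, _ in runs:
            # excising [start, end] and [start+1, end+1] is equivalent iff
            # seq[start] == seq[end+1] (1-based)
            while end + 1 <= len(seq) and seq[start - 1] == seq[end]:
                start += 1
                end += 1
            shifted.append((start, end, seq[start - 1 : end]))
        runs = shifted
    return runs


def detect_insertions(
    query: MatureSubunit,
    ref: MatureSubunit,
    min_block: int = 30,
    params: AlignParams | None = None,
    lexicon: MotifLexicon = DEFAULT_LEXICON,
    verify: bool = True,
) -> list[InsertionBlock]:
    """Find insertion blocks of at least ``min_block`` residues in query vs ref.

    Both subunits must be of the same (known) type.  Each block receives a
    motif census and, when ``verify``, tandem-duplication evidence from its
    flanking windows.
    """
    if query.subunit_type != ref.subunit_type or query.subunit_type == "unknown":
        raise InsertionTypeError(
            f"subunit types differ or unknown: query {query.subunit_type!r}, "
            f"ref {ref.subunit_type!r}"
        )
    aln = global_align(query.residues, ref.residues, params)
    blocks = []
    for start, end, seq in gap_runs(aln, row="ref"):
        length = end - start + 1
        if length < min_block:
            continue
        block = InsertionBlock(
            query_span=(start, end),
            length=length,
            sequence=seq,
            motif_census=motif_census(segment_repeats(seq, lexicon)),
        )
        if verify:
            block.duplication_evidence = verify_tandem_duplication(query, block, params)
        blocks.append(block)
    return blocks


def _flank_evidence(block_seq: str, window: str, params: AlignParams | None) -> tuple[float, list[int]]:
    aln = global_align(block_seq, window, params)
    ncols = len(aln.aligned_query)
    matches = 0
    variants = []
    qpos = 0
    for q, r in zip(aln.aligned_query, aln.aligned_ref):
        if q != "-":
            qpos += 1
        if q == r and q != "-":
            matches += 1
        else:
            variants.append(qpos if qpos >= 1 else 1)
    return 100.0 * matches / ncols, variants


def verify_tandem_duplication(
    query: MatureSubunit,
    block: InsertionBlock,
    params: AlignParams | None = None,
) -> DuplicationEvidence:
    """Compare a block with its equal-length adjacent windows in the query.

    The window with the higher percent identity is reported as the donor
    flank, with variant positions (1-based within the block).  A block
    touching the sequence edge is compared on its single available flank.
    """
    start, end = block.query_span
    L = block.length
    res = query.residues
    candidates: list[tuple[str, float, list[int]]] = []
    note = ""
    if start - L >= 1:
        win = res[start - 1 - L : start - 1]
        ident, var = _flank_evidence(block.sequence, win, params)
        candidates.append(("upstream", ident, var))
    if end + L <= len(res):
        win = res[end : end + L]
        ident, var = _flank_evidence(block.sequence, win, params)
        candidates.append(("downstream", ident, var))
    if not candidates:
        return DuplicationEvidence("upstream", 0.0, [], note="no full flanking window available")
    if len(candidates) == 1:
        note = "single flank compared (block touches sequence edge)"
    flank, ident, var = max(candidates, key=lambda c: c[1])
    return DuplicationEvidence(flank, ident, var, note=note)
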