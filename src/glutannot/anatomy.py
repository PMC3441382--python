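"""Subunit anatomy: signal peptide, x/y typing, domain partition, cysteines.

A mature HMW glutenin subunit begins with the conserved pentapeptide EGEAS.
Residue 6 of the mature N-terminus distinguishes the two subfamilies: G or E
for x-type subunits, R or K for y-type.  Where residue 6 is uninformative
(e.g. an X from an ambiguous codon), typing falls back on the N-terminal
domain length, which is ~81-89 residues in x-type and ~104 in y-type
subunits.

The mature subunit partitions into three contiguous domains: the conserved
N-terminal domain, the central repetitive domain, and a 42-residue conserved
C-terminal domain.  The C-terminal domain is fixed at the final 42 residues;
the repetitive domain starts at the first position from which at least three
consecutive repeat motifs (per the lexicon) can be chained, which makes the
boundary robust to single spurious motif-like words inside the N-terminal
domain.

Cysteine counts per domain are censused and checked against the conserved
patterns: x-type (3, 0, 1), y-type (5, 1, 1), with the known x-type variant
(3, 1, 1) carrying an extra repetitive-domain cysteine (as in subunit 1Dx5)
accepted as conforming.

All residue numbering is 1-based.
"""
from __future__ import annotations

from dataclasses import dataclass

from .repeats import CLASS_LENGTH, DEFAULT_LEXICON, MotifLexicon, hamming
from .seq_io import ProteinSeq

MATURE_ANCHOR = "EGEAS"
ANCHOR_SEARCH_LIMIT = 40       # anchor must start within the first 40 residues
C_TERMINAL_LENGTH = 42
X_TYPE_RESIDUE6 = frozenset("GE")
Y_TYPE_RESIDUE6 = frozenset("RK")
# N-terminal domain length ranges used by the fallback typing rule
X_NTERM_RANGE = (75, 95)
Y_NTERM_RANGE = (96, 112)

CONFORMING_CYSTEINES = {
    "x": {(3, 0, 1), (3, 1, 1)},   # (3,1,1): 1Dx5-like extra repetitive cysteine
    "y": {(5, 1, 1)},
}


@dataclass
class MatureSubunit:
    id: str
    residues: str
    signal_peptide: str
    subunit_type: str = "unknown"   # "x" | "y" | "unknown"
    status: str = "ok"
    message: str = ""


@dataclass
class DomainPartition:
    """1-based inclusive spans tiling the mature sequence; empty spans are None."""

    n_terminal: tuple[int, int] | None
    repetitive: tuple[int, int] | None
    c_terminal: tuple[int, int]
    status: str = "ok"
    message: str = ""

    @staticmethod
    def span_length(span: tuple[int, int] | None) -> int:
        return 0 if span is None else span[1] - span[0] + 1


@dataclass
class CysteineCensus:
    n_cys_nterm: int
    n_cys_rep: int
    n_cys_cterm: int
    n_cys_total: int
    conforms: bool


def strip_signal_peptide(protein: ProteinSeq) -> MatureSubunit:
    """Split a full translation at the leftmost EGEAS mature-start anchor.

    The anchor must begin within the first 40 residues; if it is absent the
    whole sequence is kept, the signal peptide is empty and the subunit is
    flagged (type unknown, warning status).
    """
    idx = protein.residues.find(MATURE_ANCHOR)
    if idx < 0 or idx >= ANCHOR_SEARCH_LIMIT:
        return MatureSubunit(
            id=protein.id,
            residues=protein.residues,
            signal_peptide="",
            subunit_type="unknown",
            status="warning",
            message=f"{protein.id}: mature-start anchor {MATURE_ANCHOR} not found "
            f"within the first {ANCHOR_SEARCH_LIMIT} residues",
        )
    mature = MatureSubunit(
        id=protein.id,
        residues=protein.residues[idx:],
        signal_peptide=protein.residues[:idx],
    )
    mature.subunit_type = classify_subunit_type(mature)
    return mature


def classify_subunit_type(mature: MatureSubunit, nterm_len: int | None = None) -> str:
    """Type a mature subunit from residue 6, else from N-terminal domain length."""
    if len(mature.residues) < 12:
        return "unknown"
    r6 = mature.residues[5]
    if r6 in X_TYPE_RESIDUE6:
        return "x"
    if r6 in Y_TYPE_RESIDUE6:
        return "y"
    if nterm_len is not None:
        if X_NTERM_RANGE[0] <= nterm_len <= X_NTERM_RANGE[1]:
            return "x"
        if Y_NTERM_RANGE[0] <= nterm_len <= Y_NTERM_RANGE[1]:
            return "y"
    return "unknown"


def _consecutive_motif_run(
    residues: str, start: int, stop: int, lexicon: MotifLexicon, needed: int
) -> int:
    """Greedy count of consecutive lexicon motifs from ``start`` (0-based),
    not crossing ``stop``; longer motifs tried first.  Stops early at ``needed``."""
    by_length = sorted(lexicon, key=lambda e: -len(e.consensus))
    j = start
    count = 0
    while count < needed:
        matched = None
        for e in by_length:
            L = len(e.consensus)
            if j + L <= stop and hamming(residues[j : j + L], e.consensus) <= e.max_mismatch:
                matched = L
                break
        if matched is None:
            break
        j += matched
        count += 1
    return count


def partition_domains(
    mature: MatureSubunit,
    lexicon: MotifLexicon = DEFAULT_LEXICON,
    min_consecutive: int = 3,
) -> DomainPartition:
    """Partition the mature subunit into N-terminal / repetitive / C-terminal.

    The C-terminal domain is the final 42 residues.  The repetitive domain is
    the maximal region starting at the first position from which at least
    ``min_consecutive`` lexicon motifs chain, ending at length - 42.  If no
    such onset exists, the whole body is reported as N-terminal with a
    warning.
    """
    L = len(mature.residues)
    if L <= C_TERMINAL_LENGTH:
        raise ValueError(
            f"{mature.id}: mature sequence ({L} aa) not longer than the "
            f"{C_TERMINAL_LENGTH}-residue C-terminal domain"
        )
    cterm = (L - C_TERMINAL_LENGTH + 1, L)
    body_stop = L - C_TERMINAL_LENGTH      # 0-based exclusive end of the body
    onset = None
    min_motif = min(CLASS_LENGTH[e.motif_class] for e in lexicon) if lexicon else 0
    for i in range(0, body_stop - min_motif + 1 if lexicon else 0):
        if _consecutive_motif_run(mature.residues, i, body_stop, lexicon, min_consecutive) >= min_consecutive:
            onset = i
            break
    if onset is None:
        return DomainPartition(
            n_terminal=(1, body_stop) if body_stop >= 1 else None,
            repetitive=None,
            c_terminal=cterm,
            status="warning",
            message=f"{mature.id}: no repeat onset found; repetitive domain empty",
        )
    return DomainPartition(
        n_terminal=(1, onset) if onset >= 1 else None,
        repetitive=(onset + 1, body_stop),
        c_terminal=cterm,
    )


def domain_sequences(mature: MatureSubunit, part: DomainPartition) -> dict[str, str]:
    """Extract the three domain strings from a partition."""
    res = mature.residues

    def cut(span):
        return "" if span is None else res[span[0] - 1 : span[1]]

    return {
        "n_terminal": cut(part.n_terminal),
        "repetitive": cut(part.repetitive),
        "c_terminal": cut(part.c_terminal),
    }


def cysteine_census(mature: MatureSubunit, part: DomainPartition) -> CysteineCensus:
    doms = domain_sequences(mature, part)
    n_n = doms["n_terminal"].count("C")
    n_r = doms["repetitive"].count("C")
    n_c = doms["c_terminal"].count("C")
    pattern = (n_n, n_r, n_c)
    conforms = pattern in CONFORMING_CYSTEINES.get(mature.subunit_type, set())
    return CysteineCensus(n_n, n_r, n_c, n_n + n_r + n_c, conforms)
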