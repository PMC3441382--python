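"""Repeat-motif grammar for the central repetitive domain of HMW-GS proteins.

The repetitive domain of a high molecular weight glutenin subunit is a
low-complexity region built almost entirely from three classes of short
tandem repeat motifs: tripeptides, hexapeptides and nonapeptides.  This
module decomposes a repetitive-domain protein string into an ordered series
of motif tokens (with per-token mismatch counts against the class consensus)
plus unassigned runs, and turns a segmentation into the motif census used
throughout the package: counts per class and the closed-form length
accounting 3a + 6b + 9c residues.

The default lexicon uses the canonical HMW-GS consensus motifs: GQQ
(tripeptide), PGQGQQ (hexapeptide) and GYYPTSPQQ / GYYPTSLQQ (nonapeptide).
It can be replaced by a small whitespace-delimited config file, one motif per
line: ``class consensus max_mismatch``.

Segmentation is an exact dynamic program that minimizes, lexicographically,
(1) the number of unassigned residues and (2) the total mismatch count, and
breaks remaining ties deterministically by preferring longer motifs earlier
in the string.  Mismatches are Hamming substitutions only; indels are left to
the unassigned spans.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

CLASS_LENGTH = {"tri": 3, "hexa": 6, "nona": 9}

CANONICAL_MOTIFS = {"tri": "GQQ", "hexa": "PGQGQQ", "nona": "GYYPTSPQQ"}


@dataclass(frozen=True)
class MotifEntry:
    motif_class: str
    consensus: str
    max_mismatch: int

    def __post_init__(self):
        if self.motif_class not in CLASS_LENGTH:
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        if len(self.consensus) != CLASS_LENGTH[self.motif_class]:
            raise ValueError(
                f"{self.motif_class} consensus must have length "
                f"{CLASS_LENGTH[self.motif_class]}, got {self.consensus!r}"
            )
        if not 0 <= self.max_mismatch < len(self.consensus):
            raise ValueError("max_mismatch must be in [0, motif length)")


MotifLexicon = Sequence[MotifEntry]

DEFAULT_LEXICON: tuple[MotifEntry, ...] = (
    MotifEntry("tri", "GQQ", 1),
    MotifEntry("hexa", "PGQGQQ", 2),
    MotifEntry("nona", "GYYPTSPQQ", 2),
    MotifEntry("nona", "GYYPTSLQQ", 2),
)


@dataclass
class Token:
    start: int           # 1-based position in the domain
    motif_class: str
    observed: str
    mismatches: int


@dataclass
class RepeatSegmentation:
    domain: str
    tokens: list[Token]
    unassigned: list[tuple[int, int]]   # 1-based inclusive spans


@dataclass
class MotifCensus:
    n_tri: int
    n_hexa: int
    n_nona: int
    n_unassigned_residues: int
    total_residues: int


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def load_lexicon(path: str | Path) -> list[MotifEntry]:
    """Read a lexicon config file: ``class consensus max_mismatch`` per line."""
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cls, cons, mm = line.split()
        entries.append(MotifEntry(cls, cons.upper(), int(mm)))
    if not entries:
        raise ValueError(f"{path}: empty lexicon")
    return entries


def dump_lexicon(lexicon: MotifLexicon, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# motif_class consensus max_mismatch\n")
        for e in lexicon:
            fh.write(f"{e.motif_class} {e.consensus} {e.max_mismatch}\n")


def segment_repeats(domain: str, lexicon: MotifLexicon = DEFAULT_LEXICON) -> RepeatSegmentation:
    """Tile ``domain`` with motif tokens; exact DP, deterministic tie-breaking.

    Objective (lexicographic minimum): unassigned residues, then total
    mismatches.  Reconstruction walks left to right taking, at each position
    among the optimal choices, a motif over a skip and a longer motif over a
    shorter one.
    """
    n = len(domain)
    # order used for tie-breaking during reconstruction: longer motifs first,
    # then original lexicon order (stable)
    recon_order = sorted(
        range(len(lexicon)), key=lambda i: (-len(lexicon[i].consensus), i)
    )
    INF = (n + 1, 0)
    best: list[tuple[int, int]] = [(0, 0)] * (n + 1)
    for i in range(n - 1, -1, -1):
        b = (best[i + 1][0] + 1, best[i + 1][1])
        for e in lexicon:
            L = len(e.consensus)
            if i + L <= n:
                hd = hamming(domain[i : i + L], e.consensus)
                if hd <= e.max_mismatch:
                    cand = (best[i + L][0], best[i + L][1] + hd)
                    if cand < b:
                        b = cand
        best[i] = b

    tokens: list[Token] = []
    unassigned: list[tuple[int, int]] = []
    i = 0
    while i < n:
        chosen = None
        for idx in recon_order:
            e = lexicon[idx]
            L = len(e.consensus)
            if i + L <= n:
                hd = hamming(domain[i : i + L], e.consensus)
                if hd <= e.max_mismatch and (best[i + L][0], best[i + L][1] + hd) == best[i]:
                    chosen = (e, L, hd)
                    break
        if chosen is not None:
            e, L, hd = chosen
            tokens.append(Token(i + 1, e.motif_class, domain[i : i + L], hd))
            i += L
        else:
            # residue i is unassigned in every optimal parse
            if unassigned and unassigned[-1][1] == i:
                unassigned[-1] = (unassigned[-1][0], i + 1)
            else:
                unassigned.append((i + 1, i + 1))
            i += 1
    return RepeatSegmentation(domain, tokens, unassigned)


def motif_census(seg: RepeatSegmentation) -> MotifCensus:
    counts = {"tri": 0, "hexa": 0, "nona": 0}
    for t in seg.tokens:
        counts[t.motif_class] += 1
    n_un = sum(end - start + 1 for start, end in seg.unassigned)
    census = MotifCensus(
        counts["tri"], counts["hexa"], counts["nona"], n_un, len(seg.domain)
    )
    assert (
        3 * census.n_tri + 6 * census.n_hexa + 9 * census.n_nona + n_un
        == census.total_residues
    ), "length accounting identity violated"
    return census


def census_length(n_tri: int, n_hexa: int, n_nona: int) -> int:
    """Residue length of a block with the given motif composition (3a+6b+9c)."""
    for v in (n_tri, n_hexa, n_nona):
        if v < 0:
            raise ValueError("motif counts must be non-negative")
    return 3 * n_tri + 6 * n_hexa + 9 * n_nona


def build_fragment(
    n_tri: int,
    n_hexa: int,
    n_nona: int,
    order: Sequence[str] | None = None,
    rng=None,
) -> str:
    """Concatenate canonical motifs into a fragment of the given composition.

    ``order`` fixes the token class order explicitly; otherwise tokens are
    interleaved round-robin, or shuffled when ``rng`` (a numpy Generator) is
    given.  Used by the synthetic generator and for re-enacting printed motif
    compositions.
    """
    classes = fragment_token_order(n_tri, n_hexa, n_nona, order=order, rng=rng)
    return "".join(CANONICAL_MOTIFS[c] for c in classes)


def fragment_token_order(
    n_tri: int,
    n_hexa: int,
    n_nona: int,
    order: Sequence[str] | None = None,
    rng=None,
) -> list[str]:
    """Token class order used by :func:`build_fragment` (exposed for ground truth)."""
    classes = ["tri"] * n_tri + ["hexa"] * n_hexa + ["nona"] * n_nona
    if order is not None:
        if sorted(order) != sorted(classes):
            raise ValueError("explicit order does not match the composition")
        return list(order)
    if rng is not None:
        return [classes[i] for i in rng.permutation(len(classes))]
    # deterministic round-robin interleave
    pools = {
        "tri": ["tri"] * n_tri,
        "hexa": ["hexa"] * n_hexa,
        "nona": ["nona"] * n_nona,
    }
    out: list[str] = []
    while any(pools.values()):
        for cls in ("tri", "hexa", "nona"):
            if pools[cls]:
                out.append(pools[cls].pop())
    return out
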