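"""Cis-regulatory element annotation of HMW-GS 5'-flanking promoters.

Glu-1 promoters carry six conserved regulatory elements, in 5'->3' order:
the E motif (TGTAACCC), the N motif (TGAGTCAT), the partial HMW enhancer
(TTTGCAAA), the complete 38-bp HMW enhancer, the TATA box (CTATAAAAG) and
the transcription start motif (TTATCA).  A promoter is annotated by locating
each element's best-matching window, reporting the observed sequence and its
substitutions against the consensus, or a ``deleted`` status when no window
within the element's mismatch budget exists.

Assignment is done jointly over all six elements rather than greedily one at
a time: elements must occur in their canonical order without overlap, and
among all consistent assignments the annotation minimizes, in order, the
number of deleted elements, the total unmatched element length, the total
substitution count, the number of gapped hits, and finally prefers leftmost
placements.  The joint criterion matters because the partial enhancer is an
exact substring of the complete enhancer: a greedy scan would claim the
enhancer's internal copy for the partial element whenever the true partial
copy has been deleted (as in promoters carrying the 85-bp deletion), and
thereby mis-report the enhancer itself as lost.

Single-base deletions inside an element (seen in some enhancer alleles) are
handled by also scoring windows of length L-1 with one free gap; such hits
are reported as found with a deletion flag, not as element loss.

Scanning is on the given strand only; promoters are supplied in gene
orientation.  Offsets are 1-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

from .repeats import hamming

ELEMENT_ORDER = (
    "E_motif",
    "N_motif",
    "partial_enhancer",
    "enhancer",
    "TATA_box",
    "start_motif",
)


@dataclass(frozen=True)
class ElementDefinition:
    name: str
    consensus: str
    max_mismatch: int


# mismatch budgets: up to 2 substitutions are observed in the short (6-9 bp)
# elements and up to 3 (incl. one deletion) in the 38-bp enhancer among known
# alleles; stricter caps would misclassify real promoters as deleted.
DEFAULT_ELEMENTS: tuple[ElementDefinition, ...] = (
    ElementDefinition("E_motif", "TGTAACCC", 2),
    ElementDefinition("N_motif", "TGAGTCAT", 2),
    ElementDefinition("partial_enhancer", "TTTGCAAA", 2),
    ElementDefinition(
        "enhancer", "GTTTTGCAAAGCTCCAATTGCTCCTTGCTTATCCAGCT", 3
    ),
    ElementDefinition("TATA_box", "CTATAAAAG", 2),
    ElementDefinition("start_motif", "TTATCA", 1),
)


@dataclass
class ElementHit:
    name: str
    status: str                                  # "found" | "deleted"
    offset: int | None = None                    # 1-based start in the promoter
    observed: str = ""
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    has_gap: bool = False                        # hit contains a 1-bp deletion


@dataclass
class PromoterAnnotation:
    promoter_id: str
    hits: list[ElementHit]

    @property
    def by_name(self) -> dict[str, ElementHit]:
        return {h.name: h for h in self.hits}


def load_elements(path: str | Path) -> list[ElementDefinition]:
    """Element config file: ``name consensus max_mismatch`` per line."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, cons, mm = line.split()
        out.append(ElementDefinition(name, cons.upper(), int(mm)))
    if not out:
        raise ValueError(f"{path}: empty element config")
    return out


def compare_to_consensus(observed: str, consensus: str) -> list[tuple[int, str, str]]:
    """Substituted positions (1-based) between equal-length strings.

    Returns (position, consensus base, observed base) tuples.
    """
    if len(observed) != len(consensus):
        raise ValueError(
            f"length mismatch: observed {len(observed)} vs consensus {len(consensus)}"
        )
    return [
        (i + 1, c, o) for i, (c, o) in enumerate(zip(consensus, observed)) if c != o
    ]


def _candidates(promoter: str, element: ElementDefinition) -> list[tuple[int, int, int, int]]:
    """All qualifying windows for one element.

    Each candidate is (start0, window_length, mismatches, gap_flag); gapped
    candidates score the window of length L-1 against the consensus with one
    base deleted (best deletion position).
    """
    cons = element.consensus
    L = len(cons)
    cands = []
    for s in range(0, len(promoter) - L + 1):
        hd = hamming(promoter[s : s + L], cons)
        if hd <= element.max_mismatch:
            cands.append((s, L, hd, 0))
    # single-base-deletion windows: only meaningful for long elements (the
    # 38-bp enhancer); on 6-9 bp elements a gapped match carries no signal.
    # The gap counts as one edit against the mismatch budget.
    if L >= 20:
        reduced = [cons[:j] + cons[j + 1 :] for j in range(L)]
        for s in range(0, len(promoter) - (L - 1) + 1):
            w = promoter[s : s + L - 1]
            hd = min(hamming(w, r) for r in reduced)
            if hd + 1 <= element.max_mismatch:
                cands.append((s, L - 1, hd, 1))
    return cands


def scan_elements(
    promoter: str,
    elements: tuple[ElementDefinition, ...] = DEFAULT_ELEMENTS,
    promoter_id: str = "",
) -> PromoterAnnotation:
    """Annotate a promoter against the element set (joint optimal assignment)."""
    promoter = promoter.upper()
    if elements and len(promoter) < max(len(e.consensus) for e in elements):
        raise ValueError("promoter shorter than the longest element")
    per_element = [sorted(_candidates(promoter, e)) for e in elements]

    # DP over elements in order; state = minimum allowed start position.
    # Cost vector (lexicographic): (n_deleted, unmatched_length, mismatches,
    # gaps, offsets tuple) -- offsets last so placements are leftmost.
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def solve(idx: int, cursor: int):
        if idx == len(elements):
            return (0, 0, 0, 0, ()), ()
        el = elements[idx]
        # option: element deleted
        best_cost, best_choice = None, None
        sub_cost, sub_choice = solve(idx + 1, cursor)
        cost = (
            sub_cost[0] + 1,
            sub_cost[1] + len(el.consensus),
            sub_cost[2],
            sub_cost[3],
            sub_cost[4],
        )
        best_cost, best_choice = cost, (None,) + sub_choice
        for s, wlen, hd, gap in per_element[idx]:
            if s < cursor:
                continue
            sub_cost, sub_choice = solve(idx + 1, s + wlen)
            cost = (
                sub_cost[0],
                sub_cost[1],
                sub_cost[2] + hd,
                sub_cost[3] + gap,
                (s,) + sub_cost[4],
            )
            if cost < best_cost:
                best_cost, best_choice = cost, ((s, wlen, hd, gap),) + sub_choice
        return best_cost, best_choice

    _, choices = solve(0, 0)
    solve.cache_clear()

    hits = []
    for el, choice in zip(elements, choices):
        if choice is None:
            hits.append(ElementHit(el.name, "deleted"))
            continue
        s, wlen, hd, gap = choice
        observed = promoter[s : s + wlen]
        if gap:
            # report substitutions against the best single-deletion consensus
            reduced = min(
                (el.consensus[:j] + el.consensus[j + 1 :] for j in range(len(el.consensus))),
                key=lambda r: hamming(observed, r),
            )
            subs = compare_to_consensus(observed, reduced)
        else:
            subs = compare_to_consensus(observed, el.consensus)
        hits.append(
            ElementHit(el.name, "found", offset=s + 1, observed=observed,
                       substitutions=subs, has_gap=bool(gap))
        )
    return PromoterAnnotation(promoter_id, hits)
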