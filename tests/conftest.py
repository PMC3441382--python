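"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from glutannot.repeats import DEFAULT_LEXICON


@pytest.fixture
def lexicon():
    return DEFAULT_LEXICON


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def write_fasta_text(path, entries):
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")
    return path


def brute_tiling_cost(domain: str, lexicon) -> tuple[int, int]:
    """Exhaustive enumeration of every motif tiling of ``domain``.

    Returns the lexicographically minimal (unassigned residues, total
    mismatches) over all complete parses.  Plain depth-first enumeration,
    independent of the package's dynamic program.
    """
    n = len(domain)
    best = [(n + 1, 0)]

    def go(i: int, unassigned: int, mism: int):
        if i == n:
            cand = (unassigned, mism)
            if cand < best[0]:
                best[0] = cand
            return
        # prune: cannot improve on current best
        if (unassigned, mism) > best[0]:
            return
        go(i + 1, unassigned + 1, mism)
        for e in lexicon:
            L = len(e.consensus)
            if i + L <= n:
                hd = sum(a != b for a, b in zip(domain[i : i + L], e.consensus))
                if hd <= e.max_mismatch:
                    go(i + L, unassigned, mism + hd)

    go(0, 0, 0)
    return best[0]
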