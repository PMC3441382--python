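"""Synthetic HMW-GS genes, promoters and sequence families with known truth.

Every downstream stage of the pipeline is testable without downloads because
this module emits sequences whose ground truth is fully recorded: a subunit
generator that assembles signal peptide + conserved N-terminal + motif-built
repetitive domain + 42-residue C-terminal architecture (with the conserved
x-type (3,0,1) or y-type (5,1,1) cysteine placement) and reverse-translates
it with seeded synonymous-codon choice; a promoter generator that embeds the
six regulatory elements in random background at recorded offsets, with
planted substitutions or deletions; and a family generator that evolves a
root sequence along a known tree with stated per-branch mutation counts.

What the generator deliberately controls, so planted truth is recoverable in
principle rather than by luck:

* The N-terminal and C-terminal filler alphabets contain no G or Q, so no
  repeat-motif word can match there and the repetitive-domain onset is
  unambiguous.
* Promoter background spacers are rejection-sampled to contain no window
  within any element's mismatch budget, so a planted deletion is a real
  absence, not a coin flip against ~0.4%-per-window false positives.
* ``sub_rate`` substitutions are applied at the DNA level but spare the
  signal peptide, the 12-codon N-terminal consensus, and the trailing stops,
  and are redrawn if they would create an in-frame stop.

Everything is deterministic given the seed.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import cycle, islice

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .promoter import DEFAULT_ELEMENTS, ElementDefinition
from .repeats import CANONICAL_MOTIFS, build_fragment, fragment_token_order
from .seq_io import GeneRecord

SIGNAL_PEPTIDE = "MAKRLVLFAAVVVALVALTAA"          # 21 aa, no C/G/Q
TRAILING_STOPS = "TGATAG"                          # tandem stop codons
X_NTERM_LEN = 86
Y_NTERM_LEN = 104
X_NTERM_PREFIX = "EGEASGQLQCER"
Y_NTERM_PREFIX = "EGEASRQLQCER"
C_TERMINAL_LEN = 42
# filler alphabet free of G and Q so no repeat motif can match outside the
# repetitive domain, and free of C so cysteine placement stays exact
_FILLER = "ELKARDVSTHFINPWYM"
_MUTATION_AA = "ARNDEFHIKLMPSTVWY"                 # no C/G/Q

_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for aa in _AA_TO_CODONS:
    _AA_TO_CODONS[aa].sort()

DNA = "ACGT"
STOPS = frozenset(standard_dna_table.stop_codons)


@dataclass
class InsertionSpec:
    """A planted tandem duplication: ``composition`` = (n_tri, n_hexa, n_nona)
    of the duplicated block; ``n_substitutions`` single-residue changes are
    applied to the inserted copy (one per affected motif token)."""

    composition: tuple[int, int, int]
    n_substitutions: int = 0


@dataclass
class SyntheticTruth:
    seed: int
    architecture: dict = field(default_factory=dict)
    planted_insertion: dict | None = None
    promoter_truth: dict | None = None
    family_truth: dict | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _filler(n: int, cys_at: tuple[int, ...] = ()) -> str:
    """Deterministic filler of length n over the motif-free alphabet, with
    cysteines planted at the given 0-based offsets."""
    s = list(islice(cycle(_FILLER), n))
    for i in cys_at:
        s[i] = "C"
    return "".join(s)


def _nterm(subunit_type: str) -> str:
    if subunit_type == "x":
        # prefix already carries 1 C; plant 2 more -> (3,·,·)
        return X_NTERM_PREFIX + _filler(X_NTERM_LEN - len(X_NTERM_PREFIX), cys_at=(20, 45))
    # y-type: 4 more C for a total of 5
    return Y_NTERM_PREFIX + _filler(Y_NTERM_LEN - len(Y_NTERM_PREFIX), cys_at=(15, 35, 55, 75))


def _cterm() -> str:
    return _filler(C_TERMINAL_LEN, cys_at=(8,))


def _plant_repetitive_cysteine(tokens: list[str]) -> tuple[list[str], int]:
    """Replace one residue of the first hexapeptide token with C (y-type
    repetitive-domain cysteine); returns token strings and the token index."""
    strings = [CANONICAL_MOTIFS[c] for c in tokens]
    for i, cls in enumerate(tokens):
        if cls == "hexa":
            strings[i] = "PGCGQQ"          # 1 mismatch vs PGQGQQ, within budget
            return strings, i
    raise ValueError("y-type subunit needs at least one hexapeptide for its repetitive cysteine")


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))] for aa in protein
    )


def _apply_dna_substitutions(
    dna: str, rate: float, rng: np.random.Generator, protected_prefix: int
) -> str:
    """Seeded substitutions at ``rate`` per base, sparing a 5' prefix and the
    trailing stops, redrawn where they would create an in-frame stop."""
    if rate == 0:
        return dna
    seq = list(dna)
    n_mutable_end = len(dna) - len(TRAILING_STOPS)
    for i in range(protected_prefix, n_mutable_end):
        if rng.random() >= rate:
            continue
        orig = seq[i]
        choices = [b for b in DNA if b != orig]
        order = rng.permutation(3)
        for k in order:
            seq[i] = choices[k]
            codon_start = (i // 3) * 3
            if "".join(seq[codon_start : codon_start + 3]) not in STOPS:
                break
            seq[i] = orig
    return "".join(seq)


def generate_subunit(
    seed: int,
    subunit_type: str = "x",
    n_tri: int = 10,
    n_hexa: int = 60,
    n_nona: int = 30,
    insertion_spec: InsertionSpec | None = None,
    sub_rate: float = 0.0,
    record_id: str | None = None,
    with_promoter: bool = False,
) -> tuple[GeneRecord, SyntheticTruth]:
    """Generate one synthetic HMW-GS gene with recorded architecture.

    ``(n_tri, n_hexa, n_nona)`` is the motif composition of the base
    repetitive domain (defaults sized like real x-type domains).  With
    ``insertion_spec`` the emitted gene additionally carries a tandem
    duplication: a block of the stated composition is placed mid-domain and
    immediately followed by a copy of itself with ``n_substitutions``
    single-residue variants; the copy's span is recorded as the planted
    insertion.  Use the same seed without ``insertion_spec`` via
    :func:`generate_insertion_pair` to obtain the matching reference gene.
    """
    if subunit_type not in ("x", "y"):
        raise ValueError("subunit_type must be 'x' or 'y'")
    if not 0 <= sub_rate <= 0.1:
        raise ValueError("sub_rate must be in [0, 0.1]")
    rng = np.random.default_rng([seed, 0xA11E1E])
    record_id = record_id or f"syn_{subunit_type}_{seed}"

    if insertion_spec is None:
        tokens = fragment_token_order(n_tri, n_hexa, n_nona, rng=rng)
        pre_tokens, dup_tokens, post_tokens = tokens, [], []
    else:
        ct, ch, cn = insertion_spec.composition
        if ct > n_tri or ch > n_hexa or cn > n_nona:
            raise ValueError("insertion composition exceeds the domain composition")
        dup_tokens = fragment_token_order(ct, ch, cn, rng=rng)
        rest = fragment_token_order(n_tri - ct, n_hexa - ch, n_nona - cn, rng=rng)
        half = len(rest) // 2
        pre_tokens, post_tokens = rest[:half], rest[half:]
        # the residue right after the duplicated copy must differ from the
        # copy's first residue, otherwise the copy's 3' boundary is not
        # identifiable (an indel can slide across equal residues)
        first = CANONICAL_MOTIFS[dup_tokens[0]][0]
        if post_tokens and CANONICAL_MOTIFS[post_tokens[0]][0] == first:
            for i, c in enumerate(post_tokens):
                if CANONICAL_MOTIFS[c][0] != first:
                    post_tokens.insert(0, post_tokens.pop(i))
                    break
            else:
                for i, c in enumerate(pre_tokens):
                    if CANONICAL_MOTIFS[c][0] != first:
                        post_tokens.insert(0, pre_tokens.pop(i))
                        break
        tokens = pre_tokens + dup_tokens + post_tokens

    token_strings = [CANONICAL_MOTIFS[c] for c in tokens]
    cys_token = None
    if subunit_type == "y":
        if insertion_spec is None:
            token_strings, cys_token = _plant_repetitive_cysteine(tokens)
        else:
            # keep the repetitive cysteine outside the duplicated region so
            # the copy does not silently duplicate it
            n_pre_, n_dup_ = len(pre_tokens), len(dup_tokens)
            outside = [
                i for i, c in enumerate(tokens)
                if c == "hexa" and not (n_pre_ <= i < n_pre_ + n_dup_)
            ]
            if not outside:
                raise ValueError(
                    "y-type subunit needs a hexapeptide outside the duplicated "
                    "region for its repetitive cysteine"
                )
            cys_token = outside[0]
            token_strings[cys_token] = "PGCGQQ"

    nterm = _nterm(subunit_type)
    cterm = _cterm()
    planted_insertion = None

    if insertion_spec is None:
        rep_domain = "".join(token_strings)
    else:
        n_pre = len(pre_tokens)
        n_dup = len(dup_tokens)
        donor_strings = token_strings[n_pre : n_pre + n_dup]
        copy_strings = list(donor_strings)
        n_sub = insertion_spec.n_substitutions
        if n_sub > n_dup:
            raise ValueError("more substitutions than duplicated motif tokens")
        sub_positions = []
        if n_sub:
            which = rng.choice(n_dup, size=n_sub, replace=False)
            offset = 0
            offsets = []
            for s in copy_strings:
                offsets.append(offset)
                offset += len(s)
            for t in sorted(which):
                s = copy_strings[t]
                pos = int(rng.integers(len(s)))
                new = _MUTATION_AA[rng.integers(len(_MUTATION_AA))]
                while new == s[pos]:
                    new = _MUTATION_AA[rng.integers(len(_MUTATION_AA))]
                copy_strings[t] = s[:pos] + new + s[pos + 1 :]
                sub_positions.append(offsets[t] + pos + 1)   # 1-based in block
        pre_str = "".join(token_strings[:n_pre])
        donor_str = "".join(donor_strings)
        copy_str = "".join(copy_strings)
        post_str = "".join(token_strings[n_pre + n_dup :])
        rep_domain = pre_str + donor_str + copy_str + post_str
        ins_start = len(nterm) + len(pre_str) + len(donor_str) + 1   # mature coords
        planted_insertion = {
            "start": ins_start,
            "end": ins_start + len(copy_str) - 1,
            "composition": list(insertion_spec.composition),
            "substitution_positions": sub_positions,
        }

    mature = nterm + rep_domain + cterm
    protein = SIGNAL_PEPTIDE + mature
    dna = _reverse_translate(protein, rng) + TRAILING_STOPS
    protected = 3 * (len(SIGNAL_PEPTIDE) + 12)     # signal + N-terminal consensus
    dna = _apply_dna_substitutions(dna, sub_rate, rng, protected)

    promoter_truth = None
    promoter_dna = None
    if with_promoter:
        promoter_dna, ptruth = generate_promoter(seed)
        promoter_truth = ptruth.promoter_truth

    truth = SyntheticTruth(
        seed=seed,
        architecture={
            "subunit_type": subunit_type,
            "signal_len": len(SIGNAL_PEPTIDE),
            "nterm_len": len(nterm),
            "rep_len": len(rep_domain),
            "cterm_len": C_TERMINAL_LEN,
            "mature_len": len(mature),
            "n_tri": n_tri if insertion_spec is None else n_tri + insertion_spec.composition[0],
            "n_hexa": n_hexa if insertion_spec is None else n_hexa + insertion_spec.composition[1],
            "n_nona": n_nona if insertion_spec is None else n_nona + insertion_spec.composition[2],
            "token_order": tokens,
            "cysteine_token": cys_token,
            "protein": protein,
            "sub_rate": sub_rate,
        },
        planted_insertion=planted_insertion,
        promoter_truth=promoter_truth,
    )
    record = GeneRecord(
        id=record_id, orf_dna=dna, promoter_dna=promoter_dna, source="synthetic"
    )
    return record, truth


def generate_insertion_pair(
    seed: int,
    subunit_type: str = "x",
    n_tri: int = 10,
    n_hexa: int = 60,
    n_nona: int = 30,
    composition: tuple[int, int, int] = (5, 15, 4),
    n_substitutions: int = 0,
    sub_rate: float = 0.0,
) -> tuple[GeneRecord, GeneRecord, SyntheticTruth]:
    """Reference/query gene pair differing by one planted tandem duplication.

    The reference carries the base domain (with the donor block in place);
    the query additionally carries the duplicated copy.  Identical seeds
    guarantee the shared parts are identical, so the only query/reference
    difference is the planted block (plus any ``sub_rate`` noise).
    """
    spec = InsertionSpec(composition, n_substitutions)
    query, truth = generate_subunit(
        seed, subunit_type, n_tri, n_hexa, n_nona,
        insertion_spec=spec, sub_rate=sub_rate,
        record_id=f"syn_{subunit_type}_{seed}_query",
    )
    # The reference allele shares its ancestry (and hence its ``sub_rate``
    # divergence) with the expanded allele: it is the query with the inserted
    # copy's codons excised.  Post-duplication divergence of the copy itself
    # is what ``n_substitutions`` models.
    ins = truth.planted_insertion
    sig = truth.architecture["signal_len"]
    dna = query.orf_dna
    ref_dna = dna[: 3 * (sig + ins["start"] - 1)] + dna[3 * (sig + ins["end"]) :]
    ref = GeneRecord(
        id=f"syn_{subunit_type}_{seed}_ref", orf_dna=ref_dna, source="synthetic"
    )
    return ref, query, truth


# ---------------------------------------------------------------------------
# Promoters


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=n))


def _has_near_match(seq: str, elements) -> bool:
    from .repeats import hamming

    for el in elements:
        L = len(el.consensus)
        for s in range(len(seq) - L + 1):
            if hamming(seq[s : s + L], el.consensus) <= el.max_mismatch:
                return True
    return False


def generate_promoter(
    seed: int,
    element_plan: dict | None = None,
    elements: tuple[ElementDefinition, ...] = DEFAULT_ELEMENTS,
    spacer_range: tuple[int, int] = (25, 60),
    flank_5: int = 120,
    flank_3: int = 30,
) -> tuple[str, SyntheticTruth]:
    """Synthetic promoter with the elements planted in canonical order.

    ``element_plan`` maps element name to ``"deleted"`` or
    ``{"substitutions": [(pos, base), ...]}`` (1-based positions within the
    element).  Background is rejection-sampled so that no background window
    lies within any element's mismatch budget; planted truth (offsets,
    substitutions, deletions) is recorded.
    """
    element_plan = element_plan or {}
    names = {e.name for e in elements}
    for k in element_plan:
        if k not in names:
            raise ValueError(f"element_plan names unknown element {k!r}")
    rng = np.random.default_rng([seed, 0x9E0])

    for _attempt in range(200):
        parts: list[str] = []
        offsets: dict[str, int] = {}
        planted_subs: dict[str, list] = {}
        deleted: list[str] = []
        pos = 0

        def spacer(n):
            for _ in range(500):
                s = _random_dna(n, rng)
                if not _has_near_match(s, elements):
                    return s
            raise RuntimeError("could not sample a motif-free spacer")

        s = spacer(flank_5)
        parts.append(s)
        pos += len(s)
        for el in elements:
            plan = element_plan.get(el.name)
            if plan == "deleted":
                deleted.append(el.name)
                continue
            obs = el.consensus
            subs = []
            if isinstance(plan, dict):
                for p, base in plan.get("substitutions", []):
                    if not 1 <= p <= len(obs):
                        raise ValueError(f"substitution position {p} outside {el.name}")
                    subs.append((p, obs[p - 1], base))
                    obs = obs[: p - 1] + base + obs[p:]
            offsets[el.name] = pos + 1
            planted_subs[el.name] = subs
            parts.append(obs)
            pos += len(obs)
            sp = spacer(int(rng.integers(*spacer_range)))
            parts.append(sp)
            pos += len(sp)
        parts.append(spacer(flank_3))
        promoter = "".join(parts)

        # junction windows may straddle a planted element and background;
        # verify each planted element is still the unique in-budget match in
        # its neighbourhood by checking no extra in-budget window exists
        # outside the planted spans (enhancer-internal partial copies exempt)
        ok = True
        from .repeats import hamming

        spans = {
            name: (offsets[name] - 1, offsets[name] - 1 + len(next(e.consensus for e in elements if e.name == name)))
            for name in offsets
        }
        for el in elements:
            L = len(el.consensus)
            for s0 in range(len(promoter) - L + 1):
                if hamming(promoter[s0 : s0 + L], el.consensus) <= el.max_mismatch:
                    inside_own = el.name in spans and spans[el.name][0] == s0
                    inside_other = any(
                        a <= s0 and s0 + L <= b for a, b in spans.values()
                    )
                    if not (inside_own or inside_other):
                        ok = False
        if ok:
            break
    else:
        raise RuntimeError("failed to assemble a clean synthetic promoter")

    truth = SyntheticTruth(
        seed=seed,
        promoter_truth={
            "offsets": offsets,
            "substitutions": {k: [list(t) for t in v] for k, v in planted_subs.items()},
            "deleted": deleted,
            "length": len(promoter),
        },
    )
    return promoter, truth


# ---------------------------------------------------------------------------
# Sequence families along a known tree


def _parse_tree_spec(spec):
    """Nested tuples/lists of leaf names, e.g. ((\"A\",\"B\"),(\"C\",\"D\"))."""
    if isinstance(spec, str):
        return spec
    return tuple(_parse_tree_spec(s) for s in spec)


def _spec_newick(spec) -> str:
    if isinstance(spec, str):
        return spec
    return "(" + ",".join(_spec_newick(s) for s in spec) + ")"


def _spec_leaves(spec) -> list[str]:
    if isinstance(spec, str):
        return [spec]
    out = []
    for s in spec:
        out.extend(_spec_leaves(s))
    return out


def generate_family(
    seed: int,
    tree_spec,
    region_len: int = 600,
    mut_per_branch: int = 5,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Evolve a family of aligned sequences along a known topology.

    Each branch receives exactly ``mut_per_branch`` substitutions (an int, or
    a dict mapping the subtree's leaf-name tuple to a count), placed at
    distinct alignment sites while unused sites remain, which keeps the
    leaf-to-leaf distances additive on the true tree.  Returns the aligned
    sequences (no indels) and the truth, including the true topology in
    newick form.
    """
    spec = _parse_tree_spec(tree_spec)
    leaves = _spec_leaves(spec)
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf names in tree_spec")

    def branch_mut(sub) -> int:
        if isinstance(mut_per_branch, dict):
            key = tuple(_spec_leaves(sub))
            return int(mut_per_branch.get(key, mut_per_branch.get("default", 0)))
        return int(mut_per_branch)

    max_needed = sum(
        branch_mut(s) for s in _iter_subtrees(spec)
    )
    if isinstance(mut_per_branch, int) and mut_per_branch > region_len:
        raise ValueError("mut_per_branch exceeds region_len")
    if max_needed > 0 and region_len < 1:
        raise ValueError("region too short")

    rng = np.random.default_rng([seed, 0xFA31])
    root = _random_dna(region_len, rng)
    site_pool = list(rng.permutation(region_len))
    seqs: dict[str, str] = {}

    def mutate(seq: str, n: int) -> str:
        s = list(seq)
        for _ in range(n):
            site = site_pool.pop() if site_pool else int(rng.integers(region_len))
            alt = [b for b in DNA if b != s[site]]
            s[site] = alt[rng.integers(3)]
        return "".join(s)

    def descend(sub, seq: str):
        if isinstance(sub, str):
            seqs[sub] = seq
            return
        for child in sub:
            descend(child, mutate(seq, branch_mut(child)))

    # the root's immediate children each get their own branch mutations
    descend(spec, root)

    truth = SyntheticTruth(
        seed=seed,
        family_truth={
            "newick": _spec_newick(spec) + ";",
            "leaves": leaves,
            "region_len": region_len,
            "mut_per_branch": mut_per_branch
            if isinstance(mut_per_branch, int)
            else {str(k): v for k, v in mut_per_branch.items()},
        },
    )
    return seqs, truth


def _iter_subtrees(spec):
    if isinstance(spec, str):
        yield spec
        return
    for s in spec:
        yield s
        if not isinstance(s, str):
            yield from _iter_subtrees(s)
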