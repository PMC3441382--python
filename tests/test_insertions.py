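"""Global alignment, insertion-block detection, tandem-duplication evidence."""
from functools import lru_cache

import numpy as np
import pytest

from glutannot import seq_io
from glutannot.anatomy import MatureSubunit, strip_signal_peptide
from glutannot.insertions import (
    AlignParams,
    InsertionTypeError,
    detect_insertions,
    gap_runs,
    global_align,
    verify_tandem_duplication,
)
from glutannot.synth import generate_insertion_pair, generate_subunit


def oracle_align_score(query: str, ref: str, p: AlignParams) -> float:
    """Independent affine-gap DP: recursion over (i, j, last move).

    Gap of length k costs gap_open + k * gap_extend, as in the package's
    convention.
    """

    @lru_cache(maxsize=None)
    def go(i, j, last):
        if i == len(query) and j == len(ref):
            return 0.0
        best = -1e18
        if i < len(query) and j < len(ref):
            s = p.match if query[i] == ref[j] else p.mismatch
            best = max(best, s + go(i + 1, j + 1, "m"))
        if i < len(query):   # gap in ref
            s = p.gap_extend + (p.gap_open if last != "q" else 0.0)
            best = max(best, s + go(i + 1, j, "q"))
        if j < len(ref):     # gap in query
            s = p.gap_extend + (p.gap_open if last != "r" else 0.0)
            best = max(best, s + go(i, j + 1, "r"))
        return best

    return go(0, 0, "m")


def _mature(residues, subunit_type="x"):
    return MatureSubunit(id="m", residues=residues, signal_peptide="", subunit_type=subunit_type)


class TestGlobalAlign:
    def test_identical_sequences_gap_free(self):
        r = global_align("EGEASGQLQ", "EGEASGQLQ")
        assert r.aligned_query == r.aligned_ref == "EGEASGQLQ"
        assert r.score == 18.0

    def test_minimal_indel(self):
        r = global_align("ACD", "AD")
        assert len(r.aligned_query) == 3
        assert r.aligned_ref.count("-") == 1
        assert r.aligned_query.replace("-", "") == "ACD"

    def test_degap_reconstructs_inputs(self):
        rng = np.random.default_rng(3)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            q = "".join(rng.choice(list(aa), size=rng.integers(5, 40)))
            s = "".join(rng.choice(list(aa), size=rng.integers(5, 40)))
            r = global_align(q, s)
            assert r.aligned_query.replace("-", "") == q
            assert r.aligned_ref.replace("-", "") == s

    def test_score_matches_exhaustive_dp_oracle(self):
        rng = np.random.default_rng(17)
        aa = "ACDEFG"
        p = AlignParams()
        for _ in range(40):
            q = "".join(rng.choice(list(aa), size=rng.integers(1, 13)))
            s = "".join(rng.choice(list(aa), size=rng.integers(1, 13)))
            assert global_align(q, s, p).score == pytest.approx(oracle_align_score(q, s, p))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "A")


class TestDetectInsertions:
    def test_planted_141_block_recovered(self):
        ref, query, truth = generate_insertion_pair(
            seed=3, subunit_type="x", n_tri=10, n_hexa=40, n_nona=20,
            composition=(5, 15, 4),
        )
        mq = strip_signal_peptide(seq_io.translate_orf(query.orf_dna).protein)
        mr = strip_signal_peptide(seq_io.translate_orf(ref.orf_dna).protein)
        blocks = detect_insertions(mq, mr)
        assert len(blocks) == 1
        b = blocks[0]
        ti = truth.planted_insertion
        assert b.query_span == (ti["start"], ti["end"]) and b.length == 141
        c = b.motif_census
        assert (c.n_tri, c.n_hexa, c.n_nona) == (5, 15, 4)

    def test_query_equals_ref_gives_no_blocks(self):
        rec, _ = generate_subunit(seed=4, n_tri=4, n_hexa=12, n_nona=4)
        m = strip_signal_peptide(seq_io.translate_orf(rec.orf_dna).protein)
        assert detect_insertions(m, m) == []

    def test_two_planted_blocks(self):
        """Two duplications of 75 and 105 residues are both found."""
        rec, _ = generate_subunit(seed=6, subunit_type="x", n_tri=6, n_hexa=40, n_nona=20)
        ref = strip_signal_peptide(seq_io.translate_orf(rec.orf_dna).protein)
        res = ref.residues
        # duplicate two disjoint windows of the repetitive domain in place
        a0, a1 = 150, 225      # 75 residues
        b0, b1 = 300, 405      # 105 residues
        q = res[:a1] + res[a0:a1] + res[a1:b1] + res[b0:b1] + res[b1:]
        mq = _mature(q)
        blocks = detect_insertions(mq, ref, min_block=30)
        assert sorted(b.length for b in blocks) == [75, 105]
        # excising each found block (in reverse order) reconstructs the reference
        out = q
        for b in sorted(blocks, key=lambda b: -b.query_span[0]):
            out = out[: b.query_span[0] - 1] + out[b.query_span[1] :]
        assert out == res

    def test_min_block_filters_short_gaps(self):
        rec, _ = generate_subunit(seed=6, n_tri=4, n_hexa=20, n_nona=8)
        ref = strip_signal_peptide(seq_io.translate_orf(rec.orf_dna).protein)
        res = ref.residues
        q = res[:200] + res[194:200] + res[200:]   # 6-residue duplication
        assert detect_insertions(_mature(q), ref, min_block=30) == []
        assert len(detect_insertions(_mature(q), ref, min_block=5)) == 1

    def test_type_mismatch_rejected(self):
        with pytest.raises(InsertionTypeError):
            detect_insertions(_mature("A" * 50, "x"), _mature("A" * 50, "y"))
        with pytest.raises(InsertionTypeError):
            detect_insertions(_mature("A" * 50, "unknown"), _mature("A" * 50, "unknown"))

    def test_insertions_appear_as_deletions_in_swapped_comparison(self):
        ref, query, truth = generate_insertion_pair(
            seed=9, subunit_type="y", n_tri=4, n_hexa=30, n_nona=14,
            composition=(0, 7, 7),
        )
        mq = strip_signal_peptide(seq_io.translate_orf(query.orf_dna).protein)
        mr = strip_signal_peptide(seq_io.translate_orf(ref.orf_dna).protein)
        fwd = global_align(mq.residues, mr.residues)
        rev = global_align(mr.residues, mq.residues)
        ins = [(s, e, seq) for s, e, seq in gap_runs(fwd, row="ref") if e - s + 1 >= 30]
        dels = [(s, e, seq) for s, e, seq in gap_runs(rev, row="query") if e - s + 1 >= 30]
        assert [(s, e) for s, e, _ in ins] == [(s, e) for s, e, _ in dels]
        assert [seq for *_, seq in ins] == [seq for *_, seq in dels]


class TestVerifyTandemDuplication:
    def test_perfect_adjacent_copy(self):
        ref, query, _ = generate_insertion_pair(
            seed=21, subunit_type="x", n_tri=8, n_hexa=30, n_nona=10,
            composition=(4, 10, 2),
        )
        mq = strip_signal_peptide(seq_io.translate_orf(query.orf_dna).protein)
        mr = strip_signal_peptide(seq_io.translate_orf(ref.orf_dna).protein)
        (block,) = detect_insertions(mq, mr)
        ev = block.duplication_evidence
        assert ev.flank == "upstream"
        assert ev.identity_pct == 100.0 and ev.variant_positions == []

    def test_planted_substitutions_reported(self):
        ref, query, truth = generate_insertion_pair(
            seed=22, subunit_type="x", n_tri=8, n_hexa=30, n_nona=10,
            composition=(4, 10, 2), n_substitutions=3,
        )
        mq = strip_signal_peptide(seq_io.translate_orf(query.orf_dna).protein)
        mr = strip_signal_peptide(seq_io.translate_orf(ref.orf_dna).protein)
        (block,) = detect_insertions(mq, mr)
        ev = block.duplication_evidence
        L = block.length
        assert ev.identity_pct == pytest.approx(100.0 * (L - 3) / L)
        assert ev.variant_positions == truth.planted_insertion["substitution_positions"]

    def test_shuffled_block_near_background_identity(self):
        """A random-shuffle block shows near-null identity to its flanks."""
        rec, _ = generate_subunit(seed=30, n_tri=6, n_hexa=30, n_nona=10)
        m = strip_signal_peptide(seq_io.translate_orf(rec.orf_dna).protein)
        rng = np.random.default_rng(1)
        idents = []
        for _ in range(100):
            res = m.residues
            window = list(res[250:310])
            rng.shuffle(window)
            q = res[:310] + "".join(window) + res[310:]
            from glutannot.insertions import InsertionBlock
            from glutannot.repeats import motif_census, segment_repeats

            seq = "".join(window)
            block = InsertionBlock(
                query_span=(311, 370), length=60, sequence=seq,
                motif_census=motif_census(segment_repeats(seq)),
            )
            ev = verify_tandem_duplication(_mature(q), block)
            idents.append(ev.identity_pct)
        # the repetitive-domain alphabet is extremely low complexity (~45% Q),
        # so the shuffle null sits near 43%, far from true-duplication values
        assert np.mean(idents) < 50.0
        assert max(idents) < 70.0

    def test_block_at_edge_uses_single_flank(self):
        rec, _ = generate_subunit(seed=31, n_tri=4, n_hexa=12, n_nona=4)
        m = strip_signal_peptide(seq_io.translate_orf(rec.orf_dna).protein)
        from glutannot.insertions import InsertionBlock
        from glutannot.repeats import motif_census, segment_repeats

        seq = m.residues[:40]
        block = InsertionBlock((1, 40), 40, seq, motif_census(segment_repeats(seq)))
        ev = verify_tandem_duplication(m, block)
        assert ev.flank == "downstream" and "single flank" in ev.note
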