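"""Label aligner: identity, accounting, brute-force optimality, spanning."""

import itertools

import numpy as np
import pytest

from ogmrepeat.align import (
    Aligner,
    MoleculeAlignment,
    Penalties,
    align_molecule,
    alignment_score,
    select_spanning,
)
from ogmrepeat.labelmap import ReferenceLabelMap, build_locus
from ogmrepeat.simulate import Molecule


def _map(positions, contig="c", pad=10_000):
    return ReferenceLabelMap(
        contig, int(max(positions)) + pad, tuple((i + 1, int(p)) for i, p in enumerate(positions))
    )


def brute_force_best(ref_pos, qry_pos, pen, free_gap=None):
    """Enumerate every monotone pairing and score it independently."""
    n, m = len(ref_pos), len(qry_pos)
    best = -np.inf
    for k in range(1, min(n, m) + 1):
        for ridx in itertools.combinations(range(n), k):
            for qidx in itertools.combinations(range(m), k):
                score = pen.match_bonus * k - pen.miss_qry * (m - k)
                for (r1, q1), (r2, q2) in zip(
                    zip(ridx, qidx), zip(ridx[1:], qidx[1:])
                ):
                    score -= pen.miss_ref * (r2 - r1 - 1)
                    free = free_gap is not None and (
                        ref_pos[r1] <= free_gap[0] and ref_pos[r2] >= free_gap[1]
                    )
                    if not free:
                        dr = ref_pos[r2] - ref_pos[r1]
                        dq = qry_pos[q2] - qry_pos[q1]
                        score -= pen.size_cost * (dq - dr) ** 2
                best = max(best, score)
    return best


class TestAlignIdentity:
    def test_verbatim_copy_aligns_identically(self):
        ref = _map([5000, 12_000, 20_000, 31_000, 45_000, 60_000])
        mol = Molecule(1, 61_000, tuple(ref.positions))
        aln = align_molecule(mol, ref)
        assert aln is not None
        assert aln.orientation == "+"
        assert aln.pairs == tuple((i + 1, i + 1) for i in range(6))

    def test_single_deletion_score_accounting(self):
        """Dropping one interior molecule label forfeits that pair's bonus
        plus the skipped-reference penalty, exactly."""
        pen = Penalties()
        ref = _map([5000, 12_000, 20_000, 31_000, 45_000, 60_000])
        full = Molecule(1, 61_000, tuple(ref.positions))
        missing = Molecule(2, 61_000, tuple(p for p in ref.positions if p != 20_000))
        a_full = align_molecule(full, ref, pen)
        a_miss = align_molecule(missing, ref, pen)
        assert len(a_miss.pairs) == len(a_full.pairs) - 1
        assert a_full.confidence - a_miss.confidence == pytest.approx(
            pen.match_bonus + pen.miss_ref
        )

    def test_reversal_invariance(self, rng):
        """Reversing the molecule flips the orientation but not the score."""
        ref = _map(sorted(rng.choice(np.arange(2000, 200_000, 7), 12, replace=False)))
        offs = np.array(ref.positions[2:9]) - 1000
        fwd = Molecule(1, 210_000, tuple(int(o) for o in offs))
        rev = Molecule(2, 210_000, tuple(int(210_000 + 1 - o) for o in offs[::-1]))
        a_fwd = align_molecule(fwd, ref)
        a_rev = align_molecule(rev, ref)
        assert a_fwd.confidence == pytest.approx(a_rev.confidence)
        assert {a_fwd.orientation, a_rev.orientation} == {"+", "-"}
        # same reference labels matched either way
        assert a_fwd.ref_ids == a_rev.ref_ids

    def test_too_few_labels_rejected(self):
        ref = _map([5000, 12_000, 20_000])
        assert align_molecule(Molecule(1, 30_000, (5000, 12_000)), ref) is None


class TestBruteForceOracle:
    def test_dp_matches_exhaustive_search_on_small_instances(self, rng):
        """DP optimum equals exhaustive monotone-pairing enumeration on
        random instances with <= 8 labels on each side."""
        pen = Penalties(max_skip=7)
        for trial in range(25):
            n = int(rng.integers(5, 9))
            m = int(rng.integers(5, 9))
            ref_pos = np.sort(rng.choice(np.arange(1000, 80_000), n, replace=False))
            # molecule: jittered subset of ref intervals plus noise labels
            base = np.sort(rng.choice(ref_pos, min(m, n), replace=False)).astype(float)
            base += rng.normal(0, 300, base.size)
            extra = rng.uniform(1000, 80_000, m - base.size)
            qry = np.sort(np.abs(np.concatenate([base, extra]))) + 1
            qry_off = tuple(int(q) for q in np.unique(qry.astype(int)))
            if len(qry_off) < 5:
                continue
            mol = Molecule(1, int(max(qry_off)) + 1000, qry_off)
            ref = _map(ref_pos)
            aligner = Aligner(ref, pen, min_flank_pairs=0)
            aln = aligner.align(mol)
            got = alignment_score(aln.pairs, ref, mol, aln.orientation, pen)
            assert got == pytest.approx(aln.confidence, abs=1e-9)
            expect_fwd = brute_force_best(
                [float(p) for p in ref_pos], [float(q) for q in qry_off], pen
            )
            flipped = [mol.length + 1 - q for q in qry_off[::-1]]
            expect_rev = brute_force_best(
                [float(p) for p in ref_pos], [float(q) for q in flipped], pen
            )
            assert aln.confidence == pytest.approx(max(expect_fwd, expect_rev))

    def test_free_gap_restores_expanded_alignment(self):
        """A large insertion between the flanking markers is penalty-free
        when the locus interval is declared, and crippling otherwise."""
        pen = Penalties()
        ref = _map([5000, 12_000, 20_000, 31_000, 45_000, 60_000])
        # expansion of 15 kb between labels 3 (20 kb) and 4 (31 kb)
        offs = [5000, 12_000, 20_000, 46_000, 60_000, 75_000]
        mol = Molecule(1, 80_000, tuple(offs))
        with_gap = align_molecule(mol, ref, pen, free_gap_interval=(20_000, 31_000),
                                  min_flank_pairs=3)
        assert with_gap is not None
        assert len(with_gap.pairs) == 6
        without = align_molecule(mol, ref, pen, min_flank_pairs=0)
        assert without.confidence < with_gap.confidence


class TestSpanning:
    @pytest.fixture()
    def locus_map(self):
        positions = [40_000, 50_000, 60_288, 61_078, 70_000]
        m = _map(positions)
        locus = build_locus(m, 2, 3, ref_repeat_count=24)
        return m, locus

    def _aln(self, mid, ref_ids):
        pairs = tuple((r, i + 1) for i, r in enumerate(sorted(ref_ids)))
        return MoleculeAlignment(mid, "c", "+", pairs, 1.0)

    def test_both_markers_retained_upstream_only_excluded(self, locus_map):
        _, locus = locus_map
        alns = [
            self._aln(1, [1, 2, 3, 5]),   # upstream + downstream
            self._aln(2, [1, 2, 4, 5]),   # upstream + companion (dropout case)
            self._aln(3, [1, 2]),         # upstream marker only
            self._aln(4, [3, 4, 5]),      # downstream only
        ]
        span = select_spanning(alns, locus)
        assert [a.molecule_id for a in span.members] == [1, 2]
        assert span.downstream_matched[1] == (3,)
        assert span.downstream_matched[2] == (4,)

    def test_idempotent(self, locus_map):
        _, locus = locus_map
        alns = [self._aln(1, [1, 2, 3, 5]), self._aln(3, [1, 2])]
        once = select_spanning(alns, locus)
        twice = select_spanning(once.members, locus)
        assert twice.members == once.members

    def test_empty_allowed(self, locus_map):
        _, locus = locus_map
        assert select_spanning([], locus).members == ()


class TestFlankSupport:
    def test_insufficient_flank_labels_rejected(self):
        ref = _map([5000, 12_000, 20_000, 31_000, 45_000, 60_000])
        # only two labels upstream of the declared gap (20k..31k)
        mol = Molecule(1, 61_000, (12_000, 20_000, 31_000, 45_000, 60_000))
        assert (
            align_molecule(mol, ref, free_gap_interval=(20_000, 31_000)) is None
        )
        # three on each side passes
        mol2 = Molecule(2, 61_000, (5000, 12_000, 20_000, 31_000, 45_000, 60_000))
        assert (
            align_molecule(mol2, ref, free_gap_interval=(20_000, 31_000)) is not None
        )
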