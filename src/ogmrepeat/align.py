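"""Place labelled molecules on a reference label map.

Real OGM runs use the vendor alignment tool and are imported here as XMAP
files (see :mod:`ogmrepeat.formats`).  For synthetic molecules the package
provides a simplified dynamic-programming label aligner: a monotone pairing
of molecule label sites to reference labels maximising

    score = match_bonus * (matched pairs)
            - miss_ref * (reference labels skipped inside the aligned span)
            - miss_qry * (molecule sites left unmatched)
            - size_cost * sum (molecule interval - reference interval)^2

with the locus interval between the flanking markers exempt from the size
term (``free_gap_interval``), so molecules carrying arbitrarily large repeat
expansions still align.  This is a declared simplification of the vendor
aligner, intended for synthetic data; it makes no attempt to reproduce
vendor confidence scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .labelmap import LocusDefinition, ReferenceLabelMap
from .simulate import Molecule

__all__ = [
    "Penalties",
    "MoleculeAlignment",
    "SpanningSet",
    "Aligner",
    "align_molecule",
    "alignment_score",
    "select_spanning",
]


@njit(cache=True)
def _dp_kernel(R, Q, refdiff, freegap, match_bonus, miss_ref, miss_qry, size_cost, delta):
    """Label-pairing DP: dp[i, j] = best score of an alignment whose last
    matched pair is (ref i, qry j), with leading unmatched qry sites
    penalised and reference labels left of the span free (the molecule is a
    genome fragment)."""
    n = R.shape[0]
    m = Q.shape[0]
    dp = np.empty((n, m))
    npairs = np.zeros((n, m), np.int32)
    back_a = np.zeros((n, m), np.int8)
    back_b = np.zeros((n, m), np.int8)
    for j in range(m):
        for i in range(n):
            best = match_bonus - miss_qry * j
            bp = 1
            ba = 0
            bb = 0
            bmax = j if j < delta else delta
            amax = i if i < delta else delta
            for b in range(1, bmax + 1):
                dq = Q[j] - Q[j - b]
                for a in range(1, amax + 1):
                    if freegap[a - 1, i - a]:
                        cost = 0.0
                    else:
                        d = dq - refdiff[a - 1, i - a]
                        cost = size_cost * d * d
                    cand = (
                        dp[i - a, j - b]
                        + match_bonus
                        - miss_ref * (a - 1)
                        - miss_qry * (b - 1)
                        - cost
                    )
                    cp = npairs[i - a, j - b] + 1
                    if cand > best + 1e-12 or (
                        abs(cand - best) <= 1e-12 and cp > bp
                    ):
                        best = cand
                        bp = cp
                        ba = a
                        bb = b
            dp[i, j] = best
            npairs[i, j] = bp
            back_a[i, j] = ba
            back_b[i, j] = bb
    return dp, npairs, back_a, back_b


@dataclass(frozen=True)
class Penalties:
    """Scoring parameters of the label aligner.

    ``size_cost`` is per bp^2; the default tolerates the assay's per-interval
    sizing noise (a few hundred bp costs well under one match bonus) while a
    ~790 bp systematic mismatch -- pairing a collapsed label with the wrong
    member of a sub-resolution reference pair -- costs more than a skip.
    ``max_skip`` bounds consecutive unmatched labels per transition.
    """

    match_bonus: float = 1.0
    miss_ref: float = 0.4
    miss_qry: float = 0.4
    size_cost: float = 3e-6
    max_skip: int = 4


@dataclass(frozen=True)
class MoleculeAlignment:
    """Monotone pairing of molecule label sites to reference labels.

    ``pairs`` holds (reference label id, molecule site index, 1-based) in
    increasing reference order; site indices increase for '+' orientation
    and decrease for '-'.  ``confidence`` is the aligner score (or the
    vendor confidence when parsed from XMAP).
    """

    molecule_id: int
    contig: str
    orientation: str
    pairs: tuple[tuple[int, int], ...]
    confidence: float

    def __post_init__(self) -> None:
        if self.orientation not in "+-":
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        refs = [r for r, _ in self.pairs]
        qrys = [q for _, q in self.pairs]
        if sorted(set(refs)) != refs:
            raise ValueError("reference label ids must strictly increase")
        step = qrys if self.orientation == "+" else qrys[::-1]
        if sorted(set(step)) != step:
            raise ValueError("query site indices must be strictly monotone")

    @property
    def ref_ids(self) -> frozenset[int]:
        return frozenset(r for r, _ in self.pairs)

    def site_for_ref(self, ref_id: int) -> int | None:
        for r, q in self.pairs:
            if r == ref_id:
                return q
        return None


class Aligner:
    """Reusable DP aligner bound to one reference map.

    Precomputes reference interval tables once; :meth:`align` then runs both
    orientations of a molecule and returns the better alignment, or ``None``
    when the molecule has fewer than 5 labels, fewer than
    ``min_flank_pairs`` matched pairs in total, or -- when a free-gap
    interval is declared and the alignment bridges it -- fewer than
    ``min_flank_pairs`` matched pairs on either flank (a bridging alignment
    is only trusted for sizing with enough anchors on both sides;
    one-sided alignments are kept and simply never qualify as spanning).
    """

    def __init__(
        self,
        ref: ReferenceLabelMap,
        penalties: Penalties | None = None,
        free_gap_interval: tuple[int, int] | None = None,
        min_flank_pairs: int = 3,
    ) -> None:
        self.ref = ref
        self.pen = penalties or Penalties()
        self.free_gap = free_gap_interval
        self.min_flank_pairs = min_flank_pairs
        self._R = np.asarray(ref.positions, dtype=np.float64)
        d = self.pen.max_skip
        n = self._R.size
        # refdiff[a-1, i-a] = R[i] - R[i-a]; freegap marks transitions whose
        # reference interval contains the declared locus gap.
        self._refdiff = np.zeros((d, n), dtype=np.float64)
        self._freegap = np.zeros((d, n), dtype=np.bool_)
        for a in range(1, min(d, n - 1) + 1):
            self._refdiff[a - 1, : n - a] = self._R[a:] - self._R[:-a]
            if free_gap_interval is not None:
                lo, hi = free_gap_interval
                self._freegap[a - 1, : n - a] = (self._R[:-a] <= lo) & (
                    self._R[a:] >= hi
                )

    # -- core DP on one orientation -------------------------------------
    def _dp(self, Q: np.ndarray):
        pen = self.pen
        dp, npairs, back_a, back_b = _dp_kernel(
            self._R,
            np.asarray(Q, dtype=np.float64),
            self._refdiff,
            self._freegap,
            pen.match_bonus,
            pen.miss_ref,
            pen.miss_qry,
            pen.size_cost,
            pen.max_skip,
        )
        m = Q.size
        total = dp - pen.miss_qry * (m - 1 - np.arange(m))[None, :]
        return total, npairs, back_a, back_b

    def _best_cell(self, total, npairs):
        score = total.max()
        ii, jj = np.nonzero(np.abs(total - score) <= 1e-9)
        order = sorted(
            range(ii.size), key=lambda k: (-npairs[ii[k], jj[k]], ii[k], jj[k])
        )
        k = order[0]
        return float(score), int(ii[k]), int(jj[k])

    def _traceback(self, back_a, back_b, i, j):
        pairs = []
        while True:
            pairs.append((i, j))
            a, b = int(back_a[i, j]), int(back_b[i, j])
            if a == 0:
                break
            i -= a
            j -= b
        return pairs[::-1]

    def align(self, molecule: Molecule) -> MoleculeAlignment | None:
        offs = np.asarray(molecule.label_positions, dtype=np.float64)
        if offs.size < 5 or self._R.size < 2:
            return None
        flipped = molecule.length + 1 - offs[::-1]

        results = []
        for orientation, Q in (("+", offs), ("-", flipped)):
            total, npairs, ba, bb = self._dp(Q)
            score, i, j = self._best_cell(total, npairs)
            results.append((score, int(npairs[i, j]), orientation, (total, ba, bb, i, j)))

        results.sort(key=lambda r: (-r[0], -r[1], r[2]))
        score, _, orientation, (total, ba, bb, i, j) = results[0]
        cells = self._traceback(ba, bb, i, j)

        m = offs.size
        pairs = []
        for ri, qj in cells:
            ref_id = self.ref.labels[ri][0]
            site = qj + 1 if orientation == "+" else m - qj
            pairs.append((ref_id, site))

        if len(pairs) < self.min_flank_pairs:
            return None
        if self.free_gap is not None:
            # an alignment bridging the locus gap is only trusted with
            # enough anchor labels on each flank; one-sided alignments are
            # kept (they can never be selected as spanning)
            lo, hi = self.free_gap
            pos = {lid: p for lid, p in self.ref.labels}
            n_up = sum(1 for r, _ in pairs if pos[r] <= lo)
            n_down = sum(1 for r, _ in pairs if pos[r] >= hi)
            if n_up > 0 and n_down > 0 and (
                n_up < self.min_flank_pairs or n_down < self.min_flank_pairs
            ):
                return None

        return MoleculeAlignment(
            molecule_id=molecule.molecule_id,
            contig=self.ref.contig_name,
            orientation=orientation,
            pairs=tuple(pairs),
            confidence=score,
        )


def align_molecule(
    molecule: Molecule,
    ref: ReferenceLabelMap,
    penalties: Penalties | None = None,
    free_gap_interval: tuple[int, int] | None = None,
    min_flank_pairs: int = 3,
) -> MoleculeAlignment | None:
    """One-shot convenience wrapper around :class:`Aligner`."""
    return Aligner(ref, penalties, free_gap_interval, min_flank_pairs).align(molecule)


def alignment_score(
    pairs: Sequence[tuple[int, int]],
    ref: ReferenceLabelMap,
    molecule: Molecule,
    orientation: str = "+",
    penalties: Penalties | None = None,
    free_gap_interval: tuple[int, int] | None = None,
) -> float:
    """Score an explicit pairing under the aligner's objective.

    Pairs are (ref label id, molecule site index, 1-based, original
    orientation).  Used for score accounting and cross-checks.
    """
    pen = penalties or Penalties()
    pos = {lid: float(p) for lid, p in ref.labels}
    offs = np.asarray(molecule.label_positions, dtype=np.float64)
    if orientation == "-":
        q = {s: molecule.length + 1 - offs[s - 1] for _, s in pairs}
    else:
        q = {s: offs[s - 1] for _, s in pairs}
    ordered = sorted(pairs, key=lambda p: pos[p[0]])
    score = pen.match_bonus * len(ordered)
    score -= pen.miss_qry * (len(offs) - len(ordered))
    idx = {lid: k for k, (lid, _) in enumerate(ref.labels)}
    for (r1, s1), (r2, s2) in zip(ordered, ordered[1:]):
        score -= pen.miss_ref * (idx[r2] - idx[r1] - 1)
        dr = pos[r2] - pos[r1]
        dq = abs(q[s2] - q[s1])
        free = free_gap_interval is not None and (
            pos[r1] <= free_gap_interval[0] and pos[r2] >= free_gap_interval[1]
        )
        if not free:
            score -= pen.size_cost * (dq - dr) ** 2
    return float(score)


@dataclass(frozen=True)
class SpanningSet:
    """Alignments whose pairs cover both flanking markers of a locus.

    ``downstream_matched`` records, per molecule, which of the downstream /
    companion labels the alignment actually paired (the random-dropout case
    pairs exactly one of the two).
    """

    locus: LocusDefinition
    members: tuple[MoleculeAlignment, ...]
    downstream_matched: dict[int, tuple[int, ...]]


def select_spanning(
    alignments: Iterable[MoleculeAlignment], locus: LocusDefinition
) -> SpanningSet:
    """Keep alignments matching the upstream marker and at least one of the
    downstream/companion markers."""
    up_id = locus.upstream[0]
    down_ids = set(locus.downstream_ids)
    members = []
    matched: dict[int, tuple[int, ...]] = {}
    for aln in alignments:
        ids = aln.ref_ids
        hit = tuple(sorted(ids & down_ids))
        if up_id in ids and hit:
            members.append(aln)
            matched[aln.molecule_id] = hit
    return SpanningSet(locus, tuple(members), matched)
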