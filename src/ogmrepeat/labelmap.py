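"""In-silico reference label maps and locus definitions.

Optical genome mapping (OGM) images long DNA molecules whose occurrences of a
labelling-enzyme recognition motif (DLE-1, ``CTTAAG``) carry a fluorophore.
Structure is read from inter-label distances, so the reference against which
molecules are compared is not a sequence but a *label map*: the ordered motif
positions along a contig.

Two reference-side corrections matter when sizing a repeat between two
flanking labels:

* **Sub-resolution merging.**  Two recognition sites closer than roughly
  1 kb are imaged as a single spot, so the reference position used for the
  merged site is the average of the underlying site positions.
* **Reference-repeat subtraction.**  The reference assembly already carries
  some copies of the repeat (24 CTG units at the TCF4 CTG18.1 locus in
  hg38, i.e. 72 bp), which must be subtracted so that a molecule's excess
  distance reads out the *full* repeat tract length of that molecule.

:class:`LocusDefinition` captures a flanking-marker pair together with the
corrected reference distance combining both corrections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ReferenceLabelMap",
    "LocusDefinition",
    "scan_labels",
    "effective_positions",
    "build_locus",
    "reverse_complement",
    "DEFAULT_MOTIF",
    "CTG18_UPSTREAM_POS",
    "CTG18_DOWNSTREAM_POS",
    "CTG18_COMPANION_POS",
    "CTG18_REF_REPEATS",
]

DEFAULT_MOTIF = "CTTAAG"

# hg38 coordinates of the DLE-1 labels flanking the TCF4 CTG18.1 repeat on
# chromosome 18.  The repeat lies between the first two; the third sits
# 790 bp beyond the second, inside the imaging resolution limit.
CTG18_UPSTREAM_POS = 55_584_360
CTG18_DOWNSTREAM_POS = 55_594_648
CTG18_COMPANION_POS = 55_595_438
CTG18_REF_REPEATS = 24

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class ReferenceLabelMap:
    """Ordered label positions along one contig (1-based, inclusive)."""

    contig_name: str
    contig_length: int
    labels: tuple[tuple[int, int], ...]  # (label_id, position)

    def __post_init__(self) -> None:
        prev = 0
        seen: set[int] = set()
        for label_id, pos in self.labels:
            if not (1 <= pos <= self.contig_length):
                raise ValueError(
                    f"label {label_id} at {pos} outside contig "
                    f"[1, {self.contig_length}]"
                )
            if pos <= prev:
                raise ValueError("label positions must be strictly increasing")
            if label_id in seen:
                raise ValueError(f"duplicate label id {label_id}")
            seen.add(label_id)
            prev = pos

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(pos for _, pos in self.labels)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.labels)

    def position_of(self, label_id: int) -> int:
        for lid, pos in self.labels:
            if lid == label_id:
                return pos
        raise KeyError(f"label id {label_id} not in map {self.contig_name!r}")

    def index_of(self, label_id: int) -> int:
        for idx, (lid, _) in enumerate(self.labels):
            if lid == label_id:
                return idx
        raise KeyError(f"label id {label_id} not in map {self.contig_name!r}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class LocusDefinition:
    """A repeat locus flanked by two reference labels.

    ``corrected_ref_distance`` is the distance a molecule carrying exactly
    zero repeat units would show between the upstream marker and the
    (companion-averaged) downstream marker; a molecule's expansion size is
    its observed inter-marker distance minus this quantity and equals the
    molecule's full repeat tract length in bp.
    """

    name: str
    contig: str
    upstream: tuple[int, int]  # (label_id, position)
    downstream: tuple[int, int]
    companion: tuple[int, int] | None
    ref_repeat_count: int
    repeat_unit_len: int = 3
    resolution_limit: int = 1000
    corrected_ref_distance: int = field(default=0)

    def __post_init__(self) -> None:
        if self.upstream[1] >= self.downstream[1]:
            raise ValueError("upstream marker must precede downstream marker")
        if self.companion is not None:
            gap = abs(self.companion[1] - self.downstream[1])
            if gap > self.resolution_limit:
                raise ValueError(
                    f"companion gap {gap} exceeds resolution limit "
                    f"{self.resolution_limit}"
                )
        expected = (
            self.averaged_downstream_position
            - self.upstream[1]
            - self.ref_repeat_count * self.repeat_unit_len
        )
        if self.corrected_ref_distance == 0:
            object.__setattr__(self, "corrected_ref_distance", expected)
        elif self.corrected_ref_distance != expected:
            raise ValueError(
                f"corrected_ref_distance {self.corrected_ref_distance} "
                f"inconsistent with markers (expected {expected})"
            )

    @property
    def averaged_downstream_position(self) -> int:
        if self.companion is None:
            return self.downstream[1]
        return _round_half_up((self.downstream[1] + self.companion[1]) / 2.0)

    @property
    def raw_distance(self) -> int:
        """Downstream minus upstream position, no corrections."""
        return self.downstream[1] - self.upstream[1]

    @property
    def averaged_distance(self) -> int:
        """Companion-averaged distance, before repeat subtraction."""
        return self.averaged_downstream_position - self.upstream[1]

    @property
    def downstream_ids(self) -> tuple[int, ...]:
        if self.companion is None:
            return (self.downstream[0],)
        return (self.downstream[0], self.companion[0])


def scan_labels(
    sequence: str, motif: str = DEFAULT_MOTIF, contig_name: str = "contig"
) -> ReferenceLabelMap:
    """Scan a sequence for motif label sites on both strands.

    Returns every 1-based start position of ``motif`` on the forward strand
    together with occurrences of its reverse complement (reported at their
    forward-strand start), duplicates collapsed.  Overlapping occurrences are
    all reported.  ``CTTAAG`` is its own reverse complement, so the default
    motif needs only a single scan.
    """
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 bases")
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    sequence = sequence.upper()
    if not sequence:
        return ReferenceLabelMap(contig_name, 0 if not sequence else len(sequence), ())

    hits: set[int] = set()
    for m in (motif, reverse_complement(motif)):
        start = sequence.find(m)
        while start != -1:
            hits.add(start + 1)  # 1-based
            start = sequence.find(m, start + 1)
    labels = tuple((i + 1, pos) for i, pos in enumerate(sorted(hits)))
    return ReferenceLabelMap(contig_name, len(sequence), labels)


def effective_positions(
    labelmap: ReferenceLabelMap, resolution_limit: int
) -> list[tuple[tuple[int, ...], int]]:
    """Merge sub-resolution neighbours into effective imaging sites.

    Greedy left-to-right: a label within ``resolution_limit`` of the current
    effective site is absorbed, moving the effective position to the
    (half-up rounded) mean of the current effective position and the new
    label.  A merged pair is only chained with a third label when the pair's
    mean is itself within the limit of that label.
    """
    if resolution_limit <= 0:
        raise ValueError("resolution_limit must be positive")
    merged: list[tuple[list[int], int]] = []
    for label_id, pos in labelmap.labels:
        if merged and pos - merged[-1][1] <= resolution_limit:
            ids, eff = merged[-1]
            ids.append(label_id)
            merged[-1] = (ids, _round_half_up((eff + pos) / 2.0))
            if len(ids) > 2:
                warnings.warn(
                    f"{len(ids)} labels chained into one effective site at "
                    f"{merged[-1][1]} on {labelmap.contig_name}",
                    stacklevel=2,
                )
        else:
            merged.append(([label_id], pos))
    return [(tuple(ids), eff) for ids, eff in merged]


def build_locus(
    labelmap: ReferenceLabelMap,
    upstream_id: int,
    downstream_id: int,
    ref_repeat_count: int,
    repeat_unit_len: int = 3,
    resolution_limit: int = 1000,
    name: str = "locus",
) -> LocusDefinition:
    """Build a :class:`LocusDefinition` from two marker ids on a map.

    The companion label is auto-detected as the next label after the
    downstream marker when it falls within ``resolution_limit``; its position
    is averaged with the downstream marker (half-up rounding) before the
    reference repeat content (``ref_repeat_count * repeat_unit_len`` bp) is
    subtracted.
    """
    up_idx = labelmap.index_of(upstream_id)
    down_idx = labelmap.index_of(downstream_id)
    up_pos = labelmap.labels[up_idx][1]
    down_pos = labelmap.labels[down_idx][1]
    if up_pos >= down_pos:
        raise ValueError("upstream marker must precede downstream marker")

    # The averaging scheme assumes the upstream marker itself is resolved.
    for neigh in (up_idx - 1, up_idx + 1):
        if 0 <= neigh < len(labelmap.labels) and neigh != down_idx:
            if abs(labelmap.labels[neigh][1] - up_pos) <= resolution_limit:
                raise ValueError(
                    "upstream marker has a neighbour within the resolution "
                    "limit; unsupported marker configuration"
                )

    companion: tuple[int, int] | None = None
    if down_idx + 1 < len(labelmap.labels):
        cand_id, cand_pos = labelmap.labels[down_idx + 1]
        if cand_pos - down_pos <= resolution_limit:
            companion = (cand_id, cand_pos)

    return LocusDefinition(
        name=name,
        contig=labelmap.contig_name,
        upstream=(upstream_id, up_pos),
        downstream=(downstream_id, down_pos),
        companion=companion,
        ref_repeat_count=ref_repeat_count,
        repeat_unit_len=repeat_unit_len,
        resolution_limit=resolution_limit,
    )
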