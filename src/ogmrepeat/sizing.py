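"""Per-molecule repeat-expansion sizing and per-sample summaries.

For each locus-spanning molecule the expansion size is the molecule-frame
distance between the sites paired to the upstream marker and to the
downstream representative, minus the corrected reference distance.  Because
that reference distance already removes the reference repeat content, the
expansion size equals the molecule's full repeat tract length in bp; it may
be negative for short alleles under sizing noise, and such molecules are
retained (filtered means would be biased).  Samples are summarised the way
the assay reports them: pooled over both (unphased) alleles, with 200 bp
histogram bins and the fraction of molecules above a configurable 2,000 bp
expanded-molecule threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .align import MoleculeAlignment, SpanningSet
from .labelmap import LocusDefinition
from .simulate import Molecule

__all__ = [
    "MoleculeSizeCall",
    "SampleSummary",
    "size_molecule",
    "size_spanning_set",
    "to_repeats",
    "histogram_sizes",
    "modal_bin",
    "summarize_sample",
    "calls_to_frame",
]


@dataclass(frozen=True)
class MoleculeSizeCall:
    """Sizing result for one spanning molecule."""

    molecule_id: int
    observed_distance: float  # bp, molecule frame
    expansion_size: float  # bp; may be negative under noise
    repeat_estimate: float  # expansion_size / repeat_unit_len


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample pooled summary over all spanning molecules."""

    sample_id: str
    tissue: str
    n_molecules: int
    mean_size: float  # bp; nan when n == 0
    max_size: float
    histogram: pd.DataFrame  # columns bin_start, count
    expanded_fraction: float  # fraction of molecules above the threshold
    expanded_threshold: float = 2000.0

    @property
    def undefined_mean(self) -> bool:
        return self.n_molecules == 0


def size_molecule(
    alignment: MoleculeAlignment,
    molecule: Molecule,
    locus: LocusDefinition,
) -> MoleculeSizeCall:
    """Size one spanning molecule against the corrected reference distance.

    The downstream anchor is the molecule site paired to the downstream
    marker, or to its companion when only that one was detected; when both
    are present their mean molecule position is used, matching the averaged
    reference position in the corrected distance.
    """
    up_site = alignment.site_for_ref(locus.upstream[0])
    if up_site is None:
        raise ValueError(
            f"alignment of molecule {alignment.molecule_id} does not cover "
            "the upstream marker"
        )
    down_sites = [
        alignment.site_for_ref(rid)
        for rid in locus.downstream_ids
        if alignment.site_for_ref(rid) is not None
    ]
    if not down_sites:
        raise ValueError(
            f"alignment of molecule {alignment.molecule_id} does not cover "
            "the downstream marker"
        )
    if any(s == up_site for s in down_sites):
        raise ValueError(
            f"molecule {alignment.molecule_id}: upstream and downstream "
            "markers paired to the same molecule site"
        )
    up_pos = molecule.label_positions[up_site - 1]
    down_pos = float(
        np.mean([molecule.label_positions[s - 1] for s in down_sites])
    )
    observed = abs(down_pos - up_pos)
    expansion = observed - locus.corrected_ref_distance
    return MoleculeSizeCall(
        molecule_id=alignment.molecule_id,
        observed_distance=observed,
        expansion_size=expansion,
        repeat_estimate=expansion / locus.repeat_unit_len,
    )


def size_spanning_set(
    spanning: SpanningSet, molecules: dict[int, Molecule]
) -> list[MoleculeSizeCall]:
    """Size every member of a spanning set."""
    return [
        size_molecule(aln, molecules[aln.molecule_id], spanning.locus)
        for aln in spanning.members
    ]


def to_repeats(
    size_bp: float,
    unit: int = 3,
    mode: Literal["exact", "floor", "nearest_hundred"] = "exact",
) -> float | int:
    """Convert an expansion size in bp to repeat units.

    ``floor`` gives the conservative whole-repeat count (500 bp -> 166 CTG
    repeats); ``nearest_hundred`` is the reporting convention for large
    estimates (16,803 bp -> ~5600 repeats).
    """
    if unit <= 0:
        raise ValueError("unit must be positive")
    repeats = size_bp / unit
    if mode == "exact":
        return repeats
    if mode == "floor":
        return math.floor(repeats)
    if mode == "nearest_hundred":
        return int(math.floor(repeats / 100.0 + 0.5)) * 100
    raise ValueError(f"unknown mode {mode!r}")


def histogram_sizes(
    calls: Sequence[MoleculeSizeCall] | Sequence[float], bin_width: int = 200
) -> pd.DataFrame:
    """Bin expansion sizes into half-open [k*w, (k+1)*w) bins.

    Negative sizes fall into negative-k bins; total counts equal the number
    of calls.  Returns a DataFrame with columns ``bin_start`` and ``count``
    sorted by bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sizes = np.asarray(
        [c.expansion_size if isinstance(c, MoleculeSizeCall) else c for c in calls],
        dtype=float,
    )
    if sizes.size == 0:
        return pd.DataFrame({"bin_start": pd.Series(dtype=int), "count": pd.Series(dtype=int)})
    k = np.floor(sizes / bin_width).astype(np.int64)
    uniq, counts = np.unique(k, return_counts=True)
    return pd.DataFrame({"bin_start": uniq * bin_width, "count": counts})


def modal_bin(histogram: pd.DataFrame, min_bin_start: float | None = None) -> int:
    """Bin start of the most populated bin (lowest bin on ties), optionally
    restricted to bins at or above ``min_bin_start``."""
    h = histogram
    if min_bin_start is not None:
        h = h[h["bin_start"] >= min_bin_start]
    if h.empty:
        raise ValueError("no bins in requested range")
    top = h[h["count"] == h["count"].max()]
    return int(top["bin_start"].min())


def summarize_sample(
    calls: Sequence[MoleculeSizeCall],
    sample_id: str,
    tissue: str = "",
    bin_width: int = 200,
    expanded_threshold: float = 2000.0,
) -> SampleSummary:
    """Pooled per-sample summary (both alleles, no phasing)."""
    sizes = np.asarray([c.expansion_size for c in calls], dtype=float)
    n = sizes.size
    return SampleSummary(
        sample_id=sample_id,
        tissue=tissue,
        n_molecules=int(n),
        mean_size=float(sizes.mean()) if n else float("nan"),
        max_size=float(sizes.max()) if n else float("nan"),
        histogram=histogram_sizes(calls, bin_width),
        expanded_fraction=float((sizes > expanded_threshold).mean()) if n else 0.0,
        expanded_threshold=expanded_threshold,
    )


def plot_histogram(
    summary: SampleSummary, path: str, annotate_threshold: bool = True
) -> None:
    """Render a sample's 200 bp size histogram to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    h = summary.histogram
    width = 200 if h.empty else int(np.diff(np.sort(h["bin_start"].unique())).min(initial=200))
    ax.bar(h["bin_start"], h["count"], width=width, align="edge", color="#2c7fb8")
    if annotate_threshold:
        ax.axvline(summary.expanded_threshold, color="red", ls="--", lw=0.8)
    ax.set_xlabel("expansion size (bp)")
    ax.set_ylabel("molecules")
    ax.set_title(
        f"{summary.sample_id}: n={summary.n_molecules}, "
        f"mean={summary.mean_size:.0f} bp"
        if summary.n_molecules
        else f"{summary.sample_id}: no spanning molecules"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def calls_to_frame(calls: Iterable[MoleculeSizeCall]) -> pd.DataFrame:
    """Per-molecule sizing table (the pipeline's molecule-level output)."""
    return pd.DataFrame(
        [
            (c.molecule_id, c.observed_distance, c.expansion_size, c.repeat_estimate)
            for c in calls
        ],
        columns=["molecule_id", "observed_distance", "expansion_size", "repeat_estimate"],
    )
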