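"""End-to-end convenience: simulate -> align -> select -> size -> summarise."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import Aligner, Penalties, select_spanning
from .simulate import (
    LengthModel,
    LocusRegion,
    Molecule,
    NoiseModel,
    TissueProfile,
    simulate_molecules,
)
from .sizing import MoleculeSizeCall, SampleSummary, size_spanning_set, summarize_sample

__all__ = ["SampleRun", "run_sample"]


@dataclass
class SampleRun:
    """All intermediate products of one simulated sample analysis."""

    molecules: list[Molecule]
    truth: pd.DataFrame
    calls: list[MoleculeSizeCall]
    summary: SampleSummary
    n_aligned: int


def run_sample(
    profile: TissueProfile,
    region: LocusRegion,
    n_molecules: int,
    noise: NoiseModel | None = None,
    seed: int = 0,
    sample_id: str = "sample",
    tissue: str = "",
    penalties: Penalties | None = None,
    length_model: LengthModel | None = None,
    expanded_threshold: float = 2000.0,
) -> SampleRun:
    """Simulate one sample and run the full sizing pipeline on it.

    The aligner is given the locus interval as a size-cost-free gap so that
    arbitrarily expanded molecules still place on the reference.
    """
    molecules, truth = simulate_molecules(
        profile, region, n_molecules, noise=noise, length_model=length_model, seed=seed
    )
    locus = region.locus
    aligner = Aligner(
        region.labelmap,
        penalties=penalties,
        free_gap_interval=(locus.upstream[1], locus.downstream[1]),
    )
    alignments = [a for a in (aligner.align(m) for m in molecules) if a is not None]
    spanning = select_spanning(alignments, locus)
    by_id = {m.molecule_id: m for m in molecules}
    calls = size_spanning_set(spanning, by_id)
    summary = summarize_sample(
        calls, sample_id=sample_id, tissue=tissue, expanded_threshold=expanded_threshold
    )
    return SampleRun(
        molecules=molecules,
        truth=truth,
        calls=calls,
        summary=summary,
        n_aligned=len(alignments),
    )
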