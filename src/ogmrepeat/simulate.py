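"""Synthetic OGM molecule generator with tissue-specific repeat mosaicism.

Generates labelled single molecules from a diploid allele model over a
reference label map, with ground truth, so the sizing pipeline and the
downstream instability statistics can be exercised without external data.

The generator emulates the salient properties of a nanochannel OGM run at a
repeat locus: heavy-tailed molecule lengths (length-weighted median N50
above 150 kb), 14-17 labels per 100 kb, random label dropout and spurious
labels, Gaussian inter-label sizing noise with a floor, and collapse of
label pairs below the ~1 kb imaging resolution with a uniformly random
survivor.  Somatic mosaicism is modelled per allele: a degenerate (point)
tract, a truncated normal around the progenitor length (leukocyte-like low
instability), or a lognormal expansion mode thousands of repeats long
(corneal-endothelium-like extreme instability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .labelmap import LocusDefinition, ReferenceLabelMap, build_locus

__all__ = [
    "AlleleModel",
    "TissueProfile",
    "NoiseModel",
    "Molecule",
    "LengthModel",
    "LocusRegion",
    "sample_tract",
    "simulate_molecules",
    "make_locus_region",
    "leukocyte_like",
    "cec_like",
    "f35t_like",
    "paired_tissue_cohort",
    "synthesize_cohort",
    "label_density_per_100kb",
    "molecule_n50",
]


@dataclass(frozen=True)
class AlleleModel:
    """Mosaic tract-length distribution of one allele, in repeat units.

    kind:
        ``point``      -- no somatic variation, always ``progenitor_repeats``.
        ``truncnorm``  -- normal around the progenitor length, truncated at 0;
                          ``sd`` in repeat units.
        ``lognormal``  -- expansion cloud with modal length ``mode`` repeats
                          and log-scale spread ``sigma``.
    """

    progenitor_repeats: int
    kind: Literal["point", "truncnorm", "lognormal"] = "point"
    sd: float = 0.0
    mode: float | None = None
    sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.progenitor_repeats < 0:
            raise ValueError("progenitor_repeats must be >= 0")
        if self.kind == "truncnorm" and self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.kind == "lognormal" and (self.mode is None or self.mode <= 0):
            raise ValueError("lognormal allele needs a positive mode")


@dataclass(frozen=True)
class TissueProfile:
    """Diploid (unphased) allele pair for one tissue."""

    name: str
    allele_a: AlleleModel
    allele_b: AlleleModel


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters of the simulated assay.

    ``sizing_sd_fraction``/``sizing_sd_floor`` set per-interval Gaussian
    noise sd = max(floor, fraction * interval).  ``label_fn_rate`` drops each
    true label independently; ``label_fp_per_100kb`` adds spurious labels as
    a Poisson process.  Label pairs closer than ``resolution_limit`` collapse
    to a single, uniformly chosen survivor.  ``detection_floor`` documents
    the assay's ~500 bp lower size detection limit; it is a reporting aid,
    not a filter.
    """

    sizing_sd_fraction: float = 0.01
    sizing_sd_floor: float = 100.0
    label_fn_rate: float = 0.10
    label_fp_per_100kb: float = 0.5
    resolution_limit: int = 1000
    detection_floor: int = 500

    def __post_init__(self) -> None:
        for r in (self.label_fn_rate,):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.sizing_sd_fraction < 0 or self.sizing_sd_floor < 0:
            raise ValueError("sd parameters must be >= 0")

    @classmethod
    def none(cls) -> "NoiseModel":
        """Noise-free assay: exact positions, no dropout, no collapse."""
        return cls(0.0, 0.0, 0.0, 0.0, resolution_limit=0)


@dataclass(frozen=True)
class Molecule:
    """One simulated or parsed labelled DNA molecule."""

    molecule_id: int
    length: int
    label_positions: tuple[int, ...]  # 1-based offsets from molecule start
    origin: tuple[str, int, str] | None = None  # (contig, start bp, strand)
    truth_repeats: int | None = None

    def __post_init__(self) -> None:
        prev = 0
        for off in self.label_positions:
            if not (0 < off <= self.length):
                raise ValueError(
                    f"label offset {off} outside molecule (len {self.length})"
                )
            if off <= prev:
                raise ValueError("label offsets must be strictly increasing")
            prev = off


@dataclass(frozen=True)
class LengthModel:
    """Lognormal molecule-length distribution calibrated by its N50.

    For a lognormal, the length-weighted median (N50) is exp(mu + sigma^2);
    the median is exp(mu).  Lengths below ``min_length`` are redrawn,
    mirroring the instrument's minimum reported molecule size.
    """

    n50_target: int = 180_000
    log_sigma: float = 0.45
    min_length: int = 20_000

    @property
    def log_mu(self) -> float:
        return math.log(self.n50_target) - self.log_sigma**2

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = rng.lognormal(self.log_mu, self.log_sigma, size=n - filled)
            keep = draw[draw >= self.min_length]
            out[filled : filled + keep.size] = keep.astype(np.int64)
            filled += keep.size
        return out


@dataclass(frozen=True)
class LocusRegion:
    """A reference label map bundled with its repeat locus.

    ``tract_start`` is the 1-based position where the reference repeat tract
    begins (its reference extent is ``ref_repeat_count * repeat_unit_len``
    bp, between the flanking markers).
    """

    labelmap: ReferenceLabelMap
    locus: LocusDefinition
    tract_start: int

    @property
    def tract_end(self) -> int:
        return self.tract_start + (
            self.locus.ref_repeat_count * self.locus.repeat_unit_len
        )


def make_locus_region(
    contig_length: int = 1_000_000,
    density_per_100kb: float = 16.5,
    min_gap: int = 1200,
    ref_repeat_count: int = 24,
    repeat_unit_len: int = 3,
    seed: int = 20_240_914,
    contig_name: str = "region",
) -> LocusRegion:
    """Build a synthetic 1 Mb locus region mirroring the CTG18.1 geometry.

    The three locus-proximal labels reproduce the hg38 marker spacing: a
    10,288 bp marker interval containing the repeat tract, with a companion
    label 790 bp beyond the downstream marker (inside the imaging
    resolution).  Background labels are laid down as a renewal process with
    a hard minimum gap so that, other than the deliberate companion pair, no
    reference pair is sub-resolution.
    """
    rng = np.random.default_rng(seed)
    up = contig_length // 2
    down = up + 10_288
    comp = down + 790
    mean_gap = 100_000 / density_per_100kb
    exp_mean = mean_gap - min_gap
    if exp_mean <= 0:
        raise ValueError("density too high for the minimum gap")

    def walk(start: int, limit: int, sign: int) -> list[int]:
        out = []
        pos = start
        while True:
            pos = pos + sign * int(min_gap + rng.exponential(exp_mean))
            if not (1 <= pos <= limit if sign > 0 else pos >= limit):
                break
            out.append(pos)
        return out

    left = walk(up, 1, -1)[::-1]
    right = walk(comp, contig_length, +1)
    positions = left + [up, down, comp] + right
    labels = tuple((i + 1, p) for i, p in enumerate(positions))
    labelmap = ReferenceLabelMap(contig_name, contig_length, labels)
    up_id = len(left) + 1
    locus = build_locus(
        labelmap,
        upstream_id=up_id,
        downstream_id=up_id + 1,
        ref_repeat_count=ref_repeat_count,
        repeat_unit_len=repeat_unit_len,
        name="CTG18.1-like",
    )
    tract_start = up + 5_000
    return LocusRegion(labelmap, locus, tract_start)


# ---------------------------------------------------------------------------
# tract sampling


def sample_tract(allele: AlleleModel, rng: np.random.Generator | int) -> int:
    """Draw one somatic tract length (repeat units) from an allele model."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if allele.kind == "point":
        return allele.progenitor_repeats
    if allele.kind == "truncnorm":
        if allele.sd == 0:
            return allele.progenitor_repeats
        while True:
            x = rng.normal(allele.progenitor_repeats, allele.sd)
            if x >= 0:
                return int(round(x))
    if allele.kind == "lognormal":
        mu = math.log(allele.mode) + allele.sigma**2
        x = rng.lognormal(mu, allele.sigma)
        return int(round(x))
    raise ValueError(f"unknown allele kind {allele.kind!r}")


# ---------------------------------------------------------------------------
# molecule simulation


def _apply_noise(
    offsets: np.ndarray, length: int, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    # 1. label dropout
    if noise.label_fn_rate > 0 and offsets.size:
        offsets = offsets[rng.random(offsets.size) >= noise.label_fn_rate]
    # 2. spurious labels
    if noise.label_fp_per_100kb > 0:
        n_fp = rng.poisson(noise.label_fp_per_100kb * length / 1e5)
        if n_fp:
            fp = rng.integers(1, length + 1, size=n_fp)
            offsets = np.unique(np.concatenate([offsets, fp]))
    # 3. inter-label sizing noise (first label anchors the molecule frame)
    if offsets.size >= 2 and (noise.sizing_sd_fraction > 0 or noise.sizing_sd_floor > 0):
        gaps = np.diff(offsets).astype(float)
        sd = np.maximum(noise.sizing_sd_floor, noise.sizing_sd_fraction * gaps)
        gaps = np.maximum(1.0, gaps + rng.normal(0.0, 1.0, gaps.size) * sd)
        offsets = offsets[0] + np.concatenate([[0.0], np.cumsum(gaps)])
        offsets = np.round(offsets).astype(np.int64)
        offsets = np.minimum(offsets, length)
        offsets = np.unique(offsets)
    # 4. sub-resolution collapse, uniformly random survivor
    if noise.resolution_limit > 0 and offsets.size >= 2:
        kept: list[int] = []
        for off in offsets:
            if kept and off - kept[-1] < noise.resolution_limit:
                if rng.random() < 0.5:
                    kept[-1] = int(off)
            else:
                kept.append(int(off))
        offsets = np.asarray(kept, dtype=np.int64)
    return offsets


def simulate_molecules(
    profile: TissueProfile,
    region: LocusRegion,
    n_molecules: int,
    noise: NoiseModel | None = None,
    length_model: LengthModel | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[Molecule], pd.DataFrame]:
    """Simulate labelled molecules from a diploid tissue profile.

    Each molecule takes a random footprint on the reference contig and a
    random strand; reference labels inside the footprint are copied over.
    When the footprint contains the repeat tract, the reference tract is
    replaced by ``repeat_unit_len * sampled_repeats`` bp (shifting all
    downstream labels), then assay noise is applied.

    Returns the molecules and a truth table with one row per molecule:
    molecule_id, allele, truth_repeats, start, strand, covers_locus (does
    the footprint contain both flanking markers).
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    noise = NoiseModel.none() if noise is None else noise
    length_model = length_model or LengthModel()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    ref_pos = np.asarray(region.labelmap.positions, dtype=np.int64)
    locus = region.locus
    up_pos = locus.upstream[1]
    last_marker = (locus.companion or locus.downstream)[1]
    unit = locus.repeat_unit_len
    ref_tract_bp = locus.ref_repeat_count * unit
    contig_len = region.labelmap.contig_length

    lengths = length_model.draw(rng, n_molecules)
    molecules: list[Molecule] = []
    truth_rows = []
    for i in range(n_molecules):
        length = int(min(lengths[i], contig_len - 1))
        start = int(rng.integers(1, contig_len - length + 1))
        end = start + length  # footprint is (start, end]
        allele_name = "a" if rng.random() < 0.5 else "b"
        allele = profile.allele_a if allele_name == "a" else profile.allele_b
        repeats = sample_tract(allele, rng)
        strand = "+" if rng.random() < 0.5 else "-"

        offs = ref_pos[(ref_pos > start) & (ref_pos <= end)] - start
        covers_tract = start < region.tract_start and end >= region.tract_end
        delta = 0
        if covers_tract:
            delta = repeats * unit - ref_tract_bp
            offs = offs.copy()
            offs[offs > region.tract_start - start] += delta
            length += delta
        covers_locus = bool(start < up_pos and end >= last_marker)

        if strand == "-":
            offs = (length + 1 - offs)[::-1]
        offs = _apply_noise(np.asarray(offs, dtype=np.int64), length, noise, rng)

        molecules.append(
            Molecule(
                molecule_id=i + 1,
                length=length,
                label_positions=tuple(int(o) for o in offs),
                origin=(region.labelmap.contig_name, start, strand),
                truth_repeats=repeats if covers_tract else None,
            )
        )
        truth_rows.append(
            (i + 1, allele_name, repeats, start, strand, covers_locus)
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "molecule_id",
            "allele",
            "truth_repeats",
            "start",
            "strand",
            "covers_locus",
        ],
    )
    return molecules, truth


# ---------------------------------------------------------------------------
# tissue profiles matching the study's qualitative contrast


def leukocyte_like(
    short_repeats: int,
    long_repeats: int,
    base_sd: float = 2.0,
    sd_efold_repeats: float = 45.0,
) -> TissueProfile:
    """Low-instability diploid profile: truncated-normal mosaicism whose
    spread grows exponentially with the progenitor length."""

    def allele(p: int) -> AlleleModel:
        return AlleleModel(
            p, kind="truncnorm", sd=base_sd * math.exp(p / sd_efold_repeats)
        )

    return TissueProfile(
        f"leukocyte-like-{short_repeats}-{long_repeats}",
        allele(short_repeats),
        allele(long_repeats),
    )


def cec_like(
    short_repeats: int,
    expansion_mode_repeats: float = 5000.0,
    sigma: float = 0.12,
) -> TissueProfile:
    """Extreme-instability diploid profile: one near-stable short allele and
    one lognormal expansion cloud with a modal tract thousands of repeats
    long (modal range observed in diseased corneal endothelium:
    ~3,900-6,400 repeats)."""
    return TissueProfile(
        f"cec-like-{short_repeats}-{expansion_mode_repeats:g}",
        AlleleModel(short_repeats, kind="truncnorm", sd=2.0),
        AlleleModel(
            short_repeats,
            kind="lognormal",
            mode=expansion_mode_repeats,
            sigma=sigma,
        ),
    )


def f35t_like() -> TissueProfile:
    """Profile mimicking the F35T corneal endothelial line: a 21-repeat
    short allele (the one STR-PCR sees) plus a large expansion clustering at
    ~4500 repeats (13,500 bp)."""
    return TissueProfile(
        "F35T-like",
        AlleleModel(21, kind="truncnorm", sd=2.0),
        AlleleModel(21, kind="lognormal", mode=4500.0, sigma=0.015),
    )


def paired_tissue_cohort(
    n_subjects: int = 9, seed: int = 0
) -> list[dict]:
    """Synthetic subjects with paired leukocyte-like and CEC-like profiles.

    Progenitor genotypes mirror the study cohort: short alleles 11-31
    repeats, long expanded alleles 63-107 repeats; the CEC expansion mode is
    drawn from 3,900-6,400 repeats.  Ages span 54-83 years.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for s in range(n_subjects):
        short = int(rng.integers(11, 32))
        long = int(rng.integers(63, 108))
        cohort.append(
            {
                "subject_id": f"S{s + 1}",
                "age": int(rng.integers(54, 84)),
                "sex": "F" if rng.random() < 0.5 else "M",
                "progenitor_short": short,
                "progenitor_long": long,
                "leukocyte_profile": leukocyte_like(short, long),
                "cec_profile": cec_like(
                    short, expansion_mode_repeats=float(rng.integers(3900, 6401))
                ),
            }
        )
    return cohort


def synthesize_cohort(
    n_subjects: int,
    beta0: float = 4.5,
    beta_size: float = 0.02,
    beta_age: float = 0.01,
    beta_interaction: float = 0.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Subject-level cohort with a known log-linear mean-size law.

    log(mean_size) = beta0 + beta_size*(P - mean P) + beta_age*(age - mean
    age) + beta_interaction * centred product + noise.  Used for
    parameter-recovery checks of the regression layer.
    """
    rng = np.random.default_rng(seed)
    prog = rng.integers(50, 110, size=n_subjects).astype(float)
    age = rng.integers(40, 90, size=n_subjects).astype(float)
    cp = prog - prog.mean()
    ca = age - age.mean()
    log_mean = (
        beta0
        + beta_size * cp
        + beta_age * ca
        + beta_interaction * cp * ca
        + rng.normal(0.0, noise_sd, n_subjects)
    )
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1}" for i in range(n_subjects)],
            "progenitor_long": prog,
            "age": age,
            "mean_size": np.exp(log_mean),
        }
    )


# ---------------------------------------------------------------------------
# QC metrics


def label_density_per_100kb(molecules: Sequence[Molecule]) -> float:
    """Observed labels per 100 kb across a molecule set."""
    total_labels = sum(len(m.label_positions) for m in molecules)
    total_len = sum(m.length for m in molecules)
    if total_len == 0:
        return float("nan")
    return total_labels / total_len * 1e5


def molecule_n50(molecules: Sequence[Molecule]) -> int:
    """Length-weighted median molecule length."""
    lengths = np.sort(np.array([m.length for m in molecules], dtype=np.int64))
    if lengths.size == 0:
        return 0
    csum = np.cumsum(lengths)
    return int(lengths[np.searchsorted(csum, csum[-1] / 2.0)])
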