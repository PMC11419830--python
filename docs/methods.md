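# Methods

## Measurement model

A repeat locus is defined by an upstream flanking label, a downstream
flanking label and, optionally, a *companion* label within the imaging
resolution limit of the downstream marker.  Coordinates are 1-based
inclusive: subtracting the printed hg38 marker positions directly
reproduces the CTG18.1 marker distance (55,594,648 − 55,584,360 =
10,288 bp), which fixes the convention.

Two corrections define the reference distance against which molecules are
sized:

1. **Sub-resolution merging.**  Label sites closer than the resolution
   limit (default 1,000 bp) are imaged as one spot.  Merging is greedy
   left-to-right: a label within the limit of the current effective site is
   absorbed and the effective position moves to the pairwise mean, rounded
   half-up to integer bp (this rounding reproduces (55,594,648 +
   55,595,438)/2 = 55,595,043 exactly; the choice is only observable for
   odd position sums).  Chains of more than two labels are merged the same
   way and logged with a warning — the CTG18.1 geometry only ever merges a
   pair, so longer chains signal an unusual map.  A locus whose *upstream*
   marker has a sub-resolution neighbour is rejected: the averaging scheme
   has no defined behaviour there.
2. **Reference repeat subtraction.**  The reference's own repeat content
   (`ref_repeat_count × repeat_unit_len`, 24 × 3 = 72 bp for CTG18.1/hg38)
   is subtracted, so a molecule's expansion size equals its *full* tract
   length in bp rather than the excess over the reference.

Per molecule, the downstream anchor is the site paired to the downstream
marker or its companion; when both are present their mean molecule position
is used, mirroring the averaged reference position.  When only one is
present — the typical case once collapse has occurred — the molecule-frame
distance to that site is still compared against the *averaged* corrected
distance.  The estimate is then exactly ±g/2 around the truth (g = the
companion gap, 790 bp at CTG18.1) depending on which label survived:
per-molecule estimates are mean-zero but bimodal at ±395 bp.  This is a
property of the measurement itself, not of the simulation; it is why
cluster locations should be summarised by the cluster mean rather than by
the single most populated 200 bp histogram bin, and the package's own
checks locate the expanded cluster that way.

## Synthetic molecule generator

The generator emulates a nanochannel OGM run over a 1 Mb locus region (a
desk-scale stand-in for genome-wide coverage):

| parameter | default | rationale |
|---|---|---|
| reference label density | 16.5 / 100 kb | renewal process with a 1.2 kb minimum gap; with dropout and spurious labels the *observed* molecule density lands inside the 14–17 / 100 kb QC window |
| locus geometry | 10,288 bp marker interval, companion at +790 bp | mirrors CTG18.1 so all corrections are exercised |
| molecule lengths | lognormal, N50 = 180 kb, σ_log = 0.45, min 20 kb | heavy-tailed two-parameter family; length-weighted median (N50) of a lognormal is exp(μ+σ²), making calibration to the ≥150 kb QC target closed-form |
| label dropout | 10 % per label | typical single-label detection failure |
| spurious labels | 0.5 / 100 kb | rare non-specific labelling |
| interval sizing noise | sd = max(100 bp, 1 % of interval) | Gaussian per inter-label interval; at the ~24 kb expanded locus interval this contributes ~240 bp sd, consistent with an assay whose quoted lower detection limit is ±500 bp |
| sub-resolution collapse | pairs < 1,000 bp; survivor uniform at random | the random-survivor behaviour that motivates companion averaging |

Noise is applied in that order (dropout, spurious labels, interval
perturbation anchored at the first label, collapse).  With the noise model
zeroed the generator is exact: every spanning molecule's expansion size
equals 3 × its true repeat count, which the end-to-end tests assert
literally.

Somatic mosaicism is modelled per allele.  The distribution families are a
modelling choice (single-molecule data constrain the observed histograms,
not a generative law):

* **point** — degenerate, for exact arithmetic checks;
* **truncated normal** (≥0) around the progenitor repeat count — the
  *leukocyte-like* profile uses sd = 2 · exp(P/45) repeats so that spread
  grows exponentially with progenitor size P, matching the qualitative
  blood-leukocyte behaviour (detectable instability only for large
  progenitor alleles);
* **lognormal expansion** parameterised by its modal repeat count — the
  *CEC-like* profile draws the mode from 3,900–6,400 repeats, the modal
  range observed in diseased corneal endothelium; the *F35T-like* fixture
  uses mode 4,500 (13,500 bp) with σ_log = 0.015, a tight cloud appropriate
  for a clonal immortalised line.

The synthetic cohort (`paired_tissue_cohort`) pairs a leukocyte-like and a
CEC-like profile per subject with progenitor genotypes spanning 11–31
(short) and 63–107 (long, expansion-positive ≥ 50) repeats and ages 54–83.

What the generator does **not** model: optical point-spread simulation,
chimeric molecules or fragile sites, two-channel labelling, and
length-dependent capture bias (real instruments under-sample the longest
molecules).  Passing tests therefore demonstrate correctness of the
*pipeline arithmetic and statistics* under realistic noise, not robustness
to every instrument artefact; real-data users should import vendor
alignments rather than rely on the built-in aligner.

## Label aligner

The built-in aligner is a deliberate simplification used so synthetic data
can be processed end-to-end; it does not reproduce the vendor aligner or
its confidence model.  It maximises, over monotone pairings of molecule
sites to reference labels,

    score = 1.0·(pairs) − 0.4·(skipped interior reference labels)
            − 0.4·(unmatched molecule sites) − 3·10⁻⁶/bp² · Σ (Δq − Δr)²

by dynamic programming (numba kernel; transitions bounded at 4 consecutive
skips).  Both orientations are scored; ties prefer more matched pairs, then
the leftmost reference placement, then '+'.  The interval between the
locus flanking markers can be declared a *free gap*, exempt from the size
term, so molecules carrying arbitrarily large expansions still align.  The
size-cost default makes ordinary sizing noise cheap (300 bp mismatch ≈ 0.27)
while the 790 bp error of pairing a collapsed survivor with the wrong
member of the reference pair (≈ 1.9) is dearer than the correct
skip-one-label solution (0.4) — so the DP identifies the surviving label
from the downstream interval pattern.

An alignment that bridges the free gap is only trusted when it has at
least 3 matched pairs on each flank; one-sided alignments are kept (they
can never be selected as spanning).  Molecules with fewer than 5 labels
are not aligned.  On small instances the DP optimum is verified against
exhaustive enumeration of all monotone pairings.

Spanning selection keeps alignments matching the upstream marker and at
least one of the downstream/companion labels.  Under zero noise, every
truth-covering molecule with that flank support is recovered — the
end-to-end test computes the expected set from the truth table and map
geometry alone.

## Statistics

* All tests are two-sided; no multiple-testing correction (p-values are
  reported individually).
* **Anderson-Darling** composite normality (mean and variance estimated)
  with the standard small-sample modification and case-3 p-value
  approximation, via statsmodels.
* **Mann-Whitney**: exact enumeration of all group labelings for
  n₁+n₂ ≤ 12 (midranks, so ties are exact); otherwise normal approximation
  with tie and continuity correction.
* **Wilcoxon matched-pairs**: zeros dropped, |differences| midranked;
  exact 2ⁿ sign-flip enumeration for n ≤ 15, else normal approximation
  with tie-corrected variance.  Nine uniformly positive pairs give the
  exact two-sided p = 2/2⁹ = 0.0039.
* **Spearman** with a percentile bootstrap CI (default 2,000 resamples);
  resampling is at the subject level when subject ids are supplied, since
  molecules cluster within subjects and observation-level resampling would
  understate the CI.
* **Log-linear model**: OLS of log mean molecule size on progenitor
  long-allele size and age, both mean-centred before the interaction
  product is formed.  Centring leaves the fit invariant but removes the
  spurious correlation between a positive-valued main effect and its
  product term; the fit reports that correlation before and after centring,
  and rejects designs that remain collinear.  An allele of ≥ 50 repeats
  defines expansion-positive status.

Cohort-specific published quantities (correlation CIs, adjusted R² values)
depend on raw subject data that are not packaged; the statistics layer is
instead validated by parameter recovery on synthetic cohorts with known
coefficients.

## Problem sizes and determinism

The packaged checks simulate 2,000 molecules per profile for the noiseless
identity and the F35T-like fixture (~250–300 spanning molecules, matching
the scale of a real locus extraction) and 800 molecules per sample for the
9-subject paired tissue contrast; these sizes give stable cluster means
(standard error ≈ 50 bp at the expanded cluster) at interactive runtimes.
All randomness flows through explicit integer seeds; identical seeds yield
byte-identical BNX output.  `scripts/acceptance.py` derives all sub-seeds
from its `--seed` argument.

## Known limitations

* The aligner is only validated on synthetic data; vendor XMAP input is
  the supported route for real runs.
* Alleles are not phased and no mixture model is fitted to histograms;
  clusters are reported descriptively (threshold classifier at 2,000 bp,
  configurable).
* Single non-clustering molecules (likely misalignment artefacts in real
  data) are not filtered by default; an optional minimum-cluster-support
  filter would be a natural extension.
* The ±g/2 bimodality induced by random-survivor collapse is inherent to
  the averaged-reference correction; studies needing per-molecule accuracy
  below g/2 must resolve which label survived (the built-in DP usually
  can, but sizing deliberately follows the averaged-reference convention).
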