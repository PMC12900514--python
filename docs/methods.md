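# Methods

## The pause → premature-termination model

The simulator treats Pol I elongation as a site-by-site walk over the
L = 6859 nt 35S unit. At site x a molecule dwells for an
Exponential(mean τ(x)) time; during the dwell it is exposed to a constant
termination hazard κ (per dwell-time unit), so its per-visit release
probability is p(x) = 1 − exp(−κ·τ(x)). This is the simplest law with the
qualitative behaviour the assay family reports — longer pauses produce more
frequent release — and it has clean limits: κ = 0 gives p ≡ 0 (a
never-terminating enzyme), and p is monotone in both κ and τ.

Assumptions worth keeping in mind:

* **Memoryless dwells.** Pauses are single-rate exponentials. Backtracking
  and transcript-cleavage cycles are absorbed into τ(x) rather than
  modelled explicitly: occupancy profiling cannot distinguish them, and the
  downstream analytics see only residence time.
* **Occupancy by residence time.** Cross-linking captures an enzyme in
  proportion to the time it spends at a position, so read 3' ends are
  sampled with probability proportional to the total simulated dwell at
  each site — giving expected coverage ∝ O(x) = α·S(x)·τ(x), which counts
  the dwell of a molecule that terminates at x as well.
* **No sequence, no torsion, no processing.** Positions are bare
  coordinates; co-transcriptional assembly, supercoiling, and the 3'-end
  torpedo pathway are out of scope.

The walk is sampled exactly by inverting the discrete cumulative hazard
H(x) = Σ_{y≤x} −ln(1 − p(y)) against a unit-exponential draw per molecule
(identical in law to site-by-site Bernoulli termination, at vector speed).
Per-site dwell totals are drawn as Gamma(n(x), τ(x)) — the distribution of
the sum of the n(x) visiting molecules' exponential dwells — rather than
materializing an n×L dwell matrix.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| τ baseline | 1 | time (arbitrary) | sets the time scale; only ratios matter |
| 5'ETS pause sites | 8 sites at nt 60–285, τ = 80 | — | a strong early pause cluster inside nt 1–300, where occupancy accumulates and abortive transcripts originate |
| secondary pause sites | 4 sites at nt 3000–3300, τ = 25 | — | the weaker accumulation spanning the 5.8S / early-25S boundary |
| κ (wild type) | 9×10⁻⁵ | per dwell-time unit | puts the wild-type full-length fraction near 0.5, i.e. abortive output of the same order as productive output |
| α | 1 | initiations per time unit | scale-free; all outputs are ratios or per-million |
| replicates | 3 | — | the emulated study design |
| CRAC events / replicate | 50,000 | deduplicated events | desk-scale while keeping per-base counting error small |
| molecules / replicate | 5,000 | — | termination statistics; full-length-ratio SE ≈ 1% pooled |
| read length | 30 | nt | fixed; 5' ends clipped at position 1 |
| UMI length | 5 | nt | five random nucleotides in the 5' adaptor |
| PCR duplication | 1.0 | mean extra copies per fragment | Geometric-distributed; gives ≈50% duplicate reads, a realistic small-library rate |
| mask threshold c_min | 5 | raw counts | a position is excluded from the log2 ratio when any replicate of either condition has fewer counts |

Absolute dwell times and the termination rate constant are not measurable
from occupancy profiles, so all of these are calibration choices, fixed
once and documented here.

### Preset calibration

The `superpol` preset scales the 5'ETS-cluster τ by s and κ by g, with
(s, g) solved by 2-D root finding so that the closed-form steady state
gives a **normalized** 5'ETS occupancy-share ratio (WT/variant) of exactly
1.25 and a full-length ratio (variant/WT) of exactly 1.5. Shares are
normalized (O(x)/ΣO) because that is what per-million profiles measure.
The solved values are s ≈ 0.826, g ≈ 0.412; `preset_model("superpol")`
re-derives both ratios from `steady_state` on every construction and
refuses to return a model that misses them.

The `*-bmh21` presets multiply κ by 40 at pause sites only (sites with
τ above 10). Because per-million normalization rescales each profile, the
resulting log2-ratio track (untreated/treated) is depressed ahead of and
within the 5'ETS pause cluster and mildly elevated downstream, so the
maximum |log2 ratio| localizes to the configured cluster (nt 1–300); the
treated enzyme's absolute 5'ETS occupancy and full-length yield both drop.

## What the generator emulates — and what it does not

Emulated: three-replicate condition pairs; heavily non-uniform 3'-end
coverage concentrated in the 5'ETS and around the 5.8S/25S boundary;
UMI-tagged reads with Geometric PCR duplication sharing exact coordinates;
abortive-transcript length spectra dominated by early 5'ETS species;
slot-blot-style probe tables with 5S loading controls, an intergenic
background probe, and multiplicative lognormal noise.

Not emulated: sequencing errors in UMIs (duplicates are exact, so
deduplication is a clean key-collapse); antisense or genome-wide reads;
alignment artefacts (soft clipping, multimapping); biological replicate
heterogeneity beyond sampling noise; rDNA copy-number variation. Passing
tests therefore validate the arithmetic of the pipeline under the stated
statistical structure, not robustness to alignment- or chemistry-level
artefacts in real libraries.

One deliberate realism consequence: with 5-nt UMIs and fixed-length reads,
strong pause sites receive hundreds of events competing for 1024 UMIs, so
deduplication removes some genuine events there (UMI saturation). This
compresses measured condition ratios slightly below the closed-form
calibration (≈1.20 observed vs 1.25 generative for the 5'ETS share ratio
at default depth) — the same distortion a real library at this depth and
UMI complexity would show.

## Numerical and statistical choices

* **Deduplication key** is (start, end, strand, UMI); the first record in
  input order survives. Including strand is a no-op for sense-only data
  but correct when antisense reads are retained.
* **Normalization denominator** is reads mapped to the rDNA unit (the
  package sees nothing else); user-supplied tables should be pre-filtered
  to the unit.
* **Welch t-test, two-sided**, for all region and fold-change comparisons:
  the robust default at n = 3. Degenerate zero-variance comparisons with
  equal means report t = 0, p = 1. Stars: *** p<0.005, ** p<0.01, * p<0.05.
* **Envelope difference** is the gap between disjoint min–max envelopes
  (zero on overlap), a conservative lower bound on |Δmean|; the sign is
  positive where the first condition lies above.
* **CDF medians** use the first position at which the cumulative reaches
  0.5 (deterministic on step functions); the signed area between mean CDFs
  is Σ(C_A − C_B)/L, positive when A accumulates earlier.
* **Low-coverage masking** precedes the log2 ratio; any position that
  still has a zero mean at an unmasked position is force-masked rather
  than propagating ±inf.
* **5S normalization** divides by the mean (not sum) of the two 5S probes;
  ratios are scale-free so the choice is a fixed constant. Because all
  probes in a replicate share that denominator, their measured fold
  changes are positively correlated within one experiment — single-run
  composite fold changes scatter with SD ≈ 0.11 around the generative
  value at CV = 0.1, n = 3, while the 200-repetition mean is unbiased.
* **Lane-trace integration** is trapezoidal with interpolated window
  edges; the abortive-species window defaults to 70–90 nt and is a
  parameter, since reported band sizes are approximate.

## Problem sizes

Default analyses and the acceptance script use 3 replicates × 50,000
events × 5,000 molecules per condition — the scale at which per-region
sampling error is ≲1% and a full two-condition comparison completes in a
few seconds — and 200 repetitions for fold-change recovery statistics.

## Known limitations

* unit_length is parameterized; the packaged annotation uses the 6859-nt
  region map as canonical.
* The calibrated 1.25/1.5 contrasts are properties of the preset pair,
  not estimates of any enzyme's true kinetics; only their recovery
  through the pipeline is a testable claim.
* The hazard-multiplication treatment preset captures occupancy
  redistribution and yield loss, not drug-induced enzyme degradation.
* Minus-strand reads are parsed and retained in files but excluded from
  coverage by default (`strand_policy="both"` to include them).
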