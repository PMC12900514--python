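# polone

Comparative occupancy analytics for RNA polymerase I (Pol I) transcription,
built around a mechanistic simulator in which site-specific pausing is
coupled to premature termination of transcription (PTT).

## Who this is for

Groups profiling Pol I elongation on the ribosomal DNA (rDNA) unit with
CRAC- or NET-seq-style assays, where the 3' end of each recovered read marks
the polymerase position at nucleotide resolution. The package implements the
full desk-side analysis chain — PCR-duplicate removal, per-base 3'-end
coverage, per-million normalization, replicate envelopes, conservative
two-condition differencing, region statistics, CDF-shift analysis, and
slot-blot/northern densitometry arithmetic — together with a generative
model that reproduces the statistical structure of such experiments, so
every analysis step can be validated against a known ground truth.

## The model

A polymerase initiates at rate α and walks through sites x = 1..L of the
35S unit (default annotation: 5'ETS 1–700, 18S 701–2499, ITS1 2500–2858,
5.8S 2859–3019, ITS2 3020–3250, 25S 3251–6647, 3'ETS 6648–6859). At site x
it dwells for an exponential time with mean τ(x) and, while paused, is
exposed to a termination hazard κ, so it releases there (PTT, producing an
abortive transcript of length x) with probability

    p(x) = 1 − exp(−κ·τ(x))        — the longer the pause, the more likely
                                      the release.

The closed-form steady state follows from the survival product
S(x) = Π_{y<x} (1 − p(y)):

    J(x) = α·S(x)        flux        O(x) = J(x)·τ(x)   occupancy
    A(x) = J(x)·p(x)     abortive    F    = α·S(L+1)    full-length rate

with exact conservation α = F + Σ_x A(x). CRAC coverage samples O(x)
(cross-linking captures enzymes in proportion to residence time). Two
packaged presets put numbers on the biology: the `superpol` preset (a
hyperactive enzyme variant with shorter 5'ETS pauses and a lower hazard) is
calibrated so the normalized 5'ETS occupancy ratio WT/variant is exactly
1.25 and the full-length yield ratio variant/WT exactly 1.5; the `*-bmh21`
presets multiply κ at pause sites only, emulating a drug that targets
paused elongation complexes.

## Worked example

Simulate both enzymes (3 replicates × 50,000 CRAC events each), run the
read pipeline, and compare:

```sh
python analysis/01_simulate.py
python analysis/02_crac_pipeline.py
python analysis/03_compare_wt_superpol.py
```

The comparison step prints per-region summed frequencies (hits per million)
with Welch t-tests:

```
region        mean_a        mean_b          t        p stars
 5'ETS 205474.444920 171070.244669  25.941643 0.000015   ***
   18S 276672.943445 256778.560204  13.582210 0.000182   ***
  ITS1  50539.193446  49105.219452   0.942045 0.403710    ns
   ...
 3'ETS  19677.864393  24725.252838 -11.981460 0.001875   ***

5'ETS frequency ratio WT/SuperPol: 1.201 (calibrated closed form 1.25)
CDF median positions: WT 2625 nt, SuperPol 3001 nt (SuperPol shifted
376 nt rightward; signed area 0.0384)
```

Read: the wild-type enzyme piles up ~1.2× more normalized occupancy in the
5'ETS (the calibrated ground truth is 1.25; UMI saturation at strong pause
sites compresses the measured ratio slightly, see `docs/methods.md`), while
the variant's cumulative occupancy distribution is shifted toward the 3'
end — less early pausing, more productive elongation. `analysis/04_bmh21.py`
then localizes drug-induced occupancy loss (max |log2 ratio| inside the
5'ETS pause cluster), and `analysis/05_blot_quantification.py` recovers
generative fold changes from simulated densitometry tables.

The same steps are available as a CLI for user-supplied read tables:
`polone simulate|dedup|coverage|aggregate|compare|regions|cdf|quant|abortive`
(see `polone --help`).

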