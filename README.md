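# mwibeam

Radar-based microwave breast imaging in Python: rotation-subtraction skin
removal, confocal delay-and-sum (DAS) / delay-multiply-and-sum (DMAS)
beamforming, and the iteratively corrected DMAS (IC-DMAS) refinement, with a
synthetic multistatic acquisition simulator so that the entire chain runs at
desk scale — no antenna array, network analyzer or turntable required.

## Who this is for

Researchers prototyping confocal microwave imaging reconstruction: the
package turns a frequency-domain multistatic data cube *S(f, tx, rx, φ)* —
complex scattering parameters over frequency, transmit antenna, receive
antenna and rotation position — into a scattering-intensity map with
quantitative quality metrics. Its own simulator emulates the canonical
acquisition (8 Tx × 8 Rx interleaved on a cylinder, 50 rotations at 7.2°,
201 frequency points over 2.7–8.0 GHz) with a rotation-invariant skin
reflection, weak point-scatterer tumors, tissue retardation and complex
Gaussian noise.

## The reconstruction chain

1. **Rotation subtraction.** Split the cube by rotation parity and
   difference paired frames:
   `S_skin_removed(f,tx,rx,φ_odd) = S_odd − S_even`.
   The air–skin reflection is identical at every rotation, so it cancels
   exactly; tumor responses move with the array and survive.
2. **Time synthesis.** A band-limited inverse Fourier transform, with the
   band at its true position, yields real signals Γ(t, tx, rx, φ_odd) with
   Δt = 1/(pad · N_f · Δf).
3. **Delays.** Two-way propagation delays through the background medium:
   `τ(i,tx,rx,φ_odd) = √ε_b (P_tx→i + P_i→rx) / c`.
4. **Beamforming.** Per voxel, channels are aligned by τ and scored at the
   expected arrival: DAS squares the coherent sum; DMAS sums products over
   all unordered distinct channel pairs, computed with the identity
   `Σ_{k<k'} x_k x_k' = ((Σx)² − Σx²)/2`.
5. **Iterative correction (IC-DMAS).** Tissue slows propagation, so the
   background delays underestimate true round-trip times. Each iteration
   smooths the map with a distance-inverse kernel `w ∝ 1/(1+p(i,j))`,
   converts the normalized result into extra path
   `τ′ = τ + path_scale·Υ̂′(i)/c`, re-beamforms, and stops when the L1
   distance between successive peak-normalized maps falls below 10⁻⁵ (at
   most 7 iterations).
6. **Metrics.** Signal-to-mean ratio `SMR = 10·log₁₀(tumor energy / mean
   energy)` in both its peak and region-mean variants, plus localization
   error against ground truth.

A small side module provides the closed-form LC circuit model of the
metasurface unit cell that loads the physical antennas
(`f = 1/(π√(LC))`, split capacitance `ε₀ε_r A/d`, microstrip inductance).

## Worked example

`python examples/01_single_tumor_reconstruction.py` simulates a skin ring
with one 8.5 mm-offset tumor, reconstructs it three ways and prints:

```
true tumor position: (8.5, 8.5) mm
DAS      argmax (  8.0,  16.0) mm, error  7.5 mm, SMR peak  9.47 dB, region-mean  5.66 dB
DMAS     argmax (  8.0,  16.0) mm, error  7.5 mm, SMR peak 10.52 dB, region-mean  6.21 dB
IC-DMAS  argmax (  6.0,  14.0) mm, error  6.0 mm, SMR peak 12.63 dB, region-mean  8.68 dB
IC-DMAS ran 7 iterations; E history: ['7.55e+01', '1.39e+00', ..., '8.85e-07']
```

The uncorrected beamformers place the peak several millimeters outward —
the signature of air-assumed delays underestimating the tissue path — and
the iterative correction pulls it back while raising both SMR variants by
~2 dB. `examples/03_two_tumor_detection.py` shows the same effect on a noisy
two-tumor phantom (localization error 17 mm → 6 mm per tumor), and
`examples/02_skin_artifact_removal.py` demonstrates the exact skin
cancellation (the skin dominates the raw data by two orders of magnitude
and vanishes identically after subtraction).

The same chain is scriptable from the shell:

```bash
mwibeam simulate --seed 1 --out dataset.csv
mwibeam reconstruct --algorithm icdmas --in dataset.csv --out image.txt
mwibeam metrics --in image.txt --truth '[[0.0085, 0.0085, 0.0]]'
mwibeam run --seed 1 --out results/   # end-to-end with summary.json
```

## Layout

- `src/mwibeam/geometry.py` — array, grid, distance and delay tables
- `src/mwibeam/simulate.py` — phantom presets and the forward model
- `src/mwibeam/preprocess.py` — rotation subtraction, time synthesis
- `src/mwibeam/beamform.py` — DAS and DMAS
- `src/mwibeam/correction.py` — the IC-DMAS loop
- `src/mwibeam/metrics.py` — SMR and localization error
- `src/mwibeam/unitcell.py` — LC circuit closed forms
- `src/mwibeam/io.py`, `pipeline.py`, `cli.py` — persistence, end-to-end run,
  command line
- `docs/methods.md` — model assumptions, parameter choices, limitations
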