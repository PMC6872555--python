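# Methods

This note records the model this package implements, the design choices made
where the problem left them open, and what the synthetic study conditions do
and do not establish about real measurements.

## Acquisition model

A cylindrical array of interleaved transmit and receive antennas surrounds
the object and steps through a full rotation. Transmit antennas sit at
`k·360/n_tx` degrees, receivers offset by half the transmit spacing (uniform
bistatic coverage); rotation index `k` places the array `k·phi_step` degrees
past those base angles, counter-clockwise. All indices at the API surface
are 1-based (tx = 1..8, φ = 1..N_φ), matching how multistatic rigs are
usually logged. The full-scale configuration is 8×8 antennas, 50 rotations
at 7.2°, 201 frequency points over 2.7–8.0 GHz; the desk-scale configuration
used by the test suite and the acceptance script is 4×4 antennas, 10
rotations at 36°, 101 frequency points, a 2 mm imaging grid over an
80 mm × 80 mm slice. Both run in seconds.

## Forward model (synthetic data)

The simulator is a scalar Born-type point-scatterer model: each scatterer
contributes `a/(d_tx·d_rx) · exp(−j2πf·τ)` per channel, with 1/r spreading
per leg and two-way delay through the background medium. Three features of
measured data matter to the reconstruction chain and are modeled explicitly:

* **Skin reflection** — an additive term per (f, tx, rx), identical across
  rotation positions by construction, 100× the tumor reflectivity (the
  air–skin return dominates raw data by orders of magnitude). Its path runs
  via the skin-ring point between each antenna pair. Rotation subtraction
  cancels it exactly because it is exactly rotation-invariant; that is the
  premise of the subtraction step, not an approximation of it.
* **Interior retardation** — scatterer responses accumulate extra electrical
  path `(√ε_int − √ε_b)·L_chord` along the ray chords inside a retarding
  disk (effective relative permittivity 1.2, radius = skin radius). This is
  the physical error the iterative delay
  correction exists to remove: delays computed for the air background
  underestimate the true round-trip times through tissue. With
  `interior=None` the model reduces to pure background delays, which is the
  configuration the delay-oracle and linearity tests use. The effective
  permittivity is deliberately mild (1.2, i.e. ~30 ps of common two-way
  retardation at the preset tumor positions): the correction adds a *common*
  per-voxel delay, so only the channel-averaged part of the retardation is
  correctable, and the study conditions are chosen so that the correctable
  part dominates. Real breast tissue is far more strongly retarding and
  dispersive; a matched `path_scale` and a better propagation model would be
  needed there.
* **Noise** — i.i.d. circularly-symmetric complex Gaussian per sample from a
  single seeded stream. The "moderate" level used in the two-tumor study is
  defined relative to the data, not as a magic constant: σ = 0.1 × RMS of
  the noiseless scatterer-only response (≈20 dB per-sample SNR on the tumor
  signal), computed at run time.

Optional tissue dispersion (complex permittivity `ε_r + iσ/(ωε₀)`) modulates
scatterer reflectivity across the band, normalized at the band center; it is
off by default because the reconstructor only assumes geometric delays.

### Preset phantoms

Presets mirror a skin/fat/gland phantom series: A (no tumor), B (one tumor),
C (two tumors). Tumors sit at mid-radius offsets (8.5, 8.5) mm and, for C,
the point reflection (−8.5, −8.5) mm. Two structural facts drove this
placement, both documented because they are properties of the *method*, not
of this implementation:

1. Rotation subtraction leaves a sign-flipped replica of every scatterer at
   its position rotated by one rotation step. Rotating the whole scene by
   −phi_step maps the odd-rotation acquisition onto the even one, so the
   replica's beamformed magnitude equals the truth's essentially exactly;
   which of the two wins the global argmax is a tie decided by sub-percent
   numerical margins. The replica sits `2r·sin(phi_step/2)` from the truth —
   negligible at 7.2° but ~7 mm at the desk-scale 36° step — so mid-radius
   placement keeps it inside the main response blob.
2. The point-symmetric two-tumor layout is invariant under the array's 180°
   rotational symmetry, so both tumors provably see identical imaging
   conditions and behave identically; this was verified stable across noise
   seeds.

## Preprocessing

The differenced spectra are synthesized to the time domain with the band at
its true position (zeros implied below band), so delays map to true
round-trip times: `y(t_k) = (1/N_f)·Σ_n w_n S(f_n) e^{+2πi f_n t_k}` on
`N_t = pad·N_f` samples with `Δt = 1/(pad·N_f·Δf)` (record length 1/Δf,
≈37.7 ns for the full band). Defaults: Hann window (sidelobe suppression
materially affects DMAS clutter) and pad factor 4. One eighth of the record
is placed ahead of t = 0 so that wavelets whose corrected arrival falls at
or slightly before zero keep their left tail. The real part is retained as
Γ because the beamformer multiplies signed signals; envelopes are display
only. With no window and no padding the synthesis satisfies the discrete
Parseval identity exactly, which the tests check.

## Beamforming and the coherence gate

Per voxel, every channel is aligned by its delay (`x_c(t) = Γ_c(t + τ)`,
linear interpolation, zero outside the record) and scored at the expected
arrival. DAS squares the coherent sum; DMAS sums products over all unordered
distinct channel pairs of the flattened (tx, rx, φ_odd) set, evaluated with
the `((Σx)² − Σx²)/2` identity and verified against explicit pair
enumeration. A printed variant of the pair ranges (φ′ ≥ φ, tx′ ≥ tx,
rx′ ≥ rx+1) skips cross terms; it is available as `pair_mode="literal"` for
comparison but the unordered-pair reading is the standard construction and
the default.

The default score is the single time sample at the aligned arrival — the
classic confocal evaluation. This choice is load-bearing: integrated over
the whole record, every pairwise product is a cross-correlation at a fixed
channel-pair lag, *invariant* under a delay shift applied equally to all
channels, which is exactly the shift the iterative correction applies — the
correction would be a provable no-op. Worse, a window of about a carrier
period sampled at quarter-period spacing (what pad factor 4 produces over
this band) scores `1 + sin²θ` in the common phase offset θ, actively
rewarding misalignment. Scored at the arrival itself, a common delay error
Δτ costs `cos²(2πf_c·Δτ)` — ~6 dB at the 30 ps retardation of the study
conditions — which the correction then visibly recovers. Full-record
integration remains available (`gate=None`), as do explicit windows.

Signed products are summed as-is; maps may go negative. Metrics and display
clamp at zero, the raw map is preserved.

## The iterative correction

Iteration 0 is plain DMAS. Each subsequent iteration: (1) smooth the
previous map with the distance-inverse kernel `w(i,j) ∝ 1/(1 + p(i,j))`,
row-normalized, distances in grid-spacing units (a convex smoother: it
preserves uniform maps and contracts the range; note that row normalization
can make the far boundary voxel of a finite grid tick up slightly, so the
monotone-decay property holds away from edges); (2) clamp the smoothed map
at zero, normalize to peak 1, and add `path_scale·Υ̂′(i)/c` to every delay of
voxel i — corrections only ever lengthen the assumed path; (3) re-beamform;
(4) evaluate `E = Σ_i |Υ̂ⁿ − Υ̂ⁿ⁻¹|` on peak-normalized maps and stop when
E < threshold (default 10⁻⁵) or after max_iter (default 7) iterations.

Peak-normalizing before the E comparison makes the 10⁻⁵ threshold scale-free;
the raw L1 difference would depend on the data's absolute scale and make a
fixed threshold meaningless. `path_scale` (meters of maximum added
electrical path) defaults to 0.01 m, chosen to match the ~0.01 m of two-way
retardation the study conditions embody: a correction scale far above the
actual delay error over-corrects and blurs. With `path_scale = 0` the loop
reproduces plain DMAS exactly and terminates after one iteration with E = 0.

## Metrics

SMR is reported as `10·log₁₀(tumor_energy / mean_energy)` with "energy" the
zero-clamped intensity (the DMAS map is already a quadratic quantity; a
`squared=True` flag applies the squared convention). Two variants exist in
the literature — maximum over the tumor region, and region mean — and both
are implemented because results tables rarely state which was used. The
tumor mask is a sphere (default radius 5 mm) around each true position.
Localization takes the k strongest local maxima separated by at least 2 grid
spacings (configurable; the two-tumor analysis uses 12 mm so that a response
and its rotation replica merge into one detection) and greedily matches them
to truths; unmatched truths are reported as missed detections, never raised.

## Unit-cell circuit model

`f = 1/(π√(LC))`, `C = ε₀ε_r A/d`, and the microstrip inductance
`L(nH) = 2·10⁻⁴·l·[ln(l/(w+t)) + 1.193 + 0.02235(w+t)/l]·K_g` with l, w, t
in micrometers (the convention under which the prefactor yields nH; the API
takes millimeters and converts). `K_g = 0.57 − 0.145·ln(w′/h′)` where one
printed source defines w′ as the substrate thickness and h′ as its width —
the reverse of the usual convention; both orderings are exposed via a flag
(default as-printed) rather than silently corrected. Non-physical regimes
(K_g ≤ 0, or strips short enough to flip the bracket's sign) warn and flag
rather than raise.

## What the synthetic results do and do not show

The desk-scale runs demonstrate that the chain is implemented correctly and
that the iterative correction recovers a genuine, physically-modeled delay
error: on the frozen study conditions IC-DMAS improves SMR by ~1–3 dB in
both modes and localization error never worsens. They do not reproduce any
hardware-measured SMR table: those numbers depend on antenna transfer
functions, real heterogeneous tissue, calibration and clutter that the
point-scatterer model does not contain. Known limitations: no antenna
patterns or mutual coupling; no skin refraction (the skin term is exactly
rotation-invariant by construction); retardation is a homogenized disk, not
a dielectric map; the rotation-subtraction replica is inherent to the method
and bounds achievable localization accuracy at coarse rotation steps; and
the truth-vs-replica argmax tie means single-argmax localization on
noiseless symmetric scenes is decided by small numerical margins (the
shipped study conditions were verified stable across noise seeds).
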