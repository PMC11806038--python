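# wingshear

Quantification of tissue flow gradients, planar-polarity nematics and
junctional protein stability in tracked epithelia.

During *Drosophila* pupal wing morphogenesis, anisotropic tissue stress from
hinge contraction drives a proximal-distal (PD) flow of cells in which
adjacent rows move at different speeds. This *gradient of cell flow* exerts
shear on cell-cell junctions aligned with the flow and destabilises core
planar-polarity proteins (Frizzled, Flamingo) on those junctions — a
tissue-level cue for global polarity alignment. `wingshear` implements the
quantification machinery needed to measure this process in segmented,
tracked time-lapse data:

- **Tissue velocity gradients** — per-cell velocities from tracked
  centroids are coarse-grained onto a grid (one to two centroids per
  element), differenced forward into a 2×2 velocity-gradient tensor
  D = ∂(vₓ,v_y)/∂(x,y), rotated into the frame of the nematic mean flow
  direction θ = ½·atan2(v̄_y, v̄ₓ) with
  (v̄ₓ, v̄_y) = n⁻¹ Σₖ |vₖ|² (cos 2φₖ, sin 2φₖ), and aggregated as the mean
  absolute off-diagonal component ⟨|∂v′ₓ/∂y′|⟩ (min⁻¹) — the relative
  motion of adjacent cell rows along the flow axis.
- **Planar-polarity nematics** — per-cell polarity from the
  intensity-weighted second moment of boundary directions (magnitude
  (λ₁−λ₂)/(λ₁+λ₂) ∈ [0,1], axial angle), coarse-grained nematic averages,
  axial circular variance, 20-bin weighted circular histograms and cell
  eccentricity.
- **Tandem fluorescent-timer stability** — the mKate/sfGFP intensity ratio
  S reporting the relative stable protein fraction, pooled over a wing or a
  junction class (Σ I_mKate / Σ I_sfGFP) or per junction (mean-intensity
  ratio), with percent-change metrics (X_t − X₀)/X₀ × 100 for density,
  length and stability.
- **Topological events** — T1 neighbour exchanges (lost edge A–B, gained
  edge C–D with persistence / no-reversion rules) and sliding junctions
  (4-way → 3-way vertex transitions), with post-event accumulation profiles
  and sliding-vs-control stability comparisons.
- **Ablation and FRAP** — circular-wound ellipse fits and the anisotropic
  recoil velocity v_a = (v_maj − v_min)/2 as a stress-anisotropy proxy;
  one-phase exponential association fits
  F(t) = F₀ + (plateau − F₀)(1 − e^(−kt)) to normalised FRAP recovery.
- **Synthetic tissue generator** — fully ground-truthed tracked meshes
  (jittered hex-lattice Voronoi) advected by uniform / shear / rotational
  flows, two-channel timer intensities with shear-coupled stability, and
  injected T1 / sliding events, so every stage is testable without any
  microscopy data.

## Worked example

Generate a sheared tissue whose timer stability is coupled to the local
shear, then run the pipeline:

```sh
wingshear simulate --preset fig4-like --rows 12 --cols 12 --frames 9 \
    --gamma 0.01 --beta 20 --noise 0.02 --seed 1 -o scene/
wingshear all -i scene/ -o results/
cat results/report.md
```

```
# wingshear run report

- seed: 0
- flow direction theta (deg, axial): 0.000
- window |dv'x/dy'| (1/min): 0.01
- window |dv'y/dx'| (1/min): 0
- S[wing/all] = 0.393787 (n=261)
- S[class/horizontal] = 0.300153 (n=256)
- S[class/vertical] = 0.499107 (n=156)
- coarse-grain polarity: magnitude 0.1607, angle 16.03 deg
- polarity angle variance: 0.2953
```

The recovered tissue gradient |∂v′ₓ/∂y′| equals the imposed shear rate
0.01 min⁻¹; the flow axis is the PD (x) axis; and the stable fraction S is
markedly lower on flow-parallel (horizontal) junctions (0.30) than on
vertical ones (0.50) — exactly the shear-destabilisation signature the
pipeline is built to detect. The coarse-grained polarity axis sits near the
painted PD axis (0°), displaced a little by the shear advecting junction
orientations over the 2-h window and by the intensity noise.

The same stages are available as library calls (`wingshear.flow`,
`wingshear.polarity`, `wingshear.junctions`, `wingshear.ablation`,
`wingshear.mesh`, `wingshear.synthetic`) and as further subcommands
(`gradient`, `ablation`, `frap`).

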