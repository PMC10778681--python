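# Methods

## Model overview

`helixgauge` treats the DNA duplex as a discrete ribbon: the two backbone
curves bound a surface whose centerline — the helical axis — is traced by
the midpoints of paired backbone representative points. The geometry of that
axis, expressed through a discrete frame and its Euler angles, feeds a
Landau-type free-energy density with a chiral gauge term. The package
evaluates this energy on given structures; it does not minimize it or
predict equilibrium conformations.

Stages, each behind its own module:

1. **structure_io** — PDB parsing (gemmi), reduction of each nucleotide to
   the mean of C3′, C4′, O3′, C1′ (both prime and asterisk atom-name
   dialects accepted; alternate locations resolved to highest occupancy;
   first model used unless another is requested). Strands are paired
   positionally (index reversal, antiparallel), truncated to the shorter
   strand; Watson–Crick complementarity is a recorded validation flag, not
   the pairing driver — modified nucleotides carrying the four sugar atoms
   are accepted. Units missing sugar atoms are flagged and skipped, never
   silently dropped.
2. **axis_frame** — midpoint axis r_i, converted once from Å to nm
   (curvatures ~0.5 nm⁻¹ and the elastic prefactor are only dimensionally
   sensible on the nm scale); arc steps Δs_{i,i−1} = |r_i − r_{i−1}|, with
   consecutive points closer than 0.01 nm rejected as degenerate. Frames
   t_i, b_i = t̂_{i−1}×t̂_i, n_i = b_i×t_i; sites with
   |t_{i−1}×t_i| < 10⁻⁸ (locally collinear axis) are marked invalid,
   excluded from statistics and counted.
3. **euler_series** — transfer rotations R_{i+1,i} = F_{i+1}F_iᵀ (frames as
   row-stacked (n, b, t) matrices) and their ordered cumulative products;
   zyz Euler angles; gauge potential (below).
4. **geometry** — k_n = Δβ/Δs, k_g = −(Δα/Δs)sin β_i, τ_g = (Δα/Δs)cos β_i,
   k = √(k_g²+k_n²), τ = τ_g + Δχ/Δs − Δρ.
5. **energy** — per-site free energy, its split into geometric (Fs) and
   effective-potential parts, chirality call, per-structure summaries.
6. **model / cli** — a Model→fit()→Results interface over the stages, and
   `analyze`/`simulate` commands.

## Euler-angle and gauge conventions

All matrices here are proper rotations; zyz means R = Rz(α)·Ry(β)·Rz(γ),
angles stored in [0, 2π) (negative atan2 branches shifted by +2π), with the
gimbal convention γ = 0, α = total z-rotation when sin β < 10⁻⁸.

A per-site orientation must be referenced to something. Referencing each
frame to the *first frame* splits the per-step twist between α and γ in a
geometry-dependent way and destroys the interpretation of the angles. The
package therefore expresses each site's absolute orientation (the cumulative
transfer rotation composed with the anchor frame, R_{i,1}F₁ = F_i) in
**helix-aligned coordinates**: the structure's mean tangent direction is
rotated onto +z by the minimal rotation, making the decomposition
orientation-independent — analyses of the same structure in different PDB
frames give identical angles. In these coordinates

* α is the precession of the base-pair frame about the helical axis,
* β is the tilt of the local tangent away from it (≈ 0.35 rad for a
  canonical B helix),
* γ is the spin of the frame about its own tangent.

The **helical phase** is defined as χ = α + γ (mod 2π). Its period-corrected
step — the minimal signed wrap of χ_{i+1} − χ_i into (−π, π] — is the gauge
potential Δρ ≡ Δχ, the signed rotation angle between consecutive base
pairs. On an ideal duplex it equals the generator twist essentially exactly
(α advances by the twist per step and γ is constant; the small residual
comes from the finite-length mean-tangent estimate). Two properties motivate
this definition:

* it is continuous through the gimbal singularity β → 0 (a perfectly
  straight, axis-aligned duplex still has a well-defined twist), where α and
  γ separately are chart artifacts;
* mirror reflection of the structure negates it *exactly*: the aligned
  mirror configuration is a fixed vertical-plane reflection of the aligned
  original, so every azimuthal quantity flips sign at machine precision.

Right-handed helices have Δρ > 0, left-handed Δρ < 0. The classifier calls
"right"/"left" when the mean over evaluable sites exceeds ±0.05 rad and
"ambiguous" inside that band (the band guards against noise-dominated or
nearly untwisted traces; 0.05 rad is ~8% of a canonical twist).

The minimal signed wrap is used for all angular differences. A one-sided
"+2π to the latter point" correction handles only right-handed steps; the
symmetric wrap reduces to it for right-handed rotation and produces the
negative steps a left-handed helix requires.

### Site accounting ("blind spots")

The tangent consumes one neighbour, the binormal a second, and the angle
chain one further site at the head; the package follows the published
accounting in which exactly **four** terminal sites — two at each end — lack
a complete free-energy evaluation. A clean N-bp duplex therefore has N − 4
evaluable sites, and valid + invalid + blind = N in every summary.

## Free energy

Per evaluable site,

F_i = (B_i/2)(k_n²+k_g²) + (C_i/2)(τ_g + Δχ/Δs − Δρ)² + (d₁/2)(Δρ/Δs)² + τ_c·Δρ

with B_i = (b/Δs)·10⁻¹·4.1×10⁻²¹ J, C_i = (c/Δs)·10⁻¹·4.1×10⁻²¹ J,
d₁ = D₁/ω₀². Fs collects the first two (geometric) terms; the d₁ and τ_c
terms form the effective potential. F = Fs + potential holds elementwise by
construction and is cross-checked in tests against an independent
term-by-term evaluation.

Parameters, defaults, units:

| parameter | default | unit | meaning |
|---|---|---|---|
| b | 50 | nm | bending persistence length (literature-typical B-DNA) |
| c | 100 | nm | twisting persistence length |
| D₁ | 4.1×10⁻²¹ | J | effective-potential scale |
| ω₀ | 0.6 | rad/bp | reference twist; d₁ = D₁/ω₀² |
| τ_c | −7.9×10⁻²¹ | J | critical torque; negative ⇒ rewards right-handed twist |

b and c are deliberately visible configuration: absolute F scales with them
and they are not observables of a single structure, so reported energies are
comparative, not absolute. The overall torsion τ = τ_g + Δχ/Δs − Δρ mixes
rad/nm with rad once discretized (Δρ = Δχ is a per-step angle); it is kept
in the model's literal form and reported in "model units".

The mixed index pairing Δ(angle)_{i+1,i} / Δs_{i,i−1} is the model's printed
convention and the default (`step_pairing="paper"`); a `"forward"` mode
(Δs_{i+1,i}) exists for sensitivity checks. On uniform helices the two
coincide.

Because τ_c < 0 is the only chirally asymmetric term, a right-handed duplex
and its exact mirror differ in mean free energy by −2·τ_c·⟨Δρ⟩ ≈ +9.5×10⁻²¹ J
per site in favour of the right-handed form — the testable core of the
B-cheaper-than-Z ordering. Between *non*-mirror-matched forms (e.g. the
default B and Z generators) the quadratic geometry terms differ by far more
than the τ_c term, so the energy ordering there reflects geometry choices,
not chirality alone.

## Synthetic generator

`ideal_duplex(HelixSpec)` places both strands' backbone points on a common
cylinder: strand A at azimuth i·twist, height i·rise; strand B at azimuth
i·twist + gap, same height; chain B listed in its own 5′→3′ order
(antiparallel). Because the strand phase gap is not 180°, the midpoint axis
is itself a helix of radius backbone_radius·|cos(gap/2)| — emulating the
groove asymmetry that makes real helical axes genuinely curved. Four
pseudo-atoms C3′, C4′, O3′, C1′ sit at tetrahedral offsets scaled by
`atom_jitter` (randomly oriented per site from `seed`); the offsets sum to
zero, so their mean reproduces the backbone point exactly at any jitter.

Defaults:

* **B form** — twist +2π/10.5 rad/bp, rise 0.34 nm, backbone radius
  0.94 nm, gap 154° (canonical fiber-diffraction values); axis radius
  0.211 nm, closed-form axis curvature ≈ 0.57 nm⁻¹.
* **Z form** — twist −2π/12 rad/bp, rise 0.37 nm, alternating d(CG), gap
  167°, chosen so the axis curvature ≈ 0.21 nm⁻¹, the scale observed for
  left-handed duplexes; all fields overridable.

What the generator does **not** emulate: sequence-dependent roll/slide/
propeller, base atoms beyond the four sugar pseudo-atoms, bending of the
global axis, thermal disorder beyond isotropic pseudo-atom jitter, solvent.
Passing tests on generator output therefore demonstrate correctness of the
geometry/energy machinery on regular helices, not fidelity to any particular
experimental structure; real structures add noise that chiefly widens the
per-site distributions.

`continuous_helix_forms(R, c)` supplies the classical circular-helix closed
forms k = R/(R²+c²), τ = c/(R²+c²); the discrete curvature estimate
converges to them at first order in the sampling step (relative error
~3×10⁻⁶ at angular step 0.01 rad).

## Numerical choices

* Frame degeneracy: |t_{i−1}×t_i| < 10⁻⁸ ⇒ invalid site; runs of invalid
  frames split the rotation chain into independently anchored segments.
* Gimbal threshold sin β < 10⁻⁸; orthogonality accepted to 10⁻⁶ in
  `extract_zyz`.
* Axis-direction estimate: normalized mean of all defined tangents;
  an error is raised if the mean is shorter than 10⁻⁶ (no well-defined
  advance direction, e.g. closed or hairpin-like traces).
* Minimum usable duplex: 5 paired sites (below that no site is evaluable).
* Output serialization uses 10 significant digits; identical inputs and
  configuration yield byte-identical CSV/JSON (a timestamp field is off by
  default).

## Problem sizes

Validation runs use 50-bp synthetic duplexes (several thousand sites for
the convergence study); a fit takes well under a second, and the whole test
suite a few seconds.

## Known limitations

* The helical-axis direction is a single global estimate; strongly bent or
  supercoiled duplexes violate the near-straight-axis assumption and would
  need a windowed estimate (not implemented).
* Absolute free energies depend on b and c and on the model's literal
  mixed-unit torsion term; only comparisons under identical parameters are
  meaningful.
* Base pairing is positional; bulges, mismatched or non-Watson–Crick
  regions are flagged via the complementarity mask but still paired by
  index — inspect the mask before trusting energies there.
* mmCIF input and RNA are out of scope.
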