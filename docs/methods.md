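# Methods

## Model overview

`hoxspring` couples a macroscale reaction–diffusion field to a microscale
mechanical model of the HoxD cluster through the force law `F = P × N`.

**Gradient.** Concentration obeys `∂C/∂t = D ∂²C/∂x² − k_deg·C` on the axis
`[0, L]` (x = 0 anterior), with the source held at a fixed concentration
(Dirichlet) and zero initial condition. The steady state with a single source
is the exponential `C(x) = C0·exp(−|x − x_src|/λ)`, `λ = √(D/k_deg)`.
Implanted beads are extra clamped sources; profiles superpose (the PDE is
linear; transients are integrated per source and summed, which keeps the
steady-state superposition identity exact).

**Positional factor.** `P(x, t) = #{j : C(x,t) ≥ Tj}` for the threshold
ladder `T1 < … < Tm`. P saturates at m posterior of the last threshold; the
model is silent about what happens beyond, and capping is the least
committal choice. A continuous variant (`P = m·C/Tm`, capped at m) is exposed
via `p_mode="continuous"`, but the quantized count is the default and the
mode all phenotype claims are stated in.

**Cluster and force.** Each gene contributes unit charge q = 1 (uniform
density), so `N` is the gene count for the wild type (9). `F = P·N` acts on
the telomeric end of an ideal massless spring. Anchored: `En = F/k_spring`,
uniform segment strain `En/L0` (tension is uniform in an ideal spring; the
alternative of a tension gradient along the fiber is not modeled).
Unanchored: the friction fraction φ splits the pulling work, `Ed =
(1−φ)F/k_spring`, `d = φF/k_slide`, hence `Ed < En` strictly whenever
`F > 0` and `φ > 0`.

**Extrusion → expression.** Rank i is extruded (and flagged transcribing —
downstream transcriptional organization is outside this model's scope) once
the drive `F + σ·d` reaches `τ·i`; ties count as extruded. A linear schedule
makes the extruded set a rank prefix by construction and turns the
deletion/duplication rules into arithmetic: with wild-type gene count
m_wt = 9 and `τ = q·m_wt = 9`, wild-type rank i needs exactly `P = i`, a
posterior deletion of a genes raises the probe's requirement to
`⌈9i/(9−a)⌉ > i`, and an anterior deletion lowers it to `⌈9(i−a)/(9−a)⌉ ≤ i`
(strict in the unquantized ratio whenever i < 9; the integer ceiling can
absorb a one-gene edit, which is why single-gene duplications classify as
"unchanged" in the default quantized mode while the three-gene duplication is
strictly premature).

## Parameters, units, defaults

| parameter | meaning | default | why |
| --- | --- | --- | --- |
| L (mm) | axis length | 1.0 | early-embryo scale; with L0 = 100 nm gives the 4-orders scale gap |
| k_deg (1/t) | morphogen decay | 0.1 | sets the developmental clock; equilibration horizon 10/k_deg |
| D (mm²/t) | diffusion | k_deg·(L/6)² | decay length λ = L/6 spans the axis yet leaves the far end equilibrated at 10/k_deg |
| C0 | source amplitude | 1.0 | concentrations are in units of the source |
| Tj | thresholds | C(d_j), d_j = (10−j)L/10 | steady-state boundaries evenly spaced along the axis, one per gene |
| L0 (nm) | rest length | 100 | compact-cluster length from imaging |
| k_spring (force/nm) | Hooke constant | 81/(4.6·100) ≈ 0.17609 | calibrated so F_max = 81 gives a 5.6× stretch (the 5–6× imaging range, >500 nm) |
| φ | friction fraction | 0.5 | even split of pulling work between slide and stretch; only φ ∈ (0,1) matters qualitatively |
| k_slide (force/nm) | slide stiffness | 0.25 | with σ below, drive gain g = 1 + σφ/k_slide = 3 |
| σ (force/nm) | slide→drive coupling | 1.0 | g = 3 is the smallest integer gain that makes the anchor-cut configurations *strictly* premature for both probes under quantized P (g = 2 leaves Hoxd4's requirement at ⌈27/12⌉ = 3, tied with wild type) |
| τ (force/rank) | extrusion slope | 9 | = q·m_wt, makes wild-type rank i require P = i |

Force, P and N are dimensionless model units; only lengths are physical (nm
for the cluster, mm for the axis).

## Numerics

- Transient solver: backward Euler (L-stable; preserves the monotone rise
  from the zero initial condition) on a uniform grid, default 401 nodes and
  `dt = 0.25·dx²/D`; the constant tridiagonal system is LU-factorized once
  per run. Non-source boundary nodes use a second-order (ghost-node) Robin
  condition `∂C/∂x = ±C/λ` matching the decaying exponential, so the discrete
  steady state is the closed form itself rather than the reflecting-boundary
  cosh profile; at `t = 10/k_deg` the remaining transient deficit is below
  10⁻³ relative on every node (the acceptance tolerance), provided the
  furthest cell is within ~6–7 decay lengths of the source — the default
  λ = L/6 respects this.
- Scenario runs default to 201 nodes and a time grid of t = 0 plus 64
  log-spaced points up to 10/k_deg; log spacing resolves the geometric ladder
  of threshold-crossing times near the source. These resolutions keep a full
  four-scenario suite under a second while leaving boundary positions
  (spaced L/10) and onset orderings far above grid resolution.
- Onset = first time-grid point with the extrusion inequality satisfied;
  anterior boundary = first grid node expressed. Mutant/wild-type onsets are
  compared at a shared readout cell placed 0.05·L posterior of the most
  anterior of the compared final boundaries — off the exact domain edge,
  where crossing times diverge, but inside every compared domain.
- Tie-breaks stated once and tested: `C ≥ Tj` counts toward P;
  `F + σd = τ·i` counts as extruded.
- Degenerate inputs: zero-amplitude sources give identically zero fields and
  no expression; deleting every locus, unknown gene names, non-increasing
  thresholds, non-positive rates and φ ∉ [0,1) raise typed errors naming the
  field.
- Determinism: the only randomness is the geometry-readout localization
  noise, behind one integer seed; identical configuration and seed reproduce
  byte-identical output tables (floats printed at 6 significant digits).

## What the scenarios emulate — and what they do not

Scenario presets encode the classical manipulations: posterior deletions
(Del I), deletions including the centromeric Evx2 flank (Del II), the
flank-only deletion (Del III, with predictions: premature expression and
strictly reduced elongation at every matched stage), bead implants (source
removal/rescue, tip implantation with band-pass windows reproducing
inhibition around the tip), and arbitrary contiguous deletions/duplications.
The generator produces idealized 1D fields and noiseless expression calls;
real embryos add 3D geometry, growth, transport and measurement noise, gene-
specific regulatory elements, and absolute developmental time, none of which
are modeled. Passing tests therefore validate the internal logic of the
force model — orderings, inequalities and scaling — not quantitative
agreement with any particular embryo; the only imaging-anchored quantities
are the 100 nm rest length and the calibrated 5.6× elongation.

## Design choices on open points

- The centromeric flank is the spring's fixed end only; it carries no charge
  even when present, and the flank-only deletion (Del III) leaves N at 9.
- Under edits the rest length scales with locus count (uniform charge
  density preserved); a fixed-rest-length mode is available.
- Anchored and unanchored responses are separate operations with explicit
  contract errors rather than one silent dispatch (a convenience dispatcher
  `spring_response` exists for pipeline code).
- E8-style staging ("expression present at stage X") is a helper predicate
  over onset times against a user-chosen reference time; no absolute clock
  is imposed. Because a single reference time cannot separate both probes in
  every mutant simultaneously, staging claims are per probe.

## Known limitations

- Quantized P makes the phenotype map piecewise constant: edits whose
  continuous requirement shifts by less than one quantum classify as
  "unchanged" (e.g. single-gene duplications) — a resolution limit of the
  threshold-count mechanism, not a failure of the rules' direction.
- The tension along the fiber is uniform (ideal spring); a
  telomeric→centromeric tension gradient would require a non-ideal spring
  model and is not implemented.
- 1D axis only; no polymer dynamics, thermal fluctuations, loop extrusion or
  TAD-level regulatory mechanics.
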