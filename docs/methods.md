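# Methods

## Scope and model structure

`amyturb` predicts the turbidity trace produced by a growing population of
protein aggregates. The calculation has three stages, each with its own
assumptions:

1. **Chemistry.** A kinetic mechanism is integrated to give, per aggregate
   type, the number concentration, the monomer-in-aggregate concentration
   and their ratio, the weight-average polymer degree ⟨i⟩.
2. **Geometry.** At every time point each aggregate type is mapped to a
   single mesoscopic particle: a rod of fixed cross-sectional radius whose
   length grows with ⟨i⟩, or a sphere whose radius grows as ⟨i⟩^(1/3). The
   map is volume conservation, V_trace = ⟨i⟩·M₁·ῡ/(α·N_A), with packing
   fraction α ∈ (0,1] parameterizing compact (α = 1) versus diffuse
   aggregates.
3. **Optics.** Each particle contributes τ_i = C_i·F_i·Q_i; contributions
   add in the dilute limit.

## Chemistry

### Closure

All reduced mechanisms represent each aggregate type by a single
weight-average degree ⟨i⟩ = Σ C_i·i²/Σ C_i·i. Full distribution
information is available only through the Smoluchowski integrator (below),
which exists to validate the closure, not to replace it.

### Nucleated growth with breakage

State (C_N, C_A, C_M→A), free monomer by conservation
C_M = C_tot − n·C_N − C_M→A:

    dC_N/dt   = f_N·C_M^n − f_A·C_M·C_N
    dC_A/dt   = f_A·C_M·C_N + b_A·(C_M→A − C_A)
    dC_M→A/dt = (n+1)·f_A·C_M·C_N + f_A·C_M·C_A − 2·b_A·C_A

Nucleation consumes n monomers; conversion of a nucleus by monomer addition
commits n+1. Breakage treats every internal bond (C_M→A − C_A per volume)
as scissile at b_A; the two terminal bonds per fibre release monomer on
breaking. Nuclei do not dissolve — consistent with a residual nucleus mass
at reaction end. b_A = 0 recovers the irreversible model exactly.

### Joining mechanisms and time-scale separation

End-to-end joining (f_JEE) and lateral dimerization (f_JLA) are slow
redistribution processes (f_J ≪ f_A). They are implemented under a
structural time-scale separation: the monomer/polymer-mass reaction is
untouched by joining, carried by a growing-units state C_U that counts
protofibril equivalents whose ends stay reactive. Countable particles
(C_A, and lateral dimers C_A2) evolve separately:

    dC_U/dt  = production (nucleation conversion + breakage)
    dC_A/dt  = production − f_JEE·C_A² − f_JLA·C_A²
    dC_A2/dt = f_JLA·C_A²/2

Lateral association is capped at the dimer stage and assumed centre-aligned:
dimers have doubled cross-sectional area (radius ×√2) at unchanged length.
Off-centre overlap, point contacts and higher-order bundles are not
modelled. A consequence worth knowing: monomer-in-aggregate is *exactly*
invariant under both joining modes, so any turbidity change under joining is
purely optical.

### Seeded competition

Two types grow reversibly from fixed, non-dissociable seeds by monomer
exchange only (no nucleation, no fragmentation):

    dC_M→X/dt = f_X·C_M·C_X − b_X·C_X·s(⟨i_X⟩ − ⟨i_X⟩₀)

The shrink gate s is a smooth switch, s(Δ) = Δ²/(Δ² + w²) with width
w = 0.1 monomer units of ⟨i⟩, which suppresses monomer loss at the seed
floor without integrator event chatter; far from the floor s ≈ 1 and the
equilibrium monomer concentration is the critical concentration b/f of the
more stable type, unaffected by the gate. Seed mass (⟨i⟩₀·C_seed) is
carried in addition to the stated free-monomer pool.

### Full-distribution oracle

`simulate_smoluchowski` integrates the truncated coagulation–fragmentation
master equations up to degree z ≤ 2000. Conventions: `f_mat[i-1,j-1]` is
the chemical rate constant of i + j → i+j (an i = j event consumes two
i-mers), `b_mat` gives ordered-fragment breakage rates whose antidiagonal
sum is the total scission rate of a parent. The boundary at z is closed —
associations that would exceed z are switched off — so total monomer mass
is conserved identically; a run is rejected when more than 0.1% of the mass
reaches the top species (truncation too small). Matched-rate comparisons
against the reduced nucleated-growth model use faster nucleation
(f_N = 3×10⁻³ M⁻¹s⁻¹) than the canonical simulated scenarios so that the
entire distribution fits below z = 200; for pure monomer-addition schemes
the reduced mass equations are exact, and the measured sup-norm discrepancy
is at integrator tolerance.

### Signatures

A growth curve reduces to (t₁₀, t₅₀ − t₁₀, asymptote): crossing times by
linear interpolation of C_M→A(t)/asymptote, the asymptote as the mean over
the trailing 5% of the time grid. The reduction refuses trajectories that
drift more than 1% across that window (unconverged) or dip more than 1% of
the asymptote (non-monotone).

## Optics

### Constants

Solvent index and protein refractive increment follow empirical visible-band
dispersion formulas (λ in metres):

    n₀(λ)    = 1.3403·(0.9922 + 2.31×10⁻¹⁵/λ²)
    dn/dc(λ) = 0.19×10⁻³·(0.925 + 2.2×10⁻¹⁴/λ²)   [m³/kg]

both overridable per run. The relative refractive index
m = 1 + α·(dn/dc)/(ῡ·n₀) stays below the anomalous-diffraction validity
bound m < 1.3 for aqueous protein at any α ≤ 1. Light is treated as
non-polarized; particles are randomly oriented (the Debye double sum is
itself an isotropic orientation average).

### F and Q

F = 24π³V²/λ⁴·((m²−1)/(m²+2))² uses the full trace volume and is common to
all regimes; all shape and size dependence of the signal therefore sits in
Q. Q paths:

- **Fitted interpolants** (the default inside the pipeline), with
  x₁ = R·n₀/λ and x₂ = L·n₀/λ:
  Q_sphere = 1 − 0.955(1 − e^(−6.48x₁))^2.40;
  Q_rod = Q_sphere(x₁)·[1 − 0.955(1 − e^(−1.08x₂))^1.275] for x₂ < 1 and
  Q_sphere(x₁)/(2.4·x₂^0.95) for x₂ ≥ 1. The two rod branches are
  independent fits and meet at x₂ = 1 only within ~5%; panel traces can
  show a comparable blip where a fibre population crosses that length.
- **Direct Debye quadrature** (`Q_numeric`): Q = (3/8)∫P(θ)(1+cos²θ)sinθ dθ
  with P from the Debye double sum over scattering centres sampled inside
  the body by scrambled Sobol sequences (low-discrepancy sampling keeps the
  pair-sum error orders of magnitude below pseudo-random at equal n). The
  3/8 normalization enforces Q = 1 for a point particle, matching the
  Rayleigh row. Pair distances are histogram-compressed (4096 bins) before
  the θ quadrature; Gauss–Legendre order doubles until convergence.
- **Anomalous diffraction** (spheres, R ≥ 2λ): Q = K(ρ)·πR²/F_Rayleigh with
  the van de Hulst efficiency K(ρ) = 2 − (4/ρ)sinρ + (4/ρ²)(1 − cosρ),
  ρ = 4πR(m−1)/λ, evaluated by series below ρ = 10⁻³ to avoid cancellation.
  This normalization makes τ reduce to the AD extinction result C·K·πR².

### Splice

`Q_continuous` dispatches on radius: the fitted RGD curve up to λ/2
(labelled "rayleigh" below λ/20, where it sits within a few 10⁻³ of 1 —
returning exactly 1 there would introduce a discontinuity at the regime
edge, so the fitted value is preferred), AD from 2λ, and a bridge linear in
log₁₀Q vs log₁₀R between those endpoints, where no printed formula exists.
Rods multiply the spliced sphere Q of their cross-sectional radius by the
fitted length factor; the x₂ ≥ 1 branch is retained for arbitrarily long
rods. A least-squares 2-D polynomial surface over log₁₀Q
(`fit_logQ_polynomial`, degree ≤ 6) mirrors the fast-interpolant design;
the direct splice remains the reference path.

A documented consequence of the fitted rod tail: specific turbidity of long
rods scales as L^0.05 (the fit's exponent is −0.95 rather than −1), i.e.
~12% per decade of length. Length-insensitivity beyond L ≈ 2λ is therefore
approximate, and the package's acceptance checks that assert tighter bounds
(<10%/decade; <1% turbidity shift under end-to-end joining) fail by exactly
this margin — retained deliberately as a record of the fit's residual.

### Assembly

Molar concentrations convert to molecules/m³ internally; OD = τ·L_path/ln10.
Monomer and nuclei contribute no turbidity (background-subtracted, below
Rayleigh detectability at n = 2). A warning fires when τ·L_path > 0.1,
where the single-scattering series truncation becomes inaccurate; no
multiple-scattering correction is attempted.

## Geometry module

The sphero-cylinder deconvolution solves (−π/4)W² + (P/2)W − A = 0 taking
the smaller positive root (the larger implies negative internal length);
the discriminant P² − 4πA equals (2L)² identically, so a negative value
beyond 10⁻⁹·P² rejects the measurement as non-sphero-cylindrical. The
turning-angle statistic marches fixed-length chords (conventionally one
fibre width) along the linearly interpolated backbone, discarding the tail
shorter than one chord, and averages |acos| of successive chord cosines;
angles are radians internally, degrees only in reports. Count histograms
convert to solution concentrations by mid-bin mass weighting, anchored to
an independently measured aggregate mass concentration, so the
monomer-weighted bin sum recovers that concentration exactly.

## Simulated scenarios and defaults

Named presets encode the canonical parameter sets: common nucleated-growth
conditions f_A = 10 M⁻¹s⁻¹, f_N = 10⁻⁷ M⁻¹s⁻¹, n = 2, C_tot = 1 mM,
monomer radius 2 nm (hence M₁ = 27.64 kg/mol at ῡ = 0.73×10⁻³ m³/kg,
α = 1), fibre radius 6 nm unless scanned; competition scenarios use
f_A = 250 M⁻¹s⁻¹, b_A = 10⁻³ s⁻¹ against amorphous b_G = 10⁻² s⁻¹ with
10⁻⁷ M seeds of degree 100 per type. The strain-competition preset reuses
those seed properties, which its source leaves unstated. Turbidity is
evaluated at λ = 400 nm and a 1 cm path by default (the wavelength at which
the reference interpolants were computed); both are config keys. Panel time
grids are logarithmic, 500 points over five decades, with t_max chosen per
scenario so the mass reaction reaches a drift-free plateau and an order of
magnitude of slow redistribution remains visible (10⁷ s for the
nucleated-growth family, 3×10⁶ s for seeded competition).

## Numerics

Kinetic ODEs integrate with Radau (master equations: BDF) at rtol 10⁻⁸,
atol 10⁻¹⁴ M, overridable per run; free monomer is reconstructed from
conservation, so the mass-balance residual measures integrator error and is
asserted ≤ 10⁻⁸ relative. Everything is deterministic given a
configuration; randomness enters only through seeded generators (fixture
sampling, replicate jitter, scattering-centre placement), and reruns are
bit-identical.

## Synthetic data

The fixture generators produce inputs with known ground truth: fibre tables
by forward-applying the perimeter/area relations to lognormal (L, W) draws
with optional multiplicative lognormal observation noise (microscopy
segmentation error scales with the feature); constant-curvature backbones
whose mean turning angle has the closed form 2·asin(l/2ρ); and
median-preserving lognormal jitter for replicate ensembles. They emulate
measurement tables, not images: segmentation artefacts, stain contrast,
overlapping fibres and finite pixel size are outside the model, so passing
tests validate the reduction pipeline downstream of segmentation, not
segmentation itself.

## Known limitations

- Single-moment closure: polydispersity within an aggregate type is
  invisible to the optics; a distribution with the same ⟨i⟩ but broad tails
  would scatter differently.
- No full Mie solution: spheres between λ/2 and 2λ rely on the log–log
  bridge; rod optics beyond the RGD cross-section regime lean on the
  asymptotic fitted branch.
- Dilute-limit, single-scattering optics only; the τ·L > 0.1 warning is the
  extent of the treatment.
- No heterogeneous surface nucleation, spherulites, off-centre lateral
  association, position-dependent breakage, or fitting of experimental
  traces (forward simulation only).
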