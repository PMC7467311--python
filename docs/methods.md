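# Methods

## The lattice model

The simulator reduces each protofilament (PF) to a single stochastic
variable, the dimer rise r (nm), the axial lattice period per αβ-tubulin
dimer. One to three PFs evolve by overdamped (Brownian) Euler–Maruyama
dynamics on the potential (energies in kBT)

    U(r) = Σ_i u_ax(r_i) + Σ_<ij> ½ k_lat (r_i − r_j)² − f Σ_i r_i ,

where the axial term u_ax is bilinear about the rest rise r0 — stiffness
k_comp for r < r0, k_ext for r > r0, continuous in value and force at r0 —
and f is the force equivalent of an externally applied axial stress,
f = σ·A_z with the effective PF cross-section A_z = 14.2 nm². Only
equilibrium statistics are meaningful: the friction sets an arbitrary time
scale, kinetics are not modeled, and the integrator exists solely to
sample the Boltzmann density of U.

### Parameter defaults and their provenance

| parameter | GTP | GDP | unit | rationale |
|---|---|---|---|---|
| r0 | 8.40 | 8.15 | nm | compacted GDP spacing 8.15 nm; GTP = GDP + 0.25 nm expansion observed in stress-free simulation ensembles |
| k_comp | 367 | 730 | kBT/nm² | k = E·A_z/L from the compression-regime moduli 0.89 / 1.77 GPa with A_z = 14.2 nm², L = 8.31 nm |
| k_ext | 153 | 219 | kBT/nm² | same conversion from the extension-regime moduli 0.37 / 0.53 GPa |
| k_lat | 200 | 600 | kBT/nm² | see below |
| temperature | 300 | 300 | K | room-temperature reference |
| dt | 0.02/k_comp | — | arb. | keeps the Euler stationary-variance bias ≈ 1% |

Note the stiffness conversion uses L = 8.31 nm for both nucleotides,
consistently with the definition of A_z (which is itself derived at
8.31 nm); converting the GDP moduli at 8.15 nm would change k by ~2%.

**Lateral coupling.** k_lat is the one parameter with no direct
experimental anchor. It was calibrated once, analytically, against the
Gaussian-chain closed form: for two harmonically coupled PFs the rise
correlation is ρ = α/(1+α) with α = k_lat/k_axial. The defaults give
ρ ≈ 0.46 (GTP, α ≈ 0.84 at the geometric-mean axial stiffness 237) and
ρ ≈ 0.60 (GDP, α ≈ 1.5 at 400). This choice (i) produces diagonally
elongated, visibly elliptic two-PF free-energy surfaces, (ii) makes the
GDP pair more correlated *and* more confined than the GTP pair — the
double-PF runs give ΔNMI ≈ +0.06 and ΔH_conf ≈ −1.0 bits (GDP − GTP) at
the default 30-bin discretization — and (iii) transmits correlation to
non-adjacent PFs through the middle one in three-PF chains. A single
nucleotide-independent coupling cannot reproduce the GDP > GTP correlation
ordering, because at fixed k_lat a stiffer axial spring *lowers* the
relative coupling; the nucleotide dependence is therefore part of the
model definition. Exact non-adjacent/adjacent NMI ratios are not
calibration targets: for a binned estimator they depend strongly on the
bias floor of the small NMI₁₃ values.

### Integration details

The Euler–Maruyama update is r ← r + F dt/γ + √(2 dt/γ) ξ with unit-free
kBT. The step is automatically sub-divided whenever the stiffest local
curvature violates k_max·dt/γ ≤ 0.05 (k_max includes the umbrella bias and
2 k_lat for multi-PF runs), bounding the scheme's stationary-variance
inflation at ~2.5%; frames are saved every `stride` (default 10) steps and
a burn-in of ~20 relaxation times of the softest mode is discarded. All
randomness flows from one master seed (`numpy` `SeedSequence` spawning for
umbrella windows), so trajectories are bit-reproducible.

### Synthesized box and pressure series

L_z is the per-frame mean rise; L_x = L_y are fixed at the solvated-box
sizes of the corresponding 1/2/3-PF systems (8.0/12.7/19.0 nm). The
pressure-tensor diagonal is Gaussian noise (sd 30 bar, configurable,
emulating barostat fluctuation) around a setpoint whose axial component is
offset so that inverting σ_zz = −(P_zz − P_⊥)·L_x L_y/(n_pf·A_z) recovers
the applied stress; the n_pf divisor shares the box force equally among
filaments and reduces to the standard single-PF definition at n_pf = 1.

### What the generator does *not* emulate

No atomistic coordinates, solvent, or periodic-image bookkeeping; no
rupture/plasticity (the axial potential is purely elastic); no kinetics;
no seam or heterotypic interfaces; Gaussian barostat noise instead of
correlated barostat dynamics; the rise variables are exactly Markovian in
the chain sense, so "diagonal" interlayer correlations are absent by
construction. Passing tests therefore validate the estimators and the
analysis chain under a controlled, near-Gaussian statistical structure —
not force-field realism.

## Analysis chain

**Reaction coordinate.** One PLS component regressed on the target L_z,
features mean-centered but (by default) not variance-scaled because
coordinate features share units; a `scale=True` flag enables scaling. The
score is calibrated to nm by an affine regression against the training
target, which makes projections invariant under a global rescaling of the
features. Exactly one component is computed; requesting more is rejected
by design.

**Stress–strain.** Means and errors by block averaging with five
contiguous blocks (error = sd of block means/√5). Only the trailing 20% of
each loaded trajectory enters the analysis window (configurable), a
trailing-fraction generalization of using the last segment of a long
equilibration. Moduli by weighted least squares (weights 1/sd², ordinary
fit when any error is zero; whether error weighting was used in the
original workflow is unstated, so the choice is documented here), with
regimes split exactly at σ = 0.

**Continuum layer.** All printed-constant reproductions (A_z ≈ 14.2 nm²,
ΔG_el ≈ 28.9 kJ/mol ≈ 11.6 kBT, R_out ≈ 12.95 nm, I ≈ 1.31×10⁻³² m⁴)
carry a ±5% tolerance attributable to 3-significant-figure rounding;
recomputing I from the printed R_out gives 1.36×10⁻³² m⁴ (~4% above the
printed value), a rounding-chain discrepancy that is flagged, not
resolved. L_z,eq defaults to 8.31 nm for both A_z and the strain-energy
volume, for self-consistency. The packaged measurement table
(`data/experimental_ei_synthetic.csv`) is a synthetic stand-in with
realistic thermal-fluctuation magnitudes — the consensus machinery is
exercised on it, but its numbers are not literature values.

**Free energy.** WHAM is the standard binned self-consistent iteration
(window free energies to tolerance 10⁻⁸ kBT, max 10⁵ iterations); a
single unbiased window reduces exactly to Boltzmann inversion, which is
tested. Default binning: 0.005 nm over [7.9, 8.7] nm. Empty bins are
missing (NaN), never zero or capped; downstream operations treat
missingness explicitly and querying it raises a coverage error.
Uncertainties are seeded bootstrap (50 resamples by default) rather than
analytic. Minima are grid argmins refined by a 3-point quadratic fit per
dimension, clamped to the argmin bin (noise on flat wells can otherwise
push the vertex outside it); ties break toward the lowest coordinate and
set a multimodality flag; boundary minima warn and skip refinement.

**Information metrics.** The jackknife is the leave-one-**sample**-out
estimator, computed in O(bins) by histogram decrement (all leave-outs from
one bin coincide). The literal leave-one-*bin*-out reading of the defining
text mis-scales badly (a two-bin uniform distribution would read 2 bits)
and is available only behind `convention="bin"` for comparison. The NMI
denominator is the geometric mean √(H₁H₂) — the only normalization for
which identical series give exactly 1. Marginals and joint share one
fixed-width grid over the pooled range of both series (30 bins default);
negative finite-sample MI is clipped to zero for NMI only and reported
unclipped otherwise. Bin counts are summed in sorted order so that
nmi(x, y) = nmi(y, x) holds exactly in floating point.

**Thermodynamic cycle.** With all three surfaces min-referenced, the
cycle-closure map is ΔΔG(r₁,r₂) = G_d(r₁,r₂) − G_s1(r₁) − G_s2(r₂), with
errors combined in quadrature, zero at the double-PF equilibrium by
construction, and exactly ½ k_c (r₁ − r₂)² for the analytic coupled-spring
model. The scalar evaluation point defaults to the sampled bin maximizing
|r₁ − r₂| (the strongest observed mismatch) and is overrideable, since the
reference analysis does not specify its coordinates numerically. Absolute
association free energies (the horizontal cycle legs) are never computed.

**Three-PF inference.** The prior multiplies densities
(q = p₁₂·p₂₃(·|r₂)); masked r₂ rows yield zero-probability conditionals.
The posterior-mean density is (counts + α·n·q)/normalization — a Dirichlet
pseudo-count scheme in which the prior carries an α fraction of the
evidence (default α = 0.1). The scheme is this package's own definition of
the pairwise-prior inference, chosen for transparent statistics; it is a
faithful-but-not-verbatim stand-in for the original (unpublished) scheme.
An additive-on-free-energy variant was considered and rejected: it does
not preserve the exact marginal-consistency property q → p₁₂ that makes
the construction testable. Projections marginalize the Boltzmann weight,
never slice.

## Problem sizes

Tests and the acceptance script use 2×10⁴–10⁵ frames per trajectory, eight
stress setpoints per sweep, ten umbrella windows of 3×10³ samples, and six
three-PF runs of 10⁴ frames per state — sizes at which every estimator's
tolerance (equipartition and curvature within 5%, modulus recovery within
10%, MI null bias below 0.02 bits) is met with margin while the whole
suite runs in seconds.

## Known limitations

- The bilinear axial potential makes the stress-free rise distribution
  slightly asymmetric; the mean rise therefore sits marginally above r0,
  and recovered "combined" moduli fall between the regime values rather
  than matching either.
- Binned NMI/H_conf values depend on the discretization; only signs,
  orderings and magnitude orders of differences are meaningful, and the
  defaults (30 bins, pooled or fixed [7.9, 8.7] nm range) are part of the
  metric definition.
- WHAM bootstrap resamples within windows only; window-placement error is
  not modeled.
- The chain prior imposes conditional independence of non-adjacent PFs
  given the middle one; real lattices may violate this through the closed
  microtubule geometry, which is out of scope here.
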