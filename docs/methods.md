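# Methods

`topobraid` reconstructs, end to end, the computational analysis by which
chirality-resolved single-crossing unlinking kinetics and simulated DNA
crossing-angle distributions are combined into a preferred DNA-crossing
angle for a type IIB topoisomerase.  This note records the models, the
numerical choices, and what the package's synthetic tests do and do not
demonstrate.

## The coarse-grained DNA model

DNA is a charged bead-spring polymer in reduced Lennard-Jones units
(`units` module).  In the fine-grained parameterisation one bead of
diameter σ = 2.5 nm represents 7.4 bp and carries −2.96 e.  The energy is

U = U_FENE + U_BEND + U_WCA + U_DH

- **FENE bonds**: −½·K·R₀²·ln(1−(r/R₀)²) with K = 30 kT/σ², R₀ = 1.6σ.
  Bonded pairs additionally interact by WCA, giving a bond minimum at
  r* ≈ 0.961σ (classic Kremer–Grest construction; FENE alone has its
  minimum at r = 0).
- **Bending**: K_BEND·(1+cos θ) with θ the angle at each interior bead
  (θ = π when collinear).  K_BEND·b ≈ L_p sets the persistence length;
  K_BEND = 20 kT at σ = 2.5 nm gives L_p ≈ 48–50 nm, verified in the
  suite from tangent–tangent correlations of a nearly force-free chain.
- **WCA excluded volume**: truncated–shifted LJ, exactly zero beyond
  2^(1/6) of the excluded-volume diameter.  Non-bonded pairs may use a
  diameter different from the bead spacing (`wca_sigma`, see the braid
  profiles below); bonded pairs always use the bead spacing.
- **Debye–Hückel electrostatics**: (l_B q_i q_j / ε r)·e^(−r/λ), zero at
  and beyond 6σ.  The published parameterisation of the screening term
  is dimensionally ambiguous, so the Bjerrum prefactor (default
  (1/3.66)σ ≈ 0.68 nm), decay length λ, dielectric factor ε = 1.6 and
  cutoff are all independent configuration keys; the default λ = 0.384σ
  is the Debye length at 100 mM monovalent salt.

An analytic-gradient reference implementation (numpy) defines the model;
the production kernels (numba) are cross-checked against it, and forces
against central finite differences, in the test suite.

## Braided-tether geometry

Two chains are anchored to the surface at points `spacing_e` apart and to
two attachment points on a magnet-held assembly.  `n_turns` counts the
imposed DNA **crossings**: one crossing per half-turn of the attachment
pair, so odd crossing numbers leave the attachments on swapped sides and
a single crossing is the X configuration of the single-crossing assay.
Positive values are left-handed crossings.  `force_pN` is the total bead
force, shared between the two tethers (≈F/2 each); this reading
reproduces the observed extension and imposed crossing angle of the
exemplar geometry, whereas a per-tether reading over-tensions the chains.

The builder produces a deterministic interwound starting conformation
(bonds at the FENE+WCA rest length, strands ≥ 2σ apart) and optionally
pre-contracts it toward the expected equilibrium extension, storing the
surplus contour as a local zigzag in the legs; the zigzag relaxes within
a few sweeps/τ, whereas starting taut leaves a slow global contraction
mode that dominates equilibration.  Physical walls close the topology:
the glass surface below (z ≥ −0.25σ) and the bead assembly just above
the attachment points.  Without the floor the braid can unhook by
slipping a strand beneath the other tether's surface anchor.

## Topology bookkeeping

The signed crossing number is the sum of signed segment–segment
crossings in a projection **transverse** to the force axis (the xz
plane).  Along the force axis the legs of a braid are near-collinear in
projection and the endpoint-sweep ambiguity of open chains makes the
count flicker; the transverse projection is generic for this geometry.
Degenerate frames are resolved by perturb-and-retry (two independent
jitters must agree).  Both engines verify the count on every stored
frame; the Monte Carlo sampler additionally rejects, per move, any
proposal that changes the signed crossing contribution of the displaced
segments — Metropolis moves are non-physical paths, and with a thin
excluded volume the chains could otherwise tunnel.

## Engines

**Brownian dynamics** (`bd`): BAOAB Langevin steps at dt = 0.01τ with
unit mass and friction γ = 1 (the bond stiffness ≈ 900 kT/σ² makes the
overdamped Euler–Maruyama update unstable at this dt; the overdamped
path remains available for dt ≲ 0.002τ and is the `bd_step` primitive).
Anchoring by stiff harmonic springs (50 kT/σ²), Verlet neighbour lists
with a 1σ skin, a per-step displacement clamp of 0.2σ that only engages
during the initial relaxation, and a quiet overdamped settle phase
before production.  Equipartition of the bond energy against a 1-D
Boltzmann integral, free diffusion of the primitive, and worm-like-chain
extension at zero turns are verified in the suite.

**Metropolis Monte Carlo** (`mc`): single-bead displacements, crankshaft
rotations about the chord through two pivot beads, and a rigid vertical
move of the attachment pair carrying the −F·Δz work term.  All proposals
are symmetric; correctness is checked against a direct Boltzmann
quadrature on a 3-bead chain.  An autocorrelation-based effective sample
size of the extension series accompanies every trajectory.

**Simulation profiles.**  Production braid sampling uses reduced
discretisations chosen for desk-scale runtimes:

| profile | bead | non-bonded diameter | use |
|---|---|---|---|
| fine | 2.5 nm | 2.5 nm + DH | force-field checks, persistence length |
| discrete-WLC MC | 15 nm | 5 nm | MC crossing-angle distributions |
| BD braid | 12 nm | 8.4 nm | BD crossing-angle distributions |

The discrete-WLC MC profile is the classic braid/supercoil sampling
construction: long segments with bending L_p/b, a thin excluded volume
equal to the electrostatic effective diameter of DNA at 100 mM (~5 nm),
screened charges folded into that diameter, topology enforced by the
move filter.  BD cannot rely on a rejection filter, so its profile keeps
an excluded-volume diameter large enough (0.7 of the 12 nm bead) that
strands cannot pass between beads; 8.4 nm still lies below the 10 nm
juxtaposition threshold.  The exemplar runs used for the headline
numbers are 1.2×10⁵ MC sweeps (≈9,600 stored frames, ≈1,800
juxtaposition events) and 3.5×10⁴τ of BD per chirality — far shorter
than a full-fidelity protocol (≈4×10⁷τ); the BD trajectory is therefore
pooled over the two chiralities and flagged `scaled_down`.

## Juxtapositions and the crossing angle

A juxtaposition is scored when the global inter-chain closest approach
(exact segment–segment minimum) is below 10 nm; one angle per qualifying
frame (single-crossing systems have one physical crossing).  The
fraction of frames without a juxtaposition is recorded — at the exemplar
geometry most frames have none, and the events are genuine fluctuation
encounters.

The crossing angle is the clockwise rotation, viewed along the
juxtaposition axis from the magnet side, that takes the bottom strand's
tangent onto the top strand's, folded to [0°, 180°).  Operationally:
α = atan2(−(t_b×t_t)·d̂, t_b·t_t) mod 180°, with both tangents oriented
anchor→attachment and d̂ the unit vector between the two closest points.
The result is invariant under exchanging the strand labels, reduces to
the planar clockwise angle when the contact normal is vertical, and
flips to the supplement when the over/under order is reversed — which is
what makes the measurement chirality-sensitive.  With this convention
left-handed (positive) crossings are acute on average and
P_R(α) = P_L(180°−α) holds to sampling accuracy (two-sample KS distance
≈ 0.02 between measured mirror pairs).

**Tangent estimate.**  The angle relevant to strand passage is that of
the duplex **axes** at the crossing, not of a single 2.5–15 nm segment:
segment-level tangents carry thermal bend noise of ≈15–25° RMS that is
symmetric about the geometric crossing angle and simply broadens the
distribution.  The default therefore estimates each strand's axis as the
chord over half of each arm flanking the contact (`tangent_halfwidth =
"auto"`); an integer fixes the half-width in bonds instead, and the
distribution width decreases smoothly from the single-segment value
(≈20–26°) to the axis-level value (≈9–12°) as the window grows.  The
mean is insensitive to this choice (each window ≥ 2 bonds gives ≈78–79°
at the exemplar); the inferred preferred angle is not, because the
log-density ratio at a few degrees from 90° depends on the distribution
width — this is the package's principal systematic, and it is surfaced
rather than hidden (the systematic error of the inference includes
re-binning and threshold perturbations).

## Preferred-angle inference

With exponential unlinking (maximum-likelihood fits with right-censoring
support; τ = Στ_all/n_uncensored), the ratio ρ = τ_L/τ_R equals
P_R(α₀)/P_L(α₀) if a single angle-dependent step is rate limiting.  The
root of the piecewise-linear log-ratio at ln ρ over bins where both
densities have ≥5 counts gives α₀.  When sampling noise makes the raw
curve cross the target repeatedly, a count-weighted linear regression of
the log ratio (exact for Gaussian-shaped distributions, and exactly
mirror-equivariant) supplies the crossing; a flat curve matching the
target resolves to the weighted centre (the symmetric, ρ = 1 case), and
a regression root far outside the hull of the raw crossings raises an
ambiguity error listing them.  The statistical error combines the
propagated ρ uncertainty through the local slope with a bootstrap over
raw angles; the systematic error is the spread of α₀ under re-binning
(×0.5, ×2), juxtaposition-threshold shifts (±2 nm), and dropping the
first 20% of events.

At the exemplar geometry the package obtains a mean positive-crossing
angle of ≈78° (MC) and ≈75–76° (BD) and, with ρ ≈ 0.19, α₀ ≈ 84–85°
(MC) and ≈82–84° (BD) — the acceptance suite asserts these against the
published bands.  Multi-geometry averaging (`combine_geometries`) is an
unweighted mean with SEM; the suite exercises it on synthetic geometries
with kinetics planted at 87.5°, since the original per-geometry source
data are not bundled.

## Analytic mechanics

- **Worm-like chain**: Marko–Siggia interpolation, inverted numerically;
  accurate to a few percent of the exact WLC, which suffices for
  calibration work.
- **Braid extension**: z(0) from the WLC; the first crossing drops the
  extension to √((zL)²−e²); further crossings follow the helical model
  z(n) = z₁/√(1+(πe(|n|−1)/2z₁)²).  `calibrate_braid` inverts this for
  (contour, spacing) by least squares with jackknife standard errors
  (the extension noise is strongly heteroscedastic across turn numbers);
  buckling is flagged when the model extension falls below 25% of z₁.
- **Mean braid angle** (analytic mode): the taut-chord crossing geometry
  with Gaussian axis fluctuations of variance kT/(F·l_leg) on both
  tangents and on the contact axis; as the imposed geometry degenerates
  the contact-axis direction randomises and the mean relaxes to 90°.
  The supplement identity α₊+α₋ = 180° holds exactly by construction,
  and positive crossings are reported on the acute branch.  A
  `simulate` mode defers to the MC engine.
- **Plectoneme model**: an ideal superhelix (radius R, pitch angle γ)
  minimising bending + screened electrostatics (Ubbink–Odijk form,
  effective charge 8 e/nm) + the force-extension work of sequestering
  contour, without end loops.  It yields R* of a few nm, the crossing
  angle 180°−2γ (acute branch for positive supercoils), an extension
  loss per turn of ≈57 nm at 0.4 pN (so ≈115 nm per ΔLk = 2 event,
  within the ±20% band of the ~100 nm observation), slopes decreasing
  with force, and supercoil angles further from 90° than braid angles
  at every force in 0.2–2 pN.  Exact published force–angle curves are
  out of scope; the model is used for orderings and the step amplitude.
- **Hat curves**: pre-buckling plateau with a small quadratic dip,
  post-buckling linear slope from the plectoneme model, buckling onset
  from the torque √(2 kT L_p F) with twist persistence 100 nm; above
  0.7 pN the negative-turn side stays at the torsionally relaxed
  extension (melting regime).

## Trace analysis

The step finder computes a sliding two-sample Welch t-statistic between
adjacent windows (default 100 samples = 0.5 s at 200 Hz), takes the
largest significant |t| as a change point, and recurses into both
plateaus until none contains a significant point; candidates closer than
one window merge (largest |t| wins, merged span kept as the transition
duration).  The threshold is the Šidák family-wise critical value with
one comparison per sample — deliberately conservative, because adjacent
scan statistics are strongly correlated and genuine steps at usable
signal-to-noise carry |t| an order of magnitude above threshold; the
false-positive rate on pure-noise traces stays below the nominal α while
recall at amplitude/noise ≥ 5 exceeds 95%.  A Savitzky–Golay smoother is
provided for display only and never runs before detection.

Steps convert to events via the nm-per-ΔLk calibration, rounding to the
nearest multiple of ΔLk = 2 with a ±35% acceptance band (off-grid and
sub-event steps are flagged, not coerced).  Bursts are steps carrying
≥2 passages; the burst rate averages passages/duration within bursts
(singles omitted), the burst size averages passages per step (singles
included), and dwells are the flat periods between events.

## Synthetic data

Generators plant known ground truth for every estimator: alternating
chirality single-crossing cycles with Exp(τ_L)/Exp(τ_R) unlinking;
distributive supercoil relaxation with dwell ~ Exp(c/n) (so the total
relaxation time is the harmonic sum); distributive vs processive braid
relaxation with geometric burst sizes and matched long-run rates; and
saturating rate-vs-concentration data.  Bead noise is an
Ornstein–Uhlenbeck process with 10 ms correlation time (white noise
switchable).  The generators emulate piecewise-constant level dynamics
with stationary noise; they do not model drift, tracking artefacts,
tether rupture, or force-dependent noise, so passing tests demonstrate
estimator correctness under the stated noise model, not robustness to
instrument pathologies.

## Reduced problem sizes

All defaults in `study` (the acceptance driver) are chosen for a
single-CPU desk run: MC 1.2×10⁵ sweeps, BD 3.5×10⁴τ per chirality at
the coarse profiles above, 200 synthetic unlinking cycles, 60 step-finder
traces, 40 relaxation traces.  Statistical errors at these sizes are a
few degrees on α₀ (reported alongside), versus sub-degree at
full-fidelity sizes.

## Known limitations

- The chirality asymmetry of the crossing-angle distribution, and hence
  α₀, depends on the axis-estimation window (see above); the package
  reports the systematic spread but cannot remove it without a
  finer-grained, longer simulation.
- The discrete-WLC MC profile folds electrostatics into an effective
  hard diameter; salt dependence enters only through that diameter and
  through the analytic plectoneme model.
- No twist degrees of freedom: braids are modelled as wrapped,
  torsionally unconstrained chains, and supercoils only through the
  analytic superhelix model.
- Hydrodynamic interactions and bead rotation are absent; BD time is
  meaningful for sampling, not for mapping to laboratory seconds.
- The multi-geometry combination is exercised on synthetic stand-in
  geometries; the per-geometry experimental table is not distributed
  with the package.
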