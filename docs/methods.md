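# Methods

## The problem

Gangliosides — glycosphingolipids (GSLs) whose glycan headgroup carries one
or more sialic-acid (Sia) residues — self-organise into nanoscopic lateral
domains in lipid bilayers, even at a few mol%. Two computational pipelines
probe this behaviour at complementary scales:

1. **MC-FRET** — Förster resonance energy transfer between donor- and
   acceptor-labelled gangliosides, read out as time-resolved donor decays
   (TCSPC photon histograms) in giant unilamellar vesicles (GUVs). A Monte
   Carlo forward model of FRET in a nanodomain-structured membrane is
   compared with each measured decay to infer, per vesicle, the domain
   radius ⟨R⟩ and the membrane area fraction ⟨A⟩ covered by domains.
2. **Membrane bookkeeping** — given atomistic bilayer configurations and a
   per-atom topology, count hydrogen bonds between GSLs per sugar moiety
   (Glc1, Gal2, Sia3, GalNAc4, Gal5, Sia6), compute pairwise interaction
   energies with per-partner normalisation, count headgroup–water bonds,
   and build partial density profiles along the membrane normal.

## The membrane model (MC-FRET forward problem)

The membrane is a flat square patch of side `L` with periodic boundary
conditions, carrying `N = round(A·L²/(π R²))` identical hard discs of
radius `R` (the nanodomains), covering an exact area fraction
`N·πR²/L²`. Discs are placed by random initialisation followed by
iterative pair-separation relaxation (each overlapping pair is pushed
apart along its minimum-image axis until the configuration is
overlap-free); this converges well beyond the ~55 % jamming limit of
random sequential adsorption and supports every coverage up to the hard
cap of `A = 0.65`. Domains are registered across the two leaflets.

Probes partition between domain and bulk phases with coefficient `K`: the
probability that a probe sits inside a domain is `p_in = K·A/(K·A + 1 −
A)`, and positions are uniform within the assigned phase. Donors and
acceptors split 50/50 between leaflets; cross-leaflet pairs add the
leaflet-plane separation `Δz` in quadrature to the lateral minimum-image
distance. A donor–acceptor excluded volume `r_min` keeps the Förster rate
finite.

A donor excited at `t = 0` decays as

    F(t) = (1/N_D) Σ_i exp( −(t/τ_D) [1 + Σ_j (R0/r_ij)^6] ),

with probe positions frozen during the excited-state lifetime (lateral
lipid diffusion covers ≪ R0 over nanoseconds), κ² = 2/3 absorbed into R0,
and only donor→acceptor transfer modelled.

### Two forward-model routes

* `ensemble_decay` — the plainly sampled Monte Carlo route: average the
  snapshot decay over independently drawn domain and probe configurations.
  It carries the full sampling noise of both donor and acceptor positions.
* `nanodomain_decay` — a semi-analytic route used by the inverse problem
  and the synthetic-data generator. Donor positions are sampled (half in,
  half out of the domains, radially stratified inside, recombined with the
  exact weight `p_in`), but the acceptor ensemble is treated as a two-level
  Poisson field (density `σ_in` inside the discs, `σ_out` outside) and each
  donor's transfer exponent is integrated **exactly** over that field: a
  full-plane term (adaptive quadrature, cached), per-disc lens corrections
  (tabulated against donor–disc distance; arc-length-weighted radial
  quadrature; the excluded volume enters through the 3-D distance), and a
  mean-field term for discs beyond an adaptive explicit-search reach
  (`min(R + 4R0, max(R + 1.5R0, 5R/√A))`, which keeps ~25 explicit discs
  per donor at every grid node; the far field of many small discs
  self-averages to the covered area fraction). The disc correction is
  evaluated exactly on the first 32 time channels (it rises steeply and
  concavely as near-donor acceptors saturate) and on every 4th channel
  afterwards, with linear upsampling.

The semi-analytic route removes acceptor sampling noise entirely; its
residual Monte Carlo error (donor geometry only) is roughly an order of
magnitude below the sampled route at equal cost — per-channel relative
errors of a few 10⁻³ at the default 12 configurations × 1536 donor
samples. The two routes agree within their combined Monte Carlo errors,
and both reduce **exactly** to the analytic uniform-plane (Poisson) decay

    F(t) = exp(−t/τ_D) · exp(−Σ_planes 2π σ ∫_{d_min}^∞ [1 − e^{−(t/τ_D)(R0/r)^6}] r dr)

at `A = 0`, whose `d_min = 0` limit has the closed form
`π σ R0² Γ(2/3) (t/τ_D)^{1/3}` (verified to 10⁻⁶ relative).

### Default parameters

| parameter | default | why |
|---|---|---|
| Förster radius R0 | 5.7 nm | typical of the green/orange dipyrromethene (Bodipy-class) FRET pairs used on labelled gangliosides; a required input, not a constant |
| donor lifetime τ_D | 5.7 ns | same class of donor |
| probe density σ | 0.00769 nm⁻² per leaflet per species | 0.5 mol% labelled lipid at 0.65 nm² per lipid |
| partition coefficient K | 20 | the labelled ganglioside is itself the domain-forming species; K = 20 puts ≈95 % of it inside the domains at A = 0.5, matching the picture of domains as ganglioside clusters. Lower K (≲5) makes ⟨R⟩ unidentifiable at realistic photon counts |
| leaflet separation Δz | 4.0 nm | headgroup-to-headgroup distance of a bilayer |
| excluded volume r_min | 1.0 nm | probe contact distance; prevents divergence of (R0/r)^6 |
| patch side L | max(16 R, 20 R0) | ≥10 R controls finite size; 16 R also suppresses disc-count quantisation of the realised coverage |
| time grid | 1024 channels of τ_D/64 (span 16 τ_D) | TCSPC-like histogram |

## The inverse problem

Each GUV decay is fitted on a grid of candidate states — 12 log-spaced
radii (2–200 nm) × coverages 0–0.65 in steps of 0.05 — by simulating the
forward model at every node, scaling it to the data with a free amplitude
and a free constant background (iteratively reweighted least squares,
non-negative), and scoring with the Poisson-weighted chi-square
`χ² = Σ_k (c_k − m_k)²/max(m_k, 1)`. Three local bisection passes around
the minimum refine the radius to ~5.5 % and the coverage to 0.0125. The
full χ² surface is returned so flat directions can be inspected.

Numerical choices that matter:

* **Shared model library.** The same per-realisation seeds are reused at
  every grid node, and one simulated-model cache can be shared across all
  GUVs of a cohort, so the χ² surface is smooth in (R, A) rather than
  jittered by independent Monte Carlo noise. Per-GUV fits remain
  statistically independent through their photon noise.
* **Uniform-model parsimony.** A uniform membrane and domains much smaller
  than R0 produce essentially identical decays (the acceptor field
  self-averages below the Förster length), so their χ² difference is pure
  noise. The no-domain state therefore wins whenever it comes within 3 χ²
  units of the global minimum; exact ties go to smaller A, then smaller R.
  Without this rule, no-domain data is randomly assigned `A ≈ 0.65`
  microdomain states.
* **Identifiability.** ⟨R⟩ information lives in the domain-boundary zone
  (width ~R0) and in per-domain acceptor-number fluctuations; both vanish
  as R/R0 → ∞, so per-vesicle radius errors grow for R ≳ 100 nm and the
  radius is unidentifiable as A → 0. The surface is kept so these flat
  directions are visible to the user.

Cohorts are summarised by per-GUV histograms and arithmetic means ⟨R⟩, ⟨A⟩.

## Synthetic data

`make_guv_cohort` emulates the per-vesicle measurements: each of `n_guvs`
(default 8, matching cohorts of 5–10 vesicles per composition) draws its
own generating state — the scenario (R, A) jittered by 10 % relative on R
and 0.05 absolute on A, truncated at physical bounds, standing in for
vesicle-to-vesicle variability — simulates the forward decay, and draws
independent Poisson photon counts (default 10⁵ per decay, 1 % flat
background). A manifest records the per-GUV truth for recovery scoring.

What the generator does **not** emulate: instrument response convolution,
detector afterpulsing and dead time, dye photophysics beyond a single
exponential, domain-size polydispersity within one vesicle, membrane
curvature, and non-disc domain shapes. Passing recovery tests therefore
demonstrate the self-consistency and statistical power of the inference
under the stated model, not robustness to these instrumental or structural
effects.

`make_membrane_fixture` builds coordinate/topology fixtures for the
bookkeeping pipeline with hydrogen bonds planted at ideal geometry
(O–O 0.28 nm, collinear O–H), decoys that violate either the distance or
the angle criterion, water, per-element charges and Lennard-Jones
parameters with exactly neutral molecules, and an analytic ground truth
(planted triples plus every within-cutoff molecule-pair energy by direct
all-pairs summation). The geometry is bookkeeping scaffolding — atoms of
one molecule are scattered over bond sites, not arranged as a lipid — and
is labelled as synthetic wherever it is written to disk.

## Membrane bookkeeping

* **Hydrogen bond**: donor–acceptor distance ≤ 0.35 nm and
  hydrogen–donor–acceptor angle ≤ 30° (N/O donors with bound H; N/O
  acceptors), the common geometric convention; both thresholds are
  configurable and recorded in output metadata. Neighbour search uses a
  periodic k-d tree under the minimum-image convention; correctness is
  pinned to an all-pairs brute-force oracle in the tests.
* **Moiety attribution**: each intermolecular GSL–GSL bond contributes 0.5
  to the donor-end moiety and 0.5 to the acceptor-end moiety, so the
  moiety columns sum exactly to total bonds per molecule. Standard errors
  come from block averaging over contiguous trajectory blocks.
* **Energies**: plain-cutoff (1.2 nm) Coulomb + Lennard-Jones with
  Lorentz–Berthelot combination rules and `f = 138.935458 kJ·mol⁻¹·nm·e⁻²`;
  no reciprocal-space term, because a per-pair decomposition is only well
  defined for direct-space interactions — absolute values therefore differ
  from Ewald-based force-field energies by construction.
* **Interacting partner**: a molecule with ≥1 atom pair within the cutoff
  in ≥50 % of the analysed frames (configurable); normalised energy =
  class total / partner count, reported as missing when a class has no
  partner.
* **Density profiles**: per-bin linear density along a box axis, frame
  averaged, number- or mass-weighted, optionally normalised to unit peak;
  the un-normalised profile integrates back to the selection size.

Published reference tables for GSL bilayers (hydrogen-bond counts per
moiety, interaction energies, headgroup-water counts) ship in
`gslnano.reference` and are used to cross-check the arithmetic conventions
(row totals, Sia/headgroup fractions, per-partner normalisation, percent
energy changes); the package does not recompute those values, which would
require force-field trajectories far beyond desk scale.

## Validation problem sizes

The shipped validation suite runs at desk scale, chosen for thorough
coverage rather than production statistics: recovery uses four cohorts of
10 GUVs × 10⁵ photons on the full default grid (the dominant cost, a few
minutes), forward-model oracle checks use 48 Monte Carlo realisations per
density, and bookkeeping fixtures stay below ~10³ atoms with exact
brute-force cross-checks.

## Known limitations

* Domains are monodisperse discs; mixtures of sizes within one vesicle are
  out of scope, and the fitted ⟨R⟩ of a polydisperse membrane would be an
  effective value.
* Registration of domains across leaflets is assumed; independent leaflets
  would halve the cross-leaflet FRET contrast.
* R0 and τ_D must be supplied; the defaults used in the synthetic studies
  are literature-typical, not measured values for a specific dye pair.
* The per-vesicle radius becomes noisy above ~100 nm and meaningless as
  A → 0 (see Identifiability).
* Fitted background is a single constant per decay; structured backgrounds
  (afterpulsing, scattered excitation) are not modelled.
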