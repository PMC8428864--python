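# Methods

This note documents the models implemented in `psispec`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Scientific setting

Cyanobacterial photosystem I (PSI) binds on the order of a hundred
chlorophyll *a* molecules per monomer. A handful of them — the
long-wavelength chlorophylls (LWC) — absorb beyond 700 nm because of their
protein environment and excitonic coupling to neighbours. Small structural
changes (a shifted pigment, a lost Ca²⁺ ion, a swapped aromatic residue)
reshape the red edge of the Qy absorption band. `psispec` implements the
computational chain that connects pigment coordinates to these spectral
observables, plus the spectral workup used to measure them experimentally.

## TrESP couplings and transition dipoles

A pigment's Qy transition density is represented by atom-centered
transition charges q_i (units of e) on the chlorin macrocycle. From the
coordinates r_i of a pigment:

* transition dipole: **μ** = Σ_i q_i **r**_i (e·Å; reported in Debye via
  1 e·Å = 4.80320 D). The charge set must have zero net monopole
  (|Σq| ≤ 10⁻³ e), which makes **μ** origin-independent.
* coupling between pigments m and n: the full Coulomb sum
  V_mn = f · Σ_{i∈m, j∈n} q_i q_j / |r_i − r_j|, with
  f = e²/4πε₀ = 1.16140×10⁵ cm⁻¹·Å.

No dielectric screening factor enters the Coulomb sum. Instead, every
pigment's charges are rescaled (all charges multiplied by one scalar) so
that |**μ**| equals an effective Qy dipole strength of **4.3 D** — the
standard effective value for chlorophyll *a* in a protein, which absorbs
medium screening. Rescaling preserves the zero monopole and is idempotent.

The point-dipole formula V = f·[μ_a·μ_b − 3(μ_a·n̂)(μ_b·n̂)]/R³
(equivalently 5034·κ·μ_a μ_b/R³ with μ in Debye) is implemented only as a
far-field oracle; tests verify the Coulomb sum converges to it to <1% for
center separations ≥50 Å and that it agrees within ~2% already at 10 Å for
collinear two-point fixtures.

### Charge set

The packaged charge table (`data/chla_qy_tresp_synthetic.csv`) is a
**synthetic stand-in**, constructed in-package: zero monopole, charges
confined to macrocycle atoms, dipole along the NB→ND axis (the Qy
polarization direction). It is *not* a literature gas-phase TrESP set.
Because every pipeline step rescales to the 4.3 D target, the stand-in is
sufficient for all geometry-driven quantities (dipole directions, coupling
ratios, rotation angles) on synthetic fixtures; absolute couplings computed
for real deposited structures will depend on the charge-set variant, so the
report records the charge-table provenance. Users with a literature set
supply it as a CSV (`atom_name,charge_e`).

### Dipole reorientation between structures

To compare one pigment's dipole between two structures, the second
structure is superposed onto the first by a least-squares rigid (Kabsch)
fit of paired anchor atoms — by convention the macrocycle heavy atoms of
two conserved neighbouring pigments. The reported angle is
arccos(μ̂₁·μ̂₂′) ∈ [0°, 180°] (unsigned). It is decomposed against the
least-squares plane of a reference macrocycle into an out-of-plane part
(change of tilt relative to the plane, sign fixed by orienting the normal
toward the reference dipole) and an in-plane part (angle between the
projections). The decomposition is exact for rotations about an in-plane
axis and approximate otherwise; both parts are always reported.

## Frenkel exciton model and disorder averaging

The N-pigment Hamiltonian has site energies E_m (cm⁻¹) on the diagonal and
couplings V_mn off it. Eigenstates k (coefficients c_mk) carry dipoles
μ_k = Σ_m c_mk μ_m and absorb with intensity |μ_k|² (D²). Two sum rules are
enforced by construction and checked in tests: Σ_k E_k = tr(H) and
Σ_k |μ_k|² = Σ_m |μ_m|² — couplings redistribute dipole strength but never
create it.

Site energies are **inputs**, never fitted by the package: no quantitative
method assigns chlorophyll site energies from structure, so they are chosen
by the user (the shipped default for the B18/B19/B40 cluster is
14600/14950/14950 cm⁻¹) and recorded verbatim in every report.

Static disorder is handled by Monte-Carlo averaging:

1. per iteration, each diagonal entry is perturbed independently by
   Gaussian noise of FWHM `site_fwhm` (default **300 cm⁻¹**;
   σ = FWHM/2√(2 ln 2)); couplings and dipoles are held fixed,
2. the perturbed Hamiltonian is rediagonalized and each state deposits
   |μ_k|² into the wavenumber-grid bin nearest E_k,
3. the iteration-averaged histogram is convolved with a unit-area Gaussian
   of FWHM `conv_fwhm` (default **10 cm⁻¹**) for visualization.

Numerical choices: the default grid is 12 000–16 000 cm⁻¹ in 1 cm⁻¹ steps
(the grid must cover the site energies ±5σ plus the convolution width, else
a coverage error is raised; the vanishingly rare draws beyond the margin
are dropped, not wrapped). Stick intensities carry no frequency prefactor
and the wavelength conversion λ = 10⁷/ν̃ applies no Jacobian — over the
narrow Qy band both are near-constant scalings. Diagonalization is batched
(20 000 samples per `numpy.linalg.eigh` call), so the production
default of 10⁶ iterations runs in seconds for small clusters; tests use
10⁵ iterations, for which the moment-based spectral FWHM of a single
pigment reproduces √(300² + 10²) ≈ 300.2 cm⁻¹ within ±2 cm⁻¹. With a fixed
seed the simulation is bit-reproducible.

Simulated difference spectra normalize each spectrum to unit integrated
area over its grid before subtracting, so equal total dipole strength
cancels and only redistribution survives.

No homogeneous lineshape theory is included: no vibronic sidebands, no
CD or fluorescence, no energy-transfer rates. The absence of vibronic
coupling means simulated spectra lack intensity on the blue side of the
Qy 0-0 region; only band positions and intensity redistribution are
meaningful.

## Experimental-spectra workup

* **Area normalization**: spectra are scaled so the trapezoidal integral
  over a window (default 550–775 nm, the chlorophyll Q-band region) equals
  one; window edges are interpolated so the integral is exact. Idempotent;
  the scale is recorded in metadata. This makes complexes of equal
  chlorophyll content comparable per pigment.
* **Difference spectra**: the second operand is linearly interpolated onto
  the first's axis over the overlap; antisymmetric on the common grid.
  Linear interpolation is used throughout — experimental sampling is dense
  and splines risk ringing in difference features.
* **Gaussian deconvolution**: nonlinear least squares (lmfit,
  Levenberg–Marquardt) of a sum of Gaussians, fitted in the wavelength
  domain because component centers are conventionally reported in nm.
  Defaults: region 680–730 nm for the ~701 nm LWC difference feature,
  FWHM bounds [1, 40] nm, no width ties, no baseline term. Because such
  fits are initialization-sensitive, 16 multistarts are run: a greedy
  "peeling" start (repeatedly place a component at the residual extremum
  and subtract), a quantile start, a quantile-plus-observed-extremum start,
  and jittered variants; the converged solution with the lowest RMS wins
  and the convergence flag is honest. The fit region and component count
  are user-configurable — reported centers can shift with the window, so
  reports carry the region used.
* **Band features**: extrema are refined by a three-point parabola around
  the extreme sample (error <0.1 nm for noiseless Gaussians at 1 nm
  sampling); probe intensities (e.g. for an F722:F685 emission ratio) use
  linear interpolation of the raw, unsmoothed curve.

## Structure handling

mmCIF/PDB files are read with gemmi. Alternate locations are resolved at
parse time: highest occupancy wins, ties go to the first alt-loc id —
deterministic and standard. Coordinates are used in the deposited frame;
no symmetry expansion (deposited trimers are already explicit).

Canonical pigment labels (B40, A31, L3, …) are a configuration input
(YAML label map) because the residue numbering behind them is a property
of each deposited model; the package never hard-codes label→residue
assignments.

Cofactor inventories classify residues by wwPDB component id (CLA and the
P700 epimer CL0 count as chlorophyll; BCR/ECH/ECN/CAN/ZEX as carotenoid;
PQN phylloquinone; SF4/FES iron–sulfur). Amino-acid residues are detected
through gemmi's component tables; unknown names are counted as "other" and
logged, never dropped, so class counts always sum to the residue total.
Protein subunits are reported separately as the number of chains containing
amino acids.

"Distance from a chlorophyll" is defined as the minimum heavy-atom pair
distance between named atom subsets (tryptophan indole ring;
chlorin macrocycle including Mg; or all heavy atoms). Ring-centroid
distances would differ; the subset definition is always part of the
reported value.

## Conservation tabulation

The alignment-column survey takes an aligned FASTA, anchors a column by the
n-th ungapped residue of a named reference sequence, and tabulates exact
residue counts. Class fractions (negatively charged D/E; positively charged
K/R/H; asparagine; other) are computed over non-gap entries, with the gap
fraction reported separately — percentages "of sequences" are therefore
percentages of sequences with a residue at that column. Histidine is
classified as positively charged but also reported individually in the raw
counts. Retrieval and alignment building are out of scope; published survey
percentages depend on the sequence set and aligner and are not reproducible
from the code alone.

## Synthetic data: what it emulates, what it does not

The generators produce every fixture the tests need, each returning its
exact ground truth alongside the data:

* **Chlorin template**: an idealized planar macrocycle (Mg, NA–ND at
  2.05 Å, methine and ring carbons out to 4.2 Å) with canonical atom
  names, placed by rotation+translation with optional Gaussian jitter.
  It is not a real chlorophyll conformer: bond lengths are stylized and
  there is no phytyl tail. Tests on it validate geometry handling
  (superposition, couplings, subsets), not chemistry.
* **Pigment pairs** with two-point toy charges in κ=1 / κ=0 / κ=−2
  geometries, returning the analytic point-dipole coupling as oracle.
* **Spectra** as sums of Gaussian components plus additive i.i.d. Gaussian
  intensity noise — adequate for fit-recovery tests, but without the
  correlated baselines, scattering and instrument response of real
  absorption data.
* **Alignments** with one column drawn from a planted class distribution
  (default mirroring the survey structure: 0.48 negatively charged /
  0.30 asparagine / 0.22 other) over an i.i.d. uniform background — no
  phylogenetic correlation between sequences.

The canonical three-band recovery fixture places components at
699/704/711 nm. Widths and amplitudes are free choices of the generator and
were set to FWHM 4/5/4.5 nm with amplitudes −0.6/−1.0/−0.5 so that the
5/7 nm center spacing is statistically resolvable at the 1% noise level to
the documented 0.5 nm recovery tolerance (with broad, heavily overlapped
components the centers are not identifiable to 0.5 nm at that noise level
by any fitting method — an intrinsic limit worth remembering when
interpreting deconvolutions of real difference spectra).

Passing these tests demonstrates correctness of the implemented operations
under controlled conditions; it does not validate charge sets, site-energy
choices, or deconvolution identifiability on any particular experimental
dataset.

## Known limitations

* Absolute TrESP couplings for deposited structures depend on the
  transition-charge variant; the shipped set is a labelled synthetic
  stand-in (see above).
* Site energies are user inputs; the package deliberately refuses to fit
  them.
* No vibronic/homogeneous lineshape; simulated spectra are for band
  positions and intensity redistribution only.
* Deconvolution centers depend on the fit window and component count;
  both are recorded in every report.
* Inputs that cannot be redistributed (deposited coordinate files,
  published source-data spectra) must be supplied by the user; the test
  suite checks for them under `data/external/` and reports exactly what is
  missing.

## Problem sizes used by the test suite

Monte-Carlo spectra are exercised at 10⁵ iterations (the config default for
production runs remains 10⁶); deconvolution robustness uses 20 seeded
mixtures with 16 multistarts each; the conservation recovery uses a
680-sequence synthetic alignment. All randomness flows through explicit
integer seeds and is bit-reproducible.
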