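# psispec

Excitonic couplings, disorder-averaged Qy absorption simulation and
experimental-spectra workup for photosystem I pigment clusters.

Photosystem I (PSI) binds ~100 chlorophyll *a* per monomer, and a few of
them — the long-wavelength chlorophylls — absorb beyond 700 nm because of
their protein pocket and excitonic coupling to neighbours. Small structural
changes (a pigment shifted by a protein-loop insertion, a lost inter-monomer
Ca²⁺, a swapped tryptophan) measurably reshape the red edge of the Qy band.
`psispec` is for structural biologists and spectroscopists who want to close
that loop quantitatively: it computes pigment–pigment couplings from
coordinates, simulates the resulting absorption, and applies the standard
workup to the experimental spectra being compared.

## What it computes

* **TrESP couplings and dipoles** — a pigment's Qy transition density is a
  set of atom-centered transition charges q_i; its dipole is
  **μ** = Σ q_i **r**_i and the coupling between pigments m, n is the full
  Coulomb sum V_mn = f·Σ_{ij} q_i q_j / r_ij (f = 1.1614×10⁵ cm⁻¹·Å).
  Charges are rescaled so each pigment carries an effective 4.3 D Qy dipole.
  A point-dipole evaluation (5034·κ·μ_aμ_b/R³) serves as the far-field
  cross-check, and a Kabsch-anchored comparison reports how much a pigment's
  dipole rotates between two structures (with an in-plane/out-of-plane
  decomposition).
* **Frenkel exciton spectra** — H with site energies E_m on the diagonal and
  V_mn off it; eigenstates absorb with intensity |Σ_m c_mk μ_m|².
  Inhomogeneous disorder is Monte-Carlo averaged: site energies are
  perturbed per iteration by Gaussian noise (default FWHM 300 cm⁻¹,
  10⁶ iterations), rediagonalized, stick spectra accumulated on a 1 cm⁻¹
  grid and convolved with a 10 cm⁻¹ Gaussian.
* **Spectral workup** — area normalization over the chlorophyll Q bands
  (550–775 nm), difference spectra, multi-Gaussian deconvolution of
  difference features (multistart least squares), and band features
  (refined extrema, probe intensities, ratios such as F722:F685).
* **Structure queries** — mmCIF/PDB parsing (gemmi), cofactor inventories
  (chlorophylls, carotenoids, phylloquinones, Fe–S clusters), minimum
  ring–ring contact distances (e.g. Trp indole to chlorin macrocycle).
* **Conservation tabulation** — residue composition of a reference-anchored
  alignment column, classified by charge (the PsaL Ca²⁺-coordinating
  position survey).
* **Synthetic data** — seeded generators for chlorin placements, toy charge
  pairs with analytic coupling oracles, noisy multi-Gaussian spectra and
  alignments with planted column compositions; every generator returns its
  ground truth.

## Worked example

Build the three-pigment wild-type cluster Hamiltonian (site energies
14600/14950/14950 cm⁻¹; couplings B18/B19 = −71, B18/B40 = −20,
B19/B40 = −106 cm⁻¹) and find its lowest exciton:

```python
import numpy as np
from psispec import build_hamiltonian, diagonalize
from psispec.tresp import CouplingMatrix

V = np.array([[0, -71, -20], [-71, 0, -106], [-20, -106, 0]], dtype=float)
H = build_hamiltonian([14600.0, 14950.0, 14950.0],
                      CouplingMatrix(["B18", "B19", "B40"], V))
states = diagonalize(H, np.eye(3))
print(np.round(states.energies, 2), round(1e7 / states.energies[0], 1))
```

```
[14581.49 14859.56 15058.96] 685.8
```

The couplings push the lowest state of the cluster down to
14581 cm⁻¹ ≈ 686 nm — a low-energy exciton red of the bulk antenna.

The same pipeline runs end-to-end from coordinate files via the CLI. On a
synthetic structure pair in which one pigment (labelled B40) is rotated by
25° about an in-plane axis:

```bash
psispec synth structure-pair --angle 25 --out fixtures
psispec couplings --config run.yaml --out report
psispec spectra --config run.yaml --out spectra
```

```
{
  "B18/B19": 0.0,
  "B18/B40": 10.829276329817944,
  "B19/B40": 0.9877179626879684
}
B40 dipole rotation: 25.0 deg (out-of-plane 25.0, in-plane 0.2)
...
  "simulated_difference": {
    "max_nm": 666.320358535212,
    "min_nm": 687.632904452347
  }
```

Rotating a single pigment changes its couplings to both neighbours
(first block: coupling deltas in cm⁻¹, reference → comparison), and the
disorder-averaged difference spectrum shows the signature of oscillator-
strength redistribution: intensity leaves the low-energy exciton
(minimum near 688 nm) and reappears in a higher-energy band (maximum near
666 nm). `run.yaml` points at the two structures, their label maps, and the
shared site energies; see `docs/methods.md` for every knob.

Deconvolving a (synthetic) difference feature into three Gaussian bands:

```bash
psispec synth spectrum --seed 3 --out diff.csv
psispec deconvolve --spectrum diff.csv --region 680 730 --out fit
```

recovers centers at 699/704/711 nm within 0.5 nm at 1% noise.

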