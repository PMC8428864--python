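"""Seeded generators for every fixture the pipeline needs, with ground truth.

Each generator returns its exact ground-truth parameters (transforms, planted
charges, component parameters, drawn counts) alongside the data, so recovery
tests never re-derive truth from the generated data.  All randomness flows
through ``numpy.random.default_rng(seed)``; a fixed seed gives byte-identical
output.

The chlorin template is an idealized planar geometry (central Mg, four
pyrrole nitrogens NA–ND at canonical names, methine bridges and ring
carbons), not a real chlorophyll conformer: property tests need controlled
geometry with a known dipole axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .conservation import AMINO_ACIDS, GAP, RESIDUE_CLASSES, Alignment
from .spectrum import Spectrum
from .spectra_analysis import GaussianComponent
from .structure_io import Atom, Residue, StructureModel
from .tresp import (
    PigmentSite,
    TransitionChargeSet,
    coupling_point_dipole,
    orientation_factor,
)


def _chlorin_template() -> dict:
    """Idealized planar chlorin: atom name → (3,) Å, macrocycle in z=0."""
    atoms = {"MG": np.zeros(3)}
    ring_azimuth = {"A": 0.0, "B": 90.0, "C": 180.0, "D": 270.0}
    for ring, phi in ring_azimuth.items():
        rad = math.radians(phi)
        atoms[f"N{ring}"] = 2.05 * np.array([math.cos(rad), math.sin(rad), 0.0])
        for name, dphi, radius in (
            (f"C1{ring}", +25.0, 3.0),
            (f"C4{ring}", -25.0, 3.0),
            (f"C2{ring}", +15.0, 4.2),
            (f"C3{ring}", -15.0, 4.2),
        ):
            a = math.radians(phi + dphi)
            atoms[name] = radius * np.array([math.cos(a), math.sin(a), 0.0])
    for name, phi in (("CHB", 45.0), ("CHC", 135.0), ("CHD", 225.0), ("CHA", 315.0)):
        a = math.radians(phi)
        atoms[name] = 3.3 * np.array([math.cos(a), math.sin(a), 0.0])
    return atoms


#: The idealized template; Qy-like dipole axis is NB→ND (the y axis).
CHLORIN_TEMPLATE = _chlorin_template()


@dataclass
class PlacementSpec:
    """Rigid placement (rotation about origin, then translation) + jitter."""

    axis: tuple = (0.0, 0.0, 1.0)
    angle_deg: float = 0.0
    translation: tuple = (0.0, 0.0, 0.0)
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        norm = float(np.linalg.norm(self.axis))
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-8):
            if norm == 0:
                raise ValueError("rotation axis must be nonzero")
            self.axis = tuple(np.asarray(self.axis, dtype=float) / norm)
        if self.jitter_sigma < 0:
            raise ValueError("jitter sigma must be nonnegative")

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_rotvec(
            np.radians(self.angle_deg) * np.asarray(self.axis)
        ).as_matrix()


def make_chlorin(
    spec: PlacementSpec,
    template: str = "chlorin",
    chain: str = "X",
    seqid: int = 1,
) -> tuple:
    """Place the chlorin template rigidly; returns ``(Residue, truth)``.

    ``truth`` records the exact rotation matrix, translation and per-atom
    jitter so superposition oracles can recover the planted transform.
    """
    if template != "chlorin":
        raise KeyError(f"unknown template {template!r}")
    R = spec.rotation_matrix
    t = np.asarray(spec.translation, dtype=float)
    rng = np.random.default_rng(spec.seed)
    atoms = {}
    jitters = {}
    for name, pos in CHLORIN_TEMPLATE.items():
        j = rng.normal(0.0, spec.jitter_sigma, 3) if spec.jitter_sigma > 0 else np.zeros(3)
        jitters[name] = j
        atoms[name] = Atom(
            name=name,
            element="MG" if name == "MG" else name[0],
            pos=R @ pos + t + j,
        )
    res = Residue(chain=chain, seqid=seqid, icode=" ", name="CLA", het=True, atoms=atoms)
    truth = {"rotation": R, "translation": t, "jitter": jitters, "spec": spec}
    return res, truth


def make_structure(placements, structure_id: str = "synthetic") -> tuple:
    """Place several chlorins into one model; returns ``(model, truths)``.

    ``placements`` is a list of PlacementSpec (chains A, B, ... seqid 1, 2,
    ...) or of ``(chain, seqid, PlacementSpec)`` triples.
    """
    residues, truths = [], []
    for i, item in enumerate(placements):
        if isinstance(item, PlacementSpec):
            chain, seqid, spec = chr(ord("A") + i), i + 1, item
        else:
            chain, seqid, spec = item
        res, truth = make_chlorin(spec, chain=chain, seqid=seqid)
        residues.append(res)
        truths.append(truth)
    return StructureModel(structure_id=structure_id, residues=residues), truths


def toy_charge_set(q: float = 0.1) -> TransitionChargeSet:
    """Two-point toy charges: +q on NB, −q on ND (dipole exactly along −y→+y)."""
    if q <= 0:
        raise ValueError("charge magnitude must be positive")
    return TransitionChargeSet(
        pigment_type="toy",
        charges={"NB": q, "ND": -q},
        provenance="synthetic two-point toy set",
    )


_PAIR_ORIENTATIONS = {
    # (separation direction, rotation applied to the second pigment)
    "parallel": (np.array([1.0, 0.0, 0.0]), Rotation.identity()),
    "perpendicular": (np.array([1.0, 0.0, 0.0]), Rotation.from_euler("x", 90, degrees=True)),
    "head_to_tail": (np.array([0.0, 1.0, 0.0]), Rotation.identity()),
}


def make_pigment_pair(
    separation: float,
    orientation="parallel",
    q: float = 0.1,
    site_energy: float = 14700.0,
) -> tuple:
    """Two placed chlorins with toy charges plus the analytic coupling oracle.

    ``orientation`` is one of ``parallel`` (κ=1: dipoles parallel, both ⊥ to
    the separation axis), ``perpendicular`` (κ=0), ``head_to_tail`` (κ=−2),
    or any :class:`scipy.spatial.transform.Rotation` applied to the second
    pigment (separation then along x).  Returns ``(site_a, site_b, oracle)``
    where the oracle holds the point-dipole coupling and κ computed from the
    planted geometry.
    """
    if separation < 1.0:
        raise ValueError("separation below 1 Å: point charges would collide")
    if isinstance(orientation, str):
        try:
            direction, rot = _PAIR_ORIENTATIONS[orientation]
        except KeyError:
            raise ValueError(
                f"unknown orientation {orientation!r} "
                f"(known: {sorted(_PAIR_ORIENTATIONS)})"
            ) from None
    else:
        direction, rot = np.array([1.0, 0.0, 0.0]), orientation

    charges = toy_charge_set(q)
    res_a, _ = make_chlorin(PlacementSpec(), chain="A", seqid=1)
    angle = rot.magnitude()
    spec_b = PlacementSpec(
        axis=tuple(rot.as_rotvec() / angle) if angle > 0 else (0.0, 0.0, 1.0),
        angle_deg=math.degrees(angle),
        translation=tuple(separation * direction),
    )
    res_b, _ = make_chlorin(spec_b, chain="B", seqid=2)
    site_a = PigmentSite("P1", res_a.coords(), charges, site_energy)
    site_b = PigmentSite("P2", res_b.coords(), charges, site_energy)
    oracle = {
        "kappa": orientation_factor(site_a, site_b),
        "coupling_point_dipole_cm1": coupling_point_dipole(site_a, site_b),
        "separation": separation,
        "mu_debye": site_a.dipole_debye,
    }
    return site_a, site_b, oracle


@dataclass
class SyntheticSpectrumSpec:
    """Sum-of-Gaussians spectrum with additive i.i.d. Gaussian noise."""

    components: list = field(default_factory=list)
    axis: np.ndarray = field(default_factory=lambda: np.arange(650.0, 750.0 + 0.5, 0.5))
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis grid must be strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")


def make_spectrum(spec: SyntheticSpectrumSpec) -> tuple:
    """Evaluate the component sum on the grid and add noise.

    Returns ``(Spectrum, truth)``; the truth dict carries the exact
    component parameters and the drawn noise vector.
    """
    x = spec.axis
    y = np.zeros_like(x)
    for comp in spec.components:
        y = y + comp(x)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sigma, x.size) if spec.noise_sigma > 0 else np.zeros_like(x)
    meta = {
        "synthetic": True,
        "seed": spec.seed,
        "noise_sigma": spec.noise_sigma,
        "components": [(c.center, c.fwhm, c.amplitude) for c in spec.components],
    }
    truth = {"components": list(spec.components), "noise": noise, "spec": spec}
    return Spectrum(x.copy(), y + noise, unit="nm", metadata=meta), truth


def three_band_difference_spec(
    noise_fraction: float = 0.01, seed: int = 0
) -> SyntheticSpectrumSpec:
    """Canonical three-component negative feature used across recovery tests.

    Centers 699/704/711 nm (the component positions typical of
    long-wavelength chlorophyll difference bands), distinct widths, negative
    amplitudes; noise σ = ``noise_fraction`` × max |amplitude|.
    """
    comps = [
        GaussianComponent(center=699.0, fwhm=4.0, amplitude=-0.6),
        GaussianComponent(center=704.0, fwhm=5.0, amplitude=-1.0),
        GaussianComponent(center=711.0, fwhm=4.5, amplitude=-0.5),
    ]
    return SyntheticSpectrumSpec(
        components=comps,
        axis=np.arange(680.0, 730.0 + 0.5, 0.5),
        noise_sigma=noise_fraction * max(abs(c.amplitude) for c in comps),
        seed=seed,
    )


_CLASS_MEMBERS = {name: sorted(members) for name, members in RESIDUE_CLASSES.items()}
_OTHER_RESIDUES = sorted(
    AMINO_ACIDS - frozenset().union(*RESIDUE_CLASSES.values())
)


def make_alignment(
    n_sequences: int,
    length: int,
    planted_column: tuple,
    seed: int = 0,
) -> tuple:
    """Random alignment with one column drawn from a class distribution.

    ``planted_column`` is ``(column_index_0based, probabilities)`` where the
    probabilities map class names (``negatively_charged``, ``asparagine``,
    ``positively_charged``, ``other``, ``gap``) or single residue letters to
    weights summing to 1.  Background columns are uniform over the 20 amino
    acids.  Returns ``(Alignment, truth)``; the truth dict records the drawn
    class of every sequence and the exact class counts.
    """
    column, probs = planted_column
    if not 0 <= column < length:
        raise ValueError("planted column outside the alignment")
    total = sum(probs.values())
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"class probabilities sum to {total}, not 1")
    rng = np.random.default_rng(seed)
    choices = list(probs.keys())
    weights = np.array([probs[c] for c in choices], dtype=float)
    drawn = rng.choice(len(choices), size=n_sequences, p=weights)
    background = rng.choice(sorted(AMINO_ACIDS), size=(n_sequences, length))

    seqs = []
    drawn_classes = []
    for i in range(n_sequences):
        row = background[i].tolist()
        choice = choices[drawn[i]]
        if choice == "gap":
            row[column] = GAP
        elif choice in _CLASS_MEMBERS:
            row[column] = _CLASS_MEMBERS[choice][rng.integers(len(_CLASS_MEMBERS[choice]))]
        elif choice == "other":
            row[column] = _OTHER_RESIDUES[rng.integers(len(_OTHER_RESIDUES))]
        elif choice in AMINO_ACIDS:
            row[column] = choice
        else:
            raise ValueError(f"unknown class or residue {choice!r}")
        drawn_classes.append(choice)
        seqs.append("".join(row))
    ids = [f"seq{i:04d}" for i in range(n_sequences)]
    counts = {c: drawn_classes.count(c) for c in choices}
    truth = {"column": column, "drawn_classes": drawn_classes, "class_counts": counts}
    return Alignment(ids=ids, seqs=seqs), truth
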