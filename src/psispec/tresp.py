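"""Transition charges, Qy dipoles and TrESP excitonic couplings.

The transition electrostatic potential (TrESP) method represents a pigment's
Qy transition density as atom-centered point charges.  The coupling between
two pigments is then the plain Coulomb interaction between the two charge
sets,

    V_mn = f · Σ_{i∈m, j∈n} q_i q_j / |r_i − r_j|       [cm⁻¹],

with f = e²/4πε₀ expressed in cm⁻¹·Å.  No dielectric screening factor is
applied: charges are rescaled so every pigment carries an effective Qy dipole
of 4.3 D, which absorbs medium screening.  A point-dipole evaluation with the
orientation factor κ is provided as the far-field oracle, and a Kabsch
superposition supports comparing the dipole orientation of the same pigment
between two structures.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .constants import COULOMB_CM1_ANGSTROM, DEBYE_PER_E_ANGSTROM
from .structure_io import Residue

logger = logging.getLogger(__name__)

MONOPOLE_TOLERANCE_E = 1e-3
MIN_ATOM_SEPARATION = 1.0   # Å; point-charge Coulomb diverges on contact
WARN_CENTER_GAP = 3.5       # Å

#: Standard effective Qy dipole strength for chlorophyll a in a protein.
DEFAULT_TARGET_DIPOLE_D = 4.3


class ChargeSetError(Exception):
    """Invalid transition-charge set (monopole, degeneracy, coverage)."""


class GeometryError(Exception):
    """Pigment geometry unusable for a coupling computation."""


@dataclass(frozen=True)
class TransitionChargeSet:
    """Atom-centered transition charges for one pigment type.

    ``charges`` maps atom name → charge in units of e.  The net monopole must
    vanish (|Σq| ≤ 1e-3 e), which makes the transition dipole independent of
    the coordinate origin.
    """

    pigment_type: str
    charges: dict
    provenance: str = ""
    applied_scale: float = 1.0

    def __post_init__(self):
        vals = np.array(list(self.charges.values()), dtype=float)
        if vals.size == 0 or np.abs(vals).sum() == 0.0:
            raise ChargeSetError("all transition charges are zero: dipole degenerate")
        monopole = float(vals.sum())
        if abs(monopole) > MONOPOLE_TOLERANCE_E:
            raise ChargeSetError(
                f"net transition monopole {monopole:.3e} e exceeds "
                f"{MONOPOLE_TOLERANCE_E:g} e"
            )
        if self.applied_scale <= 0:
            raise ChargeSetError("applied_scale must be positive")

    @classmethod
    def from_csv(cls, path=None, pigment_type: str = "CLA") -> "TransitionChargeSet":
        """Load ``atom_name,charge_e`` CSV (``#`` header lines = provenance).

        With no path, the packaged synthetic chlorophyll-a Qy set is used
        (constructed in-package, labelled synthetic; dipole along NB→ND).
        """
        if path is None:
            ref = importlib.resources.files("psispec.data") / "chla_qy_tresp_synthetic.csv"
            text = ref.read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        provenance_lines, charges = [], {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                provenance_lines.append(line.lstrip("# "))
                continue
            if line.lower().startswith("atom_name"):
                continue
            try:
                name, q = line.split(",")
                charges[name.strip()] = float(q)
            except ValueError as exc:
                raise ChargeSetError(f"bad charge-table row {lineno}: {line!r}") from exc
        return cls(
            pigment_type=pigment_type,
            charges=charges,
            provenance="\n".join(provenance_lines),
        )

    def scaled(self, s: float) -> "TransitionChargeSet":
        if s <= 0:
            raise ChargeSetError("scale factor must be positive")
        return replace(
            self,
            charges={k: v * s for k, v in self.charges.items()},
            applied_scale=self.applied_scale * s,
        )


def transition_dipole(coords: dict, charges: TransitionChargeSet):
    """μ = Σ q_i r_i over the charged atoms.

    Returns ``(vector in e·Å, magnitude in Debye)``.  Raises if any charged
    atom has no coordinate — partial macrocycles are a hard error, never
    silently skipped.
    """
    missing = [name for name in charges.charges if name not in coords]
    if missing:
        raise ChargeSetError(
            f"coordinates missing for charged atoms: {sorted(missing)}"
        )
    mu = np.zeros(3)
    for name, q in charges.charges.items():
        mu += q * np.asarray(coords[name], dtype=float)
    return mu, float(np.linalg.norm(mu) * DEBYE_PER_E_ANGSTROM)


@dataclass
class PigmentSite:
    """One pigment: coordinates of its charged atoms, charges, site energy.

    ``site_energy`` is the Qy transition energy of the pigment in its pocket
    absent inter-pigment coupling (cm⁻¹) — the diagonal of the exciton
    Hamiltonian.
    """

    label: str
    coords: dict                       # atom name -> (3,) Å
    charges: TransitionChargeSet
    site_energy: float = 15000.0      # cm⁻¹
    residue_ref: tuple | None = None

    def __post_init__(self):
        self.coords = {k: np.asarray(v, dtype=float) for k, v in self.coords.items()}
        if self.site_energy <= 0:
            raise ValueError("site energy must be positive (cm⁻¹)")
        # validates coverage eagerly
        transition_dipole(self.coords, self.charges)

    @property
    def dipole(self) -> np.ndarray:
        """Transition dipole vector in e·Å."""
        return transition_dipole(self.coords, self.charges)[0]

    @property
    def dipole_debye(self) -> float:
        return transition_dipole(self.coords, self.charges)[1]

    def charged_positions(self):
        """(positions (n,3), charges (n,)) over atoms carrying charge."""
        names = list(self.charges.charges)
        pos = np.array([self.coords[n] for n in names], dtype=float)
        q = np.array([self.charges.charges[n] for n in names], dtype=float)
        return pos, q

    def center(self, rule: str = "Mg") -> np.ndarray:
        """Pigment center: the Mg position, or the |q|-weighted centroid."""
        if rule == "Mg":
            if "MG" not in self.coords:
                raise GeometryError(f"site {self.label}: no MG atom for center rule 'Mg'")
            return self.coords["MG"]
        if rule == "dipole-weighted":
            pos, q = self.charged_positions()
            w = np.abs(q)
            return (pos * w[:, None]).sum(axis=0) / w.sum()
        raise ValueError(f"unknown center rule {rule!r}")

    def transformed(self, rotation=None, translation=None) -> "PigmentSite":
        """Rigidly moved copy (rotation about the origin, then translation)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return replace(self, coords={k: R @ v + t for k, v in self.coords.items()})


def site_from_residue(
    res: Residue, charges: TransitionChargeSet, site_energy: float, label: str | None = None
) -> PigmentSite:
    """Build a :class:`PigmentSite` from a parsed chlorophyll residue."""
    coords = res.coords()
    return PigmentSite(
        label=label or f"{res.chain}{res.seqid}",
        coords={n: coords[n] for n in charges.charges if n in coords},
        charges=charges,
        site_energy=site_energy,
        residue_ref=res.key,
    )


def rescale_charges(site: PigmentSite, target: float = DEFAULT_TARGET_DIPOLE_D) -> PigmentSite:
    """Rescale the site's charges so |μ| equals ``target`` Debye exactly.

    Multiplying every charge by s = target/|μ| preserves the zero monopole
    and is idempotent at the target.
    """
    mu_d = site.dipole_debye
    if mu_d == 0.0:
        raise ChargeSetError(f"site {site.label}: zero transition dipole, cannot rescale")
    s = target / mu_d
    return replace(site, charges=site.charges.scaled(s))


def coupling_tresp(site_a: PigmentSite, site_b: PigmentSite) -> float:
    """Full Coulomb sum between two transition-charge sets, in cm⁻¹.

    Vacuum prefactor (screening is implicit in the 4.3 D effective dipole).
    Exactly symmetric in its arguments.
    """
    pos_a, q_a = site_a.charged_positions()
    pos_b, q_b = site_b.charged_positions()
    dist = cdist(pos_a, pos_b)
    dmin = dist.min()
    if dmin == 0.0:
        raise GeometryError(
            f"sites {site_a.label}/{site_b.label} share an atom position"
        )
    if dmin < MIN_ATOM_SEPARATION:
        raise GeometryError(
            f"sites {site_a.label}/{site_b.label}: minimum interatomic separation "
            f"{dmin:.2f} Å below the {MIN_ATOM_SEPARATION} Å sanity bound"
        )
    try:
        gap = np.linalg.norm(site_a.center("Mg") - site_b.center("Mg"))
    except GeometryError:
        gap = dmin
    if gap < WARN_CENTER_GAP:
        logger.warning(
            "sites %s/%s: center gap %.2f Å < %.1f Å, point-charge coupling "
            "may be unreliable",
            site_a.label, site_b.label, gap, WARN_CENTER_GAP,
        )
    return float(COULOMB_CM1_ANGSTROM * (np.outer(q_a, q_b) / dist).sum())


def coupling_point_dipole(
    site_a: PigmentSite, site_b: PigmentSite, center_rule: str = "Mg"
) -> float:
    """Point-dipole coupling V = f·[μ_a·μ_b − 3(μ_a·n̂)(μ_b·n̂)]/R³ in cm⁻¹.

    Equivalent to 5034·κ·μ_a[D]·μ_b[D]/R³ with the orientation factor
    κ = μ̂_a·μ̂_b − 3(μ̂_a·n̂)(μ̂_b·n̂).  Far-field oracle for
    :func:`coupling_tresp`.
    """
    r_ab = site_b.center(center_rule) - site_a.center(center_rule)
    R = np.linalg.norm(r_ab)
    if R == 0.0:
        raise GeometryError("coincident pigment centers")
    n_hat = r_ab / R
    mu_a, mu_b = site_a.dipole, site_b.dipole
    num = mu_a @ mu_b - 3.0 * (mu_a @ n_hat) * (mu_b @ n_hat)
    return float(COULOMB_CM1_ANGSTROM * num / R**3)


def orientation_factor(site_a: PigmentSite, site_b: PigmentSite, center_rule="Mg") -> float:
    """κ for the pair (dimensionless)."""
    r_ab = site_b.center(center_rule) - site_a.center(center_rule)
    R = np.linalg.norm(r_ab)
    if R == 0.0:
        raise GeometryError("coincident pigment centers")
    n_hat = r_ab / R
    ua = site_a.dipole / np.linalg.norm(site_a.dipole)
    ub = site_b.dipole / np.linalg.norm(site_b.dipole)
    return float(ua @ ub - 3.0 * (ua @ n_hat) * (ub @ n_hat))


@dataclass
class CouplingMatrix:
    """Symmetric pairwise excitonic couplings in cm⁻¹, zero diagonal."""

    labels: list
    V: np.ndarray
    method: str = "tresp"

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        n = len(self.labels)
        if self.V.shape != (n, n):
            raise ValueError("coupling matrix shape does not match labels")
        if not np.array_equal(self.V, self.V.T):
            raise ValueError("coupling matrix must be exactly symmetric")
        if np.any(np.diagonal(self.V) != 0.0):
            raise ValueError("coupling matrix diagonal must be exactly zero")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label," + ",".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.V):
                fh.write(lab + "," + ",".join(f"{v:.6g}" for v in row) + "\n")


def coupling_matrix(sites, method: str = "tresp", center_rule: str = "Mg") -> CouplingMatrix:
    """All pairwise couplings among ``sites`` (TrESP or point-dipole)."""
    n = len(sites)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if method == "tresp":
                v = coupling_tresp(sites[i], sites[j])
            elif method == "point_dipole":
                v = coupling_point_dipole(sites[i], sites[j], center_rule)
            else:
                raise ValueError(f"unknown coupling method {method!r}")
            V[i, j] = V[j, i] = v
    return CouplingMatrix(labels=[s.label for s in sites], V=V, method=method)


@dataclass
class RotationReport:
    """Dipole reorientation of one pigment between two structures."""

    angle_deg: float
    out_of_plane_deg: float
    in_plane_deg: float
    rmsd: float
    rotation: np.ndarray = field(repr=False, default=None)

    @property
    def predominantly_out_of_plane(self) -> bool:
        return abs(self.out_of_plane_deg) > abs(self.in_plane_deg)


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through ``points``."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-9:
        raise GeometryError("plane atoms are collinear; normal undefined")
    return vt[2]


def dipole_rotation_angle(
    site_ref: PigmentSite,
    site_cmp: PigmentSite,
    anchors_ref: np.ndarray,
    anchors_cmp: np.ndarray,
    plane_atoms: np.ndarray | None = None,
) -> RotationReport:
    """Angle between one pigment's dipole in two structures, after anchoring.

    The comparison structure is superposed onto the reference by a
    least-squares rigid (Kabsch) fit of paired anchor atoms (typically the
    ring heavy atoms of two neighbouring, conserved pigments).  The angle is
    arccos(μ̂_ref·μ̂_cmp′) ∈ [0°, 180°] with μ̂_cmp′ the transformed
    comparison dipole.  If ``plane_atoms`` (reference frame) is given, the
    angle is decomposed into the change of tilt relative to that
    least-squares plane (out-of-plane) and the angle between the in-plane
    projections (in-plane).
    """
    anchors_ref = np.asarray(anchors_ref, dtype=float)
    anchors_cmp = np.asarray(anchors_cmp, dtype=float)
    if anchors_ref.shape != anchors_cmp.shape or anchors_ref.ndim != 2:
        raise GeometryError("anchor atom arrays must be paired and of equal shape")
    if anchors_ref.shape[0] < 3:
        raise GeometryError("at least 3 anchor atom pairs are required")
    a_c = anchors_ref - anchors_ref.mean(axis=0)
    b_c = anchors_cmp - anchors_cmp.mean(axis=0)
    if np.linalg.matrix_rank(a_c, tol=1e-8) < 2:
        raise GeometryError("anchor atoms are collinear; superposition is rank-deficient")
    rot, rssd = Rotation.align_vectors(a_c, b_c)
    R = rot.as_matrix()
    mu_ref = site_ref.dipole
    mu_cmp = R @ site_cmp.dipole
    u1 = mu_ref / np.linalg.norm(mu_ref)
    u2 = mu_cmp / np.linalg.norm(mu_cmp)
    angle = float(np.degrees(np.arccos(np.clip(u1 @ u2, -1.0, 1.0))))

    out_of_plane = in_plane = float("nan")
    if plane_atoms is not None:
        n_hat = _plane_normal(np.asarray(plane_atoms, dtype=float))
        if u1 @ n_hat < 0:  # orient the normal toward the reference dipole
            n_hat = -n_hat
        tilt1 = np.degrees(np.arcsin(np.clip(u1 @ n_hat, -1.0, 1.0)))
        tilt2 = np.degrees(np.arcsin(np.clip(u2 @ n_hat, -1.0, 1.0)))
        out_of_plane = float(tilt2 - tilt1)
        p1 = u1 - (u1 @ n_hat) * n_hat
        p2 = u2 - (u2 @ n_hat) * n_hat
        if np.linalg.norm(p1) < 1e-12 or np.linalg.norm(p2) < 1e-12:
            in_plane = 0.0
        else:
            p1 /= np.linalg.norm(p1)
            p2 /= np.linalg.norm(p2)
            in_plane = float(np.degrees(np.arccos(np.clip(p1 @ p2, -1.0, 1.0))))
    rmsd = float(rssd / np.sqrt(anchors_ref.shape[0]))
    return RotationReport(
        angle_deg=angle,
        out_of_plane_deg=out_of_plane,
        in_plane_deg=in_plane,
        rmsd=rmsd,
        rotation=R,
    )
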