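"""Configuration-driven orchestration of the two headline computations.

1. The coupling report: per-structure Qy dipoles (rescaled to the target
   strength) and full TrESP coupling matrices for a named pigment cluster,
   plus cross-structure coupling deltas and the dipole-rotation angle of a
   pigment of interest after anchoring on conserved neighbours.
2. The spectrum comparison: disorder-averaged simulated absorption for both
   structures (shared site energies; only dipoles and couplings differ),
   their simulated difference, and — when experimental spectra are supplied —
   the area-normalization / difference / deconvolution workup.

Site energies are configuration inputs and are never fitted automatically:
assigning pigment site energies from structure alone is an open problem, so
they are chosen by the user and recorded verbatim in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import spectra_analysis as sa
from .exciton import (
    DisorderModel,
    LineShape,
    build_hamiltonian,
    simulate_absorption,
    simulated_difference,
)
from .structure_io import (
    MACROCYCLE_ATOMS,
    PigmentLabelMap,
    extract_pigment,
    parse_structure,
)
from .tresp import (
    DEFAULT_TARGET_DIPOLE_D,
    TransitionChargeSet,
    coupling_matrix,
    dipole_rotation_angle,
    rescale_charges,
    site_from_residue,
)


class ConfigError(Exception):
    """Invalid or incomplete run configuration."""


@dataclass
class StructureConfig:
    path: str
    label_map: str


@dataclass
class RunConfig:
    """Everything needed to rerun a comparison exactly.

    Defaults mirror the standard three-pigment antenna cluster analysis:
    labels B18/B19/B40 with site energies 14600/14950/14950 cm⁻¹ and a
    4.3 D target dipole.
    """

    reference: StructureConfig = None
    comparison: StructureConfig = None
    charge_table: str | None = None
    labels: list = field(default_factory=lambda: ["B18", "B19", "B40"])
    site_energies: dict = field(
        default_factory=lambda: {"B18": 14600.0, "B19": 14950.0, "B40": 14950.0}
    )
    target_dipole: float = DEFAULT_TARGET_DIPOLE_D
    rotation_pigment: str = "B40"
    rotation_anchors: list = field(default_factory=lambda: ["B18", "B19"])
    rotation_plane: str = "B19"
    disorder: DisorderModel = field(default_factory=DisorderModel)
    lineshape: LineShape = field(default_factory=LineShape)
    experimental: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        kwargs = {}
        for role in ("reference", "comparison"):
            if role in doc:
                entry = doc[role]
                if "path" not in entry or "label_map" not in entry:
                    raise ConfigError(f"{role}: both 'path' and 'label_map' are required")
                kwargs[role] = StructureConfig(str(entry["path"]), str(entry["label_map"]))
        for key in ("charge_table", "labels", "site_energies", "target_dipole",
                    "rotation_pigment", "rotation_anchors", "rotation_plane",
                    "experimental", "seed"):
            if key in doc:
                kwargs[key] = doc[key]
        dis = doc.get("disorder", {})
        kwargs["disorder"] = DisorderModel(
            site_fwhm=float(dis.get("site_fwhm", 300.0)),
            n_samples=int(dis.get("n_samples", 1_000_000)),
            seed=int(dis.get("seed", doc.get("seed", 0))),
        )
        ls = doc.get("lineshape", {})
        grid = ls.get("grid", {})
        kwargs["lineshape"] = LineShape(
            conv_fwhm=float(ls.get("conv_fwhm", 10.0)),
            grid=np.arange(
                float(grid.get("start", 12000.0)),
                float(grid.get("stop", 16000.0)) + float(grid.get("step", 1.0)),
                float(grid.get("step", 1.0)),
            ),
        )
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for role in ("reference", "comparison"):
            sc = getattr(self, role)
            if sc is None:
                raise ConfigError(f"missing structure config {role!r}")
            for p in (sc.path, sc.label_map):
                if not Path(p).exists():
                    raise ConfigError(f"{role}: path does not exist: {p}")
        missing = [lab for lab in self.labels if lab not in self.site_energies]
        if missing:
            raise ConfigError(f"no site energy configured for labels {missing}")


def _load_sites(cfg: RunConfig, role: str):
    sc = getattr(cfg, role)
    model = parse_structure(sc.path)
    labelmap = PigmentLabelMap.from_yaml(sc.label_map)
    for lab in set(cfg.labels) | {cfg.rotation_pigment} | set(cfg.rotation_anchors):
        if lab not in labelmap.entries:
            raise ConfigError(
                f"{role}: pigment label {lab!r} not resolvable in {sc.label_map}"
            )
    charges = TransitionChargeSet.from_csv(cfg.charge_table)
    sites = []
    for lab in cfg.labels:
        res = extract_pigment(model, labelmap, lab)
        site = site_from_residue(res, charges, float(cfg.site_energies[lab]), label=lab)
        sites.append(rescale_charges(site, cfg.target_dipole))
    return model, labelmap, sites


def _anchor_coords(model, labelmap, labels):
    pts = []
    for lab in labels:
        res = extract_pigment(model, labelmap, lab)
        coords = res.coords()
        pts.extend(coords[n] for n in MACROCYCLE_ATOMS if n in coords)
    return np.array(pts, dtype=float)


def run_coupling_report(cfg: RunConfig, out_dir=None) -> dict:
    """Dipoles, TrESP couplings and the cross-structure rotation report."""
    cfg.validate()
    report = {"target_dipole_D": cfg.target_dipole, "labels": list(cfg.labels)}
    per_structure = {}
    sites_by_role = {}
    anchors = {}
    planes = {}
    for role in ("reference", "comparison"):
        model, labelmap, sites = _load_sites(cfg, role)
        sites_by_role[role] = sites
        cm = coupling_matrix(sites, method="tresp")
        per_structure[role] = {
            "structure": getattr(cfg, role).path,
            "charge_table_provenance": sites[0].charges.provenance.splitlines()[:1],
            "dipoles_debye": {s.label: s.dipole_debye for s in sites},
            "dipole_vectors_eA": {s.label: s.dipole.tolist() for s in sites},
            "couplings_cm1": {
                f"{cm.labels[i]}/{cm.labels[j]}": cm.V[i, j]
                for i in range(len(cm.labels))
                for j in range(i + 1, len(cm.labels))
            },
        }
        if out_dir is not None:
            cm.to_csv(Path(out_dir) / f"couplings_{role}.csv")
        anchors[role] = _anchor_coords(model, labelmap, cfg.rotation_anchors)
        plane_res = extract_pigment(model, labelmap, cfg.rotation_plane)
        coords = plane_res.coords()
        planes[role] = np.array(
            [coords[n] for n in MACROCYCLE_ATOMS if n in coords], dtype=float
        )
    report["structures"] = per_structure
    ref_c = per_structure["reference"]["couplings_cm1"]
    cmp_c = per_structure["comparison"]["couplings_cm1"]
    report["coupling_delta_cm1"] = {k: cmp_c[k] - ref_c[k] for k in ref_c}

    if anchors["reference"].shape != anchors["comparison"].shape:
        raise ConfigError(
            "anchor pigments expose different macrocycle atoms in the two structures"
        )
    pig = cfg.rotation_pigment
    ref_site = next(
        (s for s in sites_by_role["reference"] if s.label == pig), None
    )
    cmp_site = next(
        (s for s in sites_by_role["comparison"] if s.label == pig), None
    )
    if ref_site is None or cmp_site is None:
        raise ConfigError(f"rotation pigment {pig!r} must be one of the cluster labels")
    rot = dipole_rotation_angle(
        ref_site,
        cmp_site,
        anchors["reference"],
        anchors["comparison"],
        plane_atoms=planes["reference"],
    )
    report["rotation"] = {
        "pigment": pig,
        "anchors": list(cfg.rotation_anchors),
        "angle_deg": rot.angle_deg,
        "out_of_plane_deg": rot.out_of_plane_deg,
        "in_plane_deg": rot.in_plane_deg,
        "predominantly_out_of_plane": rot.predominantly_out_of_plane,
        "anchor_rmsd_A": rot.rmsd,
    }
    if out_dir is not None:
        with open(Path(out_dir) / "coupling_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report


def run_spectrum_compare(cfg: RunConfig, out_dir=None) -> dict:
    """Simulated spectra and difference; optional experimental workup."""
    cfg.validate()
    report = {
        "seed": cfg.disorder.seed,
        "n_samples": cfg.disorder.n_samples,
        "site_fwhm_cm-1": cfg.disorder.site_fwhm,
        "conv_fwhm_cm-1": cfg.lineshape.conv_fwhm,
    }
    spectra = {}
    for role in ("reference", "comparison"):
        _, _, sites = _load_sites(cfg, role)
        cm = coupling_matrix(sites, method="tresp")
        H = build_hamiltonian(sites, cm)
        spec = simulate_absorption(H, sites, cfg.disorder, cfg.lineshape)
        spectra[role] = spec
        if out_dir is not None:
            spec.write_csv(Path(out_dir) / f"simulated_{role}.csv")
    diff = simulated_difference(spectra["comparison"], spectra["reference"])
    if out_dir is not None:
        diff.write_csv(Path(out_dir) / "simulated_difference.csv")
    diff_nm = diff.to_wavelength()
    feats = sa.spectral_features(diff_nm, region=(640.0, 740.0))
    report["simulated_difference"] = {
        "max_nm": feats["argmax"],
        "min_nm": feats["argmin"],
    }

    exp = cfg.experimental or {}
    if exp:
        if "a" not in exp or "b" not in exp:
            raise ConfigError("experimental comparison requires spectra 'a' and 'b'")
        window = sa.NormalizationWindow(
            *(exp.get("window", (550.0, 775.0)))
        )
        spec_a = sa.normalize_area(sa.read_spectrum(exp["a"]), window)
        spec_b = sa.normalize_area(sa.read_spectrum(exp["b"]), window)
        ediff = sa.difference_spectrum(spec_a, spec_b)
        region = tuple(exp.get("fit_region", (680.0, 730.0)))
        efeats = sa.spectral_features(ediff, region=region)
        fit = sa.fit_gaussians(
            ediff, region=region, n_components=int(exp.get("n_components", 3)),
            seed=cfg.seed,
        )
        report["experimental_difference"] = {
            "max_nm": efeats["argmax"],
            "min_nm": efeats["argmin"],
            "fit_converged": fit.converged,
            "components": [
                {"center_nm": c.center, "fwhm_nm": c.fwhm, "amplitude": c.amplitude}
                for c in fit.components
            ],
            "rms_residual": fit.rms_residual,
        }
        if out_dir is not None:
            ediff.write_csv(Path(out_dir) / "experimental_difference.csv")
            fit.to_frame().to_csv(Path(out_dir) / "fit_components.csv", index=False)
    if out_dir is not None:
        with open(Path(out_dir) / "spectrum_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
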