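"""Reading macromolecular coordinate files and structure-level queries.

Built on :mod:`gemmi` for the wwPDB dialects (mmCIF and PDB). The module
resolves alternate locations up front (highest occupancy wins, ties broken by
the first alt-loc id), maps canonical pigment labels such as ``B40`` or ``L3``
to residues via a user-supplied YAML label map, counts cofactors by class, and
answers minimum-distance queries between named atom subsets (e.g. a tryptophan
indole ring versus a chlorin macrocycle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: Heavy atoms of the tryptophan indole ring.
INDOLE_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")

#: Heavy atoms of the chlorin macrocycle (central Mg, pyrrole nitrogens,
#: methine bridges and ring carbons).  Chlorophyll a and a' share this set.
MACROCYCLE_ATOMS = tuple(
    ["MG", "NA", "NB", "NC", "ND", "CHA", "CHB", "CHC", "CHD"]
    + [f"C{i}{r}" for r in "ABCD" for i in (1, 2, 3, 4)]
)

ATOM_SUBSETS = {
    "indole": INDOLE_ATOMS,
    "macrocycle": MACROCYCLE_ATOMS,
    "all": None,  # every heavy atom of the residue
}

#: Default residue-name → cofactor-class table (wwPDB chemical component ids).
DEFAULT_CLASSIFICATION = {
    "CLA": "chlorophyll",   # chlorophyll a
    "CL0": "chlorophyll",   # chlorophyll a' (C13 epimer, one per P700)
    "BCR": "carotenoid",    # beta-carotene
    "ECH": "carotenoid",    # echinenone
    "ECN": "carotenoid",
    "CAN": "carotenoid",    # canthaxanthin
    "ZEX": "carotenoid",    # zeaxanthin
    "PQN": "phylloquinone",
    "SF4": "iron_sulfur",   # Fe4S4 cluster
    "FES": "iron_sulfur",
}

COFACTOR_CLASSES = (
    "amino_acid",
    "chlorophyll",
    "carotenoid",
    "phylloquinone",
    "iron_sulfur",
    "other",
)


class StructureError(Exception):
    """Problem reading or querying a coordinate file."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    chain: str
    seqid: int
    icode: str
    name: str
    het: bool
    atoms: dict = field(default_factory=dict)  # atom name -> Atom

    @property
    def key(self):
        return (self.chain, self.seqid, self.icode)

    def coords(self, atom_names=None) -> dict:
        """Return ``{atom name: xyz}`` for the selected (default: all) atoms."""
        if atom_names is None:
            return {n: a.pos for n, a in self.atoms.items()}
        return {n: self.atoms[n].pos for n in atom_names if n in self.atoms}


@dataclass
class StructureModel:
    """A parsed coordinate file after alt-loc resolution.

    Atom names are unique within each residue, all coordinates finite.
    Hetero residues (cofactors) are retained.
    """

    structure_id: str
    residues: list = field(default_factory=list)

    def __post_init__(self):
        self._index = {r.key: r for r in self.residues}

    @property
    def chains(self):
        seen = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    @property
    def n_atoms(self):
        return sum(len(r.atoms) for r in self.residues)

    def residue(self, chain: str, seqid: int, icode: str = " ") -> Residue:
        key = (chain, seqid, icode or " ")
        if key not in self._index:
            raise StructureError(f"residue {key} not present in {self.structure_id}")
        return self._index[key]

    def has_residue(self, chain, seqid, icode=" ") -> bool:
        return (chain, seqid, icode or " ") in self._index


def _resolve_altlocs(raw_atoms):
    """Keep one atom per name: highest occupancy, ties by first alt-loc id."""
    by_name = {}
    for atom in raw_atoms:
        by_name.setdefault(atom.name, []).append(atom)
    resolved = {}
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occupancy, a.altloc))
        resolved[name] = group[0]
    return resolved


def parse_structure(path, fmt: str = "auto") -> StructureModel:
    """Read an mmCIF or PDB file into a :class:`StructureModel`.

    ``fmt`` may be ``"mmCIF"``, ``"PDB"`` or ``"auto"`` (extension sniffing
    via gemmi). Alternate locations are resolved immediately: per atom name
    the highest-occupancy conformer is kept, ties broken by the first
    alt-loc id.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"coordinate file not found: {path}")
    try:
        if fmt == "auto":
            st = gemmi.read_structure(str(path))
        elif fmt.lower() in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt.lower() == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    residues = []
    model = st[0]
    for chain in model:
        for res in chain:
            raw = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    pos=np.array([a.pos.x, a.pos.y, a.pos.z], dtype=float),
                    occupancy=a.occ,
                    altloc=(a.altloc if a.altloc and a.altloc != "\x00" else ""),
                )
                for a in res
            ]
            atoms = _resolve_altlocs(raw)
            residues.append(
                Residue(
                    chain=chain.name,
                    seqid=res.seqid.num,
                    icode=res.seqid.icode or " ",
                    name=res.name,
                    het=(res.het_flag == "H"),
                    atoms=atoms,
                )
            )
    model_out = StructureModel(structure_id=st.name or path.stem, residues=residues)
    if model_out.n_atoms == 0:
        raise StructureError(f"{path} contains zero atoms")
    for res in model_out.residues:
        for atom in res.atoms.values():
            if not np.isfinite(atom.pos).all():
                raise StructureError(f"non-finite coordinates in {res.key}/{atom.name}")
    return model_out


def write_structure(model: StructureModel, path) -> None:
    """Write a :class:`StructureModel` back out as a PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = model.structure_id
    gm = gemmi.Model("1")
    chains = {}
    for res in model.residues:
        if res.chain not in chains:
            chains[res.chain] = gemmi.Chain(res.chain)
        gr = gemmi.Residue()
        gr.name = res.name
        gr.seqid = gemmi.SeqId(res.seqid, res.icode if res.icode.strip() else " ")
        gr.het_flag = "H" if res.het else "A"
        for atom in res.atoms.values():
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.pos = gemmi.Position(*atom.pos)
            ga.occ = atom.occupancy
            ga.element = gemmi.Element(atom.element)
            gr.add_atom(ga)
        chains[res.chain].add_residue(gr)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass
class PigmentLabelMap:
    """Canonical pigment labels (``B40``, ``A31``, ``L3`` ...) → residues.

    The numeric residue assignments behind the canonical antenna labels are a
    property of each deposited model, so the map is a configuration input
    (YAML), never hard-coded.
    """

    structure_id: str
    entries: dict  # label -> (chain, seqid, resname)

    @classmethod
    def from_yaml(cls, path) -> "PigmentLabelMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        entries = {
            str(label): (str(v["chain"]), int(v["seqid"]), str(v.get("resname", "CLA")))
            for label, v in doc["entries"].items()
        }
        return cls(structure_id=str(doc.get("structure_id", "")), entries=entries)

    def to_yaml(self, path) -> None:
        doc = {
            "structure_id": self.structure_id,
            "entries": {
                label: {"chain": c, "seqid": s, "resname": n}
                for label, (c, s, n) in self.entries.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class CofactorInventory:
    """Residue counts per cofactor class plus the protein-chain count."""

    counts: dict
    n_protein_chains: int
    unclassified: list = field(default_factory=list)

    @property
    def total_residues(self):
        return sum(self.counts.values())

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("class,count\n")
            for cls in COFACTOR_CLASSES:
                fh.write(f"{cls},{self.counts.get(cls, 0)}\n")
            fh.write(f"protein_chains,{self.n_protein_chains}\n")


def load_classification(path=None) -> dict:
    """Load a residue-name → class table from YAML, or the built-in default."""
    if path is None:
        return dict(DEFAULT_CLASSIFICATION)
    with open(path) as fh:
        table = yaml.safe_load(fh)
    bad = set(table.values()) - set(COFACTOR_CLASSES)
    if bad:
        raise StructureError(f"unknown cofactor classes in table: {sorted(bad)}")
    return {str(k): str(v) for k, v in table.items()}


def cofactor_inventory(model: StructureModel, classification=None) -> CofactorInventory:
    """Count residues of a structure by cofactor class.

    Amino-acid residues fall in class ``amino_acid``; residue names missing
    from the classification table are counted as ``other`` and logged, never
    dropped, so class counts always sum to the total residue count.
    Protein subunits are counted as chains containing at least one
    amino-acid residue.
    """
    table = dict(DEFAULT_CLASSIFICATION) if classification is None else dict(classification)
    counts = {cls: 0 for cls in COFACTOR_CLASSES}
    protein_chains = set()
    unclassified = []
    for res in model.residues:
        if gemmi.find_tabulated_residue(res.name) is not None and gemmi.find_tabulated_residue(
            res.name
        ).is_amino_acid():
            counts["amino_acid"] += 1
            protein_chains.add(res.chain)
        elif res.name in table:
            counts[table[res.name]] += 1
        else:
            counts["other"] += 1
            unclassified.append(res.name)
    if unclassified:
        logger.warning(
            "%d residues with unclassified names counted as 'other': %s",
            len(unclassified),
            sorted(set(unclassified)),
        )
    return CofactorInventory(
        counts=counts, n_protein_chains=len(protein_chains), unclassified=unclassified
    )


def extract_pigment(model: StructureModel, labelmap: PigmentLabelMap, label: str) -> Residue:
    """Resolve a canonical pigment label to its residue in the model."""
    if label not in labelmap.entries:
        known = ", ".join(sorted(labelmap.entries))
        raise KeyError(f"pigment label {label!r} not in label map (known: {known})")
    chain, seqid, resname = labelmap.entries[label]
    if not model.has_residue(chain, seqid):
        raise StructureError(
            f"label {label!r} maps to {chain}/{seqid} which is absent from "
            f"{model.structure_id}"
        )
    res = model.residue(chain, seqid)
    if res.name != resname:
        raise StructureError(
            f"label {label!r}: expected residue name {resname}, found {res.name}"
        )
    return res


def _subset_positions(res: Residue, tag: str) -> np.ndarray:
    if tag not in ATOM_SUBSETS:
        raise StructureError(f"unknown atom subset tag {tag!r} (known: {sorted(ATOM_SUBSETS)})")
    wanted = ATOM_SUBSETS[tag]
    if wanted is None:
        names = [n for n, a in res.atoms.items() if a.element != "H"]
    else:
        names = [n for n in wanted if n in res.atoms]
        if not names:
            raise StructureError(
                f"atom subset {tag!r} selects no atoms of {res.name} {res.key}; "
                f"expected any of {wanted}"
            )
    return np.array([res.atoms[n].pos for n in names], dtype=float)


def min_ring_distance(model: StructureModel, ref_a, ref_b) -> float:
    """Minimum heavy-atom pair distance between two named atom subsets.

    ``ref_a``/``ref_b`` are ``(chain, seqid, tag)`` triples with tag one of
    ``"indole"``, ``"macrocycle"``, ``"all"``.  Symmetric in its arguments.
    """
    chain_a, seq_a, tag_a = ref_a
    chain_b, seq_b, tag_b = ref_b
    pos_a = _subset_positions(model.residue(chain_a, seq_a), tag_a)
    pos_b = _subset_positions(model.residue(chain_b, seq_b), tag_b)
    diff = pos_a[:, None, :] - pos_b[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())
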