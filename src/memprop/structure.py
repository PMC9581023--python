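"""Structure loading, residue containers, and per-residue membrane labels.

Structures are read with gemmi (PDB or mmCIF, auto-detected) and reduced to a
light-weight residue list holding heavy-atom coordinates and B-factors. Files
are treated as the biological assembly they contain: every chain in the file
is kept as interaction context, while ``scored_chains`` restricts which
residues later receive scores.

Membrane annotations come either from an explicit per-residue TSV
(``chain  resnum  icode  label``) or from a hydrophobic slab bounded by two
planes normal to z (the usual convention of membrane-oriented coordinates):
a residue is transmembrane iff its side-chain centroid lies inside the closed
interval [z_lo, z_hi].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .config import AA3_TO_1
from .errors import CoverageError, EmptyModelError, InvalidSlabError, ParseError

log = logging.getLogger(__name__)

#: Atom names counted as backbone; everything else heavy is side chain.
BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")
#: Backbone heavy atoms entering the main-chain B-factor average.
MAINCHAIN_B_ATOMS = ("N", "CA", "C", "O")

ResidueKey = tuple[str, int, str]  # (chain id, residue number, insertion code)


@dataclass
class Residue:
    """One amino-acid residue: heavy atoms, B-factors, derived geometry."""

    chain_id: str
    resnum: int
    icode: str
    name: str                      # three-letter code, canonical 20
    atom_names: list = field(default_factory=list)
    coords: np.ndarray = None      # (n_atoms, 3) in Angstrom
    bfactors: np.ndarray = None    # (n_atoms,) in Angstrom^2
    elements: list = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.resnum, self.icode)

    @property
    def aa1(self) -> str:
        return AA3_TO_1[self.name]

    def atom(self, name: str) -> np.ndarray | None:
        try:
            return self.coords[self.atom_names.index(name)]
        except ValueError:
            return None

    def _sidechain_idx(self) -> list:
        return [i for i, n in enumerate(self.atom_names) if n not in BACKBONE_ATOMS]

    @property
    def sidechain_coords(self) -> np.ndarray:
        return self.coords[self._sidechain_idx()]

    @property
    def centroid(self) -> np.ndarray:
        """Unweighted mean of side-chain heavy atoms; CA for Gly or when none."""
        sc = self.sidechain_coords
        if len(sc) == 0:
            ca = self.atom("CA")
            if ca is None:
                raise ParseError(f"residue {self.key} has neither side chain nor CA")
            return ca.copy()
        return sc.mean(axis=0)


@dataclass
class StructureModel:
    """An ordered multi-chain structure, used as its biological assembly."""

    structure_id: str
    chains: dict                       # chain id -> list[Residue], file order
    source_format: str = "PDB"         # "PDB" or "mmCIF"
    is_biounit: bool = True
    het_records: list = field(default_factory=list)
    scored_chains: list = field(default_factory=list)

    def __post_init__(self):
        if not self.scored_chains:
            self.scored_chains = list(self.chains)
        seen = set()
        for res in self.residues():
            if res.key in seen:
                raise ParseError(f"duplicate residue key {res.key}")
            seen.add(res.key)

    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def residue_keys(self) -> list:
        return [r.key for r in self.residues()]

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def chain_length(self, chain_id: str) -> int:
        return len(self.chains[chain_id])


def _pick_altlocs(res: gemmi.Residue) -> list:
    """Resolve alternate conformers: highest occupancy, ties -> first in file."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        if atom.is_hydrogen():
            continue
        name = atom.name
        if name not in best:
            best[name] = atom
            order.append(name)
        elif atom.occ > best[name].occ:
            best[name] = atom
    return [best[n] for n in order]


def load_structure(path: str | Path, chain_selection: list | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Non-amino-acid components (waters, lipids, ligands, non-canonical
    residues) are dropped from the residue lists but recorded in
    ``het_records``. ``chain_selection`` restricts which chains are scored
    downstream; all chains are retained as interaction context.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    fmt = "mmCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"
    st.remove_hydrogens()
    if len(st) == 0:
        raise ParseError(f"{path}: no coordinate model found")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    het: list[tuple] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            icode = res.seqid.icode.strip()
            if res.name not in AA3_TO_1:
                het.append((chain.name, res.name, res.seqid.num, icode))
                if res.name not in ("HOH", "DOD"):
                    log.warning("%s: non-canonical residue %s %s/%d kept as het record",
                                path.name, res.name, chain.name, res.seqid.num)
                continue
            atoms = _pick_altlocs(res)
            if not atoms:
                continue
            residues.append(Residue(
                chain_id=chain.name, resnum=res.seqid.num, icode=icode,
                name=res.name,
                atom_names=[a.name for a in atoms],
                coords=np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms]),
                bfactors=np.array([a.b_iso for a in atoms]),
                elements=[a.element.name for a in atoms],
            ))
        if residues:
            chains[chain.name] = residues

    if chain_selection is not None:
        missing = [c for c in chain_selection if c not in chains]
        if missing or not chain_selection:
            raise EmptyModelError(
                f"{path}: selected chain(s) {missing or chain_selection} contain no "
                f"amino-acid residues; available: {sorted(chains)}")
    if not chains:
        raise EmptyModelError(f"{path}: no amino-acid residues in any chain")

    return StructureModel(
        structure_id=path.stem, chains=chains, source_format=fmt,
        het_records=het, scored_chains=list(chain_selection or chains),
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model to a PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = model.structure_id
    gmodel = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gchain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.resnum, res.icode or " ")
            for name, xyz, b, el in zip(res.atom_names, res.coords,
                                        res.bfactors, res.elements):
                atom = gemmi.Atom()
                atom.name = name
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.b_iso = float(b)
                atom.occ = 1.0
                atom.element = gemmi.Element(el)
                gres.add_atom(atom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Membrane labels
# ---------------------------------------------------------------------------

@dataclass
class MembraneLabels:
    """Per-residue TM/EM assignment covering exactly one structure."""

    labels: dict                   # ResidueKey -> "TM" | "EM"
    provenance: str                # "explicit_file" | "z_slab"

    def __getitem__(self, key: ResidueKey) -> str:
        return self.labels[key]

    def is_tm(self, key: ResidueKey) -> bool:
        return self.labels[key] == "TM"

    def tm_fraction(self) -> float:
        vals = list(self.labels.values())
        return sum(v == "TM" for v in vals) / len(vals)


def read_label_file(path: str | Path) -> dict:
    """Parse a label TSV with header ``chain  resnum  icode  label``."""
    labels: dict[ResidueKey, str] = {}
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.strip() or line.startswith("#") or line.startswith("chain\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 4 or parts[3] not in ("TM", "EM"):
            raise ParseError(f"{path}:{i + 1}: bad label record {line!r}")
        chain, resnum, icode, label = parts
        labels[(chain, int(resnum), icode.strip())] = label
    return labels


def write_label_file(labels: MembraneLabels, path: str | Path) -> None:
    rows = ["chain\tresnum\ticode\tlabel"]
    rows += [f"{c}\t{n}\t{i}\t{lab}" for (c, n, i), lab in labels.labels.items()]
    Path(path).write_text("\n".join(rows) + "\n")


def assign_membrane_labels(model: StructureModel,
                           annotation) -> MembraneLabels:
    """Attach TM/EM labels from an explicit file or a membrane slab.

    ``annotation`` is either a path to a label TSV, a pre-parsed
    ``{key: label}`` dict, or a ``(z_lo, z_hi)`` pair in Angstrom defining a
    slab normal to z. Slab mode labels a residue TM iff its side-chain
    centroid z lies in the **closed** interval [z_lo, z_hi].
    """
    if isinstance(annotation, (tuple, list)) and len(annotation) == 2:
        z_lo, z_hi = map(float, annotation)
        if z_lo >= z_hi:
            raise InvalidSlabError(f"z_lo={z_lo} must be < z_hi={z_hi}")
        labels = {
            res.key: "TM" if z_lo <= res.centroid[2] <= z_hi else "EM"
            for res in model.residues()
        }
        return MembraneLabels(labels=labels, provenance="z_slab")

    table = annotation if isinstance(annotation, dict) else read_label_file(annotation)
    keys = model.residue_keys()
    missing = [k for k in keys if k not in table]
    if missing:
        raise CoverageError(
            f"label file misses {len(missing)} residue(s), e.g. {missing[:5]}")
    return MembraneLabels(labels={k: table[k] for k in keys},
                          provenance="explicit_file")
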