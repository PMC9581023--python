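"""Per-residue sequence/structure descriptors.

Four elementary descriptors drive the statistical potentials:

``s``  amino-acid type (index 0-19, alphabetical one-letter order);
``d``  distance between side-chain geometric centers of two residues,
       binned on [d_min, d_max) — same-chain pairs need sequence separation
       >= 2, inter-chain pairs have no separation constraint;
``t``  (phi, psi, omega) backbone torsion domain (7 domains by default, with
       a dedicated cis-omega domain); terminal or broken-backbone residues
       carry the sentinel -1 and are excluded from torsion-based counts;
``a``  solvent-accessibility bin, where accessibility is the percentage of
       the residue's ASA relative to an extended Gly-X-Gly reference.

ASA uses the Shrake-Rupley rolling-probe algorithm (biotite backend) over all
heavy atoms of the full assembly, so buried interfaces count as buried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import biotite.structure as bst
import numpy as np
from scipy.spatial import cKDTree

from .config import AA_INDEX, TORSION_DOMAIN_ORDER, DescriptorConfig
from .structure import StructureModel

log = logging.getLogger(__name__)

#: Maximum peptide-bond C-N distance; larger gaps are chain breaks.
PEPTIDE_BOND_CUTOFF = 2.5


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, range (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def _in_ranges(value: float, ranges) -> bool:
    return any(lo <= value < hi for lo, hi in ranges)


def assign_torsion_domain(phi, psi, omega, config: DescriptorConfig) -> int:
    """Map (phi, psi, omega) to a torsion-domain index; -1 if undefined."""
    if phi is None or psi is None or omega is None:
        return -1
    if abs(omega) < config.omega_cis_cutoff:
        return TORSION_DOMAIN_ORDER.index("O")
    for rule in config.torsion_domains:
        if _in_ranges(phi, rule["phi"]) and _in_ranges(psi, rule["psi"]):
            return TORSION_DOMAIN_ORDER.index(rule["name"])
    return TORSION_DOMAIN_ORDER.index("E")


@dataclass
class ResidueDescriptorTable:
    """Descriptor arrays for one structure, aligned over included residues."""

    structure_id: str
    keys: list                    # ResidueKey per row
    aa3: list
    s: np.ndarray                 # int, 0-19
    t: np.ndarray                 # int, -1 = undefined
    a: np.ndarray                 # int accessibility bin
    accessibility: np.ndarray     # percent, >= 0 (may exceed 100)
    centroids: np.ndarray         # (n, 3) Angstrom
    chain_of: np.ndarray          # int chain index per row
    pos: np.ndarray               # 0-based position within its chain
    chain_ids: list               # chain index -> chain id
    chain_lengths: np.ndarray     # residues per chain
    scored: np.ndarray            # bool, True if residue's chain is scored
    pair_i: np.ndarray            # global row index, pair partner 1 (i < j)
    pair_j: np.ndarray
    pair_d: np.ndarray            # Angstrom
    pair_dbin: np.ndarray         # int bin on [d_min, d_max)
    config_hash: str = ""

    @property
    def n_residues(self) -> int:
        return len(self.s)

    def chain_slice(self, chain_idx: int) -> slice:
        start = int(np.searchsorted(self.chain_of, chain_idx, side="left"))
        stop = int(np.searchsorted(self.chain_of, chain_idx, side="right"))
        return slice(start, stop)

    def mu_mask(self, labels, environment: str) -> np.ndarray:
        """Boolean row mask: residue carries membrane label ``environment``.

        ``labels`` is a MembraneLabels / dict keyed by residue key, or a bare
        label string applying to every residue (synthetic datasets).
        """
        if isinstance(labels, str):
            return np.full(self.n_residues, labels == environment)
        return np.array([labels[k] == environment for k in self.keys])


def _chain_torsions(residues, config: DescriptorConfig) -> np.ndarray:
    n = len(residues)
    N = [r.atom("N") for r in residues]
    CA = [r.atom("CA") for r in residues]
    C = [r.atom("C") for r in residues]
    linked = np.zeros(n, dtype=bool)  # peptide bond between i-1 and i intact
    for i in range(1, n):
        if C[i - 1] is not None and N[i] is not None:
            linked[i] = np.linalg.norm(C[i - 1] - N[i]) <= PEPTIDE_BOND_CUTOFF
    t = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        ok_here = N[i] is not None and CA[i] is not None and C[i] is not None
        if not ok_here:
            log.warning("missing backbone atoms at %s; torsion undefined",
                        residues[i].key)
            continue
        if i == 0 or i == n - 1 or not linked[i] or not linked[i + 1]:
            continue  # terminal or chain break: (phi, psi, omega) undefined
        if CA[i - 1] is None or C[i - 1] is None or N[i + 1] is None:
            continue
        phi = dihedral(C[i - 1], N[i], CA[i], C[i])
        psi = dihedral(N[i], CA[i], C[i], N[i + 1])
        omega = dihedral(CA[i - 1], C[i - 1], N[i], CA[i])
        t[i] = assign_torsion_domain(phi, psi, omega, config)
    return t


def _residue_asa(model: StructureModel, config: DescriptorConfig) -> np.ndarray:
    """Shrake-Rupley ASA per residue (sum over its heavy atoms), file order."""
    coords, elements, owner = [], [], []
    for ridx, res in enumerate(model.residues()):
        for xyz, el in zip(res.coords, res.elements):
            coords.append(xyz)
            elements.append(el if el else "C")
            owner.append(ridx)
    n_atoms = len(coords)
    arr = bst.AtomArray(n_atoms)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.element = np.asarray(elements)
    arr.res_id = np.asarray(owner) + 1
    arr.chain_id = np.full(n_atoms, "A")
    arr.atom_name = np.full(n_atoms, "X")
    arr.res_name = np.full(n_atoms, "UNK")
    atom_sasa = bst.sasa(arr, probe_radius=config.probe_radius,
                         point_number=config.sasa_points, vdw_radii="Single")
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)
    n_res = model.n_residues
    out = np.zeros(n_res)
    np.add.at(out, np.asarray(owner), atom_sasa)
    return out


def compute_descriptors(model: StructureModel,
                        config: DescriptorConfig | None = None) -> ResidueDescriptorTable:
    """Compute s, t, a, side-chain centroids and pair distances for a model."""
    config = config or DescriptorConfig()
    keys, aa3, s_idx, centroids = [], [], [], []
    chain_of, pos, scored_rows = [], [], []
    chain_ids = list(model.chains)
    t_all = []
    for ci, (chain_id, residues) in enumerate(model.chains.items()):
        t_all.append(_chain_torsions(residues, config))
        for pi, res in enumerate(residues):
            keys.append(res.key)
            aa3.append(res.name)
            s_idx.append(AA_INDEX[res.aa1])
            centroids.append(res.centroid)
            chain_of.append(ci)
            pos.append(pi)
            scored_rows.append(chain_id in model.scored_chains)
    t = np.concatenate(t_all) if t_all else np.zeros(0, dtype=np.int64)
    centroids = np.asarray(centroids).reshape(-1, 3)
    chain_of = np.asarray(chain_of, dtype=np.int64)
    pos = np.asarray(pos, dtype=np.int64)

    asa = _residue_asa(model, config)
    ref = np.array([config.ref_asa[a] for a in aa3])
    accessibility = 100.0 * asa / ref
    edges = np.asarray(config.acc_bin_edges)
    a_bin = np.clip(np.searchsorted(edges, accessibility, side="right") - 1,
                    0, len(edges) - 1)

    # Pair distances between side-chain centroids.
    tree = cKDTree(centroids)
    pairs = tree.query_pairs(r=config.d_max, output_type="ndarray")
    if len(pairs):
        pi, pj = pairs[:, 0], pairs[:, 1]
        d = np.linalg.norm(centroids[pi] - centroids[pj], axis=1)
        same_chain = chain_of[pi] == chain_of[pj]
        sep = np.abs(pos[pi] - pos[pj])
        keep = (d >= config.d_min) & (d < config.d_max) & \
               (~same_chain | (sep >= config.pair_min_sep))
        pi, pj, d = pi[keep], pj[keep], d[keep]
        dbin = np.minimum((d - config.d_min) // config.d_bin_width,
                          config.n_d_bins - 1).astype(np.int64)
    else:
        pi = pj = dbin = np.zeros(0, dtype=np.int64)
        d = np.zeros(0)

    return ResidueDescriptorTable(
        structure_id=model.structure_id, keys=keys, aa3=aa3,
        s=np.asarray(s_idx, dtype=np.int64), t=t, a=a_bin.astype(np.int64),
        accessibility=accessibility, centroids=centroids,
        chain_of=chain_of, pos=pos, chain_ids=chain_ids,
        chain_lengths=np.array([len(c) for c in model.chains.values()]),
        scored=np.asarray(scored_rows, dtype=bool),
        pair_i=pi, pair_j=pj, pair_d=d, pair_dbin=dbin,
        config_hash=config.hash(),
    )
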