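"""Synthetic structures and datasets with known ground truth.

The generator emulates what the method needs from a real membrane-protein
set: multi-chain alpha-helical bundles whose middle segment sits in a
hydrophobic slab around z = 0, with distinct amino-acid composition inside
(L/I/V/F/A-rich) versus outside (D/E/K/R/S/N-rich) the slab, realistic
backbone geometry (ideal helical torsions built by internal-coordinate
chain extension), a single pseudo-atom side chain at a residue-dependent
C-beta-direction offset, and per-residue TM/EM labels.

Ground-truth labels are defined by the geometry itself (side-chain centroid
inside the closed slab |z| <= halfwidth), so slab-mode annotation of the
written PDB reproduces the stored labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import AA1_TO_3, AA1, DescriptorConfig, load_compositions
from .energy import EnergyFeatureMatrix
from .descriptors import ResidueDescriptorTable
from .errors import MempropError
from .potentials import ENVIRONMENTS
from .structure import MembraneLabels, Residue, StructureModel

# Ideal backbone internal coordinates (Angstrom / degrees).
BOND_N_CA, BOND_CA_C, BOND_C_N, BOND_C_O = 1.458, 1.525, 1.329, 1.231
ANG_N_CA_C, ANG_CA_C_N, ANG_C_N_CA = 111.0, 116.6, 121.7
ANG_CA_C_O = 120.8
HELIX_PHI, HELIX_PSI, HELIX_OMEGA = -57.0, -47.0, 180.0

#: Pseudo side-chain offset from CA (Angstrom) per amino acid; Gly has none.
SIDECHAIN_OFFSET = {
    "A": 1.5, "C": 2.0, "D": 2.4, "E": 2.5, "F": 2.5, "H": 2.4, "I": 2.3,
    "K": 2.5, "L": 2.5, "M": 2.5, "N": 2.4, "P": 1.9, "Q": 2.5, "R": 2.5,
    "S": 1.9, "T": 1.9, "V": 1.9, "W": 2.5, "Y": 2.5,
}

_DEFAULT_TM, _DEFAULT_EM = load_compositions()


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension placement: new atom bonded to c with given internal
    coordinates (angle b-c-new, torsion a-b-c-new, degrees)."""
    theta, chi = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * (-np.cos(theta) * bc
                + np.sin(theta) * (np.cos(chi) * m + np.sin(chi) * n))
    return c + d


@dataclass
class ToyMembraneSpec:
    """Parameters of one synthetic helical membrane bundle."""

    n_chains: int = 2
    residues_per_chain: int = 50
    tm_span: tuple = (16, 35)        # 1-based inclusive residue range per chain
    tm_composition: dict = field(default_factory=lambda: dict(_DEFAULT_TM))
    em_composition: dict = field(default_factory=lambda: dict(_DEFAULT_EM))
    helix_rise: float = 1.5          # informational; set by ideal torsions
    slab_halfwidth: float = 15.0     # Angstrom
    axis_separation: float = 9.5     # helix-axis packing distance, Angstrom
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.tm_span
        if not (1 <= lo <= hi <= self.residues_per_chain):
            raise MempropError(f"tm_span {self.tm_span} outside chain bounds")
        for comp in (self.tm_composition, self.em_composition):
            if abs(sum(comp.values()) - 1.0) > 1e-6:
                raise MempropError("composition probabilities must sum to 1")


def _build_backbone(n: int) -> dict:
    """Ideal alpha-helical N/CA/C/O traces via internal-coordinate extension."""
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - ANG_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(n - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANG_CA_C_N, HELIX_PSI)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANG_C_N_CA,
                               HELIX_OMEGA)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANG_N_CA_C,
                              HELIX_PHI)
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANG_CA_C_O,
                          HELIX_PSI + 180.0)
    O[n - 1] = place_atom(N[n - 1], CA[n - 1], C[n - 1], BOND_C_O, ANG_CA_C_O,
                          HELIX_PSI + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def _align_to_z(atoms: dict, span0: int, span1: int) -> dict:
    """Rotate the helix axis onto z and center the TM span at z = 0."""
    CA = atoms["CA"]
    centered = CA - CA.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(CA[-1] - CA[0], axis) < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(np.dot(axis, z))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    out = {k: a @ R.T for k, a in atoms.items()}
    shift = out["CA"][span0:span1 + 1, 2].mean()
    for a in out.values():
        a[:, 2] -= shift
    return out


def make_toy_membrane_structure(spec: ToyMembraneSpec) -> tuple:
    """Build one synthetic bundle and its membrane labels.

    Returns ``(StructureModel, MembraneLabels)``; labels follow the slab
    criterion on side-chain centroids, so they round-trip exactly through
    slab-mode annotation of the written file.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.tm_span
    aas = sorted(spec.tm_composition)
    p_tm = np.array([spec.tm_composition[a] for a in aas])
    p_em = np.array([spec.em_composition[a] for a in aas])
    p_tm, p_em = p_tm / p_tm.sum(), p_em / p_em.sum()

    n_ch = spec.n_chains
    radius = (0.0 if n_ch == 1
              else spec.axis_separation / (2.0 * np.sin(np.pi / n_ch)))
    chains: dict[str, list[Residue]] = {}
    labels: dict = {}
    L = spec.residues_per_chain
    for ci in range(n_ch):
        chain_id = chr(ord("A") + ci)
        atoms = _build_backbone(L)
        atoms = _align_to_z(atoms, lo - 1, hi - 1)
        angle = 2.0 * np.pi * ci / n_ch
        offset = np.array([radius * np.cos(angle), radius * np.sin(angle), 0.0])
        axis_xy = atoms["CA"][:, :2].mean(axis=0)
        seq = []
        for i in range(L):
            p = p_tm if lo <= i + 1 <= hi else p_em
            seq.append(aas[rng.choice(len(aas), p=p)])
        residues = []
        for i, aa1 in enumerate(seq):
            names = ["N", "CA", "C", "O"]
            coords = [atoms[n][i] + offset for n in names]
            if aa1 != "G":
                # pseudo side chain along the radial C-beta direction: points
                # outward from the helix axis, z-component zero, so the
                # centroid height equals the CA height exactly
                radial = np.append(atoms["CA"][i, :2] - axis_xy, 0.0)
                radial /= np.linalg.norm(radial)
                cb = atoms["CA"][i] + SIDECHAIN_OFFSET[aa1] * radial
                names.append("CB")
                coords.append(cb + offset)
            coords = np.asarray(coords)
            z_ca = coords[1][2]
            bf = 15.0 + 0.5 * abs(z_ca) + rng.normal(0.0, 2.0, size=len(names))
            res = Residue(chain_id=chain_id, resnum=i + 1, icode="",
                          name=AA1_TO_3[aa1], atom_names=names, coords=coords,
                          bfactors=np.abs(bf),
                          elements=[n[0] for n in names])
            residues.append(res)
            labels[res.key] = ("TM" if abs(res.centroid[2]) <= spec.slab_halfwidth
                               else "EM")
        chains[chain_id] = residues

    model = StructureModel(structure_id=f"toy{spec.seed:04d}", chains=chains)
    # construction guarantee: the TM span sits inside the slab
    for residues in chains.values():
        for res in residues[lo - 1:hi]:
            assert abs(res.centroid[2]) <= spec.slab_halfwidth
    return model, MembraneLabels(labels=labels, provenance="z_slab")


def make_synthetic_dataset(n_proteins: int,
                           spec_template: ToyMembraneSpec | None = None,
                           seed: int = 0) -> list:
    """A varied set of polytopic bundles; ~40% TM residues overall.

    Each synthetic protein is a bundle of 6-10 transmembrane helices of
    45-55 residues — the size class of the polytopic alpha-helical membrane
    proteins this kind of analysis is derived from. Chain lengths, bundle
    sizes and span positions vary around the template; per-protein seeds are
    derived deterministically from ``seed``.
    """
    if n_proteins < 1:
        raise MempropError("n_proteins must be >= 1")
    template = spec_template or ToyMembraneSpec()
    master = np.random.default_rng(seed)
    out = []
    for p in range(n_proteins):
        n_chains = int(master.integers(6, 11))
        L = int(master.integers(45, 56))
        # 18-20 residues: the longest helical stretch that fits a 30 A slab
        tm_len = int(master.integers(18, 21))
        start = (L - tm_len) // 2 + int(master.integers(-2, 3))
        start = max(1, start)
        spec = replace(template, n_chains=n_chains, residues_per_chain=L,
                       tm_span=(start, min(L, start + tm_len - 1)),
                       seed=int(master.integers(2 ** 31)))
        model, labels = make_toy_membrane_structure(spec)
        model.structure_id = f"syn{p:03d}"
        out.append((model, labels))
    return out


# ---------------------------------------------------------------------------
# Regression and counting fixtures
# ---------------------------------------------------------------------------

def make_regression_instance(n_residues: int, alpha_true=None,
                             noise_sd: float = 0.0, seed: int = 0,
                             combos: list | None = None,
                             alpha_N: float = 0.5, clip: bool = True):
    """Synthetic (features, labels) drawn from the linear scoring model.

    Feature columns (every combo/environment energy plus logL) are iid
    standard normal; O = X alpha + alpha_N + noise, clipped to [-0.5, 1.5].
    Returns (EnergyFeatureMatrix, O, alpha_true, alpha_N).
    """
    combos = combos or DescriptorConfig().combos
    columns = [f"{c}.{e}" for c in combos for e in ENVIRONMENTS] + ["logL"]
    rng = np.random.default_rng(seed)
    if alpha_true is None:
        alpha_true = rng.normal(0.0, 0.015, size=len(columns))
    alpha_true = np.asarray(alpha_true, dtype=float)
    if len(alpha_true) != len(columns):
        raise MempropError("alpha_true length does not match combo manifest")
    X = rng.standard_normal((n_residues, len(columns)))
    O = X @ alpha_true + alpha_N + rng.normal(0.0, noise_sd, size=n_residues)
    if clip:
        O = np.clip(O, -0.5, 1.5)
    index = pd.MultiIndex.from_arrays(
        [np.full(n_residues, "A"), np.arange(1, n_residues + 1),
         np.full(n_residues, "")], names=["chain", "resnum", "icode"])
    df = pd.DataFrame(X, columns=columns, index=index)
    feats = EnergyFeatureMatrix(features=df, aa=["ALA"] * n_residues,
                                beta=0.0, gamma=0.0, config_hash="")
    return feats, O, alpha_true, alpha_N


def make_independent_descriptor_table(n_residues: int,
                                      pairs_per_residue: int = 20,
                                      seed: int = 0,
                                      config: DescriptorConfig | None = None
                                      ) -> ResidueDescriptorTable:
    """One long synthetic chain with mutually independent descriptors.

    s, t and a are drawn iid uniform per residue and pair distances iid
    uniform per random residue pair, so every derived potential should
    vanish up to counting noise — the independence null of the inverse
    Boltzmann construction.
    """
    config = config or DescriptorConfig()
    rng = np.random.default_rng(seed)
    n = n_residues
    s = rng.integers(0, len(AA1), n)
    t = rng.integers(0, config.n_torsion_domains, n)
    a = rng.integers(0, config.n_acc_bins, n)
    m = n * pairs_per_residue
    pi = rng.integers(0, n - 2, m)
    pj = rng.integers(pi + 2, n)
    d = rng.uniform(config.d_min, config.d_max, m)
    dbin = np.minimum((d - config.d_min) // config.d_bin_width,
                      config.n_d_bins - 1).astype(np.int64)
    return ResidueDescriptorTable(
        structure_id=f"iid{seed}", keys=None, aa3=None,
        s=s.astype(np.int64), t=t.astype(np.int64), a=a.astype(np.int64),
        accessibility=np.zeros(n), centroids=np.zeros((n, 3)),
        chain_of=np.zeros(n, dtype=np.int64), pos=np.arange(n),
        chain_ids=["A"], chain_lengths=np.array([n]),
        scored=np.ones(n, dtype=bool),
        pair_i=pi.astype(np.int64), pair_j=pj.astype(np.int64),
        pair_d=d, pair_dbin=dbin, config_hash=config.hash())
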