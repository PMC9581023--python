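"""Descriptor configuration: torsion domains, bins, ASA reference, combo list.

Everything that parameterizes descriptor extraction and potential derivation
lives here, so that a potential suite can record exactly how it was built
(``config_hash``) and refuse to score structures described differently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

#: Canonical amino acids, one-letter, alphabetical. Index = descriptor ``s``.
AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA1)}

AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: Default (phi, psi) torsion domains, checked in order; the cis-omega domain
#: "O" (|omega| < 90 deg) takes precedence over all of them. Ranges are
#: half-open [lo, hi) in degrees on (-180, 180]; a residue matching no rule
#: falls into the catch-all "E". The map is data and can be replaced wholesale.
DEFAULT_TORSION_DOMAINS = [
    {"name": "A", "phi": [[-120.0, 0.0]], "psi": [[-90.0, 30.0]]},
    {"name": "C", "phi": [[-120.0, 0.0]], "psi": [[30.0, 120.0]]},
    {"name": "P", "phi": [[-120.0, 0.0]], "psi": [[120.0, 150.0]]},
    {"name": "B", "phi": [[-180.0, -120.0], [150.0, 180.001]],
     "psi": [[60.0, 180.001], [-180.0, -150.0]]},
    {"name": "G", "phi": [[0.0, 180.001]], "psi": [[-60.0, 120.0]]},
]
TORSION_DOMAIN_ORDER = ["A", "C", "P", "B", "G", "E", "O"]

#: The eleven descriptor combinations named in the main derivation; the suite
#: accepts any combo string over {s, d, t, a} with <= 3 slots that matches a
#: supported counting pattern.
DEFAULT_COMBOS = ["st", "sa", "sst", "ssa", "sd", "tt", "aa", "sds", "saa", "stt", "ss"]


def _load_ref_asa() -> dict[str, float]:
    text = resources.files("memprop.data").joinpath("ref_asa_gxg.tsv").read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("aa\t"):
            continue
        aa, val = line.split("\t")
        table[aa] = float(val)
    return table


def load_class_colors() -> list[tuple[str, str]]:
    """Return the nine (label, hex color) stability classes, index order."""
    text = resources.files("memprop.data").joinpath("class_colors.tsv").read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("index\t"):
            continue
        _, label, color = line.split("\t")
        rows.append((label, color))
    return rows


def load_compositions() -> tuple[dict[str, float], dict[str, float]]:
    """Default (tm, em) amino-acid compositions for the fixture generator."""
    text = resources.files("memprop.data").joinpath("compositions.tsv").read_text()
    tm: dict[str, float] = {}
    em: dict[str, float] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("aa\t"):
            continue
        aa, p_tm, p_em = line.split("\t")
        tm[aa] = float(p_tm)
        em[aa] = float(p_em)
    return tm, em


@dataclass
class DescriptorConfig:
    """All knobs of descriptor extraction and potential derivation.

    Intervals are half-open [lo, hi) throughout, except the membrane slab
    (closed, see :func:`memprop.structure.assign_membrane_labels`).
    """

    torsion_domains: list = field(default_factory=lambda: [dict(d) for d in DEFAULT_TORSION_DOMAINS])
    omega_cis_cutoff: float = 90.0          # |omega| below this (deg) -> domain "O"
    acc_bin_edges: list = field(default_factory=lambda: [0.0, 5.0, 15.0, 30.0, 50.0])
    d_min: float = 3.0                      # Angstrom
    d_max: float = 8.0
    d_bin_width: float = 0.2
    probe_radius: float = 1.4               # Angstrom, rolling probe
    sasa_points: int = 10000                # sphere points per atom; keeps the
                                            # ASA rotation error below ~0.25%
    window: int = 8                         # |i-j| <= window for t/a vs s pairing
    pair_min_sep: int = 2                   # min |i-j| for same-chain pair combos
    combos: list = field(default_factory=lambda: list(DEFAULT_COMBOS))
    pseudocount: float = 1.0                # added to every joint count cell
    kT: float = 1.0                         # energy unit of the potentials
    ref_asa: dict = field(default_factory=_load_ref_asa)

    # ---- derived dimensions -------------------------------------------------

    @property
    def n_torsion_domains(self) -> int:
        return len(TORSION_DOMAIN_ORDER)

    @property
    def n_acc_bins(self) -> int:
        return len(self.acc_bin_edges)

    @property
    def n_d_bins(self) -> int:
        span = self.d_max - self.d_min
        return int(round(span / self.d_bin_width))

    def descriptor_dim(self, letter: str) -> int:
        return {"s": len(AA1), "t": self.n_torsion_domains,
                "a": self.n_acc_bins, "d": self.n_d_bins}[letter]

    # ---- provenance ---------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorConfig":
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "DescriptorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
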