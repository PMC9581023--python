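"""Environment-specific statistical mean-force potentials.

Frequencies of descriptor combinations are counted over a structure set,
restricted to residues of one membrane environment (TM or EM), and turned
into free-energy-like scores with the inverse Boltzmann law:

    first order    dW(x, y)    = -kT * ln[ F(x,y) / (F(x) F(y)) ]
    second order   dW(x, y, z) = -kT * ln[ F(x,y,z) F(x) F(y) F(z)
                                           / (F(x,y) F(x,z) F(y,z)) ]

An observation enters the counts of environment mu only if *every* residue
carrying one of its descriptors is labeled mu. Torsion (t) and accessibility
(a) descriptors must lie within ``window`` (default 8) sequence positions of
the amino-acid descriptor s they are paired with — a 17-residue window
centered on s. Distance (d) observations use the configured distance range;
same-chain structure-descriptor pairs (ss, tt, aa) use separations in
[pair_min_sep, window].

Counting is symmetrized wherever two slots are exchangeable, so e.g. the
"ss" and "sds" tables are exactly symmetric under swapping the two s axes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .config import DescriptorConfig
from .descriptors import ResidueDescriptorTable
from .errors import EmptyCountsError, MempropError
from .structure import MembraneLabels

log = logging.getLogger(__name__)

ENVIRONMENTS = ("TM", "EM")

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Combo grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComboSpec:
    """How a combo string over {s, d, t, a} is counted and allocated.

    families:
      ``pair_same``            xx   — unordered same-chain pair, both slots x
      ``center_partner``       xy   — partner slot 0 within the window of the
                                      center residue carrying slot 1
      ``center_two_partners``  xxy  — two unordered partners + center (slot 2)
      ``center_pair_struct``   xyy  — center s-like slot 0, structure slots on
                                      an unordered residue pair in its window
      ``dist_endpoint``        xd   — distance pair, endpoint descriptor x
      ``dist_pair``            xdy  — distance pair with both endpoint slots
    """

    combo: str
    family: str
    letters: tuple
    sym_axes: tuple | None = None  # axis pair symmetrized during counting

    @property
    def order(self) -> int:
        return len(self.letters)


def parse_combo(combo: str) -> ComboSpec:
    if not (2 <= len(combo) <= 3) or any(c not in "sdta" for c in combo):
        raise MempropError(f"unsupported combo {combo!r}")
    letters = tuple(combo)
    if "d" in combo:
        if len(combo) == 2:
            if combo.count("d") != 1:
                raise MempropError(f"unsupported combo {combo!r}")
            return ComboSpec(combo, "dist_endpoint", letters)
        if combo[1] != "d" or "d" in (combo[0], combo[2]):
            raise MempropError(f"unsupported combo {combo!r}: distance slot "
                               "must be the middle of three")
        sym = (0, 2) if combo[0] == combo[2] else None
        return ComboSpec(combo, "dist_pair", letters, sym)
    if len(combo) == 2:
        if combo[0] == combo[1]:
            return ComboSpec(combo, "pair_same", letters, (0, 1))
        return ComboSpec(combo, "center_partner", letters)
    if combo[0] == combo[1]:
        return ComboSpec(combo, "center_two_partners", letters, (0, 1))
    if combo[1] == combo[2]:
        return ComboSpec(combo, "center_pair_struct", letters, (1, 2))
    raise MempropError(f"unsupported combo {combo!r}: three distinct slots")


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def _role_arrays(table: ResidueDescriptorTable, mu: np.ndarray):
    vals = {"s": table.s, "t": table.t, "a": table.a}
    ok = {"s": mu, "t": mu & (table.t >= 0), "a": mu}
    return vals, ok


def _windows(L: int, o: int):
    """Slices (center, shifted) such that shifted = center + o, both in range."""
    if o >= 0:
        return slice(0, L - o), slice(o, L)
    return slice(-o, L), slice(0, L + o)


def count_raw(table: ResidueDescriptorTable, labels,
              combo: str, environment: str,
              config: DescriptorConfig) -> np.ndarray:
    """Raw integer count tensor of one combo/environment for one structure."""
    spec = parse_combo(combo)
    dims = tuple(config.descriptor_dim(l) for l in spec.letters)
    counts = np.zeros(int(np.prod(dims)), dtype=np.int64)
    mu = table.mu_mask(labels, environment)
    vals, ok = _role_arrays(table, mu)
    W = config.window

    def bump(idx_arrays, mask):
        flat = np.ravel_multi_index([ix[mask] for ix in idx_arrays], dims)
        counts[:] += np.bincount(flat, minlength=counts.size)

    if spec.family in ("pair_same", "center_partner",
                       "center_two_partners", "center_pair_struct"):
        for ci in range(len(table.chain_ids)):
            sl = table.chain_slice(ci)
            L = sl.stop - sl.start
            v = {k: a[sl] for k, a in vals.items()}
            o_ = {k: a[sl] for k, a in ok.items()}
            if spec.family == "center_partner":
                p, c = spec.letters
                for o in range(-W, W + 1):
                    si, sj = _windows(L, o)
                    m = o_[c][si] & o_[p][sj]
                    bump((v[p][sj], v[c][si]), m)
            elif spec.family == "pair_same":
                x = spec.letters[0]
                for o in range(config.pair_min_sep, W + 1):
                    si, sj = _windows(L, o)
                    m = o_[x][si] & o_[x][sj]
                    bump((v[x][si], v[x][sj]), m)
                    bump((v[x][sj], v[x][si]), m)
            elif spec.family == "center_two_partners":
                p, _, c = spec.letters
                for o1, o2 in combinations(range(-W, W + 1), 2):
                    lo, hi = max(0, -o1, -o2), L - max(0, o1, o2)
                    if hi <= lo:
                        continue
                    i = slice(lo, hi)
                    j = slice(lo + o1, hi + o1)
                    k = slice(lo + o2, hi + o2)
                    m = o_[c][i] & o_[p][j] & o_[p][k]
                    bump((v[p][j], v[p][k], v[c][i]), m)
                    bump((v[p][k], v[p][j], v[c][i]), m)
            else:  # center_pair_struct
                c, x, _ = spec.letters
                for o1, o2 in combinations(range(-W, W + 1), 2):
                    lo, hi = max(0, -o1, -o2), L - max(0, o1, o2)
                    if hi <= lo:
                        continue
                    kc = slice(lo, hi)
                    i = slice(lo + o1, hi + o1)
                    j = slice(lo + o2, hi + o2)
                    m = o_[c][kc] & o_[x][i] & o_[x][j]
                    bump((v[c][kc], v[x][i], v[x][j]), m)
                    bump((v[c][kc], v[x][j], v[x][i]), m)
    elif spec.family == "dist_endpoint":
        d_axis = spec.letters.index("d")
        x = spec.letters[1 - d_axis]
        pi, pj, db = table.pair_i, table.pair_j, table.pair_dbin
        m = ok[x][pi] & ok[x][pj]
        for end in (pi, pj):
            ix = [None, None]
            ix[d_axis] = db
            ix[1 - d_axis] = vals[x][end]
            bump(tuple(ix), m)
    else:  # dist_pair
        x, _, y = spec.letters
        pi, pj, db = table.pair_i, table.pair_j, table.pair_dbin
        for a_end, b_end in ((pi, pj), (pj, pi)):
            m = ok[x][a_end] & ok[y][b_end]
            bump((vals[x][a_end], db, vals[y][b_end]), m)

    return counts.reshape(dims)


@dataclass
class FrequencyModel:
    """Regularized relative frequencies of one combo in one environment.

    The pseudocount is added to every joint cell; marginals and lower-order
    joints are re-derived from the regularized joint, so that marginalizing
    any table reproduces the corresponding marginal exactly.
    """

    combo: str
    environment: str
    raw_counts: np.ndarray
    pseudocount: float = 1.0

    @property
    def n_obs(self) -> int:
        return int(self.raw_counts.sum())

    @property
    def joint(self) -> np.ndarray:
        reg = self.raw_counts + self.pseudocount
        total = reg.sum()
        if total == 0:
            raise EmptyCountsError(
                f"no observations for combo {self.combo!r} / {self.environment}")
        return reg / total

    def marginal(self, axes) -> np.ndarray:
        """Frequency table keeping only ``axes`` (tuple of axis indices)."""
        drop = tuple(i for i in range(self.raw_counts.ndim) if i not in axes)
        return self.joint.sum(axis=drop)


def count_frequencies(dataset, combo: str, environment: str,
                      config: DescriptorConfig) -> FrequencyModel:
    """Count a combo over a dataset of (descriptor table, labels) pairs."""
    if not dataset:
        raise EmptyCountsError(f"empty dataset for combo {combo!r} / {environment}")
    total = None
    for table, labels in dataset:
        c = count_raw(table, labels, combo, environment, config)
        total = c if total is None else total + c
    model = FrequencyModel(combo, environment, total, config.pseudocount)
    if model.n_obs == 0:
        raise EmptyCountsError(
            f"zero observations for combo {combo!r} / {environment}")
    return model


# ---------------------------------------------------------------------------
# Inverse Boltzmann
# ---------------------------------------------------------------------------

@dataclass
class PotentialTable:
    """dW lookup over the descriptor-index grid, in units of kT."""

    combo: str
    environment: str
    letters: tuple
    values: np.ndarray
    kT: float = 1.0


def derive_potential(freqs: FrequencyModel, kT: float = 1.0) -> PotentialTable:
    """Turn regularized frequencies into a mean-force potential table."""
    if np.isnan(freqs.raw_counts).any():
        raise MempropError("NaN in frequency counts")
    spec = parse_combo(freqs.combo)
    joint = freqs.joint
    support = (freqs.raw_counts + freqs.pseudocount) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        if joint.ndim == 2:
            fx = freqs.marginal((0,))
            fy = freqs.marginal((1,))
            ratio = joint / (fx[:, None] * fy[None, :])
        else:
            fx, fy, fz = (freqs.marginal((i,)) for i in range(3))
            fxy = freqs.marginal((0, 1))
            fxz = freqs.marginal((0, 2))
            fyz = freqs.marginal((1, 2))
            num = joint * fx[:, None, None] * fy[None, :, None] * fz[None, None, :]
            den = fxy[:, :, None] * fxz[:, None, :] * fyz[None, :, :]
            ratio = num / den
        values = -kT * np.log(ratio)
    if not support.all():
        log.warning("combo %s/%s: %d cells without support set to 0",
                    freqs.combo, freqs.environment, int((~support).sum()))
        values = np.where(support, values, 0.0)
    if np.isnan(values).any():
        raise MempropError(f"NaN potential cells in {freqs.combo}/{freqs.environment}")
    return PotentialTable(freqs.combo, freqs.environment, spec.letters, values, kT)


# ---------------------------------------------------------------------------
# Suite
# ---------------------------------------------------------------------------

@dataclass
class PotentialSuite:
    """All dW tables, one per (combo, environment), plus provenance."""

    tables: dict                       # (combo, env) -> PotentialTable
    config: DescriptorConfig
    provenance: list = field(default_factory=list)

    @property
    def combos(self) -> list:
        seen = []
        for combo, _ in self.tables:
            if combo not in seen:
                seen.append(combo)
        return seen

    def __getitem__(self, key) -> PotentialTable:
        return self.tables[key]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": FORMAT_VERSION,
            "kind": "potential_suite",
            "combos": self.combos,
            "environments": list(ENVIRONMENTS),
            "config": self.config.to_dict(),
            "config_hash": self.config.hash(),
            "provenance": self.provenance,
            "tables": {},
        }
        for (combo, env), table in self.tables.items():
            fname = f"{combo}.{env}.tsv"
            manifest["tables"][f"{combo}.{env}"] = fname
            lines = ["\t".join(list(table.letters) + ["dW"])]
            for idx in np.ndindex(table.values.shape):
                lines.append("\t".join(
                    [str(i) for i in idx] + [repr(float(table.values[idx]))]))
            (path / fname).write_text("\n".join(lines) + "\n")
        (path / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PotentialSuite":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        config = DescriptorConfig.from_dict(manifest["config"])
        tables = {}
        # rebuild in manifest combo order (the JSON dict keys are sorted)
        keys = [f"{combo}.{env}" for combo in manifest["combos"]
                for env in manifest["environments"]]
        for key in keys:
            fname = manifest["tables"][key]
            combo, env = key.rsplit(".", 1)
            spec = parse_combo(combo)
            dims = tuple(config.descriptor_dim(l) for l in spec.letters)
            values = np.zeros(dims)
            for line in (path / fname).read_text().splitlines()[1:]:
                *idx, v = line.split("\t")
                values[tuple(map(int, idx))] = float(v)
            tables[(combo, env)] = PotentialTable(
                combo, env, spec.letters, values, config.kT)
        return cls(tables=tables, config=config,
                   provenance=manifest["provenance"])


def build_potential_suite(dataset, combos: list | None = None,
                          config: DescriptorConfig | None = None) -> PotentialSuite:
    """Derive TM and EM potentials for every combo from a labeled dataset.

    ``dataset`` is a list of (ResidueDescriptorTable, MembraneLabels). The
    result is deterministic and independent of dataset order.
    """
    config = config or DescriptorConfig()
    combos = combos if combos is not None else config.combos
    if not combos:
        raise MempropError("empty combo list")
    tables = {}
    for combo in combos:
        for env in ENVIRONMENTS:
            freqs = count_frequencies(dataset, combo, env, config)
            tables[(combo, env)] = derive_potential(freqs, config.kT)
    provenance = [t.structure_id for t, _ in dataset]
    return PotentialSuite(tables=tables, config=config, provenance=provenance)
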