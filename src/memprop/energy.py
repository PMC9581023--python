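"""Per-residue folding free-energy decomposition and feature assembly.

Each potential table is decomposed into per-residue contributions by giving
the energy of every counted observation to the residues that carry its
structure descriptors:

* combos whose structure descriptor sits on a single residue (st, sa, sst,
  ssa) assign the full dW to that center residue, summed over all s-partners
  in the 17-residue window;
* combos whose structure descriptors sit on two residues (sd, tt, aa, sds,
  saa, stt, and the pure-sequence ss) split the observation energy half/half
  between the two carriers.

Where counting symmetrized an observation into both slot orders, each order
carries half of the symmetric dW, so per-residue sums recombine exactly to
the per-interaction totals (the conservation property tested in the suite).

Both environments (TM and EM) are evaluated for every residue irrespective
of where the residue actually sits; the smoothed profiles for all (combo,
environment) pairs, plus a log-length column, form the feature matrix of the
membrane propensity model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .config import DescriptorConfig
from .descriptors import ResidueDescriptorTable, compute_descriptors
from .errors import ConfigMismatchError, ParameterError
from .potentials import ENVIRONMENTS, PotentialSuite, PotentialTable, parse_combo
from .structure import StructureModel


@dataclass
class EnergyProfile:
    """Per-residue dG of one (combo, environment) over one structure."""

    desc: ResidueDescriptorTable
    combo: str
    environment: str
    values: np.ndarray
    mask: np.ndarray            # True = residue lacks a descriptor the combo needs
    smoothed: bool = False
    beta: float = 0.0
    gamma: float = 0.0


def per_residue_energy(desc: ResidueDescriptorTable, table: PotentialTable,
                       config: DescriptorConfig | None = None) -> EnergyProfile:
    """Allocate a potential table's energies onto the residues of one structure."""
    config = config or DescriptorConfig()
    if desc.config_hash and desc.config_hash != config.hash():
        raise ConfigMismatchError(
            "descriptor table and potential config hashes differ")
    spec = parse_combo(table.combo)
    W = table.values
    n = desc.n_residues
    out = np.zeros(n)
    vals = {"s": desc.s, "t": desc.t, "a": desc.a}
    ok = {"s": np.ones(n, dtype=bool), "t": desc.t >= 0,
          "a": np.ones(n, dtype=bool)}
    Wn = config.window

    if spec.family in ("center_partner", "pair_same",
                       "center_two_partners", "center_pair_struct"):
        for ci in range(len(desc.chain_ids)):
            sl = desc.chain_slice(ci)
            L = sl.stop - sl.start
            base = sl.start
            v = {k: a[sl] for k, a in vals.items()}
            o_ = {k: a[sl] for k, a in ok.items()}

            def idx_of(s, m):
                return base + np.arange(s.start, s.stop)[m]

            if spec.family == "center_partner":
                p, c = spec.letters
                for o in range(-Wn, Wn + 1):
                    lo, hi = max(0, -o), L - max(0, o)
                    if hi <= lo:
                        continue
                    si, sj = slice(lo, hi), slice(lo + o, hi + o)
                    m = o_[c][si] & o_[p][sj]
                    out[idx_of(si, m)] += W[v[p][sj][m], v[c][si][m]]
            elif spec.family == "pair_same":
                x = spec.letters[0]
                for o in range(config.pair_min_sep, Wn + 1):
                    lo, hi = 0, L - o
                    if hi <= lo:
                        continue
                    si, sj = slice(lo, hi), slice(lo + o, hi + o)
                    m = o_[x][si] & o_[x][sj]
                    w = W[v[x][si][m], v[x][sj][m]]
                    out[idx_of(si, m)] += w / 2
                    out[idx_of(sj, m)] += w / 2
            elif spec.family == "center_two_partners":
                p, _, c = spec.letters
                for o1, o2 in combinations(range(-Wn, Wn + 1), 2):
                    lo, hi = max(0, -o1, -o2), L - max(0, o1, o2)
                    if hi <= lo:
                        continue
                    si = slice(lo, hi)
                    sj = slice(lo + o1, hi + o1)
                    sk = slice(lo + o2, hi + o2)
                    m = o_[c][si] & o_[p][sj] & o_[p][sk]
                    out[idx_of(si, m)] += W[v[p][sj][m], v[p][sk][m], v[c][si][m]]
            else:  # center_pair_struct
                c, x, _ = spec.letters
                for o1, o2 in combinations(range(-Wn, Wn + 1), 2):
                    lo, hi = max(0, -o1, -o2), L - max(0, o1, o2)
                    if hi <= lo:
                        continue
                    sc = slice(lo, hi)
                    si = slice(lo + o1, hi + o1)
                    sj = slice(lo + o2, hi + o2)
                    m = o_[c][sc] & o_[x][si] & o_[x][sj]
                    w = W[v[c][sc][m], v[x][si][m], v[x][sj][m]]
                    out[idx_of(si, m)] += w / 2
                    out[idx_of(sj, m)] += w / 2
    elif spec.family == "dist_endpoint":
        d_axis = spec.letters.index("d")
        x = spec.letters[1 - d_axis]
        pi, pj, db = desc.pair_i, desc.pair_j, desc.pair_dbin
        m = ok[x][pi] & ok[x][pj]
        for end in (pi, pj):
            ix = [None, None]
            ix[d_axis] = db[m]
            ix[1 - d_axis] = vals[x][end][m]
            w = W[tuple(ix)] / 2          # each endpoint observation: dW / 2
            np.add.at(out, pi[m], w / 2)  # split half/half between carriers
            np.add.at(out, pj[m], w / 2)
    else:  # dist_pair
        x, _, y = spec.letters
        pi, pj, db = desc.pair_i, desc.pair_j, desc.pair_dbin
        for a_end, b_end in ((pi, pj), (pj, pi)):
            m = ok[x][a_end] & ok[y][b_end]
            w = W[vals[x][a_end][m], db[m], vals[y][b_end][m]] / 2
            np.add.at(out, a_end[m], w / 2)
            np.add.at(out, b_end[m], w / 2)

    mask = np.zeros(n, dtype=bool)
    for letter in set(spec.letters) - {"d"}:
        mask |= ~ok[letter]
    out[mask] = 0.0
    return EnergyProfile(desc=desc, combo=table.combo,
                         environment=table.environment,
                         values=out, mask=mask)


def smooth_profile(profile: EnergyProfile, beta: float, gamma: float) -> EnergyProfile:
    """Weighted 5-residue window average of a per-residue energy profile.

    dGbar_i = [g*(dG_{i-2}+dG_{i+2}) + b*(dG_{i-1}+dG_{i+1}) + dG_i]
              / (1 + 2b + 2g); at chain termini the window truncates to the
    residues present and the normalizer shrinks accordingly.
    """
    if beta < 0 or gamma < 0:
        raise ParameterError(f"smoothing weights must be >= 0, got {beta}, {gamma}")
    desc = profile.desc
    weights = {-2: gamma, -1: beta, 0: 1.0, 1: beta, 2: gamma}
    out = np.zeros_like(profile.values)
    for ci in range(len(desc.chain_ids)):
        sl = desc.chain_slice(ci)
        v = profile.values[sl]
        L = len(v)
        num = np.zeros(L)
        den = np.zeros(L)
        for o, w in weights.items():
            lo, hi = max(0, -o), L - max(0, o)
            if hi <= lo:
                continue
            num[lo:hi] += w * v[lo + o:hi + o]
            den[lo:hi] += w
        out[sl] = num / den
    return replace(profile, values=out, smoothed=True, beta=beta, gamma=gamma)


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass
class EnergyFeatureMatrix:
    """Smoothed (combo, environment) energies per scored residue + log length."""

    features: pd.DataFrame      # index (chain, resnum, icode); manifest order
    aa: list                    # three-letter code per row
    beta: float
    gamma: float
    config_hash: str

    @property
    def columns(self) -> list:
        return list(self.features.columns)

    def to_tsv(self, path) -> None:
        df = self.features.reset_index()
        df.insert(3, "aa", self.aa)
        df.to_csv(path, sep="\t", index=False)


def raw_profiles(desc: ResidueDescriptorTable,
                 suite: PotentialSuite) -> dict:
    """Unsmoothed per-residue profiles for every (combo, environment)."""
    return {key: per_residue_energy(desc, table, suite.config)
            for key, table in suite.tables.items()}


def feature_matrix_from_profiles(desc: ResidueDescriptorTable, profiles: dict,
                                 combos: list, beta: float, gamma: float,
                                 config_hash: str = "") -> EnergyFeatureMatrix:
    columns = [f"{combo}.{env}" for combo in combos for env in ENVIRONMENTS]
    scored = desc.scored
    data = {}
    for combo in combos:
        for env in ENVIRONMENTS:
            prof = smooth_profile(profiles[(combo, env)], beta, gamma)
            data[f"{combo}.{env}"] = prof.values[scored]
    data["logL"] = np.log(desc.chain_lengths[desc.chain_of])[scored]
    index = pd.MultiIndex.from_tuples(
        [k for k, s in zip(desc.keys, scored) if s],
        names=["chain", "resnum", "icode"])
    df = pd.DataFrame(data, index=index, columns=columns + ["logL"])
    aa = [a for a, s in zip(desc.aa3, scored) if s]
    return EnergyFeatureMatrix(features=df, aa=aa, beta=beta, gamma=gamma,
                               config_hash=config_hash)


def energy_feature_matrix(model, suite: PotentialSuite,
                          beta: float, gamma: float) -> EnergyFeatureMatrix:
    """Full per-residue feature block for one structure.

    ``model`` may be a :class:`StructureModel` (descriptors are computed) or
    an already-computed :class:`ResidueDescriptorTable`. Rows cover scored
    chains only; unselected chains still contribute as interaction partners.
    The length column is ln(L) with L the residue count of the chain holding
    each residue.
    """
    desc = (compute_descriptors(model, suite.config)
            if isinstance(model, StructureModel) else model)
    profiles = raw_profiles(desc, suite)
    return feature_matrix_from_profiles(desc, profiles, suite.combos,
                                        beta, gamma, suite.config.hash())
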