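"""Downstream analyses on MPr profiles and structures.

* nine stability classes partitioning the MPr axis around the threshold
  phi0, graded in half-sigma steps of the EM-side and TM-side score spreads;
* the helix-association score T comparing an oligomer's summed MPr with its
  isolated monomers (per-monomer normalization, dimers and tetramers);
* per-residue MPr differences between two conformations of one protein;
* crystallographic B-factor normalization (zero-mean-unit-variance and
  min-max), per chain, separately for main-chain and side-chain atoms, with
  robust MAD-based outlier trimming;
* a PyMOL command-script writer coloring residues by stability class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import load_class_colors
from .errors import AlignmentError, MempropError, ParameterError
from .structure import MAINCHAIN_B_ATOMS, StructureModel

log = logging.getLogger(__name__)

CLASS_TABLE = load_class_colors()   # index -> (label, hex color)


@dataclass(frozen=True)
class StabilityClass:
    index: int
    label: str
    color: str


def class_boundaries(phi0: float, sigma_tm: float, sigma_em: float) -> np.ndarray:
    """The eight strictly increasing boundaries separating the nine classes."""
    if sigma_tm <= 0 or sigma_em <= 0:
        raise ParameterError("sigma_TM and sigma_EM must be > 0")
    return np.array([
        phi0 - 2.0 * sigma_em, phi0 - 1.5 * sigma_em,
        phi0 - 1.0 * sigma_em, phi0 - 0.5 * sigma_em,
        phi0 + 0.5 * sigma_tm, phi0 + 1.0 * sigma_tm,
        phi0 + 1.5 * sigma_tm, phi0 + 2.0 * sigma_tm,
    ])


def stability_classes(mpr, phi0: float, sigma_tm: float, sigma_em: float):
    """Vectorized class assignment: (index, label, color) arrays.

    Intervals are upper-inclusive: class k covers (b_{k-1}, b_k], the lowest
    class covers mpr <= b_0. The top boundary is claimed by the top class
    (phi0 + 2 sigma_TM <= mpr -> "Highly stable in lipids"), which resolves
    the one point the printed inequalities assign to two classes.
    """
    b = class_boundaries(phi0, sigma_tm, sigma_em)
    scores = np.atleast_1d(np.asarray(mpr, dtype=float))
    idx = np.searchsorted(b, scores, side="left")
    idx = np.where(scores >= b[-1], 8, idx)
    labels = np.array([CLASS_TABLE[i][0] for i in idx])
    colors = np.array([CLASS_TABLE[i][1] for i in idx])
    return idx, labels, colors


def stability_class(mpr: float, phi0: float, sigma_tm: float,
                    sigma_em: float) -> StabilityClass:
    """The unique stability class containing one MPr value."""
    idx, labels, colors = stability_classes([mpr], phi0, sigma_tm, sigma_em)
    return StabilityClass(int(idx[0]), str(labels[0]), str(colors[0]))


# ---------------------------------------------------------------------------
# Helix association
# ---------------------------------------------------------------------------

def association_score(complex_profile, monomer_profiles) -> float:
    """Per-monomer MPr gain of an oligomer over its isolated monomers.

    T = [ sum_i MPr_i(complex) - sum over monomers of sum_i MPr_i(monomer) ]
        / n_monomers, with n_monomers in {2, 4} (dimer or tetramer).
    """
    n = len(monomer_profiles)
    if n not in (2, 4):
        raise MempropError(f"unsupported oligomer order {n}; need 2 or 4 monomers")
    n_complex = len(complex_profile.table)
    n_monomers = sum(len(p.table) for p in monomer_profiles)
    if n_complex != n_monomers:
        raise AlignmentError(
            f"complex has {n_complex} residues but monomers total {n_monomers}")
    return (complex_profile.total()
            - sum(p.total() for p in monomer_profiles)) / n


def delta_mpr(profile_a, profile_b, mapping: dict | None = None) -> pd.Series:
    """Per-residue MPr difference a - b between two conformations.

    Profiles are matched by (chain, resnum, icode); ``mapping`` optionally
    renames keys of ``a`` onto keys of ``b`` for renumbered structures. Keys
    present in only one profile are dropped with a warning.
    """
    a = profile_a.table["mpr"]
    b = profile_b.table["mpr"]
    if mapping:
        a = a.rename(index=None)
        a.index = pd.MultiIndex.from_tuples(
            [mapping.get(k, k) for k in profile_a.table.index],
            names=profile_a.table.index.names)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise AlignmentError("profiles share no residue keys")
    if len(shared) < max(len(a), len(b)):
        log.warning("delta_mpr: only %d of %d/%d residues shared",
                    len(shared), len(a), len(b))
    return (a.loc[shared] - b.loc[shared]).rename("delta_mpr")


# ---------------------------------------------------------------------------
# B-factor normalization
# ---------------------------------------------------------------------------

def _mad_trim(values: np.ndarray, max_iter: int = 5) -> np.ndarray:
    """Boolean keep-mask after iterative median/MAD outlier removal."""
    keep = np.isfinite(values)
    for _ in range(max_iter):
        if not keep.any():
            break
        x = values[keep]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            break
        new = keep & (np.abs(values - med) <= 3.0 * 1.4826 * mad)
        if new.sum() == keep.sum():
            break
        keep = new
    return keep


def normalize_bfactors(model: StructureModel, scheme: str = "zero_mean_unit_variance",
                       remove_outliers: bool = True) -> pd.DataFrame:
    """Per-residue normalized B-factors, main chain and side chain separately.

    Per residue, B-factors are averaged over heavy main-chain atoms
    (N, CA, C, O) and over heavy side-chain atoms (absent for Gly -> NaN).
    Outliers are trimmed per chain with an iterative 3 x 1.4826 x MAD rule,
    then each chain's surviving values are normalized with the requested
    scheme: ``zero_mean_unit_variance`` -> (x - mean) / sd, or ``min_max``
    -> (x - min) / (max - min). Trimmed residues carry NaN.
    """
    if scheme not in ("zero_mean_unit_variance", "min_max"):
        raise ParameterError(f"unknown scheme {scheme!r}")
    keys, chains, mc, sc = [], [], [], []
    for res in model.residues():
        keys.append(res.key)
        chains.append(res.chain_id)
        names = res.atom_names
        mc_b = [b for n, b in zip(names, res.bfactors) if n in MAINCHAIN_B_ATOMS]
        sc_idx = res._sidechain_idx()
        mc.append(np.mean(mc_b) if mc_b else np.nan)
        sc.append(np.mean(res.bfactors[sc_idx]) if sc_idx else np.nan)
    df = pd.DataFrame({"chain": chains, "mainchain": mc, "sidechain": sc},
                      index=pd.MultiIndex.from_tuples(
                          keys, names=["chain_id", "resnum", "icode"]))
    if np.isfinite(df["mainchain"]).sum() < 2:
        raise MempropError("need B-factors for at least 2 residues")

    for col in ("mainchain", "sidechain"):
        out = np.full(len(df), np.nan)
        for chain in df["chain"].unique():
            rows = (df["chain"] == chain).to_numpy()
            x = df[col].to_numpy()[rows]
            keep = _mad_trim(x) if remove_outliers else np.isfinite(x)
            if keep.sum() < 2:
                continue
            kept = x[keep]
            if scheme == "zero_mean_unit_variance":
                sd = kept.std()
                if sd == 0:
                    raise ParameterError(
                        f"zero variance in {col} B-factors of chain {chain}")
                norm = (kept - kept.mean()) / sd
            else:
                rng = kept.max() - kept.min()
                if rng == 0:
                    raise ParameterError(
                        f"zero range in {col} B-factors of chain {chain}")
                norm = (kept - kept.min()) / rng
            tmp = np.full(keep.shape, np.nan)
            tmp[keep] = norm
            out[rows] = tmp
        df[col + "_norm"] = out
    return df.drop(columns=["chain"])


# ---------------------------------------------------------------------------
# PyMOL output
# ---------------------------------------------------------------------------

def write_pymol_script(profile, path: str | Path) -> None:
    """Write a .pml script coloring residues by their stability class."""
    lines = ["bg_color white", "hide everything", "show cartoon",
             "color gray80, all"]
    for (chain, resnum, icode), row in profile.table.iterrows():
        resi = f"{resnum}{icode}" if icode else str(resnum)
        color = "0x" + row["color"].lstrip("#")
        lines.append(f"color {color}, chain {chain} and resi {resi}")
    Path(path).write_text("\n".join(lines) + "\n")
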