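"""Stability classes, association score, MPr differences, B-factors."""

import numpy as np
import pandas as pd
import pytest

from memprop import (association_score, delta_mpr, normalize_bfactors,
                     stability_class, stability_classes, write_pymol_script)
from memprop.analysis import class_boundaries
from memprop.errors import AlignmentError, MempropError, ParameterError
from memprop.model import MPrProfile
from memprop.structure import Residue, StructureModel


def _profile(scores, chain="A", start=1, structure_id="p"):
    index = pd.MultiIndex.from_arrays(
        [np.full(len(scores), chain), np.arange(start, start + len(scores)),
         np.full(len(scores), "")], names=["chain", "resnum", "icode"])
    table = pd.DataFrame({"mpr": np.asarray(scores, dtype=float)}, index=index)
    return MPrProfile(structure_id=structure_id, table=table)


class TestStabilityClasses:
    PHI0, S_TM, S_EM = 0.45, 0.25, 0.2

    def test_first_row(self):
        c = stability_class(self.PHI0 - 2 * self.S_EM - 0.01,
                            self.PHI0, self.S_TM, self.S_EM)
        assert c.label == "Highly stable in water" and c.index == 0

    def test_threshold_itself_is_neutral(self):
        c = stability_class(self.PHI0, self.PHI0, self.S_TM, self.S_EM)
        assert c.label == "Neutral" and c.index == 4

    def test_printed_boundary_membership(self):
        b = class_boundaries(self.PHI0, self.S_TM, self.S_EM)
        # "MPr <= phi0 - 2 sigma_EM" belongs to the lowest class
        assert stability_class(b[0], self.PHI0, self.S_TM, self.S_EM).index == 0
        # upper-inclusive interior boundaries
        assert stability_class(b[3], self.PHI0, self.S_TM, self.S_EM).index == 3
        assert stability_class(b[4], self.PHI0, self.S_TM, self.S_EM).index == 4
        # "phi0 + 2 sigma_TM <= MPr" claims the top boundary point
        assert stability_class(b[7], self.PHI0, self.S_TM, self.S_EM).index == 8

    def test_partition_and_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            phi0 = rng.normal(0.4, 0.2)
            s_tm, s_em = rng.uniform(0.05, 0.5, 2)
            grid = np.sort(rng.uniform(phi0 - 2, phi0 + 2, 500))
            idx, _, _ = stability_classes(grid, phi0, s_tm, s_em)
            assert set(np.unique(idx)) <= set(range(9))
            assert (np.diff(idx) >= 0).all()   # non-decreasing in MPr

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ParameterError):
            stability_class(0.5, 0.45, 0.0, 0.2)
        with pytest.raises(ParameterError):
            stability_class(0.5, 0.45, 0.2, -0.1)


class TestAssociationScore:
    def test_identical_profiles_give_zero(self):
        a = _profile([0.5] * 10, chain="A")
        b = _profile([0.4] * 10, chain="B")
        complex_ = _profile(list(a.table["mpr"]) + list(b.table["mpr"]))
        assert association_score(complex_, [a, b]) == pytest.approx(0.0)

    def test_dimer_uniform_excess(self):
        """Every complex residue 0.1 above its monomer: T = 20*0.1/2 = 1.0."""
        a = _profile([0.5] * 10)
        b = _profile([0.3] * 10)
        complex_ = _profile([0.6] * 10 + [0.4] * 10)
        assert association_score(complex_, [a, b]) == pytest.approx(1.0)

    def test_tetramer_divisor(self):
        monos = [_profile([0.2] * 5) for _ in range(4)]
        complex_ = _profile([0.2 + 0.1] * 20)  # total excess 2.0
        assert association_score(complex_, monos) == pytest.approx(0.5)

    def test_unsupported_oligomer_order(self):
        monos = [_profile([0.1] * 5) for _ in range(3)]
        complex_ = _profile([0.1] * 15)
        with pytest.raises(MempropError):
            association_score(complex_, monos)

    def test_residue_count_mismatch(self):
        with pytest.raises(AlignmentError):
            association_score(_profile([0.1] * 9),
                              [_profile([0.1] * 5), _profile([0.1] * 5)])

    def test_antisymmetry(self):
        a, b = _profile([0.5] * 8), _profile([0.2] * 8)
        cx = _profile([0.7] * 16)
        t = association_score(cx, [a, b])
        # swapping the roles of bound and free negates the difference
        t_swapped = -(sum(p.total() for p in (a, b)) - cx.total()) / 2
        assert t == pytest.approx(t_swapped)


class TestDeltaMPr:
    def test_identical_gives_zeros(self):
        a = _profile([0.1, 0.5, 0.9])
        d = delta_mpr(a, _profile([0.1, 0.5, 0.9]))
        np.testing.assert_allclose(d, 0.0)

    def test_constant_shift(self):
        a = _profile([0.1, 0.5, 0.9])
        b = _profile([0.3, 0.7, 1.1])
        np.testing.assert_allclose(delta_mpr(a, b), -0.2)

    def test_mapping_spot_checks(self):
        a = _profile(np.linspace(0, 1, 5), start=101)
        b = _profile(np.linspace(1, 0, 5), start=1)
        mapping = {("A", 100 + i, ""): ("A", i, "") for i in range(1, 6)}
        d = delta_mpr(a, b, mapping)
        for i in (1, 3, 5):
            expected = a.table["mpr"].iloc[i - 1] - b.table["mpr"].iloc[i - 1]
            assert d.loc[("A", i, "")] == pytest.approx(expected)

    def test_partial_overlap_and_empty_intersection(self):
        a = _profile([0.1, 0.2, 0.3], start=1)
        b = _profile([0.0, 0.0], start=2)
        assert len(delta_mpr(a, b)) == 2
        with pytest.raises(AlignmentError):
            delta_mpr(a, _profile([0.5], start=50))


def _bfactor_model(mainchain_values, sidechain_values=None, chain="A"):
    residues = []
    for i, mc in enumerate(mainchain_values):
        names = ["N", "CA", "C", "O"]
        bf = [mc] * 4
        if sidechain_values is not None and sidechain_values[i] is not None:
            names.append("CB")
            bf.append(sidechain_values[i])
        coords = np.tile(np.array([[3.0 * i, 0, 0]]), (len(names), 1)) \
            + np.arange(len(names))[:, None] * 0.5
        residues.append(Residue(chain_id=chain, resnum=i + 1, icode="",
                                name="ALA" if names[-1] == "CB" else "GLY",
                                atom_names=names, coords=coords,
                                bfactors=np.array(bf, dtype=float),
                                elements=[n[0] for n in names]))
    return StructureModel(structure_id="bf", chains={chain: residues})


class TestBFactorNormalization:
    def test_three_point_min_max(self):
        model = _bfactor_model([10.0, 20.0, 30.0])
        df = normalize_bfactors(model, "min_max", remove_outliers=False)
        np.testing.assert_allclose(df["mainchain_norm"], [0.0, 0.5, 1.0])

    def test_zscore_postconditions(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(10, 60, 40)
        model = _bfactor_model(vals)
        df = normalize_bfactors(model, "zero_mean_unit_variance",
                                remove_outliers=False)
        assert df["mainchain_norm"].mean() == pytest.approx(0.0, abs=1e-9)
        assert df["mainchain_norm"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_min_max_range_attained(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(5, 80, 30)
        df = normalize_bfactors(_bfactor_model(vals), "min_max",
                                remove_outliers=False)
        col = df["mainchain_norm"]
        assert col.min() == 0.0 and col.max() == 1.0
        assert ((col >= 0) & (col <= 1)).all()

    def test_gly_sidechain_masked(self):
        model = _bfactor_model([10.0, 20.0, 30.0, 40.0],
                               sidechain_values=[15.0, None, 25.0, 35.0])
        df = normalize_bfactors(model, "min_max", remove_outliers=False)
        assert np.isnan(df["sidechain_norm"].iloc[1])
        assert np.isfinite(df["sidechain_norm"].iloc[0])

    def test_outlier_removal_masks_extremes(self):
        vals = [20.0, 21.0, 19.0, 20.5, 19.5, 21.5, 20.2, 500.0]
        df = normalize_bfactors(_bfactor_model(vals), "zero_mean_unit_variance")
        assert np.isnan(df["mainchain_norm"].iloc[-1])
        kept = df["mainchain_norm"].dropna()
        assert kept.mean() == pytest.approx(0.0, abs=1e-9)

    def test_shift_invariance(self):
        vals = np.array([10.0, 25.0, 17.0, 31.0, 22.0])
        a = normalize_bfactors(_bfactor_model(vals), "min_max",
                               remove_outliers=False)["mainchain_norm"]
        b = normalize_bfactors(_bfactor_model(vals + 100.0), "min_max",
                               remove_outliers=False)["mainchain_norm"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ParameterError):
            normalize_bfactors(_bfactor_model([10.0, 10.0, 10.0]), "min_max",
                               remove_outliers=False)
        with pytest.raises(ParameterError):
            normalize_bfactors(_bfactor_model([10.0, 10.0, 10.0]),
                               "zero_mean_unit_variance",
                               remove_outliers=False)
        with pytest.raises(MempropError):
            normalize_bfactors(_bfactor_model([10.0]), "min_max")
        with pytest.raises(ParameterError):
            normalize_bfactors(_bfactor_model([1.0, 2.0, 3.0]), "nope")


def test_pymol_script_matches_classes(tmp_path):
    scores = [0.0, 0.45, 1.2]
    idx, labels, colors = stability_classes(scores, 0.45, 0.25, 0.2)
    table = pd.DataFrame({
        "mpr": scores, "label": ["EM", "TM", "TM"],
        "class_index": idx, "class_label": labels, "color": colors,
    }, index=pd.MultiIndex.from_tuples(
        [("A", 1, ""), ("A", 2, ""), ("B", 7, "A")],
        names=["chain", "resnum", "icode"]))
    profile = MPrProfile(structure_id="x", table=table)
    path = tmp_path / "color.pml"
    write_pymol_script(profile, path)
    text = path.read_text()
    for (chain, resnum, icode), row in table.iterrows():
        resi = f"{resnum}{icode}" if icode else str(resnum)
        assert f"color 0x{row['color'].lstrip('#')}, chain {chain} and resi {resi}" in text
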