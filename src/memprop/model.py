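"""The membrane propensity index: training, prediction, evaluation.

The per-residue score is a linear model over the smoothed folding
free-energy features,

    MPr_i = sum_mu sum_chi alpha_chi^mu * dGbar_chi^{i,mu}
            + alpha_L * ln(L) + alpha_N,

fitted by ordinary least squares against binary membrane annotations
(O_i = 1 for TM, 0 for EM), i.e. by minimizing C = sum_i (MPr_i - O_i)^2.
Scores near 1 flag residues stable in the lipid bilayer, scores near 0
residues stable in water; the smoothing weights (beta, gamma) are picked by
a small grid search on the same cost. A residue is called TM when its score
reaches the threshold phi0 that maximizes balanced accuracy on training
scores. Evaluation is protein-level leave-one-out: potentials, smoothing
weights, coefficients and threshold are all re-derived per fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from sklearn.linear_model import LinearRegression, LogisticRegression

from .analysis import stability_classes
from .config import DescriptorConfig
from .descriptors import ResidueDescriptorTable, compute_descriptors
from .energy import (EnergyFeatureMatrix, feature_matrix_from_profiles,
                     raw_profiles)
from .errors import (DegenerateFitError, ManifestError, MempropError,
                     ParameterError)
from .potentials import (ENVIRONMENTS, FrequencyModel, PotentialSuite,
                         count_raw, derive_potential)
from .structure import StructureModel

log = logging.getLogger(__name__)

FORMAT_VERSION = 1

#: Default smoothing-weight grid searched during training.
DEFAULT_BETA_GAMMA_GRID = [0.0, 0.25, 0.5, 0.75, 1.0]


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == "TM").astype(int)
    return arr.astype(int)


def _as_target(labels) -> np.ndarray:
    """Regression target: binary O for TM/EM labels, floats pass through."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == "TM").astype(float)
    return arr.astype(float)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class MPrModel:
    """Trained coefficients and classification parameters."""

    column_order: list            # energy columns in manifest order + "logL"
    coef: np.ndarray              # aligned with column_order
    intercept: float              # alpha_N
    beta: float
    gamma: float
    phi0: float
    sigma_TM: float
    sigma_EM: float
    combos: list = field(default_factory=list)
    config_hash: str = ""

    @property
    def alpha(self) -> dict:
        """Coefficient per (combo, environment) column, e.g. ``"sd.TM"``."""
        return {c: float(v) for c, v in zip(self.column_order, self.coef)
                if c != "logL"}

    @property
    def alpha_L(self) -> float:
        return float(self.coef[self.column_order.index("logL")])

    @property
    def alpha_N(self) -> float:
        return float(self.intercept)

    def scores(self, features) -> np.ndarray:
        df = features.features if isinstance(features, EnergyFeatureMatrix) else features
        if list(df.columns) != self.column_order:
            extra = [c for c in df.columns if c not in self.column_order]
            missing = [c for c in self.column_order if c not in df.columns]
            raise ManifestError(
                f"feature columns do not match model manifest; "
                f"missing={missing}, unexpected={extra}")
        return df.to_numpy() @ self.coef + self.intercept

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        payload = {
            "format_version": FORMAT_VERSION,
            "kind": "mpr_model",
            "column_order": self.column_order,
            "coef": [float(v) for v in self.coef],
            "intercept": float(self.intercept),
            "beta": self.beta, "gamma": self.gamma,
            "phi0": self.phi0,
            "sigma_TM": self.sigma_TM, "sigma_EM": self.sigma_EM,
            "combos": self.combos,
            "config_hash": self.config_hash,
        }
        (path / "model.json").write_text(json.dumps(payload, indent=1))
        rows = ["term\tcoefficient"]
        rows += [f"{c}\t{v!r}" for c, v in zip(self.column_order, self.coef)]
        rows += [f"alpha_N\t{self.intercept!r}", f"phi0\t{self.phi0!r}",
                 f"sigma_TM\t{self.sigma_TM!r}", f"sigma_EM\t{self.sigma_EM!r}",
                 f"beta\t{self.beta!r}", f"gamma\t{self.gamma!r}"]
        (path / "coefficients.tsv").write_text("\n".join(rows) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "MPrModel":
        payload = json.loads((Path(path) / "model.json").read_text())
        return cls(column_order=payload["column_order"],
                   coef=np.array(payload["coef"]),
                   intercept=payload["intercept"],
                   beta=payload["beta"], gamma=payload["gamma"],
                   phi0=payload["phi0"],
                   sigma_TM=payload["sigma_TM"], sigma_EM=payload["sigma_EM"],
                   combos=payload["combos"],
                   config_hash=payload["config_hash"])


@dataclass
class MPrProfile:
    """Per-residue MPr scores with TM/EM calls and stability classes."""

    structure_id: str
    table: pd.DataFrame   # index (chain,resnum,icode); mpr, label, class_*, color

    @property
    def mpr(self) -> pd.Series:
        return self.table["mpr"]

    def total(self) -> float:
        return float(self.table["mpr"].sum())

    def to_tsv(self, path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _ols_fit(df: pd.DataFrame, y: np.ndarray, estimator: str = "ols"):
    """Least-squares fit dropping constant columns (coefficient 0)."""
    X = df.to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        log.warning("dropping %d constant feature column(s): %s",
                    int((~keep).sum()),
                    [c for c, k in zip(df.columns, keep) if not k])
    coef = np.zeros(X.shape[1])
    if not keep.any():
        intercept = float(np.mean(y))
        fitted = np.full(len(y), intercept)
        return coef, intercept, fitted, float(((fitted - y) ** 2).sum())
    if estimator == "logistic":
        reg = LogisticRegression(penalty=None, max_iter=1000).fit(X[:, keep], y)
        coef[keep] = reg.coef_[0]
        intercept = float(reg.intercept_[0])
    else:
        reg = LinearRegression().fit(X[:, keep], y)
        coef[keep] = reg.coef_
        intercept = float(reg.intercept_)
    fitted = X @ coef + intercept
    cost = float(((fitted - y) ** 2).sum())
    return coef, intercept, fitted, cost


def fit_mpr(features: EnergyFeatureMatrix, labels,
            estimator: str = "ols") -> MPrModel:
    """Fit the linear MPr model to stacked features and TM/EM labels.

    ``labels`` is the stacked O-vector (1 = TM, 0 = EM; a continuous target
    is also accepted) aligned with the feature rows. The classification
    threshold and the per-class standard deviations are derived from the
    fitted training scores.
    """
    y = _as_target(labels)
    if len(y) != len(features.features):
        raise MempropError("features and labels have different lengths")
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("training labels contain a single class")
    coef, intercept, fitted, _ = _ols_fit(features.features, y, estimator)
    ybin = (y >= 0.5).astype(int)
    if len(np.unique(ybin)) == 2:
        sigma_tm = float(np.std(fitted[ybin == 1]))
        sigma_em = float(np.std(fitted[ybin == 0]))
        phi0 = choose_threshold(fitted, ybin)
    else:  # continuous target without both classes: neutral calibration
        sigma_tm = sigma_em = float(np.std(fitted)) or 1.0
        phi0 = 0.5
    return MPrModel(column_order=list(features.features.columns),
                    coef=coef, intercept=intercept,
                    beta=features.beta, gamma=features.gamma,
                    phi0=float(phi0), sigma_TM=sigma_tm, sigma_EM=sigma_em,
                    combos=sorted({c.split(".")[0]
                                   for c in features.features.columns
                                   if c != "logL"}),
                    config_hash=features.config_hash)


def predict_mpr(model: MPrModel, features: EnergyFeatureMatrix,
                structure_id: str = "") -> MPrProfile:
    """Score residues and attach TM/EM calls and stability classes."""
    scores = model.scores(features)
    cls_idx, cls_label, cls_color = stability_classes(
        scores, model.phi0, model.sigma_TM, model.sigma_EM)
    table = pd.DataFrame({
        "mpr": scores,
        "label": np.where(scores >= model.phi0, "TM", "EM"),
        "class_index": cls_idx,
        "class_label": cls_label,
        "color": cls_color,
    }, index=features.features.index)
    table.insert(0, "aa", features.aa)
    return MPrProfile(structure_id=structure_id, table=table)


# ---------------------------------------------------------------------------
# Threshold and metrics
# ---------------------------------------------------------------------------

def choose_threshold(scores, labels) -> float:
    """Threshold maximizing balanced accuracy for the rule score >= phi0 -> TM.

    Candidates are the midpoints between adjacent sorted unique scores
    (exhaustive, exact); ties resolve to the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("need both classes to choose a threshold")
    u, inv = np.unique(scores, return_inverse=True)
    if len(u) < 2:
        return float(u[0])
    pos = np.bincount(inv, weights=y, minlength=len(u))
    neg = np.bincount(inv, weights=1 - y, minlength=len(u))
    P, N = pos.sum(), neg.sum()
    # candidate k: threshold between u[k] and u[k+1]; TM pred iff score >= u[k+1]
    cum_pos = np.cumsum(pos)[:-1]
    cum_neg = np.cumsum(neg)[:-1]
    bacc = 0.5 * ((P - cum_pos) / P + cum_neg / N)
    k = int(np.argmax(bacc))  # first max = smallest candidate
    return float((u[k] + u[k + 1]) / 2)


def balanced_accuracy(pred, truth) -> float:
    """Mean of sensitivity (TM) and specificity (EM)."""
    p, t = _as_binary(pred), _as_binary(truth)
    if len(p) != len(t) or len(t) == 0:
        raise MempropError("prediction/truth vectors empty or mismatched")
    if len(np.unique(t)) < 2:
        raise DegenerateFitError("truth contains a single class")
    return float(_skm.balanced_accuracy_score(t, p))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; ties count one half."""
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("need both classes for AUC")
    return float(_skm.roc_auc_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Training pipeline and leave-one-out
# ---------------------------------------------------------------------------

def _prepare(dataset, config):
    """Descriptor tables + label objects for (StructureModel | table, labels)."""
    prepared = []
    for item, labels in dataset:
        desc = (compute_descriptors(item, config)
                if isinstance(item, StructureModel) else item)
        prepared.append((desc, labels))
    return prepared


def _scored_labels(desc: ResidueDescriptorTable, labels) -> np.ndarray:
    return np.array([1 if labels[k] == "TM" else 0
                     for k, s in zip(desc.keys, desc.scored) if s])


def _suite_from_counts(counts: dict, config, provenance) -> PotentialSuite:
    tables = {}
    for (combo, env), raw in counts.items():
        freqs = FrequencyModel(combo, env, raw, config.pseudocount)
        tables[(combo, env)] = derive_potential(freqs, config.kT)
    return PotentialSuite(tables=tables, config=config, provenance=provenance)


def _grid_fit(prepared, suite, grid, estimator="ols"):
    """Select (beta, gamma) minimizing the training cost C; return best fit."""
    profiles = [raw_profiles(desc, suite) for desc, _ in prepared]
    y = np.concatenate([_scored_labels(desc, labels)
                        for desc, labels in prepared])
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("training labels contain a single class")
    best = None
    for beta, gamma in product(grid, grid):
        mats = [feature_matrix_from_profiles(desc, prof, suite.combos,
                                             beta, gamma, suite.config.hash())
                for (desc, _), prof in zip(prepared, profiles)]
        stacked = EnergyFeatureMatrix(
            features=pd.concat([m.features for m in mats]),
            aa=sum((m.aa for m in mats), []),
            beta=beta, gamma=gamma, config_hash=suite.config.hash())
        *_, cost = _ols_fit(stacked.features, y, estimator)
        if best is None or cost < best[0]:
            best = (cost, beta, gamma, stacked)
    _, beta, gamma, stacked = best
    model = fit_mpr(stacked, y, estimator)
    return model, (beta, gamma)


@dataclass
class TrainedModel:
    """An MPr model together with the potential suite it scores with."""

    model: MPrModel
    suite: PotentialSuite

    def score_structure(self, model_or_desc) -> MPrProfile:
        from .energy import energy_feature_matrix
        feats = energy_feature_matrix(model_or_desc, self.suite,
                                      self.model.beta, self.model.gamma)
        sid = getattr(model_or_desc, "structure_id", "")
        return predict_mpr(self.model, feats, sid)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.model.save(path)
        self.suite.save(path / "suite")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        return cls(model=MPrModel.load(path),
                   suite=PotentialSuite.load(path / "suite"))


def train_model(dataset, config: DescriptorConfig | None = None,
                grid=None, estimator: str = "ols") -> TrainedModel:
    """Derive potentials and fit the MPr model on a full labeled dataset."""
    config = config or DescriptorConfig()
    grid = grid if grid is not None else DEFAULT_BETA_GAMMA_GRID
    prepared = _prepare(dataset, config)
    counts = _all_counts(prepared, config)
    suite = _suite_from_counts(
        _sum_counts(counts), config, [d.structure_id for d, _ in prepared])
    model, _ = _grid_fit(prepared, suite, grid, estimator)
    return TrainedModel(model=model, suite=suite)


def _all_counts(prepared, config):
    """Per-structure raw count tensors, additive over structures."""
    out = []
    for desc, labels in prepared:
        entry = {}
        for combo in config.combos:
            for env in ENVIRONMENTS:
                entry[(combo, env)] = count_raw(desc, labels, combo, env, config)
        out.append(entry)
    return out

def _sum_counts(counts_list):
    total = {}
    for entry in counts_list:
        for key, arr in entry.items():
            total[key] = arr if key not in total else total[key] + arr
    return total


@dataclass
class CVReport:
    """Pooled held-out predictions from protein-level leave-one-out."""

    per_residue: pd.DataFrame     # structure_id, chain, resnum, icode, mpr, pred, true
    folds: list
    pooled_bacc: float
    pooled_auc: float
    skipped: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        path = Path(path)
        self.per_residue.to_csv(path, sep="\t", index=False)
        summary = path.with_suffix(".summary.tsv")
        lines = ["metric\tvalue",
                 f"pooled_bacc\t{self.pooled_bacc!r}",
                 f"pooled_auc\t{self.pooled_auc!r}",
                 f"n_folds\t{len(self.folds)}",
                 f"n_skipped\t{len(self.skipped)}"]
        for f in self.folds:
            lines.append(f"fold:{f['structure_id']}\t"
                         f"beta={f['beta']} gamma={f['gamma']} phi0={f['phi0']!r}")
        summary.write_text("\n".join(lines) + "\n")


def loo_cross_validate(dataset, config: DescriptorConfig | None = None,
                       grid=None, estimator: str = "ols") -> CVReport:
    """Strict protein-level leave-one-out over a labeled structure dataset.

    For each held-out protein the statistical potentials, the smoothing
    weights, the regression coefficients and the threshold phi0 are all
    re-derived from the remaining proteins; the held-out residues are then
    scored blind and pooled.
    """
    config = config or DescriptorConfig()
    grid = grid if grid is not None else DEFAULT_BETA_GAMMA_GRID
    if len(dataset) < 3:
        raise MempropError("leave-one-out needs at least 3 proteins")
    prepared = _prepare(dataset, config)
    counts = _all_counts(prepared, config)
    total = _sum_counts(counts)

    rows, folds, skipped = [], [], []
    for f, (desc, labels) in enumerate(prepared):
        train = [p for i, p in enumerate(prepared) if i != f]
        fold_counts = {key: total[key] - counts[f][key] for key in total}
        try:
            suite = _suite_from_counts(
                fold_counts, config,
                [d.structure_id for i, (d, _) in enumerate(prepared) if i != f])
            model, (beta, gamma) = _grid_fit(train, suite, grid, estimator)
        except DegenerateFitError as exc:
            log.warning("fold %s skipped: %s", desc.structure_id, exc)
            skipped.append(desc.structure_id)
            continue
        feats = feature_matrix_from_profiles(
            desc, raw_profiles(desc, suite), suite.combos,
            beta, gamma, config.hash())
        profile = predict_mpr(model, feats, desc.structure_id)
        truth = _scored_labels(desc, labels)
        df = profile.table.reset_index()
        df.insert(0, "structure_id", desc.structure_id)
        df["pred"] = (profile.table["mpr"] >= model.phi0).astype(int).values
        df["true"] = truth
        rows.append(df)
        folds.append({"structure_id": desc.structure_id,
                      "n_residues": len(truth),
                      "beta": beta, "gamma": gamma, "phi0": model.phi0})
    if not rows:
        raise DegenerateFitError("every fold was skipped")
    pooled = pd.concat(rows, ignore_index=True)
    bacc = balanced_accuracy(pooled["pred"].to_numpy(), pooled["true"].to_numpy())
    auc = roc_auc(pooled["mpr"].to_numpy(), pooled["true"].to_numpy())
    return CVReport(per_residue=pooled, folds=folds,
                    pooled_bacc=bacc, pooled_auc=auc, skipped=skipped)
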