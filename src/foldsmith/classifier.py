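"""Stability classification: features, Gini forest, OOB, fold-dropout AUC.

A design is labelled stable when its combined protease stability score
exceeds 0.5.  Named sequence/structure features feed a random forest of
Gini-criterion decision trees (500 by default) grown on bootstrap
resamples, with out-of-bag votes estimating generalisation accuracy and
fivefold cross-validation as a second check.  Generalisation to unseen
topologies is measured by leave-one-fold-out ("dropout") ROC/AUC.

The feature registry here is a representative ~20-feature set covering the
classes that matter most for fold stability — local-geometry fragment
agreement, buried hydrophobics, residue-contact network degree and the
most-connected ("hub") residue's packing context, charge and composition —
and is data-driven so users can register more.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .abego import SAMPLING, OMEGA_TRANS
from .geometry import BackboneChain, superpose_rmsd, torsions_to_coords
from .seqdesign import HYDROPHOBIC, assign_layers

CONTACT_CUTOFF = 8.0  # CA-CA, angstroms
CONTACT_MIN_SEPARATION = 2
FRAGMENT_WINDOW = 9

POSITIVE = set("KR")
NEGATIVE = set("DE")

AUC_UNDEFINED = math.nan


# ---------------------------------------------------------------------------
# Gini impurity


def gini_index(probabilities: Sequence[float]) -> float:
    """Gini impurity: one minus the sum of squared class probabilities."""
    p = np.asarray(probabilities, dtype=float)
    if (p < 0).any() or abs(float(p.sum()) - 1.0) > 1e-9:
        raise ValueError("probabilities must be nonnegative and sum to 1")
    return float(1.0 - (p**2).sum())


# ---------------------------------------------------------------------------
# features


def contact_degrees(chain: BackboneChain) -> np.ndarray:
    """Per-residue count of CA contacts below 8 A with |i-j| >= 2."""
    ca = chain.ca_coords()
    d = cdist(ca, ca)
    n = len(ca)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    return ((d < CONTACT_CUTOFF) & (sep >= CONTACT_MIN_SEPARATION)).sum(axis=1)


def fragment_agreement_rmsd(chain: BackboneChain) -> float:
    """Mean CA RMSD of 9-residue windows against ideal-torsion rebuilds.

    Each window is rebuilt from the canonical torsions of its residues'
    ABEGO letters and superposed onto the design window; low values mean
    the local geometry matches ideal secondary structure.
    """
    n = len(chain)
    if n < FRAGMENT_WINDOW:
        return 0.0
    ca = chain.ca_coords()
    rmsds = []
    for start in range(0, n - FRAGMENT_WINDOW + 1):
        letters = chain.abego[start : start + FRAGMENT_WINDOW]
        tors = []
        for letter in letters:
            if letter == "-":
                letter = "B"
            (phi, psi), _ = SAMPLING[letter]
            tors.append((phi, psi, OMEGA_TRANS))
        ideal = torsions_to_coords(tors)
        rmsd, _, _ = superpose_rmsd(ideal.ca_coords(), ca[start : start + FRAGMENT_WINDOW])
        rmsds.append(rmsd)
    return float(np.mean(rmsds))


def _feat_length(chain, seq):
    return float(len(chain))


def _feat_net_charge(chain, seq):
    return float(sum(aa in POSITIVE for aa in seq) - sum(aa in NEGATIVE for aa in seq))


def _feat_hydrophobic_fraction(chain, seq):
    return sum(aa in HYDROPHOBIC for aa in seq) / len(seq)


def _feat_ss_fraction(label):
    def fn(chain, seq):
        return chain.ss.count(label) / len(chain)

    return fn


def _feat_mean_degree(chain, seq):
    return float(contact_degrees(chain).mean())


def _feat_max_degree(chain, seq):
    return float(contact_degrees(chain).max())


def _feat_hub_energy_proxy(chain, seq):
    """Contact-count-weighted burial of the most-connected residue."""
    deg = contact_degrees(chain)
    hub = int(np.argmax(deg))  # ties -> lowest index
    burial = assign_layers(chain).burial
    return float(deg[hub] * burial[hub])


def _feat_hub_hydrophobic(chain, seq):
    deg = contact_degrees(chain)
    hub = int(np.argmax(deg))
    return 1.0 if seq[hub] in HYDROPHOBIC else 0.0


def _feat_buried_hydrophobic_count(chain, seq):
    layers = assign_layers(chain).layers
    return float(
        sum(l == "core" and aa in HYDROPHOBIC for l, aa in zip(layers, seq))
    )


def _feat_exposed_hydrophobic_count(chain, seq):
    layers = assign_layers(chain).layers
    return float(
        sum(l == "surface" and aa in HYDROPHOBIC for l, aa in zip(layers, seq))
    )


def _feat_core_fraction(chain, seq):
    layers = assign_layers(chain).layers
    return layers.count("core") / len(layers)


def _feat_mean_burial(chain, seq):
    return float(np.mean(assign_layers(chain).burial))


def _feat_fragment_rmsd(chain, seq):
    return fragment_agreement_rmsd(chain)


def _feat_contact_order(chain, seq):
    ca = chain.ca_coords()
    d = cdist(ca, ca)
    n = len(ca)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    mask = np.triu((d < CONTACT_CUTOFF) & (sep >= CONTACT_MIN_SEPARATION), k=1)
    if not mask.any():
        return 0.0
    return float(sep[mask].mean() / n)


def _feat_radius_of_gyration(chain, seq):
    ca = chain.ca_coords()
    return float(np.sqrt(((ca - ca.mean(axis=0)) ** 2).sum(axis=1).mean()))


def _feat_n_contacts(chain, seq):
    return float(contact_degrees(chain).sum() / 2.0)


def _feat_glycine_fraction(chain, seq):
    return seq.count("G") / len(seq)


def _feat_proline_count(chain, seq):
    return float(seq.count("P"))


def _feat_abego_a_fraction(chain, seq):
    return chain.abego.count("A") / len(chain)


def _feat_abego_b_fraction(chain, seq):
    return chain.abego.count("B") / len(chain)


DEFAULT_REGISTRY: dict[str, Callable[[BackboneChain, str], float]] = {
    "length": _feat_length,
    "net_charge": _feat_net_charge,
    "hydrophobic_fraction": _feat_hydrophobic_fraction,
    "helix_fraction": _feat_ss_fraction("H"),
    "strand_fraction": _feat_ss_fraction("E"),
    "loop_fraction": _feat_ss_fraction("L"),
    "mean_contact_degree": _feat_mean_degree,
    "max_contact_degree": _feat_max_degree,
    "hub_energy_proxy": _feat_hub_energy_proxy,
    "hub_is_hydrophobic": _feat_hub_hydrophobic,
    "buried_hydrophobic_count": _feat_buried_hydrophobic_count,
    "exposed_hydrophobic_count": _feat_exposed_hydrophobic_count,
    "core_fraction": _feat_core_fraction,
    "mean_burial": _feat_mean_burial,
    "fragment_agreement_rmsd": _feat_fragment_rmsd,
    "relative_contact_order": _feat_contact_order,
    "radius_of_gyration": _feat_radius_of_gyration,
    "n_contacts": _feat_n_contacts,
    "glycine_fraction": _feat_glycine_fraction,
    "proline_count": _feat_proline_count,
    "abego_a_fraction": _feat_abego_a_fraction,
    "abego_b_fraction": _feat_abego_b_fraction,
}


def extract_features(
    chain: BackboneChain,
    sequence: str,
    registry: dict[str, Callable] | None = None,
) -> pd.Series:
    """Compute the named features for one design (deterministic).

    Values are keyed by registry name, so permuting registry order permutes
    nothing semantically.  Chain/sequence length mismatch is an error.
    """
    if len(sequence) != len(chain):
        raise ValueError("sequence and chain lengths differ")
    registry = DEFAULT_REGISTRY if registry is None else registry
    return pd.Series({name: float(fn(chain, sequence)) for name, fn in registry.items()})


# ---------------------------------------------------------------------------
# dataset


@dataclass
class LabeledDataset:
    """Feature matrix with binary stability labels and fold labels."""

    X: pd.DataFrame
    y: np.ndarray
    folds: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y).astype(int)
        self.folds = np.asarray(self.folds).astype(str)
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary")
        if len(self.X) != len(self.y) or len(self.X) != len(self.folds):
            raise ValueError("X, y, folds must align")
        if self.X.isna().any().any():
            raise ValueError("missing feature values")

    @classmethod
    def from_csv(cls, path) -> "LabeledDataset":
        df = pd.read_csv(path)
        for col in ("id", "fold", "label"):
            if col not in df.columns:
                raise ValueError(f"dataset CSV missing column {col!r}")
        X = df.drop(columns=["id", "fold", "label"])
        X.index = df["id"]
        return cls(X=X, y=df["label"].to_numpy(), folds=df["fold"].to_numpy())

    def to_csv(self, path) -> None:
        df = self.X.copy()
        df.insert(0, "label", self.y)
        df.insert(0, "fold", self.folds)
        df.insert(0, "id", self.X.index)
        df.to_csv(path, index=False)

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[mask], self.y[mask], self.folds[mask])


# ---------------------------------------------------------------------------
# forest


@dataclass
class ForestConfig:
    n_trees: int = 500
    criterion: str = "gini"
    bootstrap: bool = True
    max_features: str = "sqrt"


@dataclass
class TrainedForest:
    model: RandomForestClassifier
    feature_names: list[str]
    oob_accuracy: float
    cv_accuracy: float | None = None

    def predict_proba_stable(self, X: pd.DataFrame) -> np.ndarray:
        """P(stable) per row; columns are aligned by feature name."""
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        X = X[self.feature_names]
        stable_col = list(self.model.classes_).index(1)
        return self.model.predict_proba(X.to_numpy())[:, stable_col]


def train_forest(
    dataset: LabeledDataset,
    config: ForestConfig | None = None,
    seed: int = 0,
    cv_folds: int | None = 5,
) -> TrainedForest:
    """Grow a bootstrap Gini forest and estimate accuracy out-of-bag.

    Each tree sees an n-sample bootstrap resample; splits maximise the Gini
    decrease over a random sqrt-sized feature subset.  ``cv_folds``-fold
    stratified cross-validation accuracy is computed alongside (None skips
    it).  Deterministic for (dataset, config, seed).
    """
    config = config or ForestConfig()
    if len(np.unique(dataset.y)) < 2:
        raise ValueError("training requires both classes present")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion=config.criterion,
        bootstrap=config.bootstrap,
        max_features=config.max_features,
        oob_score=config.bootstrap,
        random_state=seed,
        n_jobs=1,
    )
    Xn = dataset.X.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small OOB sets warn harmlessly
        model.fit(Xn, dataset.y)
        cv_acc = None
        if cv_folds:
            skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            cv_acc = float(
                cross_val_score(model, Xn, dataset.y, cv=skf, n_jobs=1).mean()
            )
    return TrainedForest(
        model=model,
        feature_names=list(dataset.X.columns),
        oob_accuracy=float(model.oob_score_) if config.bootstrap else math.nan,
        cv_accuracy=cv_acc,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC with average-rank tie handling (Mann-Whitney U).

    Returns the NaN sentinel when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return AUC_UNDEFINED
    ranks = rankdata(scores)  # average ranks for ties
    sum_pos = float(ranks[labels == 1].sum())
    u = sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# fold-dropout evaluation


@dataclass
class DropoutReport:
    per_fold: dict[str, dict]
    whole_set_auc: float
    mixed_heldout_auc: float
    degenerate_folds: list[str] = field(default_factory=list)


def dropout_eval(
    dataset: LabeledDataset,
    config: ForestConfig | None = None,
    n_repeats: int = 3,
    seed: int = 0,
    cv_in_repeats: bool = False,
) -> DropoutReport:
    """Leave-one-fold-out AUC, repeated with fresh seeds.

    For each fold label F the forest trains on every other fold and scores
    F; min/median/max over ``n_repeats`` repetitions are reported per fold,
    alongside a whole-set AUC (OOB votes on everything) and a pooled
    "mixed" AUC over all held-out scores.  Folds lacking both classes are
    flagged and receive the NaN sentinel.
    """
    config = config or ForestConfig()
    fold_labels = sorted(set(dataset.folds))
    if len(fold_labels) < 2:
        raise ValueError("need at least 2 fold labels")
    per_fold: dict[str, list[float]] = {f: [] for f in fold_labels}
    degenerate = [
        f for f in fold_labels
        if len(np.unique(dataset.y[dataset.folds == f])) < 2
    ]
    mixed_scores: list[float] = []
    mixed_labels: list[int] = []
    rng = np.random.default_rng(seed)
    for _ in range(n_repeats):
        rep_seed = int(rng.integers(2**31 - 1))
        for f in fold_labels:
            test_mask = dataset.folds == f
            train = dataset.subset(~test_mask)
            if len(np.unique(train.y)) < 2:
                per_fold[f].append(AUC_UNDEFINED)
                continue
            forest = train_forest(train, config, seed=rep_seed, cv_folds=None)
            scores = forest.predict_proba_stable(dataset.X[test_mask])
            auc = roc_auc(scores, dataset.y[test_mask])
            per_fold[f].append(auc)
            if f not in degenerate:
                mixed_scores.extend(scores.tolist())
                mixed_labels.extend(dataset.y[test_mask].tolist())
    whole = train_forest(dataset, config, seed=seed, cv_folds=None)
    oob_votes = whole.model.oob_decision_function_
    stable_col = list(whole.model.classes_).index(1)
    whole_auc = roc_auc(np.nan_to_num(oob_votes[:, stable_col], nan=0.5), dataset.y)
    summary = {}
    for f in fold_labels:
        vals = np.asarray(per_fold[f], dtype=float)
        finite = vals[np.isfinite(vals)]
        if len(finite) == 0:
            summary[f] = {"aucs": vals.tolist(), "min": AUC_UNDEFINED,
                          "median": AUC_UNDEFINED, "max": AUC_UNDEFINED,
                          "degenerate": True}
        else:
            summary[f] = {
                "aucs": vals.tolist(),
                "min": float(finite.min()),
                "median": float(np.median(finite)),
                "max": float(finite.max()),
                "degenerate": f in degenerate,
            }
    return DropoutReport(
        per_fold=summary,
        whole_set_auc=whole_auc,
        mixed_heldout_auc=roc_auc(mixed_scores, mixed_labels)
        if mixed_labels
        else AUC_UNDEFINED,
        degenerate_folds=degenerate,
    )
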