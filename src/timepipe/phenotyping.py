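"""Hierarchical two-tier phenotype classification.

Tier 1 predicts the broad class (Tumor / Stroma / Immune) from arcsinh-
transformed marker means with a gradient-boosted tree ensemble; tier 2
resolves cells tier 1 called Immune into the nine immune phenotypes with a
maximum-margin (SVM) classifier. Tier 2 is never applied to Tumor or Stroma
calls, so hierarchical consistency holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import io, scheme
from .errors import SchemaError, StratificationError

TRAIN_FRACTION = 2.0 / 3.0


def default_tier1() -> ClassifierMixin:
    """Gradient-boosted classifier: 500 estimators, depth 4, learning rate 0.25."""
    return GradientBoostingClassifier(
        n_estimators=500, max_depth=4, learning_rate=0.25
    )


def default_tier2() -> ClassifierMixin:
    """Standardized RBF support-vector classifier."""
    return make_pipeline(StandardScaler(), SVC())


@dataclass
class TierModel:
    """Fitted two-tier phenotype model."""

    tier1: ClassifierMixin
    tier2: ClassifierMixin | None
    feature_list: list[str]
    split_fraction: float
    seed: int

    def to_dict(self) -> dict:
        """JSON-serializable audit record (estimator configs, not weights)."""
        return {
            "feature_list": self.feature_list,
            "split_fraction": self.split_fraction,
            "seed": self.seed,
            "tier1": repr(self.tier1),
            "tier2": repr(self.tier2),
        }


@dataclass
class AccuracyReport:
    tier1_train: float
    tier1_test: float
    tier2_train: float | None
    tier2_test: float | None
    n_train: int
    n_test: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _check_class_counts(labels: pd.Series) -> None:
    counts = labels.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise StratificationError(
            f"classes with a single annotated example: {sorted(singletons.index)}"
        )


def fit_hierarchical_classifier(
    annotations: pd.DataFrame,
    feature_list: list[str] | None = None,
    split_fraction: float = TRAIN_FRACTION,
    seed: int = 0,
    tier1: ClassifierMixin | None = None,
    tier2: ClassifierMixin | None = None,
) -> tuple[TierModel, AccuracyReport]:
    """Train both tiers on an annotation table (``label`` column + markers).

    The annotation set is split ``split_fraction`` / rest into train/test,
    stratified on the fine label. Tier 1 is trained on the broad-class
    collapse of all annotations; tier 2 only on annotated immune cells.
    """
    if "label" not in annotations.columns:
        raise SchemaError("annotation table needs a 'label' column")
    if feature_list is None:
        feature_list = io.marker_names(annotations)
    _check_class_counts(annotations["label"])

    X = io.arcsinh_means(annotations, feature_list)
    y_fine = annotations["label"].to_numpy()
    y_broad = np.array([scheme.broad_class(l) for l in y_fine])

    idx_train, idx_test = train_test_split(
        np.arange(len(X)),
        train_size=split_fraction,
        stratify=y_fine,
        random_state=seed,
    )

    t1 = clone(tier1) if tier1 is not None else default_tier1()
    if "random_state" in t1.get_params():
        t1.set_params(random_state=seed)
    t1.fit(X[idx_train], y_broad[idx_train])
    rep1_train = float(t1.score(X[idx_train], y_broad[idx_train]))
    rep1_test = float(t1.score(X[idx_test], y_broad[idx_test]))

    imm_train = idx_train[y_broad[idx_train] == scheme.IMMUNE]
    imm_test = idx_test[y_broad[idx_test] == scheme.IMMUNE]
    t2 = None
    rep2_train = rep2_test = None
    if len(imm_train) and len(np.unique(y_fine[imm_train])) >= 2:
        t2 = clone(tier2) if tier2 is not None else default_tier2()
        if "random_state" in t2.get_params():
            t2.set_params(random_state=seed)
        t2.fit(X[imm_train], y_fine[imm_train])
        rep2_train = float(t2.score(X[imm_train], y_fine[imm_train]))
        if len(imm_test):
            rep2_test = float(t2.score(X[imm_test], y_fine[imm_test]))

    model = TierModel(
        tier1=t1,
        tier2=t2,
        feature_list=list(feature_list),
        split_fraction=split_fraction,
        seed=seed,
    )
    report = AccuracyReport(
        tier1_train=rep1_train,
        tier1_test=rep1_test,
        tier2_train=rep2_train,
        tier2_test=rep2_test,
        n_train=len(idx_train),
        n_test=len(idx_test),
    )
    return model, report


def classify_cells(model: TierModel, cells: pd.DataFrame) -> pd.DataFrame:
    """Assign every cell exactly one phenotype from the full scheme.

    Tier 1 decides Tumor/Stroma/Immune; tier 2 refines Immune calls. If no
    tier-2 model exists (e.g. no annotated immune cells), immune calls
    become UnclassifiedImmune.
    """
    out = cells.copy()
    if out.empty:
        out["phenotype"] = pd.Series(dtype=object)
        return out
    X = io.arcsinh_means(out, model.feature_list)
    broad = model.tier1.predict(X)
    pheno = broad.astype(object).copy()
    imm = broad == scheme.IMMUNE
    if imm.any():
        if model.tier2 is not None:
            pheno[imm] = model.tier2.predict(X[imm])
        else:
            pheno[imm] = "UnclassifiedImmune"
    out["phenotype"] = pheno
    return out
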