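"""PMT/vPvM classifier with applicability-domain gating and Shapley explanations.

A random-forest classifier predicts a pooled positive class (PMT or vPvM or
both, under the updated CLP selection criteria) from the molecular descriptor
vector.  Predictions are only trusted inside the model's applicability domain
(AD): the Euclidean distance from a query compound to its nearest training
compound, computed in z-scored feature space, must not exceed a threshold
fixed at training time (mean + 3 SD of the within-training nearest-neighbor
distances by default).  Out-of-domain compounds stay unresolved.

Explanations are exact interventional Shapley values on the positive-class
probability (see :mod:`pmtscreen.treeshap`).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestClassifier

from . import treeshap
from .rules import CANDIDATE, NOT_PMT_VPVM, UNRESOLVED, CriterionTier, HazardAssessment

logger = logging.getLogger(__name__)

LABEL_DEFINITION = "positive = PMT or vPvM or both (updated CLP criteria)"


@dataclass
class ADConfig:
    """Applicability-domain rule: threshold = mean + multiplier * SD of the
    k-nearest-neighbor (excluding self) distances within the training set."""

    k: int = 1
    multiplier: float = 3.0


@dataclass
class DomainStats:
    compound_id: str
    distance: float
    in_domain: bool


@dataclass
class ExplanationRecord:
    compound_id: str
    shap_values: pd.Series  # indexed by feature name
    base_value: float
    interaction_matrix: pd.DataFrame | None = None


@dataclass
class ModelBundle:
    """Trained classifier plus everything needed to reproduce its decisions:
    imputation medians, scaling parameters, the scaled training matrix the AD
    is measured against, the AD threshold and the training seed."""

    model: RandomForestClassifier
    feature_names: list[str]
    impute_medians: np.ndarray
    scale_center: np.ndarray
    scale_spread: np.ndarray
    training_scaled: np.ndarray
    ad_threshold: float
    ad_config: ADConfig
    seed: int
    label_definition: str = LABEL_DEFINITION
    nn_index: cKDTree | None = field(default=None, repr=False)

    def _nn(self) -> cKDTree:
        # cKDTree computes squared differences directly (no dot-product
        # shortcut), so the distance from a point to itself is exactly zero
        if self.nn_index is None:
            self.nn_index = cKDTree(self.training_scaled)
        return self.nn_index

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        """Impute (training medians) and z-score (training center/spread)."""
        if list(features.columns) != self.feature_names:
            raise ValueError("feature columns do not match the bundle manifest")
        X = features.to_numpy(dtype=np.float64, copy=True)
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.broadcast_to(self.impute_medians, X.shape)[nan]
        return (X - self.scale_center) / self.scale_spread


def train(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    seed: int = 42,
    n_estimators: int = 200,
    max_leaf_nodes: int = 64,
    ad_config: ADConfig | None = None,
) -> ModelBundle:
    """Fit the screening classifier and freeze its applicability domain.

    ``features`` is a compound x descriptor frame (NaN allowed — median
    imputation is fit on the training data); ``labels`` is the pooled binary
    outcome.  Deterministic for a given seed.
    """
    ad_config = ad_config or ADConfig()
    y = np.asarray(labels).astype(int)
    if len(y) != len(features):
        raise ValueError("feature/label length mismatch")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")

    X_raw = features.to_numpy(dtype=np.float64, copy=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(X_raw, axis=0)
    medians = np.where(np.isfinite(medians), medians, 0.0)
    nan = np.isnan(X_raw)
    X_raw[nan] = np.broadcast_to(medians, X_raw.shape)[nan]

    center = X_raw.mean(axis=0)
    spread = X_raw.std(axis=0)
    spread = np.where(spread > 0, spread, 1.0)  # constant features carry no distance
    X = (X_raw - center) / spread

    model = RandomForestClassifier(
        n_estimators=n_estimators,
        max_leaf_nodes=max_leaf_nodes,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)

    dists, _ = cKDTree(X).query(X, k=ad_config.k + 1)
    knn = dists[:, ad_config.k]  # k-th neighbor excluding self
    threshold = float(knn.mean() + ad_config.multiplier * knn.std())

    return ModelBundle(
        model=model,
        feature_names=list(features.columns),
        impute_medians=medians,
        scale_center=center,
        scale_spread=spread,
        training_scaled=X,
        ad_threshold=threshold,
        ad_config=ad_config,
        seed=seed,
    )


def applicability_domain(
    bundle: ModelBundle, features: pd.DataFrame
) -> list[DomainStats]:
    """Euclidean distance to the nearest training compound in scaled space."""
    X = bundle.transform(features)
    dists, _ = bundle._nn().query(X, k=1)
    out = []
    for cid, d in zip(features.index, dists):
        d = float(d)
        out.append(DomainStats(compound_id=str(cid), distance=d,
                               in_domain=d <= bundle.ad_threshold))
    return out


def predict(
    bundle: ModelBundle,
    features: pd.DataFrame,
    domain: list[DomainStats] | None = None,
) -> list[HazardAssessment]:
    """Classify compounds, withholding judgement outside the domain.

    In-domain positives become ``candidate_PMT_vPvM`` (the model cannot
    confirm a class, only nominate); in-domain negatives are negative;
    out-of-domain compounds stay unresolved.
    """
    if domain is None:
        domain = applicability_domain(bundle, features)
    dom = {d.compound_id: d for d in domain}
    X = bundle.transform(features)
    proba = bundle.model.predict_proba(X)[:, 1]
    out = []
    for cid, p in zip(features.index, proba):
        cid = str(cid)
        stats = dom[cid]
        if not stats.in_domain:
            out.append(
                HazardAssessment(
                    compound_id=cid, tier=CriterionTier(), hazard_class=UNRESOLVED,
                    decided_by="none",
                    detail=f"outside AD (distance {stats.distance:.3f} "
                           f"> threshold {bundle.ad_threshold:.3f})",
                )
            )
            continue
        positive = p >= 0.5
        out.append(
            HazardAssessment(
                compound_id=cid, tier=CriterionTier(),
                hazard_class=CANDIDATE if positive else NOT_PMT_VPVM,
                decided_by="ml_model",
                detail=f"P(PMT/vPvM)={p:.3f}, AD distance {stats.distance:.3f}",
            )
        )
    return out


def _background(bundle: ModelBundle, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    train = bundle.training_scaled
    if len(train) <= n:
        return train
    idx = rng.choice(len(train), size=n, replace=False)
    return train[idx]


def explain(
    bundle: ModelBundle,
    features: pd.DataFrame,
    background_size: int = 25,
    with_interactions: bool = False,
) -> tuple[list[ExplanationRecord], pd.Series]:
    """Shapley attributions per compound plus the global importance ranking.

    Global importance is the mean absolute Shapley value per feature, sorted
    descending.  Interaction matrices (optional — quadratic cost) share the
    attribution background, so they are symmetric and their row sums equal
    the per-feature attributions exactly.
    """
    X = bundle.transform(features)
    bg = _background(bundle, background_size, bundle.seed)
    phi, base = treeshap.shap_values(bundle.model, X, bg)
    inter = None
    if with_interactions:
        inter = treeshap.shap_interaction_values(bundle.model, X, bg)

    names = bundle.feature_names
    records = []
    for i, cid in enumerate(features.index):
        mat = None
        if inter is not None:
            mat = pd.DataFrame(inter[i], index=names, columns=names)
        records.append(
            ExplanationRecord(
                compound_id=str(cid),
                shap_values=pd.Series(phi[i], index=names),
                base_value=float(base[i]),
                interaction_matrix=mat,
            )
        )
    importance = pd.Series(np.abs(phi).mean(axis=0), index=names).sort_values(
        ascending=False, kind="mergesort"
    )
    return records, importance


def dependence_data(
    records: list[ExplanationRecord], features: pd.DataFrame, feature: str
) -> pd.DataFrame:
    """Feature value vs its Shapley value, with a suggested coloring feature.

    The coloring feature is the one whose values correlate most strongly with
    the residual attribution after removing the linear trend in the plotted
    feature — a cheap stand-in for the strongest interaction partner.
    """
    x = features[feature].to_numpy(dtype=float)
    s = np.array([r.shap_values[feature] for r in records])
    finite = np.isfinite(x)
    resid = s.copy()
    if finite.sum() >= 3 and np.nanstd(x) > 0:
        coef = np.polyfit(x[finite], s[finite], 1)
        resid = s - np.polyval(coef, np.where(finite, x, np.nanmean(x[finite])))
    best, best_corr = None, 0.0
    for other in features.columns:
        if other == feature:
            continue
        xo = features[other].to_numpy(dtype=float)
        ok = np.isfinite(xo) & np.isfinite(resid)
        if ok.sum() < 3 or np.std(xo[ok]) == 0 or np.std(resid[ok]) == 0:
            continue
        r = abs(np.corrcoef(xo[ok], resid[ok])[0, 1])
        if r > best_corr:
            best, best_corr = other, r
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "value": x,
            "shap": s,
            "color_feature": best or "",
            "color_value": features[best].to_numpy(dtype=float) if best else np.nan,
        }
    )


def dependence_sign(records: list[ExplanationRecord], features: pd.DataFrame,
                    feature: str) -> float:
    """Sign of the correlation between a feature's value and its attribution."""
    df = dependence_data(records, features, feature)
    ok = np.isfinite(df["value"]) & np.isfinite(df["shap"])
    if ok.sum() < 3:
        return 0.0
    return float(np.sign(np.corrcoef(df["value"][ok], df["shap"][ok])[0, 1]))


def contrast_importance_by_origin(
    records: list[ExplanationRecord],
    origins: pd.Series,
    k: int = 20,
) -> dict:
    """Top-k descriptors by mean |Shapley value| within each origin stratum.

    Strata are synthetic vs natural/undefined (natural and unknown-origin
    compounds grouped).  Returns both rankings and the descriptors unique to
    each stratum's top-k.
    """
    phi = pd.DataFrame(
        {r.compound_id: r.shap_values for r in records}
    ).T  # compounds x features
    strata = {
        "synthetic": [r.compound_id for r in records
                      if origins.get(r.compound_id) == "synthetic"],
        "natural_or_other": [r.compound_id for r in records
                             if origins.get(r.compound_id) in ("natural", "undefined")],
    }
    rankings: dict[str, pd.Series] = {}
    for label, ids in strata.items():
        if not ids:
            raise ValueError(f"empty origin stratum {label!r}")
        imp = phi.loc[ids].abs().mean(axis=0).sort_values(
            ascending=False, kind="mergesort"
        )
        if k > len(imp):
            logger.warning("k=%d exceeds feature count %d; full ranking", k, len(imp))
        rankings[label] = imp.head(k)
    a, b = (set(rankings[s].index) for s in ("synthetic", "natural_or_other"))
    return {
        "rankings": rankings,
        "unique_to_synthetic": sorted(a - b),
        "unique_to_natural_or_other": sorted(b - a),
        "shared": sorted(a & b),
    }


# ---------------------------------------------------------------------------
# serialization

def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Serialize as a directory: sklearn model + JSON sidecars + npy arrays."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(bundle.model, path / "model.joblib")
    np.save(path / "training_scaled.npy", bundle.training_scaled)
    meta = {
        "feature_names": bundle.feature_names,
        "impute_medians": bundle.impute_medians.tolist(),
        "scale_center": bundle.scale_center.tolist(),
        "scale_spread": bundle.scale_spread.tolist(),
        "ad_threshold": bundle.ad_threshold,
        "ad_config": {"k": bundle.ad_config.k, "multiplier": bundle.ad_config.multiplier},
        "seed": bundle.seed,
        "label_definition": bundle.label_definition,
    }
    (path / "bundle.json").write_text(json.dumps(meta, indent=1))


def load_bundle(path: str | Path) -> ModelBundle:
    path = Path(path)
    meta = json.loads((path / "bundle.json").read_text())
    return ModelBundle(
        model=joblib.load(path / "model.joblib"),
        feature_names=meta["feature_names"],
        impute_medians=np.array(meta["impute_medians"]),
        scale_center=np.array(meta["scale_center"]),
        scale_spread=np.array(meta["scale_spread"]),
        training_scaled=np.load(path / "training_scaled.npy"),
        ad_threshold=meta["ad_threshold"],
        ad_config=ADConfig(**meta["ad_config"]),
        seed=meta["seed"],
        label_definition=meta["label_definition"],
    )
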