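"""Population-level analyses of glomerulus-odor response tables.

Individuals (flies or simulated antennal lobes) are rows of a feature
matrix whose columns are (glomerulus, odor) response pairs, ordered in
glomerulus-major blocks.  The analyses here mirror the calcium-imaging
pipeline: mean-imputation and trial averaging, PCA with a deterministic
sign convention, a glomerular-organization index of PCA loadings,
application of fitted linear preference models, linear-logistic decoding
with twofold cross-validation, and within- vs. across-individual response
distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "PCAResult",
    "LinearPreferenceModel",
    "PN_PC2_OCT_MCH_MODEL",
    "impute_and_average",
    "pca_responses",
    "glomerular_organization_index",
    "apply_preference_model",
    "classify_individuals",
    "response_distances",
]


@dataclass
class PCAResult:
    """Loadings (n_pc x n_features), scores (n_obs x n_pc), variance fractions."""

    loadings: np.ndarray
    scores: np.ndarray
    variance_fraction: np.ndarray
    feature_labels: list[str] | None = None
    mean: np.ndarray | None = None


@dataclass(frozen=True)
class LinearPreferenceModel:
    """Affine behavior-prediction model: preference = beta0 + beta1 * predictor."""

    beta0: float
    beta1: float
    predictor: str = ""

    @classmethod
    def from_json(cls, path) -> "LinearPreferenceModel":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        return cls(beta0=d["beta0"], beta1=d["beta1"], predictor=d.get("predictor", ""))

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(
            json.dumps({"beta0": self.beta0, "beta1": self.beta1, "predictor": self.predictor})
        )


#: Fitted model predicting OCT-vs-MCH preference from PC 2 of PN calcium
#: responses (n = 47 flies, R^2 = 0.15).
PN_PC2_OCT_MCH_MODEL = LinearPreferenceModel(beta0=-0.058, beta1=-0.081, predictor="PN calcium PC2")


def impute_and_average(
    table: pd.DataFrame,
    individual_col: str = "individual",
    drop_cols: tuple[str, ...] = ("trial", "hemisphere"),
) -> pd.DataFrame:
    """Mean-impute missing cells, then average trials within individual.

    Missing feature values are replaced by that feature's mean over
    non-missing rows; each individual then contributes one row (the mean of
    its trials).
    """
    feats = [c for c in table.columns if c != individual_col and c not in drop_cols]
    X = table[feats].apply(pd.to_numeric)
    if X.isna().all(axis=0).any():
        dead = X.columns[X.isna().all(axis=0)].tolist()
        raise ValueError(f"feature(s) missing for every row: {dead}")
    X = X.fillna(X.mean(axis=0))
    X[individual_col] = table[individual_col].to_numpy()
    out = X.groupby(individual_col, sort=True).mean()
    if len(out) < 2:
        raise ValueError("need at least 2 individuals")
    return out


def pca_responses(features: pd.DataFrame | np.ndarray) -> PCAResult:
    """PCA of mean-centered features with a fixed sign convention.

    Each component's sign is chosen so that its largest-magnitude loading is
    positive, making loadings and downstream regression signs reproducible.
    """
    labels = list(features.columns) if isinstance(features, pd.DataFrame) else None
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    mu = X.mean(axis=0)
    Xc = X - mu
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix has no principal components")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| feature positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = s**2
    return PCAResult(
        loadings=Vt,
        scores=U * s,
        variance_fraction=var / var.sum(),
        feature_labels=labels,
        mean=mu,
    )


def glomerular_organization_index(
    pca: PCAResult,
    feature_blocks: list[np.ndarray] | dict[str, np.ndarray],
    n_pcs: int = 5,
) -> float:
    """Between-glomerulus share of PCA loading energy, in [0, 1].

    For PC k with loadings l_(g,o) grouped into glomerulus blocks g of size
    n_g, the per-component index is

        GOI_k = sum_g n_g * (mean_o l_(g,o))^2 / sum_(g,o) l_(g,o)^2,

    i.e. 1 when loadings are constant within every glomerulus (variation is
    organized by glomerulus) and 0 when loadings average out within each
    glomerulus.  The index is the variance-fraction-weighted mean over the
    top ``n_pcs`` components.
    """
    blocks = list(feature_blocks.values()) if isinstance(feature_blocks, dict) else feature_blocks
    if any(len(b) == 0 for b in blocks):
        raise ValueError("empty glomerulus block")
    K = min(n_pcs, pca.loadings.shape[0])
    goi = np.empty(K)
    for k in range(K):
        l = pca.loadings[k]
        between = sum(len(b) * np.mean(l[b]) ** 2 for b in blocks)
        total = float(np.sum(l**2))
        goi[k] = between / total
    w = pca.variance_fraction[:K]
    return float(np.sum(w * goi) / np.sum(w))


def apply_preference_model(model: LinearPreferenceModel, scores) -> np.ndarray:
    """Predicted preference per individual: beta0 + beta1 * score."""
    s = np.asarray(scores, dtype=float)
    return model.beta0 + model.beta1 * s


def _two_folds(n: int, labels: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stratified halves whose sizes differ by at most one."""
    fold = np.empty(n, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        half = len(idx) // 2
        fold[idx[:half]] = 0
        fold[idx[half:]] = 1
    # rebalance if stratification left the folds uneven by more than one
    while abs((fold == 0).sum() - (fold == 1).sum()) > 1:
        big = 0 if (fold == 0).sum() > (fold == 1).sum() else 1
        movable = np.flatnonzero(fold == big)
        fold[rng.choice(movable)] = 1 - big
    return np.flatnonzero(fold == 0), np.flatnonzero(fold == 1)


def classify_individuals(
    scores: np.ndarray,
    labels,
    n_pcs: int | None = None,
    seed: int | np.random.Generator = 0,
) -> float:
    """Twofold cross-validated linear-logistic classification accuracy.

    A model is trained on half the observations and evaluated on the other
    half, then the halves are reversed; accuracy is the fraction of correct
    predictions over both test halves.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if n_pcs is not None:
        X = X[:, :n_pcs]
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")
    a, b = _two_folds(len(y), y, rng)
    correct = 0
    for train, test in ((a, b), (b, a)):
        clf = LogisticRegression(max_iter=1000)
        clf.fit(X[train], y[train])
        correct += int((clf.predict(X[test]) == y[test]).sum())
    return correct / len(y)


def response_distances(
    projections: pd.DataFrame,
    individual_col: str = "individual",
    hemisphere_col: str | None = "hemisphere",
) -> pd.DataFrame:
    """Within- and across-individual mean distances between trial projections.

    Per individual, the within distance is the mean of the average pairwise
    distances (1) among left-hemisphere trials, (2) among right-hemisphere
    trials, and (3) between left and right trials; categories without a pair
    are skipped.  The across distance is computed identically against the
    trials of all other individuals.  Without hemisphere labels both reduce
    to plain trial-pair averages.
    """
    feats = [c for c in projections.columns if c not in (individual_col, hemisphere_col)]
    X = projections[feats].to_numpy(dtype=float)
    indiv = projections[individual_col].to_numpy()
    hemi = (
        projections[hemisphere_col].to_numpy()
        if hemisphere_col and hemisphere_col in projections.columns
        else np.full(len(projections), "L")
    )
    D = np.sqrt(np.maximum(
        np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1), 0.0
    ))
    hemis = np.unique(hemi)
    rows = []
    for ind in pd.unique(indiv):
        mine = indiv == ind
        within = _hemi_paired_mean(D, mine, mine, hemi, hemis, same_group=True)
        across = _hemi_paired_mean(D, mine, ~mine, hemi, hemis, same_group=False)
        if within is None:
            warnings.warn(f"individual {ind!r} has no trial pair; excluded")
            continue
        rows.append({"individual": ind, "within": within, "across": across})
    if len(rows) < 2:
        raise ValueError("need at least 2 usable individuals")
    return pd.DataFrame(rows).set_index("individual")


def _hemi_paired_mean(D, rows_mask, cols_mask, hemi, hemis, same_group):
    vals = []
    pairs = (
        [(h, h) for h in hemis] + [(a, b) for i, a in enumerate(hemis) for b in hemis[i + 1:]]
    )
    for ha, hb in pairs:
        r = np.flatnonzero(rows_mask & (hemi == ha))
        c = np.flatnonzero(cols_mask & (hemi == hb))
        if len(r) == 0 or len(c) == 0:
            continue
        block = D[np.ix_(r, c)]
        if same_group and ha == hb:
            if len(r) < 2:
                continue
            iu = np.triu_indices(len(r), 1)
            vals.append(float(block[iu].mean()))
        else:
            if same_group and ha != hb:
                vals.append(float(block.mean()))
            elif not same_group:
                vals.append(float(block.mean()))
    if not vals:
        return None
    return float(np.mean(vals))
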