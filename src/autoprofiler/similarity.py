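"""Embeddings, hierarchical clustering of treatment profiles, and the
profile-similarity -> cargo-degradation standard curve.

The core idea: the Pearson correlation between a treatment's median temporal
feature profile and the profile of a reference inducer (100 nM rapamycin by
default) summarises how similarly the treatment perturbs autophagy.  An
ordinary least-squares regression of externally measured normalised cargo
degradation on this similarity over a training panel of treatments gives a
standard curve from which the degradative output of a *new* treatment can be
predicted from imaging alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
from scipy.cluster.hierarchy import linkage

__all__ = [
    "LDAResult",
    "SimilarityRecord",
    "StandardCurve",
    "fit_lda",
    "hcluster_profiles",
    "profile_similarity",
    "normalize_cargo",
    "fit_standard_curve",
    "predict_cargo",
]


@dataclass
class LDAResult:
    """Fisher discriminant embedding: projection and projected coordinates."""

    projection: np.ndarray  # (p, d)
    embedding: np.ndarray  # (n, d)
    class_means: dict[str, np.ndarray]
    eigenvalues: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.projection


def fit_lda(X, y, d: int = 2, shrinkage: float = 0.0) -> LDAResult:
    """Fisher linear discriminant embedding into ``d`` dimensions.

    Maximises between-class over within-class scatter by solving the
    generalised eigenproblem S_b w = lambda (S_w + shrinkage * tau I) w with
    tau the mean within-class variance.  Deterministic up to sign (signs are
    fixed so each axis' largest-magnitude coefficient is positive).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    d = min(d, len(classes) - 1, X.shape[1])
    overall = X.mean(axis=0)
    p = X.shape[1]
    s_w = np.zeros((p, p))
    s_b = np.zeros((p, p))
    means = {}
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        means[str(c)] = mu
        s_w += (Xc - mu).T @ (Xc - mu)
        s_b += len(Xc) * np.outer(mu - overall, mu - overall)
    if shrinkage > 0:
        s_w = s_w + shrinkage * (np.trace(s_w) / p) * np.eye(p)
    else:
        ev = np.linalg.eigvalsh(s_w)
        if ev[0] <= 1e-10 * max(ev[-1], 1e-300):
            raise np.linalg.LinAlgError(
                "within-class scatter is singular; pass shrinkage > 0"
            )
    evals, evecs = scipy.linalg.eigh(s_b, s_w)
    order = np.argsort(evals)[::-1][:d]
    W = evecs[:, order]
    for j in range(W.shape[1]):
        if W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] = -W[:, j]
    return LDAResult(
        projection=W,
        embedding=X @ W,
        class_means=means,
        eigenvalues=evals[order],
    )


def hcluster_profiles(profiles: dict[str, pd.Series]) -> tuple[np.ndarray, list[str]]:
    """Average-linkage (UPGMA) dendrogram on Euclidean distances between
    median treatment profiles.  Returns (scipy linkage matrix, labels)."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    labels = list(profiles)
    ref_index = profiles[labels[0]].index
    mat = []
    for lab in labels:
        s = profiles[lab]
        if not s.index.equals(ref_index):
            raise ValueError(f"profile {lab!r} has a mismatched (feature, time) index")
        mat.append(s.to_numpy(dtype=float))
    Z = linkage(np.vstack(mat), method="average", metric="euclidean")
    return Z, labels


@dataclass
class SimilarityRecord:
    """Pearson similarity of one treatment profile to the reference profile."""

    treatment: str
    reference: str
    r: float
    n: int
    feature_set: str = "all"  # "all" | "vesicle_numbers"


def profile_similarity(
    profile: pd.Series,
    reference_profile: pd.Series,
    treatment: str = "",
    reference: str = "rapamycin_100nM",
    feature_set: str = "all",
) -> SimilarityRecord:
    """Pearson correlation between two profiles over their shared index."""
    shared = profile.index.intersection(reference_profile.index)
    if len(shared) < 3:
        raise ValueError("profiles share fewer than 3 (feature, timepoint) entries")
    a = profile[shared].to_numpy(dtype=float)
    b = reference_profile[shared].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance profile; correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    return SimilarityRecord(
        treatment=treatment or str(profile.name),
        reference=reference,
        r=r,
        n=len(shared),
        feature_set=feature_set,
    )


def normalize_cargo(cargo: dict[str, float], reference: str) -> dict[str, float]:
    """Express cargo degradation relative to the reference treatment."""
    if reference not in cargo:
        raise ValueError(f"reference treatment {reference!r} missing from cargo table")
    ref = cargo[reference]
    if ref == 0:
        raise ValueError("reference cargo value is zero")
    return {k: v / ref for k, v in cargo.items()}


@dataclass
class StandardCurve:
    """OLS map from profile similarity to normalised cargo degradation."""

    slope: float
    intercept: float
    r_squared: float
    treatments: list[str]
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    feature_set: str = "all"

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def residual_sd(self) -> float:
        resid = self.y - (self.slope * self.x + self.intercept)
        return float(np.sqrt(resid @ resid / max(self.n - 2, 1)))

    def _se_terms(self, x0: np.ndarray) -> np.ndarray:
        sxx = np.sum((self.x - self.x.mean()) ** 2)
        return 1.0 / self.n + (x0 - self.x.mean()) ** 2 / sxx

    def mean_ci(self, x0, alpha: float = 0.05):
        """Confidence band for the mean response at x0 (the plotted band)."""
        x0 = np.asarray(x0, dtype=float)
        yhat = self.slope * x0 + self.intercept
        t = stats.t.ppf(1 - alpha / 2, self.n - 2)
        half = t * self.residual_sd * np.sqrt(self._se_terms(x0))
        return yhat, yhat - half, yhat + half

    def prediction_interval(self, x0, alpha: float = 0.05):
        """Prediction interval for a new observation at x0."""
        x0 = np.asarray(x0, dtype=float)
        yhat = self.slope * x0 + self.intercept
        t = stats.t.ppf(1 - alpha / 2, self.n - 2)
        half = t * self.residual_sd * np.sqrt(1.0 + self._se_terms(x0))
        return yhat, yhat - half, yhat + half

    def slope_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        sxx = np.sum((self.x - self.x.mean()) ** 2)
        se = self.residual_sd / np.sqrt(sxx)
        t = stats.t.ppf(1 - alpha / 2, self.n - 2)
        return self.slope - t * se, self.slope + t * se


def fit_standard_curve(
    similarities: list[SimilarityRecord],
    cargo: dict[str, float],
    feature_set: str | None = None,
) -> StandardCurve:
    """OLS of normalised cargo degradation on profile similarity.

    Training treatments are those present in both inputs; fewer than 3 is an
    error.
    """
    pairs = [(s.treatment, s.r, cargo[s.treatment]) for s in similarities
             if s.treatment in cargo]
    if len(pairs) < 3:
        raise ValueError("need at least 3 treatments with both similarity and cargo")
    treatments, xs, ys = zip(*pairs)
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    res = stats.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        treatments=list(treatments),
        x=x,
        y=y,
        feature_set=feature_set or (similarities[0].feature_set if similarities else "all"),
    )


@dataclass
class CargoPrediction:
    treatment: str
    similarity: float
    predicted: float
    lower: float
    upper: float
    extrapolated: bool


def predict_cargo(
    curve: StandardCurve, new_similarity: SimilarityRecord, alpha: float = 0.05
) -> CargoPrediction:
    """Predict normalised cargo degradation for a new treatment.

    Uses the fitted line for the point estimate and the 95% prediction
    interval from the residual variance; predictions outside the training
    similarity range are flagged as extrapolation.
    """
    if new_similarity.treatment in curve.treatments:
        warnings.warn(
            f"treatment {new_similarity.treatment!r} was in the training set",
            stacklevel=2,
        )
    x0 = new_similarity.r
    yhat, lo, hi = curve.prediction_interval(np.array([x0]), alpha=alpha)
    return CargoPrediction(
        treatment=new_similarity.treatment,
        similarity=x0,
        predicted=float(yhat[0]),
        lower=float(lo[0]),
        upper=float(hi[0]),
        extrapolated=bool(x0 < curve.x.min() or x0 > curve.x.max()),
    )
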