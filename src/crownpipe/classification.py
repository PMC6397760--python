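"""Species classification of segmented crowns by Gaussian maximum likelihood.

Per-crown pixel observations are aggregated into one feature vector per
tree: four structural features (mean, min and max canopy height, and the
square root of the pixel count, which approximates crown diameter at 1 m
pixels) plus the per-band mean reflectance spectrum.  Two separate PCA
routines reduce the structural block to 3 components and the spectral
block to 10, giving a 13-dimensional feature space.  Each species is
modelled as a multivariate normal (template mean T and covariance Y) fit
on its training trees, and a test tree t is assigned to the species with
the highest density

    log L = -N/2 ln(2 pi) - 1/2 ln|Y| - 1/2 (t - T)' Y^-1 (t - T)

Likelihoods are compared in log space: the raw density underflows in 13
dimensions, and the argmax is unchanged.  Posteriors (for the
cross-entropy metric) are the softmax of the log-likelihoods under a
uniform class prior.

Covariance estimation with few trees per species is the known weak point
of this classifier family, so covariances are regularized with a small
ridge, and species with fewer training trees than the feature dimension
plus one fall back to the pooled within-class covariance.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.decomposition import PCA

from .io_core import PixelObservation

__all__ = [
    "TreeFeatureVector",
    "FeatureReducer",
    "SpeciesTemplate",
    "Prediction",
    "aggregate_features",
    "fit_reducer",
    "reduce",
    "fit_templates",
    "gaussian_log_likelihood",
    "classify",
]

N_STRUCTURAL = 4  # mean height, min height, max height, sqrt(pixel count)


@dataclass
class TreeFeatureVector:
    """One tree's aggregated features: 4 structural + per-band spectral means."""

    crown_id: str
    structural: np.ndarray
    spectral: np.ndarray

    def __post_init__(self) -> None:
        self.structural = np.asarray(self.structural, dtype=float)
        self.spectral = np.asarray(self.spectral, dtype=float)
        if self.structural.shape != (N_STRUCTURAL,):
            raise ValueError(
                f"structural block must have {N_STRUCTURAL} entries "
                f"(mean/min/max height, sqrt pixel count)"
            )
        mean_h, min_h, max_h, sqrt_n = self.structural
        if not (min_h <= mean_h <= max_h):
            raise ValueError("need min height <= mean height <= max height")
        if sqrt_n < 1:
            raise ValueError("sqrt(pixel count) must be >= 1 for a non-empty crown")


@dataclass
class FeatureReducer:
    """Dual PCA bases: 3 structural + 10 spectral components (by default).

    When fitted with ``standardize=True`` the scale vectors hold the
    per-feature training standard deviations applied before projection;
    otherwise they are all ones.
    """

    structural_mean: np.ndarray
    structural_basis: np.ndarray  # (n_structural_components, 4), rows orthonormal
    spectral_mean: np.ndarray
    spectral_basis: np.ndarray  # (n_spectral_components, n_bands)
    explained_variance: np.ndarray  # structural then spectral eigenvalues
    structural_scale: np.ndarray | None = None
    spectral_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("structural_basis", "spectral_basis"):
            basis = getattr(self, name)
            gram = basis @ basis.T
            if not np.allclose(gram, np.eye(basis.shape[0]), atol=1e-8):
                raise ValueError(f"{name} rows are not orthonormal")
        if self.structural_scale is None:
            self.structural_scale = np.ones(self.structural_mean.size)
        if self.spectral_scale is None:
            self.spectral_scale = np.ones(self.spectral_mean.size)

    @property
    def n_components(self) -> int:
        return self.structural_basis.shape[0] + self.spectral_basis.shape[0]


@dataclass
class SpeciesTemplate:
    """Gaussian species signature in the reduced feature space."""

    species: str
    mean_vector: np.ndarray
    covariance: np.ndarray
    n_train: int

    def __post_init__(self) -> None:
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.n_train < 1:
            raise ValueError("n_train must be >= 1")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        # positive definiteness is verified by the Cholesky in the likelihood


@dataclass
class Prediction:
    """Per-tree classification output."""

    crown_id: str
    log_likelihoods: dict[str, float]
    posterior: dict[str, float]
    label: str

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.posterior.values()), 1.0, abs_tol=1e-9):
            raise ValueError("posterior must sum to 1")
        best = max(self.log_likelihoods.values())
        if not math.isclose(self.log_likelihoods[self.label], best, abs_tol=1e-12):
            raise ValueError("label must attain the maximum log-likelihood")


def aggregate_features(
    pixels: Sequence[PixelObservation],
) -> list[TreeFeatureVector]:
    """Aggregate per-pixel observations into one feature vector per crown.

    Structural block: [mean height, min height, max height, sqrt(pixel
    count)].  Spectral block: per-band mean reflectance, with NaN values
    excluded from that band's mean.  Crowns are returned in first-seen
    order; an empty input is an error.
    """
    if not pixels:
        raise ValueError("no pixel observations supplied")
    by_crown: dict[str, list[PixelObservation]] = defaultdict(list)
    order: list[str] = []
    for p in pixels:
        if p.crown_id not in by_crown:
            order.append(p.crown_id)
        by_crown[p.crown_id].append(p)
    out: list[TreeFeatureVector] = []
    for crown_id in order:
        group = by_crown[crown_id]
        heights = np.array([p.height_m for p in group], dtype=float)
        refl = np.vstack([p.reflectances for p in group])
        with np.errstate(invalid="ignore"):
            spectral = np.nanmean(refl, axis=0)
        out.append(
            TreeFeatureVector(
                crown_id=crown_id,
                structural=np.array(
                    [
                        float(heights.mean()),
                        float(heights.min()),
                        float(heights.max()),
                        math.sqrt(len(group)),
                    ]
                ),
                spectral=spectral,
            )
        )
    return out


def fit_reducer(
    training: Sequence[TreeFeatureVector],
    n_structural: int = 3,
    n_spectral: int = 10,
    standardize: bool = False,
) -> FeatureReducer:
    """Fit the two PCA bases on training feature vectors.

    Inputs are centred; with ``standardize=True`` they are additionally
    divided by the per-feature training standard deviation (a correlation
    rather than covariance PCA).  Requires at least
    ``max(n_structural, n_spectral) + 1`` training vectors.
    """
    n_min = max(n_structural, n_spectral) + 1
    if len(training) < n_min:
        raise ValueError(
            f"need at least {n_min} training vectors, got {len(training)}"
        )
    structural = np.vstack([t.structural for t in training])
    spectral = np.vstack([t.spectral for t in training])
    if standardize:
        s_scale = np.where(structural.std(axis=0) > 0, structural.std(axis=0), 1.0)
        b_scale = np.where(spectral.std(axis=0) > 0, spectral.std(axis=0), 1.0)
    else:
        s_scale = np.ones(structural.shape[1])
        b_scale = np.ones(spectral.shape[1])
    pca_s = PCA(n_components=n_structural, svd_solver="full").fit(structural / s_scale)
    pca_b = PCA(n_components=n_spectral, svd_solver="full").fit(spectral / b_scale)
    return FeatureReducer(
        structural_mean=pca_s.mean_ * s_scale,
        structural_basis=pca_s.components_,
        spectral_mean=pca_b.mean_ * b_scale,
        spectral_basis=pca_b.components_,
        explained_variance=np.concatenate(
            [pca_s.explained_variance_, pca_b.explained_variance_]
        ),
        structural_scale=s_scale,
        spectral_scale=b_scale,
    )


def reduce(vector: TreeFeatureVector, reducer: FeatureReducer) -> np.ndarray:
    """Project one feature vector into the reduced (default 13-D) space."""
    if vector.spectral.size != reducer.spectral_mean.size:
        raise ValueError(
            f"band count {vector.spectral.size} does not match reducer "
            f"({reducer.spectral_mean.size} bands)"
        )
    s = reducer.structural_basis @ (
        (vector.structural - reducer.structural_mean) / reducer.structural_scale
    )
    b = reducer.spectral_basis @ (
        (vector.spectral - reducer.spectral_mean) / reducer.spectral_scale
    )
    return np.concatenate([s, b])


def _regularize(cov: np.ndarray, ridge_rel: float) -> np.ndarray:
    mean_diag = float(np.mean(np.diag(cov)))
    lam = ridge_rel * mean_diag if mean_diag > 0 else ridge_rel
    return cov + lam * np.eye(cov.shape[0])


def fit_templates(
    reduced: Sequence[np.ndarray],
    labels: Sequence[str],
    ridge_rel: float = 1e-6,
    pooled_below: int | None = None,
) -> list[SpeciesTemplate]:
    """Fit one Gaussian template per species from reduced training vectors.

    Each template's covariance is the sample covariance (ddof=1) plus a
    ridge of ``ridge_rel`` times its mean diagonal.  Species with fewer
    than ``pooled_below`` training trees (default: feature dimension + 1,
    where the per-class covariance is necessarily singular) use the pooled
    within-class covariance instead — small classes are exactly where
    per-class covariances are estimated too poorly to invert.
    """
    if len(reduced) != len(labels):
        raise ValueError("one label per training vector is required")
    if not reduced:
        raise ValueError("no training vectors supplied")
    X = np.vstack(reduced)
    dim = X.shape[1]
    if pooled_below is None:
        pooled_below = dim + 1
    y = np.asarray(labels)
    classes = sorted(set(labels))
    means = {k: X[y == k].mean(axis=0) for k in classes}
    # pooled within-class covariance: sum of per-class scatters / (N - K)
    scatter = np.zeros((dim, dim))
    dof = 0
    for k in classes:
        Xk = X[y == k] - means[k]
        scatter += Xk.T @ Xk
        dof += Xk.shape[0] - 1
    pooled = scatter / dof if dof > 0 else np.zeros((dim, dim))
    templates: list[SpeciesTemplate] = []
    for k in classes:
        Xk = X[y == k]
        if Xk.shape[0] >= pooled_below:
            cov = np.cov(Xk, rowvar=False, ddof=1)
        else:
            cov = pooled
        templates.append(
            SpeciesTemplate(
                species=k,
                mean_vector=means[k],
                covariance=_regularize(cov, ridge_rel),
                n_train=int(Xk.shape[0]),
            )
        )
    return templates


def gaussian_log_likelihood(t: np.ndarray, tpl: SpeciesTemplate) -> float:
    """Log multivariate-normal density of a reduced vector under a template.

    Computed via a Cholesky factorization of the covariance; raises if the
    covariance is not positive definite.
    """
    t = np.asarray(t, dtype=float)
    if t.shape != tpl.mean_vector.shape:
        raise ValueError(
            f"vector dimension {t.shape} does not match template "
            f"{tpl.mean_vector.shape}"
        )
    n = t.size
    try:
        factor = cho_factor(tpl.covariance, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises LinAlgError
        raise ValueError(f"covariance of {tpl.species} is not positive definite") from exc
    resid = t - tpl.mean_vector
    maha = float(resid @ cho_solve(factor, resid))
    log_det = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
    return -0.5 * (n * math.log(2.0 * math.pi) + log_det + maha)


def classify(
    vectors: Sequence[tuple[str, np.ndarray]],
    templates: Sequence[SpeciesTemplate],
) -> list[Prediction]:
    """Assign each reduced vector to the species with the highest likelihood.

    ``vectors`` holds (crown_id, reduced vector) pairs.  Posterior =
    softmax of the log-likelihoods (uniform prior); likelihood ties go to
    the lexicographically smaller species name.
    """
    if not templates:
        raise ValueError("at least one species template is required")
    species = sorted(t.species for t in templates)
    by_name = {t.species: t for t in templates}
    out: list[Prediction] = []
    for crown_id, vec in vectors:
        logls = {k: gaussian_log_likelihood(vec, by_name[k]) for k in species}
        values = np.array([logls[k] for k in species])
        shifted = np.exp(values - values.max())
        probs = shifted / shifted.sum()
        label = species[int(np.argmax(values))]  # argmax takes first (lexicographic) tie
        out.append(
            Prediction(
                crown_id=crown_id,
                log_likelihoods=logls,
                posterior={k: float(p) for k, p in zip(species, probs)},
                label=label,
            )
        )
    return out
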