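"""Per-stimulus target / non-target scorers.

Three pipelines, named as in the field:

* ``lda`` — interval-mean features classified with shrinkage-regularized
  linear discriminant analysis.  The discriminant is the binary Fisher
  direction ``w = Sw^{-1} (m1 - m0)`` with the pooled within-class covariance
  shrunk toward a scaled identity (Ledoit-Wolf intensity), and the score
  ``d_i = w^T x_i + b`` is a signed distance from the separating hyperplane.
* ``xdw_lda`` — an xDAWN spatial filter (generalized eigenproblem maximizing
  the evoked signal-to-signal-plus-noise ratio) reduces the epochs to a few
  virtual channels before interval means + shrinkage LDA.
* ``xdwcov_ts_lda`` — xDAWN-filtered epochs are augmented with the filtered
  evoked prototype, per-epoch covariance matrices are formed, mapped to the
  tangent space at their affine-invariant Riemannian geometric mean, and the
  resulting vectors are classified with shrinkage LDA.

Only the decision-relevant direction of the LDA matters downstream: the trial
rule compares relative score magnitudes, so any monotone bias convention is
decision-equivalent; we pin b so the projected midpoint of the class means
scores zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import scipy.linalg

from .signal import Epochs, FeatureMatrix, interval_means


# ---------------------------------------------------------------------------
# shrinkage LDA

@dataclass
class LdaModel:
    w: np.ndarray
    b: float
    shrinkage_lambda: float
    class_means: tuple[np.ndarray, np.ndarray]  # (m0 non-target, m1 target)
    within_cov: np.ndarray


def fit_shrinkage_lda(features: FeatureMatrix | np.ndarray, labels: np.ndarray) -> LdaModel:
    """Fisher discriminant with Ledoit-Wolf-shrunk pooled within-class covariance.

    ``Sw = (1 - lam) * S + lam * (tr S / p) * I`` where ``S`` is the pooled
    covariance of class-centered data with the unbiased ``N - 2`` denominator
    and ``lam`` the Ledoit-Wolf intensity; ``w = Sw^{-1} (m1 - m0)``; ``b``
    makes the projected midpoint of the class means score 0.  Targets
    (label 1) score positive on the training means.
    """
    from sklearn.covariance import ledoit_wolf

    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels).astype(int).ravel()
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("features/labels shape mismatch")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    lo, hi = classes
    m0 = x[y == lo].mean(axis=0)
    m1 = x[y == hi].mean(axis=0)
    centered = x.astype(float).copy()
    centered[y == lo] -= m0
    centered[y == hi] -= m1
    n, p = centered.shape
    if n <= 2:
        raise ValueError("need more than two samples")
    s = centered.T @ centered / (n - 2)
    _, lam = ledoit_wolf(centered, assume_centered=True)
    sw = (1.0 - lam) * s + lam * (np.trace(s) / p) * np.eye(p)
    w = np.linalg.solve(sw, m1 - m0)
    b = -float(w @ (m0 + m1) / 2.0)
    return LdaModel(w=w, b=b, shrinkage_lambda=float(lam), class_means=(m0, m1), within_cov=sw)


def lda_score(model: LdaModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Signed hyperplane distances ``d_i = w^T x_i + b``."""
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.w.size:
        raise ValueError(f"feature dimension {x.shape[1]} != model {model.w.size}")
    return x @ model.w + model.b


# ---------------------------------------------------------------------------
# xDAWN spatial filtering

@dataclass
class SpatialFilter:
    projection: np.ndarray  # n_components x channels
    patterns: np.ndarray  # channels x n_components (forward model Cx @ w)
    eigenvalue_ratios: np.ndarray  # non-increasing
    evoked_prototype: np.ndarray  # channels x samples (target class average)


def fit_xdawn(epochs: Epochs, labels: np.ndarray | None = None, n_components: int = 2,
              jitter: float = 1e-10) -> SpatialFilter:
    """Spatial filters maximizing evoked-to-total power ratio.

    Solves the generalized eigenproblem (evoked covariance ``P P^T / T`` vs
    total covariance of the concatenated epochs), keeping the top
    ``n_components`` eigenvectors in non-increasing eigenvalue order.  Signs
    are fixed by making the largest-magnitude filter coefficient positive.
    """
    y = epochs.labels if labels is None else np.asarray(labels).astype(int)
    n_ev, n_ch, n_t = epochs.data.shape
    if n_components > n_ch:
        raise ValueError("n_components exceeds channel count")
    if not np.any(y == 1):
        raise ValueError("no target epochs")
    proto = epochs.data[y == 1].mean(axis=0)  # channels x samples
    cs = proto @ proto.T / n_t
    flat = np.moveaxis(epochs.data, 1, 0).reshape(n_ch, -1)
    cx = flat @ flat.T / flat.shape[1]
    cx = cx + jitter * np.trace(cx) / n_ch * np.eye(n_ch)
    vals, vecs = scipy.linalg.eigh(cs, cx)
    order = np.argsort(vals)[::-1][:n_components]
    filters = vecs[:, order].T  # n_comp x channels
    for k in range(filters.shape[0]):
        j = np.argmax(np.abs(filters[k]))
        if filters[k, j] < 0:
            filters[k] = -filters[k]
    patterns = cx @ filters.T
    return SpatialFilter(
        projection=filters,
        patterns=patterns,
        eigenvalue_ratios=vals[order],
        evoked_prototype=proto,
    )


def apply_spatial_filter(epochs: Epochs, filt: SpatialFilter) -> Epochs:
    """Project epochs onto the xDAWN components (virtual channels)."""
    data = np.einsum("kc,ecs->eks", filt.projection, epochs.data)
    labels = [f"xdw{k}" for k in range(filt.projection.shape[0])]
    return Epochs(
        data=data,
        tmin_s=epochs.tmin_s,
        tmax_s=epochs.tmax_s,
        fs_hz=epochs.fs_hz,
        channel_labels=labels,
        metadata=epochs.metadata,
    )


# ---------------------------------------------------------------------------
# Riemannian geometry on SPD matrices

@dataclass
class SpdSet:
    matrices: np.ndarray  # n x d x d, symmetric positive definite
    reference_mean: np.ndarray | None = None


def erp_covariances(epochs: Epochs, filt: SpatialFilter, shrink: float = 1e-8) -> SpdSet:
    """Prototype-augmented covariance per epoch.

    Each xDAWN-filtered epoch ``X`` (n_comp x T) is stacked under the filtered
    evoked prototype ``P`` and the second-moment matrix of ``[P; X]`` is taken
    (no mean removal), giving 2n x 2n matrices whose off-diagonal block
    carries the epoch-prototype covariance.  A small trace-scaled ridge keeps
    them positive definite.
    """
    xf = np.einsum("kc,ecs->eks", filt.projection, epochs.data)
    pf = filt.projection @ filt.evoked_prototype
    n_ev, n_comp, n_t = xf.shape
    z = np.concatenate([np.broadcast_to(pf, (n_ev, *pf.shape)), xf], axis=1)
    covs = np.einsum("eis,ejs->eij", z, z) / n_t
    d = 2 * n_comp
    tr = np.trace(covs, axis1=1, axis2=2)
    covs = covs + (shrink * tr / d)[:, None, None] * np.eye(d)
    return SpdSet(matrices=covs)


def _sqrtm_spd(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(a)
    if np.any(vals <= 0):
        raise ValueError("matrix is not positive definite")
    s = np.sqrt(vals)
    return (vecs * s) @ vecs.T, (vecs / s) @ vecs.T


def _logm_spd(a: np.ndarray) -> np.ndarray:
    """Matrix log of an SPD matrix or a stack of them (batched eigh)."""
    vals, vecs = np.linalg.eigh(a)
    if np.any(vals <= 0):
        raise ValueError("matrix is not positive definite")
    return np.einsum("...ik,...k,...jk->...ij", vecs, np.log(vals), vecs)


def geometric_mean(spd: SpdSet | np.ndarray, tol: float = 1e-8, max_iter: int = 50) -> np.ndarray:
    """Affine-invariant Riemannian (Karcher) mean by fixed-point iteration.

    Warns (and returns the last iterate) on non-convergence.
    """
    mats = spd.matrices if isinstance(spd, SpdSet) else np.asarray(spd)
    if mats.ndim != 3 or mats.shape[0] == 0:
        raise ValueError("need a non-empty set of square matrices")
    g = mats.mean(axis=0)
    for _ in range(max_iter):
        g_half, g_ihalf = _sqrtm_spd(g)
        whitened = np.einsum("ij,njk,kl->nil", g_ihalf, mats, g_ihalf)
        whitened = (whitened + np.swapaxes(whitened, 1, 2)) / 2
        step = _logm_spd(whitened).mean(axis=0)
        step = (step + step.T) / 2
        norm = np.linalg.norm(step)
        vals, vecs = np.linalg.eigh(step)
        exp_step = (vecs * np.exp(vals)) @ vecs.T
        g = g_half @ exp_step @ g_half
        g = (g + g.T) / 2
        if norm < tol:
            return g
    warnings.warn(f"geometric mean did not reach tol={tol} in {max_iter} iterations")
    return g


def tangent_embed(spd: SpdSet | np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Log-map vectorization at ``reference``: upper triangle of
    ``log(G^{-1/2} C G^{-1/2})`` with off-diagonals scaled by sqrt(2).

    The Euclidean norm of a vector equals the affine-invariant Riemannian
    distance between ``C`` and the reference.  d x d matrices give
    d(d+1)/2 features.
    """
    mats = spd.matrices if isinstance(spd, SpdSet) else np.asarray(spd)
    single = mats.ndim == 2
    if single:
        mats = mats[None]
    _, g_ihalf = _sqrtm_spd(reference)
    d = mats.shape[1]
    iu = np.triu_indices(d)
    scale = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    whitened = np.einsum("ij,njk,kl->nil", g_ihalf, mats, g_ihalf)
    whitened = (whitened + np.swapaxes(whitened, 1, 2)) / 2
    logs = _logm_spd(whitened)
    out = logs[:, iu[0], iu[1]] * scale
    return out[0] if single else out


# ---------------------------------------------------------------------------
# pipelines

class Pipeline(Protocol):
    name: str

    def fit(self, epochs: Epochs) -> "Pipeline": ...
    def score(self, epochs: Epochs) -> np.ndarray: ...


@dataclass
class LdaPipeline:
    """Interval means -> shrinkage LDA."""

    name: str = "lda"
    bin_s: float = 0.1
    model: LdaModel | None = None

    def _features(self, epochs: Epochs) -> FeatureMatrix:
        return interval_means(epochs, start_s=0.0, end_s=epochs.tmax_s, bin_s=self.bin_s)

    def fit(self, epochs: Epochs) -> "LdaPipeline":
        f = self._features(epochs)
        self.model = fit_shrinkage_lda(f, f.labels)
        return self

    def score(self, epochs: Epochs) -> np.ndarray:
        return lda_score(self.model, self._features(epochs))

    def fit_features(self, features: FeatureMatrix, labels: np.ndarray) -> "LdaPipeline":
        self.model = fit_shrinkage_lda(features, labels)
        return self


@dataclass
class XdawnLdaPipeline:
    """xDAWN projection -> interval means -> shrinkage LDA."""

    name: str = "xdw_lda"
    n_components: int = 2
    bin_s: float = 0.1
    filt: SpatialFilter | None = None
    model: LdaModel | None = None

    def fit(self, epochs: Epochs) -> "XdawnLdaPipeline":
        self.filt = fit_xdawn(epochs, n_components=self.n_components)
        virt = apply_spatial_filter(epochs, self.filt)
        f = interval_means(virt, 0.0, virt.tmax_s, self.bin_s)
        self.model = fit_shrinkage_lda(f, f.labels)
        return self

    def score(self, epochs: Epochs) -> np.ndarray:
        virt = apply_spatial_filter(epochs, self.filt)
        return lda_score(self.model, interval_means(virt, 0.0, virt.tmax_s, self.bin_s))


@dataclass
class XdawnCovTsLdaPipeline:
    """xDAWN -> prototype-augmented covariances -> tangent space -> shrinkage LDA."""

    name: str = "xdwcov_ts_lda"
    n_components: int = 2
    filt: SpatialFilter | None = None
    reference: np.ndarray | None = None
    model: LdaModel | None = None

    def fit(self, epochs: Epochs) -> "XdawnCovTsLdaPipeline":
        self.filt = fit_xdawn(epochs, n_components=self.n_components)
        covs = erp_covariances(epochs, self.filt)
        self.reference = geometric_mean(covs)
        vecs = tangent_embed(covs, self.reference)
        self.model = fit_shrinkage_lda(vecs, epochs.labels)
        return self

    def score(self, epochs: Epochs) -> np.ndarray:
        covs = erp_covariances(epochs, self.filt)
        return lda_score(self.model, tangent_embed(covs, self.reference))


PIPELINES = {
    "lda": LdaPipeline,
    "xdw_lda": XdawnLdaPipeline,
    "xdwcov_ts_lda": XdawnCovTsLdaPipeline,
}


def make_pipeline(name: str, **kwargs) -> Pipeline:
    try:
        return PIPELINES[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown pipeline {name!r}; choose from {sorted(PIPELINES)}")


# ---------------------------------------------------------------------------
# serialization

def save_model(pipeline, path) -> None:
    """Serialize a fitted pipeline to HDF5 (weights, shrinkage, filters, reference)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["pipeline"] = pipeline.name
        m = pipeline.model
        g = f.create_group("lda")
        g.create_dataset("w", data=m.w)
        g.attrs["b"] = m.b
        g.attrs["shrinkage_lambda"] = m.shrinkage_lambda
        g.create_dataset("m0", data=m.class_means[0])
        g.create_dataset("m1", data=m.class_means[1])
        if getattr(pipeline, "filt", None) is not None:
            x = f.create_group("xdawn")
            x.create_dataset("projection", data=pipeline.filt.projection)
            x.create_dataset("patterns", data=pipeline.filt.patterns)
            x.create_dataset("eigenvalue_ratios", data=pipeline.filt.eigenvalue_ratios)
            x.create_dataset("evoked_prototype", data=pipeline.filt.evoked_prototype)
        if getattr(pipeline, "reference", None) is not None:
            f.create_dataset("reference_mean", data=pipeline.reference)


def load_model(path):
    """Load a pipeline serialized with :func:`save_model`."""
    import h5py

    with h5py.File(path, "r") as f:
        pipe = make_pipeline(f.attrs["pipeline"])
        g = f["lda"]
        pipe.model = LdaModel(
            w=g["w"][()],
            b=float(g.attrs["b"]),
            shrinkage_lambda=float(g.attrs["shrinkage_lambda"]),
            class_means=(g["m0"][()], g["m1"][()]),
            within_cov=np.empty((0, 0)),
        )
        if "xdawn" in f:
            x = f["xdawn"]
            pipe.filt = SpatialFilter(
                projection=x["projection"][()],
                patterns=x["patterns"][()],
                eigenvalue_ratios=x["eigenvalue_ratios"][()],
                evoked_prototype=x["evoked_prototype"][()],
            )
        if "reference_mean" in f:
            pipe.reference = f["reference_mean"][()]
    return pipe
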