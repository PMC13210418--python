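"""Basis material decomposition: features, calibration grids, and regressors.

Per-pixel measurements are reduced to log-normalized features

    f_k = -log(n_k / n_{k,0}),    k = 1..N_b,

where ``n_k`` are the counts in energy bin k and ``n_{k,0}`` the matching
open-beam counts.  Calibration grids are uniform GxG lattices of known
(Al, PMMA) thickness pairs whose noise-free forward-model features train the
inverse mapping.  Three regressor families are provided, all trained on
identical grids:

* ``poly2`` — full second-degree polynomial least squares per material
  (a third-degree variant exists behind a flag but is off by default);
* ``mlp`` — two hidden layers x 128 ReLU units, dropout 0.01, L2 weight
  decay, Adam, smooth-L1 loss (see :mod:`pcdspect._mlp`);
* ``svr`` — epsilon-insensitive RBF support vector regression per material
  (C=100, epsilon=0.010, gamma="scale").

Features are standardized and targets min-max scaled to [0, 1] per material
for the MLP and SVR, so that the SVR epsilon-tube width means the same
fraction of range for the ~10 mm Al scale and the ~120 mm PMMA scale.
Predictions are never clipped: negative thickness estimates must remain
visible to the signed bias metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import PolynomialFeatures
from sklearn.svm import SVR

from . import _mlp
from .detector import (BinnedCountImage, DRFMatrix, ThresholdConfig,
                       expected_bin_counts)
from .phantom import ThicknessMaps
from .physics import Spectrum

#: calibration thickness ranges, mm — cover all phantom ground truths
DEFAULT_AL_RANGE = (0.0, 10.0)
DEFAULT_PMMA_RANGE = (0.0, 120.0)

ZERO_COUNT_CLAMP = 0.5  # counts; keeps features finite in empty bins


@dataclass
class FeatureImage:
    """Per-pixel log-normalized feature vectors, shape (H, W, N_b)."""

    features: np.ndarray
    pitch: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")

    @property
    def n_bins(self) -> int:
        return self.features.shape[-1]

    def flat(self) -> np.ndarray:
        return self.features.reshape(-1, self.n_bins)


@dataclass
class CalibrationGrid:
    """G x G lattice of (Al, PMMA) thicknesses with noise-free features."""

    thicknesses: np.ndarray  # (G*G, 2): columns Al, PMMA in mm
    features: np.ndarray     # (G*G, N_b)
    g: int
    al_range: tuple[float, float]
    pmma_range: tuple[float, float]

    def to_csv(self, path: str) -> None:
        import pandas as pd

        nb = self.features.shape[1]
        df = pd.DataFrame(self.thicknesses, columns=["x_al", "x_pmma"])
        for k in range(nb):
            df[f"f_{k + 1}"] = self.features[:, k]
        df.to_csv(path, index=False)


def to_features(noisy: BinnedCountImage, open_beam: BinnedCountImage | np.ndarray
                ) -> FeatureImage:
    """Compute f = -log(n / n0) per pixel per bin.

    Measured counts below :data:`ZERO_COUNT_CLAMP` are clamped up to it so
    that empty bins at ultra-low dose stay finite.  ``open_beam`` may be a
    BinnedCountImage (uniform open-beam stack) or a per-bin count vector.
    """
    n0 = open_beam.open_beam if isinstance(open_beam, BinnedCountImage) \
        else np.asarray(open_beam, dtype=float)
    if n0.shape != (noisy.n_bins,):
        raise ValueError("open-beam reference must have one count per bin")
    if np.any(n0 <= 0):
        raise ValueError("open-beam counts must be positive in every bin")
    n = np.maximum(noisy.counts.astype(float), ZERO_COUNT_CLAMP)
    f = -np.log(n / n0[:, None, None])
    return FeatureImage(features=np.moveaxis(f, 0, -1), pitch=noisy.pitch,
                        provenance={"thresholds": list(noisy.thresholds.thresholds),
                                    "exposure_mAs": noisy.exposure_mas,
                                    "seed": noisy.seed})


def make_calibration_grid(g: int, spectrum: Spectrum, drf: DRFMatrix,
                          thresholds: ThresholdConfig,
                          al_range: tuple[float, float] = DEFAULT_AL_RANGE,
                          pmma_range: tuple[float, float] = DEFAULT_PMMA_RANGE
                          ) -> CalibrationGrid:
    """Noise-free features on a uniform G x G thickness lattice (endpoints included).

    Each node is a uniform slab, so a single representative pixel suffices and
    charge sharing (a unit-sum convolution of a constant image) is a no-op.
    """
    if g < 2:
        raise ValueError("grid size must be at least 2")
    if al_range[1] <= al_range[0] or pmma_range[1] <= pmma_range[0]:
        raise ValueError("empty calibration range")
    al = np.linspace(*al_range, g)
    pmma = np.linspace(*pmma_range, g)
    aa, pp = np.meshgrid(al, pmma, indexing="ij")
    thicknesses = np.column_stack([aa.ravel(), pp.ravel()])
    features = features_for_thicknesses(thicknesses, spectrum, drf, thresholds)
    return CalibrationGrid(thicknesses=thicknesses, features=features, g=g,
                           al_range=al_range, pmma_range=pmma_range)


def features_for_thicknesses(thicknesses: np.ndarray, spectrum: Spectrum,
                             drf: DRFMatrix, thresholds: ThresholdConfig
                             ) -> np.ndarray:
    """Noise-free features for arbitrary (Al, PMMA) slab pairs, shape (N, N_b)."""
    maps = ThicknessMaps(al_map=thicknesses[:, :1].copy(),
                         pmma_map=thicknesses[:, 1:].copy(), pitch=1.0)
    img = expected_bin_counts(maps, spectrum, drf, thresholds,
                              exposure_mas=spectrum.reference_exposure)
    f = -np.log(img.counts / img.open_beam[:, None, None])
    return np.moveaxis(f, 0, -1).reshape(-1, thresholds.n_bins)


# ---------------------------------------------------------------------------
# models

@dataclass
class DecompModel:
    """A fitted decomposition regressor; predict maps (N, N_b) -> (N, 2) mm."""

    kind: str
    n_bins: int
    metadata: dict = field(default_factory=dict)

    def predict(self, features: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class PolyModel(DecompModel):
    poly: PolynomialFeatures | None = None
    coef: np.ndarray | None = None  # (n_terms, 2)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.poly.transform(features) @ self.coef


@dataclass
class MLPModel(DecompModel):
    net: _mlp.MLPNetwork | None = None
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None
    y_min: np.ndarray | None = None
    y_max: np.ndarray | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        z = (features - self.x_mean) / self.x_std
        y = self.net.predict(z)
        return y * (self.y_max - self.y_min) + self.y_min


@dataclass
class SVRModel(DecompModel):
    svrs: list[SVR] | None = None
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None
    y_min: np.ndarray | None = None
    y_max: np.ndarray | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        z = (features - self.x_mean) / self.x_std
        y = np.column_stack([s.predict(z) for s in self.svrs])
        return y * (self.y_max - self.y_min) + self.y_min


def _poly_term_count(n_bins: int, degree: int) -> int:
    from math import comb

    return comb(n_bins + degree, degree)


def fit_poly2(grid: CalibrationGrid, degree: int = 2,
              rcond: float = 1e-4) -> PolyModel:
    """Least-squares fit of a full degree-2 polynomial in f per material.

    Raises if the grid has fewer samples than polynomial terms; an
    under-determined fit is reported as an error, never silently completed.
    ``degree=3`` is available but off by default.

    ``rcond`` is the relative singular-value cutoff of the truncated
    pseudo-inverse.  With more than two energy bins the calibration features
    lie on a two-dimensional thickness manifold, so the polynomial design
    contains directions that the grid constrains only at the 1e-5 level;
    inverting those amplifies measurement noise by an order of magnitude
    while changing the noise-free fit negligibly.  The default keeps the
    solution minimal-norm along such unidentifiable directions (effective
    rank is recorded in the model metadata).
    """
    if degree not in (2, 3):
        raise ValueError("only degree 2 (default) and 3 are supported")
    nb = grid.features.shape[1]
    n_terms = _poly_term_count(nb, degree)
    n_samples = grid.features.shape[0]
    if n_samples < n_terms:
        raise ValueError(
            f"degree-{degree} polynomial in {nb} features has {n_terms} terms "
            f"but the grid provides only {n_samples} samples")
    poly = PolynomialFeatures(degree=degree, include_bias=True)
    design = poly.fit_transform(grid.features)
    coef, _, rank, _ = np.linalg.lstsq(design, grid.thicknesses, rcond=rcond)
    if rank == 0:
        raise ValueError("degenerate polynomial design matrix")
    return PolyModel(kind=f"poly{degree}", n_bins=nb, poly=poly, coef=coef,
                     metadata={"degree": degree, "n_terms": n_terms,
                               "rcond": rcond, "effective_rank": int(rank)})


@dataclass(frozen=True)
class MLPHyper:
    hidden: tuple[int, ...] = (128, 128)
    dropout: float = 0.01
    weight_decay: float = 1e-4
    lr: float = 3e-3
    epochs: int = 10000
    smooth_l1_beta: float = 1.0
    seed: int = 0


def fit_mlp(grid: CalibrationGrid, hyper: MLPHyper = MLPHyper()) -> MLPModel:
    """Train the decomposition MLP on a calibration grid (deterministic per seed)."""
    x = grid.features
    y = grid.thicknesses
    x_mean, x_std = x.mean(axis=0), x.std(axis=0)
    x_std = np.where(x_std > 0, x_std, 1.0)
    y_min, y_max = y.min(axis=0), y.max(axis=0)
    span = np.where(y_max > y_min, y_max - y_min, 1.0)
    net = _mlp.train_mlp((x - x_mean) / x_std, (y - y_min) / span,
                         hidden=hyper.hidden, lr=hyper.lr, epochs=hyper.epochs,
                         dropout=hyper.dropout, weight_decay=hyper.weight_decay,
                         smooth_l1_beta=hyper.smooth_l1_beta, seed=hyper.seed)
    return MLPModel(kind="mlp", n_bins=x.shape[1], net=net, x_mean=x_mean,
                    x_std=x_std, y_min=y_min, y_max=y_min + span,
                    metadata={"hyper": hyper.__dict__ | {"hidden": list(hyper.hidden)},
                              "n_parameters": net.n_parameters})


def fit_svr(grid: CalibrationGrid, c: float = 100.0, epsilon: float = 0.010,
            gamma: str | float = "scale") -> SVRModel:
    """One RBF support vector regressor per material on the scaled grid."""
    x = grid.features
    if np.allclose(x, x[0]):
        raise ValueError("degenerate calibration grid: identical features")
    y = grid.thicknesses
    x_mean, x_std = x.mean(axis=0), x.std(axis=0)
    x_std = np.where(x_std > 0, x_std, 1.0)
    y_min, y_max = y.min(axis=0), y.max(axis=0)
    span = np.where(y_max > y_min, y_max - y_min, 1.0)
    z = (x - x_mean) / x_std
    svrs = []
    for col in range(2):
        s = SVR(kernel="rbf", C=c, epsilon=epsilon, gamma=gamma)
        s.fit(z, (y[:, col] - y_min[col]) / span[col])
        svrs.append(s)
    return SVRModel(kind="svr", n_bins=x.shape[1], svrs=svrs, x_mean=x_mean,
                    x_std=x_std, y_min=y_min, y_max=y_min + span,
                    metadata={"C": c, "epsilon": epsilon, "gamma": gamma})


def decompose(model: DecompModel, features: FeatureImage) -> ThicknessMaps:
    """Apply a fitted model pixel-wise; negative estimates are not clipped."""
    if features.n_bins != model.n_bins:
        raise ValueError(
            f"model expects {model.n_bins} feature bins, got {features.n_bins}")
    pred = model.predict(features.flat())
    h, w = features.features.shape[:2]
    al = pred[:, 0].reshape(h, w)
    pmma = pred[:, 1].reshape(h, w)
    # ThicknessMaps forbids negative values by contract; carry raw arrays here
    maps = ThicknessMaps.__new__(ThicknessMaps)
    maps.al_map, maps.pmma_map, maps.pitch = al, pmma, features.pitch
    return maps


# ---------------------------------------------------------------------------
# model persistence

def save_model(model: DecompModel, path: str) -> None:
    """Persist a fitted model to HDF5 (kind, scalers, parameters)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["kind"] = model.kind
        fh.attrs["n_bins"] = model.n_bins
        fh.attrs["metadata"] = json.dumps(model.metadata)
        if isinstance(model, PolyModel):
            fh.create_dataset("coef", data=model.coef)
            fh.attrs["degree"] = model.metadata["degree"]
        elif isinstance(model, MLPModel):
            for i, (w, b) in enumerate(zip(model.net.weights, model.net.biases)):
                fh.create_dataset(f"w{i}", data=w)
                fh.create_dataset(f"b{i}", data=b)
            fh.attrs["n_layers"] = len(model.net.weights)
            for name in ("x_mean", "x_std", "y_min", "y_max"):
                fh.create_dataset(name, data=getattr(model, name))
        elif isinstance(model, SVRModel):
            for i, s in enumerate(model.svrs):
                fh.create_dataset(f"sv{i}", data=s.support_vectors_)
                fh.create_dataset(f"dual{i}", data=s.dual_coef_[0])
                fh.create_dataset(f"intercept{i}", data=s.intercept_)
                fh.attrs[f"gamma{i}"] = s._gamma
            for name in ("x_mean", "x_std", "y_min", "y_max"):
                fh.create_dataset(name, data=getattr(model, name))
        else:  # pragma: no cover
            raise TypeError(f"cannot serialize model kind {model.kind!r}")


def load_model(path: str) -> DecompModel:
    import h5py

    with h5py.File(path, "r") as fh:
        kind = str(fh.attrs["kind"])
        nb = int(fh.attrs["n_bins"])
        meta = json.loads(fh.attrs["metadata"])
        if kind.startswith("poly"):
            poly = PolynomialFeatures(degree=int(fh.attrs["degree"]),
                                      include_bias=True)
            poly.fit(np.zeros((1, nb)))
            return PolyModel(kind=kind, n_bins=nb, metadata=meta, poly=poly,
                             coef=fh["coef"][()])
        if kind == "mlp":
            n = int(fh.attrs["n_layers"])
            net = _mlp.MLPNetwork(
                weights=[fh[f"w{i}"][()] for i in range(n)],
                biases=[fh[f"b{i}"][()] for i in range(n)])
            return MLPModel(kind=kind, n_bins=nb, metadata=meta, net=net,
                            x_mean=fh["x_mean"][()], x_std=fh["x_std"][()],
                            y_min=fh["y_min"][()], y_max=fh["y_max"][()])
        if kind == "svr":
            model = _RawSVRModel(kind=kind, n_bins=nb, metadata=meta,
                                 x_mean=fh["x_mean"][()], x_std=fh["x_std"][()],
                                 y_min=fh["y_min"][()], y_max=fh["y_max"][()])
            model.params = [
                (fh[f"sv{i}"][()], fh[f"dual{i}"][()],
                 float(fh[f"intercept{i}"][()][0]), float(fh.attrs[f"gamma{i}"]))
                for i in range(2)]
            return model
        raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class _RawSVRModel(DecompModel):
    """SVR restored from its dual form: y = sum_i (a_i - a_i*) K(x_i, x) + b."""

    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None
    y_min: np.ndarray | None = None
    y_max: np.ndarray | None = None
    params: list = field(default_factory=list)

    def predict(self, features: np.ndarray) -> np.ndarray:
        z = (features - self.x_mean) / self.x_std
        cols = []
        for sv, dual, intercept, gamma in self.params:
            d2 = ((z[:, None, :] - sv[None, :, :]) ** 2).sum(axis=-1)
            cols.append(np.exp(-gamma * d2) @ dual + intercept)
        y = np.column_stack(cols)
        return y * (self.y_max - self.y_min) + self.y_min
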