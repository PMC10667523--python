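"""Kernel-regression calibration from SNV spectra to lipid, HCL and DS.

Support vector regression (epsilon-insensitive loss, RBF kernel by
default) maps per-sample SNV absorbance spectra to each target — total
lipid content (mg/g), hydrocarbon chain length and degree of saturation
— with one independent model per target.  Internal validation is
leave-one-out cross-validation and models are scored with the
cross-validated coefficient of determination

    R^2 = 1 - sum_i (yhat_i - y_i)^2 / sum_i (y_i - ybar)^2,

residuals of predictions against measurements, total sum of squares
about the measured mean.

Hyperparameters are not dictated by the data model, so defaults are
conservative and recorded in :class:`RegressionConfig`: the RBF width is
set by the median pairwise feature-distance heuristic, targets are
standardized internally and back-transformed on prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.svm import SVR

from .preprocess import ReflectanceCube, SampleSpectrum

__all__ = [
    "CalibrationSet",
    "RegressionConfig",
    "RegressionModel",
    "CrossValidationReport",
    "fit",
    "loocv",
    "r_squared",
    "predict_pixels",
]

Target = Literal["lipid", "hcl", "ds"]
_TARGET_COLUMNS = {"lipid": "total_lipid", "hcl": "hcl", "ds": "ds"}


@dataclass
class CalibrationSet:
    """Per-sample SNV spectra paired with their reference targets."""

    features: np.ndarray  # (n_samples, n_bands) SNV absorbance
    wavelengths: np.ndarray
    targets: pd.DataFrame  # columns total_lipid, hcl, ds (+ optional diet)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be (samples, bands)")
        n = self.features.shape[0]
        if len(self.sample_ids) != n or len(self.targets) != n:
            raise ValueError("sample count mismatch between features and targets")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        for col in _TARGET_COLUMNS.values():
            if col in self.targets and not np.all(np.isfinite(self.targets[col])):
                raise ValueError(f"target {col!r} contains non-finite values")

    @classmethod
    def from_spectra(
        cls, spectra: Sequence[SampleSpectrum], truth: pd.DataFrame
    ) -> "CalibrationSet":
        """Assemble features from preprocessed sample spectra and a truth
        table indexed by ``sample_id``."""
        truth = truth.set_index("sample_id")
        ids = [s.sample_id for s in spectra]
        feats = np.vstack([s.snv for s in spectra])
        return cls(
            features=feats,
            wavelengths=spectra[0].wavelengths,
            targets=truth.loc[ids].reset_index(),
            sample_ids=ids,
        )

    def target_values(self, target: Target) -> np.ndarray:
        col = _TARGET_COLUMNS[target]
        if col not in self.targets:
            raise KeyError(f"calibration set has no {col!r} column")
        return np.asarray(self.targets[col], dtype=float)

    def subset(self, idx: np.ndarray) -> "CalibrationSet":
        return CalibrationSet(
            features=self.features[idx],
            wavelengths=self.wavelengths,
            targets=self.targets.iloc[idx].reset_index(drop=True),
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
        )

    def __len__(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class RegressionConfig:
    """SVR hyperparameters.  ``gamma=None`` selects the median pairwise
    squared-distance heuristic gamma = 1 / median(||x_i - x_j||^2)."""

    kernel: str = "rbf"
    C: float = 100.0
    epsilon: float = 0.01
    gamma: float | None = None
    tol: float = 1e-4  # libsvm stopping tolerance

    def resolve_gamma(self, features: np.ndarray) -> float | str:
        if self.kernel != "rbf":
            return "scale"
        if self.gamma is not None:
            return self.gamma
        if features.shape[0] < 2:
            return "scale"
        d2 = pdist(features, "sqeuclidean")
        med = float(np.median(d2))
        if med <= 0:
            return "scale"
        return 1.0 / med


@dataclass
class RegressionModel:
    """A fitted SVR for one target, with the target standardization
    constants and the training wavelength grid baked in."""

    target: Target
    config: RegressionConfig
    svr: SVR
    y_mean: float
    y_scale: float
    wavelengths: np.ndarray
    format_version: int = 1

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(spectra, dtype=float))
        return self.svr.predict(x) * self.y_scale + self.y_mean


@dataclass
class CrossValidationReport:
    """Held-out predictions (one per sample) and the cross-validated R²."""

    target: Target
    sample_ids: list[str]
    measured: np.ndarray
    predicted: np.ndarray
    r2: float | None  # None when the measured variance is zero

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "target": self.target,
                "measured": self.measured,
                "predicted": self.predicted,
            }
        )

    def group_means(self, groups: Sequence[str]) -> pd.DataFrame:
        df = self.to_frame()
        df["group"] = list(groups)
        return df.groupby("group")[["measured", "predicted"]].mean()


def fit(
    train: CalibrationSet,
    target: Target,
    config: RegressionConfig = RegressionConfig(),
) -> RegressionModel:
    """Fit one SVR for one target on per-sample SNV spectra.

    Features enter as-is (SNV already standardizes each spectrum);
    targets are standardized internally.  Degenerate feature sets
    (all-identical spectra with varying targets) are rejected.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 samples to fit")
    y = train.target_values(target)
    if np.ptp(train.features, axis=0).max() == 0 and np.ptp(y) > 0:
        raise ValueError("degenerate features: all spectra identical")
    y_mean = float(y.mean())
    y_scale = float(y.std(ddof=0))
    if y_scale == 0:
        y_scale = 1.0  # constant target: SVR sees zeros, predicts ~constant
    gamma = config.resolve_gamma(train.features)
    svr = SVR(
        kernel=config.kernel, C=config.C, epsilon=config.epsilon,
        gamma=gamma, tol=config.tol,
    )
    svr.fit(train.features, (y - y_mean) / y_scale)
    return RegressionModel(
        target=target,
        config=config,
        svr=svr,
        y_mean=y_mean,
        y_scale=y_scale,
        wavelengths=np.asarray(train.wavelengths, float),
    )


def loocv(
    cal: CalibrationSet,
    target: Target,
    config: RegressionConfig = RegressionConfig(),
) -> CrossValidationReport:
    """Leave-one-out cross-validation: each sample is predicted by a model
    fitted on the remaining n-1.  R² is None when the measured values
    carry no variance (degenerate, reported rather than divided by zero)."""
    n = len(cal)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    measured = cal.target_values(target)
    predicted = np.empty(n)
    for i in range(n):
        keep = np.array([j for j in range(n) if j != i])
        try:
            model = fit(cal.subset(keep), target, config)
        except ValueError as err:
            raise ValueError(f"LOOCV fold {i} ({cal.sample_ids[i]}): {err}") from err
        predicted[i] = model.predict(cal.features[i][None, :])[0]
    r2 = None
    if np.ptp(measured) > 0:
        r2 = r_squared(measured, predicted)
    return CrossValidationReport(
        target=target,
        sample_ids=list(cal.sample_ids),
        measured=measured,
        predicted=predicted,
        r2=r2,
    )


def r_squared(measured: np.ndarray, predicted: np.ndarray) -> float:
    """Cross-validation R²: 1 - SS_res / SS_tot, with SS_res the squared
    prediction residuals and SS_tot about the mean measured value."""
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("measured and predicted must be equal-length vectors")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero variance in measured values: R² undefined")
    ss_res = float(((yhat - y) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def predict_pixels(model: RegressionModel, cube: ReflectanceCube) -> np.ndarray:
    """Apply a fitted model to every masked-in pixel of a processed cube.

    ``cube`` must hold SNV spectra on the model's training wavelength
    grid.  Returns a (y, x) raster with NaN outside the mask.
    """
    if cube.shape[2] != model.wavelengths.size or not np.allclose(
        cube.wavelengths, model.wavelengths
    ):
        raise ValueError(
            "cube wavelength grid does not match the training grid "
            "(incompatible instrument or preprocessing config)"
        )
    raster = np.full(cube.shape[:2], np.nan)
    if cube.mask.any():
        raster[cube.mask] = model.predict(cube.values[cube.mask])
    return raster
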