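"""Process-specific mutational topography.

Each latent process k carries a topography over (bin, mutation type):

    p(b, m | z=k) ∝ t_bm · exp( f_k(X_b) + g_km(X_b) )

where t_bm is context availability, f_k a macro-scale log-rate function of
broad genomic features (boosted trees, linear, or constant), and g_km a
spectra effect combining a baseline log-spectrum with sparse L1-penalized
adjustments from meso-scale features plus a tiered strand term: one
lightly-penalized strand coefficient uniform across types and per-type
deviations under a heavy L1 penalty, favoring uniform strand asymmetries
over type-specific ones.  Normalization runs over all bins and types.
Availability-zero cells carry probability exactly 0.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.linear_model import PoissonRegressor

from . import contexts
from .binning import FeatureMatrix

MACRO_FLAVORS = ("boosted_trees", "linear", "constant")

SCHEMA_VERSION = 1


@dataclass
class TreeParams:
    max_depth: int = 3
    max_iter: int = 100
    learning_rate: float = 0.1
    min_samples_leaf: int = 4

    def build(self) -> HistGradientBoostingRegressor:
        return HistGradientBoostingRegressor(
            loss="poisson", max_depth=self.max_depth, max_iter=self.max_iter,
            learning_rate=self.learning_rate,
            min_samples_leaf=self.min_samples_leaf, early_stopping=False)


@dataclass
class MacroEffect:
    """Macro-scale log-rate function f_k over declared macro features."""

    flavor: str
    feature_names: list[str]
    model: object | None = None  # HGBT regressor or (coef, intercept)

    def __post_init__(self):
        if self.flavor not in MACRO_FLAVORS:
            raise ValueError(f"unknown macro flavor {self.flavor!r}")

    def log_rate(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            Xm = X.subset(self.feature_names)
        else:
            Xm = np.asarray(X)
        if self.flavor == "constant" or self.model is None:
            return np.zeros(Xm.shape[0])
        if self.flavor == "boosted_trees":
            return np.log(np.clip(self.model.predict(Xm), 1e-300, None))
        coef, intercept = self.model
        return Xm @ coef + intercept

    def fit(self, X: np.ndarray, target_rate: np.ndarray,
            exposure: np.ndarray, tree_params: TreeParams) -> None:
        """Poisson fit of counts = target_rate*exposure with offset exposure."""
        if self.flavor == "constant":
            return
        w = np.clip(exposure, 1e-12, None)
        y = np.clip(target_rate, 0.0, None)
        if self.flavor == "boosted_trees":
            reg = tree_params.build()
            reg.fit(X, y, sample_weight=w)
            self.model = reg
        else:
            # weakly-informative ridge stabilizes slopes fit to noisy
            # per-process responsibility counts
            reg = PoissonRegressor(alpha=1e-2, max_iter=300)
            reg.fit(X, y, sample_weight=w)
            self.model = (reg.coef_.copy(), float(reg.intercept_))


@dataclass
class SpectraEffect:
    """Baseline log-spectrum + sparse feature-driven adjustments g_km."""

    baseline: np.ndarray  # (192,)
    meso_features: list[str] = field(default_factory=list)
    strand_features: list[str] = field(default_factory=list)
    meso_coef: np.ndarray | None = None      # (n_meso, 192), L1-sparse
    strand_uniform: np.ndarray | None = None  # (n_strand,)
    strand_dev: np.ndarray | None = None      # (n_strand, 192), heavy L1
    l1_meso: float = 1.0
    l1_strand_uniform: float = 0.01
    l1_strand_dev: float = 10.0

    def __post_init__(self):
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.baseline.shape != (contexts.N_TYPES,):
            raise ValueError("baseline must be a 192-vector")
        nm, ns = len(self.meso_features), len(self.strand_features)
        if self.meso_coef is None:
            self.meso_coef = np.zeros((nm, contexts.N_TYPES))
        if self.strand_uniform is None:
            self.strand_uniform = np.zeros(ns)
        if self.strand_dev is None:
            self.strand_dev = np.zeros((ns, contexts.N_TYPES))

    def log_adjustment(self, X: FeatureMatrix) -> np.ndarray:
        """(N_bins, 192) array of baseline + feature-driven log adjustments."""
        n = X.values.shape[0]
        out = np.tile(self.baseline, (n, 1))
        if self.meso_features:
            out += X.subset(self.meso_features) @ self.meso_coef
        if self.strand_features:
            Xs = X.subset(self.strand_features)
            sign = contexts.ORIENTATION_SIGN
            eff = self.strand_uniform[:, None] + self.strand_dev  # (ns,192)
            out += (Xs @ eff) * sign[None, :]
        return out


@dataclass
class ProcessTopography:
    macro: MacroEffect
    spectra: SpectraEffect
    label: str = ""


@dataclass
class ModelState:
    """A fitted (or reference) topography model over K processes."""

    processes: list[ProcessTopography]
    dirichlet_alpha: np.ndarray
    macro_features: list[str]
    meso_features: list[str] = field(default_factory=list)
    strand_features: list[str] = field(default_factory=list)
    binning_hash: str | None = None
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self):
        self.dirichlet_alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if len(self.processes) < 1:
            raise ValueError("need at least one process")
        if np.any(self.dirichlet_alpha <= 0):
            raise ValueError("Dirichlet alpha must be positive")

    @property
    def K(self) -> int:
        return len(self.processes)

    def log_topographies(self, X: FeatureMatrix, t: np.ndarray) -> np.ndarray:
        """(K, N_bins, 192) normalized log-probabilities."""
        return np.stack([
            topography_log_distribution(p, X, t) for p in self.processes])

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"schema_version": self.schema_version, "model": self},
                        fh)

    @classmethod
    def load(cls, path) -> "ModelState":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        return payload["model"]


def topography_logits(process: ProcessTopography, X: FeatureMatrix,
                      t: np.ndarray) -> np.ndarray:
    """Unnormalized log weights log t_bm + f_k(X_b) + g_km(X_b).

    Cells with zero availability are exactly -inf.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("availability must be nonnegative")
    with np.errstate(divide="ignore"):
        logits = np.where(t > 0, np.log(np.where(t > 0, t, 1.0)), -np.inf)
    logits = logits + process.macro.log_rate(X)[:, None]
    logits = logits + process.spectra.log_adjustment(X)
    return np.where(t > 0, logits, -np.inf)


def topography_log_distribution(process: ProcessTopography, X: FeatureMatrix,
                                t: np.ndarray) -> np.ndarray:
    """Normalized log p(b, m | z=k) over all bins and types."""
    logits = topography_logits(process, X, t)
    norm = logsumexp(logits)
    if not np.isfinite(norm):
        raise ValueError("all availability is zero; topography undefined")
    return logits - norm


def topography_distribution(process: ProcessTopography, X: FeatureMatrix,
                            t: np.ndarray) -> np.ndarray:
    """Probability table over (bin, type); sums to 1."""
    return np.exp(topography_log_distribution(process, X, t))


def marginal_spectrum(process: ProcessTopography, X: FeatureMatrix,
                      t: np.ndarray) -> np.ndarray:
    """p(m | z=k): 192-vector marginal over bins."""
    return topography_distribution(process, X, t).sum(axis=0)


def marginal_genomic(process: ProcessTopography, X: FeatureMatrix,
                     t: np.ndarray) -> np.ndarray:
    """p(b | z=k): per-bin marginal over mutation types."""
    return topography_distribution(process, X, t).sum(axis=1)


collapse_to_96 = contexts.collapse_to_96
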