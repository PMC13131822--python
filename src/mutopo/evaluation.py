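"""Goodness-of-fit metrics, ablated model variants, and NNLS validation.

The headline metric is a multinomial pseudo-R2 on held-out chromosomes: a
model's per-sample log score S = sum Y log p_hat(b,m|n) is normalized
between an availability-proportional null (score 0) and the empirical
saturated model (score 1).  A Poisson deviance pseudo-R2 plays the role of
correlation when comparing rate profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import contexts
from .binning import FeatureMatrix, GenomeBinning
from .ingest import WeightedCountTensor
from .inference import FitConfig, VariationalState, fit
from .model import ModelState, topography_distribution
from .outputs import process_contributions


@dataclass
class PseudoR2Report:
    score: float
    null_score: float
    saturated_score: float
    pseudo_r2: float


def pseudo_r2(Y_heldout: WeightedCountTensor,
              predictions: np.ndarray,
              availability: np.ndarray) -> PseudoR2Report:
    """Multinomial pseudo-R2 of per-sample predictions on held-out counts.

    ``predictions``: (N_samples, N_bins, 192) per-sample probabilities over
    the held-out (bin, type) cells; rows are normalized here.  Cells with
    Y = 0 contribute nothing to any score.
    """
    Y = Y_heldout
    pred = np.asarray(predictions, dtype=float)
    norm = pred.reshape(Y.n_samples, -1).sum(axis=1)
    if np.any(norm <= 0):
        raise ValueError("each sample's prediction must have positive mass")
    pred = pred / norm[:, None, None]

    t = np.asarray(availability, dtype=float)
    p0 = t / t.sum()

    with np.errstate(divide="ignore"):
        s = float(np.sum(Y.weight * np.log(
            pred[Y.sample_idx, Y.bin_idx, Y.type_idx])))
        s0 = float(np.sum(Y.weight * np.log(p0[Y.bin_idx, Y.type_idx])))

    burdens = Y.burdens()
    with np.errstate(divide="ignore"):
        s1 = float(np.sum(Y.weight * np.log(
            Y.weight / burdens[Y.sample_idx])))
    if np.isclose(s1, s0):
        raise ValueError("degenerate held-out data: saturated equals null")
    return PseudoR2Report(s, s0, s1, 1.0 - (s1 - s) / (s1 - s0))


def poisson_pseudo_r2(observed: np.ndarray, predicted: np.ndarray,
                      tol: float = 1e-12) -> float:
    """Deviance-based pseudo-R2 between nonnegative rate profiles.

    The prediction is rescaled to the observed mass; the null is uniform at
    the same mass; the saturated model is the observation itself.  Equals 1
    at exact (proportional) match.
    """
    y = np.asarray(observed, dtype=float)
    mu = np.asarray(predicted, dtype=float)
    if y.shape != mu.shape or y.ndim != 1:
        raise ValueError("profiles must be equal-length vectors")
    if np.any(y < 0) or np.any(mu < 0):
        raise ValueError("profiles must be nonnegative")
    total = y.sum()
    if total <= 0:
        raise ValueError("observed profile has zero mass")
    if mu.sum() <= 0:
        raise ValueError("predicted profile has zero mass")
    mu = mu * (total / mu.sum())
    null = np.full_like(y, total / y.size)

    def deviance(m):
        m = np.clip(m, 1e-300, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / m), 0.0)
        return 2.0 * float(np.sum(term - y + m))

    d_model, d_null = deviance(mu), deviance(null)
    if d_null <= tol:
        return 1.0 if d_model <= tol else -np.inf
    return 1.0 - d_model / d_null


def heldout_predictions(model: ModelState, exposures: np.ndarray,
                        X: FeatureMatrix, t: np.ndarray,
                        mask: np.ndarray) -> np.ndarray:
    """Per-sample topography restricted to masked bins, renormalized."""
    tables = np.stack([topography_distribution(p, X, t)[mask]
                       for p in model.processes])
    pred = np.tensordot(exposures, tables, axes=(1, 0))
    return pred


def heldout_pseudo_r2(model: ModelState, state: VariationalState,
                      Y: WeightedCountTensor, binning: GenomeBinning,
                      heldout_chrom: str) -> PseudoR2Report:
    """Pseudo-R2 of a trained model on one held-out chromosome.

    Exposures come from the training-time variational state (fit on
    non-held-out bins); predictions are the exposure-weighted topographies
    evaluated on the held-out bins.
    """
    mask = binning.bins_on_chroms([heldout_chrom])
    X, t = binning.feature_matrix, binning.availability.counts
    Y_held = Y.subset_bins(mask, renumber=True)
    pi = process_contributions(state)
    pred = heldout_predictions(model, pi, X, t, mask)
    return pseudo_r2(Y_held, pred, t[mask])


ABLATION_VARIANTS = ("full", "linear", "lda", "locus_only")


def _variant_config(base: FitConfig, variant: str) -> FitConfig:
    if variant == "full":
        return base
    if variant == "linear":
        return replace(base, macro_flavor="linear")
    if variant == "lda":
        return replace(base, macro_flavor="constant",
                       spectra_adjustments=False)
    if variant == "locus_only":
        return replace(base, K=1, spectra_adjustments=False)
    raise ValueError(f"unknown ablation variant {variant!r}")


def ablation_suite(Y: WeightedCountTensor, binning: GenomeBinning,
                   base_config: FitConfig, heldout_chrom: str,
                   variants: Sequence[str] = ABLATION_VARIANTS
                   ) -> pd.DataFrame:
    """Train each ablated variant on identical folds/seeds; score held out.

    Variants: ``full`` (boosted trees), ``linear`` (linear macro effects),
    ``lda`` (constant macro effects, baseline spectra only — LDA up to the
    availability factor), ``locus_only`` (K = 1 tree regression).
    """
    train_mask = ~binning.bins_on_chroms([heldout_chrom])
    rows = []
    for variant in variants:
        cfg = _variant_config(base_config, variant)
        model, state = fit(Y, binning, cfg, bin_mask=train_mask)
        report = heldout_pseudo_r2(model, state, Y, binning, heldout_chrom)
        rows.append({"variant": variant, "K": cfg.K,
                     "pseudo_r2": report.pseudo_r2, "score": report.score,
                     "seed": cfg.seed})
    return pd.DataFrame(rows)


def quantile_groups(values: np.ndarray, lengths: np.ndarray,
                    n_groups: int = 8) -> np.ndarray:
    """Assign bins to ~equal-base-pair groups by a feature's quantiles."""
    order = np.argsort(values, kind="mergesort")
    cum = np.cumsum(lengths[order])
    frac = (cum - lengths[order] / 2) / cum[-1]
    group_of_sorted = np.minimum((frac * n_groups).astype(int), n_groups - 1)
    groups = np.empty(len(values), dtype=int)
    groups[order] = group_of_sorted
    return groups


def nnls_validation(model: ModelState, state: VariationalState,
                    Y: WeightedCountTensor, X: FeatureMatrix,
                    t: np.ndarray, groups: np.ndarray,
                    collapse: bool = False) -> pd.DataFrame:
    """Compare model group contributions with NNLS on pooled group spectra.

    For each bin group G the model contribution of process k is
    p(z=k | G) ∝ sum_{b in G} p(b|k) * sum_n p(n) pi_nk; the NNLS estimate
    decomposes the group's pooled observed spectrum over the model's
    marginal spectra.  Both vectors live on the simplex.
    """
    K = model.K
    tables = np.stack([topography_distribution(p, X, t)
                       for p in model.processes])
    genomic = tables.sum(axis=2)  # (K, N_bins)
    spectra = tables.sum(axis=1)  # (K, 192)
    p_n = Y.burdens()
    p_n = p_n / p_n.sum()
    pi = process_contributions(state)
    cohort_k = p_n @ pi  # (K,)

    basis = spectra.T  # (192, K)
    if collapse:
        basis = contexts.collapse_to_96(spectra).T

    rows = []
    for g in np.unique(groups):
        in_g = groups == g
        contrib = np.array([genomic[k, in_g].sum() * cohort_k[k]
                            for k in range(K)])
        contrib = contrib / contrib.sum()
        pooled = np.zeros(contexts.N_TYPES)
        sel = in_g[Y.bin_idx]
        np.add.at(pooled, Y.type_idx[sel], Y.weight[sel])
        row = {"group": int(g), "n_mutations": float(pooled.sum())}
        if pooled.sum() <= 0:
            row.update({"nnls_ok": False})
            for k in range(K):
                row[f"model_{k}"] = contrib[k]
                row[f"nnls_{k}"] = np.nan
            rows.append(row)
            continue
        target = contexts.collapse_to_96(pooled) if collapse else pooled
        coef, _ = nnls(basis, target)
        total = coef.sum()
        coef = coef / total if total > 0 else np.full(K, 1.0 / K)
        row.update({"nnls_ok": True})
        for k in range(K):
            row[f"model_{k}"] = contrib[k]
            row[f"nnls_{k}"] = coef[k]
        rows.append(row)
    return pd.DataFrame(rows)
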