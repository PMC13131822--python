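"""Mean-field variational inference for the topography mixture.

The variational family factorizes as q(pi, z | beta, phi) =
prod_n q(pi_n | beta_n) prod_cells q(z | phi), with Dirichlet exposure
posteriors and per-cell assignment posteriors, exactly as in LDA.  Fitting
alternates a variational E-step (phi, beta updates using the digamma
identity for E[log pi]) with an M-step that refits each process's macro
rate function and spectra effects by responsibility-weighted Poisson
regression and updates the Dirichlet prior by Minka's fixed point.

Weighted counts are real-valued: every multinomial expression treats Y as
fractional log-likelihood weights.  Each M-step process update is guarded —
reverted when its ELBO contribution would decrease — so full-batch
coordinate ascent is monotone up to floating-point noise.
"""

from __future__ import annotations

import copy
import logging
import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from . import contexts
from .binning import GenomeBinning
from .ingest import WeightedCountTensor
from .model import (MacroEffect, ModelState, ProcessTopography, SpectraEffect,
                    TreeParams, topography_log_distribution)

logger = logging.getLogger(__name__)

SPECTRUM_PSEUDOCOUNT = 1e-2  # pseudo-mutations per type in baseline refits
ALPHA_FLOOR = 1e-3


@dataclass
class VariationalState:
    beta: np.ndarray  # (N_samples, K) Dirichlet posterior parameters
    phi: np.ndarray   # (C, K) assignment posteriors for nonzero cells
    elbo_trace: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def K(self) -> int:
        return self.beta.shape[1]


@dataclass
class FitConfig:
    K: int = 2
    seed: int = 0
    max_epochs: int = 200
    tol: float = 1e-6
    tol_window: int = 10
    batch_fraction: float = 1.0
    m_step_every: int = 1
    macro_flavor: str = "boosted_trees"
    spectra_adjustments: bool = False
    spectra_sweeps: int = 3
    l1_meso: float = 1.0
    l1_strand_uniform: float = 0.01
    l1_strand_dev: float = 10.0
    tree_params: TreeParams = field(default_factory=TreeParams)
    init_spectra: np.ndarray | None = None  # (K, 192) seeding spectra
    guard_m_step: bool = True
    e_step_iters: int = 30
    e_step_tol: float = 1e-8
    macro_features: list[str] | None = None
    meso_features: list[str] | None = None
    strand_features: list[str] | None = None


def expected_log_pi(beta: np.ndarray) -> np.ndarray:
    """E_q[log pi] under Dirichlet(beta): digamma identity."""
    return digamma(beta) - digamma(beta.sum(axis=1, keepdims=True))


def cell_log_topographies(model: ModelState, Y: WeightedCountTensor,
                          X, t) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (K, N_bins, 192) log table and its (C, K) cell gather."""
    logP = model.log_topographies(X, t)
    cells = logP[:, Y.bin_idx, Y.type_idx].T
    if np.any(np.isneginf(cells)):
        bad = int(np.where(np.isneginf(cells).any(axis=1))[0][0])
        raise FloatingPointError(
            f"observed cell (sample={Y.sample_ids[Y.sample_idx[bad]]}, "
            f"bin={Y.bin_idx[bad]}, type={Y.type_idx[bad]}) has zero "
            "probability under the model (zero availability?)")
    return logP, cells


def e_step(Y: WeightedCountTensor, alpha: np.ndarray, cell_logp: np.ndarray,
           state: VariationalState | None = None, max_iters: int = 30,
           tol: float = 1e-8) -> VariationalState:
    """Coordinate-ascent updates of phi and beta to a fixed point.

    phi ∝ exp(E[log pi]) * p(b,m|k); beta = alpha + sum of weighted
    responsibilities.  Iterating to the fixed point makes a repeated call a
    no-op.
    """
    K = alpha.shape[0]
    if state is None:
        beta = np.tile(alpha, (Y.n_samples, 1)) + Y.burdens()[:, None] / K
    else:
        beta = state.beta.copy()
    phi = None
    for _ in range(max_iters):
        logits = expected_log_pi(beta)[Y.sample_idx] + cell_logp
        logits -= logsumexp(logits, axis=1, keepdims=True)
        phi = np.exp(logits)
        new_beta = np.tile(alpha, (Y.n_samples, 1))
        np.add.at(new_beta, Y.sample_idx, Y.weight[:, None] * phi)
        if not np.all(np.isfinite(new_beta)):
            raise FloatingPointError("non-finite beta in E-step")
        delta = np.abs(new_beta - beta).max()
        beta = new_beta
        if delta < tol:
            break
    trace = state.elbo_trace if state is not None else []
    return VariationalState(beta, phi, trace)


def elbo(Y: WeightedCountTensor, alpha: np.ndarray, cell_logp: np.ndarray,
         state: VariationalState) -> float:
    """Mean-field evidence lower bound (Y acting as fractional counts)."""
    beta, phi = state.beta, state.phi
    el = expected_log_pi(beta)
    n = Y.n_samples
    prior = n * (gammaln(alpha.sum()) - gammaln(alpha).sum()) \
        + ((alpha - 1.0) * el.sum(axis=0)).sum()
    with np.errstate(invalid="ignore"):
        assign = phi * (el[Y.sample_idx] + cell_logp)
    data = float(np.sum(Y.weight[:, None] * np.where(phi > 0, assign, 0.0)))
    # E[log q(pi)]
    q_pi = float(np.sum(gammaln(beta.sum(axis=1)) - gammaln(beta).sum(axis=1)
                        + ((beta - 1.0) * el).sum(axis=1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(phi > 0, phi * np.log(phi), 0.0)
    q_z = float(np.sum(Y.weight[:, None] * plogp))
    return prior + data - q_pi - q_z


def _responsibility_counts(Y: WeightedCountTensor, phi: np.ndarray, k: int,
                           n_bins: int) -> np.ndarray:
    """(N_bins, 192) responsibility-weighted counts for process k."""
    counts = np.zeros((n_bins, contexts.N_TYPES))
    np.add.at(counts, (Y.bin_idx, Y.type_idx), Y.weight * phi[:, k])
    return counts


def _refit_baseline(spectra: SpectraEffect, counts: np.ndarray, t: np.ndarray,
                    f: np.ndarray, X) -> None:
    """Closed-form Poisson-MLE baseline given f and current adjustments."""
    adj = spectra.log_adjustment(X) - spectra.baseline[None, :]
    denom = np.sum(t * np.exp(f[:, None] + adj), axis=0)
    num = counts.sum(axis=0) + SPECTRUM_PSEUDOCOUNT
    denom = np.clip(denom, 1e-300, None)
    spectra.baseline = np.log(num / denom)


def _fit_adjustments(spectra: SpectraEffect, counts: np.ndarray,
                     t: np.ndarray, f: np.ndarray, X,
                     sweeps: int) -> None:
    """Coordinate-wise proximal Newton on the L1 Poisson objective."""
    sign = contexts.ORIENTATION_SIGN
    Xm = X.subset(spectra.meso_features) if spectra.meso_features else None
    Xs = X.subset(spectra.strand_features) if spectra.strand_features else None
    for _ in range(sweeps):
        mu = t * np.exp(f[:, None] + spectra.log_adjustment(X))
        if Xm is not None:
            for j in range(Xm.shape[1]):
                xj = Xm[:, j]
                g = xj @ (mu - counts)
                H = (xj ** 2) @ mu + 1e-12
                w = spectra.meso_coef[j]
                new = np.sign(w * H - g) * np.maximum(
                    np.abs(w * H - g) - spectra.l1_meso, 0.0) / H
                delta = new - w
                if np.any(delta):
                    mu *= np.exp(np.outer(xj, delta))
                    spectra.meso_coef[j] = new
        if Xs is not None:
            for j in range(Xs.shape[1]):
                s = np.outer(Xs[:, j], sign)  # (N, 192) signed covariate
                # uniform-across-types coefficient, light penalty
                g = float(np.sum(s * (mu - counts)))
                H = float(np.sum(s ** 2 * mu)) + 1e-12
                w = spectra.strand_uniform[j]
                new = np.sign(w * H - g) * max(
                    abs(w * H - g) - spectra.l1_strand_uniform, 0.0) / H
                if new != w:
                    mu *= np.exp(s * (new - w))
                    spectra.strand_uniform[j] = new
                # per-type deviations, heavy penalty
                g = np.sum(s * (mu - counts), axis=0)
                H = np.sum(s ** 2 * mu, axis=0) + 1e-12
                w = spectra.strand_dev[j]
                new = np.sign(w * H - g) * np.maximum(
                    np.abs(w * H - g) - spectra.l1_strand_dev, 0.0) / H
                delta = new - w
                if np.any(delta):
                    mu *= np.exp(s * delta[None, :])
                    spectra.strand_dev[j] = new


def _data_term(counts: np.ndarray, logP_k: np.ndarray) -> float:
    with np.errstate(invalid="ignore"):
        vals = np.where(counts > 0, counts * logP_k, 0.0)
    return float(np.sum(vals))


def _invert_digamma(y: np.ndarray, iters: int = 5) -> np.ndarray:
    with np.errstate(divide="ignore"):
        x = np.where(y >= -2.22, np.exp(y) + 0.5,
                     -1.0 / np.where(y < -2.22, y - digamma(1.0), -1.0))
    for _ in range(iters):
        x = x - (digamma(x) - y) / _trigamma(x)
    return x


def _trigamma(x: np.ndarray) -> np.ndarray:
    from scipy.special import polygamma
    return polygamma(1, x)


def update_alpha(alpha: np.ndarray, beta: np.ndarray, iters: int = 20
                 ) -> np.ndarray:
    """Minka fixed-point MLE of the Dirichlet prior from E_q[log pi]."""
    s = expected_log_pi(beta).mean(axis=0)
    a = alpha.copy()
    for _ in range(iters):
        a_new = _invert_digamma(digamma(a.sum()) + s)
        a_new = np.clip(a_new, ALPHA_FLOOR, None)
        if np.allclose(a_new, a, rtol=1e-10, atol=1e-12):
            a = a_new
            break
        a = a_new
    return a


def _alpha_elbo_term(alpha: np.ndarray, beta: np.ndarray) -> float:
    el = expected_log_pi(beta)
    n = beta.shape[0]
    return float(n * (gammaln(alpha.sum()) - gammaln(alpha).sum())
                 + ((alpha - 1.0) * el.sum(axis=0)).sum())


def m_step(Y: WeightedCountTensor, state: VariationalState,
           model: ModelState, X, t: np.ndarray, config: FitConfig,
           bin_mask: np.ndarray | None = None,
           logP: np.ndarray | None = None) -> ModelState:
    """Refit process topographies and the Dirichlet prior.

    With ``bin_mask`` set (stochastic variant) regressions use only the
    sampled bins; sufficient statistics on a uniformly sampled subset are
    unbiased for the full-genome objective up to the shared 1/rho scale,
    which cancels inside each regression.  Guarding applies only full-batch.
    """
    n_bins = t.shape[0]
    full_batch = bin_mask is None or bool(np.all(bin_mask))
    rows = np.arange(n_bins) if full_batch else np.where(bin_mask)[0]
    guard = config.guard_m_step and full_batch and logP is not None
    for k, proc in enumerate(model.processes):
        counts = _responsibility_counts(Y, state.phi, k, n_bins)
        mass = counts.sum()
        if mass <= 1e-12:
            logger.warning("process %d has no attributed mass; frozen", k)
            continue
        old_proc = copy.deepcopy(proc) if guard else None
        adj = proc.spectra.log_adjustment(X) - proc.spectra.baseline[None, :]
        f_cur = proc.macro.log_rate(X)
        if proc.macro.flavor != "constant":
            spec_w = np.exp(proc.spectra.baseline)
            exposure = np.sum(t * np.exp(adj) * spec_w[None, :], axis=1)
            c_kb = counts.sum(axis=1)
            Xmac = X.subset(model.macro_features)
            with np.errstate(divide="ignore", invalid="ignore"):
                target = np.where(exposure[rows] > 0,
                                  c_kb[rows] / np.clip(exposure[rows], 1e-300, None),
                                  0.0)
            proc.macro.fit(Xmac[rows], target, exposure[rows],
                           config.tree_params)
        f_new = proc.macro.log_rate(X)
        if config.spectra_adjustments and (
                proc.spectra.meso_features or proc.spectra.strand_features):
            _refit_baseline(proc.spectra, counts[rows], t[rows], f_new[rows],
                            _row_view(X, rows))
            _fit_adjustments(proc.spectra, counts[rows], t[rows], f_new[rows],
                             _row_view(X, rows), config.spectra_sweeps)
        _refit_baseline(proc.spectra, counts[rows], t[rows], f_new[rows],
                        _row_view(X, rows))
        if guard:
            old_term = _data_term(counts, logP[k])
            new_logP = topography_log_distribution(proc, X, t)
            if _data_term(counts, new_logP) < old_term - 1e-9:
                model.processes[k] = old_proc
    new_alpha = update_alpha(model.dirichlet_alpha, state.beta)
    if (not guard) or (_alpha_elbo_term(new_alpha, state.beta)
                       >= _alpha_elbo_term(model.dirichlet_alpha, state.beta)
                       - 1e-9):
        model.dirichlet_alpha = new_alpha
    return model


def _row_view(X, rows):
    from .binning import FeatureMatrix
    return FeatureMatrix(X.values[rows], X.feature_names, X.feature_classes)


def _initial_model(Y: WeightedCountTensor, binning: GenomeBinning,
                   config: FitConfig, rng: np.random.Generator) -> ModelState:
    fm = binning.feature_matrix
    macro = config.macro_features if config.macro_features is not None else [
        n for n, c in zip(fm.feature_names, fm.feature_classes) if c == "macro"]
    meso = config.meso_features if config.meso_features is not None else [
        n for n, c in zip(fm.feature_names, fm.feature_classes) if c == "meso"]
    strand = config.strand_features if config.strand_features is not None else [
        n for n, c in zip(fm.feature_names, fm.feature_classes) if c == "strand"]
    if not config.spectra_adjustments:
        meso_eff, strand_eff = [], []
    else:
        meso_eff, strand_eff = list(meso), list(strand)
    empirical = np.full(contexts.N_TYPES, SPECTRUM_PSEUDOCOUNT)
    np.add.at(empirical, Y.type_idx, Y.weight)
    empirical /= empirical.sum()
    processes = []
    for k in range(config.K):
        if config.init_spectra is not None:
            base = np.log(np.clip(config.init_spectra[k], 1e-12, None))
        else:
            # perturbed empirical spectrum breaks symmetry between processes
            base = np.log(empirical) + rng.gamma(5.0, 0.2,
                                                 contexts.N_TYPES) - 1.0
        spectra = SpectraEffect(
            baseline=base, meso_features=meso_eff, strand_features=strand_eff,
            l1_meso=config.l1_meso,
            l1_strand_uniform=config.l1_strand_uniform,
            l1_strand_dev=config.l1_strand_dev)
        macro_eff = MacroEffect(config.macro_flavor, list(macro))
        processes.append(ProcessTopography(macro_eff, spectra, label=f"P{k}"))
    return ModelState(processes, np.ones(config.K), list(macro), list(meso),
                      list(strand), binning_hash=None)


def fit(Y: WeightedCountTensor, binning: GenomeBinning, config: FitConfig,
        bin_mask: np.ndarray | None = None
        ) -> tuple[ModelState, VariationalState]:
    """Fit the model by (stochastic) variational EM.

    ``bin_mask`` restricts training to a subset of bins (held-out
    evaluation); the topography normalization then runs over those bins.
    With ``batch_fraction`` 1.0 this is exactly full coordinate ascent.
    All randomness (initialization, bin subsampling) flows from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    X, t = binning.feature_matrix, binning.availability.counts
    if bin_mask is not None:
        Y = Y.subset_bins(bin_mask, renumber=True)
        X = _row_view(X, np.where(bin_mask)[0])
        t = t[bin_mask]
    model = _initial_model(Y, binning, config, rng)
    model.binning_hash = None  # set by callers that persist the model
    state: VariationalState | None = None
    elbo_trace: list[float] = []
    n_bins = t.shape[0]
    start = time.time()
    converged = False
    for epoch in range(config.max_epochs):
        logP, cell_logp = cell_log_topographies(model, Y, X, t)
        state = e_step(Y, model.dirichlet_alpha, cell_logp, state,
                       config.e_step_iters, config.e_step_tol)
        if epoch % config.m_step_every == 0:
            if config.batch_fraction < 1.0:
                m = max(1, int(round(config.batch_fraction * n_bins)))
                sub = np.zeros(n_bins, dtype=bool)
                sub[rng.choice(n_bins, size=m, replace=False)] = True
            else:
                sub = None
            model = m_step(Y, state, model, X, t, config, sub, logP)
        _, cell_logp = cell_log_topographies(model, Y, X, t)
        value = elbo(Y, model.dirichlet_alpha, cell_logp, state)
        elbo_trace.append(value)
        logger.info("epoch %d elbo %.6f (%.1fs)", epoch, value,
                    time.time() - start)
        w = config.tol_window
        if len(elbo_trace) > w:
            prev, cur = elbo_trace[-w - 1], elbo_trace[-1]
            if abs(cur - prev) / (abs(prev) + 1e-12) < config.tol:
                converged = True
                break
    if not converged:
        logger.warning("fit did not converge within %d epochs",
                       config.max_epochs)
    state.elbo_trace = elbo_trace
    state.converged = converged
    return model, state


def random_search(Y: WeightedCountTensor, binning: GenomeBinning,
                  search_space: dict[str, Sequence], n_trials: int,
                  seed: int, heldout_chrom: str,
                  base_config: FitConfig | None = None):
    """Seeded random hyperparameter search scored by held-out pseudo-R2.

    ``search_space`` maps FitConfig field names to candidate value lists.
    Returns a (scores DataFrame, best FitConfig) pair; deterministic given
    ``seed``.
    """
    import pandas as pd

    from .evaluation import heldout_pseudo_r2

    if not search_space or any(len(v) == 0 for v in search_space.values()):
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    base = base_config or FitConfig()
    train_mask = ~binning.bins_on_chroms([heldout_chrom])
    rows, configs = [], []
    for trial in range(n_trials):
        choice = {k: v[rng.integers(len(v))] for k, v in search_space.items()}
        trial_seed = int(rng.integers(2 ** 31 - 1))
        cfg = replace(base, seed=trial_seed, **choice)
        model, state = fit(Y, binning, cfg, bin_mask=train_mask)
        report = heldout_pseudo_r2(model, state, Y, binning, heldout_chrom)
        rows.append({"trial": trial, "seed": trial_seed,
                     "pseudo_r2": report.pseudo_r2, **choice})
        configs.append(cfg)
    table = pd.DataFrame(rows).sort_values("pseudo_r2", ascending=False)
    best = configs[int(table.iloc[0]["trial"])]
    return table, best
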