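"""Synthetic tumor cohorts drawn from a reference topography model.

Each synthetic sample resamples an exposure vector uniformly from the
reference cohort's exposures (preserving exposure covariance), draws a
Poisson(gamma * M_n) mutation count, assigns each mutation a process from
the exposures, a (bin, type) cell from that process's topography, and a
genomic position uniformly among the bin's context-compatible sites.  VAFs
are Beta-distributed around the purity-consistent heterozygous-diploid mean
so ingestion is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import contexts
from .binning import GenomeBinning
from .model import ModelState, marginal_genomic, marginal_spectrum


@dataclass
class SimulationSpec:
    reference_model: ModelState
    reference_exposures: np.ndarray  # (N_ref, K) pool sampled uniformly
    reference_burdens: np.ndarray    # (N_ref,) mutation counts M_n
    n_samples: int = 100
    gamma: float = 1.0
    seed: int = 0
    purity_range: tuple[float, float] = (0.5, 0.95)
    vaf_concentration: float = 30.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")


class PositionSampler:
    """Uniform sampling of genomic positions by (bin, context group)."""

    def __init__(self, binning: GenomeBinning, genome: Mapping[str, str],
                 count_soft_masked: bool = True):
        group_cache: dict[str, np.ndarray] = {}
        self._index: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        for b in binning.bins:
            acc: dict[int, list[tuple[str, np.ndarray]]] = {}
            for seg in b.segments:
                if seg.chrom not in group_cache:
                    codes = contexts.encode_sequence(str(genome[seg.chrom]),
                                                     count_soft_masked)
                    group_cache[seg.chrom] = contexts.context_groups(codes)
                groups = group_cache[seg.chrom][seg.start:seg.end]
                pos = np.arange(seg.start, seg.end)
                for g in np.unique(groups[groups >= 0]):
                    acc.setdefault(int(g), []).append(
                        (seg.chrom, pos[groups == g]))
            for g, parts in acc.items():
                chroms = np.concatenate([np.full(len(p), c, dtype=object)
                                         for c, p in parts])
                positions = np.concatenate([p for _, p in parts])
                self._index[(b.bin_id, g)] = (positions, chroms)

    def sample(self, bin_id: int, type_idx: int,
               rng: np.random.Generator) -> tuple[str, int]:
        g = int(contexts.TYPE_TO_GROUP[type_idx])
        entry = self._index.get((bin_id, g))
        if entry is None:
            raise ValueError(
                f"bin {bin_id} has no sites for context group {g}")
        positions, chroms = entry
        i = rng.integers(len(positions))
        return str(chroms[i]), int(positions[i])


def simulate_cohort(spec: SimulationSpec, binning: GenomeBinning,
                    genome: Mapping[str, str],
                    sampler: PositionSampler | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort; returns (mutations, truth, sample_meta).

    ``truth`` holds per-sample ground-truth exposures and process counts;
    ``sample_meta`` holds purity per sample.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.reference_model
    X, t = binning.feature_matrix, binning.availability.counts
    K = model.K
    from .model import topography_distribution
    tables = np.stack([topography_distribution(p, X, t)
                       for p in model.processes])
    flat = tables.reshape(K, -1)
    flat_cum = np.cumsum(flat, axis=1)
    if sampler is None:
        sampler = PositionSampler(binning, genome)

    seqs = {c: str(genome[c]).upper() for c in binning.chrom_lengths}
    n_ref = spec.reference_exposures.shape[0]
    rows, truth_rows, meta_rows = [], [], []
    for s in range(spec.n_samples):
        sid = f"sim{s:04d}"
        ref_i = rng.integers(n_ref)
        pi = spec.reference_exposures[ref_i]
        m_n = rng.poisson(spec.gamma * spec.reference_burdens[ref_i])
        purity = rng.uniform(*spec.purity_range)
        meta_rows.append({"sample_id": sid, "purity": purity})
        z = rng.choice(K, size=m_n, p=pi)
        counts_k = np.bincount(z, minlength=K)
        truth_rows.append({"sample": sid, "ref_index": int(ref_i),
                           **{f"pi_{k}": pi[k] for k in range(K)},
                           **{f"count_{k}": int(counts_k[k])
                              for k in range(K)}})
        for k in range(K):
            if counts_k[k] == 0:
                continue
            u = rng.random(counts_k[k])
            cells = np.searchsorted(flat_cum[k], u * flat_cum[k, -1],
                                    side="right")
            cells = np.minimum(cells, flat.shape[1] - 1)
            for cell in cells:
                b, m = divmod(int(cell), contexts.N_TYPES)
                chrom, pos = sampler.sample(b, m, rng)
                ref = seqs[chrom][pos]
                alt = contexts.alt_base(m, ref)
                mean_vaf = purity / 2.0
                kappa = spec.vaf_concentration
                vaf = rng.beta(mean_vaf * kappa, (1 - mean_vaf) * kappa)
                rows.append({"sample": sid, "chrom": chrom, "pos": pos,
                             "ref": ref, "alt": alt,
                             "vaf": float(np.clip(vaf, 1e-4, 1.0)),
                             "process": k})
    mutations = pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref", "alt", "vaf",
                       "process"])
    return mutations, pd.DataFrame(truth_rows), pd.DataFrame(meta_rows)


def match_components(true_spectra: np.ndarray, fit_spectra: np.ndarray
                     ) -> np.ndarray:
    """Hungarian matching of fitted to true components on spectra cosine.

    Returns ``perm`` with fitted component perm[k] matched to true k.
    """
    def unit(a):
        n = np.linalg.norm(a, axis=1, keepdims=True)
        return a / np.clip(n, 1e-300, None)

    cos = unit(true_spectra) @ unit(fit_spectra).T
    r, c = linear_sum_assignment(-cos)
    perm = np.empty(true_spectra.shape[0], dtype=int)
    perm[r] = c
    return perm


def recovery_metrics(reference: ModelState, fitted: ModelState,
                     X, t) -> pd.DataFrame:
    """Matched per-component spectra cosine and genomic-profile pseudo-R2."""
    from .evaluation import poisson_pseudo_r2

    true_spec = np.stack([marginal_spectrum(p, X, t)
                          for p in reference.processes])
    fit_spec = np.stack([marginal_spectrum(p, X, t)
                         for p in fitted.processes])
    true_gen = np.stack([marginal_genomic(p, X, t)
                         for p in reference.processes])
    fit_gen = np.stack([marginal_genomic(p, X, t)
                        for p in fitted.processes])
    perm = match_components(true_spec, fit_spec)
    rows = []
    for k in range(reference.K):
        a, b = true_spec[k], fit_spec[perm[k]]
        cos = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        ppr2 = poisson_pseudo_r2(true_gen[k], fit_gen[perm[k]])
        rows.append({"component": k, "matched_to": int(perm[k]),
                     "cosine": cos, "poisson_pseudo_r2": ppr2})
    return pd.DataFrame(rows)


def recovery_benchmark(reference: ModelState, reference_exposures: np.ndarray,
                       reference_burdens: np.ndarray, binning: GenomeBinning,
                       genome: Mapping[str, str], gammas, n_samples_grid,
                       k_fit: int, replicates: int, seed: int,
                       fit_config=None) -> pd.DataFrame:
    """Simulate/fit grid over (gamma, n_samples); best replicate per cell.

    Mirrors the simulation benchmark design: per cell, ``replicates``
    models are trained and the best by training pseudo-R2 proxy (ELBO) is
    scored by matched cosine and Poisson pseudo-R2.
    """
    from .inference import FitConfig, fit as fit_model
    from .ingest import SampleMeta, build_count_tensor

    rng = np.random.default_rng(seed)
    base = fit_config or FitConfig(K=k_fit)
    rows = []
    sampler = PositionSampler(binning, genome)
    X, t = binning.feature_matrix, binning.availability.counts
    for gamma in gammas:
        for n_samples in n_samples_grid:
            sim_seed = int(rng.integers(2 ** 31 - 1))
            spec = SimulationSpec(reference, reference_exposures,
                                  reference_burdens, n_samples=n_samples,
                                  gamma=gamma, seed=sim_seed)
            muts, truth, meta = simulate_cohort(spec, binning, genome, sampler)
            samples = [SampleMeta(r.sample_id, r.purity)
                       for r in meta.itertuples()]
            Y = build_count_tensor(muts, binning, genome, samples)
            best = None
            for _ in range(replicates):
                cfg_seed = int(rng.integers(2 ** 31 - 1))
                cfg = FitConfig(**{**base.__dict__, "K": k_fit,
                                   "seed": cfg_seed})
                model, state = fit_model(Y, binning, cfg)
                score = state.elbo_trace[-1]
                if best is None or score > best[0]:
                    best = (score, model)
            metrics = recovery_metrics(reference, best[1], X, t)
            for r in metrics.itertuples():
                rows.append({"gamma": gamma, "n_samples": n_samples,
                             "n_mutations": len(muts),
                             "component": r.component, "cosine": r.cosine,
                             "poisson_pseudo_r2": r.poisson_pseudo_r2})
    return pd.DataFrame(rows)
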