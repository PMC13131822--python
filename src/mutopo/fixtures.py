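"""Seeded toy genomes, feature tracks, and reference models.

The generator emulates the full input surface — a small multi-chromosome
genome with heterogeneous GC, macro-scale continuous tracks (replication
timing, heterochromatin mark, expression), meso-scale gene bodies with
strand, and a reference topography model whose processes have distinct
spectra and planted *nonlinear* feature→rate maps (thresholds and an
interaction), so that tree-based and linear rate models are separable.
Everything is a deterministic function of one integer seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import contexts
from .binning import (ContinuousTrack, DiscreteTrack, GenomeBinning,
                      build_binning)
from .model import (MacroEffect, ModelState, ProcessTopography, SpectraEffect,
                    TreeParams)

DEFAULT_CHROM_LENGTHS = {"chr1": 450_000, "chr2": 400_000, "chr3": 350_000}
MACRO_FEATURES = ["reptime", "h3k9me3", "expression"]


def _smooth_signal(n_points: int, rng: np.random.Generator,
                   scale: float = 0.15) -> np.ndarray:
    walk = np.cumsum(rng.normal(0, scale, n_points))
    walk = (walk - walk.min()) / max(walk.max() - walk.min(), 1e-9)
    return walk


def toy_genome(seed: int = 0,
               chrom_lengths: Mapping[str, int] | None = None
               ) -> dict[str, str]:
    """Random genome with smoothly varying GC content."""
    rng = np.random.default_rng(seed)
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    genome = {}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        block = 5_000
        n_blocks = (length + block - 1) // block
        gc = 0.3 + 0.4 * _smooth_signal(n_blocks, rng)
        probs = np.repeat(gc, block)[:length]
        u = rng.random(length)
        v = rng.random(length)
        bases = np.where(u < probs,
                         np.where(v < 0.5, "C", "G"),
                         np.where(v < 0.5, "A", "T"))
        genome[chrom] = "".join(bases)
    return genome


def toy_tracks(genome: Mapping[str, str], seed: int = 0,
               genes_per_100kb: float = 2.0
               ) -> tuple[list[DiscreteTrack], list[ContinuousTrack]]:
    """Gene bodies (+strand), replication timing, heterochromatin, expression."""
    rng = np.random.default_rng(seed + 101)
    gene_ivals: dict[str, list[tuple[int, int, float]]] = {}
    strand_ivals: dict[str, list[tuple[int, int, float]]] = {}
    expr_ivals: dict[str, list[tuple[int, int, float]]] = {}
    rep_ivals: dict[str, list[tuple[int, int, float]]] = {}
    het_ivals: dict[str, list[tuple[int, int, float]]] = {}
    step = 10_000
    for chrom in sorted(genome):
        length = len(genome[chrom])
        n_genes = rng.poisson(genes_per_100kb * length / 100_000)
        starts = np.sort(rng.choice(length - 25_000, size=n_genes,
                                    replace=False)) if n_genes else []
        genes, pos = [], 0
        for s in starts:
            if s < pos:
                continue
            g_len = int(rng.integers(4_000, 20_000))
            genes.append((int(s), min(int(s) + g_len, length)))
            pos = s + g_len + 2_000
        gene_ivals[chrom] = [(s, e, 1.0) for s, e in genes]
        strand_ivals[chrom] = [(s, e, float(rng.choice([-1.0, 1.0])))
                               for s, e in genes]
        expr_ivals[chrom] = [(s, e, float(rng.gamma(2.0, 0.4)))
                             for s, e in genes]
        n_steps = (length + step - 1) // step
        rep = _smooth_signal(n_steps, rng, scale=0.3)
        het = _smooth_signal(n_steps, rng, scale=0.3)
        rep_ivals[chrom] = [(i * step, min((i + 1) * step, length), float(r))
                            for i, r in enumerate(rep)]
        het_ivals[chrom] = [(i * step, min((i + 1) * step, length), float(h))
                            for i, h in enumerate(het)]
    discrete = [
        DiscreteTrack("gene", "meso", gene_ivals),
        DiscreteTrack("gene_strand", "strand", strand_ivals),
    ]
    continuous = [
        ContinuousTrack("reptime", "macro", rep_ivals),
        ContinuousTrack("h3k9me3", "macro", het_ivals),
        ContinuousTrack("expression", "macro", expr_ivals),
    ]
    return discrete, continuous


def toy_binning(seed: int = 0,
                chrom_lengths: Mapping[str, int] | None = None,
                interval_bp: int = 10_000
                ) -> tuple[GenomeBinning, dict[str, str]]:
    genome = toy_genome(seed, chrom_lengths)
    discrete, continuous = toy_tracks(genome, seed)
    binning = build_binning(genome, discrete, continuous,
                            interval_bp=interval_bp)
    return binning, genome


def _planted_log_rates(X: np.ndarray, K: int) -> np.ndarray:
    """Planted nonlinear macro log-rate maps (thresholds + interaction)."""
    rep, het, expr = X[:, 0], X[:, 1], X[:, 2]
    # each map couples a broad monotone trend (captured by a linear model)
    # with strong non-monotone structure (bands, interactions) only a
    # nonlinear regressor can represent
    fs = [
        1.2 * rep + 1.6 * ((rep > 0.35) & (rep < 0.65)),
        -1.2 * rep + 1.8 * (rep > 0.8),
        0.8 * het + 1.8 * ((expr > 0.15) & (rep < 0.6)),
        1.2 * het + 1.5 * ((het > 0.3) & (het < 0.6)),
        1.0 * rep + 1.8 * ((rep > 0.55) ^ (het > 0.5)),
        -1.0 * het + 1.2 * ((expr > 0.3) & (rep > 0.5)),
        0.8 * rep + 1.8 * (rep > 0.7) * het,
    ]
    return np.stack([np.asarray(f, dtype=float) for f in fs[:K]])


def _distinct_spectra(K: int, rng: np.random.Generator) -> np.ndarray:
    """Spectra concentrated on distinct substitution classes."""
    spectra = np.empty((K, contexts.N_TYPES))
    for k in range(K):
        sub = k % 6
        spec = np.full(contexts.N_TYPES, 0.25 / (contexts.N_TYPES - 32))
        block = np.zeros(contexts.N_TYPES, dtype=bool)
        for orient in (0, 1):
            lo = orient * 96 + sub * 16
            block[lo:lo + 16] = True
        flank_w = rng.dirichlet(np.full(32, 5.0))
        spec[block] = 0.75 * flank_w
        spectra[k] = spec / spec.sum()
    return spectra


def toy_reference_model(binning: GenomeBinning, K: int = 4, seed: int = 0,
                        strand_effects: bool = True) -> ModelState:
    """Reference model with planted nonlinear rates and distinct spectra.

    Macro effects are boosted-tree fits of the planted maps on the binning's
    own feature matrix (so they remain evaluable on any feature matrix with
    the same names).
    """
    if K > 7:
        raise ValueError("toy reference supports at most 7 processes")
    rng = np.random.default_rng(seed + 202)
    X = binning.feature_matrix
    Xm = X.subset(MACRO_FEATURES)
    log_rates = _planted_log_rates(Xm, K)
    spectra = _distinct_spectra(K, rng)
    tree_params = TreeParams(max_depth=3, max_iter=300, learning_rate=0.2,
                             min_samples_leaf=2)
    processes = []
    for k in range(K):
        macro = MacroEffect("boosted_trees", list(MACRO_FEATURES))
        macro.fit(Xm, np.exp(log_rates[k]), np.ones(Xm.shape[0]), tree_params)
        eff = SpectraEffect(baseline=np.log(spectra[k]),
                            strand_features=(["gene_strand"]
                                             if strand_effects else []))
        if strand_effects and k % 2 == 1:
            eff.strand_uniform = np.array([0.4])
        processes.append(ProcessTopography(macro, eff, label=f"ref{k}"))
    return ModelState(processes, np.full(K, 0.8), list(MACRO_FEATURES),
                      meso_features=[],
                      strand_features=(["gene_strand"] if strand_effects
                                       else []),
                      binning_hash=binning.content_hash())


def toy_reference_cohort(K: int, seed: int = 0, n_ref: int = 200,
                         mean_burden: float = 125.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Reference exposure pool and per-sample burdens for the simulator."""
    rng = np.random.default_rng(seed + 303)
    exposures = rng.dirichlet(np.full(K, 0.8), size=n_ref)
    burdens = np.maximum(
        rng.lognormal(np.log(mean_burden) - 0.125, 0.5, size=n_ref), 5.0
    ).round().astype(int)
    burdens = (burdens * (mean_burden * n_ref / burdens.sum())).round()
    return exposures, burdens.astype(int)


def write_fixtures(outdir, seed: int = 0, n_samples: int = 50,
                   gamma: float = 1.0, k_reference: int = 4) -> dict:
    """Write a complete runnable toy dataset; returns a manifest dict.

    Emits genome FASTA, BED/bedGraph tracks, a simulated cohort (MAF-style
    TSV + purity table + truth JSON) and a pickled reference model.
    """
    from .simulate import SimulationSpec, simulate_cohort

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = toy_genome(seed)
    discrete, continuous = toy_tracks(genome, seed)
    binning = build_binning(genome, discrete, continuous)
    model = toy_reference_model(binning, K=k_reference, seed=seed)
    exposures, burdens = toy_reference_cohort(k_reference, seed)
    spec = SimulationSpec(model, exposures, burdens, n_samples=n_samples,
                          gamma=gamma, seed=seed + 404)
    mutations, truth, meta = simulate_cohort(spec, binning, genome)

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    for track in discrete:
        with open(outdir / f"{track.name}.bed", "w") as fh:
            for chrom in sorted(track.intervals):
                for s, e, v in sorted(track.intervals[chrom]):
                    if track.feature_class == "strand":
                        strand = "+" if v > 0 else "-"
                        fh.write(f"{chrom}\t{s}\t{e}\t{track.name}\t0\t{strand}\n")
                    else:
                        fh.write(f"{chrom}\t{s}\t{e}\n")
    for track in continuous:
        with open(outdir / f"{track.name}.bedgraph", "w") as fh:
            for chrom in sorted(track.intervals):
                for s, e, v in sorted(track.intervals[chrom]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
    mutations.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    meta.rename(columns={"sample_id": "sample_id"}).to_csv(
        outdir / "samples.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    model.save(outdir / "reference_model.pkl")
    manifest = {"seed": seed, "n_samples": n_samples, "gamma": gamma,
                "k_reference": k_reference, "n_mutations": len(mutations),
                "n_bins": binning.n_bins,
                "binning_hash": binning.content_hash(),
                "files": ["genome.fa", "cohort.tsv", "samples.tsv",
                          "truth.tsv", "reference_model.pkl"]}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
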