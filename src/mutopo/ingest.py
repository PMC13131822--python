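"""Sample ingestion: SNV calls -> weighted count tensor.

Each mutation receives weight VAF/purity (capped), approximating the
copy-number multiplicity CN_mut/CN_tot under the diploid reduction, so that
summed weights per (sample, bin, type) estimate normalized mutation rates.
Runs of closely spaced mutations — closer than expected under a local
Poisson null — are grouped into clusters and down-weighted so that each
cluster contributes the equivalent of one observation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import contexts
from .binning import GenomeBinning

logger = logging.getLogger(__name__)

WINDOW_BP = 50_000  # cohort background-rate window, centered on the mutation
CLUSTER_CAP_BP = 10_000  # hard cap on the linking distance
DEFAULT_ALPHA_CLUST = 0.005
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class SampleMeta:
    sample_id: str
    purity: float = 1.0
    total_burden: int = 0

    def __post_init__(self):
        if not (0 < self.purity <= 1):
            raise ValueError(f"purity must be in (0,1], got {self.purity}")


@dataclass
class ClusterCall:
    member_indices: list[int]
    mu_hat: np.ndarray  # per-member local rate estimates
    d_star: np.ndarray  # per-member critical distances (bp)

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass
class WeightedCountTensor:
    """Sparse (N_samples x N_bins x 192) nonnegative weight tensor."""

    sample_ids: list[str]
    n_bins: int
    sample_idx: np.ndarray
    bin_idx: np.ndarray
    type_idx: np.ndarray
    weight: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cells(self) -> int:
        return self.weight.shape[0]

    def total_weight(self) -> float:
        return float(self.weight.sum())

    def burdens(self) -> np.ndarray:
        """Per-sample total weight."""
        out = np.zeros(self.n_samples)
        np.add.at(out, self.sample_idx, self.weight)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": [self.sample_ids[i] for i in self.sample_idx],
            "bin": self.bin_idx, "type": self.type_idx, "weight": self.weight})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_ids: Sequence[str],
                   n_bins: int) -> "WeightedCountTensor":
        order = {s: i for i, s in enumerate(sample_ids)}
        return cls(list(sample_ids), n_bins,
                   df["sample"].map(order).to_numpy(int),
                   df["bin"].to_numpy(int), df["type"].to_numpy(int),
                   df["weight"].to_numpy(float))

    def subset_bins(self, mask: np.ndarray, renumber: bool = False
                    ) -> "WeightedCountTensor":
        keep = mask[self.bin_idx]
        bin_idx = self.bin_idx[keep]
        n_bins = self.n_bins
        if renumber:
            new_ids = np.cumsum(mask) - 1
            bin_idx = new_ids[bin_idx]
            n_bins = int(mask.sum())
        return WeightedCountTensor(self.sample_ids, n_bins,
                                   self.sample_idx[keep], bin_idx,
                                   self.type_idx[keep], self.weight[keep])


def mutation_weight(vaf: float, purity: float, cap: float | None = 2.0) -> float:
    """Copy-number-aware mutation weight VAF/purity (diploid reduction)."""
    if purity <= 0:
        raise ValueError("purity must be positive")
    if vaf < 0:
        raise ValueError("VAF must be nonnegative")
    w = vaf / purity
    return min(w, cap) if cap is not None else w


def full_multiplicity_weight(vaf: float, purity: float, cn_total: float) -> float:
    """CN_mut/CN_tot from VAF, purity and total copy number.

    Reduces to VAF/purity when cn_total == 2; exposed for validation of the
    simplified weight.
    """
    return vaf * (1 + 2 * (1 - purity) / (cn_total * purity))


@dataclass
class CohortWindowRates:
    """Cohort-average per-base relative mutation density in 50-kb windows.

    ``rate_at`` returns mu_i: the per-base fraction of all cohort mutations
    within a window centered on a position (sums to ~1 genome-wide under
    uniform rates).
    """

    positions: dict[str, np.ndarray]
    total: int
    genome_length: int
    window_bp: int = WINDOW_BP

    @classmethod
    def from_mutations(cls, df: pd.DataFrame,
                       chrom_lengths: Mapping[str, int],
                       window_bp: int = WINDOW_BP) -> "CohortWindowRates":
        pos = {c: np.sort(df.loc[df["chrom"] == c, "pos"].to_numpy(int))
               for c in chrom_lengths}
        return cls(pos, len(df), sum(chrom_lengths.values()), window_bp)

    def rate_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(pos, dtype=float))
        arr = self.positions.get(chrom, np.empty(0, dtype=int))
        half = self.window_bp / 2
        lo = np.searchsorted(arr, pos - half, side="left")
        hi = np.searchsorted(arr, pos + half, side="right")
        count = (hi - lo).astype(float)
        mu = count / (self.window_bp * self.total) if self.total else count * 0.0
        # windows with no cohort coverage fall back to the genome-wide mean
        mu = np.where(count > 0, mu, 1.0 / self.genome_length)
        return mu


def local_rate(mu_window: np.ndarray, burden: float,
               pseudocount: float = DEFAULT_PSEUDOCOUNT,
               window_bp: int = WINDOW_BP) -> np.ndarray:
    """Expected mutations per base at a site: burden * mu_i + pseudoterm.

    The pseudocount adds ``pseudocount`` pseudo-mutations to the 50-kb
    window before normalizing, i.e. pseudocount/window_bp per base.
    """
    mu_hat = burden * np.asarray(mu_window, dtype=float) + pseudocount / window_bp
    if np.any(mu_hat <= 0):
        raise ValueError("nonpositive local rate")
    return mu_hat


def critical_distance(mu_hat: np.ndarray, alpha_clust: float = DEFAULT_ALPHA_CLUST
                      ) -> np.ndarray:
    """alpha-quantile of the Exp(mu_hat/2) inter-mutation distance null."""
    if not (0 < alpha_clust < 1):
        raise ValueError("alpha_clust must be in (0,1)")
    return -2.0 * math.log1p(-alpha_clust) / np.asarray(mu_hat, dtype=float)


def detect_clusters(sample_df: pd.DataFrame,
                    cohort_rates: CohortWindowRates,
                    burden: float | None = None,
                    alpha_clust: float = DEFAULT_ALPHA_CLUST,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT
                    ) -> list[ClusterCall]:
    """Group consecutive same-chromosome mutations within min(10kb, d*).

    ``sample_df`` holds one sample's mutations with columns chrom, pos; the
    returned clusters index into its (sorted) rows.  Singletons are clusters
    of size 1.
    """
    df = sample_df.sort_values(["chrom", "pos"], kind="mergesort")
    idx = df.index.to_numpy()
    if burden is None:
        burden = len(df)
    clusters: list[ClusterCall] = []
    for chrom, grp in df.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(float)
        rows = grp.index.to_numpy()
        mu = cohort_rates.rate_at(chrom, pos)
        mu_hat = local_rate(mu, burden, pseudocount, cohort_rates.window_bp)
        d_star = critical_distance(mu_hat, alpha_clust)
        gaps = np.diff(pos)
        link = gaps <= np.minimum(CLUSTER_CAP_BP, d_star[:-1])
        start = 0
        for i in range(len(pos)):
            if i == len(pos) - 1 or not link[i]:
                sl = slice(start, i + 1)
                clusters.append(ClusterCall(list(rows[sl]), mu_hat[sl],
                                            d_star[sl]))
                start = i + 1
    return clusters


def linked_gap_fraction(sample_df: pd.DataFrame,
                        cohort_rates: CohortWindowRates,
                        burden: float | None = None,
                        alpha_clust: float = DEFAULT_ALPHA_CLUST,
                        pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Fraction of nearest-neighbor distance tests rejecting the null.

    Under a homogeneous Poisson null this equals alpha_clust by
    construction, making it the natural calibration statistic.
    """
    df = sample_df.sort_values(["chrom", "pos"], kind="mergesort")
    if burden is None:
        burden = len(df)
    n_links = n_gaps = 0
    for chrom, grp in df.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(float)
        if len(pos) < 2:
            continue
        mu = cohort_rates.rate_at(chrom, pos[:-1])
        mu_hat = local_rate(mu, burden, pseudocount, cohort_rates.window_bp)
        d_star = critical_distance(mu_hat, alpha_clust)
        gaps = np.diff(pos)
        n_links += int(np.sum(gaps <= np.minimum(CLUSTER_CAP_BP, d_star)))
        n_gaps += len(gaps)
    return n_links / n_gaps if n_gaps else 0.0


def adjust_cluster_weights(weights: np.ndarray,
                           clusters: Sequence[ClusterCall],
                           enabled: bool = True) -> np.ndarray:
    """Divide each member's weight by its cluster size (identity if disabled)."""
    out = np.asarray(weights, dtype=float).copy()
    if not enabled:
        return out
    for cl in clusters:
        if cl.size > 1:
            out[cl.member_indices] /= cl.size
    return out


def _resolve_types(df: pd.DataFrame, genome: Mapping[str, str]) -> np.ndarray:
    codes = {c: str(genome[c]).upper() for c in set(df["chrom"])}
    types = np.empty(len(df), dtype=int)
    for i, (chrom, pos, ref, alt) in enumerate(
            zip(df["chrom"], df["pos"], df["ref"], df["alt"])):
        seq = codes[chrom]
        if not (1 <= pos < len(seq) - 1):
            types[i] = -1
            continue
        trip = seq[pos - 1:pos + 2]
        if trip[1] != ref.upper():
            raise ValueError(
                f"reference mismatch at {chrom}:{pos}: genome {trip[1]}, call {ref}")
        types[i] = contexts.type_index(ref, alt, trip)
    return types


def build_count_tensor(mutations: pd.DataFrame,
                       binning: GenomeBinning,
                       genome: Mapping[str, str],
                       samples: Sequence[SampleMeta] | None = None,
                       alpha_clust: float = DEFAULT_ALPHA_CLUST,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT,
                       cluster_adjust: bool = True,
                       weight_cap: float | None = 2.0,
                       cohort_rates: CohortWindowRates | None = None
                       ) -> WeightedCountTensor:
    """Full ingestion pipeline.

    ``mutations`` needs columns sample, chrom, pos, ref, alt and optionally
    vaf (missing VAF falls back to weight 1.0 x 1/purity... i.e. vaf = purity,
    giving weight 1).  Mutations at ambiguous contexts are dropped with a
    logged count; a mutation outside the binned genome is an error.
    """
    df = mutations.reset_index(drop=True)
    if "vaf" not in df.columns:
        df = df.assign(vaf=np.nan)
    meta = {m.sample_id: m for m in (samples or [])}
    for sid in pd.unique(df["sample"]):
        if sid not in meta:
            logger.warning("sample %s has no metadata; assuming purity 1.0", sid)
            meta[sid] = SampleMeta(str(sid))
    sample_ids = sorted(meta)

    types = _resolve_types(df, genome)
    dropped = int(np.sum(types < 0))
    if dropped:
        logger.info("dropped %d mutations with ambiguous context", dropped)
    df, types = df[types >= 0].reset_index(drop=True), types[types >= 0]
    df = df.assign(type_idx=types)

    if cohort_rates is None:
        cohort_rates = CohortWindowRates.from_mutations(df, binning.chrom_lengths)

    s_idx, b_idx, t_idx, w = [], [], [], []
    order = {s: i for i, s in enumerate(sample_ids)}
    for sid, grp in df.groupby("sample", sort=True):
        grp = grp.sort_values(["chrom", "pos"], kind="mergesort")
        purity = meta[sid].purity
        vaf = grp["vaf"].to_numpy(float)
        vaf = np.where(np.isnan(vaf), purity, vaf)  # missing VAF -> weight 1
        weights = np.array([mutation_weight(v, purity, weight_cap) for v in vaf])
        clusters = detect_clusters(grp.reset_index(drop=True), cohort_rates,
                                   burden=len(grp), alpha_clust=alpha_clust,
                                   pseudocount=pseudocount)
        weights = adjust_cluster_weights(weights, clusters, cluster_adjust)
        bins = np.array([binning.bin_index_of(c, p)
                         for c, p in zip(grp["chrom"], grp["pos"])])
        s_idx.append(np.full(len(grp), order[sid]))
        b_idx.append(bins)
        t_idx.append(grp["type_idx"].to_numpy(int))
        w.append(weights)

    if s_idx:
        s_idx = np.concatenate(s_idx)
        b_idx = np.concatenate(b_idx)
        t_idx = np.concatenate(t_idx)
        w = np.concatenate(w)
    else:
        s_idx = b_idx = t_idx = np.empty(0, dtype=int)
        w = np.empty(0)
    # accumulate duplicates into single cells
    key = (s_idx * binning.n_bins + b_idx) * contexts.N_TYPES + t_idx
    uniq, inv = np.unique(key, return_inverse=True)
    weight = np.zeros(len(uniq))
    np.add.at(weight, inv, w)
    t_out = (uniq % contexts.N_TYPES).astype(int)
    b_out = ((uniq // contexts.N_TYPES) % binning.n_bins).astype(int)
    s_out = (uniq // (contexts.N_TYPES * binning.n_bins)).astype(int)
    return WeightedCountTensor(sample_ids, binning.n_bins, s_out, b_out,
                               t_out, weight)
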