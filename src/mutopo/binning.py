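"""Feature-defined genome binning.

The genome is partitioned at every discrete-feature state change plus a
fixed-width grid (10 kb by default), producing fine segments of constant
discrete state.  Segments sharing an identical discrete state within a
chromosome are aggregated into bins — even when non-contiguous — so that
small annotations (gene bodies, peaks) and broad domains can be modeled
jointly.  Each bin carries a feature vector (length-weighted averages of
continuous tracks plus the discrete state itself) and a context-availability
row counting, per mutation type, the sites at which that type can occur.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import contexts

FEATURE_CLASSES = ("macro", "meso", "strand")


@dataclass(frozen=True)
class GenomeSegment:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DiscreteTrack:
    """Interval annotation with a constant value per interval.

    ``intervals`` maps chromosome -> list of (start, end, value); bases not
    covered by any interval take ``default``.  Values must be numeric so the
    discrete state can double as a model feature (e.g. 1 = in gene,
    strand +1/-1/0).
    """

    name: str
    feature_class: str
    intervals: Mapping[str, Sequence[tuple[int, int, float]]]
    default: float = 0.0

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        for chrom, ivals in self.intervals.items():
            prev_end = -1
            for start, end, _ in sorted(ivals):
                if start < prev_end:
                    raise ValueError(
                        f"track {self.name!r}: overlapping intervals on {chrom}")
                prev_end = end

    def value_at(self, chrom: str, pos: int) -> float:
        for start, end, value in self.intervals.get(chrom, ()):
            if start <= pos < end:
                return value
        return self.default


@dataclass
class ContinuousTrack:
    """Per-interval continuous signal (bedGraph-like)."""

    name: str
    feature_class: str
    intervals: Mapping[str, Sequence[tuple[int, int, float]]]

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")


@dataclass
class GenomeBin:
    bin_id: int
    segments: list[GenomeSegment]
    discrete_state_key: tuple
    length_bp: int

    @property
    def chrom(self) -> str:
        return self.segments[0].chrom


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (N_bins, N_features)
    feature_names: list[str]
    feature_classes: list[str]

    def columns(self, feature_class: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.feature_classes)
                         if c == feature_class], dtype=int)

    def subset(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise KeyError(f"features missing from matrix: {missing}")
        idx = [self.feature_names.index(n) for n in names]
        return self.values[:, idx]


@dataclass
class ContextAvailability:
    counts: np.ndarray  # (N_bins, 192)


@dataclass
class GenomeBinning:
    """Bins, features and availability for one reference genome."""

    bins: list[GenomeBin]
    feature_matrix: FeatureMatrix
    availability: ContextAvailability
    chrom_lengths: dict[str, int]
    _lookup: dict = field(default_factory=dict, repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def _build_lookup(self):
        for b in self.bins:
            for seg in b.segments:
                self._lookup.setdefault(seg.chrom, []).append(
                    (seg.start, seg.end, b.bin_id))
        for chrom in self._lookup:
            self._lookup[chrom].sort()

    def bin_index_of(self, chrom: str, pos: int) -> int:
        """Bin containing a position; raises if outside the binned genome."""
        if not self._lookup:
            self._build_lookup()
        segs = self._lookup.get(chrom)
        if segs is None:
            raise KeyError(f"chromosome {chrom!r} not in binning")
        starts = [s for s, _, _ in segs]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i < 0 or not (segs[i][0] <= pos < segs[i][1]):
            raise KeyError(f"position {chrom}:{pos} outside binned genome")
        return segs[i][2]

    def bin_chroms(self) -> np.ndarray:
        return np.array([b.chrom for b in self.bins])

    def bins_on_chroms(self, chroms: Iterable[str]) -> np.ndarray:
        chroms = set(chroms)
        return np.array([b.chrom in chroms for b in self.bins])

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for b in self.bins:
            h.update(repr((b.discrete_state_key,
                           [(s.chrom, s.start, s.end) for s in b.segments])).encode())
        h.update(np.ascontiguousarray(self.feature_matrix.values).tobytes())
        h.update(np.ascontiguousarray(self.availability.counts).tobytes())
        return h.hexdigest()


def segment_genome(chrom_lengths: Mapping[str, int],
                   discrete_tracks: Sequence[DiscreteTrack] = (),
                   interval_bp: int = 10_000) -> list[GenomeSegment]:
    """Partition each chromosome at discrete-feature boundaries + fixed grid.

    Segment boundaries are exactly the union of every discrete track's
    interval endpoints and multiples of ``interval_bp`` (restarting at 0 on
    each chromosome), clipped to chromosome ends.
    """
    if interval_bp <= 0:
        raise ValueError("interval_bp must be positive")
    for track in discrete_tracks:
        for chrom in track.intervals:
            if chrom not in chrom_lengths:
                raise ValueError(
                    f"track {track.name!r} references unknown chromosome {chrom!r}")
    segments: list[GenomeSegment] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length <= 0:
            continue
        cuts = set(range(0, length, interval_bp)) | {0, length}
        for track in discrete_tracks:
            for start, end, _ in track.intervals.get(chrom, ()):
                if end > length:
                    raise ValueError(
                        f"track {track.name!r}: interval beyond {chrom} end")
                cuts.add(start)
                cuts.add(end)
        bounds = sorted(c for c in cuts if 0 <= c <= length)
        segments.extend(GenomeSegment(chrom, a, b)
                        for a, b in zip(bounds[:-1], bounds[1:]))
    return segments


def _segment_state(seg: GenomeSegment,
                   discrete_tracks: Sequence[DiscreteTrack]) -> tuple:
    return tuple(t.value_at(seg.chrom, seg.start) for t in discrete_tracks)


def aggregate_bins(segments: Sequence[GenomeSegment],
                   discrete_tracks: Sequence[DiscreteTrack] = (),
                   interval_bp: int = 10_000) -> list[GenomeBin]:
    """Group same-state segments within each grid window into bins.

    The fixed-width grid window is part of a segment's identity: fragments
    created when annotations subdivide a window are re-merged when their
    discrete state matches (hence bins may hold non-contiguous segments),
    but bins never span grid windows or chromosomes, so broad continuous
    features retain their locus resolution.  Ordering is lexicographic on
    the state key then first-segment coordinate, fixed for reproducibility.
    """
    groups: dict[tuple, list[GenomeSegment]] = {}
    for seg in sorted(segments, key=lambda s: (s.chrom, s.start)):
        key = (seg.chrom, seg.start // interval_bp) \
            + _segment_state(seg, discrete_tracks)
        groups.setdefault(key, []).append(seg)
    ordered = sorted(groups.items(),
                     key=lambda kv: (kv[0], kv[1][0].start))
    return [GenomeBin(i, segs, key, sum(s.length for s in segs))
            for i, (key, segs) in enumerate(ordered)]


def build_feature_matrix(bins: Sequence[GenomeBin],
                         continuous_tracks: Sequence[ContinuousTrack] = (),
                         discrete_tracks: Sequence[DiscreteTrack] = (),
                         impute: str | None = "chrom_mean") -> FeatureMatrix:
    """Per-bin feature vectors.

    Continuous entries are length-weighted means over the bin's bases;
    bases not covered by a track take the chromosome's coverage-weighted
    mean (``impute='chrom_mean'``; the track-wide mean when a chromosome
    has no coverage at all) or raise (``impute=None``).  Discrete track
    states are appended as features of their declared class.
    """
    n = len(bins)
    names, classes, cols = [], [], []
    for track in continuous_tracks:
        chrom_mean: dict[str, float] = {}
        g_len = g_sum = 0.0
        for chrom, ivals in track.intervals.items():
            tot = sum((e - s) for s, e, _ in ivals)
            wsum = sum((e - s) * v for s, e, v in ivals)
            g_len += tot
            g_sum += wsum
            chrom_mean[chrom] = wsum / tot if tot else np.nan
        global_mean = g_sum / g_len if g_len else np.nan
        col = np.empty(n)
        for i, b in enumerate(bins):
            covered = weighted = 0.0
            for seg in b.segments:
                for s, e, v in track.intervals.get(seg.chrom, ()):
                    ov = min(e, seg.end) - max(s, seg.start)
                    if ov > 0:
                        covered += ov
                        weighted += ov * v
            uncovered = b.length_bp - covered
            if uncovered > 0:
                if impute is None:
                    raise ValueError(
                        f"feature {track.name!r}: bin {b.bin_id} has "
                        f"{uncovered:.0f} uncovered bases and imputation is off")
                fill = chrom_mean.get(b.chrom, np.nan)
                if np.isnan(fill):
                    fill = global_mean
                if np.isnan(fill):
                    raise ValueError(
                        f"feature {track.name!r}: no coverage anywhere")
                weighted += uncovered * fill
            col[i] = weighted / b.length_bp
        names.append(track.name)
        classes.append(track.feature_class)
        cols.append(col)
    for j, track in enumerate(discrete_tracks):
        col = np.array([float(b.discrete_state_key[1 + j]) for b in bins])
        names.append(track.name)
        classes.append(track.feature_class)
        cols.append(col)
    values = np.column_stack(cols) if cols else np.empty((n, 0))
    return FeatureMatrix(values, names, classes)


def compute_context_availability(bins: Sequence[GenomeBin],
                                 genome: Mapping[str, str],
                                 count_soft_masked: bool = True
                                 ) -> ContextAvailability:
    """Count, per bin and mutation type, the sites where the type can occur.

    A position contributes once to each of the 3 types sharing its stranded
    trinucleotide context; ambiguous (N) bases contribute nothing.
    """
    group_cache: dict[str, np.ndarray] = {}
    counts = np.zeros((len(bins), contexts.N_TYPES))
    for b in bins:
        gcounts = np.zeros(contexts.N_CONTEXT_GROUPS, dtype=np.int64)
        for seg in b.segments:
            if seg.chrom not in group_cache:
                if seg.chrom not in genome:
                    raise KeyError(f"no sequence for chromosome {seg.chrom!r}")
                codes = contexts.encode_sequence(str(genome[seg.chrom]),
                                                 count_soft_masked)
                group_cache[seg.chrom] = contexts.context_groups(codes)
            groups = group_cache[seg.chrom]
            if seg.end > groups.shape[0]:
                raise KeyError(
                    f"sequence for {seg.chrom} shorter than segment end {seg.end}")
            part = groups[seg.start:seg.end]
            part = part[part >= 0]
            gcounts += np.bincount(part, minlength=contexts.N_CONTEXT_GROUPS)
        counts[b.bin_id] = contexts.group_counts_to_availability(
            gcounts.astype(float))
    return ContextAvailability(counts)


def build_binning(genome: Mapping[str, str],
                  discrete_tracks: Sequence[DiscreteTrack] = (),
                  continuous_tracks: Sequence[ContinuousTrack] = (),
                  interval_bp: int = 10_000,
                  impute: str | None = "chrom_mean",
                  count_soft_masked: bool = True) -> GenomeBinning:
    """End-to-end binning of a genome given its feature tracks."""
    chrom_lengths = {c: len(str(genome[c])) for c in genome}
    segments = segment_genome(chrom_lengths, discrete_tracks, interval_bp)
    bins = aggregate_bins(segments, discrete_tracks, interval_bp)
    X = build_feature_matrix(bins, continuous_tracks, discrete_tracks, impute)
    t = compute_context_availability(bins, genome, count_soft_masked)
    return GenomeBinning(bins, X, t, chrom_lengths)
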