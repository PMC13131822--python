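"""Readers and writers for the standard input/output formats.

Genomes come from FASTA (pyfaidx), mutations from MAF-style TSV or VCF
(cyvcf2, optional), tracks from BED3/BED6 and bedGraph.  Binning and count
tensors round-trip through documented tab-delimited tables (+ a compressed
availability matrix).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .binning import (ContextAvailability, ContinuousTrack, DiscreteTrack,
                      FeatureMatrix, GenomeBin, GenomeBinning, GenomeSegment)
from .ingest import SampleMeta, WeightedCountTensor


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def read_bed_track(path, name: str, feature_class: str,
                   default: float = 0.0) -> DiscreteTrack:
    """BED3 (presence 1.0) or BED6 (strand column -> +1/-1 for strand class)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        if feature_class == "strand" and len(row) >= 6:
            value = 1.0 if str(row[5]) == "+" else -1.0
        else:
            value = 1.0
        intervals.setdefault(chrom, []).append((start, end, value))
    return DiscreteTrack(name, feature_class, intervals, default)


def read_bedgraph(path, name: str, feature_class: str) -> ContinuousTrack:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    for row in df.itertuples(index=False):
        intervals.setdefault(str(row.chrom), []).append(
            (int(row.start), int(row.end), float(row.value)))
    return ContinuousTrack(name, feature_class, intervals)


def read_maf(path) -> pd.DataFrame:
    """MAF-style TSV with columns sample, chrom, pos, ref, alt[, vaf]."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns {sorted(missing)}")
    return df


def read_vcf(path, sample_id: str | None = None) -> pd.DataFrame:
    """SNVs from a VCF; VAF precedence: FORMAT AF, then AD ratio, then INFO AF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    for var in vcf:
        if not var.is_snp:
            continue
        for alt in var.ALT:
            vaf = np.nan
            if samples:
                try:
                    af = var.format("AF")
                    if af is not None:
                        vaf = float(af[0][0])
                except KeyError:
                    pass
                if np.isnan(vaf):
                    try:
                        ad = var.format("AD")
                        if ad is not None and ad[0].sum() > 0:
                            vaf = float(ad[0][1]) / float(ad[0].sum())
                    except (KeyError, IndexError):
                        pass
            if np.isnan(vaf) and var.INFO.get("AF") is not None:
                vaf = float(var.INFO.get("AF"))
            rows.append({"sample": sample_id or (samples[0] if samples
                                                 else "sample0"),
                         "chrom": var.CHROM, "pos": var.POS - 1,
                         "ref": var.REF, "alt": alt, "vaf": vaf})
    return pd.DataFrame(rows)


def read_sample_meta(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    return [SampleMeta(str(r.sample_id), float(r.purity))
            for r in df.itertuples(index=False)]


def write_binning(binning: GenomeBinning, prefix) -> None:
    """Bin table as TSV plus compressed feature/availability matrices."""
    prefix = Path(prefix)
    rows = []
    for b in binning.bins:
        for seg in b.segments:
            rows.append({"bin_id": b.bin_id, "chrom": seg.chrom,
                         "start": seg.start, "end": seg.end,
                         "state_key": repr(b.discrete_state_key)})
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".bins.tsv"), sep="\t",
                              index=False)
    np.savez_compressed(
        prefix.with_suffix(".arrays.npz"),
        availability=binning.availability.counts,
        features=binning.feature_matrix.values,
        feature_names=np.array(binning.feature_matrix.feature_names),
        feature_classes=np.array(binning.feature_matrix.feature_classes),
        chroms=np.array(sorted(binning.chrom_lengths)),
        chrom_lengths=np.array([binning.chrom_lengths[c]
                                for c in sorted(binning.chrom_lengths)]))


def read_binning(prefix) -> GenomeBinning:
    prefix = Path(prefix)
    table = pd.read_csv(prefix.with_suffix(".bins.tsv"), sep="\t")
    arrays = np.load(prefix.with_suffix(".arrays.npz"), allow_pickle=False)
    bins = []
    for bin_id, grp in table.groupby("bin_id", sort=True):
        segs = [GenomeSegment(str(r.chrom), int(r.start), int(r.end))
                for r in grp.itertuples(index=False)]
        key = eval(grp.iloc[0]["state_key"])  # tuples of numbers/strings
        bins.append(GenomeBin(int(bin_id), segs, key,
                              sum(s.length for s in segs)))
    fm = FeatureMatrix(arrays["features"],
                       [str(n) for n in arrays["feature_names"]],
                       [str(c) for c in arrays["feature_classes"]])
    avail = ContextAvailability(arrays["availability"])
    chrom_lengths = {str(c): int(l) for c, l in
                     zip(arrays["chroms"], arrays["chrom_lengths"])}
    return GenomeBinning(bins, fm, avail, chrom_lengths)


def write_tensor(Y: WeightedCountTensor, path) -> None:
    # %.17g keeps the float64 round-trip exact
    Y.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_tensor(path, sample_ids: Sequence[str] | None = None,
                n_bins: int | None = None) -> WeightedCountTensor:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if sample_ids is None:
        sample_ids = sorted(df["sample"].unique())
    if n_bins is None:
        n_bins = int(df["bin"].max()) + 1
    return WeightedCountTensor.from_frame(df, sample_ids, n_bins)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
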