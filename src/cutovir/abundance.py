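"""Coverage estimation: alignment filters, pileups, trimmed means,
length-weighted rMAG coverage, and cross-sample depth normalization.

The per-target statistic is the trimmed mean of per-base depth
("tpmean"): per-base depths are sorted and the lowest and highest 10%
of positions are discarded before averaging, which suppresses both
uncovered gaps and repeat-driven pileup spikes.  Targets are retained
in a sample only when reads cover >= 70% of their length (breadth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord

# (min aligned fraction of the read, min identity) per mapping mode
VOTU_FILTER = (0.90, 0.95)
RMAG_FILTER = (0.75, 0.95)
BREADTH_MIN = 0.70


@dataclass
class DepthProfile:
    """Per-base read depth along one target sequence."""

    target_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1 or len(self.depth) < 1:
            raise ValueError("depth must be a nonempty 1-D vector")
        if (self.depth < 0).any():
            raise ValueError("depth values must be nonnegative")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class AbundanceMatrix:
    """Samples x features normalized coverage with per-sample read counts."""

    values: pd.DataFrame  # index = samples, columns = features
    reads_per_sample: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.reads_per_sample.index):
            self.reads_per_sample = self.reads_per_sample.reindex(self.values.index)
        if self.reads_per_sample.isna().any():
            raise ValueError("reads_per_sample missing for some samples")
        if (self.values.values < 0).any():
            raise ValueError("abundance values must be nonnegative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


def filter_alignments(
    records: Iterable[AlignmentRecord],
    min_query_fraction: float,
    min_identity: float,
) -> list[AlignmentRecord]:
    """Keep records aligned over >= min_query_fraction of the read at
    >= min_identity; vOTU mode uses (0.90, 0.95), rMAG mode (0.75, 0.95)."""
    return [
        r
        for r in records
        if r.query_fraction >= min_query_fraction and r.identity >= min_identity
    ]


def depth_profile(records: Sequence[AlignmentRecord], target_len: int) -> DepthProfile:
    """Pileup of half-open alignment intervals on one target."""
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    targets = {r.target_id for r in records}
    if len(targets) > 1:
        raise ValueError(f"records reference multiple targets: {sorted(targets)}")
    delta = np.zeros(target_len + 1, dtype=np.int64)
    for r in records:
        if r.target_end > target_len:
            raise ValueError(
                f"alignment {r.query_id} ends at {r.target_end} beyond "
                f"target length {target_len}"
            )
        delta[r.target_start] += 1
        delta[r.target_end] -= 1
    depth = np.cumsum(delta[:-1])
    target_id = next(iter(targets)) if targets else ""
    return DepthProfile(target_id, depth)


def breadth(profile: DepthProfile) -> float:
    """Fraction of positions covered by at least one read."""
    return float((profile.depth >= 1).mean())


def tpmean(profile: DepthProfile, trim: float = 0.10) -> float:
    """Trimmed mean depth: drop floor(trim*L) lowest and highest values.

    Profiles shorter than 10 positions are averaged without trimming.
    """
    if not 0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    d = np.sort(profile.depth)
    L = len(d)
    if L < 10:
        return float(d.mean())
    k = math.floor(trim * L)
    trimmed = d[k : L - k] if k > 0 else d
    return float(trimmed.mean())


def rmag_coverage(contig_profiles: Sequence[DepthProfile], trim: float = 0.10) -> float:
    """Length-weighted mean of per-contig tpmeans for a binned genome."""
    if not contig_profiles:
        raise ValueError("need at least one contig profile")
    num = sum(tpmean(p, trim) * len(p) for p in contig_profiles)
    den = sum(len(p) for p in contig_profiles)
    return num / den


def build_abundance_matrix(
    profiles_by_sample: Mapping[str, Mapping[str, DepthProfile]],
    reads_per_sample: Mapping[str, int],
    breadth_min: float = BREADTH_MIN,
    trim: float = 0.10,
) -> AbundanceMatrix:
    """Raw (un-normalized) coverage matrix from per-sample depth profiles.

    Coverage of a target in a sample is its tpmean when breadth >=
    ``breadth_min`` there, else 0 — the breadth filter precedes the
    trimmed mean, matching the pipeline order.
    """
    samples = sorted(profiles_by_sample)
    features = sorted({t for prof in profiles_by_sample.values() for t in prof})
    mat = np.zeros((len(samples), len(features)))
    for i, s in enumerate(samples):
        for j, f in enumerate(features):
            prof = profiles_by_sample[s].get(f)
            if prof is not None and breadth(prof) >= breadth_min:
                mat[i, j] = tpmean(prof, trim)
    values = pd.DataFrame(mat, index=samples, columns=features)
    reads = pd.Series({s: reads_per_sample[s] for s in samples}, dtype=float)
    return AbundanceMatrix(values, reads)


def normalize_depth(matrix: AbundanceMatrix, mode: str = "depth_corrected") -> AbundanceMatrix:
    """Normalize coverage for between-sample sequencing-depth variation.

    ``depth_corrected`` (default) multiplies each sample's coverages by
    mean_reads / sample_reads, equalizing features whose true relative
    abundance is constant across samples.  ``literal`` applies the
    protocol sentence verbatim (multiply by sample_reads / mean_reads),
    which up-weights deeply sequenced samples; it is retained so both
    readings of the normalization are available.
    """
    if mode not in ("depth_corrected", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    reads = matrix.reads_per_sample
    if (reads <= 0).any():
        raise ValueError("all samples must have > 0 reads")
    mean_reads = reads.mean()
    factor = mean_reads / reads if mode == "depth_corrected" else reads / mean_reads
    values = matrix.values.mul(factor, axis=0)
    return AbundanceMatrix(values, reads.copy())


def relative_abundance(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Row-normalize coverage to per-sample relative abundances."""
    totals = matrix.values.sum(axis=1)
    totals[totals == 0] = 1.0
    return matrix.values.div(totals, axis=0)
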