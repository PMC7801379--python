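"""Spike-in reference normalization and ChIP signal quantification.

Tracks are chromosome-keyed step functions (bedGraph-style, sorted,
non-overlapping); they carry a sequencing depth and a scale state so the
normalization pipeline (per-10^7 scaling followed by the spike-in factor) is
applied exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import (
    CapContactError,
    ChromosomeLookupError,
    ConfigurationError,
    InvalidInputError,
    UndefinedCorrelationError,
    UndefinedFactorError,
)


class AlignmentError(CapContactError):
    """Two signal columns do not cover the same interval set."""


@dataclass(frozen=True)
class SpikeInPair:
    """Two-genome read counts for one sample's input and IP libraries."""

    sample: str
    condition: str
    input_target_reads: int
    input_spike_reads: int
    ip_target_reads: int
    ip_spike_reads: int

    def ratio_input(self) -> float:
        return self.input_spike_reads / self.input_target_reads

    def ratio_ip(self) -> float:
        return self.ip_spike_reads / self.ip_target_reads


def spike_in_factor(
    sample: SpikeInPair,
    reference: SpikeInPair,
    input_corrected: bool = True,
) -> float:
    """Reference-anchored spike-in normalization factor for ``sample``.

    The per-sample raw factor is (input spike:target) / (IP spike:target);
    dividing by the reference's raw factor anchors ``factor(reference) = 1``.
    A sample whose target-genome IP material is globally depleted yields a
    factor < 1. With ``input_corrected=False`` the input ratio is ignored
    (uncorrected IP ratios).
    """
    for pair in (sample, reference):
        counts = (
            pair.input_target_reads,
            pair.input_spike_reads,
            pair.ip_target_reads,
            pair.ip_spike_reads,
        )
        if any(c <= 0 for c in counts):
            raise UndefinedFactorError(
                f"sample {pair.sample!r}: all four read counts must be positive"
            )

    def raw(pair: SpikeInPair) -> float:
        if input_corrected:
            return pair.ratio_input() / pair.ratio_ip()
        return 1.0 / pair.ratio_ip()

    return raw(sample) / raw(reference)


class SignalTrack:
    """Step-function coverage track over one or more chromosomes.

    ``data`` maps chromosome name to ``(starts, ends, values)`` arrays of
    sorted, non-overlapping intervals; positions not covered by any interval
    have value 0. ``depth`` is the total target-genome read count behind the
    track; ``scale_state`` is one of ``raw``, ``per-1e7``,
    ``reference-normalized``.
    """

    def __init__(
        self,
        data: Mapping[str, tuple] | None = None,
        depth: float | None = None,
        scale_state: str = "raw",
    ) -> None:
        self.data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.depth = depth
        self.scale_state = scale_state
        if data:
            for chrom, (starts, ends, values) in data.items():
                self.add_chromosome(chrom, starts, ends, values)

    def add_chromosome(self, chrom, starts, ends, values) -> None:
        s = np.asarray(starts, dtype=np.int64)
        e = np.asarray(ends, dtype=np.int64)
        v = np.asarray(values, dtype=float)
        if not (s.size == e.size == v.size):
            raise InvalidInputError(f"{chrom}: ragged track arrays")
        if np.any(e <= s):
            raise InvalidInputError(f"{chrom}: empty track interval")
        if np.any(s[1:] < e[:-1]):
            raise InvalidInputError(f"{chrom}: overlapping or unsorted intervals")
        if np.any(v < 0):
            raise InvalidInputError(f"{chrom}: negative coverage value")
        self.data[chrom] = (s, e, v)

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def interval_mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean of the step function over ``[start, end)``.

        Uncovered positions contribute 0; the chromosome itself must be known
        to the track.
        """
        if start >= end:
            raise InvalidInputError("interval start must precede end")
        if chrom not in self.data:
            raise ChromosomeLookupError(f"chromosome {chrom!r} not in track")
        s, e, v = self.data[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        return float((v[lo:hi] * ov).sum() / (end - start))

    def scaled(self, factor: float, scale_state: str) -> "SignalTrack":
        out = SignalTrack(depth=self.depth, scale_state=scale_state)
        for chrom, (s, e, v) in self.data.items():
            out.data[chrom] = (s.copy(), e.copy(), v * factor)
        return out


def normalize_chip_tracks(
    tracks: Mapping[str, SignalTrack],
    pairs: Mapping[str, SpikeInPair],
    reference: str,
    input_corrected: bool = True,
) -> dict[str, SignalTrack]:
    """Scale each track to per-10^7 target reads, then apply its spike factor."""
    if reference not in pairs:
        raise ConfigurationError(f"reference sample {reference!r} has no spike counts")
    out = {}
    for label, track in tracks.items():
        if label not in pairs:
            raise ConfigurationError(f"track {label!r} has no spike-in pair")
        if track.depth is None or track.depth <= 0:
            raise ConfigurationError(f"track {label!r} has no usable depth")
        factor = spike_in_factor(pairs[label], pairs[reference], input_corrected)
        per_1e7 = 1e7 / track.depth
        out[label] = track.scaled(per_1e7 * factor, "reference-normalized")
    return out


def quantify_windows(track: SignalTrack, intervals: pd.DataFrame) -> pd.Series:
    """Mean signal per interval; index ``(chrom, start, end)``, zeros where
    uncovered."""
    values = []
    index = []
    for row in intervals.itertuples(index=False):
        chrom, start, end = str(row.chrom), int(row.start), int(row.end)
        values.append(track.interval_mean(chrom, start, end))
        index.append((chrom, start, end))
    return pd.Series(
        values, index=pd.MultiIndex.from_tuples(index, names=["chrom", "start", "end"])
    )


def metaprofile(
    track: SignalTrack,
    peaks: pd.DataFrame,
    flank: int = 5_000,
    bin_size: int = 100,
    normalize_to_peak: bool = False,
) -> np.ndarray:
    """Mean binned signal over ``[center - flank, center + flank)`` per peak.

    Bins falling before position 0 contribute their in-range portion as 0
    coverage. With ``normalize_to_peak`` the profile is rescaled so its
    maximum is 1 (e.g. for "normalized to the peak read count" displays).
    """
    if bin_size <= 0 or flank < bin_size:
        raise InvalidInputError("need flank >= bin_size > 0")
    if len(peaks) == 0:
        raise InvalidInputError("empty peak set")
    n_bins = (2 * flank) // bin_size
    profile = np.zeros(n_bins, dtype=float)
    for row in peaks.itertuples(index=False):
        chrom = str(row.chrom)
        center = (int(row.start) + int(row.end)) // 2
        for i in range(n_bins):
            bs = center - flank + i * bin_size
            be = bs + bin_size
            if be <= 0:
                continue
            clipped_bs = max(bs, 0)
            covered = track.interval_mean(chrom, clipped_bs, be) * (be - clipped_bs)
            profile[i] += covered / bin_size
    profile /= len(peaks)
    if normalize_to_peak:
        peak_val = profile.max()
        if peak_val > 0:
            profile = profile / peak_val
    return profile


def rank_by_promoter_score(
    m3: pd.Series, m1: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Order intervals by log2((H3K4me3 + psi) / (H3K4me1 + psi)), descending.

    Promoter-like intervals rank first, enhancer-like last; ties break by
    genomic coordinate (the interval index sort order).
    """
    if len(m3) != len(m1) or not m3.index.equals(m1.index):
        raise AlignmentError("H3K4me3 and H3K4me1 columns cover different intervals")
    score = np.log2((m3 + pseudocount) / (m1 + pseudocount))
    df = pd.DataFrame({"m3": m3, "m1": m1, "score": score}).sort_index()
    return df.sort_values("score", ascending=False, kind="stable")


def correlate_datasets(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation and average-linkage leaf order.

    Clustering runs on distance ``1 - r``. Returns the symmetric correlation
    matrix (unit diagonal) and the dendrogram leaf order as column labels.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise InvalidInputError("need >= 2 datasets over >= 3 intervals")
    stds = matrix.std(axis=0, ddof=0)
    dead = stds[stds == 0]
    if len(dead):
        raise UndefinedCorrelationError(
            f"zero-variance dataset(s): {', '.join(map(str, dead.index))}"
        )
    corr = matrix.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    dist = 1.0 - corr.to_numpy()
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    order = [str(matrix.columns[i]) for i in leaves_list(z)]
    return corr, order


def build_signal_matrix(
    tracks: Mapping[str, SignalTrack], intervals: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the interval x dataset mean-signal matrix."""
    cols = {label: quantify_windows(t, intervals) for label, t in tracks.items()}
    return pd.DataFrame(cols)
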