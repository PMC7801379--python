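"""Super-enhancer stitching/calling, typical enhancers, TSS assignment, eRNA.

Super-enhancer calling uses the scaled-rank tangent rule: regions are sorted
by aggregate signal, rank and signal are rescaled to [0, 1], and the cutoff
sits where the discrete slope of the scaled curve first exceeds 1; regions
above the cutoff are super-enhancers. Stitching merges peaks whose
edge-to-edge gap is at most ``min_dist`` (default 12,500 bp), transitively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import InsufficientDataError, InvalidInputError

DEFAULT_STITCH_DIST = 12_500
DEFAULT_TSS_DIST = 1_000
ERNA_WINDOW_WIDTH = 1_000


# ---------------------------------------------------------------------------
# interval helpers (plain sorted-array arithmetic; peak sets are small)
# ---------------------------------------------------------------------------


def _merged_by_chrom(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Union of intervals per chromosome as sorted, disjoint arrays."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        ivals = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[str(chrom)] = (
            np.array([m[0] for m in merged], dtype=np.int64),
            np.array([m[1] for m in merged], dtype=np.int64),
        )
    return out


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: >= 1 bp overlap with any subject interval."""
    merged = _merged_by_chrom(subject) if len(subject) else {}
    hits = np.zeros(len(query), dtype=bool)
    for i, row in enumerate(query.itertuples(index=False)):
        chrom = str(row.chrom)
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        j = int(np.searchsorted(starts, int(row.end), side="left"))
        hits[i] = j > 0 and ends[j - 1] > int(row.start)
    return hits


# ---------------------------------------------------------------------------
# stitching and super-enhancer calling
# ---------------------------------------------------------------------------


def stitch_peaks(
    peaks: pd.DataFrame, min_dist: int = DEFAULT_STITCH_DIST
) -> pd.DataFrame:
    """Transitively merge same-chromosome peaks with gap <= ``min_dist``.

    ``peaks`` needs ``chrom``, ``start``, ``end`` and ``signal`` columns (an
    optional ``name`` column labels constituents). Each output region spans
    min start to max end of its constituents and sums their signals.
    """
    if min_dist < 0:
        raise InvalidInputError("min_dist must be >= 0")
    if len(peaks) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "signal", "n_constituents", "constituents"]
        )
    work = peaks.copy()
    if "name" not in work.columns:
        work["name"] = [f"p{i}" for i in range(len(work))]
    records = []
    for chrom, grp in work.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"], kind="stable")
        cur = None
        for row in grp.itertuples(index=False):
            s, e = int(row.start), int(row.end)
            if cur is not None and s - cur["end"] <= min_dist:
                cur["end"] = max(cur["end"], e)
                cur["signal"] += float(row.signal)
                cur["constituents"].append(str(row.name))
            else:
                if cur is not None:
                    records.append(cur)
                cur = {
                    "chrom": str(chrom),
                    "start": s,
                    "end": e,
                    "signal": float(row.signal),
                    "constituents": [str(row.name)],
                }
        if cur is not None:
            records.append(cur)
    out = pd.DataFrame.from_records(records)
    out["n_constituents"] = out["constituents"].map(len)
    out["constituents"] = out["constituents"].map(",".join)
    return out[["chrom", "start", "end", "signal", "n_constituents", "constituents"]]


def call_super_enhancers(stitched: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Flag super-enhancers by the scaled-rank slope rule.

    Regions are sorted ascending by signal; rank and signal are rescaled to
    [0, 1]; scanning the discrete slopes of that curve, the first segment
    whose slope exceeds 1 defines the cutoff, and every region with signal at
    or above the segment's right endpoint is flagged. If no segment crosses
    (e.g. all signals equal) nothing is flagged and the cutoff is NaN.
    """
    if len(stitched) < 2:
        raise InsufficientDataError("need >= 2 stitched regions to call SEs")
    signal = stitched["signal"].to_numpy(dtype=float)
    if np.any(~np.isfinite(signal)):
        raise InvalidInputError("non-finite aggregate signal")
    out = stitched.copy()
    order = np.argsort(signal, kind="stable")
    s_sorted = signal[order]
    n = len(s_sorted)
    span = s_sorted[-1] - s_sorted[0]
    if span == 0:
        out["is_super"] = False
        return out, float("nan")
    x = np.arange(n) / (n - 1)
    y = (s_sorted - s_sorted[0]) / span
    slopes = np.diff(y) / np.diff(x)
    crossing = np.nonzero(slopes > 1.0)[0]
    if crossing.size == 0:
        out["is_super"] = False
        return out, float("nan")
    cutoff = float(s_sorted[int(crossing[0]) + 1])
    out["is_super"] = signal >= cutoff
    return out, cutoff


# ---------------------------------------------------------------------------
# typical enhancers and gene assignment
# ---------------------------------------------------------------------------


def _min_tss_distance(chrom: str, start: int, end: int, tss: pd.DataFrame) -> float:
    """Minimum edge distance from a region to any TSS (0 if a TSS is inside)."""
    on_chrom = tss[tss["chrom"] == chrom]
    if on_chrom.empty:
        return float("inf")
    pos = on_chrom["tss"].to_numpy(dtype=np.int64)
    inside = (pos >= start) & (pos < end)
    if inside.any():
        return 0.0
    dist = np.where(pos < start, start - pos, pos - end)
    return float(dist.min())


def define_typical_enhancers(
    k27ac: pd.DataFrame,
    k4me1: pd.DataFrame,
    tss: pd.DataFrame,
    ses: pd.DataFrame,
    min_tss_dist: int = DEFAULT_TSS_DIST,
) -> pd.DataFrame:
    """H3K27ac peaks overlapping H3K4me1, > ``min_tss_dist`` bp from every
    TSS and not overlapping any super-enhancer region.

    ``tss`` needs ``chrom`` and ``tss`` (position) columns; ``ses`` is the
    output of :func:`call_super_enhancers` (only ``is_super`` rows exclude).
    """
    if len(k27ac) == 0:
        return k27ac.copy()
    keep = overlaps_any(k27ac, k4me1)
    se_regions = ses[ses["is_super"]] if "is_super" in ses.columns else ses
    if len(se_regions):
        keep &= ~overlaps_any(k27ac, se_regions)
    dists = np.array(
        [
            _min_tss_distance(str(r.chrom), int(r.start), int(r.end), tss)
            for r in k27ac.itertuples(index=False)
        ]
    )
    keep &= dists > min_tss_dist
    return k27ac[keep].reset_index(drop=True)


def nearest_tss_assignment(
    regions: pd.DataFrame, tss: pd.DataFrame
) -> pd.Series:
    """Assign each region the gene of its nearest TSS.

    Distance is the minimum absolute distance from the region edges (0 when
    the TSS lies inside the region); ties break towards the TSS with the
    smaller genomic coordinate. Regions on chromosomes with no TSS get
    ``None``.
    """
    if "gene" not in tss.columns:
        raise InvalidInputError("tss table needs a 'gene' column")
    assigned = []
    for row in regions.itertuples(index=False):
        chrom, start, end = str(row.chrom), int(row.start), int(row.end)
        on_chrom = tss[tss["chrom"] == chrom]
        if on_chrom.empty:
            assigned.append(None)
            continue
        pos = on_chrom["tss"].to_numpy(dtype=np.int64)
        dist = np.where(
            (pos >= start) & (pos < end),
            0,
            np.where(pos < start, start - pos, pos - end),
        )
        best = dist.min()
        candidates = on_chrom[dist == best]
        winner = candidates.loc[candidates["tss"].idxmin()]
        assigned.append(str(winner["gene"]))
    return pd.Series(assigned, index=regions.index, name="gene")


# ---------------------------------------------------------------------------
# eRNA windows and class comparisons
# ---------------------------------------------------------------------------


def erna_windows(
    atac: pd.DataFrame,
    ses: pd.DataFrame,
    tes: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """1 kb windows centered on intergenic ATAC peaks overlapping SEs or TEs.

    Intergenic means no overlap with any gene body (``genes`` needs ``chrom``,
    ``start``, ``end``). Windows overlapping a super-enhancer are class
    ``SE``; otherwise, windows overlapping a typical enhancer are ``TE``; SE
    wins when both apply. Other peaks are dropped.
    """
    if len(atac) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "klass", "source"])
    intergenic = ~overlaps_any(atac, genes) if len(genes) else np.ones(len(atac), bool)
    se_regions = ses[ses["is_super"]] if "is_super" in ses.columns else ses
    in_se = overlaps_any(atac, se_regions) if len(se_regions) else np.zeros(len(atac), bool)
    in_te = overlaps_any(atac, tes) if len(tes) else np.zeros(len(atac), bool)
    half = ERNA_WINDOW_WIDTH // 2
    records = []
    for i, row in enumerate(atac.itertuples(index=False)):
        if not intergenic[i] or not (in_se[i] or in_te[i]):
            continue
        center = (int(row.start) + int(row.end)) // 2
        records.append(
            {
                "chrom": str(row.chrom),
                "start": center - half,
                "end": center + half,
                "klass": "SE" if in_se[i] else "TE",
                "source": str(getattr(row, "name", f"atac{i}")),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["chrom", "start", "end", "klass", "source"]
    )


def class_response_compare(
    values_a, values_b
) -> tuple[float, tuple[float, float]]:
    """Two-sided Mann-Whitney rank-sum comparison of two value lists.

    Exact null distribution for combined n <= 20 without ties; otherwise a
    normal approximation with tie and continuity correction. Returns
    ``(p, (median_a, median_b))``. When the U statistic sits exactly at its
    null mean the two-sided p is 1 by symmetry.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both value lists must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if res.statistic == a.size * b.size / 2.0:
        p = 1.0
    return p, (float(np.median(a)), float(np.median(b)))
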