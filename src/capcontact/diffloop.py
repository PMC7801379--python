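"""Windowed differential interaction testing at binding peaks.

The quantification unit is a fixed-width window (default 10 kb) centered on
each binding peak. Within a window, the paired observations are
(fragment, replicate) units: for every member fragment and every replicate,
the normalized count under condition A is paired with the count under
condition B. Windows are compared with a two-sided Wilcoxon signed-rank test
(the paired analogue of the Mann-Whitney test; zero differences dropped),
p-values are Holm-Bonferroni adjusted across the tested family, and effect
sizes are summarized as the mean over replicates of the per-replicate log2
fold-change of window-mean normalized counts.

Windows on trans chromosomes, windows outside the viewpoint's interaction
domain, and windows within 10 kb of the probe are removed before testing;
windows with fewer than ``min_pairs`` nonzero paired differences are flagged
``too_few_pairs`` and excluded from the adjustment family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal
from scipy.stats import rankdata

from .errors import (
    ConfigurationError,
    EmptyWindowError,
    InvalidInputError,
    LabelLookupError,
    PairingError,
)
from .fragmap import FragmentMap, Viewpoint

#: Exact signed-rank null distribution is enumerated up to this many pairs;
#: beyond it a normal approximation with tie and continuity correction is used.
EXACT_PAIR_LIMIT = 25

#: Minimum nonzero paired differences required to test a window. An exact
#: two-sided signed-rank p cannot fall below 0.05 with fewer than 5 pairs.
DEFAULT_MIN_PAIRS = 5

DEFAULT_WINDOW_WIDTH = 10_000
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_ALPHA = 0.05


@dataclass
class PeakWindow:
    """A test window derived from one binding peak."""

    window_id: str
    chrom: str
    peak_start: int
    peak_end: int
    start: int
    end: int
    flags: set = field(default_factory=set)
    fragment_ids: list = field(default_factory=list)

    @property
    def testable(self) -> bool:
        return not self.flags


@dataclass
class DiffSummary:
    """Family-level summary of one comparison."""

    comparison: str
    n_tested: int
    n_significant: int
    n_increased: int
    n_decreased: int
    mean_logfc_significant: float  # NaN when n_significant == 0


# ---------------------------------------------------------------------------
# window construction and filtering
# ---------------------------------------------------------------------------


def build_windows(
    peaks: pd.DataFrame,
    width: int = DEFAULT_WINDOW_WIDTH,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[PeakWindow]:
    """Center a fixed-width window on each peak, clipping at chromosome bounds.

    ``peaks`` needs columns ``chrom``, ``start``, ``end`` and may carry a
    ``name`` column used as the window id.
    """
    if width <= 0:
        raise InvalidInputError("window width must be positive")
    windows = []
    for i, row in enumerate(peaks.itertuples(index=False)):
        chrom, pstart, pend = str(row.chrom), int(row.start), int(row.end)
        if pstart >= pend:
            raise InvalidInputError(f"peak {i}: start must precede end")
        center = (pstart + pend) // 2
        start = max(0, center - width // 2)
        end = center + width // 2
        if chrom_lengths is not None and chrom in chrom_lengths:
            end = min(end, int(chrom_lengths[chrom]))
        name = getattr(row, "name", None)
        wid = str(name) if name not in (None, "") else f"w{i:05d}_{chrom}_{center}"
        windows.append(
            PeakWindow(
                window_id=wid,
                chrom=chrom,
                peak_start=pstart,
                peak_end=pend,
                start=start,
                end=end,
            )
        )
    return windows


def filter_windows(
    windows: Iterable[PeakWindow],
    vp: Viewpoint,
    domains: Sequence[tuple[int, int]],
) -> list[PeakWindow]:
    """Flag windows that must not enter testing for this viewpoint.

    Flags set: ``trans`` (different chromosome), ``outside_domain`` (no
    overlap with any interaction-domain interval) and ``near_probe`` (window
    comes within the analysis exclusion radius of the probe: gap < radius or
    overlap). Only unflagged windows proceed to testing.
    """
    domains = list(domains)
    if not domains:
        raise ConfigurationError(
            f"no interaction domains supplied for viewpoint {vp.name!r}"
        )
    out = []
    for w in windows:
        flags = set(w.flags)
        if w.chrom != vp.chrom:
            flags.add("trans")
        else:
            if not any(w.start < de and ds < w.end for ds, de in domains):
                flags.add("outside_domain")
            if vp.gap_to(w.start, w.end) < vp.analysis_exclusion_radius:
                flags.add("near_probe")
        out.append(
            PeakWindow(
                window_id=w.window_id,
                chrom=w.chrom,
                peak_start=w.peak_start,
                peak_end=w.peak_end,
                start=w.start,
                end=w.end,
                flags=flags,
                fragment_ids=list(w.fragment_ids),
            )
        )
    return out


def attach_fragments(windows: Iterable[PeakWindow], fmap: FragmentMap) -> None:
    """Populate member fragments for unflagged windows (in place)."""
    for w in windows:
        if w.testable:
            w.fragment_ids = fmap.fragments_in_interval(w.chrom, w.start, w.end)


# ---------------------------------------------------------------------------
# the paired rank test
# ---------------------------------------------------------------------------


def signed_rank_p(diffs: np.ndarray) -> tuple[float | None, int]:
    """Two-sided Wilcoxon signed-rank p for a vector of paired differences.

    Zero differences are dropped (Wilcoxon convention). With ``n`` remaining
    pairs up to :data:`EXACT_PAIR_LIMIT` the exact null distribution of the
    positive-rank sum is enumerated by dynamic programming over (doubled)
    midranks, so ties are handled exactly; beyond that a normal approximation
    with tie correction (variance = sum of squared ranks / 4) and a 0.5
    continuity correction is used.

    Returns ``(p, n_pairs)``; ``p`` is ``None`` when ``n_pairs == 0``.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return None, 0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_PAIR_LIMIT:
        # Doubled midranks are integers; count sign assignments by their
        # positive-rank sum. 2**n fits comfortably in float64 for n <= 25.
        r2 = np.rint(2 * ranks).astype(np.int64)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for x in r2:
            shifted = np.zeros_like(counts)
            shifted[x:] = counts[: total + 1 - x]
            counts += shifted
        w2 = int(round(2 * w_plus))
        cdf = np.cumsum(counts)
        denom = 2.0**n
        p_le = cdf[w2] / denom
        p_ge = (denom - (cdf[w2 - 1] if w2 > 0 else 0.0)) / denom
        return min(1.0, 2.0 * min(p_le, p_ge)), n

    mean = n * (n + 1) / 4.0
    var = float((ranks**2).sum()) / 4.0
    if var == 0:
        return 1.0, n
    z = w_plus - mean
    z -= 0.5 * np.sign(z)  # continuity correction
    p = 2.0 * _normal.sf(abs(z) / math.sqrt(var))
    return min(1.0, float(p)), n


def _paired_arrays(
    window: PeakWindow,
    table: pd.DataFrame,
    cond_a: str,
    cond_b: str,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(n_fragments x n_replicates) count matrices for the two conditions.

    Missing (fragment, replicate) rows contribute 0 counts. Replicates are
    matched by label across conditions.
    """
    if not window.fragment_ids:
        raise EmptyWindowError(f"window {window.window_id!r} has no member fragments")
    present = set(table["condition"].unique())
    for cond in (cond_a, cond_b):
        if cond not in present:
            raise LabelLookupError(f"condition {cond!r} not present in table")
    sub = table[table["condition"].isin([cond_a, cond_b])]
    reps_a = set(sub.loc[sub["condition"] == cond_a, "replicate"])
    reps_b = set(sub.loc[sub["condition"] == cond_b, "replicate"])
    if reps_a != reps_b:
        raise PairingError(
            f"replicate labels differ between conditions: {sorted(reps_a)} vs "
            f"{sorted(reps_b)}"
        )
    reps = sorted(reps_a)
    wsub = sub[sub["fragment_id"].isin(window.fragment_ids)]
    piv = wsub.pivot_table(
        index="fragment_id",
        columns=["condition", "replicate"],
        values="norm_count",
        aggfunc="sum",
        fill_value=0.0,
    ).reindex(window.fragment_ids, fill_value=0.0)
    a = np.column_stack(
        [
            piv[(cond_a, r)].to_numpy() if (cond_a, r) in piv else np.zeros(len(piv))
            for r in reps
        ]
    )
    b = np.column_stack(
        [
            piv[(cond_b, r)].to_numpy() if (cond_b, r) in piv else np.zeros(len(piv))
            for r in reps
        ]
    )
    return a, b, reps


def paired_window_test(
    window: PeakWindow,
    table: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> tuple[float | None, int]:
    """Paired signed-rank test on one window's (fragment, replicate) units.

    Returns ``(p_raw, n_pairs)``. When fewer than ``min_pairs`` nonzero
    differences remain, the window is flagged ``too_few_pairs`` (in place)
    and no p is returned.
    """
    a, b, _ = _paired_arrays(window, table, cond_a, cond_b)
    p, n = signed_rank_p((b - a).ravel())
    if n < min_pairs:
        window.flags.add("too_few_pairs")
        return None, n
    return p, n


def window_logfc(
    window: PeakWindow,
    table: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[list[float], float]:
    """Per-replicate and mean log2 fold-change of window-mean counts (b vs a)."""
    a, b, _ = _paired_arrays(window, table, cond_a, cond_b)
    per_rep = np.log2((b.mean(axis=0) + pseudocount) / (a.mean(axis=0) + pseudocount))
    return [float(x) for x in per_rep], float(per_rep.mean())


# ---------------------------------------------------------------------------
# multiple testing and summaries
# ---------------------------------------------------------------------------


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm-Bonferroni adjustment, preserving input order.

    ``adj(i) = max_{j <= i} (m - j + 1) * p_(j)`` along the ascending sort,
    capped at 1 and mapped back to the original positions.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = (m - np.arange(m)) * p[order]
    adj = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def classify_direction(p_adj: float, mean_logfc: float, alpha: float) -> str:
    if np.isfinite(p_adj) and p_adj < alpha:
        if mean_logfc > 0:
            return "increased"
        if mean_logfc < 0:
            return "decreased"
    return "unchanged"


def differential_summary(
    results: pd.DataFrame, alpha: float = DEFAULT_ALPHA, comparison: str = ""
) -> DiffSummary:
    """Summarize one comparison family of per-window results.

    ``results`` must carry ``p_raw``, ``p_adj`` and ``mean_logfc`` columns;
    rows with missing ``p_raw`` (untested windows) are not part of the family.
    """
    tested = results[results["p_raw"].notna()]
    sig = tested[tested["p_adj"] < alpha]
    n_inc = int((sig["mean_logfc"] > 0).sum())
    n_dec = int((sig["mean_logfc"] < 0).sum())
    mean_sig = float(sig["mean_logfc"].mean()) if len(sig) else float("nan")
    return DiffSummary(
        comparison=comparison,
        n_tested=int(len(tested)),
        n_significant=int(len(sig)),
        n_increased=n_inc,
        n_decreased=n_dec,
        mean_logfc_significant=mean_sig,
    )


# ---------------------------------------------------------------------------
# the per-viewpoint engine
# ---------------------------------------------------------------------------


def run_differential(
    table: pd.DataFrame,
    fmap: FragmentMap,
    vp: Viewpoint,
    peaks: pd.DataFrame,
    domains: Sequence[tuple[int, int]],
    cond_a: str,
    cond_b: str,
    *,
    width: int = DEFAULT_WINDOW_WIDTH,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Window, filter and test all peaks against one viewpoint's profile.

    Returns one row per window with raw p-values; Holm adjustment is applied
    afterwards over the pooled family (see :func:`adjust_family`), which may
    span several viewpoints.
    """
    sub = table[(table["viewpoint"] == vp.name)]
    if sub.empty:
        raise InvalidInputError(f"no interaction rows for viewpoint {vp.name!r}")
    present = set(sub["condition"].unique())
    for cond in (cond_a, cond_b):
        if cond not in present:
            raise LabelLookupError(
                f"condition {cond!r} not present for viewpoint {vp.name!r}"
            )
    sub = sub[sub["condition"].isin([cond_a, cond_b])]
    reps_a = set(sub.loc[sub["condition"] == cond_a, "replicate"])
    reps_b = set(sub.loc[sub["condition"] == cond_b, "replicate"])
    if reps_a != reps_b:
        raise PairingError(
            f"viewpoint {vp.name!r}: replicate labels differ between conditions"
        )
    reps = sorted(reps_a)

    windows = build_windows(peaks, width, fmap.chrom_lengths())
    windows = filter_windows(windows, vp, domains)
    attach_fragments(windows, fmap)

    # One wide pivot per viewpoint; windows then slice rows by position.
    piv = sub.pivot_table(
        index="fragment_id",
        columns=["condition", "replicate"],
        values="norm_count",
        aggfunc="sum",
        fill_value=0.0,
    )
    row_of = {fid: i for i, fid in enumerate(piv.index)}
    a_mat = np.column_stack(
        [
            piv[(cond_a, r)].to_numpy() if (cond_a, r) in piv else np.zeros(len(piv))
            for r in reps
        ]
    )
    b_mat = np.column_stack(
        [
            piv[(cond_b, r)].to_numpy() if (cond_b, r) in piv else np.zeros(len(piv))
            for r in reps
        ]
    )

    records = []
    for w in windows:
        rec = {
            "viewpoint": vp.name,
            "window_id": w.window_id,
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "peak_start": w.peak_start,
            "peak_end": w.peak_end,
            "n_pairs": 0,
            "p_raw": np.nan,
            "mean_logfc": np.nan,
        }
        for i in range(len(reps)):
            rec[f"logfc_rep{i + 1}"] = np.nan
        if w.testable:
            rows = [row_of[f] for f in w.fragment_ids if f in row_of]
            n_frag = len(w.fragment_ids)
            if n_frag == 0:
                w.flags.add("too_few_pairs")
            else:
                # Fragments absent from the table contribute zero counts.
                a = np.zeros((n_frag, len(reps)))
                b = np.zeros((n_frag, len(reps)))
                present_pos = [
                    j for j, f in enumerate(w.fragment_ids) if f in row_of
                ]
                if rows:
                    a[present_pos] = a_mat[rows]
                    b[present_pos] = b_mat[rows]
                p, n = signed_rank_p((b - a).ravel())
                rec["n_pairs"] = n
                if n < min_pairs:
                    w.flags.add("too_few_pairs")
                else:
                    rec["p_raw"] = p
                    per_rep = np.log2(
                        (b.mean(axis=0) + pseudocount)
                        / (a.mean(axis=0) + pseudocount)
                    )
                    for i, v in enumerate(per_rep):
                        rec[f"logfc_rep{i + 1}"] = float(v)
                    rec["mean_logfc"] = float(per_rep.mean())
        rec["flags"] = ";".join(sorted(w.flags))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def adjust_family(
    results: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Holm-adjust the pooled family of tested windows and call directions.

    The family is every row with a raw p (i.e. unflagged windows that reached
    testing), pooled across viewpoints within one comparison.
    """
    out = results.copy()
    out["p_adj"] = np.nan
    mask = out["p_raw"].notna()
    if mask.any():
        out.loc[mask, "p_adj"] = holm_adjust(out.loc[mask, "p_raw"].to_numpy())
    out["direction"] = [
        classify_direction(pa, fc, alpha)
        for pa, fc in zip(out["p_adj"].fillna(np.inf), out["mean_logfc"].fillna(0.0))
    ]
    return out


# ---------------------------------------------------------------------------
# feature association
# ---------------------------------------------------------------------------


def association_enrichment(
    feature_peaks: pd.DataFrame,
    table: pd.DataFrame,
    vp: Viewpoint,
    domains: Sequence[tuple[int, int]],
    fmap: FragmentMap,
) -> float:
    """Ratio of feature-overlapping to average in-domain contact frequency.

    Numerator: mean normalized count (averaged over all rows, i.e. replicates)
    of in-domain fragments overlapping any feature peak. Denominator: the same
    mean over all in-domain fragments. Fragments within the probe analysis
    exclusion radius are excluded from both. Returns NaN when no feature
    fragment falls inside the domains.
    """
    domains = list(domains)
    if not domains:
        raise ConfigurationError(f"no domains for viewpoint {vp.name!r}")

    domain_frags: set[str] = set()
    for ds, de in domains:
        domain_frags.update(fmap.fragments_in_interval(vp.chrom, ds, de))
    # drop probe-proximal fragments
    keep = set()
    for fid in domain_frags:
        _, fs, fe = fmap.fragment_bounds(fid)
        if vp.gap_to(fs, fe) >= vp.analysis_exclusion_radius:
            keep.add(fid)
    domain_frags = keep
    if not domain_frags:
        return float("nan")

    feature_frags: set[str] = set()
    for row in feature_peaks.itertuples(index=False):
        if str(row.chrom) != vp.chrom:
            continue
        for ds, de in domains:
            s, e = max(int(row.start), ds), min(int(row.end), de)
            if s < e:
                feature_frags.update(fmap.fragments_in_interval(vp.chrom, s, e))
    feature_frags &= domain_frags
    if not feature_frags:
        return float("nan")

    sub = table[table["viewpoint"] == vp.name]
    per_frag = sub.groupby("fragment_id")["norm_count"].mean()
    per_frag = per_frag.reindex(sorted(domain_frags), fill_value=0.0)
    denom = float(per_frag.mean())
    numer = float(per_frag.loc[sorted(feature_frags)].mean())
    if denom == 0:
        return float("nan")
    return numer / denom
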