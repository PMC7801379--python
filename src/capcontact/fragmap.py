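"""Restriction-fragment coordinate maps and interaction-count normalization.

A :class:`FragmentMap` partitions each chromosome into a gapless, sorted run
of restriction fragments (0-based, half-open, BED-compatible). It is the
coordinate backbone for all fragment-level interaction data: counts are keyed
by ``fragment_id`` (``"<chrom>_<ordinal>"``), and window/domain bookkeeping is
resolved against the map.

:func:`digest_sequence` builds a single-chromosome map by in-silico digestion
(cut 5' of every motif occurrence, the DpnII ``^GATC`` convention);
:func:`normalize_interactions` rescales raw per-fragment counts to a fixed
number of reported cis reads per (viewpoint, replicate, condition), after
removing fragments inside the viewpoint exclusion zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ChromosomeLookupError,
    DegenerateLibraryError,
    InvalidInputError,
    ParseError,
)

_SEQ_ALPHABET = frozenset("ACGTN")
_MOTIF_ALPHABET = frozenset("ACGT")

#: Column order of the tab-separated interaction-table interchange format.
INTERACTION_COLUMNS = [
    "viewpoint",
    "fragment_id",
    "chrom",
    "start",
    "end",
    "replicate",
    "condition",
    "raw_count",
    "norm_count",
    "flags",
]


@dataclass(frozen=True)
class Viewpoint:
    """A Capture-C viewpoint: the captured probe interval plus exclusion radii.

    Parameters
    ----------
    name, chrom
        Viewpoint label and the chromosome carrying the probe.
    start, end
        Probe hybridization interval, 0-based half-open. Must lie within a
        single fragment of the map used for analysis.
    exclusion_radius
        Fragments closer than this (bp) to the probe are zeroed during
        normalization (default 1,000).
    analysis_exclusion_radius
        Windows closer than this (bp) to the probe are removed from
        differential testing (fixed at 10,000 in the source protocol).
    """

    name: str
    chrom: str
    start: int
    end: int
    exclusion_radius: int = 1_000
    analysis_exclusion_radius: int = 10_000

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InvalidInputError(
                f"viewpoint {self.name!r}: probe start must precede end"
            )
        if self.exclusion_radius < 0 or self.analysis_exclusion_radius < 0:
            raise InvalidInputError(f"viewpoint {self.name!r}: radii must be >= 0")

    def gap_to(self, start: int, end: int) -> int:
        """Edge-to-edge gap (bp) between the probe and ``[start, end)``; 0 if
        they overlap or abut."""
        return max(start - self.end, self.start - end, 0)


class FragmentMap:
    """Gapless partition of chromosomes into restriction fragments.

    Fragments within a chromosome are non-overlapping, sorted and tile
    ``[0, chrom_length)`` exactly; zero-length fragments are rejected.
    """

    def __init__(self) -> None:
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # -- construction -----------------------------------------------------

    def add_chromosome(
        self, chrom: str, starts: Sequence[int], ends: Sequence[int]
    ) -> None:
        starts_a = np.asarray(starts, dtype=np.int64)
        ends_a = np.asarray(ends, dtype=np.int64)
        if starts_a.size == 0 or starts_a.size != ends_a.size:
            raise InvalidInputError(f"{chrom}: empty or ragged fragment arrays")
        if starts_a[0] != 0:
            raise InvalidInputError(f"{chrom}: fragments must start at 0")
        if np.any(ends_a <= starts_a):
            raise InvalidInputError(f"{chrom}: zero-length fragment")
        if np.any(starts_a[1:] != ends_a[:-1]):
            raise InvalidInputError(f"{chrom}: fragments must tile without gaps")
        if chrom in self._chroms:
            raise InvalidInputError(f"duplicate chromosome {chrom!r}")
        self._chroms[chrom] = (starts_a, ends_a)

    # -- introspection ----------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def chrom_length(self, chrom: str) -> int:
        return int(self._bounds(chrom)[1][-1])

    def chrom_lengths(self) -> dict[str, int]:
        return {c: int(e[-1]) for c, (_, e) in self._chroms.items()}

    def n_fragments(self, chrom: str) -> int:
        return int(self._bounds(chrom)[0].size)

    def _bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self._chroms[chrom]
        except KeyError:
            raise ChromosomeLookupError(f"unknown chromosome {chrom!r}") from None

    @staticmethod
    def fragment_id(chrom: str, index: int) -> str:
        return f"{chrom}_{index}"

    @staticmethod
    def parse_id(fragment_id: str) -> tuple[str, int]:
        chrom, _, idx = fragment_id.rpartition("_")
        if not chrom or not idx.isdigit():
            raise InvalidInputError(f"malformed fragment_id {fragment_id!r}")
        return chrom, int(idx)

    def fragment_bounds(self, fragment_id: str) -> tuple[str, int, int]:
        """Return ``(chrom, start, end)`` for a fragment id."""
        chrom, idx = self.parse_id(fragment_id)
        starts, ends = self._bounds(chrom)
        if idx >= starts.size:
            raise ChromosomeLookupError(
                f"fragment index {idx} out of range on {chrom!r}"
            )
        return chrom, int(starts[idx]), int(ends[idx])

    def fragment_ids(self, chrom: str) -> list[str]:
        return [self.fragment_id(chrom, i) for i in range(self.n_fragments(chrom))]

    def iter_fragments(self) -> Iterator[tuple[str, int, int, str]]:
        for chrom, (starts, ends) in self._chroms.items():
            for i in range(starts.size):
                yield chrom, int(starts[i]), int(ends[i]), self.fragment_id(chrom, i)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for chrom, (starts, ends) in self._chroms.items():
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "fragment_id": [
                            self.fragment_id(chrom, i) for i in range(starts.size)
                        ],
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    # -- queries ----------------------------------------------------------

    def fragment_index_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Half-open ordinal range of fragments overlapping ``[start, end)``."""
        if start >= end:
            raise InvalidInputError("interval start must precede end")
        starts, ends = self._bounds(chrom)
        length = int(ends[-1])
        if start < 0 or start >= length or end > length:
            raise ChromosomeLookupError(
                f"interval [{start}, {end}) outside {chrom!r} [0, {length})"
            )
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return lo, hi

    def fragments_in_interval(self, chrom: str, start: int, end: int) -> list[str]:
        """Fragment ids with >= 1 bp overlap with ``[start, end)``, in order."""
        lo, hi = self.fragment_index_range(chrom, start, end)
        return [self.fragment_id(chrom, i) for i in range(lo, hi)]

    # -- BED4 interchange -------------------------------------------------

    def to_bed(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for chrom, start, end, fid in self.iter_fragments():
                fh.write(f"{chrom}\t{start}\t{end}\t{fid}\n")

    @classmethod
    def from_bed(cls, path) -> "FragmentMap":
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer coordinates"
                    ) from None
                if start < 0 or start >= end:
                    raise ParseError(f"{path}:{lineno}: invalid interval")
                per_chrom.setdefault(parts[0], []).append((start, end))
        fmap = cls()
        for chrom, ivals in per_chrom.items():
            ivals.sort()
            starts = [s for s, _ in ivals]
            ends = [e for _, e in ivals]
            fmap.add_chromosome(chrom, starts, ends)
        return fmap


def digest_sequence(seq: str, motif: str, chrom: str = "chr1") -> FragmentMap:
    """In-silico digestion: cut 5' of every motif occurrence.

    Overlapping motif occurrences each contribute a cut site. Terminal
    fragments are retained; zero-length fragments (e.g. a motif at position 0)
    are dropped, so the result always tiles ``[0, len(seq))`` exactly.

    Parameters
    ----------
    seq
        DNA sequence over ``{A, C, G, T, N}`` (case-insensitive).
    motif
        Recognition motif over ``{A, C, G, T}``; no ambiguity codes.
    chrom
        Name given to the single output chromosome.
    """
    if not seq:
        raise InvalidInputError("empty sequence")
    if not motif:
        raise InvalidInputError("empty motif")
    seq_u = seq.upper()
    motif_u = motif.upper()
    if not set(seq_u) <= _SEQ_ALPHABET:
        raise InvalidInputError("sequence contains characters outside {A,C,G,T,N}")
    if not set(motif_u) <= _MOTIF_ALPHABET:
        raise InvalidInputError("motif contains characters outside {A,C,G,T}")

    cuts = []
    pos = seq_u.find(motif_u)
    while pos != -1:
        cuts.append(pos)
        pos = seq_u.find(motif_u, pos + 1)

    boundaries = sorted({0, *cuts, len(seq_u)})
    starts = [b for b, e in zip(boundaries[:-1], boundaries[1:]) if e > b]
    ends = [e for b, e in zip(boundaries[:-1], boundaries[1:]) if e > b]
    fmap = FragmentMap()
    fmap.add_chromosome(chrom, starts, ends)
    return fmap


def _attach_coordinates(table: pd.DataFrame, fmap: FragmentMap) -> pd.DataFrame:
    """Fill chrom/start/end columns from the map, validating fragment ids."""
    out = table.copy()
    frame = fmap.to_frame().set_index("fragment_id")
    unknown = set(out["fragment_id"].unique()) - set(frame.index)
    if unknown:
        raise ChromosomeLookupError(
            f"fragment ids not in map: {sorted(unknown)[:5]}"
        )
    coords = frame.loc[out["fragment_id"]]
    out["chrom"] = coords["chrom"].to_numpy()
    out["start"] = coords["start"].to_numpy()
    out["end"] = coords["end"].to_numpy()
    return out


def normalize_interactions(
    table: pd.DataFrame,
    fmap: FragmentMap,
    vp: Viewpoint,
    scale: float = 100_000.0,
) -> pd.DataFrame:
    """Normalize raw fragment counts for one viewpoint.

    For each (replicate, condition) of ``vp``, the normalization total ``T``
    is the sum of raw counts over cis fragments outside the viewpoint
    exclusion radius; every count is rescaled by ``scale / T``. Fragments
    inside the exclusion zone get ``norm_count = 0`` and are flagged
    ``excluded``; trans fragments are rescaled by the same ``T`` and flagged
    ``trans`` (never dropped).

    Raises
    ------
    DegenerateLibraryError
        If ``T == 0`` for any (replicate, condition), naming the sample.
    """
    if scale <= 0:
        raise InvalidInputError("scale must be positive")
    sub = table.loc[table["viewpoint"] == vp.name]
    if sub.empty:
        raise InvalidInputError(f"no rows for viewpoint {vp.name!r}")
    if (sub["raw_count"] < 0).any():
        raise InvalidInputError("raw counts must be non-negative")
    if not {"chrom", "start", "end"} <= set(sub.columns):
        sub = _attach_coordinates(sub, fmap)
    else:
        sub = sub.copy()

    trans = (sub["chrom"] != vp.chrom).to_numpy()
    gap = np.maximum.reduce(
        [
            sub["start"].to_numpy() - vp.end,
            vp.start - sub["end"].to_numpy(),
            np.zeros(len(sub), dtype=np.int64),
        ]
    )
    excluded = (~trans) & (gap < vp.exclusion_radius)

    raw = sub["raw_count"].to_numpy(dtype=float)
    norm = np.zeros(len(sub), dtype=float)
    for (rep, cond), idx in sub.groupby(
        ["replicate", "condition"], sort=False
    ).indices.items():
        usable = (~trans[idx]) & (~excluded[idx])
        total = raw[idx][usable].sum()
        if total == 0:
            raise DegenerateLibraryError(
                f"viewpoint {vp.name!r}, replicate {rep!r}, condition {cond!r}: "
                "no cis reads outside the exclusion zone"
            )
        norm[idx] = raw[idx] * (scale / total)
    norm[excluded] = 0.0

    out = sub.copy()
    out["norm_count"] = norm
    out["excluded"] = excluded
    out["trans"] = trans
    return out


def normalize_table(
    table: pd.DataFrame,
    fmap: FragmentMap,
    viewpoints: Iterable[Viewpoint],
    scale: float = 100_000.0,
) -> pd.DataFrame:
    """Apply :func:`normalize_interactions` per viewpoint and concatenate."""
    parts = [normalize_interactions(table, fmap, vp, scale) for vp in viewpoints]
    return pd.concat(parts, ignore_index=True)


def viewpoint_from_mapping(entry: Mapping) -> Viewpoint:
    """Build a :class:`Viewpoint` from a config/TSV mapping."""
    return Viewpoint(
        name=str(entry["name"]),
        chrom=str(entry["chrom"]),
        start=int(entry["start"]),
        end=int(entry["end"]),
        exclusion_radius=int(entry.get("exclusion_radius", 1_000)),
        analysis_exclusion_radius=int(entry.get("analysis_exclusion_radius", 10_000)),
    )
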