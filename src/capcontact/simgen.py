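"""Truth-tagged synthetic data with the statistical structure the pipeline
assumes.

Viewpoint contact profiles follow a power-law distance decay with
domain-bounded contrast and localized enhancer contact peaks; replicate noise
is negative-binomial (variance mu + mu^2/k); treatment effects are
multiplicative at chosen windows. Spike-in read mixtures are two-genome
multinomials around a configurable mixing share, and enhancer signal is
two-component lognormal (SE vs TE) with class-dependent nascent-RNA
responses.

Determinism contract: a single integer seed feeds one generator family;
sub-streams are derived per output (fragment map / capture / spike-in /
signal), so each simulated product is independent of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .chipnorm import SignalTrack, SpikeInPair
from .errors import ConfigurationError, InvalidInputError
from .fragmap import FragmentMap, Viewpoint

_STREAMS = {"fragmap": 1, "capture": 2, "spikein": 3, "signal": 4}

MIN_FRAGMENT_LENGTH = 20


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, k: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + mu^2 / k."""
    mu = np.asarray(mu, dtype=float)
    p = k / (k + mu)
    return rng.negative_binomial(k, np.clip(p, 1e-12, 1.0))


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnhancerWindowDesign:
    """A contact-enriched window with an optional treatment multiplier."""

    chrom: str
    start: int
    end: int
    contact_fold: float = 1.0  # epsilon >= 1, applied in both conditions
    multiplier: float = 1.0  # delta_w > 0, applied in the treated condition

    def __post_init__(self):
        if self.contact_fold < 1:
            raise InvalidInputError("contact_fold must be >= 1")
        if self.multiplier <= 0:
            raise InvalidInputError("treatment multiplier must be > 0")


@dataclass(frozen=True)
class SpikeSampleDesign:
    label: str
    condition: str
    true_factor: float = 1.0
    input_depth: int = 1_000_000
    ip_depth: int = 1_000_000
    spike_share: float = 0.2  # 1:4 spike:target mixing


@dataclass(frozen=True)
class SignalDesign:
    """Two-component (SE/TE) enhancer signal plus eRNA response."""

    chrom: str = "chr1"
    n_regions: int = 200
    se_fraction: float = 0.05
    region_length: int = 2_000
    spacing: int = 30_000
    offset: int = 100_000
    te_mean: float = 1.0
    se_te_ratio: float = 50.0
    sigma: float = 0.15  # lognormal shape
    erna_mean: float = 200.0
    erna_dispersion: float = 10.0
    te_log2_effect: float = 0.0
    se_log2_effect: float = -1.0
    replicates: int = 3


@dataclass(frozen=True)
class SimDesign:
    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 1_000_000})
    mean_fragment_length: int = 256
    viewpoints: tuple = ()  # (name, chrom, position) triples
    domains: dict = field(default_factory=dict)  # vp name -> [(start, end), ...]
    decay_exponent: float = 1.0
    decay_offset: float = 1_000.0
    background_intensity: float = 1.0
    outside_domain_factor: float = 0.1
    enhancer_windows: dict = field(default_factory=dict)  # vp name -> [EnhancerWindowDesign]
    replicates: int = 3
    conditions: tuple = ("control", "treated")
    depth: float = 1_000_000.0
    dispersion: float = 10.0
    spike_samples: tuple = ()
    signal: SignalDesign | None = None
    emit_sequence: bool = False

    def with_seed(self, seed: int) -> "SimDesign":
        return replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# fragment maps (and optional sequences that digest back to them)
# ---------------------------------------------------------------------------


def simulate_fragment_map(
    design: SimDesign, motif: str = "GATC"
) -> tuple[FragmentMap, dict | None]:
    """Geometric fragment lengths (floor 20 bp) tiling each chromosome.

    With ``design.emit_sequence`` a random sequence is returned per
    chromosome whose motif occurrences sit exactly at the internal fragment
    boundaries, so digestion reproduces the map byte-for-byte.
    """
    if design.mean_fragment_length < 50:
        raise InvalidInputError("mean fragment length must be >= 50 bp")
    rng = _rng(design.seed, "fragmap")
    fmap = FragmentMap()
    seqs: dict[str, str] | None = {} if design.emit_sequence else None
    for chrom, length in design.chrom_lengths.items():
        length = int(length)
        mean_extra = design.mean_fragment_length - (MIN_FRAGMENT_LENGTH - 1)
        cuts: list[int] = []
        pos = 0
        while True:
            step = (MIN_FRAGMENT_LENGTH - 1) + int(rng.geometric(1.0 / mean_extra))
            pos += step
            if pos >= length:
                break
            cuts.append(pos)
        if cuts and length - cuts[-1] < MIN_FRAGMENT_LENGTH:
            cuts.pop()
        boundaries = [0, *cuts, length]
        starts = boundaries[:-1]
        ends = boundaries[1:]
        fmap.add_chromosome(chrom, starts, ends)
        if seqs is not None:
            seqs[chrom] = _emit_sequence(rng, length, cuts, motif)
    return fmap, seqs


def _emit_sequence(
    rng: np.random.Generator, length: int, cuts: Sequence[int], motif: str
) -> str:
    bases = np.array(list("ACGT"))
    arr = bases[rng.integers(0, 4, size=length)]
    m = len(motif)
    planted = np.zeros(length, dtype=bool)
    for b in cuts:
        arr[b : b + m] = list(motif)
        planted[b : b + m] = True
    cutset = set(cuts)
    for _ in range(200):
        seq = "".join(arr)
        bad = []
        pos = seq.find(motif)
        while pos != -1:
            if pos not in cutset:
                bad.append(pos)
            pos = seq.find(motif, pos + 1)
        if not bad:
            return seq
        for o in bad:
            for j in range(o + m - 1, o - 1, -1):
                if j < length and not planted[j]:
                    offset = j - o
                    choices = [c for c in "ACGT" if c != motif[offset]]
                    arr[j] = choices[int(rng.integers(0, len(choices)))]
                    break
    raise RuntimeError("could not scrub spurious motif occurrences")


# ---------------------------------------------------------------------------
# capture profiles
# ---------------------------------------------------------------------------


def _viewpoint_objects(design: SimDesign, fmap: FragmentMap) -> list[Viewpoint]:
    vps = []
    for name, chrom, pos in design.viewpoints:
        starts_ends = fmap.fragments_in_interval(chrom, int(pos), int(pos) + 1)
        _, fs, fe = fmap.fragment_bounds(starts_ends[0])
        vps.append(Viewpoint(name=str(name), chrom=str(chrom), start=fs, end=fe))
    return vps


def simulate_capture_experiment(
    design: SimDesign, fmap: FragmentMap
) -> tuple[pd.DataFrame, pd.DataFrame, list[Viewpoint]]:
    """Raw per-fragment interaction counts for every viewpoint plus truth.

    Expected intensity at distance ``d`` from the probe center is
    ``c * L_f * (d + d0)^(-alpha)``, damped by ``outside_domain_factor``
    outside the viewpoint's domains, multiplied by ``contact_fold`` inside
    enhancer windows and additionally by the window multiplier in the treated
    condition. Per-replicate counts are negative binomial with the profile
    scaled to the library depth.
    """
    if not design.viewpoints:
        raise ConfigurationError("design has no viewpoints")
    rng = _rng(design.seed, "capture")
    cond_control, cond_treated = design.conditions
    reps = [f"r{i + 1}" for i in range(design.replicates)]
    vps = _viewpoint_objects(design, fmap)

    frames = []
    truth_rows = []
    for vp in vps:
        domains = [tuple(map(int, d)) for d in design.domains.get(vp.name, [])]
        if not domains:
            raise ConfigurationError(f"no domains for viewpoint {vp.name!r}")
        windows = list(design.enhancer_windows.get(vp.name, []))
        for w in windows:
            if not any(
                w.chrom == vp.chrom and w.start < de and ds < w.end
                for ds, de in domains
            ):
                raise ConfigurationError(
                    f"enhancer window [{w.start}, {w.end}) outside all domains "
                    f"of viewpoint {vp.name!r}"
                )

        vp_center = (vp.start + vp.end) / 2.0
        # Per-chrom arrays (avoid per-fragment python lookups).
        lam_by_chrom = {}
        for chrom in design.chrom_lengths:
            starts, ends = fmap._bounds(chrom)  # internal fast path
            centers = (starts + ends) / 2.0
            lengths = (ends - starts).astype(float)
            if chrom == vp.chrom:
                d = np.abs(centers - vp_center)
                lam = (
                    design.background_intensity
                    * lengths
                    * (d + design.decay_offset) ** (-design.decay_exponent)
                )
                in_domain = np.zeros(starts.size, dtype=bool)
                for ds, de in domains:
                    in_domain |= (centers >= ds) & (centers < de)
                lam[~in_domain] *= design.outside_domain_factor
            else:
                lam = np.full(
                    starts.size,
                    design.background_intensity
                    * design.outside_domain_factor
                    * (design.decay_offset + 1e6) ** (-design.decay_exponent),
                )
            lam_by_chrom[chrom] = lam

        # condition-specific multipliers at enhancer windows
        treated = {c: arr.copy() for c, arr in lam_by_chrom.items()}
        control = {c: arr.copy() for c, arr in lam_by_chrom.items()}
        for w in windows:
            starts, ends = fmap._bounds(w.chrom)
            centers = (starts + ends) / 2.0
            mask = (centers >= w.start) & (centers < w.end)
            control[w.chrom][mask] *= w.contact_fold
            treated[w.chrom][mask] *= w.contact_fold * w.multiplier
            truth_rows.append(
                {
                    "viewpoint": vp.name,
                    "chrom": w.chrom,
                    "start": w.start,
                    "end": w.end,
                    "contact_fold": w.contact_fold,
                    "multiplier": w.multiplier,
                    "log2_multiplier": math.log2(w.multiplier),
                }
            )
        lam_cond = {cond_control: control, cond_treated: treated}

        fids: list[str] = []
        chrom_col: list[str] = []
        start_parts = []
        end_parts = []
        for chrom in design.chrom_lengths:
            ids = fmap.fragment_ids(chrom)
            fids.extend(ids)
            chrom_col.extend([chrom] * len(ids))
            starts, ends = fmap._bounds(chrom)
            start_parts.append(starts)
            end_parts.append(ends)
        fid_arr = np.array(fids, dtype=object)
        chrom_arr = np.array(chrom_col, dtype=object)
        start_arr = np.concatenate(start_parts)
        end_arr = np.concatenate(end_parts)
        for cond in design.conditions:
            lam_all = np.concatenate(
                [lam_cond[cond][c] for c in design.chrom_lengths]
            )
            lam_norm = lam_all / lam_all.sum()
            mu = design.depth * lam_norm
            for rep in reps:
                counts = _nb_draw(rng, mu, design.dispersion)
                frames.append(
                    pd.DataFrame(
                        {
                            "viewpoint": vp.name,
                            "fragment_id": fid_arr,
                            "chrom": chrom_arr,
                            "start": start_arr,
                            "end": end_arr,
                            "replicate": rep,
                            "condition": cond,
                            "raw_count": counts.astype(np.int64),
                        }
                    )
                )

    table = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame.from_records(
        truth_rows,
        columns=[
            "viewpoint",
            "chrom",
            "start",
            "end",
            "contact_fold",
            "multiplier",
            "log2_multiplier",
        ],
    )
    return table, truth, vps


# ---------------------------------------------------------------------------
# spike-in mixtures
# ---------------------------------------------------------------------------


def simulate_spikein_counts(
    design: SimDesign,
) -> tuple[list[SpikeInPair], pd.DataFrame]:
    """Two-genome multinomial read mixtures with a planted IP depletion factor.

    Input libraries split reads (spike, target) at the mixing share; IP
    libraries multiply the target share by the sample's true factor before
    renormalizing, so the spike:target IP ratio inflates as target material is
    globally depleted.
    """
    rng = _rng(design.seed, "spikein")
    pairs = []
    truth_rows = []
    for s in design.spike_samples:
        if s.true_factor <= 0 or s.input_depth <= 0 or s.ip_depth <= 0:
            raise InvalidInputError(f"sample {s.label!r}: depths and factor must be > 0")
        share = s.spike_share
        input_counts = rng.multinomial(s.input_depth, [share, 1.0 - share])
        t_share = (1.0 - share) * s.true_factor
        ip_p = np.array([share, t_share]) / (share + t_share)
        ip_counts = rng.multinomial(s.ip_depth, ip_p)
        pairs.append(
            SpikeInPair(
                sample=s.label,
                condition=s.condition,
                input_spike_reads=int(input_counts[0]),
                input_target_reads=int(input_counts[1]),
                ip_spike_reads=int(ip_counts[0]),
                ip_target_reads=int(ip_counts[1]),
            )
        )
        truth_rows.append({"sample": s.label, "true_factor": s.true_factor})
    return pairs, pd.DataFrame.from_records(truth_rows, columns=["sample", "true_factor"])


# ---------------------------------------------------------------------------
# enhancer signal and nascent RNA
# ---------------------------------------------------------------------------


def simulate_signal_and_nascent(design: SimDesign) -> dict:
    """Bimodal per-region signal, a rendered coverage track, and eRNA counts.

    Returns a dict with ``peaks`` (chrom/start/end/name/signal), ``track``
    (a :class:`SignalTrack` stepping over the peaks), ``erna`` (long counts
    per region x condition x replicate) and ``truth`` (planted class and
    eRNA log2 effect per region).
    """
    sd = design.signal
    if sd is None:
        raise ConfigurationError("design has no signal block")
    if not 0 < sd.se_fraction < 1:
        raise InvalidInputError("se_fraction must lie in (0, 1)")
    rng = _rng(design.seed, "signal")
    n = sd.n_regions
    n_se = max(1, int(round(n * sd.se_fraction)))
    is_se = np.zeros(n, dtype=bool)
    is_se[rng.choice(n, size=n_se, replace=False)] = True

    mean_log = np.where(
        is_se,
        math.log(sd.te_mean * sd.se_te_ratio),
        math.log(sd.te_mean),
    )
    signal = rng.lognormal(mean=mean_log, sigma=sd.sigma)

    starts = sd.offset + np.arange(n) * sd.spacing
    ends = starts + sd.region_length
    names = [f"enh{i:04d}" for i in range(n)]
    peaks = pd.DataFrame(
        {"chrom": sd.chrom, "start": starts, "end": ends, "name": names, "signal": signal}
    )

    track = SignalTrack(depth=1e7, scale_state="per-1e7")
    track.add_chromosome(sd.chrom, starts, ends, signal)

    effects = np.where(is_se, sd.se_log2_effect, sd.te_log2_effect)
    erna_rows = []
    cond_control, cond_treated = design.conditions
    for i in range(n):
        for cond in (cond_control, cond_treated):
            mu = sd.erna_mean * (2.0 ** effects[i] if cond == cond_treated else 1.0)
            counts = _nb_draw(
                rng, np.full(sd.replicates, mu), sd.erna_dispersion
            )
            for r in range(sd.replicates):
                erna_rows.append(
                    {
                        "name": names[i],
                        "klass": "SE" if is_se[i] else "TE",
                        "condition": cond,
                        "replicate": f"r{r + 1}",
                        "count": int(counts[r]),
                    }
                )
    erna = pd.DataFrame.from_records(erna_rows)
    truth = pd.DataFrame(
        {"name": names, "is_super": is_se, "log2_effect": effects}
    )
    return {"peaks": peaks, "track": track, "erna": erna, "truth": truth}
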