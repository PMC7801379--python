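"""Readers/writers for the text interchange formats, run configuration and
the end-to-end pipeline.

All genomic text formats are tab-separated UTF-8 with 0-based half-open
coordinates; header/comment lines begin with ``#``. The pipeline is
deterministic given a config (including its seed): identical configs produce
byte-identical outputs, and every output file is checksummed into the run
report.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import chipnorm, diffloop, enhancers, simgen
from .chipnorm import SignalTrack, SpikeInPair
from .errors import ConfigurationError, ParseError
from .fragmap import (
    INTERACTION_COLUMNS,
    FragmentMap,
    Viewpoint,
    normalize_interactions,
)

# ---------------------------------------------------------------------------
# primitive formats
# ---------------------------------------------------------------------------


def checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_bed(path) -> pd.DataFrame:
    """BED (3-6 columns) as a DataFrame; 0-based half-open, validated."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative coordinate")
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start must precede end")
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4:
                try:
                    row["score"] = float(parts[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from None
            rows.append(row)
    return pd.DataFrame(rows)


def write_bed(df: pd.DataFrame, path, score_col: str | None = None) -> None:
    cols = ["chrom", "start", "end"]
    out = df[cols].copy()
    if "name" in df.columns:
        out["name"] = df["name"]
    elif score_col is not None:
        out["name"] = [f"r{i}" for i in range(len(df))]
    if score_col is not None:
        out["score"] = df[score_col]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> SignalTrack:
    depth = None
    state = "raw"
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#depth="):
                depth = float(line.split("=", 1)[1])
                continue
            if line.startswith("#scale_state="):
                state = line.split("=", 1)[1]
                continue
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph line") from None
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid interval")
            per_chrom.setdefault(parts[0], []).append((start, end, value))
    track = SignalTrack(depth=depth, scale_state=state)
    for chrom, ivals in per_chrom.items():
        ivals.sort()
        track.add_chromosome(
            chrom,
            [s for s, _, _ in ivals],
            [e for _, e, _ in ivals],
            [v for _, _, v in ivals],
        )
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if track.depth is not None:
            fh.write(f"#depth={track.depth:g}\n")
        fh.write(f"#scale_state={track.scale_state}\n")
        for chrom in sorted(track.data):
            s, e, v = track.data[chrom]
            for i in range(s.size):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{float(v[i])!r}\n")


def write_interactions(df: pd.DataFrame, path) -> None:
    out = df.copy()
    flags = []
    exc = out["excluded"] if "excluded" in out else pd.Series(False, index=out.index)
    trn = out["trans"] if "trans" in out else pd.Series(False, index=out.index)
    for e, t in zip(exc, trn):
        parts = []
        if e:
            parts.append("excluded")
        if t:
            parts.append("trans")
        flags.append(";".join(parts))
    out["flags"] = flags
    if "norm_count" not in out:
        out["norm_count"] = 0.0
    out[INTERACTION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_interactions(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"viewpoint": str, "fragment_id": str, "replicate": str, "condition": str},
        keep_default_na=False,
        na_values=[],
    )
    missing = set(INTERACTION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df["excluded"] = df["flags"].str.contains("excluded")
    df["trans"] = df["flags"].str.contains("trans")
    return df


def write_viewpoints(viewpoints: Iterable[Viewpoint], path) -> None:
    rows = [
        {
            "name": v.name,
            "chrom": v.chrom,
            "start": v.start,
            "end": v.end,
            "exclusion_radius": v.exclusion_radius,
            "analysis_exclusion_radius": v.analysis_exclusion_radius,
        }
        for v in viewpoints
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_viewpoints(path) -> list[Viewpoint]:
    df = pd.read_csv(path, sep="\t")
    return [
        Viewpoint(
            name=str(r["name"]),
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            exclusion_radius=int(r["exclusion_radius"]),
            analysis_exclusion_radius=int(r["analysis_exclusion_radius"]),
        )
        for _, r in df.iterrows()
    ]


def write_spike_pairs(pairs: Iterable[SpikeInPair], path) -> None:
    rows = [
        {
            "sample": p.sample,
            "condition": p.condition,
            "input_target_reads": p.input_target_reads,
            "input_spike_reads": p.input_spike_reads,
            "ip_target_reads": p.ip_target_reads,
            "ip_spike_reads": p.ip_spike_reads,
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_spike_pairs(path) -> list[SpikeInPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        SpikeInPair(
            sample=str(r["sample"]),
            condition=str(r["condition"]),
            input_target_reads=int(r["input_target_reads"]),
            input_spike_reads=int(r["input_spike_reads"]),
            ip_target_reads=int(r["ip_target_reads"]),
            ip_spike_reads=int(r["ip_spike_reads"]),
        )
        for _, r in df.iterrows()
    ]


def read_domains(path) -> dict[str, list[tuple[int, int]]]:
    """Domains BED: the name column carries the owning viewpoint."""
    df = read_bed(path)
    if "name" not in df.columns:
        raise ParseError(f"{path}: domain BED needs a name column (viewpoint)")
    out: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.name), []).append((int(row.start), int(row.end)))
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_PARAMS = {
    "window_width": diffloop.DEFAULT_WINDOW_WIDTH,
    "min_pairs": diffloop.DEFAULT_MIN_PAIRS,
    "pseudocount": diffloop.DEFAULT_PSEUDOCOUNT,
    "alpha": diffloop.DEFAULT_ALPHA,
    "scale": 100_000.0,
    "min_dist": enhancers.DEFAULT_STITCH_DIST,
    "flank": 5_000,
    "bin": 100,
}


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg


def validate_config(cfg: Mapping, base: Path) -> dict:
    """Resolve defaults and check cross-references before any computation."""
    out = dict(cfg)
    out.setdefault("seed", 0)
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params", {}))
    out["params"] = params
    design = dict(cfg.get("design", {}))
    conditions = list(design.get("conditions", ["control", "treated"]))
    comparisons = [list(c) for c in design.get("comparisons", [conditions[:2]])]
    for a, b in comparisons:
        if a not in conditions or b not in conditions:
            raise ConfigurationError(
                f"comparison {a!r} vs {b!r} references undeclared conditions"
            )
    design["conditions"] = conditions
    design["comparisons"] = comparisons
    out["design"] = design
    if "simulate" not in cfg:
        paths = cfg.get("paths")
        if not paths:
            raise ConfigurationError("config needs either a simulate or a paths block")
        for key, p in paths.items():
            if not (base / p).exists():
                raise ConfigurationError(f"input path {key}={p!r} does not exist")
    return out


def build_sim_design(block: Mapping, seed: int) -> simgen.SimDesign:
    windows = {
        vp: [simgen.EnhancerWindowDesign(**w) for w in ws]
        for vp, ws in block.get("enhancer_windows", {}).items()
    }
    spikes = tuple(
        simgen.SpikeSampleDesign(**s) for s in block.get("spike_samples", [])
    )
    signal = block.get("signal")
    signal_design = simgen.SignalDesign(**signal) if signal else None
    return simgen.SimDesign(
        seed=seed,
        chrom_lengths=dict(block.get("chrom_lengths", {"chr1": 1_000_000})),
        mean_fragment_length=int(block.get("mean_fragment_length", 256)),
        viewpoints=tuple(
            (v["name"], v["chrom"], int(v["pos"])) for v in block.get("viewpoints", [])
        ),
        domains={k: [tuple(d) for d in v] for k, v in block.get("domains", {}).items()},
        decay_exponent=float(block.get("decay_exponent", 1.0)),
        decay_offset=float(block.get("decay_offset", 1_000.0)),
        background_intensity=float(block.get("background_intensity", 1.0)),
        outside_domain_factor=float(block.get("outside_domain_factor", 0.1)),
        enhancer_windows=windows,
        replicates=int(block.get("replicates", 3)),
        conditions=tuple(block.get("conditions", ("control", "treated"))),
        depth=float(block.get("depth", 1_000_000.0)),
        dispersion=float(block.get("dispersion", 10.0)),
        spike_samples=spikes,
        signal=signal_design,
        emit_sequence=bool(block.get("emit_sequence", False)),
    )


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def run_pipeline(cfg: Mapping, base_dir) -> dict:
    """Execute simulate -> normalize -> diff (-> chip/enhancer/eRNA stages).

    Returns the run report (also written to ``<outdir>/report.json``):
    per-stage inputs, parameters, output paths with sha256 checksums and row
    counts.
    """
    base = Path(base_dir)
    cfg = validate_config(cfg, base)
    params = cfg["params"]
    outdir = base / cfg.get("outdir", "out")
    inputs_dir = outdir / "inputs"
    results_dir = outdir / "results"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    results_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": cfg["seed"], "params": params, "stages": {}, "files": {}}

    def record(stage: str, outputs: Mapping[str, Path], **extra) -> None:
        rec = {"outputs": {}, **extra}
        for label, p in outputs.items():
            digest = checksum(p)
            rec["outputs"][label] = {"path": str(p.relative_to(outdir)), "sha256": digest}
            report["files"][str(p.relative_to(outdir))] = digest
        report["stages"][stage] = rec

    # -- simulate ---------------------------------------------------------
    if "simulate" in cfg:
        design = build_sim_design(cfg["simulate"], int(cfg["seed"]))
        fmap, _ = simgen.simulate_fragment_map(design)
        table, truth, vps = simgen.simulate_capture_experiment(design, fmap)
        fmap.to_bed(inputs_dir / "fragment_map.bed")
        write_viewpoints(vps, inputs_dir / "viewpoints.tsv")
        table["norm_count"] = 0.0
        write_interactions(table, inputs_dir / "interactions_raw.tsv")
        peaks = truth[["chrom", "start", "end"]].copy()
        peaks["name"] = [f"pk{i:05d}" for i in range(len(truth))]
        write_bed(peaks, inputs_dir / "peaks.bed")
        dom_rows = []
        for vp in vps:
            for ds, de in design.domains[vp.name]:
                dom_rows.append(
                    {"chrom": vp.chrom, "start": ds, "end": de, "name": vp.name}
                )
        write_bed(pd.DataFrame(dom_rows), inputs_dir / "domains.bed")
        truth_out = truth.copy()
        truth_out.insert(0, "window_name", peaks["name"])
        truth_out.to_csv(inputs_dir / "truth_windows.tsv", sep="\t", index=False)
        outputs = {
            "fragment_map": inputs_dir / "fragment_map.bed",
            "viewpoints": inputs_dir / "viewpoints.tsv",
            "interactions_raw": inputs_dir / "interactions_raw.tsv",
            "peaks": inputs_dir / "peaks.bed",
            "domains": inputs_dir / "domains.bed",
            "truth_windows": inputs_dir / "truth_windows.tsv",
        }
        if design.spike_samples:
            pairs, spike_truth = simgen.simulate_spikein_counts(design)
            write_spike_pairs(pairs, inputs_dir / "spike_counts.tsv")
            spike_truth.to_csv(inputs_dir / "truth_spike.tsv", sep="\t", index=False)
            outputs["spike_counts"] = inputs_dir / "spike_counts.tsv"
            outputs["truth_spike"] = inputs_dir / "truth_spike.tsv"
        if design.signal is not None:
            sig = simgen.simulate_signal_and_nascent(design)
            write_bed(sig["peaks"], inputs_dir / "signal_peaks.bed", score_col="signal")
            write_bedgraph(sig["track"], inputs_dir / "signal.bedgraph")
            sig["erna"].to_csv(inputs_dir / "erna_counts.tsv", sep="\t", index=False)
            sig["truth"].to_csv(inputs_dir / "truth_signal.tsv", sep="\t", index=False)
            outputs.update(
                {
                    "signal_peaks": inputs_dir / "signal_peaks.bed",
                    "signal_track": inputs_dir / "signal.bedgraph",
                    "erna_counts": inputs_dir / "erna_counts.tsv",
                    "truth_signal": inputs_dir / "truth_signal.tsv",
                }
            )
        record("simulate", outputs, n_interaction_rows=int(len(table)))
        paths = {k: str(p.relative_to(base)) for k, p in outputs.items()}
    else:
        paths = {k: str(v) for k, v in cfg["paths"].items()}

    # -- load + normalize -------------------------------------------------
    fmap = FragmentMap.from_bed(base / paths["fragment_map"])
    viewpoints = read_viewpoints(base / paths["viewpoints"])
    raw = read_interactions(base / paths["interactions"]) if "interactions" in paths \
        else read_interactions(base / paths["interactions_raw"])
    peaks = read_bed(base / paths["peaks"])
    domains = read_domains(base / paths["domains"])

    norm_parts = [
        normalize_interactions(raw, fmap, vp, float(params["scale"]))
        for vp in viewpoints
    ]
    norm = pd.concat(norm_parts, ignore_index=True)
    norm_path = results_dir / "interactions_norm.tsv"
    write_interactions(norm, norm_path)
    record("normalize", {"interactions_norm": norm_path}, scale=params["scale"])

    # -- differential testing --------------------------------------------
    summaries = []
    diff_outputs = {}
    for cond_a, cond_b in cfg["design"]["comparisons"]:
        parts = []
        for vp in viewpoints:
            if vp.name not in domains:
                raise ConfigurationError(f"no domains for viewpoint {vp.name!r}")
            parts.append(
                diffloop.run_differential(
                    norm,
                    fmap,
                    vp,
                    peaks,
                    domains[vp.name],
                    cond_a,
                    cond_b,
                    width=int(params["window_width"]),
                    min_pairs=int(params["min_pairs"]),
                    pseudocount=float(params["pseudocount"]),
                )
            )
        results = diffloop.adjust_family(
            pd.concat(parts, ignore_index=True), float(params["alpha"])
        )
        label = f"{cond_b}_vs_{cond_a}"
        rpath = results_dir / f"diff_{label}.tsv"
        results.to_csv(rpath, sep="\t", index=False)
        diff_outputs[f"diff_{label}"] = rpath
        summary = diffloop.differential_summary(
            results, float(params["alpha"]), comparison=label
        )
        summaries.append(vars(summary))
    spath = results_dir / "diff_summary.tsv"
    pd.DataFrame(summaries).to_csv(spath, sep="\t", index=False)
    diff_outputs["diff_summary"] = spath
    record("diff", diff_outputs, alpha=params["alpha"])

    # -- spike-in factors -------------------------------------------------
    spike_path = paths.get("spike_counts")
    if spike_path:
        pairs = read_spike_pairs(base / spike_path)
        reference = cfg.get("chip", {}).get("reference", pairs[0].sample)
        by_label = {p.sample: p for p in pairs}
        if reference not in by_label:
            raise ConfigurationError(f"reference sample {reference!r} not in spike table")
        rows = [
            {
                "sample": p.sample,
                "condition": p.condition,
                "factor": chipnorm.spike_in_factor(p, by_label[reference]),
            }
            for p in pairs
        ]
        fpath = results_dir / "spike_factors.tsv"
        pd.DataFrame(rows).to_csv(fpath, sep="\t", index=False)
        record("chip", {"spike_factors": fpath}, reference=reference)

    # -- enhancer classification + eRNA ----------------------------------
    sig_path = paths.get("signal_peaks")
    if sig_path:
        sig_peaks = read_bed(base / sig_path).rename(columns={"score": "signal"})
        stitched = enhancers.stitch_peaks(sig_peaks, int(params["min_dist"]))
        called, cutoff = enhancers.call_super_enhancers(stitched)
        epath = results_dir / "stitched_enhancers.tsv"
        called.to_csv(epath, sep="\t", index=False)
        ena_outputs = {"stitched_enhancers": epath}
        erna_path = paths.get("erna_counts")
        if erna_path:
            erna = pd.read_csv(base / erna_path, sep="\t")
            cond_a, cond_b = cfg["design"]["comparisons"][0]
            piv = erna.pivot_table(
                index=["name", "klass"],
                columns="condition",
                values="count",
                aggfunc="mean",
            ).reset_index()
            piv["logfc"] = np.log2((piv[cond_b] + 1.0) / (piv[cond_a] + 1.0))
            se_vals = piv.loc[piv["klass"] == "SE", "logfc"]
            te_vals = piv.loc[piv["klass"] == "TE", "logfc"]
            p, (med_se, med_te) = enhancers.class_response_compare(se_vals, te_vals)
            esum = pd.DataFrame(
                [
                    {
                        "comparison": f"{cond_b}_vs_{cond_a}",
                        "n_se": int(len(se_vals)),
                        "n_te": int(len(te_vals)),
                        "median_logfc_se": med_se,
                        "median_logfc_te": med_te,
                        "p_ranksum": p,
                    }
                ]
            )
            epath2 = results_dir / "erna_class_response.tsv"
            esum.to_csv(epath2, sep="\t", index=False)
            piv.to_csv(results_dir / "erna_logfc.tsv", sep="\t", index=False)
            ena_outputs["erna_class_response"] = epath2
            ena_outputs["erna_logfc"] = results_dir / "erna_logfc.tsv"
        record("enhancers", ena_outputs, se_cutoff=cutoff)

    # -- feature association ---------------------------------------------
    assoc_cfg = cfg.get("associate")
    if assoc_cfg:
        feature_bed = read_bed(base / assoc_cfg["features"])
        rows = []
        for vp in viewpoints:
            ratio = diffloop.association_enrichment(
                feature_bed, norm, vp, domains[vp.name], fmap
            )
            rows.append({"viewpoint": vp.name, "enrichment": ratio})
        apath = results_dir / "association.tsv"
        pd.DataFrame(rows).to_csv(apath, sep="\t", index=False)
        record("associate", {"association": apath})

    report_path = outdir / "report.json"
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
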