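"""End-to-end orchestration: simulate -> count -> normalize -> classify ->
annotate -> link -> profile, driven by one declarative YAML config.

Every stage writes its documented BED/TSV artifact into the output
directory and contributes to a machine-readable run summary
(``run_summary.json``).  Runs are fully deterministic given config + seed;
no timestamps enter any output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from chromaprime import (
    ClassParams,
    ContrastSpec,
    CountMatrix,
    SimulationConfig,
    apply_factors,
    call_dependent,
    count_cuts,
    density_matrix,
    gene_fold_changes,
    intersect_calls,
    make_windows,
    nearest_gene,
    normalize_tpm,
    pool_summits,
    rank_expression_trend,
    rank_windows,
    read_expression,
    read_intervals,
    simulate_experiment,
    topn_median_factors,
    write_intervals,
    average_profile,
)
from chromaprime.errors import ConfigError, StageError
from chromaprime.io_formats import GenomicInterval, read_tss
from chromaprime.synthetic_data import SyntheticDataset

logger = logging.getLogger(__name__)

ALL_STAGES = ("count", "normalize", "classify", "annotate", "link", "profile")


class PipelineConfig:
    """Validated view over the YAML pipeline configuration."""

    def __init__(self, data: dict[str, Any], base_dir: Path | None = None):
        self.data = data
        self.base_dir = Path(base_dir) if base_dir else Path.cwd()
        findings = validate_config(data)
        if findings:
            raise ConfigError("; ".join(findings))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data, base_dir=path.parent)

    @property
    def seed(self) -> int:
        return int(self.data.get("seed", 0))

    @property
    def out_dir(self) -> Path:
        return Path(self.data.get("out_dir", "chromaprime_out"))

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(self.data.get("stages", ALL_STAGES))

    def class_params(self) -> ClassParams:
        p = self.data.get("params", {})
        return ClassParams(
            fold_threshold=float(p.get("fold_threshold", 2.0)),
            pseudocount=float(p.get("pseudocount", 1.0)),
            min_count=float(p.get("min_count", 20.0)),
        )


def validate_config(data: dict[str, Any]) -> list[str]:
    """Return findings (empty iff the config satisfies run preconditions)."""
    findings: list[str] = []
    has_sim = "simulation" in data
    has_samples = bool(data.get("samples"))
    if has_sim == has_samples:
        findings.append("exactly one input mode required: 'simulation' or 'samples'")
    sample_conditions: dict[str, str] = {}
    if has_samples:
        seen = set()
        for i, s in enumerate(data["samples"]):
            for key in ("label", "condition", "replicate", "cuts", "summits"):
                if key not in s:
                    findings.append(f"sample #{i} missing field {key!r}")
            label = s.get("label")
            if label in seen:
                findings.append(f"duplicate sample label {label!r}")
            seen.add(label)
            if label:
                sample_conditions[label] = s.get("condition", "")
            for key in ("cuts", "summits"):
                p = s.get(key)
                if p and not Path(p).exists():
                    findings.append(f"sample {label!r}: missing file {p}")
    elif has_sim and isinstance(data["simulation"], dict):
        try:
            cfg = _sim_config(data)
            cfg.validate()
            sample_conditions = cfg.sample_conditions
        except (ConfigError, TypeError) as exc:
            findings.append(f"simulation block: {exc}")
    conditions = set(sample_conditions.values())
    for c in data.get("contrasts", []):
        for key in ("label", "condition_a", "condition_b"):
            if key not in c:
                findings.append(f"contrast missing field {key!r}")
        if conditions:
            for key in ("condition_a", "condition_b"):
                if key in c and c[key] not in conditions:
                    findings.append(
                        f"contrast {c.get('label')!r} names unknown condition {c[key]!r}"
                    )
    for key in ("tpm", "tss"):
        p = data.get("expression", {}).get(key)
        if p and not Path(p).exists():
            findings.append(f"expression: missing file {p}")
    for label, p in (data.get("annotation", {}).get("subset_beds") or {}).items():
        if not Path(p).exists():
            findings.append(f"annotation subset {label!r}: missing file {p}")
    return findings


def _sim_config(data: dict[str, Any]) -> SimulationConfig:
    block = dict(data.get("simulation", {}))
    block.setdefault("seed", int(data.get("seed", 0)))
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(block) - valid
    if unknown:
        raise ConfigError(f"unknown simulation keys {sorted(unknown)}")
    return SimulationConfig(**block)


def _build_contrasts(
    data: dict[str, Any], sample_table: pd.DataFrame
) -> list[ContrastSpec]:
    """Pair replicates positionally (rep i of A vs rep i of B)."""
    contrasts = []
    for c in data.get("contrasts", []):
        pairs = []
        by_rep_a = sample_table[sample_table["condition"] == c["condition_a"]]
        by_rep_b = sample_table[sample_table["condition"] == c["condition_b"]]
        reps = sorted(set(by_rep_a["replicate"]) & set(by_rep_b["replicate"]))
        for r in reps:
            a = by_rep_a.loc[by_rep_a["replicate"] == r, "label"].iloc[0]
            b = by_rep_b.loc[by_rep_b["replicate"] == r, "label"].iloc[0]
            pairs.append((a, b))
        if not pairs:
            raise ConfigError(f"contrast {c['label']!r}: no shared replicates")
        contrasts.append(ContrastSpec(c["label"], tuple(pairs)))
    return contrasts


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all enabled stages; returns the RunSummary dict.

    Partial outputs are removed if a stage raises, and the stage name is
    attached to the error.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "seed": config.seed,
        "params": dataclasses.asdict(config.class_params()),
        "stages": list(config.stages),
        "outputs": {},
        "sizes": {},
    }
    written: list[Path] = []
    stage = "inputs"
    try:
        dataset, sample_table, tracks, summit_sets = _load_inputs(config, out, written)
        params = config.class_params()

        stage = "count"
        union = pool_summits(
            summit_sets.values(),
            cluster_dist=int(config.data.get("cluster_dist", 200)),
        )
        windows = make_windows(union, flank=int(config.data.get("flank", 200)))
        win_bed = out / "windows.bed"
        write_intervals(
            [GenomicInterval(w.chrom, w.start, w.end, w.window_id) for w in windows],
            win_bed,
        )
        written.append(win_bed)
        raw = count_cuts(windows, tracks)
        raw_path = out / "counts_raw.tsv"
        raw.to_tsv(raw_path)
        written.append(raw_path)
        summary["sizes"]["n_union_summits"] = len(union)
        summary["sizes"]["n_windows"] = len(windows)
        summary["outputs"]["windows"] = win_bed.name
        summary["outputs"]["counts_raw"] = raw_path.name

        stage = "normalize"
        norm: CountMatrix | None = None
        if "normalize" in config.stages:
            n_top = int(config.data.get("normalization", {}).get("n_top", 25_000))
            factors = topn_median_factors(raw, n_top=n_top)
            norm = apply_factors(raw, factors)
            fpath = out / "norm_factors.tsv"
            factors.to_frame().to_csv(fpath, sep="\t", index=False)
            npath = out / "counts_normalized.tsv"
            norm.df.rename_axis("window_id").to_csv(npath, sep="\t", float_format="%.6g")
            written += [fpath, npath]
            summary["outputs"]["norm_factors"] = fpath.name
            summary["outputs"]["counts_normalized"] = npath.name
            summary["normalization"] = {
                "method": factors.method, "n_top": factors.n_top,
                "factors": {s: round(f, 6) for s, f in factors.factors.items()},
            }

        stage = "classify"
        call_sets: dict[str, Any] = {}
        contrasts: list[ContrastSpec] = []
        if "classify" in config.stages and norm is not None:
            contrasts = _build_contrasts(config.data, sample_table)
            for contrast in contrasts:
                cs = call_dependent(norm, contrast, params)
                call_sets[cs.label] = cs
                _write_call_set(cs, windows, out, written, summary)
            for pair in config.data.get("intersect", []):
                a, b = pair
                cs = intersect_calls(call_sets[a], call_sets[b])
                call_sets[cs.label] = cs
                _write_call_set(cs, windows, out, written, summary)
            if dataset is not None:
                summary["recovery"] = _recovery_vs_truth(
                    call_sets, dataset, contrasts, windows
                )

        stage = "annotate"
        if "annotate" in config.stages and call_sets:
            summary["annotation"] = _annotate(config, call_sets, windows, out, written)

        stage = "link"
        if "link" in config.stages and norm is not None:
            summary["expression"] = _link_expression(
                config, dataset, norm, windows, contrasts, out, written
            )

        stage = "profile"
        if "profile" in config.stages and norm is not None and contrasts:
            summary["profiles"] = _profiles(config, norm, windows, tracks, out, written)

        stage = "summary"
        summary["outputs"] = dict(sorted(summary["outputs"].items()))
        summary["file_hashes"] = {str(p.name): _hash_file(p) for p in sorted(set(written))}
        spath = out / "run_summary.json"
        spath.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        return summary
    except ConfigError:
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(f"stage {stage!r} failed: {exc}") from exc


def _load_inputs(config: PipelineConfig, out: Path, written: list[Path]):
    if "simulation" in config.data:
        sim_cfg = _sim_config(config.data)
        dataset = simulate_experiment(sim_cfg)
        sim_dir = out / "sim"
        manifest = dataset.write(sim_dir)
        written.extend(Path(p) for p in manifest.values())
        rows = [
            (label, cond, int(label.rsplit("_r", 1)[1]))
            for label, cond in sim_cfg.sample_conditions.items()
        ]
        table = pd.DataFrame(rows, columns=["label", "condition", "replicate"])
        return dataset, table, dataset.cut_tracks, dataset.summits
    rows, tracks, summit_sets = [], {}, {}
    for s in config.data["samples"]:
        rows.append((s["label"], s["condition"], int(s["replicate"])))
        tracks[s["label"]] = read_intervals(s["cuts"], kind="cutsite")
        summit_sets[s["label"]] = read_intervals(s["summits"], kind="summit")
    table = pd.DataFrame(rows, columns=["label", "condition", "replicate"])
    return None, table, tracks, summit_sets


def _write_call_set(cs, windows, out: Path, written: list[Path], summary: dict):
    safe = cs.label.replace("&", "_and_")
    bed = out / f"calls_{safe}.bed"
    members = [windows[w] for w in cs.members]
    write_intervals(
        [GenomicInterval(w.chrom, w.start, w.end, w.window_id) for w in members], bed
    )
    detail = out / f"calls_{safe}_detail.tsv"
    cs.to_detail_frame().rename_axis("window_id").to_csv(
        detail, sep="\t", float_format="%.6g"
    )
    written += [bed, detail]
    summary["sizes"][f"calls_{cs.label}"] = len(cs)
    summary["outputs"][f"calls_{cs.label}"] = bed.name


#: which planted class each condition contrast is designed to recover
TRUTH_CLASS_FOR_CONTRAST = {
    "A/A_nil": "dependent_primed",
    "A_stim/A_stim_nil": "dependent_primed",
    "A_stim/A": "inducible",
    "A_stim_nil/A_nil": "inducible",
}


def _recovery_vs_truth(call_sets, dataset: SyntheticDataset, contrasts, windows) -> dict:
    """Sensitivity and false-discovery proportion against the truth table.

    The pipeline assigns its own window ids, so calls are matched to
    planted windows by (chrom, summit coordinate).
    """
    out = {}
    truth = dataset.truth
    for contrast in contrasts:
        a, b = contrast.pairs[0]
        cond_pair = f"{a.rsplit('_r', 1)[0]}/{b.rsplit('_r', 1)[0]}"
        cls = TRUTH_CLASS_FOR_CONTRAST.get(cond_pair)
        if cls is None:
            continue
        sub = truth.loc[truth["class"] == cls]
        planted = set(zip(sub["chrom"], sub["summit"]))
        called = {
            (windows[w].chrom, windows[w].summit_pos)
            for w in call_sets[contrast.label].members
        }
        tp = len(called & planted)
        sens = tp / len(planted) if planted else float("nan")
        fdp = (len(called) - tp) / len(called) if called else 0.0
        out[contrast.label] = {
            "truth_class": cls, "n_called": len(called), "n_planted": len(planted),
            "sensitivity": round(sens, 4), "fdp": round(fdp, 4),
        }
    return out


def _annotate(config, call_sets, windows, out: Path, written: list[Path]) -> dict:
    from chromaprime.annotation_overlap import (
        DEFAULT_MOTIFS, nearest_distance as _nd, overlap_flags, scan_consensus,
    )

    result: dict[str, Any] = {}
    ann = config.data.get("annotation", {})
    prox = ann.get("proximity")
    if prox and prox.get("query") in call_sets and prox.get("target") in call_sets:
        q = [windows[w] for w in call_sets[prox["query"]].members]
        t = [windows[w] for w in call_sets[prox["target"]].members]
        max_dist = int(prox.get("max_dist", 25_000))
        dist = _nd(q, t, max_dist=max_dist)
        dist.insert(0, "window_id", [w.window_id for w in q])
        ppath = out / "proximity.tsv"
        dist.to_csv(ppath, sep="\t", index=False)
        written.append(ppath)
        n = len(dist)
        result["proximity"] = {
            "query": prox["query"], "target": prox["target"], "max_dist": max_dist,
            "n_query": n,
            "fraction_within": round(float(dist["within"].mean()), 4) if n else 0.0,
        }
    subset_beds = ann.get("subset_beds") or {}
    if subset_beds:
        query_label = ann.get("overlap_query") or next(iter(call_sets))
        q = [windows[w] for w in call_sets[query_label].members]
        flags = {}
        for label, path in sorted(subset_beds.items()):
            target = read_intervals(path, kind="peak")
            flags[label] = overlap_flags(q, target)
        from chromaprime.annotation_overlap import venn_partition
        part = venn_partition(flags)
        result["overlap"] = {
            "query": query_label,
            "per_target": {l: int(f.sum()) for l, f in flags.items()},
            "fraction_any": round(part["fraction_any"], 4),
        }
    fasta = ann.get("genome_fasta")
    if fasta:
        import pyfaidx

        genome = pyfaidx.Fasta(fasta)
        query_label = ann.get("motif_query") or next(iter(call_sets))
        q = [windows[w] for w in call_sets[query_label].members]
        motif_result = {}
        for motif in DEFAULT_MOTIFS:
            mflags, _missing = scan_consensus(q, genome, motif)
            motif_result[motif.name] = {
                "n_with_motif": int(mflags.sum()),
                "fraction": round(float(mflags.mean()), 4) if len(mflags) else 0.0,
            }
        result["motifs"] = {"query": query_label, "per_motif": motif_result,
                            "note": "consensus scan (approximate)"}
    return result


def _link_expression(config, dataset, norm, windows, contrasts, out, written) -> dict:
    expr_cfg = config.data.get("expression", {})
    if dataset is not None:
        table = dataset.expression
        tss = dataset.tss
    elif expr_cfg.get("tpm") and expr_cfg.get("tss"):
        table = read_expression(expr_cfg["tpm"], expr_cfg.get("sample_conditions"))
        tss = read_tss(expr_cfg["tss"])
    else:
        return {"skipped": "no expression inputs"}
    logm, uq_factors = normalize_tpm(table)
    if not contrasts:
        return {"skipped": "no contrasts"}
    contrast = contrasts[0]
    samples_a = [p[0] for p in contrast.pairs]
    samples_b = [p[1] for p in contrast.pairs]
    fc = gene_fold_changes(logm, samples_a, samples_b)
    fcpath = out / "gene_log2fc.tsv"
    fc.rename_axis("gene_id").to_csv(fcpath, sep="\t", float_format="%.6g")
    written.append(fcpath)
    links = nearest_gene(windows, tss)
    lpath = out / "gene_links.tsv"
    pd.DataFrame(
        [(l.window_id, l.gene_id or "", l.distance) for l in links],
        columns=["window_id", "gene_id", "signed_distance"],
    ).to_csv(lpath, sep="\t", index=False)
    written.append(lpath)
    ranked = rank_windows(norm, contrast.pairs[0])
    series, rho = rank_expression_trend(ranked, links, fc["log2fc"])
    tpath = out / "rank_expression_trend.tsv"
    series.to_csv(tpath, sep="\t", index=False, float_format="%.6g")
    written.append(tpath)
    return {
        "contrast": contrast.label,
        "n_genes_retained": int(logm.shape[0]),
        "n_linked": sum(l.linked for l in links),
        "n_threefold": int(fc["threefold"].sum()),
        "spearman_rho": round(rho, 4),
    }


def _profiles(config, norm, windows, tracks, out, written) -> dict:
    prof_cfg = config.data.get("profiles", {})
    sample = prof_cfg.get("sample") or norm.samples[0]
    bin_width = int(prof_cfg.get("bin", 10))
    span = int(prof_cfg.get("span", 2_000))
    win_list = list(windows)
    mat = density_matrix(win_list, tracks[sample],
                         factor=norm.factors[sample] if norm.factors else 1.0,
                         bin_width=bin_width, span=span, sample=sample)
    mpath = out / f"profile_{sample}.tsv"
    mat.to_tsv(mpath)
    written.append(mpath)
    avg = average_profile(mat)
    apath = out / f"profile_{sample}_average.tsv"
    avg.rename("density").rename_axis("offset").to_csv(apath, sep="\t",
                                                       float_format="%.6g")
    written.append(apath)
    return {"sample": sample, "bin": bin_width, "span": span,
            "n_windows": int(mat.values.shape[0])}
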