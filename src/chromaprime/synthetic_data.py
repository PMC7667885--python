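"""Synthetic DNase-Seq cut-site generator with planted differential sites.

Emulates a two-factor T-blast design: cells maintained with or without a
priming cytokine (conditions ``A`` / ``A_nil``), each optionally
restimulated (``A_stim`` / ``A_stim_nil``), with ``n_replicates``
independent replicates per condition.  Three window classes are planted:

``dependent_primed``
    accessibility ``base_mean`` with the cytokine, ``base_mean /
    effect_fold`` without it (in both stimulation states) — the synthetic
    analog of a cytokine-dependent primed DHS;
``inducible``
    ``base_mean`` unstimulated, ``base_mean * effect_fold`` after
    stimulation (in both cytokine states) — an inducible DHS;
``invariant``
    ``base_mean`` everywhere.

Window counts are negative-binomial (variance ``m + dispersion * m**2``),
cut positions are Gaussian-scattered around each summit, and a uniform
background of cuts covers every chromosome.  Each planted window is linked
to a dedicated gene whose TPM tracks the window's true per-condition mean,
so the expression-linkage stage has a recoverable monotone signal.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from chromaprime.errors import ConfigError
from chromaprime.io_formats import (
    CutSite,
    ExpressionTable,
    SummitRecord,
    TssRecord,
    write_intervals,
    write_tss,
)

__all__ = ["SimulationConfig", "SyntheticDataset", "negbin_draw", "scatter_cuts",
           "simulate_experiment", "CONDITIONS"]

CONDITIONS = ("A", "A_nil", "A_stim", "A_stim_nil")

CLASS_LABELS = ("dependent_primed", "inducible", "invariant")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Defaults are chosen for desk-scale runs that preserve the study's
    effect structure: 2 replicates per condition, at-least-twofold planted
    effects (default fold 4), negative-binomial counts, 60-bp cut scatter.
    """

    n_chroms: int = 2
    chrom_length: int = 25_000_000
    n_dependent_primed: int = 200
    n_inducible: int = 200
    n_invariant: int = 2_000
    n_background_noise_windows: int = 0
    base_mean: float = 50.0
    effect_fold: float = 4.0
    dispersion: float = 0.1
    depth_factor: dict[str, float] = field(default_factory=dict)
    cut_sd: float = 60.0
    background_rate: float = 0.002
    n_replicates: int = 2
    n_genes: int = 200
    expression_gain: float = 1.0
    expression_noise_sd: float = 0.25
    min_spacing: int = 20_000
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_dependent_primed, self.n_inducible, self.n_invariant,
                  self.n_background_noise_windows, self.n_genes)
        if any(c < 0 for c in counts):
            raise ConfigError("window/gene counts must be >= 0")
        if self.effect_fold <= 1:
            raise ConfigError("effect_fold must be > 1")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.base_mean < 0 or self.background_rate < 0:
            raise ConfigError("base_mean and background_rate must be >= 0")
        if self.n_replicates < 1 or self.n_chroms < 1 or self.chrom_length < 1:
            raise ConfigError("n_replicates, n_chroms, chrom_length must be >= 1")
        if self.min_spacing < 1:
            raise ConfigError("min_spacing must be >= 1")
        total = self.total_windows
        capacity = self.n_chroms * (self.chrom_length // self.min_spacing)
        if total > capacity:
            raise ConfigError(
                f"{total} windows do not fit {self.n_chroms} chromosome(s) of "
                f"{self.chrom_length} bp at {self.min_spacing} bp spacing"
            )
        bad = [s for s, d in self.depth_factor.items() if d <= 0]
        if bad:
            raise ConfigError(f"non-positive depth_factor for samples {bad}")

    @property
    def total_windows(self) -> int:
        return (self.n_dependent_primed + self.n_inducible + self.n_invariant
                + self.n_background_noise_windows)

    @property
    def sample_labels(self) -> list[str]:
        return [f"{cond}_r{i + 1}" for cond in CONDITIONS for i in range(self.n_replicates)]

    @property
    def sample_conditions(self) -> dict[str, str]:
        return {f"{cond}_r{i + 1}": cond
                for cond in CONDITIONS for i in range(self.n_replicates)}

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class SyntheticDataset:
    """Generated tracks, summits, truth labels and linked expression."""

    config: SimulationConfig
    cut_tracks: dict[str, list[CutSite]]
    summits: dict[str, list[SummitRecord]]
    truth: pd.DataFrame  # window_id, chrom, summit, class, mean_<cond>..., gene_id
    tss: list[TssRecord]
    expression: ExpressionTable

    def truth_ids(self, label: str) -> set[str]:
        return set(self.truth.loc[self.truth["class"] == label, "window_id"])

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write all artifacts as BED/TSV; returns a name -> path manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, str] = {}
        for sample, cuts in self.cut_tracks.items():
            p = write_intervals(cuts, out / f"cuts_{sample}.bed")
            manifest[f"cuts_{sample}"] = str(p)
        for sample, summs in self.summits.items():
            p = write_intervals(summs, out / f"summits_{sample}.bed")
            manifest[f"summits_{sample}"] = str(p)
        truth_path = out / "truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        manifest["truth"] = str(truth_path)
        manifest["tss"] = str(write_tss(self.tss, out / "tss.tsv"))
        expr_path = out / "expression_tpm.tsv"
        self.expression.tpm.rename_axis("gene_id").to_csv(expr_path, sep="\t")
        manifest["expression"] = str(expr_path)
        cfg_path = out / "sim_config.tsv"
        cfg = {k: v for k, v in asdict(self.config).items() if k != "depth_factor"}
        pd.Series(cfg, name="value").rename_axis("parameter").to_csv(cfg_path, sep="\t")
        manifest["config"] = str(cfg_path)
        return manifest


def negbin_draw(mean, dispersion: float, rng: np.random.Generator, size=None):
    """Negative-binomial draw with ``E = mean`` and ``Var = mean + a*mean**2``.

    ``dispersion == 0`` degenerates to Poisson; ``mean == 0`` always gives 0.
    Accepts scalar or array means; returns integer counts of the broadcast
    shape.
    """
    mean = np.asarray(mean, dtype=float)
    if (mean < 0).any():
        raise ValueError("mean must be >= 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        out = rng.poisson(mean, size=size)
    else:
        r = 1.0 / dispersion
        # p is the NB "success" probability in numpy's convention
        p = r / (r + np.where(mean > 0, mean, 1.0))
        out = np.where(mean > 0, rng.negative_binomial(r, p, size=size), 0)
    if np.ndim(out) == 0:
        return int(out)
    return out.astype(np.int64)


def scatter_cuts(summit_pos: int, count: int, cut_sd: float, chrom_length: int,
                 rng: np.random.Generator) -> np.ndarray:
    """``count`` integer cut positions, Gaussian around ``summit_pos``.

    Positions are rounded to the nearest base and clipped to
    ``[0, chrom_length)``.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return np.empty(0, dtype=np.int64)
    pos = np.rint(rng.normal(summit_pos, cut_sd, size=count)).astype(np.int64)
    return np.clip(pos, 0, chrom_length - 1)


def _substream(root_seed: int, label: str) -> np.random.Generator:
    """Independent generator per label; adding a sample perturbs no other."""
    digest = hashlib.sha256(f"{root_seed}:{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _class_means(cfg: SimulationConfig) -> dict[str, dict[str, float]]:
    b, f = cfg.base_mean, cfg.effect_fold
    return {
        "dependent_primed": {"A": b, "A_nil": b / f, "A_stim": b, "A_stim_nil": b / f},
        "inducible": {"A": b, "A_nil": b, "A_stim": b * f, "A_stim_nil": b * f},
        "invariant": {c: b for c in CONDITIONS},
        # low-signal decoys near the background cutoff
        "background_noise": {c: b / 10.0 for c in CONDITIONS},
    }


def _place_windows(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign summit coordinates >= min_spacing apart and shuffle class labels."""
    labels = (["dependent_primed"] * cfg.n_dependent_primed
              + ["inducible"] * cfg.n_inducible
              + ["invariant"] * cfg.n_invariant
              + ["background_noise"] * cfg.n_background_noise_windows)
    n = len(labels)
    per_chrom = cfg.chrom_length // cfg.min_spacing
    chroms, summits = [], []
    slot = 0
    for _ in range(n):
        chrom_idx, offset = divmod(slot, per_chrom)
        chroms.append(f"chr{chrom_idx + 1}")
        # center of the slot keeps neighbors >= min_spacing apart
        summits.append(offset * cfg.min_spacing + cfg.min_spacing // 2)
        slot += 1
    order = rng.permutation(n)
    df = pd.DataFrame({
        "chrom": chroms,
        "summit": summits,
        "class": [labels[i] for i in order],
    })
    df = df.sort_values(["chrom", "summit"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "window_id", [f"w{i:06d}" for i in range(len(df))])
    return df


def simulate_experiment(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic experiment, deterministic given the seed."""
    config.validate()
    layout_rng = _substream(config.seed, "layout")
    windows = _place_windows(config, layout_rng)
    means = _class_means(config)
    cond_mean = {
        cond: windows["class"].map(lambda c: means[c][cond]).to_numpy()
        for cond in CONDITIONS
    }

    cut_tracks: dict[str, list[CutSite]] = {}
    summit_sets: dict[str, list[SummitRecord]] = {}
    chrom_names = config.chrom_names()
    summit_by_chrom = {
        ch: windows.loc[windows["chrom"] == ch] for ch in chrom_names
    }
    for sample, cond in config.sample_conditions.items():
        rng = _substream(config.seed, sample)
        depth = config.depth_factor.get(sample, 1.0)
        w_means = cond_mean[cond] * depth
        counts = negbin_draw(w_means, config.dispersion, rng)
        positions: dict[str, list[np.ndarray]] = {ch: [] for ch in chrom_names}
        for (chrom, summit), c in zip(
            zip(windows["chrom"], windows["summit"]), np.atleast_1d(counts)
        ):
            if c:
                positions[chrom].append(
                    scatter_cuts(summit, int(c), config.cut_sd, config.chrom_length, rng)
                )
        for ch in chrom_names:
            n_bg = rng.poisson(config.background_rate * config.chrom_length * depth)
            if n_bg:
                positions[ch].append(
                    rng.integers(0, config.chrom_length, size=n_bg, dtype=np.int64)
                )
        track: list[CutSite] = []
        for ch in chrom_names:
            if positions[ch]:
                allpos = np.sort(np.concatenate(positions[ch]))
                track.extend(CutSite(ch, int(p)) for p in allpos)
        cut_tracks[sample] = track
        # true summits (score = true mean) are the pipeline's normal entry point
        summit_sets[sample] = [
            SummitRecord(r.chrom, int(r.summit), float(m), sample)
            for r, m in zip(windows.itertuples(index=False), w_means)
        ]

    truth = windows.copy()
    for cond in CONDITIONS:
        truth[f"mean_{cond}"] = cond_mean[cond]

    tss, expression = _linked_expression(config, truth)
    truth["gene_id"] = ["g_" + w for w in truth["window_id"]]
    return SyntheticDataset(config, cut_tracks, summit_sets, truth, tss, expression)


def _linked_expression(
    config: SimulationConfig, truth: pd.DataFrame
) -> tuple[list[TssRecord], ExpressionTable]:
    """One dedicated gene per planted window (TSS within 10 kb of the summit),
    TPM = window true mean x gain x lognormal noise, plus unlinked filler genes."""
    rng = _substream(config.seed, "expression")
    tss: list[TssRecord] = []
    rows: dict[str, list[float]] = {}
    samples = list(config.sample_conditions)
    for r in truth.itertuples(index=False):
        gene = f"g_{r.window_id}"
        offset = int(rng.integers(-10_000, 10_001))
        pos = min(max(r.summit + offset, 0), config.chrom_length - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(TssRecord(gene, r.chrom, pos, strand))
        vals = []
        for s in samples:
            m = getattr(r, f"mean_{config.sample_conditions[s]}")
            noise = rng.lognormal(0.0, config.expression_noise_sd)
            vals.append(m * config.expression_gain * noise)
        rows[gene] = vals
    for i in range(config.n_genes):
        gene = f"filler{i:05d}"
        chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
        pos = int(rng.integers(config.chrom_length))
        tss.append(TssRecord(gene, chrom, pos, "+"))
        base = rng.lognormal(np.log(10.0), 1.0)
        rows[gene] = [
            float(base * rng.lognormal(0.0, config.expression_noise_sd))
            for _ in samples
        ]
    tpm = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    tpm.index.name = "gene_id"
    return tss, ExpressionTable(tpm, config.sample_conditions)
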