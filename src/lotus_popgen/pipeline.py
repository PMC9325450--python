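"""End-to-end pipeline: simulate/read -> filter -> stats -> sweeps -> structure.

One structured config (YAML) drives every stage; all defaults — window
geometry, FST estimator, merge gap — are echoed into the run manifest so
the exact analysis conditions are always on record.  Identical config and
seed give byte-identical outputs (the manifest's timestamp field aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

import lotus_popgen
from lotus_popgen import qc, stats, structure, sweep, vcfio
from lotus_popgen.containers import GenotypeMatrix
from lotus_popgen.sim import ConfigError, Population, SimConfig, Sweep, simulate_dataset, write_fixture

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of inputs/simulate present."""

    out_dir: str
    seed: int = 0
    vcf: str | None = None
    gff: str | None = None
    popmap: str | None = None
    simulate: SimConfig | None = None
    thresholds: qc.FilterThresholds = field(default_factory=qc.FilterThresholds)
    window: stats.WindowSpec = field(default_factory=stats.WindowSpec)
    pairs: list[tuple[str, str]] = field(default_factory=lambda: [("WL", "SL")])
    q: float = 0.05
    merge_gap_bp: int = 0
    flank_bp: int = 0
    pca_components: int = 10
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        have_paths = all(p is not None for p in (self.vcf, self.gff, self.popmap))
        if have_paths == (self.simulate is not None):
            raise ConfigError("exactly one of {vcf+gff+popmap, simulate} must be given")
        if not (0.0 < self.q <= 0.5):
            raise ConfigError(f"q must be in (0, 0.5], got {self.q}")


def load_config(path: str) -> PipelineConfig:
    """Parse a YAML pipeline config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim_cfg = None
    if "simulate" in raw:
        s = dict(raw.pop("simulate"))
        s["populations"] = tuple(Population(**p) for p in s.get("populations", []))
        s["sweeps"] = tuple(Sweep(**sw) for sw in s.get("sweeps", []))
        if not s["populations"]:
            s.pop("populations")
        if not s["sweeps"]:
            s.pop("sweeps")
        sim_cfg = SimConfig(**s)
    thresholds = qc.FilterThresholds(**raw.pop("thresholds", {}))
    window = stats.WindowSpec(**raw.pop("window", {}))
    pairs = [tuple(p) for p in raw.pop("pairs", [("WL", "SL")])]
    return PipelineConfig(
        simulate=sim_cfg, thresholds=thresholds, window=window, pairs=pairs, **raw
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _infer_chrom_lengths(geno: GenotypeMatrix) -> dict[str, int]:
    out: dict[str, int] = {}
    for chrom, sub in geno.sites.groupby("chrom", sort=False):
        out[str(chrom)] = int(sub["pos"].max())
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order, writing each stage's outputs as it completes.

    Returns the run manifest (also written to ``manifest.json``).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: list[str] = []
    counts: dict[str, object] = {}

    def out(name: str) -> str:
        path = os.path.join(config.out_dir, name)
        outputs.append(path)
        return path

    # --- stage 1: simulate or read -----------------------------------------
    if config.simulate is not None:
        sim_cfg = config.simulate
        geno, truth, genes = simulate_dataset(sim_cfg)
        fixture_dir = os.path.join(config.out_dir, "fixture")
        paths = write_fixture(geno, truth, sim_cfg, fixture_dir, genes=genes)
        outputs.extend(paths.values())
        popmap = sim_cfg.popmap()
        chrom_lengths = {c: sim_cfg.chrom_length for c in sim_cfg.chrom_names()}
    else:
        geno, genes, popmap = vcfio.read_inputs(config.vcf, config.gff, config.popmap)
        chrom_lengths = config.chrom_lengths or _infer_chrom_lengths(geno)
    groups = sorted(set(popmap.values()))
    for pair in config.pairs:
        for g in pair:
            if g not in groups:
                raise ConfigError(f"pair group {g!r} absent from population map")
    counts["n_samples"] = geno.n_samples
    counts["n_sites_raw"] = geno.n_sites

    # --- stage 2: site filtering -------------------------------------------
    mask, filter_summary = qc.filter_sites(geno.sites, config.thresholds)
    counts["filter"] = filter_summary
    geno_f = geno.take_sites(mask)
    _write_tsv(
        pd.DataFrame([filter_summary]),
        out("filter_summary.tsv"),
        "site filter: pass iff depth>=min_depth & MQ>=min_mq & maf>=min_maf & miss<=max_miss (inclusive)",
    )

    # --- stage 3: region classification + sharing --------------------------
    categories = qc.classify_snp_regions(geno_f.sites, genes, flank_bp=config.flank_bp)
    region_df = geno_f.sites[["chrom", "pos"]].copy()
    region_df["category"] = categories
    _write_tsv(region_df, out("snp_regions.tsv"), "1-based positions")
    proportions = qc.region_proportions(categories)
    counts["region_proportions"] = proportions
    sharing = qc.snp_sharing(geno_f, popmap)
    counts["snp_sharing"] = {
        "per_group_total": sharing["per_group_total"],
        "common": sharing["common"],
        "unique": sharing["unique"],
    }
    share_df = pd.DataFrame(
        {
            "group": sorted(sharing["per_group_total"]),
            "present": [sharing["per_group_total"][g] for g in sorted(sharing["per_group_total"])],
            "unique": [sharing["unique"][g] for g in sorted(sharing["unique"])],
        }
    )
    share_df["common_all_groups"] = sharing["common"]
    _write_tsv(share_df, out("snp_sharing.tsv"))

    # --- stage 4: diversity / divergence ------------------------------------
    windows = stats.make_windows(config.window, chrom_lengths)
    wstats = windows.copy()
    for group in groups:
        wp = stats.windowed_pi(geno_f, popmap, windows, group)
        wstats[f"pi_{group}"] = wp[f"pi_{group}"]
        if "n_sites" not in wstats:
            wstats["n_sites"] = wp["n_sites"]
    for a, b in config.pairs:
        wf = stats.windowed_fst(geno_f, popmap, windows, (a, b))
        wstats[f"fst_{a}_{b}"] = wf[f"fst_{a}_{b}"]
    het = stats.heterozygosity(geno_f, popmap)
    _write_tsv(het, out("heterozygosity.tsv"))
    summary = stats.subgroup_summary(geno_f, popmap, windows)
    _write_tsv(summary, out("subgroup_summary.tsv"), "pi is per bp, window-averaged")
    fst_rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            try:
                fst_rows.append({"group_a": a, "group_b": b,
                                 "fst": stats.genomewide_fst(geno_f, popmap, (a, b))})
            except ValueError:
                fst_rows.append({"group_a": a, "group_b": b, "fst": float("nan")})
    _write_tsv(pd.DataFrame(fst_rows), out("pairwise_fst.tsv"),
               "Hudson estimator, genome-wide ratio of averages")
    counts["pairwise_fst"] = {f"{r['group_a']}-{r['group_b']}": r["fst"] for r in fst_rows}

    # --- stage 5: sweep scan -------------------------------------------------
    region_sets: dict[str, list[sweep.SweepRegion]] = {}
    for a, b in config.pairs:
        ratio_col, fst_col = f"log2_ratio_{a}_{b}", f"fst_{a}_{b}"
        wstats[ratio_col] = sweep.log2_pi_ratio(
            wstats[f"pi_{a}"].to_numpy(), wstats[f"pi_{b}"].to_numpy()
        )
        called = sweep.call_sweeps(wstats, fst_col, ratio_col, q=config.q)
        wstats[f"pct_fst_{a}_{b}"] = called["pct_fst"]
        wstats[f"pct_ratio_{a}_{b}"] = called["pct_ratio"]
        wstats[f"selected_{a}_{b}"] = called["selected"]
        sel = called[called["selected"]]
        regions = sweep.merge_windows(sel, fst_col, ratio_col, gap_bp=config.merge_gap_bp)
        regions, n_genes = sweep.genes_in_sweeps(regions, genes)
        region_sets[f"{a}_{b}"] = regions
        tag = f"{a}_{b}"
        _write_tsv(sweep.regions_to_frame(regions), out(f"sweeps_{tag}.tsv"),
                   "1-based closed intervals; region stats are max over member windows")
        with open(out(f"sweeps_{tag}.bed"), "w") as fh:
            fh.write(sweep.regions_to_bed(regions))
        with open(out(f"sweep_genes_{tag}.txt"), "w") as fh:
            fh.write("\n".join(sorted({g for r in regions for g in r.gene_ids})) + "\n")
        counts[f"sweeps_{tag}"] = {"n_regions": len(regions), "n_genes": n_genes,
                                   "n_selected_windows": int(sel.shape[0])}
    if len(config.pairs) >= 2:
        tags = [f"{a}_{b}" for a, b in config.pairs[:2]]
        pairs_idx, shared = sweep.sweep_overlap(region_sets[tags[0]], region_sets[tags[1]])
        counts["sweep_overlap"] = {
            "pairs": len(pairs_idx), "shared_genes": len(shared), "genes": shared,
        }
    _write_tsv(wstats, out("window_stats.tsv"),
               f"windows 1-based closed, size={config.window.size} step={config.window.step}; "
               "fst is Hudson ratio-of-averages; pi per bp")

    # --- stage 6: structure ---------------------------------------------------
    dist = structure.p_distance_matrix(geno_f)
    dist.to_csv(out("p_distance.tsv"), sep="\t", float_format="%.10g")
    tree = structure.nj_tree(dist)
    structure.write_newick(tree, out("nj_tree.nwk"))
    k = min(config.pca_components, geno_f.n_samples - 1)
    coords, explained = structure.genotype_pca(geno_f, k=k)
    coords = coords.copy()
    coords.insert(0, "sample", coords.index)
    coords["group"] = [popmap[s] for s in coords["sample"]]
    _write_tsv(coords, out("pca_coords.tsv"))
    _write_tsv(
        pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(explained))],
                      "explained_fraction": explained}),
        out("pca_explained.tsv"),
    )

    # --- manifest ---------------------------------------------------------------
    manifest = {
        "version": lotus_popgen.__version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "counts": counts,
        "outputs": {os.path.relpath(p, config.out_dir): _sha256(p) for p in sorted(outputs)},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _config_echo(config: PipelineConfig) -> dict:
    echo = {
        "out_dir": config.out_dir,
        "seed": config.seed,
        "vcf": config.vcf,
        "gff": config.gff,
        "popmap": config.popmap,
        "thresholds": asdict(config.thresholds),
        "window": asdict(config.window),
        "pairs": [list(p) for p in config.pairs],
        "q": config.q,
        "merge_gap_bp": config.merge_gap_bp,
        "flank_bp": config.flank_bp,
        "fst_estimator": "hudson_ratio_of_averages",
        "pi_denominator": "window_bp",
    }
    if config.simulate is not None:
        echo["simulate"] = asdict(config.simulate)
    return echo


def report(manifest: dict, out_dir: str, plot: bool = False) -> str:
    """Human-readable run summary recomputed from the manifest counts.

    With ``plot=True`` also writes a Manhattan-style window plot of FST and
    log2 pi-ratio with the top-q thresholds drawn.
    """
    c = manifest["counts"]
    lines = [
        f"lotus-popgen {manifest['version']} run summary (seed {manifest['seed']})",
        f"samples: {c['n_samples']}; raw SNPs: {c['n_sites_raw']}; "
        f"pass filter: {c['filter']['n_pass']} "
        f"(fail depth {c['filter']['fail_depth']}, MQ {c['filter']['fail_mq']}, "
        f"MAF {c['filter']['fail_maf']}, miss {c['filter']['fail_miss']})",
        "SNP region proportions: "
        + ", ".join(f"{k} {v:.2%}" for k, v in c["region_proportions"].items() if v > 0),
        f"SNP sharing: common {c['snp_sharing']['common']}; unique "
        + ", ".join(f"{g}={n}" for g, n in c["snp_sharing"]["unique"].items()),
        "pairwise FST: "
        + ", ".join(f"{k}={v:.4g}" for k, v in c["pairwise_fst"].items()),
    ]
    for key, val in c.items():
        if key.startswith("sweeps_"):
            lines.append(
                f"{key}: {val['n_regions']} regions, {val['n_genes']} genes, "
                f"{val['n_selected_windows']} selected windows"
            )
    if "sweep_overlap" in c:
        so = c["sweep_overlap"]
        lines.append(
            f"sweep overlap between first two pairs: {so['pairs']} region pairs, "
            f"{so['shared_genes']} shared genes"
        )
    if plot:
        _manhattan_plot(out_dir, manifest)
        lines.append(f"plot: {os.path.join(out_dir, 'sweep_scan.png')}")
    text = "\n".join(lines) + "\n"
    with open(os.path.join(out_dir, "report.txt"), "w") as fh:
        fh.write(text)
    return text


def _manhattan_plot(out_dir: str, manifest: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wstats = pd.read_csv(os.path.join(out_dir, "window_stats.tsv"), sep="\t", comment="#")
    pairs = [tuple(p) for p in manifest["config"]["pairs"]]
    q = manifest["config"]["q"]
    fig, axes = plt.subplots(2, len(pairs), figsize=(6 * len(pairs), 6), squeeze=False)
    mid = (wstats["start"] + wstats["end"]) / 2
    for col, (a, b) in enumerate(pairs):
        for row, stat in enumerate([f"fst_{a}_{b}", f"log2_ratio_{a}_{b}"]):
            ax = axes[row][col]
            vals = wstats[stat].replace([np.inf, -np.inf], np.nan)
            ax.scatter(mid, vals, s=4, c="grey")
            finite = vals.dropna()
            if len(finite):
                thr = np.quantile(finite, 1 - q)
                ax.axhline(thr, color="red", lw=1, ls="--", label=f"top {q:.0%}")
                ax.legend(frameon=False)
            ax.set_ylabel(stat)
            ax.set_xlabel("window midpoint (bp)")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "sweep_scan.png"), dpi=120)
    plt.close(fig)
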