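#!/usr/bin/env python
"""Joint top-5% selective-sweep scan of the simulated cohort.

Computes windowed Hudson FST(WL, SL) and log2(pi_WL/pi_SL) in 4 kb tiled
windows, calls windows jointly in the top 5% of both statistics, merges
them into sweep regions, attaches overlapping genes, and scores the calls
against the planted truth.  Writes results/tables/sweeps.{tsv,bed} and
sweep_genes.txt.
"""

import argparse
import os

import pandas as pd

from lotus_popgen import qc, stats, sweep
from lotus_popgen.sim import STANDARD_WINDOW
from lotus_popgen.vcfio import read_inputs


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-dir", default="results/cohort")
    ap.add_argument("--out-dir", default="results/tables")
    ap.add_argument("--q", type=float, default=0.05)
    args = ap.parse_args()
    os.makedirs(args.out_dir, exist_ok=True)

    geno, genes, popmap = read_inputs(
        os.path.join(args.cohort_dir, "cohort.vcf"),
        os.path.join(args.cohort_dir, "annotation.gff3"),
        os.path.join(args.cohort_dir, "popmap.tsv"),
    )
    mask, _ = qc.filter_sites(geno.sites)
    geno = geno.take_sites(mask)
    chrom_lengths = {str(c): int(s["pos"].max()) for c, s in geno.sites.groupby("chrom")}
    windows = stats.make_windows(stats.WindowSpec(*STANDARD_WINDOW), chrom_lengths)

    w = windows.copy()
    w["pi_WL"] = stats.windowed_pi(geno, popmap, windows, "WL")["pi_WL"]
    w["pi_SL"] = stats.windowed_pi(geno, popmap, windows, "SL")["pi_SL"]
    w["fst"] = stats.windowed_fst(geno, popmap, windows, ("WL", "SL"))["fst_WL_SL"]
    w["log2_ratio"] = sweep.log2_pi_ratio(w["pi_WL"].to_numpy(), w["pi_SL"].to_numpy())
    called = sweep.call_sweeps(w, "fst", "log2_ratio", q=args.q)
    sel = called[called["selected"]]
    print(f"{len(sel)}/{len(w)} windows jointly in the top {args.q:.0%} of FST and "
          f"log2 pi-ratio ({len(sel) / len(w):.2%})")

    regions = sweep.merge_windows(sel, "fst", "log2_ratio")
    regions, n_genes = sweep.genes_in_sweeps(regions, genes)
    sweep.regions_to_frame(regions).to_csv(
        os.path.join(args.out_dir, "sweeps.tsv"), sep="\t", index=False
    )
    with open(os.path.join(args.out_dir, "sweeps.bed"), "w") as fh:
        fh.write(sweep.regions_to_bed(regions))
    with open(os.path.join(args.out_dir, "sweep_genes.txt"), "w") as fh:
        fh.write("\n".join(sorted({g for r in regions for g in r.gene_ids})) + "\n")
    print(f"{len(regions)} merged sweep regions containing {n_genes} genes")

    truth_path = os.path.join(args.cohort_dir, "sweeps_truth.tsv")
    if os.path.exists(truth_path):
        truth = pd.read_csv(truth_path, sep="\t")
        hits = sum(
            any(r.chrom == t.chrom and r.start <= t.end and r.end >= t.start for r in regions)
            for t in truth.itertuples()
        )
        print(f"recovered {hits}/{len(truth)} planted sweep intervals")


if __name__ == "__main__":
    main()
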