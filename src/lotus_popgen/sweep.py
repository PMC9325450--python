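"""Joint top-percentile selective-sweep caller.

A window is called a sweep candidate when it lies simultaneously in the
top q (default 5%) of the empirical distribution of (a) pairwise FST
between the wild and cultivated group and (b) log2(pi_wild / pi_cultivated).
Candidate windows are merged into sweep regions and intersected with the
gene annotation.

Percentiles use mid-rank tie handling: pct(v) = 100 (#less + 0.5 #equal)/n,
which is stable under window permutation.  A window whose cultivated pi is
exactly zero while the wild pi is positive gets a +inf log-ratio sentinel
and ranks above every finite value — total diversity loss is the strongest
sweep signal, not a numerical accident to smooth away with a pseudocount
(a pseudocount mode is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from lotus_popgen.containers import GeneModel


def log2_pi_ratio(
    pi_wild: np.ndarray, pi_cult: np.ndarray, pseudocount: bool = False
) -> np.ndarray:
    """log2(pi_wild / pi_cultivated) per window.

    Zero-denominator policy: pi_cult = 0 < pi_wild -> +inf sentinel;
    both zero -> NaN (undefined, excluded from ranking).  With
    ``pseudocount=True`` both pi values get +eps, eps = half the smallest
    nonzero window pi, and every window is finite.
    """
    w = np.asarray(pi_wild, dtype=np.float64)
    c = np.asarray(pi_cult, dtype=np.float64)
    if (w < 0).any() or (c < 0).any():
        raise ValueError("negative window pi (upstream invariant violated)")
    if pseudocount:
        nz = np.concatenate([w[w > 0], c[c > 0]])
        eps = 0.5 * nz.min() if len(nz) else 1.0
        return np.log2((w + eps) / (c + eps))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(w / c)
    out[(c == 0) & (w > 0)] = np.inf
    out[(c == 0) & (w == 0)] = np.nan
    return out


def empirical_percentile(values: np.ndarray) -> np.ndarray:
    """Mid-rank empirical percentile of each value among the defined ones.

    pct(v) = 100 (#less + 0.5 #equal) / n over non-NaN values; +inf ranks
    above all finite values; NaN propagates (undefined windows stay
    unranked).  Warns when fewer than 20 windows are rankable or all values
    tie (every percentile 50; a top-5% cut selects nothing).
    """
    v = np.asarray(values, dtype=np.float64)
    out = np.full(v.shape, np.nan)
    defined = ~np.isnan(v)
    n = int(defined.sum())
    if n == 0:
        return out
    if n < 20:
        warnings.warn(
            f"only {n} rankable windows; top-percentile selection is degenerate",
            stacklevel=2,
        )
    ranks = rankdata(v[defined], method="average")  # mid-rank: #less + (#eq+1)/2
    out[defined] = 100.0 * (ranks - 0.5) / n
    finite = v[defined]
    if n > 1 and np.all(finite == finite[0]):
        warnings.warn("all window statistics identical; every percentile is 50", stacklevel=2)
    return out


def call_sweeps(
    windows: pd.DataFrame,
    fst_col: str,
    ratio_col: str,
    q: float = 0.05,
) -> pd.DataFrame:
    """Select windows jointly in the top q of FST and log2 pi-ratio.

    Adds percentile columns ``pct_fst``/``pct_ratio`` and a boolean
    ``selected`` column: selected iff both percentiles >= 100(1-q)
    (inclusive threshold; heavy ties can push the set slightly past q n,
    and are visible in the percentile columns).
    """
    if not (0.0 < q <= 0.5):
        raise ValueError(f"q must be in (0, 0.5], got {q}")
    out = windows.copy()
    out["pct_fst"] = empirical_percentile(out[fst_col].to_numpy())
    out["pct_ratio"] = empirical_percentile(out[ratio_col].to_numpy())
    cut = 100.0 * (1.0 - q)
    out["selected"] = (out["pct_fst"] >= cut) & (out["pct_ratio"] >= cut)
    return out


@dataclass
class SweepRegion:
    """Maximal union of overlapping/adjacent selected windows."""

    chrom: str
    start: int
    end: int
    n_windows: int
    max_fst: float
    max_log2_ratio: float
    gene_ids: list[str] = field(default_factory=list)


def merge_windows(
    selected: pd.DataFrame,
    fst_col: str,
    ratio_col: str,
    gap_bp: int = 0,
) -> list[SweepRegion]:
    """Merge selected windows into maximal regions.

    Windows overlapping or within ``gap_bp`` of each other (book-ended at
    gap 0: end + 1 == next start) merge; region stats are the max over
    member windows.  Input need not be sorted.
    """
    if selected.empty:
        return []
    df = selected.sort_values(["chrom", "start", "end"], kind="mergesort")
    regions: list[SweepRegion] = []
    cur = None
    for row in df.itertuples(index=False):
        w = (row.chrom, int(row.start), int(row.end), getattr(row, fst_col), getattr(row, ratio_col))
        if cur is not None and w[0] == cur.chrom and w[1] <= cur.end + 1 + gap_bp:
            cur.end = max(cur.end, w[2])
            cur.n_windows += 1
            cur.max_fst = max(cur.max_fst, w[3])
            cur.max_log2_ratio = max(cur.max_log2_ratio, w[4])
        else:
            cur = SweepRegion(w[0], w[1], w[2], 1, w[3], w[4])
            regions.append(cur)
    return regions


def genes_in_sweeps(
    regions: list[SweepRegion], genes: list[GeneModel]
) -> tuple[list[SweepRegion], int]:
    """Attach overlapping gene IDs to each region; return distinct gene total.

    A gene counts iff its [start, end] span overlaps the region by >= 1 bp
    (closed intervals: adjacency is not overlap).  The total deduplicates
    genes spanning several regions.
    """
    all_genes: set[str] = set()
    for region in regions:
        ids = [
            g.gene_id
            for g in genes
            if g.chrom == region.chrom and g.start <= region.end and g.end >= region.start
        ]
        region.gene_ids = ids
        all_genes.update(ids)
    return regions, len(all_genes)


def sweep_overlap(
    regions_a: list[SweepRegion], regions_b: list[SweepRegion]
) -> tuple[list[tuple[int, int]], list[str]]:
    """Overlapping region pairs between two sweep sets, plus shared genes.

    Returns index pairs (i into a, j into b) with >= 1 bp overlap and the
    sorted intersection of the two sets' gene lists.
    """
    pairs = [
        (i, j)
        for i, ra in enumerate(regions_a)
        for j, rb in enumerate(regions_b)
        if ra.chrom == rb.chrom and ra.start <= rb.end and ra.end >= rb.start
    ]
    genes_a = {g for r in regions_a for g in r.gene_ids}
    genes_b = {g for r in regions_b for g in r.gene_ids}
    return pairs, sorted(genes_a & genes_b)


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    """Tabulate regions (1-based closed coordinates)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "n_windows": [r.n_windows for r in regions],
            "max_fst": [r.max_fst for r in regions],
            "max_log2_ratio": [r.max_log2_ratio for r in regions],
            "genes": [",".join(r.gene_ids) for r in regions],
        }
    )


def regions_to_bed(regions: list[SweepRegion]) -> str:
    """BED serialization (0-based half-open)."""
    lines = [f"{r.chrom}\t{r.start - 1}\t{r.end}\tsweep_{i + 1}" for i, r in enumerate(regions)]
    return "\n".join(lines) + ("\n" if lines else "")
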