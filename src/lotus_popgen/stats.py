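"""Diversity and differentiation statistics: pi, Hudson FST, heterozygosity.

Per-site nucleotide diversity is the unbiased mean pairwise difference
among called alleles, ``pi = 2 ref alt / (n (n-1))``; window pi divides the
summed site values by the full window length in bp, which puts subgroup
diversity on the per-bp scale (order 1e-3 for a typical resequencing
panel).  Pairwise differentiation uses Hudson's FST with per-window
ratio-of-averages accumulation, which is robust to rare variants and, for
populations drifted from a shared ancestral pool with parameter F, is an
unbiased estimator of F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lotus_popgen.containers import GenotypeMatrix


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: size and step in bp, 1-based closed windows."""

    size: int = 100_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"window size must be positive, got {self.size}")
        if not (0 < self.step <= self.size):
            raise ValueError(f"step must satisfy 0 < step <= size, got {self.step}")


def make_windows(spec: WindowSpec, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Tile each chromosome with full-size windows by ``spec.step``.

    Returns a DataFrame with columns chrom/start/end (1-based closed).
    """
    chroms, starts = [], []
    for chrom, length in chrom_lengths.items():
        if length < spec.size:
            s = np.array([1], dtype=np.int64)  # short chromosome: one truncated window
        else:
            s = np.arange(1, length - spec.size + 2, spec.step, dtype=np.int64)
        chroms.extend([chrom] * len(s))
        starts.append(s)
    start = np.concatenate(starts) if starts else np.array([], dtype=np.int64)
    return pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=object),
            "start": start,
            "end": start + spec.size - 1,
        }
    )


def group_allele_counts(geno: GenotypeMatrix, rows: np.ndarray):
    """Called alt count and called allele total per site for a sample subset."""
    sub = geno.dosage[rows, :]
    called = sub != -1
    alt = np.where(called, sub, 0).sum(axis=0).astype(np.int64)
    n = 2 * called.sum(axis=0).astype(np.int64)
    return alt, n


def site_pi(ref_count, alt_count):
    """Unbiased per-site pi from called allele counts.

    ``pi = 2 ref alt / (n (n-1))`` — the fraction of differing pairs among
    all C(n,2) pairs of called alleles.  Sites with n < 2 return 0 and must
    be excluded from site counts by the caller (they carry no information,
    not zero diversity).
    """
    ref = np.asarray(ref_count, dtype=np.float64)
    alt = np.asarray(alt_count, dtype=np.float64)
    n = ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n >= 2, 2.0 * ref * alt / (n * (n - 1.0)), 0.0)
    if pi.ndim == 0:
        return float(pi)
    return pi


def hudson_fst_site(p1, n1, p2, n2):
    """Hudson FST per-site numerator/denominator components.

    ``N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)``;
    ``D = p1(1-p2) + p2(1-p1)``, with p the sample alt frequencies and n
    the called allele counts.  Sites with n < 2 in either group are the
    caller's responsibility to exclude.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _window_site_slices(sites: pd.DataFrame, windows: pd.DataFrame):
    """Per-window [lo, hi) site-index ranges via searchsorted per chromosome."""
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    # contiguous chromosome blocks (sites are sorted by construction)
    blocks: dict[str, tuple[int, int]] = {}
    if len(chrom_arr):
        change = np.flatnonzero(chrom_arr[1:] != chrom_arr[:-1]) + 1
        bounds = np.concatenate(([0], change, [len(chrom_arr)]))
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            blocks[chrom_arr[b0]] = (int(b0), int(b1))
    lo = np.zeros(len(windows), dtype=np.int64)
    hi = np.zeros(len(windows), dtype=np.int64)
    for i, (chrom, start, end) in enumerate(
        zip(windows["chrom"], windows["start"], windows["end"])
    ):
        if chrom not in blocks:
            continue
        b0, b1 = blocks[chrom]
        seg = pos_arr[b0:b1]
        lo[i] = b0 + np.searchsorted(seg, start, side="left")
        hi[i] = b0 + np.searchsorted(seg, end, side="right")
    return lo, hi


def _window_sums(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    cs = np.concatenate(([0.0], np.cumsum(values, dtype=np.float64)))
    return cs[hi] - cs[lo]


def windowed_pi(
    geno: GenotypeMatrix,
    popmap: dict[str, str],
    windows: pd.DataFrame,
    group: str,
) -> pd.DataFrame:
    """Per-window pi per bp for one subgroup.

    Window pi = sum of site pi over SNPs in the window divided by the
    window length in bp; positions without a SNP contribute length only.
    """
    rows = geno.group_rows(popmap).get(group)
    if rows is None or len(rows) == 0:
        raise ValueError(f"empty or unknown group {group!r}")
    alt, n = group_allele_counts(geno, rows)
    pi_site = site_pi(n - alt, alt)
    informative = (n >= 2).astype(np.float64)
    lo, hi = _window_site_slices(geno.sites, windows)
    length = (windows["end"] - windows["start"] + 1).to_numpy(dtype=np.float64)
    out = windows.copy()
    out["n_sites"] = _window_sums(informative, lo, hi).astype(np.int64)
    out[f"pi_{group}"] = _window_sums(pi_site * informative, lo, hi) / length
    return out


def windowed_fst(
    geno: GenotypeMatrix,
    popmap: dict[str, str],
    windows: pd.DataFrame,
    pair: tuple[str, str],
) -> pd.DataFrame:
    """Per-window Hudson FST (ratio of averages) for a subgroup pair.

    Sites with fewer than 2 called alleles in either group are excluded
    from the window sums.  Windows with no included sites or a zero
    denominator get NaN (undefined; excluded from percentile ranking
    downstream, never silently zeroed).
    """
    groups = geno.group_rows(popmap)
    a, b = pair
    for g in pair:
        if g not in groups or len(groups[g]) == 0:
            raise ValueError(f"empty or unknown group {g!r}")
    alt1, n1 = group_allele_counts(geno, groups[a])
    alt2, n2 = group_allele_counts(geno, groups[b])
    ok = (n1 >= 2) & (n2 >= 2)
    p1 = np.where(ok, alt1 / np.maximum(n1, 1), 0.0)
    p2 = np.where(ok, alt2 / np.maximum(n2, 1), 0.0)
    num, den = hudson_fst_site(p1, np.maximum(n1, 2), p2, np.maximum(n2, 2))
    num = np.where(ok, num, 0.0)
    den = np.where(ok, den, 0.0)
    lo, hi = _window_site_slices(geno.sites, windows)
    wnum = _window_sums(num, lo, hi)
    wden = _window_sums(den, lo, hi)
    n_inc = _window_sums(ok.astype(np.float64), lo, hi)
    out = windows.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where((wden > 0) & (n_inc > 0), wnum / np.where(wden > 0, wden, 1.0), np.nan)
    out[f"fst_{a}_{b}"] = fst
    out["n_fst_sites"] = n_inc.astype(np.int64)
    return out


def genomewide_fst(geno: GenotypeMatrix, popmap: dict[str, str], pair: tuple[str, str]) -> float:
    """Hudson FST over all sites as one ratio of averages."""
    groups = geno.group_rows(popmap)
    alt1, n1 = group_allele_counts(geno, groups[pair[0]])
    alt2, n2 = group_allele_counts(geno, groups[pair[1]])
    ok = (n1 >= 2) & (n2 >= 2)
    p1, p2 = alt1[ok] / n1[ok], alt2[ok] / n2[ok]
    num, den = hudson_fst_site(p1, n1[ok], p2, n2[ok])
    total_den = den.sum()
    if total_den <= 0:
        raise ValueError(f"FST undefined for pair {pair}: zero denominator")
    return float(num.sum() / total_den)


def heterozygosity(geno: GenotypeMatrix, popmap: dict[str, str]) -> pd.DataFrame:
    """Per-sample heterozygote fraction and subgroup means.

    Het ratio = (# dosage-1 genotypes) / (# called genotypes) per sample;
    samples with no called genotype get NaN and are flagged.
    """
    called = geno.called()
    n_called = called.sum(axis=1)
    n_het = (geno.dosage == 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    return pd.DataFrame(
        {
            "sample": geno.samples,
            "group": [popmap[s] for s in geno.samples],
            "n_called": n_called,
            "het_ratio": het,
        }
    )


def subgroup_summary(
    geno: GenotypeMatrix,
    popmap: dict[str, str],
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Genome-wide per-subgroup pi (per bp, window-averaged) and mean het."""
    het = heterozygosity(geno, popmap)
    rows = []
    for group in sorted(set(popmap.values())):
        wpi = windowed_pi(geno, popmap, windows, group)
        rows.append(
            {
                "group": group,
                "n_samples": int((het["group"] == group).sum()),
                "pi": float(wpi[f"pi_{group}"].mean()),
                "het": float(het.loc[het["group"] == group, "het_ratio"].mean()),
            }
        )
    return pd.DataFrame(rows)
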