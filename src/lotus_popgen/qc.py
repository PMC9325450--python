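"""Site QC filtering, SNP region classification, and subgroup SNP sharing.

The filter reproduces the standard resequencing site filter — mean coverage
depth >= 4, RMS mapping quality >= 20, MAF >= 0.05, missingness <= 0.1 —
with inclusive boundaries.  Depth and MQ are site-level covariates by
default (a per-genotype depth mode is out of scope here; the thresholds are
applied to the per-site summaries the VCF carries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from lotus_popgen.containers import GeneModel, GenotypeMatrix

logger = logging.getLogger(__name__)

REGION_CATEGORIES = ("exonic", "intronic", "upstream", "downstream", "intergenic")


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusive site-filter thresholds (pass iff all four hold)."""

    min_depth: float = 4.0
    min_mq: float = 20.0
    min_maf: float = 0.05
    max_miss: float = 0.1

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_mq < 0:
            raise ValueError("depth/MQ thresholds must be non-negative")
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError(f"min_maf must be in [0, 0.5], got {self.min_maf}")
        if not (0.0 <= self.max_miss <= 1.0):
            raise ValueError(f"max_miss must be in [0, 1], got {self.max_miss}")


def filter_sites(
    sites: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()
):
    """Apply the four site predicates; boundary values pass.

    Returns ``(mask, summary)`` where ``mask`` is a boolean pass vector and
    ``summary`` counts failures per criterion (a site may fail several) plus
    totals.
    """
    t = thresholds
    depth_ok = sites["depth"].to_numpy() >= t.min_depth
    mq_ok = sites["rms_mq"].to_numpy() >= t.min_mq
    maf_ok = sites["maf"].to_numpy() >= t.min_maf
    miss_ok = (1.0 - sites["call_fraction"].to_numpy()) <= t.max_miss
    mask = depth_ok & mq_ok & maf_ok & miss_ok
    summary = {
        "n_total": int(len(sites)),
        "n_pass": int(mask.sum()),
        "fail_depth": int((~depth_ok).sum()),
        "fail_mq": int((~mq_ok).sum()),
        "fail_maf": int((~maf_ok).sum()),
        "fail_miss": int((~miss_ok).sum()),
    }
    return mask, summary


def _gene_trees(genes: list[GeneModel]):
    """Per-chromosome interval trees over gene spans (closed -> half-open)."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    return trees


def classify_snp_regions(
    sites: pd.DataFrame, genes: list[GeneModel], flank_bp: int = 0
) -> np.ndarray:
    """Classify each SNP as exonic/intronic/upstream/downstream/intergenic.

    Precedence: exonic > intronic > upstream/downstream (within ``flank_bp``
    of the gene span, strand-aware) > intergenic.  A SNP inside a gene span
    but outside every exon is intronic.  SNPs on chromosomes missing from
    the annotation are intergenic (warned once per chromosome).
    """
    trees = _gene_trees(genes)
    flank_trees: dict[str, IntervalTree] = {}
    if flank_bp > 0:
        for g in genes:
            tree = flank_trees.setdefault(g.chrom, IntervalTree())
            up = ("upstream", g)
            down = ("downstream", g)
            # 5' flank is upstream; orientation depends on strand
            left, right = (up, down) if g.strand == "+" else (down, up)
            if g.start > 1:
                tree.addi(max(1, g.start - flank_bp), g.start, left)
            tree.addi(g.end + 1, g.end + flank_bp + 1, right)

    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    warned: set[str] = set()
    out = np.empty(len(sites), dtype=object)
    for i, (chrom, pos) in enumerate(zip(chrom_arr, pos_arr)):
        tree = trees.get(chrom)
        if tree is None:
            if chrom not in warned:
                logger.warning("chromosome %s absent from annotation; SNPs intergenic", chrom)
                warned.add(chrom)
            out[i] = "intergenic"
            continue
        hits = tree[pos]
        if hits:
            category = "intronic"
            for hit in hits:
                g: GeneModel = hit.data
                if any(s <= pos <= e for s, e in g.exons):
                    category = "exonic"
                    break
            out[i] = category
            continue
        ftree = flank_trees.get(chrom)
        if ftree:
            fhits = ftree[pos]
            if fhits:
                kinds = {h.data[0] for h in fhits}
                # upstream outranks downstream when flanks of two genes meet
                out[i] = "upstream" if "upstream" in kinds else "downstream"
                continue
        out[i] = "intergenic"
    return out


def region_proportions(categories: np.ndarray) -> dict[str, float]:
    """Category proportions over all SNPs (sums to 1)."""
    n = len(categories)
    return {
        cat: float((categories == cat).sum()) / n if n else 0.0
        for cat in REGION_CATEGORIES
    }


def snp_sharing(
    geno: GenotypeMatrix, popmap: dict[str, str], polymorphic_within: bool = False
) -> dict:
    """Per-subgroup SNP presence, common and unique counts.

    A SNP is *present* in a subgroup iff at least one called genotype there
    carries at least one alt allele.  With ``polymorphic_within=True``,
    presence instead requires the subgroup to segregate (both alleles
    observed among its called genotypes).
    """
    groups = geno.group_rows(popmap)
    for label, rows in groups.items():
        if len(rows) == 0:
            raise ValueError(f"empty subgroup {label!r}")
    presence: dict[str, np.ndarray] = {}
    for label, rows in groups.items():
        sub = geno.dosage[rows, :]
        called = sub != -1
        has_alt = ((sub > 0) & called).any(axis=0)
        if polymorphic_within:
            has_ref = (called & (sub < 2)).any(axis=0)
            presence[label] = has_alt & has_ref
        else:
            presence[label] = has_alt
    labels = sorted(presence)
    stack = np.stack([presence[g] for g in labels], axis=0)
    common = stack.all(axis=0)
    result = {
        "per_group_total": {g: int(presence[g].sum()) for g in labels},
        "common": int(common.sum()),
        "unique": {},
        "presence": presence,
    }
    for i, g in enumerate(labels):
        others = np.delete(stack, i, axis=0)
        result["unique"][g] = int((stack[i] & ~others.any(axis=0)).sum())
    return result
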