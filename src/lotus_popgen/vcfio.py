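"""Input readers: multi-sample VCF, GFF3 gene models, population map.

Only biallelic SNP records are loaded; multiallelic and indel records are
skipped with a logged count.  Dosage is the alt-allele count of the diploid
GT; uncalled genotypes become the MISSING sentinel.  Site MAF and call
fraction are always recomputed from the genotypes, so they are consistent
with the matrix regardless of what INFO carries.
"""

from __future__ import annotations

import logging

import gffutils
import numpy as np
from cyvcf2 import VCF

from lotus_popgen.containers import MISSING, GeneModel, GenotypeMatrix, site_table

logger = logging.getLogger(__name__)


class PopmapError(ValueError):
    """Sample/population-map inconsistency."""


def read_popmap(path: str) -> dict[str, str]:
    """Read a ``sample<TAB>group`` TSV (optional header line)."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise PopmapError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sample, group = parts
            if lineno == 1 and (sample, group) == ("sample", "group"):
                continue
            if sample in popmap:
                raise PopmapError(f"{path}:{lineno}: duplicate sample {sample!r}")
            popmap[sample] = group
    if not popmap:
        raise PopmapError(f"{path}: empty population map")
    return popmap


def _is_biallelic_snp(variant) -> bool:
    return (
        len(variant.ALT) == 1
        and len(variant.REF) == 1
        and len(variant.ALT[0]) == 1
        and variant.REF in "ACGT"
        and variant.ALT[0] in "ACGT"
    )


def read_vcf(path: str) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix, keeping biallelic SNPs only."""
    vcf = VCF(path)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, depth, mq = [], [], [], [], [], []
    dosages = []
    n_skipped = 0
    for variant in vcf:
        if not _is_biallelic_snp(variant):
            n_skipped += 1
            continue
        gts = variant.genotypes  # [[a1, a2, phased], ...]
        d = np.fromiter(
            (
                MISSING if (g[0] < 0 or g[1] < 0) else g[0] + g[1]
                for g in gts
            ),
            dtype=np.int8,
            count=len(samples),
        )
        dosages.append(d)
        chrom.append(variant.CHROM)
        pos.append(variant.POS)
        ref.append(variant.REF)
        alt.append(variant.ALT[0])
        depth.append(float(variant.INFO.get("DP", np.nan)))
        mq.append(float(variant.INFO.get("MQ", np.nan)))
    vcf.close()
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic-SNP records", path, n_skipped)
    if not dosages:
        raise ValueError(f"{path}: no biallelic SNP records")
    dosage = np.stack(dosages, axis=1)

    called = dosage != MISSING
    n_called = called.sum(axis=0)
    call_fraction = n_called / dosage.shape[0]
    alt_af = np.where(called, dosage, 0).sum(axis=0) / np.maximum(2 * n_called, 1)
    maf = np.minimum(alt_af, 1.0 - alt_af)

    sites = site_table(chrom, pos, ref, alt, depth, mq, call_fraction, maf)
    return GenotypeMatrix(samples=samples, sites=sites, dosage=dosage)


def read_gff3(path: str) -> list[GeneModel]:
    """Load gene models (gene spans + exons) from a GFF3 file."""
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []  # header-only annotation: no genes
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = tuple(
            (e.start, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
        )
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                exons=exons,
            )
        )
    return genes


def read_inputs(vcf_path: str, gff_path: str, popmap_path: str):
    """Read the three standard inputs and cross-validate them.

    Returns ``(geno, genes, popmap)``; the site table rides on ``geno``.
    Every VCF sample must appear in the population map.
    """
    geno = read_vcf(vcf_path)
    genes = read_gff3(gff_path)
    popmap = read_popmap(popmap_path)
    unmapped = [s for s in geno.samples if s not in popmap]
    if unmapped:
        raise PopmapError(
            f"samples in VCF but absent from population map: {unmapped}"
        )
    return geno, genes, popmap
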