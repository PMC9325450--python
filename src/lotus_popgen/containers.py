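"""Core in-memory containers shared by every stage.

The substrate of all statistics is a diploid allele-dosage matrix
(samples x sites, values 0/1/2 with a missing sentinel) plus a per-site
table of coordinates and QC covariates, kept as a pandas DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for an uncalled genotype in the dosage matrix (int8).
MISSING: int = -1

#: Columns every site table carries, in order.
SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "depth", "rms_mq", "call_fraction", "maf"]


def site_table(
    chrom, pos, ref, alt, depth, rms_mq, call_fraction, maf
) -> pd.DataFrame:
    """Assemble a site table with the canonical column set."""
    return pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": np.asarray(ref, dtype=object),
            "alt": np.asarray(alt, dtype=object),
            "depth": np.asarray(depth, dtype=float),
            "rms_mq": np.asarray(rms_mq, dtype=float),
            "call_fraction": np.asarray(call_fraction, dtype=float),
            "maf": np.asarray(maf, dtype=float),
        }
    )


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosage matrix with per-site metadata.

    Parameters
    ----------
    samples :
        Ordered sample identifiers (rows of ``dosage``).
    sites :
        Per-site table with columns :data:`SITE_COLUMNS`; rows are ordered
        strictly increasing by (chrom, pos) within each chromosome block.
    dosage :
        int8 array of shape (n_samples, n_sites); values in {0, 1, 2} or
        :data:`MISSING`.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2} or MISSING")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        pos = self.sites["pos"].to_numpy()
        chrom = self.sites["chrom"].to_numpy()
        if len(pos) > 1:
            same = chrom[1:] == chrom[:-1]
            if np.any(same & (pos[1:] <= pos[:-1])):
                raise ValueError("sites must be strictly increasing by (chrom, pos)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes (samples x sites)."""
        return self.dosage != MISSING

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        """Subset sites by boolean mask or integer index, preserving order."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
        )

    def take_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        """Subset/reorder samples by identifier."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        rows = [lookup[s] for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            sites=self.sites.reset_index(drop=True),
            dosage=self.dosage[rows, :],
        )

    def group_rows(self, popmap: dict[str, str]) -> dict[str, np.ndarray]:
        """Map subgroup label -> row indices, validating full coverage."""
        unmapped = [s for s in self.samples if s not in popmap]
        if unmapped:
            raise KeyError(f"samples absent from population map: {unmapped}")
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            groups.setdefault(popmap[s], []).append(i)
        return {g: np.asarray(rows, dtype=np.intp) for g, rows in groups.items()}


@dataclass(frozen=True)
class GeneModel:
    """A gene span with exons, 1-based closed coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid gene span {self.gene_id}: [{self.start}, {self.end}]")
        ex = sorted(self.exons)
        for (s, e) in ex:
            if s < self.start or e > self.end or e < s:
                raise ValueError(f"exon [{s}, {e}] outside gene span of {self.gene_id}")
        for (_, e1), (s2, _) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
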