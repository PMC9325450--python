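"""Synthetic multi-population diploid genotype simulator with planted sweeps.

The generator emulates a resequencing panel of diverged subgroups: each
population's allele frequencies are drawn around a shared ancestral
frequency under the Balding-Nichols model, ``Beta(p(1-F)/F, (1-p)(1-F)/F)``,
whose divergence parameter F equals the expected FST between the population
and the ancestral pool.  Domestication sweeps are planted by pushing the
target population's frequencies toward fixation inside chosen intervals,
which simultaneously depresses diversity and inflates differentiation there
— the two signals the joint sweep scan keys on.

Site-level QC covariates (negative-binomial depth, Gaussian RMS mapping
quality, independent genotype missingness) make the simulated VCF a
realistic substrate for the depth/MQ/MAF/missingness filters.

No linkage disequilibrium or recombination structure is modeled: sites are
exchangeable given their frequencies, which is sufficient for
frequency-based statistics (pi, FST, heterozygosity, PCA, p-distance).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from lotus_popgen.containers import MISSING, GeneModel, GenotypeMatrix, site_table


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class Population:
    """A simulated subgroup: label, diploid sample count, drift parameter F."""

    label: str
    n_samples: int
    F: float


@dataclass(frozen=True)
class Sweep:
    """A planted sweep interval (1-based closed) in one target population.

    ``s`` in [0, 1] is the sweep intensity: 0 is a no-op, 1 forces fixation.
    """

    chrom: str
    start: int
    end: int
    population: str
    s: float


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic cohort; seed-deterministic."""

    seed: int
    n_chromosomes: int = 1
    chrom_length: int = 2_000_000
    n_sites: int = 20_000
    populations: tuple[Population, ...] = (
        Population("WL", 21, 0.05),
        Population("SL", 21, 0.05),
    )
    ancestral_sfs: str = "uniform"  # "uniform" U(0.05,0.95) | "neutral" ~1/x on [0.01,0.99]
    missing_rate: float = 0.02
    depth_mean: float = 11.0  # matches ~11x panel coverage
    depth_dispersion: float = 5.0
    mq_mean: float = 45.0
    mq_sd: float = 5.0
    sweeps: tuple[Sweep, ...] = ()
    n_genes: int = 100

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1 or self.n_sites < 1:
            raise ConfigError("n_chromosomes, chrom_length and n_sites must be positive")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"population labels must be unique: {labels}")
        for p in self.populations:
            if not (0.0 <= p.F < 1.0):
                raise ConfigError(f"drift parameter F for {p.label} must be in [0, 1), got {p.F}")
            if p.n_samples < 1:
                raise ConfigError(f"population {p.label} needs at least one sample")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.ancestral_sfs not in ("uniform", "neutral"):
            raise ConfigError(f"unknown ancestral_sfs {self.ancestral_sfs!r}")
        chroms = set(self.chrom_names())
        for sw in self.sweeps:
            if sw.chrom not in chroms:
                raise ConfigError(f"sweep chromosome {sw.chrom!r} not simulated")
            if not (1 <= sw.start <= sw.end <= self.chrom_length):
                raise ConfigError(
                    f"sweep interval [{sw.start}, {sw.end}] outside [1, {self.chrom_length}]"
                )
            if sw.population not in labels:
                raise ConfigError(f"sweep targets unknown population {sw.population!r}")
            if not (0.0 <= sw.s <= 1.0):
                raise ConfigError(f"sweep intensity must be in [0, 1], got {sw.s}")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be non-negative")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def sample_ids(self) -> list[str]:
        return [
            f"{p.label}_{i + 1:03d}" for p in self.populations for i in range(p.n_samples)
        ]

    def popmap(self) -> dict[str, str]:
        return {
            f"{p.label}_{i + 1:03d}": p.label
            for p in self.populations
            for i in range(p.n_samples)
        }


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort, for recovery tests.

    ``pop_freq`` maps population label -> post-drift (and post-sweep, if
    planted) alt-allele frequency per site.
    """

    chrom: np.ndarray  # per-site chromosome label
    pos: np.ndarray  # per-site 1-based position
    ancestral_freq: np.ndarray
    pop_freq: dict[str, np.ndarray]
    pop_F: dict[str, float]
    sweeps: tuple[Sweep, ...] = ()

    def sweep_site_mask(self, sweep: Sweep) -> np.ndarray:
        """Boolean mask of sites inside a sweep interval."""
        return (self.chrom == sweep.chrom) & (self.pos >= sweep.start) & (self.pos <= sweep.end)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage keyed on the one seed
    return np.random.default_rng([config.seed, stream])


def _draw_ancestral(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    if config.ancestral_sfs == "uniform":
        return rng.uniform(0.05, 0.95, config.n_sites)
    # neutral SFS density ~ 1/x truncated to [0.01, 0.99]; inverse-CDF sampling
    a, b = 0.01, 0.99
    u = rng.random(config.n_sites)
    return a * (b / a) ** u


def _site_positions(rng: np.random.Generator, config: SimConfig):
    """Distribute sites over chromosomes; sorted unique positions per chrom."""
    base, extra = divmod(config.n_sites, config.n_chromosomes)
    chroms, positions = [], []
    for i, name in enumerate(config.chrom_names()):
        k = base + (1 if i < extra else 0)
        if k > config.chrom_length:
            raise ConfigError("more sites than positions on a chromosome")
        pos = np.sort(rng.choice(config.chrom_length, size=k, replace=False)) + 1
        chroms.extend([name] * k)
        positions.append(pos)
    return np.asarray(chroms, dtype=object), np.concatenate(positions)


def simulate_frequencies(config: SimConfig) -> SimTruth:
    """Draw ancestral and per-population allele frequencies.

    Each population's frequency at a site is Balding-Nichols distributed,
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the ancestral frequency ``p``;
    its variance is ``F p (1-p)`` and F = 0 reduces to ``p`` exactly.
    """
    rng = _rng(config, 0)
    chrom, pos = _site_positions(rng, config)
    p = _draw_ancestral(rng, config)
    pop_freq: dict[str, np.ndarray] = {}
    for popn in config.populations:
        if popn.F == 0.0:
            pop_freq[popn.label] = p.copy()
        else:
            scale = (1.0 - popn.F) / popn.F
            pop_freq[popn.label] = rng.beta(p * scale, (1.0 - p) * scale)
    return SimTruth(
        chrom=chrom,
        pos=pos,
        ancestral_freq=p,
        pop_freq=pop_freq,
        pop_F={popn.label: popn.F for popn in config.populations},
        sweeps=(),
    )


def plant_sweeps(truth: SimTruth, config: SimConfig) -> SimTruth:
    """Push target-population frequencies toward fixation inside sweep intervals.

    Inside each interval the target population's frequency becomes
    ``p' = p (1-s) + round(p) s`` with round(0.5) = 1 (deterministic
    tie-break toward the alt allele), so s = 1 fixes every site and s = 0
    changes nothing.  Other populations are untouched.
    """
    pop_freq = {label: f.copy() for label, f in truth.pop_freq.items()}
    for sw in config.sweeps:
        mask = truth.sweep_site_mask(sw)
        p = pop_freq[sw.population][mask]
        target = np.where(p >= 0.5, 1.0, 0.0)
        pop_freq[sw.population][mask] = p * (1.0 - sw.s) + target * sw.s
    return SimTruth(
        chrom=truth.chrom,
        pos=truth.pos,
        ancestral_freq=truth.ancestral_freq,
        pop_freq=pop_freq,
        pop_F=dict(truth.pop_F),
        sweeps=tuple(config.sweeps),
    )


_NUC = np.array(list("ACGT"))


def sample_genotypes(truth: SimTruth, config: SimConfig) -> GenotypeMatrix:
    """Draw diploid genotypes and site covariates from the frequency truth.

    Genotypes are Binomial(2, p_pop) alt-dosages (Hardy-Weinberg within
    population); each genotype is masked missing independently with
    ``missing_rate``.  Site depth is gamma-Poisson (negative binomial) with
    the configured mean/dispersion; RMS MQ is Gaussian truncated at 0.
    Realized call fraction and folded MAF are recomputed from the drawn
    matrix, matching what a VCF reader would derive.
    """
    rng = _rng(config, 1)
    n_sites = len(truth.pos)
    blocks = []
    for popn in config.populations:
        p = truth.pop_freq[popn.label]
        blocks.append(rng.binomial(2, np.broadcast_to(p, (popn.n_samples, n_sites))))
    dosage = np.concatenate(blocks, axis=0).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = MISSING

    lam = rng.gamma(config.depth_dispersion, config.depth_mean / config.depth_dispersion, n_sites)
    depth = rng.poisson(lam).astype(float)
    mq = np.maximum(rng.normal(config.mq_mean, config.mq_sd, n_sites), 0.0)

    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4

    called = dosage != MISSING
    n_called = called.sum(axis=0)
    call_fraction = n_called / dosage.shape[0]
    with np.errstate(invalid="ignore"):
        alt_af = np.where(dosage == MISSING, 0, dosage).sum(axis=0) / np.maximum(2 * n_called, 1)
    maf = np.minimum(alt_af, 1.0 - alt_af)

    sites = site_table(
        chrom=truth.chrom,
        pos=truth.pos,
        ref=_NUC[ref_idx],
        alt=_NUC[alt_idx],
        depth=depth,
        rms_mq=mq,
        call_fraction=call_fraction,
        maf=maf,
    )
    return GenotypeMatrix(samples=config.sample_ids(), sites=sites, dosage=dosage)


def make_genes(config: SimConfig) -> list[GeneModel]:
    """Deterministic toy annotation: non-overlapping genes, >= 1 exon each.

    Genes are placed one per equal-width slot along each chromosome, which
    guarantees non-overlap by construction.
    """
    rng = _rng(config, 2)
    genes: list[GeneModel] = []
    base, extra = divmod(config.n_genes, config.n_chromosomes)
    gid = 0
    for i, chrom in enumerate(config.chrom_names()):
        k = base + (1 if i < extra else 0)
        if k == 0:
            continue
        slot = config.chrom_length // k
        for j in range(k):
            gid += 1
            length = int(rng.integers(2_000, min(6_000, max(2_001, slot // 2))))
            start = int(j * slot + 1 + rng.integers(0, max(1, slot - length)))
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 1, replace=False))
            bounds = np.concatenate(([0], cuts, [length]))
            exons = tuple(
                (start + int(bounds[2 * e]), start + int(bounds[2 * e + 1]) - 1)
                for e in range(n_exons)
            )
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:05d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                )
            )
    return genes


def _format_vcf(geno: GenotypeMatrix, contigs: dict[str, int]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=lotus_popgen.sim"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Mean site coverage depth">')
    lines.append('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header + list(geno.samples)))
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    s = geno.sites
    for j in range(geno.n_sites):
        info = f"DP={int(s.depth.iat[j])};MQ={s.rms_mq.iat[j]:.4f}"
        row = [
            str(s.chrom.iat[j]),
            str(int(s.pos.iat[j])),
            ".",
            str(s.ref.iat[j]),
            str(s.alt.iat[j]),
            ".",
            "PASS",
            info,
            "GT",
        ]
        row.extend(gt_code[int(d)] for d in geno.dosage[:, j])
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def _format_gff3(genes: list[GeneModel]) -> str:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id}"
        lines.append(
            f"{g.chrom}\tlotus_popgen\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for k, (s, e) in enumerate(sorted(g.exons), start=1):
            lines.append(
                f"{g.chrom}\tlotus_popgen\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.exon{k};Parent={g.gene_id}"
            )
    return "\n".join(lines) + "\n"


def write_fixture(
    geno: GenotypeMatrix,
    truth: SimTruth,
    config: SimConfig,
    out_dir: str,
    genes: list[GeneModel] | None = None,
) -> dict[str, str]:
    """Write the cohort as VCF v4.2 + toy GFF3 + popmap TSV + sweep-truth TSV.

    Returns a name -> path mapping.  Output is byte-deterministic given the
    config, and reading the VCF back reproduces the dosage matrix exactly.
    """
    os.makedirs(out_dir, exist_ok=True)
    if genes is None:
        genes = make_genes(config)
    contigs = {name: config.chrom_length for name in config.chrom_names()}
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "gff": os.path.join(out_dir, "annotation.gff3"),
        "popmap": os.path.join(out_dir, "popmap.tsv"),
        "sweeps": os.path.join(out_dir, "sweeps_truth.tsv"),
    }
    with open(paths["vcf"], "w") as fh:
        fh.write(_format_vcf(geno, contigs))
    with open(paths["gff"], "w") as fh:
        fh.write(_format_gff3(genes))
    popmap = config.popmap()
    with open(paths["popmap"], "w") as fh:
        fh.write("sample\tgroup\n")
        for s in geno.samples:
            fh.write(f"{s}\t{popmap[s]}\n")
    with open(paths["sweeps"], "w") as fh:
        fh.write("chrom\tstart\tend\tpopulation\ts\n")
        for sw in truth.sweeps:
            fh.write(f"{sw.chrom}\t{sw.start}\t{sw.end}\t{sw.population}\t{sw.s}\n")
    return paths


def simulate_dataset(config: SimConfig):
    """Run the full generator: frequencies -> sweeps -> genotypes (+ genes).

    Returns ``(geno, truth, genes)``.
    """
    truth = plant_sweeps(simulate_frequencies(config), config)
    geno = sample_genotypes(truth, config)
    return geno, truth, make_genes(config)


#: Window geometry of the standard benchmark: 4 kb tiled windows, so each
#: 12 kb planted sweep spans exactly three windows and the ten sweeps
#: (30 windows of 500) roughly fill the top-5% selection budget (25 windows).
STANDARD_WINDOW = (4_000, 4_000)


def standard_sweep_config(seed: int) -> SimConfig:
    """The standard two-population sweep benchmark.

    A 2 Mb chromosome with 20 000 SNPs, a wild (WL, F = 0.05) and a
    cultivated (SL, F = 0.05) population of 21 diploids each, and ten 12 kb
    sweeps (s = 0.95) planted in the cultivated group, aligned to the 4 kb
    scan-window grid so each spans exactly three windows.
    """
    size = STANDARD_WINDOW[0]
    sweeps = tuple(
        Sweep("chr1", start, start + 3 * size - 1, "SL", 0.95)
        for start in range(100_001, 2_000_000, 192_000)
    )
    return SimConfig(seed=seed, sweeps=sweeps)
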