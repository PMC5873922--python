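"""Synthetic inbred-line panel generator with truth files.

Emulates the statistical structure of a re-sequenced inbred panel:
neutral standing variation with a rare-allele-skewed site frequency
spectrum (recent population expansion), founding of lines from single
mated females (4 founder haplotypes), repeated brother–sister mating
with recombination, overdispersed read depth around a target mean,
collapsed-duplication artifacts that co-elevate apparent heterozygosity
and depth, optional K-subpopulation structure, and planted causal SNPs
plus a GRM-structured polygenic term for two positive, compositional
phenotypes (so the log-contrast transform is exercisable).

The base haplotype pool comes from msprime (stationary coalescent with
demography); the sib-mating pedigree forward simulation is implemented
here.  All autosomal; X transmission is not modeled.  Everything is
deterministic under (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypeMatrix, PanelError, PhenotypeTable
from .relatedness import compute_grm

CHROM = "sim1"


class MonomorphicSimulationError(PanelError):
    """Raised when the base simulation yields no segregating sites."""


@dataclass
class SimConfig:
    """Synthetic-panel parameters.

    Defaults are desk-scale study conditions: a 110-line panel after 20
    generations of full-sib inbreeding from a single expanded population,
    ~23.5× mean depth, and mutation/recombination rates calibrated on a
    100 kb region so the emitted panel shows π near 0.008, strongly
    negative Tajima's D, and LD r² dropping below 0.1 within ~100 bp.
    """

    n_base_individuals: int = 200      # diploid base-population size
    n_generations_base: int | None = None  # unused: coalescent pool is stationary
    sequence_length: int = 100_000     # bp
    mutation_rate: float = 3.6e-5      # per bp per generation (rescaled desk value)
    recombination_rate: float = 6.0e-5 # per bp per generation (rescaled desk value)
    n_lines: int = 110
    inbreeding_generations: int | Sequence[int] = 20
    n_subpops: int = 1
    divergence_generations: int = 0
    expansion_factor: float = 12.0     # present/ancestral size ratio (SFS skew)
    expansion_time: float = 100.0      # generations ago (rescaled)
    mean_depth: float = 23.5
    depth_dispersion: float = 8.0      # negative-binomial shape; larger = tighter
    missing_rate: float = 0.01
    duplication_artifact: list = field(default_factory=list)  # (start, end, depth multiplier)
    artifact_het_fraction: float = 0.3
    causal_snps: list = field(default_factory=list)  # (site index | "random", beta, trait)
    h2_polygenic: float = 0.3
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "recombination_rate", "missing_rate"):
            if getattr(self, name) < 0:
                raise PanelError(f"{name} must be >= 0")
        if self.n_lines < 2:
            raise PanelError("n_lines must be >= 2")
        gens = self.inbreeding_generations
        if isinstance(gens, (int, np.integer)):
            if gens < 0:
                raise PanelError("inbreeding_generations must be >= 0")
        else:
            gens = list(gens)
            if len(gens) != self.n_lines:
                raise PanelError("per-line inbreeding_generations length != n_lines")
            if any(g < 0 for g in gens):
                raise PanelError("inbreeding_generations must be >= 0")
        for iv in self.duplication_artifact:
            if iv[2] < 0:
                raise PanelError("artifact depth multiplier must be >= 0")
        if not (0.0 <= self.h2_polygenic < 1.0):
            raise PanelError("h2_polygenic must be in [0, 1)")

    def generations_per_line(self) -> list[int]:
        g = self.inbreeding_generations
        if isinstance(g, (int, np.integer)):
            return [int(g)] * self.n_lines
        return [int(x) for x in g]


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic panel."""

    line_ids: list[str]
    subpop: list[int]
    generations: list[int]
    causal: list[dict] = field(default_factory=list)  # {pos, trait, beta}
    sigma2_a: float = 0.0
    sigma2_e: float = 0.0
    artifact_sites: np.ndarray | None = None  # boolean per site

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("#section\tlines\nline\tsubpop\tgenerations\n")
            for l, s, g in zip(self.line_ids, self.subpop, self.generations):
                fh.write(f"{l}\t{s}\t{g}\n")
            fh.write("#section\tcausal\npos\ttrait\tbeta\n")
            for c in self.causal:
                fh.write(f"{c['pos']}\t{c['trait']}\t{c['beta']:.10g}\n")
            fh.write("#section\tvariance\nsigma2_a\tsigma2_e\n")
            fh.write(f"{self.sigma2_a:.10g}\t{self.sigma2_e:.10g}\n")
            if self.artifact_sites is not None:
                fh.write("#section\tartifact_sites\nsite_index\n")
                for i in np.flatnonzero(self.artifact_sites):
                    fh.write(f"{i}\n")


@dataclass
class HaplotypePool:
    """Neutral standing variation: haplotypes × segregating sites."""

    positions: np.ndarray        # 0-based bp, sorted
    haplotypes: np.ndarray       # (n_haplotypes, n_sites) uint8 in {0,1}
    pop_labels: np.ndarray       # subpopulation per haplotype
    sequence_length: int

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


def _derive_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([int(seed), salt]).generate_state(1)[0] % (2**31 - 1)) + 1


def simulate_base_population(cfg: SimConfig, seed: int | None = None) -> HaplotypePool:
    """Neutral haplotype pool from a stationary coalescent simulation.

    Single population by default (with a recent expansion by
    ``expansion_factor`` at ``expansion_time`` generations ago, which
    skews the SFS toward rare alleles); with ``n_subpops > 1`` the
    subpopulations split from the ancestral population
    ``divergence_generations`` ago.  Only biallelic segregating sites
    are kept; zero segregating sites raises
    :class:`MonomorphicSimulationError`.
    """
    import msprime

    seed = cfg.seed if seed is None else seed
    ne = cfg.n_base_individuals
    anc = msprime.Demography()
    if cfg.n_subpops <= 1:
        anc.add_population(name="P0", initial_size=ne)
        if cfg.expansion_factor > 1.0:
            anc.add_population_parameters_change(
                time=cfg.expansion_time, population="P0",
                initial_size=ne / cfg.expansion_factor,
            )
        samples = {"P0": 2 * ne}
    else:
        if cfg.divergence_generations <= 0:
            raise PanelError("n_subpops > 1 requires divergence_generations > 0")
        names = [f"P{k}" for k in range(cfg.n_subpops)]
        for nm in names:
            anc.add_population(name=nm, initial_size=ne)
        anc.add_population(name="ANC", initial_size=ne)
        anc.add_population_split(
            time=cfg.divergence_generations, derived=names, ancestral="ANC"
        )
        samples = {nm: 2 * ne for nm in names}
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=anc,
        sequence_length=cfg.sequence_length,
        recombination_rate=cfg.recombination_rate,
        random_seed=_derive_seed(seed, 1),
        ploidy=2,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=cfg.mutation_rate,
        model=msprime.BinaryMutationModel(),
        random_seed=_derive_seed(seed, 2),
        discrete_genome=True,
    )
    if ts.num_sites == 0:
        raise MonomorphicSimulationError(
            "monomorphic simulation: no segregating sites; increase "
            "mutation_rate, sequence_length or n_base_individuals (theta too small)"
        )
    geno = ts.genotype_matrix()  # sites × haplotypes, states {0,1}
    positions = np.array([int(s.position) for s in ts.sites()], dtype=np.int64)
    freq = geno.mean(axis=1)
    keep = (freq > 0) & (freq < 1)
    # collapse duplicate integer positions (discrete genome): keep first
    _, first = np.unique(positions, return_index=True)
    dup_mask = np.zeros(len(positions), dtype=bool)
    dup_mask[first] = True
    keep &= dup_mask
    if not keep.any():
        raise MonomorphicSimulationError(
            "monomorphic simulation: all sites fixed; increase theta"
        )
    hap = np.ascontiguousarray(geno[keep].T.astype(np.uint8))
    pops = np.zeros(hap.shape[0], dtype=int)
    for k, ind in enumerate(ts.individuals()):
        pop = ts.node(ind.nodes[0]).population
        pops[list(ind.nodes)] = min(pop, max(cfg.n_subpops - 1, 0))
    return HaplotypePool(
        positions=positions[keep],
        haplotypes=hap,
        pop_labels=pops,
        sequence_length=cfg.sequence_length,
    )


def _gamete(rng: np.random.Generator, hap_a, hap_b, positions, length, recomb_rate):
    """Recombinant gamete from a diploid parent: Poisson crossovers at
    uniform positions, alternating parental haplotypes."""
    n_cross = rng.poisson(recomb_rate * length)
    start = rng.integers(2)
    if n_cross == 0:
        return (hap_a if start == 0 else hap_b).copy()
    breaks = np.sort(rng.uniform(0, length, size=n_cross))
    seg = (np.searchsorted(breaks, positions, side="right") + start) % 2
    return np.where(seg == 0, hap_a, hap_b)


def found_and_inbreed_lines(
    pool: HaplotypePool,
    cfg: SimConfig,
    seed: int | None = None,
    drop_monomorphic: bool = True,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Found lines from single mated females and apply sib mating.

    Each line starts from 4 founder haplotypes (2 maternal + 2 paternal)
    drawn from its subpopulation's pool; each generation one brother and
    one sister are drawn from the sibship (recombination at the
    configured rate, Mendelian segregation); after t generations the
    female's diploid genotype is emitted.  t = 0 emits the founder
    female herself.

    ``drop_monomorphic`` removes sites fixed across the emitted panel
    (a joint genotyper only reports panel variants); disable it to keep
    a site set comparable across inbreeding depths.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(_derive_seed(seed, 3))
    gens = cfg.generations_per_line()
    n_sites = pool.haplotypes.shape[1]
    positions = pool.positions.astype(float)
    length = pool.sequence_length
    r = cfg.recombination_rate
    line_ids = [f"line{i + 1:03d}" for i in range(cfg.n_lines)]
    subpops = [i % max(cfg.n_subpops, 1) for i in range(cfg.n_lines)]
    geno = np.empty((cfg.n_lines, n_sites), dtype=np.int8)
    for i in range(cfg.n_lines):
        cand = np.flatnonzero(pool.pop_labels == subpops[i])
        if len(cand) < 4:
            raise PanelError("haplotype pool too small to found a line (need 4)")
        picks = rng.choice(cand, size=4, replace=False)
        mother = (pool.haplotypes[picks[0]], pool.haplotypes[picks[1]])
        father = (pool.haplotypes[picks[2]], pool.haplotypes[picks[3]])
        # t = 0 emits the founder female; otherwise the founder pair's
        # brood is generation 1 and sib matings 1..t follow, so the
        # emitted female is the offspring of the t-th sib mating (F_t)
        n_matings = gens[i] + 1 if gens[i] > 0 else 0
        for _ in range(n_matings):
            sister = (
                _gamete(rng, *mother, positions, length, r),
                _gamete(rng, *father, positions, length, r),
            )
            brother = (
                _gamete(rng, *mother, positions, length, r),
                _gamete(rng, *father, positions, length, r),
            )
            mother, father = sister, brother
        derived = mother[0].astype(np.int8) + mother[1].astype(np.int8)
        geno[i] = 2 - derived  # code counts the reference (ancestral) allele
    keep_sites = np.ones(n_sites, dtype=bool)
    if drop_monomorphic:
        keep_sites = ~((geno == geno[0]).all(axis=0) & ((geno[0] == 0) | (geno[0] == 2)))
        geno = geno[:, keep_sites]
        pool = HaplotypePool(
            positions=pool.positions[keep_sites],
            haplotypes=pool.haplotypes[:, keep_sites],
            pop_labels=pool.pop_labels,
            sequence_length=pool.sequence_length,
        )
    sites = pd.DataFrame(
        {
            "chrom": CHROM,
            "pos": pool.positions + 1,  # 1-based
            "ref": "A",
            "alt": "C",
            "biallelic": True,
        }
    )
    gm = GenotypeMatrix(
        line_ids=line_ids,
        sites=sites,
        genotypes=geno,
        counted_allele_policy="reference",
    )
    truth = SimTruth(
        line_ids=line_ids,
        subpop=subpops,
        generations=gens,
    )
    return gm, truth


def simulate_depth_and_artifacts(
    gm: GenotypeMatrix,
    cfg: SimConfig,
    seed: int | None = None,
    truth: SimTruth | None = None,
) -> GenotypeMatrix:
    """Attach overdispersed per-genotype depths and duplication artifacts.

    Depths are negative-binomial with mean ``mean_depth`` and shape
    ``depth_dispersion``.  Within each ``duplication_artifact`` interval
    (0-based half-open bp) depths are multiplied and a fraction of
    homozygous calls become spurious heterozygotes, producing the
    co-elevated depth/heterozygosity signal of collapsed duplications.
    Genotypes with zero reads, plus a ``missing_rate`` random fraction,
    are set MISSING.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(_derive_seed(seed, 4))
    out = gm.copy()
    k = cfg.depth_dispersion
    mean = np.full(out.n_sites, cfg.mean_depth, dtype=float)
    artifact = np.zeros(out.n_sites, dtype=bool)
    pos0 = out.sites["pos"].to_numpy() - 1
    for start, end, mult in cfg.duplication_artifact:
        in_iv = (pos0 >= start) & (pos0 < end)
        mean[in_iv] *= mult
        artifact |= in_iv
    p = k / (k + mean)
    depths = rng.negative_binomial(k, p[None, :], size=(out.n_lines, out.n_sites))
    out.depths = depths.astype(np.int32)
    # spurious heterozygosity inside artifact intervals
    if artifact.any() and cfg.artifact_het_fraction > 0:
        hom = (out.genotypes != 1) & (out.genotypes != MISSING) & artifact[None, :]
        flip = hom & (rng.random(out.genotypes.shape) < cfg.artifact_het_fraction)
        out.genotypes[flip] = 1
    miss = (out.depths == 0) | (rng.random(out.genotypes.shape) < cfg.missing_rate)
    out.genotypes[miss] = MISSING
    out.sites = out.sites.copy()
    out.sites["depth_mean"] = out.depths.mean(axis=0)
    out.sites["depth_median"] = np.median(out.depths, axis=0)
    if truth is not None:
        truth.artifact_sites = artifact
    return out


def effect_for_variance_fraction(
    gm: GenotypeMatrix, site_index: int, fraction: float
) -> float:
    """β per allele copy so the SNP explains ``fraction`` of unit
    phenotypic variance given its sample dosage variance."""
    g = gm.genotypes[:, site_index].astype(float)
    g = g[g != MISSING]
    v = g.var()
    if v <= 0:
        raise PanelError(f"site {site_index} is monomorphic; cannot carry an effect")
    return float(np.sqrt(fraction / v))


def plant_phenotypes(
    gm: GenotypeMatrix,
    truth: SimTruth,
    cfg: SimConfig,
    seed: int | None = None,
    maf_floor: float = 0.05,
) -> PhenotypeTable:
    """Replicate-level phenotypes with planted causal SNPs and a
    GRM-structured polygenic term.

    On the (log-contrast) analysis scale, residual variance is scaled so
    that polygenic + residual variance is 1 with polygenic share
    ``h2_polygenic``; causal effects add on top.  Two positive traits
    are emitted (``focal`` and ``divisor``) with a shared multiplicative
    nuisance, so log(focal/divisor) recovers the simulated value.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(_derive_seed(seed, 5))
    maf = gm.maf()
    eligible = np.flatnonzero(np.isfinite(maf) & (maf >= maf_floor))
    if len(eligible) == 0 and (cfg.causal_snps or cfg.h2_polygenic > 0):
        raise PanelError("no polymorphic sites at or above the MAF floor")
    gv = np.zeros(gm.n_lines)
    truth.causal = []
    gm_minor = gm.with_policy("minor")
    for spec in cfg.causal_snps:
        site, beta, trait = spec
        if site == "random":
            site = int(rng.choice(eligible))
        site = int(site)
        if maf[site] < maf_floor or not np.isfinite(maf[site]):
            raise PanelError(
                f"requested causal site {site} below MAF floor {maf_floor}; "
                f"eligible sites: {eligible[:20].tolist()}{'...' if len(eligible) > 20 else ''}"
            )
        dose = gm_minor.genotypes[:, site].astype(float)
        called = dose != MISSING
        dose[~called] = dose[called].mean()
        gv += float(beta) * dose
        truth.causal.append(
            {"pos": int(gm.sites["pos"].iloc[site]), "trait": trait,
             "beta": float(beta), "site_index": site}
        )
    sigma2_a = float(cfg.h2_polygenic)
    sigma2_e = float(1.0 - cfg.h2_polygenic)
    if sigma2_a > 0:
        sub, _ = _maf_subset(gm, eligible)
        a_mat = compute_grm(sub, scaling_mode="inbred").matrix
        w, v = np.linalg.eigh(a_mat)
        w = np.clip(w, 0.0, None)
        poly = v @ (np.sqrt(w) * rng.standard_normal(gm.n_lines)) * np.sqrt(sigma2_a)
        gv = gv + poly
    rows = []
    r = cfg.n_replicates
    for i, line in enumerate(gm.line_ids):
        for rep in range(1, r + 1):
            y = gv[i] + rng.normal(0.0, np.sqrt(sigma2_e))
            nuisance = np.exp(rng.normal(0.0, 0.2))  # body-size-like common factor
            divisor = nuisance * np.exp(rng.normal(0.0, 0.3))
            rows.append(
                {"line": line, "rep": rep, "focal": divisor * np.exp(y),
                 "divisor": divisor}
            )
    truth.sigma2_a = sigma2_a
    truth.sigma2_e = sigma2_e
    return PhenotypeTable(pd.DataFrame(rows))


def _maf_subset(gm: GenotypeMatrix, eligible: np.ndarray):
    mask = np.zeros(gm.n_sites, dtype=bool)
    mask[eligible] = True
    return gm.subset(site_mask=mask), mask


@dataclass
class SimPanel:
    """A complete synthetic panel: genotypes, truth and phenotypes."""

    gm: GenotypeMatrix
    truth: SimTruth
    phenotypes: PhenotypeTable | None


def simulate_panel(cfg: SimConfig, with_phenotypes: bool = True) -> SimPanel:
    """Run the full generator: base pool → inbred lines → depth/artifacts
    → phenotypes.  Deterministic under (cfg, cfg.seed)."""
    pool = simulate_base_population(cfg)
    gm, truth = found_and_inbreed_lines(pool, cfg)
    gm = simulate_depth_and_artifacts(gm, cfg, truth=truth)
    pheno = plant_phenotypes(gm, truth, cfg) if with_phenotypes else None
    return SimPanel(gm=gm, truth=truth, phenotypes=pheno)
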