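"""Core in-memory containers for an inbred-line panel.

The central object is :class:`GenotypeMatrix`: a lines × sites matrix of
allele-count codes together with site metadata (position, alleles, depth
summaries).  Genotypes are coded 0/1/2 as the number of copies of a
"counted" allele — either the reference allele or the per-site minor
allele — with ``MISSING`` (−1) for uncalled genotypes.  Heterozygotes are
code 1 under either policy, and flipping the policy maps codes x → 2−x at
the sites where the counted allele changes, an involution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel genotype code for an uncalled genotype.
MISSING: int = -1

_ALLOWED_CODES = frozenset({-1, 0, 1, 2})

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


class PanelError(ValueError):
    """Raised on invalid panel data or configuration."""


@dataclass
class GenotypeMatrix:
    """Lines × sites allele-count genotype matrix with site metadata.

    Parameters
    ----------
    line_ids
        Ordered line identifiers (one per row of ``genotypes``).
    sites
        DataFrame with at least columns ``chrom, pos, ref, alt`` (``pos``
        1-based), optionally ``depth_mean``, ``depth_median`` and
        ``biallelic``.  Sites must be sorted by (chrom, pos).
    genotypes
        int8 array of shape (n_lines, n_sites); entries in {−1, 0, 1, 2}.
    counted_allele_policy
        ``"reference"``: codes count copies of the reference allele.
        ``"minor"``: codes count copies of the per-site sample minor allele.
    depths
        Optional per-genotype read depth, same shape as ``genotypes``.
    gt_probs
        Optional per-genotype call probability in [0, 1], same shape.
    """

    line_ids: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    counted_allele_policy: str = "reference"
    depths: np.ndarray | None = None
    gt_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.counted_allele_policy not in ("reference", "minor"):
            raise PanelError(
                f"unknown counted_allele_policy {self.counted_allele_policy!r}; "
                "expected 'reference' or 'minor'"
            )
        if self.genotypes.shape != (len(self.line_ids), len(self.sites)):
            raise PanelError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise PanelError(f"{bad.sum()} genotype codes outside {{-1,0,1,2}}")
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise PanelError(f"sites table lacks columns {missing_cols}")
        self.sites = self.sites.reset_index(drop=True)
        key = list(zip(self.sites["chrom"], self.sites["pos"], self.sites["alt"]))
        if any(key[i] >= key[i + 1] for i in range(len(key) - 1)):
            order = self.sites.sort_values(["chrom", "pos", "alt"]).index.to_numpy()
            if len(set(key)) != len(key):
                raise PanelError("duplicate (chrom, pos, alt) site records")
            self._reorder_sites(order)

    def _reorder_sites(self, order: np.ndarray) -> None:
        self.sites = self.sites.iloc[order].reset_index(drop=True)
        self.genotypes = self.genotypes[:, order]
        if self.depths is not None:
            self.depths = self.depths[:, order]
        if self.gt_probs is not None:
            self.gt_probs = self.gt_probs[:, order]

    # ------------------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotypes."""
        return self.genotypes != MISSING

    def call_rate(self) -> np.ndarray:
        """Per-site fraction of lines with a non-missing call."""
        if self.n_lines == 0:
            return np.zeros(self.n_sites)
        return self.called().mean(axis=0)

    def counted_allele_freq(self) -> np.ndarray:
        """Per-site frequency of the counted allele among called diploid
        genotypes (heterozygotes contribute one copy).  NaN when no calls."""
        called = self.called()
        n_alleles = 2.0 * called.sum(axis=0)
        copies = np.where(called, self.genotypes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, copies / n_alleles, np.nan)

    def maf(self) -> np.ndarray:
        """Per-site sample minor allele frequency (policy-invariant)."""
        p = self.counted_allele_freq()
        return np.minimum(p, 1.0 - p)

    def depth_summary(self, stat: str = "mean") -> np.ndarray:
        """Per-site read-depth summary across lines (``mean`` or ``median``).

        Uses the per-genotype depth matrix when present, otherwise the
        ``depth_mean``/``depth_median`` site columns.
        """
        if self.depths is not None:
            f = np.mean if stat == "mean" else np.median
            return f(self.depths, axis=0)
        col = f"depth_{stat}"
        if col in self.sites.columns:
            return self.sites[col].to_numpy(dtype=float)
        raise PanelError(f"no depth information available for stat {stat!r}")

    # ------------------------------------------------------------------
    def with_policy(self, policy: str) -> "GenotypeMatrix":
        """Return a copy using the requested counted-allele policy.

        Codes flip x → 2−x at sites where the counted allele changes; the
        flip is involutive and leaves MAF and heterozygote codes unchanged.
        Minor alleles are defined from the sample frequency under the
        current coding; on a 50/50 tie the current counted allele is kept.
        """
        if policy not in ("reference", "minor"):
            raise PanelError(f"unknown counted_allele_policy {policy!r}")
        if policy == self.counted_allele_policy:
            return self.copy()
        p = self.counted_allele_freq()
        if policy == "minor":
            flip = p > 0.5  # counted allele is currently the major allele
        else:
            # minor-counted back to reference-counted: flip where the stored
            # minor allele is the alternate, recorded at conversion time.
            if "counted_is_ref" not in self.sites.columns:
                raise PanelError(
                    "cannot restore reference coding: no counted_is_ref record"
                )
            flip = ~self.sites["counted_is_ref"].to_numpy(dtype=bool)
        out = self.copy()
        g = out.genotypes
        cols = np.flatnonzero(flip)
        sub = g[:, cols]
        g[:, cols] = np.where(sub == MISSING, MISSING, 2 - sub)
        out.counted_allele_policy = policy
        if policy == "minor":
            out.sites = out.sites.copy()
            out.sites["counted_is_ref"] = ~flip
        else:
            out.sites = out.sites.drop(columns=["counted_is_ref"])
        return out

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            sites=self.sites.copy(),
            genotypes=self.genotypes.copy(),
            counted_allele_policy=self.counted_allele_policy,
            depths=None if self.depths is None else self.depths.copy(),
            gt_probs=None if self.gt_probs is None else self.gt_probs.copy(),
        )

    def subset(
        self,
        lines: Sequence[str] | np.ndarray | None = None,
        site_mask: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Subset by line ids and/or a boolean site mask."""
        out = self.copy()
        if lines is not None:
            idx = [out.line_ids.index(str(l)) for l in lines]
            out.line_ids = [out.line_ids[i] for i in idx]
            out.genotypes = out.genotypes[idx]
            if out.depths is not None:
                out.depths = out.depths[idx]
            if out.gt_probs is not None:
                out.gt_probs = out.gt_probs[idx]
        if site_mask is not None:
            site_mask = np.asarray(site_mask, dtype=bool)
            out.sites = out.sites.loc[site_mask].reset_index(drop=True)
            out.genotypes = out.genotypes[:, site_mask]
            if out.depths is not None:
                out.depths = out.depths[:, site_mask]
            if out.gt_probs is not None:
                out.gt_probs = out.gt_probs[:, site_mask]
        return out

    def drop_lines(self, lines: Sequence[str]) -> "GenotypeMatrix":
        drop = {str(l) for l in lines}
        keep = [l for l in self.line_ids if l not in drop]
        return self.subset(lines=keep)


@dataclass
class SiteFilterSpec:
    """Site/genotype quality filters applied by :func:`apply_site_filters`.

    Defaults follow common inbred-panel practice: biallelic SNPs with a
    depth summary between 5 and 60 reads, per-site call rate of at least
    80%, sample MAF of at least 5% (inclusive), and genotype calls below
    99% confidence masked to missing.
    """

    biallelic_only: bool = True
    depth_min: float = 5.0
    depth_max: float = 60.0
    maf_min: float = 0.05
    call_rate_min: float = 0.80
    genotype_prob_min: float = 0.99
    depth_stat: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min <= 0.5):
            raise PanelError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if self.depth_min > self.depth_max:
            raise PanelError("depth_min must be <= depth_max")
        if self.depth_stat not in ("mean", "median"):
            raise PanelError(f"depth_stat must be 'mean' or 'median'")


@dataclass
class PhenotypeTable:
    """Replicate-level phenotypes: one row per (line, replicate).

    ``data`` has columns ``line``, ``rep`` plus one column per trait
    (concentration-scale positive reals for compositional traits).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("line", "rep"):
            if col not in self.data.columns:
                raise PanelError(f"phenotype table lacks column {col!r}")
        self.data = self.data.copy()
        self.data["line"] = self.data["line"].astype(str)
        if self.data.duplicated(["line", "rep"]).any():
            raise PanelError("duplicate (line, rep) rows in phenotype table")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("line", "rep")]

    @property
    def lines(self) -> list[str]:
        return sorted(self.data["line"].unique())

    def unmatched_lines(self, gm: GenotypeMatrix) -> list[str]:
        """Phenotyped lines absent from the companion genotype matrix."""
        have = set(gm.line_ids)
        return [l for l in self.lines if l not in have]


@dataclass
class FilterReport:
    """Counts of sites removed per criterion, in application order."""

    n_input: int = 0
    removed_not_biallelic: int = 0
    removed_depth: int = 0
    removed_call_rate: int = 0
    removed_maf: int = 0
    n_output: int = 0

    @property
    def total_removed(self) -> int:
        return (
            self.removed_not_biallelic
            + self.removed_depth
            + self.removed_call_rate
            + self.removed_maf
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": [
                    "input",
                    "not_biallelic",
                    "depth",
                    "call_rate",
                    "maf",
                    "output",
                ],
                "count": [
                    self.n_input,
                    self.removed_not_biallelic,
                    self.removed_depth,
                    self.removed_call_rate,
                    self.removed_maf,
                    self.n_output,
                ],
            }
        )
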