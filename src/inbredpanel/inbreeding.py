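"""Full-sib inbreeding theory and residual-heterozygosity summaries.

Repeated brother–sister mating drives the inbreeding coefficient F — the
probability that the two alleles of an individual are identical by
descent — toward 1 via the classical recurrence

    F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4,   F_0 = F_{-1} = 0,

so the expected fraction of founder heterozygosity retained after t
generations is 1 − F_t (≈ 1.4% at t = 20).  The empirical summaries here
measure residual heterozygosity per line (% of genotyped sites called
heterozygous) and per site (% of genotyped lines heterozygous), plus the
heterozygosity–depth association used to spot collapsed duplications.

No MAF/depth site filtering is assumed for these summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .panel import MISSING, GenotypeMatrix, PanelError


@lru_cache(maxsize=None)
def fullsib_inbreeding_coefficient(t: int) -> float:
    """Inbreeding coefficient after ``t`` generations of full-sib mating.

    Iterates F_t = (1 + 2F_{t-1} + F_{t-2})/4 from unrelated, non-inbred
    founders (F_0 = F_{-1} = 0).  F_20 ≈ 0.986.
    """
    t = int(t)
    if t < 0:
        raise PanelError(f"generations must be >= 0, got {t}")
    f_prev2, f_prev1 = 0.0, 0.0  # F_{-1}, F_0
    f = 0.0
    for _ in range(t):
        f = (1.0 + 2.0 * f_prev1 + f_prev2) / 4.0
        f_prev2, f_prev1 = f_prev1, f
    return f


def expected_residual_heterozygosity(t: int) -> float:
    """Expected % of founder heterozygosity retained after ``t``
    generations of full-sib mating: 100·(1 − F_t).  ≈ 1.4% at t = 20."""
    return 100.0 * (1.0 - fullsib_inbreeding_coefficient(t))


@dataclass
class HetSummary:
    """Residual-heterozygosity summary for a panel.

    Percentages; ``per_line`` entries are NaN for lines with zero
    genotyped sites (excluded from the panel mean/SE), likewise
    ``per_site`` for sites with zero calls.
    """

    per_line: np.ndarray
    per_site: np.ndarray
    panel_mean: float
    panel_se: float
    theoretical_pct: float

    def line_frame(self, line_ids):
        import pandas as pd

        return pd.DataFrame({"line": line_ids, "het_pct": self.per_line})


def per_line_heterozygosity(gm: GenotypeMatrix) -> np.ndarray:
    """Per-line residual heterozygosity: 100 · #het / #genotyped.

    NaN for lines with no genotyped site.
    """
    called = gm.genotypes != MISSING
    n_called = called.sum(axis=1).astype(float)
    n_het = (gm.genotypes == 1).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, 100.0 * n_het / n_called, np.nan)


def per_site_heterozygosity(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site % of genotyped lines called heterozygous (NaN if no calls)."""
    called = gm.genotypes != MISSING
    n_called = called.sum(axis=0).astype(float)
    n_het = (gm.genotypes == 1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, 100.0 * n_het / n_called, np.nan)


def het_summary(gm: GenotypeMatrix, theory_generations: int = 20) -> HetSummary:
    per_line = per_line_heterozygosity(gm)
    per_site = per_site_heterozygosity(gm)
    ok = np.isfinite(per_line)
    mean = float(np.mean(per_line[ok])) if ok.any() else float("nan")
    se = (
        float(np.std(per_line[ok], ddof=1) / np.sqrt(ok.sum()))
        if ok.sum() > 1
        else float("nan")
    )
    return HetSummary(
        per_line=per_line,
        per_site=per_site,
        panel_mean=mean,
        panel_se=se,
        theoretical_pct=expected_residual_heterozygosity(theory_generations),
    )


def het_depth_association(
    per_site_het: np.ndarray, per_site_depth: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) between per-site residual
    heterozygosity and read depth, with its large-sample p-value.

    A positive association is the signature of collapsed duplications:
    paralogous reads stacking on one locus inflate both apparent
    heterozygosity and depth.  Raises on constant input (rho undefined).
    """
    het = np.asarray(per_site_het, dtype=float)
    depth = np.asarray(per_site_depth, dtype=float)
    if het.shape != depth.shape:
        raise PanelError("het and depth vectors differ in length")
    ok = np.isfinite(het) & np.isfinite(depth)
    if ok.sum() < 3:
        raise PanelError("need >= 3 sites with both het and depth defined")
    het, depth = het[ok], depth[ok]
    if np.ptp(het) == 0 or np.ptp(depth) == 0:
        raise PanelError("constant vector: Spearman rho undefined")
    rho, p = stats.spearmanr(het, depth)
    return float(rho), float(p)


def het_by_group_anova(per_line_het: np.ndarray, groups) -> tuple[float, float]:
    """One-way ANOVA of per-line heterozygosity by grouping factor (e.g.
    realized inbreeding generations).  Convenience check that shorter
    inbreeding did not leave detectably more heterozygosity."""
    het = np.asarray(per_line_het, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(het)
    samples = [het[ok & (groups == g)] for g in np.unique(groups[ok])]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) < 2:
        raise PanelError("need >= 2 groups for ANOVA")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)
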