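"""Individual-level mixed-model association with exact per-SNP REML Wald tests.

The model for replicate j of line i is

    y_ij = mu + beta * snp_i + g_i + e_ij,
    g ~ N(0, sigma2_A * A),   e ~ N(0, sigma2_E * I),

with A the genomic relatedness matrix between lines.  Fitting is REML
via a one-time spectral decomposition of the individual-level polygenic
covariance K = Z A Z' (Z the line-incidence map) followed by a bounded
1-D profile search over the variance ratio gamma = sigma2_A / sigma2_E.
The scan refits the variance components for every SNP (the SNP fixed
effect included), so the Wald statistic W = (beta/se)^2 is exact rather
than computed with stale null-model variances; p-values are chi2(1).

The rotation is recomputed only when the individual set changes
(missing-genotype drops), cached by line subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import MISSING, GenotypeMatrix, PanelError, PhenotypeTable
from .relatedness import GRM

logger = logging.getLogger(__name__)

_LOG_GAMMA_LO, _LOG_GAMMA_HI = -12.0, 12.0
_RATIO_TOL = 1e-8


def log_contrast(trait, divisor_trait, base: float | None = None) -> np.ndarray:
    """Log-contrast transform log(trait / divisor) per individual.

    Both traits must be strictly positive; a common multiplicative
    factor in both traits cancels.  ``base=None`` uses natural log.
    """
    t = np.asarray(trait, dtype=float)
    d = np.asarray(divisor_trait, dtype=float)
    if t.shape != d.shape:
        raise PanelError("trait and divisor differ in length")
    bad = np.flatnonzero(~((t > 0) & (d > 0)))
    if len(bad):
        raise PanelError(
            f"non-positive trait/divisor values at rows {bad[:10].tolist()}"
            f"{'...' if len(bad) > 10 else ''}"
        )
    out = np.log(t / d)
    if base is not None:
        out = out / np.log(base)
    return out


# ----------------------------------------------------------------------
# REML machinery
# ----------------------------------------------------------------------

class _Rotation:
    """Eigendecomposition of K = A[lines, lines] at the individual level."""

    __slots__ = ("d", "u", "uty", "n")

    def __init__(self, k: np.ndarray, y: np.ndarray):
        d, u = np.linalg.eigh((k + k.T) / 2.0)
        if d.min() < -1e-6 * max(1.0, d.max()):
            raise PanelError(
                "relatedness matrix not positive semidefinite beyond tolerance; "
                "clip negative eigenvalues to 0 (see GRM docs) before fitting"
            )
        self.d = np.clip(d, 0.0, None)
        self.u = u
        self.uty = u.T @ y
        self.n = len(y)


def _profile_reml(rot: _Rotation, utx: np.ndarray, gamma: float):
    """REML log-likelihood (up to a constant) and GLS pieces at ratio
    gamma = sigma2_A/sigma2_E."""
    w = 1.0 + gamma * rot.d
    xtwx = (utx.T / w) @ utx
    xtwy = (utx.T / w) @ rot.uty
    try:
        bhat = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, None
    resid = rot.uty - utx @ bhat
    rss = float(np.sum(resid**2 / w))
    n, p = rot.n, utx.shape[1]
    if rss <= 0:
        return -np.inf, None, None, None
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf, None, None, None
    ll = -0.5 * (
        (n - p) * np.log(rss / (n - p))
        + np.sum(np.log(w))
        + logdet_xtwx
    )
    return ll, bhat, rss, xtwx


def _reml_fit(rot: _Rotation, utx: np.ndarray):
    """Maximize the REML profile over gamma via grid + bounded refine."""
    grid = np.concatenate(([-np.inf], np.linspace(_LOG_GAMMA_LO, _LOG_GAMMA_HI, 25)))

    def neg(s: float) -> float:
        g = 0.0 if s == -np.inf else float(np.exp(s))
        return -_profile_reml(rot, utx, g)[0]

    vals = [neg(s) for s in grid]
    best = int(np.nanargmin(vals))
    if best == 0:
        gamma = 0.0
        boundary = True
        converged = True
    else:
        lo = grid[max(best - 1, 1)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            neg, bounds=(lo, hi), method="bounded",
            options={"xatol": _RATIO_TOL},
        )
        converged = bool(res.success)
        gamma = float(np.exp(res.x))
        # prefer the boundary if it is at least as good
        if neg(-np.inf) <= res.fun:
            gamma, boundary = 0.0, True
        else:
            boundary = res.x <= _LOG_GAMMA_LO + 1e-6 or res.x >= _LOG_GAMMA_HI - 1e-6
    ll, bhat, rss, xtwx = _profile_reml(rot, utx, gamma)
    n, p = rot.n, utx.shape[1]
    sigma2_e = rss / (n - p)
    sigma2_a = gamma * sigma2_e
    cov = np.linalg.inv(xtwx) * sigma2_e
    return {
        "gamma": gamma,
        "params": bhat,
        "cov_params": cov,
        "sigma2_a": sigma2_a,
        "sigma2_e": sigma2_e,
        "loglike": ll,
        "converged": converged,
        "boundary": boundary,
    }


# ----------------------------------------------------------------------
# Model / Results
# ----------------------------------------------------------------------

class PanelMixedLM:
    """Mixed linear model for replicated inbred-line phenotypes.

    Parameters
    ----------
    endog
        Phenotype per individual (already transformed, e.g. log-contrast).
    lines
        Line label per individual.
    grm
        :class:`~inbredpanel.relatedness.GRM` (or a (matrix, ids) pair)
        covering every phenotyped line.
    exog
        Optional fixed-effect columns beyond the intercept (e.g. the SNP
        dosage), shape (n, k).
    exog_names
        Names for those columns.
    """

    def __init__(self, endog, lines, grm, exog=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.lines = [str(l) for l in lines]
        if len(self.lines) != len(self.endog):
            raise PanelError("endog and lines differ in length")
        if isinstance(grm, GRM):
            a, ids = grm.matrix, grm.line_ids
        else:
            a, ids = grm
            ids = [str(i) for i in ids]
        missing = sorted(set(self.lines) - set(ids))
        if missing:
            raise PanelError(f"lines absent from GRM: {missing[:10]}")
        idx = np.array([ids.index(l) for l in self.lines])
        self.k = np.asarray(a, dtype=float)[np.ix_(idx, idx)]
        cols = [np.ones(len(self.endog))]
        names = ["intercept"]
        if exog is not None:
            exog = np.atleast_2d(np.asarray(exog, dtype=float))
            if exog.shape[0] != len(self.endog):
                exog = exog.T
            cols.extend(exog.T)
            names.extend(
                exog_names or [f"x{i + 1}" for i in range(exog.shape[1])]
            )
        self.exog = np.column_stack(cols)
        self.exog_names = names
        self._rotation: _Rotation | None = None

    def _rotate(self) -> _Rotation:
        if self._rotation is None:
            self._rotation = _Rotation(self.k, self.endog)
        return self._rotation

    def fit(self) -> "PanelMixedLMResults":
        """REML fit; returns a results object with estimates,
        uncertainties, variance components and Wald tests."""
        rot = self._rotate()
        utx = rot.u.T @ self.exog
        raw = _reml_fit(rot, utx)
        # identifiability: with no line replication and A ~ I the two
        # variance components enter only through their sum
        _, counts = np.unique(self.lines, return_counts=True)
        no_reps = counts.max() == 1
        a_like_i = np.allclose(self.k, np.eye(len(self.endog)), atol=1e-10)
        identifiable = not (no_reps and a_like_i)
        return PanelMixedLMResults(self, raw, identifiable=identifiable)


class PanelMixedLMResults:
    """REML estimates for :class:`PanelMixedLM`."""

    def __init__(self, model: PanelMixedLM, raw: dict, identifiable: bool = True):
        self.model = model
        self.params = pd.Series(raw["params"], index=model.exog_names)
        self.cov_params = pd.DataFrame(
            raw["cov_params"], index=model.exog_names, columns=model.exog_names
        )
        self.bse = pd.Series(
            np.sqrt(np.diag(raw["cov_params"])), index=model.exog_names
        )
        self.sigma2_a = float(raw["sigma2_a"])
        self.sigma2_e = float(raw["sigma2_e"])
        self.loglike = float(raw["loglike"])
        self.converged = bool(raw["converged"])
        self.vc_boundary = bool(raw["boundary"])
        self.identifiable = identifiable

    @property
    def heritability(self) -> float:
        """Genomic heritability sigma2_A/(sigma2_A + sigma2_E) (assumes
        the GRM diagonal is ≈ 1, as under inbred scaling)."""
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else float("nan")

    def wald_test(self, name: str) -> tuple[float, float]:
        """Wald statistic (beta/se)^2 and its chi2(1) p-value."""
        w = float((self.params[name] / self.bse[name]) ** 2)
        return w, float(stats.chi2.sf(w, df=1))

    def summary(self) -> str:
        lines = [
            "Panel mixed LM (REML)",
            "=" * 52,
            f"{'n individuals':<24}{len(self.model.endog):>10}",
            f"{'n lines':<24}{len(set(self.model.lines)):>10}",
            f"{'sigma2_A (polygenic)':<24}{self.sigma2_a:>10.4f}",
            f"{'sigma2_E (residual)':<24}{self.sigma2_e:>10.4f}",
            f"{'heritability':<24}{self.heritability:>10.4f}",
            f"{'REML loglik':<24}{self.loglike:>10.3f}",
            f"{'converged':<24}{str(self.converged):>10}",
            f"{'VC at boundary':<24}{str(self.vc_boundary):>10}",
            f"{'identifiable':<24}{str(self.identifiable):>10}",
            "-" * 52,
            f"{'term':<12}{'coef':>10}{'se':>10}{'W':>9}{'p':>11}",
        ]
        for name in self.model.exog_names:
            w, p = self.wald_test(name)
            lines.append(
                f"{name:<12}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{w:>9.3f}{p:>11.3g}"
            )
        return "\n".join(lines)


def fit_mixed_null(
    pheno: PhenotypeTable, grm: GRM, trait: str, divisor: str | None = None
) -> PanelMixedLMResults:
    """Null (no-SNP) REML fit: y = mu + g + e; gives the genomic
    heritability.  With ``divisor`` set, the trait is log-contrast
    transformed first."""
    df = pheno.data
    y = (
        log_contrast(df[trait], df[divisor])
        if divisor
        else df[trait].to_numpy(dtype=float)
    )
    model = PanelMixedLM(y, df["line"], grm)
    return model.fit()


# ----------------------------------------------------------------------
# Genome scan
# ----------------------------------------------------------------------

@dataclass
class GwasResult:
    """Per-SNP scan results plus run-level metadata."""

    table: pd.DataFrame
    n_tests: int
    bonferroni_neglog10: float
    suggestive_neglog10: float
    null_heritability: float | None = None

    def hits(self, level: str = "bonferroni") -> pd.DataFrame:
        return self.table.loc[self.table[f"sig_{level}"] == True]  # noqa: E712


def significance_thresholds(
    n_tests: int, alpha: float = 0.05, suggestive_p: float = 1e-5
) -> tuple[float, float]:
    """(-log10 Bonferroni threshold, -log10 suggestive threshold)."""
    if n_tests < 1:
        raise PanelError("n_tests must be >= 1")
    return float(-np.log10(alpha / n_tests)), float(-np.log10(suggestive_p))


def snp_wald_scan(
    pheno: PhenotypeTable,
    gm: GenotypeMatrix,
    grm: GRM,
    trait: str = "focal",
    divisor: str | None = "divisor",
    maf_min: float = 0.05,
    alpha: float = 0.05,
    suggestive_p: float = 1e-5,
) -> GwasResult:
    """Single-marker mixed-model scan with per-SNP exact REML Wald tests.

    For every SNP the full model is refit — variance components
    re-estimated with the SNP effect included.  Individuals from lines
    with a MISSING genotype at the SNP are dropped for that test (the
    spectral rotation is re-computed per line subset, cached).  SNPs
    monomorphic among phenotyped lines, or below ``maf_min`` there, are
    excluded with a reason.  The SNP fixed effect is the minor-allele
    dosage (0/1/2), heterozygotes additive.
    """
    df = pheno.data.reset_index(drop=True)
    unmatched = pheno.unmatched_lines(gm)
    if unmatched:
        raise PanelError(f"phenotyped lines absent from genotypes: {unmatched[:10]}")
    y_all = (
        log_contrast(df[trait], df[divisor])
        if divisor
        else df[trait].to_numpy(dtype=float)
    )
    ind_lines = df["line"].to_numpy()
    gm_minor = gm.with_policy("minor") if gm.counted_allele_policy != "minor" else gm
    line_idx = {l: i for i, l in enumerate(gm_minor.line_ids)}
    row_of_ind = np.array([line_idx[l] for l in ind_lines])
    a_ids = [str(i) for i in grm.line_ids]
    a_idx = {l: i for i, l in enumerate(a_ids)}
    rotations: dict[frozenset, tuple[_Rotation, np.ndarray, np.ndarray]] = {}

    def rotation_for(mask: np.ndarray):
        key = frozenset(np.flatnonzero(~mask).tolist())
        if key not in rotations:
            rows = np.array([a_idx[l] for l in ind_lines[mask]])
            k = grm.matrix[np.ix_(rows, rows)]
            rot = _Rotation(k, y_all[mask])
            ones = rot.u.T @ np.ones(mask.sum())
            rotations[key] = (rot, ones, mask.copy())
        return rotations[key]

    records = []
    null_fit = fit_mixed_null(pheno, grm, trait, divisor)
    for j in range(gm_minor.n_sites):
        site = gm_minor.sites.iloc[j]
        g_line = gm_minor.genotypes[:, j]
        dose_ind = g_line[row_of_ind].astype(float)
        keep = dose_ind != MISSING
        rec = {
            "chrom": site["chrom"],
            "pos": int(site["pos"]),
            "ref": site["ref"],
            "alt": site["alt"],
            "n_lines": int(len(set(ind_lines[keep]))),
            "maf": np.nan,
            "beta": np.nan,
            "se": np.nan,
            "sigma2_a": np.nan,
            "sigma2_e": np.nan,
            "wald": np.nan,
            "p": np.nan,
            "excluded": "",
        }
        used = dose_ind[keep]
        if keep.sum() < 3 or len(set(ind_lines[keep])) < 3:
            rec["excluded"] = "too_few_lines"
            records.append(rec)
            continue
        # per-line frequency among phenotyped+called lines
        lines_used, first = np.unique(ind_lines[keep], return_index=True)
        line_dose = used[first]
        p_snp = line_dose.mean() / 2.0
        maf = min(p_snp, 1 - p_snp)
        rec["maf"] = float(maf)
        if line_dose.var() == 0:
            rec["excluded"] = "monomorphic"
            records.append(rec)
            continue
        if maf < maf_min:
            rec["excluded"] = "maf_below_min"
            records.append(rec)
            continue
        rot, ones_rot, _ = rotation_for(keep)
        utx = np.column_stack([ones_rot, rot.u.T @ used])
        try:
            raw = _reml_fit(rot, utx)
        except PanelError:
            rec["excluded"] = "fit_failed"
            records.append(rec)
            continue
        if not raw["converged"] or raw["params"] is None:
            rec["excluded"] = "non_converged"
            records.append(rec)
            continue
        beta = float(raw["params"][1])
        se = float(np.sqrt(raw["cov_params"][1, 1]))
        w = (beta / se) ** 2
        rec.update(
            beta=beta,
            se=se,
            sigma2_a=float(raw["sigma2_a"]),
            sigma2_e=float(raw["sigma2_e"]),
            wald=float(w),
            p=float(stats.chi2.sf(w, df=1)),
        )
        records.append(rec)
    table = pd.DataFrame(records)
    tested = table["excluded"] == ""
    n_tests = int(tested.sum())
    bonf, sugg = significance_thresholds(max(n_tests, 1), alpha, suggestive_p)
    with np.errstate(divide="ignore"):
        table["neglog10p"] = -np.log10(table["p"])
    table["sig_bonferroni"] = tested & (table["neglog10p"] > bonf)
    table["sig_suggestive"] = tested & (table["neglog10p"] > sugg)
    table = table.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return GwasResult(
        table=table,
        n_tests=n_tests,
        bonferroni_neglog10=bonf,
        suggestive_neglog10=sugg,
        null_heritability=null_fit.heritability,
    )


def annotate_hits(
    results: pd.DataFrame, gene_models, flank_bp: int = 3000
) -> pd.DataFrame:
    """Label significant SNPs as within-gene / near-gene (≤ flank) /
    intergenic, with nearest gene id and distance.

    ``results`` needs chrom/pos columns; ``gene_models`` is a GFF3 path
    or the mapping from :func:`~inbredpanel.panel_io.load_gene_models`.
    """
    from .panel_io import load_gene_models

    if not isinstance(gene_models, dict):
        gene_models = load_gene_models(gene_models)
    db = gene_models["db"]
    genes = list(db.features_of_type("gene"))
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.seqid, []).append(g)
    rows = []
    for _, snp in results.iterrows():
        pos = int(snp["pos"])
        best = (None, np.inf)
        for g in by_chrom.get(snp["chrom"], []):
            if g.start <= pos <= g.end:
                dist = 0
            else:
                dist = min(abs(pos - g.start), abs(pos - g.end))
            if dist < best[1]:
                best = (g, dist)
        gene, dist = best
        if gene is None:
            ctx, gid, d = "intergenic", "", np.nan
        elif dist == 0:
            ctx, gid, d = "within_gene", gene.id, 0
        elif dist <= flank_bp:
            ctx, gid, d = "near_gene", gene.id, dist
        else:
            ctx, gid, d = "intergenic", gene.id, dist
        row = dict(snp)
        row.update(context=ctx, nearest_gene=gid, gene_distance=d)
        rows.append(row)
    return pd.DataFrame(rows)
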