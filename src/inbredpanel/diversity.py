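"""Windowed nucleotide diversity, Tajima's D, folded SFS, and LD decay.

Per site with j copies of one allele among n called alleles, the mean
pairwise difference is 2j(n−j)/(n(n−1)); windowed π divides the sum of
these by the window length in bp (per-bp diversity).  Tajima's D
standardizes the difference between the pairwise estimator and the
Watterson estimator S/a1 of θ using Tajima's (1989) constants; it is
negative when rare alleles are in excess.  LD is the squared Pearson
correlation r² of allele-count vectors for SNP pairs within
non-overlapping 500 bp tiles, summarized as a distance-binned decay
curve.

Windows are 0-based half-open tiles from coordinate 0 of each scaffold.
Sites with MISSING calls contribute their per-site called allele count
(no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypeMatrix, PanelError


# ----------------------------------------------------------------------
# Per-site building blocks
# ----------------------------------------------------------------------

def _site_counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(n_alleles, alt_copies) per site over called diploid genotypes."""
    called = gm.genotypes != MISSING
    n = 2 * called.sum(axis=0)
    j = np.where(called, gm.genotypes, 0).sum(axis=0)
    return n.astype(np.int64), j.astype(np.int64)


def site_pi(n: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Mean pairwise difference per site: 2j(n−j)/(n(n−1)); 0 when n < 2."""
    n = np.asarray(n, dtype=float)
    j = np.asarray(j, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    return np.where(n >= 2, pi, 0.0)


def folded_sfs(
    gm: GenotypeMatrix,
    classes: np.ndarray | None = None,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Folded (minor-allele) frequency spectrum, optionally by site class.

    Returns one row per (class, bin) with counts, plus the singleton
    count per class reported separately — a singleton is a variant
    carried by exactly one line (MAF = 1/n_lines for a homozygous
    carrier; 0.009 in a 110-line panel).
    """
    if bins is None:
        bins = np.linspace(0.0, 0.5, 26)
    maf = gm.maf()
    p = gm.counted_allele_freq()
    gmin = gm.with_policy("minor") if gm.counted_allele_policy != "minor" else gm
    carriers = (gmin.genotypes > 0).sum(axis=0)
    singleton = carriers == 1
    if classes is None:
        classes = np.full(gm.n_sites, "all", dtype=object)
    classes = np.asarray(classes, dtype=object)
    rows = []
    for cls in pd.unique(classes):
        in_cls = (classes == cls) & np.isfinite(maf) & (maf > 0)
        counts, edges = np.histogram(maf[in_cls & ~singleton], bins=bins)
        for lo, hi, cnt in zip(edges[:-1], edges[1:], counts):
            rows.append(
                {"class": cls, "maf_low": lo, "maf_high": hi, "count": int(cnt),
                 "singleton": False}
            )
        rows.append(
            {"class": cls, "maf_low": np.nan, "maf_high": np.nan,
             "count": int((in_cls & singleton).sum()), "singleton": True}
        )
    return pd.DataFrame(rows)


def singleton_maf(n_lines: int) -> float:
    """MAF of a variant homozygous in exactly one of ``n_lines`` lines."""
    if n_lines < 1:
        raise PanelError("n_lines must be >= 1")
    return 1.0 / n_lines


# ----------------------------------------------------------------------
# Windowed statistics
# ----------------------------------------------------------------------

def _windows(gm: GenotypeMatrix, window_bp: int, chrom_lengths=None):
    """Yield (chrom, start, end, site_index_array) for 0-based half-open
    tiles from coordinate 0; the final window of each scaffold keeps its
    true bp length when the scaffold length is known (else full tiles up
    to the last site)."""
    for chrom, sub in gm.sites.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1  # to 0-based
        idx = sub.index.to_numpy()
        length = None
        if chrom_lengths is not None and chrom in chrom_lengths:
            length = int(chrom_lengths[chrom])
        last = length if length is not None else int(pos0.max()) + 1
        start = 0
        while start < last:
            end = min(start + window_bp, last) if length is not None else start + window_bp
            in_win = (pos0 >= start) & (pos0 < end)
            yield chrom, start, min(end, last) if length is not None else end, idx[in_win]
            start += window_bp


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima's (1989) a1, a2, b1, b2, c1, c2, e1, e2 for sample size n."""
    if n < 2:
        raise PanelError("Tajima constants need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(pi_sum: float, s: int, n: int) -> float:
    """Tajima's D from the summed pairwise diversity, S and sample size n.

    NaN when S = 0 or n < 3 (statistic undefined).  At n = 3 every
    segregating site is a singleton and both estimators of theta agree,
    so the 0/0 limit is resolved to D = 0.
    """
    if s == 0 or n < 3:
        return float("nan")
    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    num = pi_sum - s / k["a1"]
    if var <= 0:
        return 0.0 if abs(num) < 1e-12 else float("nan")
    return num / np.sqrt(var)


def window_pi(
    gm: GenotypeMatrix, window_bp: int = 50_000, chrom_lengths=None
) -> pd.DataFrame:
    """Per-window nucleotide diversity (per-bp): Σ_site 2j(n−j)/(n(n−1))
    divided by the window length.  Monomorphic sites contribute 0."""
    n, j = _site_counts(gm)
    pis = site_pi(n, j)
    seg = (j > 0) & (j < n)
    rows = []
    for chrom, start, end, idx in _windows(gm, window_bp, chrom_lengths):
        length = end - start
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_segregating": int(seg[idx].sum()),
                "statistic": "pi",
                "value": float(pis[idx].sum() / length) if length > 0 else 0.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_segregating", "statistic", "value"]
    )


def window_tajimas_d(
    gm: GenotypeMatrix,
    window_bp: int = 50_000,
    chrom_lengths=None,
    ploidy_mode: str = "diploid",
) -> pd.DataFrame:
    """Per-window Tajima's D.

    The sample size n for Tajima's constants is the diploid called-allele
    count (2 × mean called lines over the window's segregating sites,
    rounded) since lines retain heterozygous calls; set
    ``ploidy_mode="haploid"`` to use the mean called-line count instead
    for fully-inbred treatments.  Windows with S = 0 or n < 3 carry NaN.
    """
    if ploidy_mode not in ("diploid", "haploid"):
        raise PanelError(f"unknown ploidy_mode {ploidy_mode!r}")
    n, j = _site_counts(gm)
    pis = site_pi(n, j)
    seg = (j > 0) & (j < n)
    rows = []
    for chrom, start, end, idx in _windows(gm, window_bp, chrom_lengths):
        sidx = idx[seg[idx]]
        s = len(sidx)
        if s == 0:
            d = float("nan")
            n_eff = 0
        else:
            mean_alleles = float(n[sidx].mean())
            n_eff = int(round(mean_alleles if ploidy_mode == "diploid" else mean_alleles / 2.0))
            d = tajimas_d(float(pis[sidx].sum()), s, n_eff)
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_segregating": s,
                "statistic": "tajimas_d",
                "value": d,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_segregating", "statistic", "value"]
    )


# ----------------------------------------------------------------------
# Linkage disequilibrium
# ----------------------------------------------------------------------

def ld_r2_pairs(
    gm: GenotypeMatrix, window_bp: int = 500, min_lines: int = 3
) -> pd.DataFrame:
    """r² for every SNP pair within the same non-overlapping window tile.

    r² is the squared Pearson correlation of allele-count vectors over
    the lines where both sites are called; pairs with fewer than
    ``min_lines`` co-called lines (or zero variance) are skipped.
    Assumes the matrix is already site-filtered and related lines
    removed.
    """
    rows = []
    n_skipped = 0
    for chrom, start, end, idx in _windows(gm, window_bp):
        if len(idx) < 2:
            continue
        g = gm.genotypes[:, idx].astype(float)
        pos = gm.sites["pos"].to_numpy()[idx]
        called = g != MISSING
        for a in range(len(idx) - 1):
            for b in range(a + 1, len(idx)):
                both = called[:, a] & called[:, b]
                if both.sum() < min_lines:
                    n_skipped += 1
                    continue
                x, y = g[both, a], g[both, b]
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    n_skipped += 1
                    continue
                r = np.corrcoef(x, y)[0, 1]
                rows.append(
                    {
                        "chrom": chrom,
                        "pos1": int(pos[a]),
                        "pos2": int(pos[b]),
                        "distance": int(abs(pos[b] - pos[a])),
                        "r2": float(r * r),
                    }
                )
    df = pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "distance", "r2"])
    df.attrs["n_skipped"] = n_skipped
    return df


def ld_decay_curve(records: pd.DataFrame, bin_bp: int = 5) -> pd.DataFrame:
    """Mean r² by half-open distance bin [k·bin_bp, (k+1)·bin_bp), per
    chromosome; empty bins are omitted."""
    if records.empty:
        raise PanelError("no LD records to bin")
    df = records.copy()
    df["bin"] = (df["distance"] // bin_bp).astype(int)
    out = (
        df.groupby(["chrom", "bin"], sort=True)
        .agg(mean_r2=("r2", "mean"), n_pairs=("r2", "size"))
        .reset_index()
    )
    out["dist_low"] = out["bin"] * bin_bp
    out["dist_high"] = (out["bin"] + 1) * bin_bp
    return out[["chrom", "dist_low", "dist_high", "mean_r2", "n_pairs"]]


def ld_halving_distance(curve: pd.DataFrame, threshold: float = 0.1) -> float:
    """Smallest bin midpoint distance at which mean r² (averaged over
    chromosomes) first drops below ``threshold``; NaN if it never does."""
    pooled = (
        curve.assign(mid=(curve["dist_low"] + curve["dist_high"]) / 2.0)
        .groupby("mid")
        .apply(
            lambda d: np.average(d["mean_r2"], weights=d["n_pairs"]),
            include_groups=False,
        )
        .sort_index()
    )
    below = pooled[pooled < threshold]
    return float(below.index[0]) if len(below) else float("nan")
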