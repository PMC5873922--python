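"""Genomic relatedness and the random-matrix-theory substructure test.

Relatedness between lines j and k is the standardized allele-sharing

    A_jk = (1/N) Σ_i (χ_ij − 2p_i)(χ_ik − 2p_i) / (2 p_i (1 − p_i)),

with χ_ij the allele-count code and p_i the sample frequency of the
counted allele (the statistic is invariant to which allele is counted).
Under this "standard" scaling a pair of identical fully-inbred lines
scores ≈ 2; the default "inbred" scaling divides by two so duplicates
score ≈ 1, the conventional scale for fully-inbred panels.

The substructure test eigendecomposes the *unnormalized* allele-count
Gram matrix X = CC′ (C the M lines × N SNPs minor-allele count matrix,
complete-data SNPs only), scaled so that for a single homogeneous
population of lines with inbreeding coefficient F the noise eigenvalues
concentrate at 1/2.  Eigenvalues exceeding t = (1 + F)/2 mark population
structure; the count of supra-threshold eigenvalues estimates the number
of subpopulations (a single population shows exactly one, carried by the
positive mean of the uncentered counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panel import MISSING, GenotypeMatrix, PanelError

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    """Square line×line genomic relatedness matrix."""

    matrix: np.ndarray
    line_ids: list[str]
    n_snps_used: int
    scaling_mode: str  # "standard" | "inbred"
    allele_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.line_ids)
        if self.matrix.shape != (n, n):
            raise PanelError("GRM shape does not match line ids")

    def index_of(self, line: str) -> int:
        return self.line_ids.index(str(line))

    def subset(self, lines) -> "GRM":
        idx = [self.index_of(l) for l in lines]
        return GRM(
            matrix=self.matrix[np.ix_(idx, idx)],
            line_ids=[self.line_ids[i] for i in idx],
            n_snps_used=self.n_snps_used,
            scaling_mode=self.scaling_mode,
            allele_freqs=self.allele_freqs,
        )


def compute_grm(gm: GenotypeMatrix, scaling_mode: str = "inbred") -> GRM:
    """Genomic relatedness matrix from allele-count genotypes.

    MISSING genotypes are mean-imputed to 2p_i (contributing zero to the
    centered cross-product); sites monomorphic after imputation are
    skipped with a warning.  ``scaling_mode="inbred"`` divides all
    entries by 2 (duplicate fully-inbred lines ≈ 1), ``"standard"``
    applies the formula literally (duplicates ≈ 2).
    """
    if scaling_mode not in ("standard", "inbred"):
        raise PanelError(f"unknown scaling_mode {scaling_mode!r}")
    if gm.n_lines < 2:
        raise PanelError("need >= 2 lines for a relatedness matrix")
    if gm.n_sites < 1:
        raise PanelError("need >= 1 site for a relatedness matrix")
    p = gm.counted_allele_freq()
    usable = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.warning(
            "%d sites monomorphic or call-free; skipped in GRM", n_skipped
        )
    if not usable.any():
        raise PanelError("no polymorphic sites available for the GRM")
    g = gm.genotypes[:, usable].astype(float)
    pu = p[usable]
    centered = np.where(g == MISSING, 0.0, g - 2.0 * pu)
    w = centered / np.sqrt(2.0 * pu * (1.0 - pu))
    n = int(usable.sum())
    a = (w @ w.T) / n
    if scaling_mode == "inbred":
        a = a / 2.0
    return GRM(
        matrix=a,
        line_ids=list(gm.line_ids),
        n_snps_used=n,
        scaling_mode=scaling_mode,
        allele_freqs=pu,
    )


def flag_related_pairs(grm: GRM, cutoff: float = 0.1) -> list[tuple[str, str, float]]:
    """All unordered line pairs with A_jk ≥ cutoff, sorted descending."""
    m = grm.matrix
    iu = np.triu_indices(len(grm.line_ids), k=1)
    vals = m[iu]
    hits = np.flatnonzero(vals >= cutoff)
    out = [
        (grm.line_ids[iu[0][h]], grm.line_ids[iu[1][h]], float(vals[h])) for h in hits
    ]
    out.sort(key=lambda x: (-x[2], x[0], x[1]))
    return out


def reduce_panel(grm: GRM, cutoff: float = 0.1) -> tuple[list[str], list[str]]:
    """Deterministically remove one line per connected component of the
    flagged-pair graph (the lexicographically last id of the component).

    Returns (kept_line_ids, removed_line_ids).
    """
    pairs = flag_related_pairs(grm, cutoff)
    adj: dict[str, set[str]] = {}
    for a, b, _ in pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    removed: list[str] = []
    seen: set[str] = set()
    for start in sorted(adj):
        if start in seen:
            continue
        comp = []
        stack = [start]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            comp.append(node)
            stack.extend(adj[node] - seen)
        removed.append(max(comp))
    kept = [l for l in grm.line_ids if l not in set(removed)]
    return kept, sorted(removed)


# ----------------------------------------------------------------------
# Random-matrix substructure test
# ----------------------------------------------------------------------

@dataclass
class StructureResult:
    """Eigenvalue spectrum of the scaled count Gram matrix and the
    supra-threshold count (= inferred number of subpopulations)."""

    eigenvalues: np.ndarray  # descending
    m_lines: int
    n_snps: int
    inbreeding_f: float
    threshold: float
    n_significant: int

    @property
    def n_subpopulations(self) -> int:
        return self.n_significant

    def to_dict(self) -> dict:
        return {
            "eigenvalues": [float(x) for x in self.eigenvalues],
            "m_lines": self.m_lines,
            "n_snps": self.n_snps,
            "inbreeding_f": self.inbreeding_f,
            "threshold": self.threshold,
            "n_significant": self.n_significant,
        }


def build_count_matrix(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """M×N minor-allele count matrix from complete-data sites only.

    No centering or frequency normalization is applied.  Returns
    (C, site_mask) where site_mask marks the complete-data sites used.
    """
    gm_minor = gm.with_policy("minor")
    complete = (gm_minor.genotypes != MISSING).all(axis=0)
    if not complete.any():
        raise PanelError("no sites without missing data for the count matrix")
    c = gm_minor.genotypes[:, complete].astype(np.float64)
    return c, complete


def rmt_scale_gram(c: np.ndarray, inbreeding_f: float) -> np.ndarray:
    """Scale the allele-count Gram matrix CC′ for the eigenvalue test.

    Scaling of the random-matrix substructure test (after Bryc and
    co-workers' analysis of count-matrix spectra): with per-SNP count
    variance var_i = 2 p_i (1 − p_i)(1 + F) for lines at inbreeding F,

        X = C C′ / ( 2 · Σ_i var_i · (1 + sqrt(M/N))² ).

    For a single homogeneous population the noise eigenvalues then
    concentrate at 1/2 — strictly below the significance threshold
    t = (1 + F)/2 — while each distinct subpopulation mean contributes
    one separated eigenvalue; the (1 + sqrt(M/N))² factor absorbs the
    finite-sample Marchenko–Pastur edge.  p_i is the sample minor-allele
    frequency.
    """
    m, n = c.shape
    if n < 1:
        raise PanelError("count matrix has no SNPs")
    p = c.mean(axis=0) / 2.0
    var = 2.0 * p * (1.0 - p) * (1.0 + inbreeding_f)
    denom = 2.0 * var.sum() * (1.0 + np.sqrt(m / n)) ** 2
    if denom <= 0:
        raise PanelError("degenerate count matrix: zero total variance")
    return (c @ c.T) / denom


def structure_test(
    c: np.ndarray | None = None,
    inbreeding_f: float = 0.986,
    x_scaled: np.ndarray | None = None,
    n_snps: int | None = None,
) -> StructureResult:
    """Count eigenvalues of the scaled count Gram matrix above
    t = (1 + F)/2; the count estimates the number of subpopulations.

    Provide either ``c`` (an M×N minor-allele count matrix, scaled here)
    or ``x_scaled`` (an already-scaled square matrix, e.g. read from a
    relatedness-matrix text file).  Ties at the threshold are not
    significant (strict inequality).
    """
    if not (0.0 <= inbreeding_f <= 1.0):
        raise PanelError(f"inbreeding coefficient outside [0,1]: {inbreeding_f}")
    if (c is None) == (x_scaled is None):
        raise PanelError("provide exactly one of c or x_scaled")
    if c is not None:
        m, n = c.shape
        x = rmt_scale_gram(np.asarray(c, dtype=float), inbreeding_f)
    else:
        x = np.asarray(x_scaled, dtype=float)
        if x.ndim != 2 or x.shape[0] != x.shape[1]:
            raise PanelError("x_scaled must be square")
        if not np.allclose(x, x.T, atol=1e-8, rtol=0.0):
            raise PanelError("x_scaled asymmetric beyond 1e-8")
        m = x.shape[0]
        n = int(n_snps) if n_snps is not None else 0
    eig = np.linalg.eigvalsh((x + x.T) / 2.0)[::-1]
    t = (1.0 + inbreeding_f) / 2.0
    n_sig = int((eig > t).sum())
    return StructureResult(
        eigenvalues=eig,
        m_lines=m,
        n_snps=n,
        inbreeding_f=float(inbreeding_f),
        threshold=float(t),
        n_significant=n_sig,
    )
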