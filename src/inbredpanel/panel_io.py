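"""Reading, writing and deterministic filtering of panel data.

Covers VCF genotype matrices (via cyvcf2 for parsing), GFF3 gene models
for site classification, square whitespace-delimited relatedness-matrix
text files, replicate-level phenotype tables, and the fixed-order site
filters (biallelic → depth → call rate → MAF) with a removal report.

Coordinates are 1-based inclusive externally (VCF/GFF); internal window
arithmetic elsewhere in the package is 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (
    MISSING,
    FilterReport,
    GenotypeMatrix,
    PanelError,
    PhenotypeTable,
    SiteFilterSpec,
)

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def read_vcf(path: str | Path, counted_allele_policy: str = "reference") -> GenotypeMatrix:
    """Read a VCF (v4.x, GT required; DP and GQ/GP used when present).

    Genotypes are decoded to counted-allele codes (heterozygote → 1 under
    either policy); ``./.`` maps to MISSING.  Multi-allelic records are
    retained but flagged ``biallelic=False`` for the biallelic filter.
    """
    from cyvcf2 import VCF

    if counted_allele_policy not in ("reference", "minor"):
        raise PanelError(
            f"unknown counted_allele_policy {counted_allele_policy!r}"
        )
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # malformed header
        raise PanelError(f"cannot parse VCF header of {path}: {exc}") from exc
    line_ids = list(vcf.samples)
    fmt_tags = set()
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "FORMAT":
                fmt_tags.add(h["ID"])
        except KeyError:
            continue
    rows = []
    codes = []
    depths = []
    probs = []
    have_depth = False
    have_prob = False
    n_rec = 0
    try:
        for var in vcf:
            n_rec += 1
            alts = var.ALT if var.ALT else []
            biallelic = (
                len(alts) == 1
                and len(var.REF) == 1
                and len(alts[0]) == 1
                and alts[0] in "ACGT"
            )
            rows.append(
                {
                    "chrom": var.CHROM,
                    "pos": var.POS,
                    "ref": var.REF,
                    "alt": ",".join(alts) if alts else ".",
                    "biallelic": biallelic,
                }
            )
            # count of reference alleles per sample
            gts = var.genotype.array()  # (n, ploidy+1), -1 for missing allele
            alleles = gts[:, :2]
            called = (alleles >= 0).all(axis=1)
            nref = (alleles == 0).sum(axis=1)
            code = np.where(called, nref, MISSING).astype(np.int8)
            codes.append(code)
            dp = var.format("DP") if "DP" in fmt_tags else None
            if dp is not None:
                have_depth = True
                d = dp.astype(float).reshape(-1)
                d[d < 0] = np.nan
                depths.append(d)
            else:
                depths.append(np.full(len(line_ids), np.nan))
            gp = var.format("GP") if "GP" in fmt_tags else None
            gq = var.format("GQ") if "GQ" in fmt_tags else None
            if gp is not None:
                have_prob = True
                pr = np.nanmax(gp.astype(float), axis=1)
                probs.append(pr)
            elif gq is not None:
                have_prob = True
                q = gq.astype(float).reshape(-1)
                pr = 1.0 - np.power(10.0, -q / 10.0)
                pr[q < 0] = np.nan
                probs.append(pr)
            else:
                probs.append(np.full(len(line_ids), np.nan))
    except PanelError:
        raise
    except Exception as exc:
        raise PanelError(
            f"malformed VCF record near data line {n_rec + 1} of {path}: {exc}"
        ) from exc
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "biallelic"])
    geno = (
        np.stack(codes, axis=1)
        if codes
        else np.zeros((len(line_ids), 0), dtype=np.int8)
    )
    depth_m = np.stack(depths, axis=1) if codes else None
    prob_m = np.stack(probs, axis=1) if codes else None
    if len(sites):
        sites["depth_mean"] = np.nanmean(depth_m, axis=0) if have_depth else np.nan
        sites["depth_median"] = (
            np.nanmedian(depth_m, axis=0) if have_depth else np.nan
        )
    else:
        sites["depth_mean"] = pd.Series(dtype=float)
        sites["depth_median"] = pd.Series(dtype=float)
    gm = GenotypeMatrix(
        line_ids=line_ids,
        sites=sites,
        genotypes=geno,
        counted_allele_policy="reference",
        depths=depth_m if have_depth else None,
        gt_probs=prob_m if have_prob else None,
    )
    if counted_allele_policy == "minor":
        gm = gm.with_policy("minor")
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a VCF v4.2 with GT (plus DP/GQ when available).

    Genotype codes round-trip exactly for biallelic sites; an empty site
    list yields a header-only VCF.
    """
    g = gm.with_policy("reference") if gm.counted_allele_policy != "reference" else gm
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=inbredpanel\n")
        for chrom in pd.unique(g.sites["chrom"]) if g.n_sites else []:
            sub = g.sites.loc[g.sites["chrom"] == chrom, "pos"]
            fh.write(f"##contig=<ID={chrom},length={int(sub.max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if g.depths is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if g.gt_probs is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.line_ids)
            + "\n"
        )
        gt_map = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
        fmt = "GT"
        if g.depths is not None:
            fmt += ":DP"
        if g.gt_probs is not None:
            fmt += ":GQ"
        for j in range(g.n_sites):
            site = g.sites.iloc[j]
            fields = []
            for i in range(g.n_lines):
                parts = [gt_map[int(g.genotypes[i, j])]]
                if g.depths is not None:
                    d = g.depths[i, j]
                    parts.append("." if not np.isfinite(d) else str(int(round(d))))
                if g.gt_probs is not None:
                    p = g.gt_probs[i, j]
                    if not np.isfinite(p):
                        parts.append(".")
                    else:
                        q = 99 if p >= 1.0 else min(99, int(round(-10 * np.log10(max(1 - p, 1e-10)))))
                        parts.append(str(q))
                fields.append(":".join(parts))
            fh.write(
                f"{site['chrom']}\t{int(site['pos'])}\t.\t{site['ref']}\t"
                f"{site['alt']}\t.\tPASS\t.\t{fmt}\t" + "\t".join(fields) + "\n"
            )


# ----------------------------------------------------------------------
# Genotype masking and site filters
# ----------------------------------------------------------------------

def mask_low_confidence(
    gm: GenotypeMatrix, genotype_prob_min: float = 0.99
) -> GenotypeMatrix:
    """Set genotype calls with probability strictly below the threshold to
    MISSING.  A matrix without confidence information is returned
    unchanged (warning logged)."""
    out = gm.copy()
    if gm.gt_probs is None:
        logger.warning(
            "no genotype confidence (GP/GQ) available; mask_low_confidence is a no-op"
        )
        return out
    with np.errstate(invalid="ignore"):
        low = (out.gt_probs < genotype_prob_min) & (out.genotypes != MISSING)
    low &= np.isfinite(out.gt_probs)
    out.genotypes[low] = MISSING
    return out


def apply_site_filters(
    gm: GenotypeMatrix, spec: SiteFilterSpec | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the panel site filters in fixed order and report removals.

    Order: biallelic → depth summary in [depth_min, depth_max] →
    call rate ≥ call_rate_min → MAF ≥ maf_min (all inclusive).  MAF is
    computed from non-MISSING diploid allele counts.
    """
    spec = spec or SiteFilterSpec()
    report = FilterReport(n_input=gm.n_sites)
    if gm.n_sites == 0:
        return gm.copy(), report
    keep = np.ones(gm.n_sites, dtype=bool)
    if spec.biallelic_only:
        if "biallelic" in gm.sites.columns:
            bi = gm.sites["biallelic"].to_numpy(dtype=bool)
        else:
            alt = gm.sites["alt"].astype(str)
            ref = gm.sites["ref"].astype(str)
            bi = (~alt.str.contains(",")).to_numpy() & (alt.str.len() == 1).to_numpy() & (
                ref.str.len() == 1
            ).to_numpy()
        report.removed_not_biallelic = int((keep & ~bi).sum())
        keep &= bi
    try:
        depth = gm.depth_summary(spec.depth_stat)
        with np.errstate(invalid="ignore"):
            ok = (depth >= spec.depth_min) & (depth <= spec.depth_max)
        ok |= ~np.isfinite(depth)  # sites without depth info pass
    except PanelError:
        logger.warning("no depth information; depth filter skipped")
        ok = np.ones(gm.n_sites, dtype=bool)
    report.removed_depth = int((keep & ~ok).sum())
    keep &= ok
    cr = gm.call_rate()
    ok = cr >= spec.call_rate_min
    report.removed_call_rate = int((keep & ~ok).sum())
    keep &= ok
    maf = gm.maf()
    with np.errstate(invalid="ignore"):
        ok = maf >= spec.maf_min
    ok &= np.isfinite(maf)
    report.removed_maf = int((keep & ~ok).sum())
    keep &= ok
    out = gm.subset(site_mask=keep)
    report.n_output = out.n_sites
    return out, report


# ----------------------------------------------------------------------
# GFF3 site classification
# ----------------------------------------------------------------------

def _merged_intervals(feats) -> dict[str, np.ndarray]:
    """Merge 1-based inclusive (start, end) features per contig into
    sorted, disjoint half-open interval arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in feats:
        by_chrom.setdefault(f.seqid, []).append((f.start, f.end + 1))
    out = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        merged = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64)
    return out


def _in_intervals(pos: np.ndarray, ivals: np.ndarray) -> np.ndarray:
    if len(ivals) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(ivals[:, 0], pos, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(len(pos), dtype=bool)
    hit[ok] = pos[ok] < ivals[idx[ok], 1]
    return hit


def load_gene_models(gff_path: str | Path):
    """Parse a GFF3 into per-contig merged gene and exon interval maps."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = list(db.features_of_type("gene"))
    exons = list(db.features_of_type("exon"))
    return {"gene": _merged_intervals(genes), "exon": _merged_intervals(exons), "db": db}


def classify_sites(gm: GenotypeMatrix, gene_models) -> np.ndarray:
    """Classify each site as ``exonic``, ``intronic`` or ``intergenic``.

    Priority exon > intron; a site inside a gene body but no exon is
    intronic.  Contigs absent from the GFF are intergenic (warning).

    ``gene_models`` is a GFF3 path or the mapping from
    :func:`load_gene_models`.
    """
    if not isinstance(gene_models, dict):
        gene_models = load_gene_models(gene_models)
    classes = np.full(gm.n_sites, "intergenic", dtype=object)
    known = set(gene_models["gene"]) | set(gene_models["exon"])
    for chrom, sub in gm.sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        idx = sub.index.to_numpy()
        if chrom not in known:
            logger.warning("contig %s absent from gene models; sites left intergenic", chrom)
            continue
        in_gene = _in_intervals(pos, gene_models["gene"].get(chrom, np.empty((0, 2), int)))
        in_exon = _in_intervals(pos, gene_models["exon"].get(chrom, np.empty((0, 2), int)))
        classes[idx[in_exon]] = "exonic"
        classes[idx[in_gene & ~in_exon]] = "intronic"
    return classes.astype(str)


# ----------------------------------------------------------------------
# Square relatedness-matrix text
# ----------------------------------------------------------------------

def read_grm_text(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a whitespace-delimited square symmetric matrix.

    A leading id row and/or id column is auto-detected.  Returns
    (matrix, ids); ids default to ``L1..Ln`` when the file has none.
    Non-square or asymmetric (beyond 1e-8) input raises ``PanelError``.
    """
    raw = [l.split() for l in Path(path).read_text().splitlines() if l.strip()]
    if not raw:
        raise PanelError(f"{path} is empty")

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    first_row_ids = not all(_numeric(t) for t in raw[0])
    body = raw[1:] if first_row_ids else raw
    if not body:
        raise PanelError(f"{path} has no matrix rows")
    first_col_ids = not all(_numeric(r[0]) for r in body)
    ids_row = raw[0] if first_row_ids else None
    if first_col_ids:
        ids = [r[0] for r in body]
        vals = [r[1:] for r in body]
    else:
        vals = body
        ids = None
    try:
        mat = np.array([[float(x) for x in r] for r in vals], dtype=float)
    except ValueError as exc:
        raise PanelError(f"non-numeric matrix entry in {path}: {exc}") from exc
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise PanelError(f"{path}: matrix is not square, shape {mat.shape}")
    if ids is None and ids_row is not None:
        # header row may carry a corner label
        ids = ids_row[-mat.shape[0]:] if len(ids_row) >= mat.shape[0] else None
    if ids is None:
        ids = [f"L{i + 1}" for i in range(mat.shape[0])]
    if len(ids) != mat.shape[0]:
        raise PanelError(f"{path}: id count {len(ids)} != matrix size {mat.shape[0]}")
    if not np.allclose(mat, mat.T, atol=1e-8, rtol=0.0):
        raise PanelError(f"{path}: matrix asymmetric beyond 1e-8")
    return mat, [str(i) for i in ids]


def write_grm_text(
    matrix: np.ndarray, path: str | Path, ids: list[str] | None = None
) -> None:
    """Write a square symmetric matrix as whitespace-delimited text with a
    leading id row and column; 12 significant digits."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise PanelError(f"matrix is not square: {matrix.shape}")
    ids = ids or [f"L{i + 1}" for i in range(n)]
    with Path(path).open("w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for i in range(n):
            fh.write(ids[i] + "\t" + "\t".join(f"{x:.12g}" for x in matrix[i]) + "\n")


# ----------------------------------------------------------------------
# Phenotype tables
# ----------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a TSV with header columns line, rep, <trait...>."""
    df = pd.read_csv(path, sep="\t")
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
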