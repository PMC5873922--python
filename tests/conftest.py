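import numpy as np
import pandas as pd
import pytest

from inbredpanel.panel import GenotypeMatrix


def make_gm(codes, positions=None, chrom="chr1", depths=None, gt_probs=None,
            policy="reference", line_ids=None):
    """Build a GenotypeMatrix from a nested list of codes (lines x sites)."""
    codes = np.asarray(codes, dtype=np.int8)
    n_lines, n_sites = codes.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": "A",
            "alt": "C",
            "biallelic": True,
        }
    )
    return GenotypeMatrix(
        line_ids=line_ids or [f"L{i + 1}" for i in range(n_lines)],
        sites=sites,
        genotypes=codes,
        counted_allele_policy=policy,
        depths=None if depths is None else np.asarray(depths, dtype=float),
        gt_probs=None if gt_probs is None else np.asarray(gt_probs, dtype=float),
    )


TOY_GFF = """\
##gff-version 3
chr1\ttest\tgene\t100\t500\t.\t+\t.\tID=geneA
chr1\ttest\texon\t100\t200\t.\t+\t.\tID=geneA.e1;Parent=geneA
chr1\ttest\texon\t400\t500\t.\t+\t.\tID=geneA.e2;Parent=geneA
chr1\ttest\tgene\t1000\t1400\t.\t-\t.\tID=geneB
chr1\ttest\texon\t1000\t1100\t.\t-\t.\tID=geneB.e1;Parent=geneB
"""


@pytest.fixture()
def toy_gff(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF)
    return path


@pytest.fixture(scope="session")
def sim_panel_small():
    """A small deterministic synthetic panel shared across tests."""
    from inbredpanel.simulate import SimConfig, simulate_panel

    cfg = SimConfig(seed=42, n_lines=40, sequence_length=30_000)
    return simulate_panel(cfg)
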