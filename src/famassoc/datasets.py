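"""Bundled example data.

``interaction_replication_table`` returns the published replication results
for 14 SNP-pair interaction tests on gene-expression probes in a 20-family
blood-pressure cohort (13 distinct SNP pairs; one gene, CTSC, contributes
two probes and hence two rows). These p-values are the worked-example input
for the combined set test: with 14 tests the Bonferroni threshold is
0.05/14 = 0.0036, two pairs fall below it, and the remaining 12 are combined
into a single overall p-value.
"""

from __future__ import annotations

import pandas as pd

from .settest import PValueSet, TestEntry

_ROWS = [
    # gene, probe, snp1, chr1, snp2, chr2, p
    ("ATP13A1", "GI_9966896-S",   "rs4284750",  19, "rs873870",   19, 0.000101),
    ("CSTB",    "GI_20357564-S",  "rs9979356",  21, "rs3761385",  21, 0.000747),
    ("CTSC",    "GI_22538439-I",  "rs7930237",  11, "rs556895",   11, 0.020446),
    ("CTSC",    "GI_22538438-I",  "rs7930237",  11, "rs556895",   11, 0.636009),
    ("FN3KRP",  "GI_20149679-S",  "rs898095",   17, "rs9892064",  17, 0.015972),
    ("GAA",     "GI_11496988-S",  "rs11150847", 17, "rs12602462", 17, 0.240101),
    ("LAX1",    "GI_8923315-S",   "rs1891432",  1,  "rs10900520", 1,  0.205055),
    ("MBNL1",   "GI_41281590-S",  "rs16864367", 3,  "rs13079208", 3,  0.01683),
    ("MBNL1",   "GI_41281590-S",  "rs7710738",  5,  "rs13069559", 3,  0.938258),
    ("MBNL1",   "GI_41281590-S",  "rs2186711",  7,  "rs13069559", 3,  0.178989),
    ("MBNL1",   "GI_41281590-S",  "rs11981513", 7,  "rs13069559", 3,  0.307821),
    ("PRMT2",   "GI_4504494-S",   "rs2839372",  21, "rs11701058", 21, 0.4209),
    ("TRA2A",   "GI_33620726-S",  "rs7776572",  7,  "rs11770192", 7,  0.51894),
    ("VASP",    "GI_4507868-S",   "rs1264226",  19, "rs2276470",  19, 0.645204),
]

#: genes whose SNP pair fell below the 0.05/14 Bonferroni threshold
SIGNIFICANT_GENES = ("ATP13A1", "CSTB")


def interaction_replication_table() -> pd.DataFrame:
    """The 14 published interaction replication tests as a DataFrame."""
    return pd.DataFrame(
        _ROWS, columns=["gene", "probe", "snp1", "chr1", "snp2", "chr2", "p"])


def interaction_pvalue_set(drop_significant: bool = False) -> PValueSet:
    """The published tests as a :class:`PValueSet` for the combined test.

    SNP positions are not part of the published table, so distinct SNPs are
    assigned placeholder coordinates farther apart than the LD window (their
    pairwise LD is unknown and treated as zero); a SNP reused across rows
    keeps one coordinate, so SNP sharing is still visible to the correlation
    model. Each row's probe is its trait id: rows on different probes are
    independent under the null.
    """
    df = interaction_replication_table()
    if drop_significant:
        df = df[~df.gene.isin(SIGNIFICANT_GENES)].reset_index(drop=True)
    coord: dict[str, tuple[str, int, int]] = {}
    for r in df.itertuples(index=False):
        for snp, chrom in ((r.snp1, r.chr1), (r.snp2, r.chr2)):
            if snp not in coord:
                coord[snp] = (snp, int(chrom),
                              1 + len(coord) * 10_000_000)
    tests = [
        TestEntry(test_id=f"{r.gene}:{r.probe}:{r.snp1}x{r.snp2}",
                  p=float(r.p),
                  snps=(coord[r.snp1], coord[r.snp2]),
                  trait=str(r.probe))
        for r in df.itertuples(index=False)
    ]
    return PValueSet(tests)
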