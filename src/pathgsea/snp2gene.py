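"""SNP-to-gene mapping with flanking windows and per-gene statistics.

A SNP belongs to a gene when it falls inside the gene interval extended by
``flank`` base pairs on both sides (default 20 kb, closed on both
boundaries, lower bound clamped at 1).  Strand is ignored: "upstream" and
"downstream" are symmetric in genomic coordinates.  A SNP inside two
overlapping flanked windows contributes to both genes.

The per-gene representative statistic is the maximum association statistic
over the gene's surviving SNPs; genes with no surviving SNP drop out, and
the count of ranked genes downstream equals the number of genes retained
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PipelineError
from .io import GeneAnnotation, GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 20_000


@dataclass
class SnpGeneMap:
    """gene_id -> list of snp_ids (genes with zero SNPs are absent)."""

    flank: int
    gene_to_snps: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_to_snps)

    def genes(self) -> list[str]:
        return list(self.gene_to_snps)


def _snp_frame(snps) -> pd.DataFrame:
    if isinstance(snps, GenotypeMatrix):
        return snps.snp_frame()
    df = pd.DataFrame(snps)
    missing = {"snp_id", "chrom", "pos"} - set(df.columns)
    if missing:
        raise PipelineError(f"SNP table missing columns {sorted(missing)}")
    return df


def map_snps_to_genes(snps, genes: GeneAnnotation, flank: int = DEFAULT_FLANK) -> SnpGeneMap:
    """Map SNPs into flanked gene windows.

    ``snps`` is a :class:`GenotypeMatrix` or a frame with snp_id/chrom/pos.
    SNP chromosomes absent from the annotation are warned about and left
    unmapped.
    """
    df = _snp_frame(snps)
    out: dict[str, list[str]] = {}
    gene_chroms = set(map(str, genes.chrom))
    orphan = sorted(set(map(str, df["chrom"])) - gene_chroms)
    if orphan:
        logger.warning(
            "SNP chromosomes %s have no annotated genes; those SNPs stay unmapped",
            orphan,
        )
    by_chrom = {
        str(c): sub.sort_values("pos") for c, sub in df.groupby(df["chrom"].astype(str))
    }
    for gi in range(len(genes)):
        c = str(genes.chrom[gi])
        sub = by_chrom.get(c)
        if sub is None:
            continue
        lo = max(1, int(genes.start[gi]) - flank)
        hi = int(genes.end[gi]) + flank
        pos = sub["pos"].to_numpy()
        a, b = np.searchsorted(pos, lo, side="left"), np.searchsorted(pos, hi, side="right")
        if b > a:
            out[str(genes.gene_ids[gi])] = sub["snp_id"].iloc[a:b].astype(str).tolist()
    return SnpGeneMap(flank=flank, gene_to_snps=out)


def gene_statistics(assoc: pd.DataFrame, snp_map: SnpGeneMap) -> pd.DataFrame:
    """Per-gene representative statistic r = max(stat over mapped, surviving SNPs).

    Ties in the maximum are broken for ``best_snp`` reporting by smaller
    P-value then lexicographic snp_id (the value of r is unaffected).
    Returns columns gene_id, r, best_snp, n_snps sorted by gene_id.
    """
    stat = dict(zip(assoc["snp_id"].astype(str), assoc["stat"].astype(float)))
    pval = dict(zip(assoc["snp_id"].astype(str), assoc["p"].astype(float)))
    rows = []
    for gene_id in sorted(snp_map.gene_to_snps):
        snps = [s for s in snp_map.gene_to_snps[gene_id] if s in stat]
        if not snps:
            continue
        best = min(snps, key=lambda s: (-stat[s], pval[s], s))
        rows.append((gene_id, stat[best], best, len(snps)))
    if not rows:
        raise PipelineError("no gene has a surviving associated SNP")
    return pd.DataFrame(rows, columns=["gene_id", "r", "best_snp", "n_snps"])


def write_gene_statistics(df: pd.DataFrame, genes: GeneAnnotation, path) -> None:
    """Optional TSV dump: GENE, CHR, START, END, N_SNPS, BEST_SNP, R_STAT."""
    ann = genes.to_frame().set_index("gene_id")
    with open(path, "w") as fh:
        fh.write("GENE\tCHR\tSTART\tEND\tN_SNPS\tBEST_SNP\tR_STAT\n")
        for _, row in df.iterrows():
            g = ann.loc[row["gene_id"]]
            fh.write(
                f"{row['gene_id']}\t{g['chrom']}\t{g['start']}\t{g['end']}\t"
                f"{row['n_snps']}\t{row['best_snp']}\t{row['r']!r}\n"
            )
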