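import numpy as np
import pandas as pd
import pytest

from pathgsea.io import GeneAnnotation, GeneSet, GeneSetCollection, GenotypeMatrix
from pathgsea.simulate import SimulationConfig, simulate_study


def make_genotypes(dosage, chrom=None, pos=None, snp_ids=None, individual_ids=None,
                   alleles=None):
    """Small GenotypeMatrix from a dosage array (NaN = missing)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    snp_ids = np.array(snp_ids if snp_ids is not None
                       else [f"snp{j}" for j in range(m)], dtype=object)
    chrom = np.array(chrom if chrom is not None else ["1"] * m, dtype=object)
    pos = np.array(pos if pos is not None else np.arange(1, m + 1) * 1000,
                   dtype=np.int64)
    individual_ids = np.array(individual_ids if individual_ids is not None
                              else [f"I{i}" for i in range(n)], dtype=object)
    alleles = np.array(alleles if alleles is not None else [("A", "G")] * m,
                       dtype=object)
    gm = GenotypeMatrix(individual_ids=individual_ids, snp_ids=snp_ids,
                        chrom=chrom, pos=pos, alleles=alleles, dosage=dosage)
    gm.validate()
    return gm


def make_genes(rows):
    """GeneAnnotation from (gene_id, chrom, start, end) tuples."""
    gene_ids, chrom, start, end = zip(*rows)
    ann = GeneAnnotation(
        gene_ids=np.array(gene_ids, dtype=object),
        chrom=np.array(chrom, dtype=object),
        start=np.array(start, dtype=np.int64),
        end=np.array(end, dtype=np.int64),
    )
    ann.validate()
    return ann


def make_sets(pairs):
    """GeneSetCollection from (set_id, member list) pairs."""
    return GeneSetCollection(
        [GeneSet(sid, "test set", tuple(members)) for sid, members in pairs]
    )


def make_pheno(tg, bmi=None, ids=None):
    tg = np.asarray(tg, dtype=float)
    n = tg.size
    return pd.DataFrame({
        "individual_id": ids if ids is not None else [f"I{i}" for i in range(n)],
        "tg": tg,
        "bmi": bmi if bmi is not None else np.linspace(22, 38, n),
    })


@pytest.fixture(scope="session")
def small_study():
    """A compact causal study reused across tests (session-scoped: read-only)."""
    cfg = SimulationConfig(
        n_individuals=300, n_snps=400, n_genes=80, n_sets=10,
        set_size_range=(5, 15), n_causal_genes=5, causal_set_index=0, seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """A no-effect study for calibration-style checks."""
    cfg = SimulationConfig(
        n_individuals=400, n_snps=500, n_genes=100, n_sets=12,
        set_size_range=(5, 20), seed=23,
    )
    return simulate_study(cfg)
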