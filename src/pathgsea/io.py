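"""File formats and core containers.

Supported text formats:

* PLINK ``.ped``/``.map`` genotypes (biallelic SNPs only);
* a TSV dosage dialect (individuals as rows, SNPs as columns, ``NA`` missing),
  paired with a ``.map`` file for SNP coordinates;
* BED3+ gene annotation (column 4 = gene id);
* GMT gene-set collections;
* TSV phenotype and result tables.

Coordinate convention: everything in memory is **1-based inclusive** (the
convention of ``.map`` positions).  BED's 0-based half-open intervals are
converted at the boundary, so BED ``[start, end)`` becomes ``[start+1, end]``.

On loading PLINK text genotypes the counted allele is re-polarized to the
*observed minor* allele (frequency ties broken toward the lexicographically
smaller allele), so dosages count minor-allele copies.  Every association
statistic downstream is invariant to this relabeling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

MISSING = np.nan

RESULT_COLUMNS = [
    "set_id",
    "description",
    "size_total",
    "size_covered",
    "ES",
    "NES",
    "empirical_P",
    "FDR",
    "mode",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-dosage matrix with its SNP map.

    ``dosage[i, j]`` counts copies of ``alleles[j][1]`` (the counted allele)
    carried by individual ``i``; values are in {0, 1, 2} or NaN for missing.
    """

    individual_ids: np.ndarray  # (n,) str
    snp_ids: np.ndarray  # (m,) str
    chrom: np.ndarray  # (m,) str
    pos: np.ndarray  # (m,) int64, 1-based
    alleles: np.ndarray  # (m, 2) str, column 1 is the counted allele
    dosage: np.ndarray  # (n, m) float, NaN = missing

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def validate(self) -> None:
        if self.dosage.shape != (self.n_individuals, self.n_snps):
            raise DataError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{self.n_individuals} individuals x {self.n_snps} SNPs"
            )
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise DataError("dosage values must be in {0, 1, 2} or missing")
        if len(set(self.snp_ids)) != self.n_snps:
            raise DataError("duplicate SNP ids")
        if len(set(self.individual_ids)) != self.n_individuals:
            raise DataError("duplicate individual ids")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise DataError(f"positions not sorted on chromosome {c}")

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individual_ids=self.individual_ids,
            snp_ids=self.snp_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            alleles=self.alleles[index],
            dosage=self.dosage[:, index],
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individual_ids=self.individual_ids[index],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            alleles=self.alleles,
            dosage=self.dosage[index, :],
        )

    def snp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chrom": self.chrom,
                "pos": self.pos,
            }
        )


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive."""

    gene_ids: np.ndarray  # (g,) str
    chrom: np.ndarray  # (g,) str
    start: np.ndarray  # (g,) int64
    end: np.ndarray  # (g,) int64

    def __len__(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene ids")
        if np.any(self.start > self.end):
            raise DataError("gene interval with start > end")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
            }
        )


@dataclass
class GeneSet:
    set_id: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Ordered collection of gene sets (input order is preserved)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, i: int) -> GeneSet:
        return self.sets[i]

    def ids(self) -> list[str]:
        return [s.set_id for s in self.sets]

    def get(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


# ---------------------------------------------------------------------------
# float formatting helpers (round-trip safe)
# ---------------------------------------------------------------------------


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return "NA"
        return repr(float(x))
    return str(x)


def _parse_float(s: str) -> float:
    if s == "NA":
        return float("nan")
    if s.startswith("<"):
        s = s[1:]
    return float(s)


# ---------------------------------------------------------------------------
# PLINK .ped/.map
# ---------------------------------------------------------------------------


def read_map(map_path) -> pd.DataFrame:
    """Read a PLINK ``.map`` file (chrom, snp_id, cM, pos)."""
    rows = []
    seen: set[str] = set()
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(
                    f"expected 4 columns in .map, got {len(parts)}", map_path, ln
                )
            chrom, snp_id, _cm, pos = parts
            if snp_id in seen:
                raise FormatError(f"duplicate SNP id {snp_id!r}", map_path, ln)
            seen.add(snp_id)
            rows.append((chrom, snp_id, int(pos)))
    return pd.DataFrame(rows, columns=["chrom", "snp_id", "pos"])


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Load PLINK text genotypes.

    The counted allele of each SNP is the observed minor allele; frequency
    ties are broken toward the lexicographically smaller allele.  A ``0`` in
    either allele slot marks the genotype missing.  Non-biallelic SNPs,
    ragged rows and duplicate ids raise :class:`FormatError` naming the line.
    """
    snp_map = read_map(map_path)
    m = len(snp_map)

    individual_ids: list[str] = []
    geno_rows: list[list[tuple[str, str]]] = []
    # per-SNP observed allele counts
    allele_counts: list[dict[str, int]] = [dict() for _ in range(m)]

    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"expected {6 + 2 * m} fields (6 + 2x{m} genotype columns), "
                    f"got {len(parts)}",
                    ped_path,
                    ln,
                )
            iid = parts[1]
            if iid in individual_ids:
                raise FormatError(f"duplicate individual id {iid!r}", ped_path, ln)
            row = []
            for j in range(m):
                a1, a2 = parts[6 + 2 * j], parts[7 + 2 * j]
                row.append((a1, a2))
                for a in (a1, a2):
                    if a == "0":
                        continue
                    counts = allele_counts[j]
                    if a not in counts and len(counts) == 2:
                        raise FormatError(
                            f"SNP {snp_map.snp_id[j]!r} is not biallelic "
                            f"(third allele {a!r})",
                            ped_path,
                            ln,
                        )
                    counts[a] = counts.get(a, 0) + 1
            individual_ids.append(iid)
            geno_rows.append(row)

    n = len(individual_ids)
    alleles = np.empty((m, 2), dtype=object)
    dosage = np.full((n, m), np.nan)
    for j in range(m):
        counts = allele_counts[j]
        if len(counts) == 0:
            major, counted = "0", "0"
        elif len(counts) == 1:
            major, counted = next(iter(counts)), "0"
        else:
            (x, cx), (y, cy) = sorted(counts.items())
            # counted = minor; tie -> lexicographically smaller
            if cx < cy or (cx == cy):
                counted, major = x, y
            else:
                counted, major = y, x
        alleles[j] = (major, counted)
        for i in range(n):
            a1, a2 = geno_rows[i][j]
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 == counted) + (a2 == counted)

    gm = GenotypeMatrix(
        individual_ids=np.array(individual_ids, dtype=object),
        snp_ids=snp_map.snp_id.to_numpy(dtype=object),
        chrom=snp_map.chrom.to_numpy(dtype=object),
        pos=snp_map.pos.to_numpy(dtype=np.int64),
        alleles=alleles,
        dosage=dosage,
    )
    gm.validate()
    return gm


def write_map(gm: GenotypeMatrix, map_path) -> None:
    with open(map_path, "w") as fh:
        for j in range(gm.n_snps):
            fh.write(f"{gm.chrom[j]}\t{gm.snp_ids[j]}\t0\t{gm.pos[j]}\n")


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK text genotypes (FID = IID, unknown sex/phenotype)."""
    write_map(gm, map_path)
    code = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}
    with open(ped_path, "w") as fh:
        for i in range(gm.n_individuals):
            fields = [str(gm.individual_ids[i]), str(gm.individual_ids[i]), "0", "0", "0", "-9"]
            row = gm.dosage[i]
            for j in range(gm.n_snps):
                d = row[j]
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    k1, k2 = code[float(d)]
                    fields += [str(gm.alleles[j][k1]), str(gm.alleles[j][k2])]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TSV dosage dialect
# ---------------------------------------------------------------------------


def read_dosage_tsv(dosage_path, map_path) -> GenotypeMatrix:
    """Read the TSV dosage dialect (rows = IID, columns = SNPs, ``NA`` missing).

    The dialect carries no allele labels, so alleles are reported as the
    placeholder pair ``("A", "B")`` with ``B`` the counted allele.
    """
    snp_map = read_map(map_path)
    df = pd.read_csv(dosage_path, sep="\t", dtype={"IID": str})
    if "IID" not in df.columns:
        raise FormatError("dosage TSV must have an IID column", dosage_path, 1)
    snp_cols = [c for c in df.columns if c != "IID"]
    if list(snp_cols) != list(snp_map.snp_id):
        raise FormatError(
            "dosage TSV SNP columns do not match the .map file", dosage_path, 1
        )
    dosage = df[snp_cols].to_numpy(dtype=float)
    gm = GenotypeMatrix(
        individual_ids=df["IID"].to_numpy(dtype=object),
        snp_ids=snp_map.snp_id.to_numpy(dtype=object),
        chrom=snp_map.chrom.to_numpy(dtype=object),
        pos=snp_map.pos.to_numpy(dtype=np.int64),
        alleles=np.array([("A", "B")] * len(snp_map), dtype=object),
        dosage=dosage,
    )
    gm.validate()
    return gm


def write_dosage_tsv(gm: GenotypeMatrix, dosage_path, map_path) -> None:
    write_map(gm, map_path)
    with open(dosage_path, "w") as fh:
        fh.write("IID\t" + "\t".join(map(str, gm.snp_ids)) + "\n")
        for i in range(gm.n_individuals):
            vals = [
                "NA" if np.isnan(d) else str(int(d)) for d in gm.dosage[i]
            ]
            fh.write(str(gm.individual_ids[i]) + "\t" + "\t".join(vals) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``set_id <TAB> description <TAB> member...``.

    Duplicate members within a line are dropped (first occurrence kept) with
    a logged warning; lines with fewer than 3 fields are a format error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"GMT line needs >=3 tab-separated fields, got {len(parts)}",
                    path,
                    ln,
                )
            set_id, desc = parts[0], parts[1]
            members: list[str] = []
            seen: set[str] = set()
            dups = False
            for g in parts[2:]:
                if not g:
                    continue
                if g in seen:
                    dups = True
                    continue
                seen.add(g)
                members.append(g)
            if dups:
                logger.warning(
                    "GMT %s line %d (%s): duplicate member genes removed",
                    path,
                    ln,
                    set_id,
                )
            sets.append(GeneSet(set_id, desc, tuple(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# BED gene annotation
# ---------------------------------------------------------------------------


def read_bed_genes(path) -> GeneAnnotation:
    """Read BED3+ gene intervals; column 4 is the gene id.

    BED 0-based half-open ``[start, end)`` becomes 1-based inclusive
    ``[start+1, end]``.
    """
    gene_ids, chroms, starts, ends = [], [], [], []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(
                    "BED gene rows need >=4 columns (chrom start end name)", path, ln
                )
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if end <= start:
                raise FormatError(f"BED interval with end <= start ({start}, {end})", path, ln)
            if name in seen:
                raise FormatError(f"duplicate gene id {name!r}", path, ln)
            seen.add(name)
            gene_ids.append(name)
            chroms.append(chrom)
            starts.append(start + 1)
            ends.append(end)
    ann = GeneAnnotation(
        gene_ids=np.array(gene_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
    )
    ann.validate()
    return ann


def write_bed_genes(ann: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for i in range(len(ann)):
            fh.write(
                f"{ann.chrom[i]}\t{ann.start[i] - 1}\t{ann.end[i]}\t{ann.gene_ids[i]}\n"
            )


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

_PHENO_OUT_COLS = {
    "individual_id": "IID",
    "tg": "TG_MGDL",
    "bmi": "BMI",
    "sex": "SEX",
    "log_tg": "LOG_TG",
    "log_tg_adj": "LOG_TG_ADJ",
    "status": "STATUS",
    "included": "INCLUDED",
}
_PHENO_IN_COLS = {v: k for k, v in _PHENO_OUT_COLS.items()}


def write_phenotypes(df: pd.DataFrame, path) -> None:
    """Write a phenotype table (raw or prepared) as TSV."""
    out = df.rename(columns=_PHENO_OUT_COLS)
    cols = [c for c in _PHENO_OUT_COLS.values() if c in out.columns]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in out[cols].iterrows():
            fields = []
            for c in cols:
                v = row[c]
                if c == "INCLUDED":
                    fields.append(str(bool(v)))
                elif isinstance(v, (float, np.floating)):
                    fields.append(_fmt(v))
                else:
                    fields.append(str(v))
            fh.write("\t".join(fields) + "\n")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    missing = {"IID", "TG_MGDL", "BMI"} - set(df.columns)
    if missing:
        raise FormatError(f"phenotype TSV missing columns {sorted(missing)}", path, 1)
    if "INCLUDED" in df.columns:
        df["INCLUDED"] = df["INCLUDED"].astype(str).str.lower().isin(("true", "1"))
    return df.rename(columns=_PHENO_IN_COLS)


# ---------------------------------------------------------------------------
# association result tables
# ---------------------------------------------------------------------------

ASSOC_COLUMNS = ["SNP", "CHR", "BP", "MAF", "TEST", "STAT", "P", "N"]


def write_assoc(df: pd.DataFrame, path) -> None:
    """Write an association table (PLINK-like columns SNP CHR BP MAF TEST STAT P N)."""
    out = df.rename(
        columns={
            "snp_id": "SNP",
            "chrom": "CHR",
            "pos": "BP",
            "maf": "MAF",
            "test": "TEST",
            "stat": "STAT",
            "p": "P",
            "n_used": "N",
        }
    )
    with open(path, "w") as fh:
        fh.write("\t".join(ASSOC_COLUMNS) + "\n")
        for _, row in out[ASSOC_COLUMNS].iterrows():
            fh.write(
                "\t".join(
                    _fmt(row[c]) if c in ("MAF", "STAT", "P") else str(row[c])
                    for c in ASSOC_COLUMNS
                )
                + "\n"
            )


def read_assoc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    return df.rename(
        columns={
            "SNP": "snp_id",
            "CHR": "chrom",
            "BP": "pos",
            "MAF": "maf",
            "TEST": "test",
            "STAT": "stat",
            "P": "p",
            "N": "n_used",
        }
    )


def read_snp_pvalues(path) -> pd.DataFrame:
    """Read a plain two-column SNP/P TSV (header optional: SNP, P)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("expected two tab-separated columns (SNP, P)", path, 1)
    if set(df.columns) >= {"SNP", "P"}:
        out = df[["SNP", "P"]]
    else:
        out = df.iloc[:, :2]
        out.columns = ["SNP", "P"]
    out = out.rename(columns={"SNP": "snp_id", "P": "p"})
    out["snp_id"] = out["snp_id"].astype(str)
    out["p"] = out["p"].astype(float)
    if ((out["p"] <= 0) | (out["p"] > 1)).any():
        raise DataError(f"{path}: P-values must lie in (0, 1]")
    return out


# ---------------------------------------------------------------------------
# enrichment result tables
# ---------------------------------------------------------------------------


def write_results(df: pd.DataFrame, path, n_perm: int | None = None) -> None:
    """Write enrichment results as TSV.

    Rows are sorted by empirical P ascending, then NES descending.  When
    ``n_perm`` is given, empirical P-values at the permutation resolution
    ``1/(n_perm+1)`` (the smallest attainable value) are printed with a
    leading ``<`` to signal "below resolution".
    """
    cols_lower = {
        "es": "ES",
        "nes": "NES",
        "empirical_p": "empirical_P",
        "fdr": "FDR",
    }
    out = df.rename(columns=cols_lower).copy()
    out = out.sort_values(
        ["empirical_P", "NES"], ascending=[True, False], kind="mergesort"
    )
    floor = 1.0 / (n_perm + 1) if n_perm else None
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for _, row in out.iterrows():
            fields = []
            for c in RESULT_COLUMNS:
                v = row[c]
                if c == "empirical_P" and floor is not None and float(v) <= floor:
                    fields.append("<" + repr(float(v)))
                elif c in ("ES", "NES", "empirical_P", "FDR"):
                    fields.append(_fmt(float(v)))
                else:
                    fields.append(str(v))
            fh.write("\t".join(fields) + "\n")


def read_results(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != RESULT_COLUMNS:
            raise FormatError(f"unexpected result columns {header}", path, 1)
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(RESULT_COLUMNS):
                raise FormatError("ragged result row", path, ln)
            rec = dict(zip(RESULT_COLUMNS, parts))
            rec["size_total"] = int(rec["size_total"])
            rec["size_covered"] = int(rec["size_covered"])
            for c in ("ES", "NES", "empirical_P", "FDR"):
                rec[c] = _parse_float(rec[c])
            rows.append(rec)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
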