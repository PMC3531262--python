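"""Standard-format I/O: VCF v4.2 for genotypes/haplotypes, TSV for
pedigree, phenotype and map tables.

Conventions: 1-based positions; genotype codes 0/1/2 count copies of the
B allele, which is written as the VCF ALT allele; simulation truth is
written with phased GT ("0|1"), assay views with unphased GT and "./." for
missing. Imputation output carries GT (best guess), DS (dosage, 3
decimals) and GP (posterior triple, 4 decimals).

Reading uses cyvcf2; writing emits plain VCF text (biallelic SNPs only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import (MISSING, GenomeMap, Pedigree, PedigreeRecord,
                      PhenotypeRecord, UNKNOWN_PARENT)

_GT_UNPHASED = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_PAIR_PH = {(0, 0): "0|0", (0, 1): "0|1", (1, 0): "1|0", (1, 1): "1|1"}


def write_vcf(path, gmap: GenomeMap, sample_ids, genotypes=None,
              haplotypes=None, ds=None, gp=None) -> None:
    """Write biallelic SNP records for all map markers.

    Provide either ``haplotypes`` (n, 2, L; phased GT) or ``genotypes``
    (n, L int8 with -1 missing; unphased GT). ``ds``/``gp`` add DS and GP
    FORMAT fields.
    """
    if (genotypes is None) == (haplotypes is None):
        raise ValueError("provide exactly one of genotypes or haplotypes")
    n = len(sample_ids)
    L = gmap.n_markers
    fmt = "GT"
    if ds is not None:
        fmt += ":DS"
    if gp is not None:
        fmt += ":GP"
    lines = ["##fileformat=VCFv4.2",
             "##source=herdimpute",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    if ds is not None:
        lines.append('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Imputed B-allele dosage">')
    if gp is not None:
        lines.append('##FORMAT=<ID=GP,Number=G,Type=Float,'
                     'Description="Genotype posterior probabilities">')
    for c in gmap.chromosomes:
        sl = gmap.chrom_slice(c)
        lines.append(f"##contig=<ID={c},length={int(gmap.bp[sl][-1]) + 1}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in sample_ids))
    for j in range(L):
        cells = []
        for i in range(n):
            if haplotypes is not None:
                gt = _GT_PAIR_PH[(int(haplotypes[i, 0, j]),
                                  int(haplotypes[i, 1, j]))]
            else:
                gt = _GT_UNPHASED[int(genotypes[i, j])]
            parts = [gt]
            if ds is not None:
                parts.append(f"{float(ds[i, j]):.3f}")
            if gp is not None:
                parts.append(",".join(f"{float(v):.4f}" for v in gp[i, j]))
            cells.append(":".join(parts))
        lines.append("\t".join([str(gmap.chrom[j]), str(int(gmap.bp[j])),
                                str(gmap.marker_id[j]), "A", "B", ".",
                                "PASS", ".", fmt] + cells))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class VcfData:
    """In-memory view of a biallelic SNP VCF."""

    gmap: GenomeMap
    samples: list
    genotypes: np.ndarray            # (n, L) int8, -1 missing
    haplotypes: np.ndarray | None    # (n, 2, L) when every call is phased
    ds: np.ndarray | None = None
    gp: np.ndarray | None = None


def read_vcf(path) -> VcfData:
    """Read a biallelic SNP VCF with cyvcf2. Multi-allelic records are
    skipped with a warning; genetic positions are assigned as 1 cM/Mb."""
    import warnings

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    chroms, mids, bps = [], [], []
    gt_rows, hap_rows, ds_rows, gp_rows = [], [], [], []
    all_phased = True
    any_ds = any_gp = False
    for k, v in enumerate(vcf):
        if len(v.ALT) != 1:
            warnings.warn(f"skipping multi-allelic record {v.CHROM}:{v.POS}",
                          stacklevel=2)
            continue
        chroms.append(v.CHROM)
        mids.append(v.ID if v.ID not in (None, ".") else
                    f"{v.CHROM}:{v.POS}")
        bps.append(v.POS)
        g = np.full(n, MISSING, dtype=np.int8)
        h = np.full((n, 2), 0, dtype=np.int8)
        for i, (a0, a1, *rest) in enumerate(v.genotypes):
            phased = bool(rest[0]) if rest else False
            if a0 < 0 or a1 < 0:
                all_phased = False
                continue
            g[i] = a0 + a1
            h[i] = (a0, a1)
            if not phased:
                all_phased = False
        gt_rows.append(g)
        hap_rows.append(h)
        try:
            dsf = v.format("DS")
        except KeyError:
            dsf = None
        if dsf is not None:
            any_ds = True
            ds_rows.append(np.asarray(dsf, dtype=np.float64).ravel())
        else:
            ds_rows.append(np.full(n, np.nan))
        try:
            gpf = v.format("GP")
        except KeyError:
            gpf = None
        if gpf is not None:
            any_gp = True
            gp_rows.append(np.asarray(gpf, dtype=np.float64).reshape(n, 3))
        else:
            gp_rows.append(np.full((n, 3), np.nan))
    if not chroms:
        raise ValueError(f"no usable biallelic records in {path}")
    bp = np.array(bps, dtype=np.int64)
    gmap = GenomeMap(np.array(chroms), np.array(mids), bp, bp / 1e6)
    genotypes = np.stack(gt_rows, axis=1)
    # hap_rows holds one (n, 2) block per marker -> (n, 2, L)
    haplotypes = (np.stack(hap_rows, axis=2).astype(np.uint8)
                  if all_phased else None)
    return VcfData(gmap, samples, genotypes, haplotypes,
                   np.stack(ds_rows, axis=1) if any_ds else None,
                   np.stack(gp_rows, axis=1) if any_gp else None)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

PEDIGREE_COLUMNS = ["animal_id", "sire_id", "dam_id", "sex", "birth_year"]
PHENOTYPE_COLUMNS = ["animal_id", "trait", "dtd", "reliability"]
MAP_COLUMNS = ["chrom", "marker_id", "bp", "cM"]


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def write_pedigree(path, pedigree: Pedigree) -> None:
    pd.DataFrame([r.__dict__ for r in pedigree]).to_csv(
        path, sep="\t", index=False, columns=PEDIGREE_COLUMNS)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, PEDIGREE_COLUMNS, path)
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(PedigreeRecord(
                row.animal_id, row.sire_id or UNKNOWN_PARENT,
                row.dam_id or UNKNOWN_PARENT, row.sex,
                int(row.birth_year)))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, row {row_no}, column birth_year: "
                             f"{exc}") from exc
    try:
        return Pedigree(records)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_phenotypes(path, records) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(
        path, sep="\t", index=False, columns=PHENOTYPE_COLUMNS)


def read_phenotypes(path) -> list[PhenotypeRecord]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PHENOTYPE_COLUMNS, path)
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rel = float(row.reliability)
        if not 0.0 < rel < 1.0:
            raise ValueError(f"{path}, row {row_no}, column reliability: "
                             f"value {rel} outside (0, 1)")
        out.append(PhenotypeRecord(str(row.animal_id), str(row.trait),
                                   float(row.dtd), rel))
    return out


def write_map(path, gmap: GenomeMap) -> None:
    pd.DataFrame({"chrom": gmap.chrom, "marker_id": gmap.marker_id,
                  "bp": gmap.bp, "cM": gmap.cm}).to_csv(
        path, sep="\t", index=False)


def read_map(path) -> GenomeMap:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, MAP_COLUMNS, path)
    chrom = df["chrom"].astype(str).to_numpy()
    bp = df["bp"].to_numpy(dtype=np.int64)
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        diffs = np.diff(bp[sel])
        if np.any(diffs <= 0):
            bad = sel[int(np.argmax(diffs <= 0)) + 1]
            raise ValueError(f"{path}, row {bad + 2}, column bp: positions "
                             f"not strictly increasing on chrom {c}")
    try:
        return GenomeMap(chrom, df["marker_id"].astype(str).to_numpy(), bp,
                         df["cM"].to_numpy(dtype=np.float64))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
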