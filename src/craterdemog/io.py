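"""Readers and writers for the pipeline's tabular, VCF and SFS artifacts.

Formats
-------
Specimen table
    Delimited text (TSV by default) with header.  Required columns:
    ``id``, ``habitat``.  Optional: ``standard_length``, ``body_height``,
    ``d13c``, ``d15n``, ``c_n_ratio``, ``measurement_mode``.
Microsatellite genotypes
    TSV with ``id``, ``population`` then two columns per locus named
    ``<locus>.1`` / ``<locus>.2`` holding allele sizes in bp; missing
    alleles are ``NA``.
VCF
    v4.2, read through cyvcf2; multiallelic records are skipped (counted),
    positions stay 1-based.  The RAD-tag grouping key is the CHROM field by
    default (STACKS catalog convention) or a regex applied to CHROM/ID.
Joint SFS
    Plain text: a header line ``n1 n2 effective_length folded`` then
    ``n1 + 1`` rows of ``n2 + 1`` full-precision floats; round-trips
    bit-exactly.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import GenotypeTable, JointSFS, Locus, Specimen

logger = logging.getLogger(__name__)

__all__ = [
    "read_specimen_table",
    "write_specimen_table",
    "read_vcf_genotypes",
    "write_vcf",
    "read_microsat_table",
    "write_microsat_table",
    "read_sfs",
    "write_sfs",
]

_SPECIMEN_NUMERIC = ("standard_length", "body_height", "d13c", "d15n", "c_n_ratio")


def read_specimen_table(
    path, sep: str = "\t"
) -> Tuple[List[Specimen], List[Tuple[int, str]]]:
    """Read a specimen table.

    Returns ``(specimens, rejected)`` where ``rejected`` lists
    ``(row_number, reason)`` for rows with unparseable or invariant-violating
    numerics (row numbers are 1-based data rows).  A missing *required*
    column is a hard error.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("id", "habitat"):
        if col not in df.columns:
            raise ValueError(f"specimen table is missing required column {col!r}")
    specimens: List[Specimen] = []
    rejected: List[Tuple[int, str]] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        kwargs = {"id": rec["id"], "habitat": rec["habitat"]}
        mode = rec.get("measurement_mode")
        if isinstance(mode, str) and mode:
            kwargs["measurement_mode"] = mode
        try:
            for col in _SPECIMEN_NUMERIC:
                v = rec.get(col)
                if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                    continue
                field = "d13c_raw" if col == "d13c" else col
                kwargs[field] = float(v)
            specimens.append(Specimen(**kwargs))
        except (TypeError, ValueError) as exc:
            rejected.append((row_no, str(exc)))
            logger.warning("specimen row %d rejected: %s", row_no, exc)
    return specimens, rejected


def write_specimen_table(specimens: Sequence[Specimen], path, sep: str = "\t") -> None:
    rows = []
    for s in specimens:
        rows.append(
            dict(
                id=s.id,
                habitat=s.habitat,
                standard_length=s.standard_length,
                body_height=s.body_height,
                d13c=s.d13c_raw,
                d15n=s.d15n,
                c_n_ratio=s.c_n_ratio,
                measurement_mode=s.measurement_mode,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------- VCF


def read_vcf_genotypes(
    path,
    tag_regex: Optional[str] = None,
    populations: Optional[dict] = None,
) -> GenotypeTable:
    """Read biallelic SNP genotypes from a VCF.

    RAD-tag grouping defaults to the CHROM field; ``tag_regex`` (applied to
    CHROM, first capture group) overrides it.  Multiallelic records and
    records without a GT field are skipped with a logged count.
    ``populations`` optionally maps sample id -> population label.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: List[Locus] = []
    calls: List[np.ndarray] = []
    n_multi = 0
    n_nogt = 0
    pattern = re.compile(tag_regex) if tag_regex else None
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        gts = var.genotypes
        if gts is None or "GT" not in (var.FORMAT or []):
            n_nogt += 1
            continue
        chrom = var.CHROM
        tag = chrom
        if pattern is not None:
            m = pattern.search(chrom) or (pattern.search(var.ID) if var.ID else None)
            if not m:
                raise ValueError(
                    f"tag regex {pattern.pattern!r} does not match {chrom!r}"
                )
            tag = m.group(1)
        lid = var.ID if var.ID not in (None, ".") else f"{chrom}:{var.POS}"
        loci.append(Locus(id=lid, tag=tag, position=int(var.POS)))
        row = np.full((len(samples), 2), GenotypeTable.MISSING, dtype=np.int32)
        for i, g in enumerate(gts):
            a1, a2 = g[0], g[1]
            if a1 >= 0 and a2 >= 0:
                row[i, 0] = a1
                row[i, 1] = a2
        calls.append(row)
    vcf.close()
    if n_multi:
        logger.warning("skipped %d non-biallelic-SNP records", n_multi)
    if n_nogt:
        logger.warning("skipped %d records without GT", n_nogt)
    if calls:
        grid = np.stack(calls, axis=1)  # (n_samples, n_loci, 2)
    else:
        grid = np.empty((len(samples), 0, 2), dtype=np.int32)
    pops = [populations[s] for s in samples] if populations else None
    return GenotypeTable(samples, loci, grid, populations=pops)


def write_vcf(table: GenotypeTable, path) -> None:
    """Write biallelic SNP calls as a minimal VCF v4.2 (A/T ref/alt codes)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=craterdemog\n")
        tags = sorted({loc.tag for loc in table.loci if loc.tag is not None})
        for t in tags:
            fh.write(f"##contig=<ID={t}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.individuals)
            + "\n"
        )
        for j, loc in enumerate(table.loci):
            gts = []
            for i in range(table.n_individuals):
                g = table.genotype(i, j)
                gts.append("./." if g is None else f"{g[0]}/{g[1]}")
            fh.write(
                f"{loc.tag or loc.id}\t{loc.position or 1}\t{loc.id}\t"
                f"A\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------- microsats


def read_microsat_table(path, sep: str = "\t") -> GenotypeTable:
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("id", "population"):
        if col not in df.columns:
            raise ValueError(f"microsat table is missing required column {col!r}")
    allele_cols = [c for c in df.columns if c.endswith(".1") or c.endswith(".2")]
    locus_names = []
    for c in allele_cols:
        base = c[:-2]
        if base not in locus_names:
            locus_names.append(base)
    for base in locus_names:
        if f"{base}.1" not in df.columns or f"{base}.2" not in df.columns:
            raise ValueError(f"locus {base!r} needs both {base}.1 and {base}.2 columns")
    n, L = len(df), len(locus_names)
    calls = np.full((n, L, 2), GenotypeTable.MISSING, dtype=np.int32)
    for j, base in enumerate(locus_names):
        for a in (0, 1):
            col = df[f"{base}.{a + 1}"]
            ok = col.notna() & (col != "NA")
            calls[ok.to_numpy(), j, a] = col[ok].astype(int).to_numpy()
    return GenotypeTable(
        df["id"].tolist(),
        [Locus(id=b) for b in locus_names],
        calls,
        populations=df["population"].tolist(),
    )


def write_microsat_table(table: GenotypeTable, path, sep: str = "\t") -> None:
    if table.populations is None:
        raise ValueError("microsat table requires population labels")
    data = {"id": table.individuals, "population": table.populations}
    for j, loc in enumerate(table.loci):
        for a in (0, 1):
            col = []
            for i in range(table.n_individuals):
                g = table.genotype(i, j)
                col.append("NA" if g is None else str(g[a]))
            data[f"{loc.id}.{a + 1}"] = col
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------- SFS text


def write_sfs(sfs: JointSFS, path) -> None:
    with open(path, "w") as fh:
        eff = "NA" if sfs.effective_length is None else repr(float(sfs.effective_length))
        fh.write(f"{sfs.n1} {sfs.n2} {eff} {int(sfs.folded)}\n")
        for row in sfs.counts:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")


def read_sfs(path) -> JointSFS:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 4:
            raise ValueError("SFS header must be: n1 n2 effective_length folded")
        n1, n2 = int(header[0]), int(header[1])
        eff = None if header[2] == "NA" else float(header[2])
        folded = bool(int(header[3]))
        rows = [list(map(float, line.split())) for line in fh if line.strip()]
    grid = np.array(rows, dtype=float)
    if grid.shape != (n1 + 1, n2 + 1):
        raise ValueError(
            f"SFS grid shape {grid.shape} does not match header ({n1 + 1}, {n2 + 1})"
        )
    return JointSFS(grid, n1, n2, effective_length=eff, folded=folded)
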