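"""From filtered RAD genotypes to the projected joint minor-allele SFS.

Filtering mirrors the RAD workflow: blacklisted tags out, tags carrying
more than ``max_snps_per_tag`` SNPs out entirely, SNPs failing the
Hardy–Weinberg exact test at ``hwe_alpha`` out, then exactly one SNP per
surviving tag (the first by position) to avoid linked markers.

The joint SFS is built per site from the *called* allele copies and
projected down hypergeometrically to the target sample sizes, so
projection doubles as the missing-data policy; folding onto the pooled
minor allele happens once on the assembled grid, splitting mass at exactly
50% between mirror cells.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import hypergeom

from .popgen import hwe_exact
from .types import FilterReport, GenotypeTable, JointSFS

__all__ = ["filter_rad_snps", "build_joint_minor_sfs", "project_sfs"]


def filter_rad_snps(
    table: GenotypeTable,
    hwe_alpha: float = 0.05,
    max_snps_per_tag: int = 3,
    blacklist: Optional[set] = None,
) -> Tuple[GenotypeTable, FilterReport]:
    """Apply the RAD SNP filters; returns the filtered table and a report."""
    if any(loc.tag is None for loc in table.loci):
        raise ValueError("RAD-tag grouping is required for filtering")
    report = FilterReport(n_input=table.n_loci)
    blacklist = blacklist or set()

    idx = list(range(table.n_loci))
    kept = [j for j in idx if table.loci[j].tag not in blacklist]
    report.removed_blacklist = len(idx) - len(kept)

    tag_counts: dict = {}
    for j in kept:
        tag_counts[table.loci[j].tag] = tag_counts.get(table.loci[j].tag, 0) + 1
    kept2 = [j for j in kept if tag_counts[table.loci[j].tag] <= max_snps_per_tag]
    report.removed_excess_snps = len(kept) - len(kept2)

    kept3 = []
    for j in kept2:
        calls = table.calls[:, j, :]
        called = calls[:, 0] != GenotypeTable.MISSING
        g = calls[called]
        n_het = int((g[:, 0] != g[:, 1]).sum())
        n_hom1 = int(((g[:, 0] == 0) & (g[:, 1] == 0)).sum())
        n_hom2 = int(((g[:, 0] == 1) & (g[:, 1] == 1)).sum())
        if hwe_exact(n_hom1, n_het, n_hom2) < hwe_alpha:
            continue
        kept3.append(j)
    report.removed_hwe = len(kept2) - len(kept3)

    first_by_tag: dict = {}
    for j in kept3:
        loc = table.loci[j]
        pos = loc.position if loc.position is not None else j
        cur = first_by_tag.get(loc.tag)
        if cur is None or pos < cur[0]:
            first_by_tag[loc.tag] = (pos, j)
    kept4 = sorted(j for (_, j) in first_by_tag.values())
    report.removed_not_first = len(kept3) - len(kept4)
    report.retained = len(kept4)
    report.check()
    return table.subset_loci(kept4), report


def _projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """P[i, k] = P(k of n_to sampled copies are derived | i of n_from are)."""
    if n_from == 0:
        return np.ones((1, 1))  # degenerate one-dimensional spectrum axis
    i = np.arange(n_from + 1)
    k = np.arange(n_to + 1)
    return hypergeom.pmf(k[None, :], n_from, i[:, None], n_to)


def build_joint_minor_sfs(
    table: GenotypeTable,
    pop_labels: Optional[Sequence[str]] = None,
    effective_length: Optional[float] = None,
    n1: Optional[int] = None,
    n2: Optional[int] = None,
) -> JointSFS:
    """Tally biallelic SNPs into the folded joint minor-allele SFS.

    ``n1`` / ``n2`` are the target haploid sample sizes per population
    (default: twice the individual counts).  Sites with missing calls are
    projected from their called copies down to the targets; sites with
    fewer called copies than the target in either population are dropped.
    When ``effective_length`` is given, the monomorphic cell (0, 0) is set
    to ``effective_length - S`` so likelihoods can use the monomorphic
    class.
    """
    labels = np.asarray(pop_labels if pop_labels is not None else table.populations)
    pops = sorted(set(labels.tolist()))
    if len(pops) != 2:
        raise ValueError(f"joint SFS needs exactly two populations, got {pops}")
    m1 = (labels == pops[0]).sum()
    m2 = (labels == pops[1]).sum()
    n1 = 2 * int(m1) if n1 is None else int(n1)
    n2 = 2 * int(m2) if n2 is None else int(n2)
    if n1 > 2 * m1 or n2 > 2 * m2:
        raise ValueError("target sample size exceeds available allele copies")

    if (table.calls > 1).any():
        raise ValueError("joint SFS requires biallelic 0/1 SNP calls")

    grid = np.zeros((n1 + 1, n2 + 1))
    idx1 = labels == pops[0]
    idx2 = labels == pops[1]
    missing = table.missing_mask()
    proj_cache: dict = {}
    n_dropped = 0
    for j in range(table.n_loci):
        called = ~missing[:, j]
        c1 = int(called[idx1].sum()) * 2
        c2 = int(called[idx2].sum()) * 2
        if c1 < n1 or c2 < n2:
            n_dropped += 1
            continue
        d1 = int(table.calls[idx1 & called, j, :].sum())
        d2 = int(table.calls[idx2 & called, j, :].sum())
        if c1 == n1 and c2 == n2:
            grid[d1, d2] += 1.0
        else:
            key1, key2 = (c1, n1), (c2, n2)
            if key1 not in proj_cache:
                proj_cache[key1] = _projection_matrix(*key1)
            if key2 not in proj_cache:
                proj_cache[key2] = _projection_matrix(*key2)
            grid += np.outer(proj_cache[key1][d1], proj_cache[key2][d2])
    sfs = JointSFS(grid, n1, n2, effective_length=effective_length, folded=False)
    folded = sfs.fold()
    if effective_length is not None:
        mono = effective_length - folded.n_polymorphic
        if mono < -1e-9:
            raise ValueError("effective_length smaller than the polymorphic count")
        folded.counts[0, 0] = max(mono, 0.0)
    return folded


def project_sfs(sfs: JointSFS, target1: int, target2: int) -> JointSFS:
    """Project a joint SFS down to smaller haploid sample sizes.

    Each cell's mass is redistributed by the product of hypergeometric
    sampling probabilities in the two dimensions; counts become fractional.
    Folded input is refolded after projection.  Total mass is conserved.
    """
    if target1 > sfs.n1 or target2 > sfs.n2:
        raise ValueError("projection target exceeds source sample size")
    if target1 == sfs.n1 and target2 == sfs.n2:
        return sfs.copy()
    P1 = _projection_matrix(sfs.n1, target1)
    P2 = _projection_matrix(sfs.n2, target2)
    grid = P1.T @ sfs.counts @ P2
    out = JointSFS(grid, target1, target2, sfs.effective_length, folded=False)
    return out.fold() if sfs.folded else out
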