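"""Weir–Cockerham F_ST with a permutation null, and the biallelic HWE exact test.

The multilocus, multiallelic θ follows Weir & Cockerham (1984): per allele
and locus the among-population (a), among-individual (b) and within-
individual (c) variance components are computed from sample allele
frequencies and observed heterozygote frequencies, and the overall
estimate is the ratio of summed components Σa / Σ(a + b + c) across
alleles and loci.  Significance comes from permuting individuals (both
alleles move together) across population labels, the scheme used for
population-differentiation testing in microsatellite software.

The Hardy–Weinberg exact test enumerates every heterozygote count
consistent with the observed allele counts and sums the probabilities of
configurations no more likely than the observed one (the standard
"SNP-HWE" two-sided test used as a RAD-locus filter downstream).
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .types import FstResult, GenotypeTable

__all__ = ["wc_fst", "fst_permutation_test", "hwe_exact"]


def _design_matrices(table: GenotypeTable):
    """Per-individual allele-copy and heterozygote indicators, all loci stacked.

    Returns (C, H, G, col_locus, keep_loci) where C[i, t] is the number of
    copies of allele column t carried by individual i, H[i, t] a heterozygote
    indicator, G[i, l] a genotyped indicator, and col_locus maps columns to
    locus indices.  Loci monomorphic across the whole data set (which
    contribute zero variance components regardless of labels) are dropped.
    """
    n, L = table.n_individuals, table.n_loci
    missing = table.missing_mask()
    C_cols, H_cols, col_locus = [], [], []
    keep_loci = []
    for j in range(L):
        called = ~missing[:, j]
        if called.sum() == 0:
            continue
        alleles = np.unique(table.calls[called, j, :])
        if len(alleles) < 2:
            continue  # monomorphic: zero components, skipped
        keep_loci.append(j)
        a1 = table.calls[:, j, 0][:, None] == alleles[None, :]
        a2 = table.calls[:, j, 1][:, None] == alleles[None, :]
        C = (a1.astype(np.int64) + a2.astype(np.int64)) * called[:, None]
        H = (a1 ^ a2).astype(np.int64) * called[:, None]
        C_cols.append(C)
        H_cols.append(H)
        col_locus.extend([len(keep_loci) - 1] * len(alleles))
    if not keep_loci:
        return None
    return (
        np.concatenate(C_cols, axis=1).astype(float),
        np.concatenate(H_cols, axis=1).astype(float),
        (~missing[:, keep_loci]).astype(float),
        np.array(col_locus),
        keep_loci,
    )


def _components(C, H, G, col_locus, masks):
    """Weir–Cockerham a, b, c sums per allele column for label masks.

    ``masks`` is a list of (n_perm, n_ind) 0/1 arrays, one per population.
    Returns (a, abc) arrays of shape (n_perm, n_columns).
    """
    r = len(masks)
    n_i = [m @ G for m in masks]  # (n_perm, L) genotyped counts
    nbar = sum(n_i) / r
    n2sum = sum(ni**2 for ni in n_i)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - n2sum / (r * nbar)) / (r - 1)
        counts = [m @ C for m in masks]  # (n_perm, T) allele copies
        hets = [m @ H for m in masks]
        ni_c = [ni[:, col_locus] for ni in n_i]
        p_i = [c / (2.0 * ni) for c, ni in zip(counts, ni_c)]
        h_i = [h / ni for h, ni in zip(hets, ni_c)]
        nbar_c = nbar[:, col_locus]
        nc_c = nc[:, col_locus]
        pbar = sum(ni * p for ni, p in zip(ni_c, p_i)) / (r * nbar_c)
        s2 = sum(ni * (p - pbar) ** 2 for ni, p in zip(ni_c, p_i)) / (
            (r - 1) * nbar_c
        )
        hbar = sum(ni * h for ni, h in zip(ni_c, h_i)) / (r * nbar_c)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        a = nbar_c / nc_c * (s2 - inner / (nbar_c - 1.0))
        b = nbar_c / (nbar_c - 1.0) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar_c - 1) / (4 * nbar_c) * hbar
        )
        c = hbar / 2.0
    valid = np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (nbar_c > 1.0)
    a = np.where(valid, a, 0.0)
    abc = np.where(valid, a + b + c, 0.0)
    return a, abc


def _pop_masks(labels: np.ndarray) -> Tuple[list, list]:
    pops = sorted(set(labels.tolist()))
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    return pops, [(labels == p).astype(float)[None, :] for p in pops]


def wc_fst(
    table: GenotypeTable, pop_labels: Optional[Sequence[str]] = None
) -> FstResult:
    """Multilocus, multiallelic Weir–Cockerham θ (point estimate).

    Missing genotypes are excluded per locus; loci monomorphic across the
    whole data set contribute nothing.  Per-locus estimates can be
    negative (the estimator is unbiased, not constrained to [0, 1]).
    """
    labels = np.asarray(
        pop_labels if pop_labels is not None else table.populations
    )
    if labels is None or labels.ndim == 0:
        raise ValueError("population labels are required")
    pops, masks = _pop_masks(labels)
    for p, m in zip(pops, masks):
        if (m.sum()) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")
    mats = _design_matrices(table)
    if mats is None:
        raise ValueError("no polymorphic loci")
    C, H, G, col_locus, keep = mats
    # every population must have >= 2 genotyped individuals at some locus
    for p, m in zip(pops, masks):
        if (m @ G).max() < 2:
            raise ValueError(
                f"population {p!r} has fewer than 2 genotyped individuals at every locus"
            )
    a, abc = _components(C, H, G, col_locus, masks)
    theta = float(a.sum() / abc.sum())
    per_locus = {}
    for li, j in enumerate(keep):
        cols = col_locus == li
        denom = abc[0, cols].sum()
        per_locus[table.loci[j].id] = float(a[0, cols].sum() / denom) if denom else np.nan
    return FstResult(theta=theta, per_locus=per_locus)


def fst_permutation_test(
    table: GenotypeTable,
    pop_labels: Optional[Sequence[str]] = None,
    n_perm: int = 20_000,
    seed: int = 0,
    block: int = 2_000,
) -> FstResult:
    """Permutation test of θ: individuals are shuffled across populations.

    p = (#{θ_perm >= θ_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = wc_fst(table, pop_labels)
    labels = np.asarray(pop_labels if pop_labels is not None else table.populations)
    pops, _ = _pop_masks(labels)
    mats = _design_matrices(table)
    C, H, G, col_locus, _ = mats
    rng = np.random.default_rng(seed)
    n = len(labels)
    codes = np.searchsorted(pops, labels)
    n_ge = 0
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        perm = np.argsort(rng.random((m, n)), axis=1)
        permuted = codes[perm]  # (m, n)
        masks = [(permuted == k).astype(float) for k in range(len(pops))]
        a, abc = _components(C, H, G, col_locus, masks)
        theta_perm = a.sum(axis=1) / abc.sum(axis=1)
        n_ge += int((theta_perm >= obs.theta).sum())
        done += m
    p = (n_ge + 1) / (n_perm + 1)
    return FstResult(
        theta=obs.theta, per_locus=obs.per_locus, n_permutations=n_perm, p_value=p
    )


def hwe_exact(n_aa_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided Hardy–Weinberg exact test p-value for a biallelic locus.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations whose probability
    does not exceed the observed one.
    """
    counts = (n_aa_hom1, n_het, n_hom2)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        return 1.0
    rare = 2 * min(n_aa_hom1, n_hom2) + n_het  # copies of the rarer allele
    # possible heterozygote counts share rare's parity, 0..rare (and <= 2n - rare)
    het_max = min(rare, 2 * n - rare)
    hets = list(range(rare % 2, het_max + 1, 2))
    # P(het | n, rare) via the standard recurrence, anchored at the smallest
    probs = np.zeros(len(hets))
    probs[0] = 1.0
    for k in range(1, len(hets)):
        h = hets[k]
        # ratio P(h) / P(h - 2)
        hom_r = (rare - (h - 2)) // 2  # rare homozygotes at h - 2
        hom_c = n - (h - 2) - hom_r
        probs[k] = probs[k - 1] * 4.0 * hom_r * hom_c / (h * (h - 1.0))
    probs /= probs.sum()
    obs = probs[hets.index(n_het)] if n_het in hets else None
    if obs is None:
        raise ValueError(
            f"heterozygote count {n_het} impossible with {rare} rare alleles"
        )
    p = float(probs[probs <= obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)
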