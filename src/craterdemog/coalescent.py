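"""Backward-time coalescent simulation for two-deme demographic models.

Scaling: time in generations, sizes in diploid individuals, so a pair of
lineages in a deme of constant size N coalesces at rate 1/(2N) per
generation (E[T2] = 2N).  Exponential size change between events, lineage
migration at the backward rates implied by the forward migration matrix,
admixture pulses and deme foundings as probabilistic lineage moves at event
times.  One genealogy per site (unlinked-SNP assumption), infinite-sites
mutations at rate ``mu`` per site per generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import _engine
from .demography import DemographicModel, EpochTable
from .types import JointSFS

__all__ = [
    "Genealogy",
    "simulate_genealogy",
    "simulate_sfs",
    "expected_branch_sfs",
    "sample_layout",
]


class StrandedLineagesError(RuntimeError):
    """Lineages cannot find a common ancestor (no coalescence/migration path)."""


@dataclass
class Genealogy:
    """A single coalescent tree over ``n`` sampled haploid lineages.

    Nodes 0..n-1 are leaves at time 0; internal nodes follow in coalescence
    order; node ``2n - 2`` is the root.  ``parent[root] == -1``.
    """

    parent: np.ndarray
    node_time: np.ndarray
    leaf_deme: np.ndarray

    @property
    def n_leaves(self) -> int:
        return (self.parent.size + 1) // 2

    @property
    def root(self) -> int:
        return self.parent.size - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    @property
    def total_branch_length(self) -> float:
        has_parent = self.parent >= 0
        return float(
            np.sum(self.node_time[self.parent[has_parent]] - self.node_time[has_parent])
        )

    def leaves_below(self, node: int) -> np.ndarray:
        """Leaf ids subtended by ``node`` (iterative descent)."""
        n = self.n_leaves
        children = [[] for _ in range(self.parent.size)]
        for c, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(c)
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend(children[v])
        return np.array(sorted(out), dtype=np.int64)


def sample_layout(model: DemographicModel) -> Tuple[np.ndarray, np.ndarray, int, int]:
    """Leaf-to-deme assignment and the two SFS sample sizes.

    Sampled demes are taken in the order they appear in ``model.demes``;
    one or two sampled demes are supported.
    """
    sampled = [
        (i, model.sample_config[d.name])
        for i, d in enumerate(model.demes)
        if model.sample_config.get(d.name, 0) > 0
    ]
    if not 1 <= len(sampled) <= 2:
        raise ValueError("need samples in one or two demes")
    leaf_deme = []
    leaf_pop = []
    for pop, (di, cnt) in enumerate(sampled):
        leaf_deme.extend([di] * cnt)
        leaf_pop.extend([pop] * cnt)
    n1 = sampled[0][1]
    n2 = sampled[1][1] if len(sampled) == 2 else 0
    return (
        np.array(leaf_deme, dtype=np.int64),
        np.array(leaf_pop, dtype=np.int64),
        n1,
        n2,
    )


def _kernel_args(model: DemographicModel):
    table = EpochTable(model)
    K = table.n_epochs
    mb, mf, mt, mp = [], [], [], []
    for k in range(K):
        for (f, t, p) in table.moves[k]:
            mb.append(k)
            mf.append(f)
            mt.append(t)
            mp.append(p)
    return (
        table.times,
        table.n_start,
        table.growth,
        table.mig,
        np.array(mb, dtype=np.int64),
        np.array(mf, dtype=np.int64),
        np.array(mt, dtype=np.int64),
        np.array(mp, dtype=float),
    )


def _sub_seed(seed: int, salt: int = 0) -> int:
    """Derive a 31-bit kernel seed deterministically from ``seed``."""
    ss = np.random.SeedSequence([int(seed), int(salt)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def simulate_genealogy(model: DemographicModel, seed: int = 0) -> Genealogy:
    """Simulate one genealogy under ``model`` for its configured samples."""
    args = _kernel_args(model)
    leaf_deme, leaf_pop, _, _ = sample_layout(model)
    if leaf_deme.size < 1:
        raise ValueError("need at least one sampled lineage")
    if leaf_deme.size == 1:
        raise ValueError("need at least two sampled lineages for a genealogy")
    parent, ntime, ok = _engine.genealogy_kernel(
        *args, leaf_deme, leaf_pop, _sub_seed(seed)
    )
    if not ok:
        raise StrandedLineagesError(
            "lineages stranded: no coalescence or migration path before time cap"
        )
    return Genealogy(parent=parent, node_time=ntime, leaf_deme=leaf_deme)


def expected_branch_sfs(
    model: DemographicModel, n_sims: int, seed: int = 0
) -> Tuple[np.ndarray, float]:
    """Monte-Carlo expected per-site branch lengths by joint-SFS cell.

    Returns ``(B, total)`` where ``B[i, j]`` is the mean (over ``n_sims``
    genealogies) total length of branches subtending ``(i, j)`` sample
    copies — unfolded, derived orientation — and ``total`` the mean total
    branch length.  ``mu * B`` is the per-site probability of a segregating
    site in each cell (small-mu limit).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    args = _kernel_args(model)
    leaf_deme, leaf_pop, n1, n2 = sample_layout(model)
    cells, total, errors = _engine.branch_sfs_kernel(
        n_sims, *args, leaf_deme, leaf_pop, n1, n2, _sub_seed(seed)
    )
    if errors == n_sims:
        raise StrandedLineagesError("all replicates stranded")
    eff = n_sims - errors
    B = cells.reshape(n1 + 1, n2 + 1) / eff
    return B, total / eff


def simulate_sfs(
    model: DemographicModel,
    mu: float,
    n_sites: Optional[int] = None,
    effective_length: Optional[float] = None,
    seed: int = 0,
    fold: bool = True,
) -> JointSFS:
    """Simulate a joint SFS: one independent genealogy per site.

    Exactly one of ``n_sites`` / ``effective_length`` must be given (they
    mean the same thing; ``effective_length`` additionally stamps the
    result).  Mutation counts per site are Poisson(mu x tree length); a
    site's allele configuration is taken from one branch drawn with
    probability proportional to length.  ``fold=True`` folds onto the
    pooled minor allele.
    """
    if (n_sites is None) == (effective_length is None):
        raise ValueError("give exactly one of n_sites / effective_length")
    L = int(n_sites) if n_sites is not None else int(round(effective_length))
    if L < 1:
        raise ValueError("need at least one site")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    args = _kernel_args(model)
    leaf_deme, leaf_pop, n1, n2 = sample_layout(model)
    cells, n_mono, errors = _engine.site_sfs_kernel(
        L, float(mu), *args, leaf_deme, leaf_pop, n1, n2, _sub_seed(seed)
    )
    if errors > 0 and errors == L:
        raise StrandedLineagesError("all sites stranded")
    grid = cells.reshape(n1 + 1, n2 + 1)
    grid[0, 0] += n_mono
    sfs = JointSFS(
        grid,
        n1,
        n2,
        effective_length=float(L) if effective_length is not None else None,
        folded=False,
    )
    return sfs.fold() if fold else sfs
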