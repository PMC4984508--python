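"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is deterministic under a fixed seed and writes files that
the readers in :mod:`craterdemog.io` accept unchanged.  Field data
(morphometrics, isotopes) are Gaussian per habitat group at configurable
means/SDs, defaulting to the published group summaries; microsatellites
follow a Balding–Nichols island model with an analytic F_ST target; RAD
genotypes come from the coalescent engine with RAD-tag ids laid out in
blocks so the per-tag filters have something to act on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _engine
from .coalescent import _kernel_args, sample_layout
from .demography import DemographicModel
from .types import GenotypeTable, JointSFS, Locus, Specimen

__all__ = [
    "FieldSimConfig",
    "gen_specimen_table",
    "gen_microsat_genotypes",
    "gen_rad_vcf",
    "gen_plasticity_broods",
]


@dataclass
class FieldSimConfig:
    """Study conditions for the synthetic field sample.

    Defaults are the published group summaries: BHI 0.430 +- 0.013 SD in
    the limnetic (mid-lake) group and 0.438 +- 0.014 SD at the shore;
    lipid-normalized d13C -33.34 +- 1.28 vs -32.05 +- 1.37 permil and d15N
    15.71 +- 0.38 vs 15.35 +- 0.50 permil.  Standard length is drawn from
    a habitat-independent Gaussian (the groups did not differ in length)
    and body height is derived as BHI x SL.  ``standardize`` rescales each
    group's draws to hit the configured moments exactly (sample mean and
    SD), which makes moment-determined statistics reproducible.
    """

    n_limnetic: int = 27
    n_benthic: int = 27
    bhi_mean: Tuple[float, float] = (0.430, 0.438)  # (limnetic, benthic)
    bhi_sd: Tuple[float, float] = (0.013, 0.014)
    d13c_mean: Tuple[float, float] = (-33.34, -32.05)
    d13c_sd: Tuple[float, float] = (1.28, 1.37)
    d15n_mean: Tuple[float, float] = (15.71, 15.35)
    d15n_sd: Tuple[float, float] = (0.38, 0.50)
    sl_mean: float = 120.0  # mm
    sl_sd: float = 15.0
    c_n_ratio: float = 3.2  # lean muscle tissue
    bhi_d13c_corr: float = 0.0  # within-group BHI-d13C correlation
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for sd in (*self.bhi_sd, *self.d13c_sd, *self.d15n_sd, self.sl_sd):
            if not sd > 0:
                raise ValueError("all SDs must be > 0")
        if min(self.n_limnetic, self.n_benthic) < 2:
            raise ValueError("need at least 2 specimens per group")
        if not -1.0 < self.bhi_d13c_corr < 1.0:
            raise ValueError("correlation must be in (-1, 1)")


def _std_normal(rng, n: int, exact: bool) -> np.ndarray:
    z = rng.standard_normal(n)
    if exact:
        z = (z - z.mean()) / z.std(ddof=1)
    return z


def gen_specimen_table(cfg: FieldSimConfig) -> List[Specimen]:
    rng = np.random.default_rng(cfg.seed)
    specimens: List[Specimen] = []
    rho = cfg.bhi_d13c_corr
    for g, (habitat, n) in enumerate(
        [("limnetic", cfg.n_limnetic), ("benthic", cfg.n_benthic)]
    ):
        z_bhi = _std_normal(rng, n, cfg.standardize)
        z_mix = rng.standard_normal(n)
        z_c = rho * z_bhi + np.sqrt(1 - rho**2) * z_mix
        if cfg.standardize:
            z_c = (z_c - z_c.mean()) / z_c.std(ddof=1)
        z_n = _std_normal(rng, n, cfg.standardize)
        bhi = cfg.bhi_mean[g] + cfg.bhi_sd[g] * z_bhi
        d13c = cfg.d13c_mean[g] + cfg.d13c_sd[g] * z_c
        d15n = cfg.d15n_mean[g] + cfg.d15n_sd[g] * z_n
        sl = cfg.sl_mean + cfg.sl_sd * rng.standard_normal(n)
        sl = np.clip(sl, 1.0, None)
        for i in range(n):
            specimens.append(
                Specimen(
                    id=f"{habitat[:3]}_{i + 1:03d}",
                    habitat=habitat,
                    standard_length=float(sl[i]),
                    body_height=float(bhi[i] * sl[i]),
                    d13c_raw=float(d13c[i]),
                    d15n=float(d15n[i]),
                    c_n_ratio=cfg.c_n_ratio,
                    measurement_mode="photo" if habitat == "limnetic" else "caliper",
                )
            )
    return specimens


def gen_microsat_genotypes(
    n_per_pop: Sequence[int] = (26, 26),
    n_loci: int = 13,
    target_fst: float = 0.005,
    n_alleles: int = 8,
    seed: int = 0,
) -> GenotypeTable:
    """Balding–Nichols island-model microsatellite genotypes.

    Ancestral allele frequencies are Dirichlet(1) per locus; each
    population's frequencies are Dirichlet(p (1 - F)/F) around them, which
    has E[F_ST] = ``target_fst``; genotypes are drawn under within-
    population Hardy–Weinberg.  Allele codes are fragment sizes in bp
    (100 + 2k).  ``target_fst = 0`` collapses to a single panmictic pool.
    """
    if not 0.0 <= target_fst <= 0.5:
        raise ValueError("target_fst must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    pops = [f"pop{k + 1}" for k in range(len(n_per_pop))]
    individuals, labels = [], []
    for p, n in zip(pops, n_per_pop):
        individuals += [f"{p}_{i + 1:03d}" for i in range(n)]
        labels += [p] * n
    n_total = len(individuals)
    calls = np.zeros((n_total, n_loci, 2), dtype=np.int32)
    loci = [Locus(id=f"ms{j + 1:02d}") for j in range(n_loci)]
    for j in range(n_loci):
        anc = rng.dirichlet(np.ones(n_alleles))
        row = 0
        for p, n in zip(pops, n_per_pop):
            if target_fst > 0:
                conc = anc * (1.0 - target_fst) / target_fst
                freq = rng.dirichlet(np.clip(conc, 1e-6, None))
            else:
                freq = anc
            draws = rng.choice(n_alleles, size=(n, 2), p=freq)
            calls[row : row + n, j, :] = 100 + 2 * draws
            row += n
    return GenotypeTable(individuals, loci, calls, populations=labels)


def _tag_layout(n_sites: int, pattern: Sequence[int]) -> List[Tuple[str, int]]:
    """Assign (tag, position) pairs cycling through the block-size pattern."""
    out = []
    tag_no, k, i = 0, 0, 0
    while len(out) < n_sites:
        size = pattern[k % len(pattern)]
        tag_no += 1
        for s in range(size):
            if len(out) >= n_sites:
                break
            out.append((f"tag{tag_no:06d}", 10 * (s + 1)))
        k += 1
    return out


def gen_rad_vcf(
    model: DemographicModel,
    n_sites: int,
    mu: float,
    missing_rate: float = 0.0,
    seed: int = 0,
    path=None,
    tag_pattern: Sequence[int] = (1, 2, 3),
) -> Tuple[GenotypeTable, JointSFS]:
    """Coalescent RAD-SNP genotypes plus the pre-missingness true SFS.

    Simulates one genealogy per candidate site, drops mutations at rate
    ``mu`` per site per generation, pairs haploid lineages into diploids,
    assigns RAD-tag ids in blocks (``tag_pattern`` SNPs per tag, cycling)
    and injects missing genotypes at ``missing_rate``.  Returns the
    genotype table (written to ``path`` as VCF if given) and the folded
    true joint SFS of the polymorphic sites before missingness.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    args = _kernel_args(model)
    leaf_deme, leaf_pop, n1, n2 = sample_layout(model)
    if n1 % 2 or n2 % 2:
        raise ValueError("haploid sample sizes must be even to form diploids")
    rng = np.random.default_rng(seed)
    n_leaves = leaf_deme.size
    true_grid = np.zeros((n1 + 1, n2 + 1))
    site_genotypes = []  # per polymorphic site: derived indicator per leaf
    for _ in range(n_sites):
        kseed = int(rng.integers(0, 2**31 - 1))
        parent, ntime, ok = _engine.genealogy_kernel(
            *args, leaf_deme, leaf_pop, kseed
        )
        if not ok:
            raise RuntimeError("stranded lineages while simulating RAD sites")
        has_parent = parent >= 0
        blen = np.zeros(parent.size)
        blen[has_parent] = ntime[parent[has_parent]] - ntime[has_parent]
        tbl = blen.sum()
        if rng.poisson(mu * tbl) == 0:
            continue
        u = rng.random() * tbl
        node = int(np.searchsorted(np.cumsum(blen), u))
        # derived = leaves below `node`
        derived = np.zeros(n_leaves, dtype=bool)
        children = [[] for _ in range(parent.size)]
        for c, p in enumerate(parent):
            if p >= 0:
                children[p].append(c)
        stack = [node]
        while stack:
            v = stack.pop()
            if v < n_leaves:
                derived[v] = True
            else:
                stack.extend(children[v])
        d1 = int(derived[leaf_pop == 0].sum())
        d2 = int(derived[leaf_pop == 1].sum()) if n2 else 0
        if (d1 + d2) in (0, n_leaves):
            continue
        true_grid[d1, d2] += 1
        site_genotypes.append(derived.astype(np.int32))

    # diploid individuals: consecutive leaf pairs within each population
    ind_ids, pops_out, pairs = [], [], []
    for pop, n_hap in ((0, n1), (1, n2)):
        leaf_ids = np.where(leaf_pop == pop)[0]
        for i in range(n_hap // 2):
            ind_ids.append(f"pop{pop + 1}_{i + 1:03d}")
            pops_out.append(f"pop{pop + 1}")
            pairs.append((leaf_ids[2 * i], leaf_ids[2 * i + 1]))
    layout = _tag_layout(len(site_genotypes), tag_pattern)
    loci = [
        Locus(id=f"{tag}:{pos}", tag=tag, position=pos)
        for (tag, pos) in layout
    ]
    calls = np.zeros((len(ind_ids), len(loci), 2), dtype=np.int32)
    for j, geno in enumerate(site_genotypes):
        for i, (a, b) in enumerate(pairs):
            calls[i, j, 0] = geno[a]
            calls[i, j, 1] = geno[b]
    if missing_rate > 0:
        miss = rng.random((len(ind_ids), len(loci))) < missing_rate
        calls[miss] = GenotypeTable.MISSING
    table = GenotypeTable(ind_ids, loci, calls, populations=pops_out)
    if path is not None:
        from .io import write_vcf

        write_vcf(table, path)
    true_sfs = JointSFS(true_grid, n1, n2, folded=False).fold()
    return table, true_sfs


# published split-brood summaries: (control mean, treatment mean,
# control SD, treatment SD, n control, n treatment)
BROOD_DEFAULTS = {
    "A.tolteca": (0.464, 0.464, 0.017, 0.014, 16, 17),
    "A.citrinellus": (0.476, 0.477, 0.009, 0.014, 24, 24),
    "A.zaliosus": (0.424, 0.421, 0.012, 0.009, 16, 31),
    "A.sagittae": (0.436, 0.442, 0.011, 0.011, 41, 42),
}


def gen_plasticity_broods(
    species_means: Optional[Sequence[float]] = None,
    sds: Optional[Sequence[float]] = None,
    n_per_cell=None,
    treatment_effect: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic split-brood experiment: 4 species x 2 flow treatments.

    Defaults take each species' mean/SD and cell sizes from the published
    control-group summaries; ``treatment_effect`` is added to every
    flow-treatment fish's BHI (0 = the no-plasticity null).  Returns a
    tidy frame with ``species``, ``treatment`` and ``bhi`` columns.
    """
    rng = np.random.default_rng(seed)
    species = list(BROOD_DEFAULTS)
    if species_means is None:
        species_means = [BROOD_DEFAULTS[s][0] for s in species]
    if sds is None:
        sds = [BROOD_DEFAULTS[s][2] for s in species]
    if n_per_cell is None:
        cells = {s: (BROOD_DEFAULTS[s][4], BROOD_DEFAULTS[s][5]) for s in species}
    elif np.isscalar(n_per_cell):
        cells = {s: (int(n_per_cell), int(n_per_cell)) for s in species}
    else:
        cells = {s: (int(a), int(b)) for s, (a, b) in zip(species, n_per_cell)}
    rows = []
    for s, mean, sd in zip(species, species_means, sds):
        for t, treat in enumerate(("control", "flow")):
            n = cells[s][t]
            if n < 2:
                raise ValueError("need at least 2 fish per cell")
            vals = mean + (treatment_effect if t else 0.0) + sd * rng.standard_normal(n)
            for v in vals:
                rows.append(dict(species=s, treatment=treat, bhi=float(v)))
    return pd.DataFrame(rows)
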