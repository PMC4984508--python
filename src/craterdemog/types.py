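"""Core domain types shared by all pipeline stages.

Conventions
-----------
* VCF positions are 1-based (as in the standard); internal site indices are
  0-based.
* Missing genotype calls are explicit ``None`` entries, never sentinel
  allele codes.
* Haploid sample sizes: a joint SFS over ``n1`` and ``n2`` allele copies has
  shape ``(n1 + 1, n2 + 1)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Specimen",
    "Locus",
    "GenotypeTable",
    "JointSFS",
    "TestResult",
    "FstResult",
    "FilterReport",
    "InferenceConfig",
    "FitResult",
]

HABITATS = ("limnetic", "benthic")


@dataclass
class Specimen:
    """One fish: morphometrics, stable isotopes and habitat of capture.

    ``bhi`` (body height index) is body height / standard length; lower
    values mean a more elongated, limnetic-like body.  δ13C and δ15N are in
    per-mil (‰) relative to the usual standards; ``c_n_ratio`` is the mass
    C:N ratio used for lipid normalization of δ13C.
    """

    id: str
    habitat: str
    standard_length: Optional[float] = None  # mm
    body_height: Optional[float] = None  # mm
    d13c_raw: Optional[float] = None  # permil
    d15n: Optional[float] = None  # permil
    c_n_ratio: Optional[float] = None
    measurement_mode: str = "caliper"  # or "photo"

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(
                f"habitat must be one of {HABITATS}, got {self.habitat!r}"
            )
        for name in ("standard_length", "body_height"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")

    @property
    def bhi(self) -> Optional[float]:
        if self.standard_length is None or self.body_height is None:
            return None
        return self.body_height / self.standard_length


@dataclass
class Locus:
    """A marker: microsatellite locus or a SNP on a RAD tag."""

    id: str
    tag: Optional[str] = None  # RAD-tag grouping key (CHROM by default)
    position: Optional[int] = None  # 1-based within tag/chromosome


class GenotypeTable:
    """Genotype calls for a set of individuals at a set of loci.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` with non-negative
    integer allele codes and ``-1`` *only internally* to mark missing; the
    public accessors return ``None`` for missing calls.  For biallelic SNPs
    the codes are 0 (REF) and 1 (ALT); for microsatellites they are allele
    sizes in bp.
    """

    MISSING = -1

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[Locus],
        calls: np.ndarray,
        populations: Optional[Sequence[str]] = None,
    ):
        calls = np.asarray(calls, dtype=np.int32)
        if calls.shape != (len(individuals), len(loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(individuals)}, {len(loci)}, 2)"
            )
        if ((calls < -1)).any():
            raise ValueError("allele codes must be non-negative (or -1 = missing)")
        # a half-missing diploid call is treated as fully missing
        half = (calls == self.MISSING).any(axis=2)
        calls = calls.copy()
        calls[half] = self.MISSING
        self.individuals = list(individuals)
        self.loci = list(loci)
        self.calls = calls
        self.populations = list(populations) if populations is not None else None
        if self.populations is not None and len(self.populations) != len(self.individuals):
            raise ValueError("populations must align with individuals")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the call is missing."""
        return (self.calls == self.MISSING).all(axis=2)

    def subset_loci(self, idx: Sequence[int]) -> "GenotypeTable":
        idx = list(idx)
        return GenotypeTable(
            self.individuals,
            [self.loci[i] for i in idx],
            self.calls[:, idx, :],
            self.populations,
        )

    def genotype(self, i: int, j: int):
        """Return the (a1, a2) call or ``None`` if missing."""
        a = self.calls[i, j]
        if a[0] == self.MISSING:
            return None
        return int(a[0]), int(a[1])


class JointSFS:
    """Two-dimensional joint site frequency spectrum.

    ``counts[i, j]`` is the (possibly fractional, after projection) number
    of sites with ``i`` copies of the focal allele among ``n1`` sampled
    copies in population 1 and ``j`` of ``n2`` in population 2.  When
    ``folded`` the focal allele is the pooled minor allele and cells with
    pooled frequency > 1/2 are zero; mass at exactly 1/2 is split between
    mirror cells.
    """

    def __init__(
        self,
        counts: np.ndarray,
        n1: int,
        n2: int,
        effective_length: Optional[float] = None,
        folded: bool = False,
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (n1 + 1, n2 + 1):
            raise ValueError(
                f"counts shape {counts.shape} != ({n1 + 1}, {n2 + 1})"
            )
        if (counts < 0).any():
            raise ValueError("SFS entries must be non-negative")
        self.counts = counts
        self.n1 = int(n1)
        self.n2 = int(n2)
        self.effective_length = effective_length
        self.folded = bool(folded)

    @property
    def n_polymorphic(self) -> float:
        """Total mass in polymorphic cells (both fixed corners excluded)."""
        s = self.counts.sum() - self.counts[0, 0] - self.counts[self.n1, self.n2]
        return float(s)

    def fold(self) -> "JointSFS":
        """Fold onto the pooled minor allele (mass at exactly 50% is split)."""
        n1, n2 = self.n1, self.n2
        c = self.counts
        i = np.arange(n1 + 1)[:, None]
        j = np.arange(n2 + 1)[None, :]
        tot = i + j
        half = (n1 + n2) / 2.0
        keep = (tot < half).astype(float) + 0.5 * (tot == half)
        # cell (i,j) keeps its own mass and receives the mirror (n1-i, n2-j)
        folded = (c + np.flipud(np.fliplr(c))) * keep
        return JointSFS(folded, n1, n2, self.effective_length, folded=True)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, JointSFS)
            and self.n1 == other.n1
            and self.n2 == other.n2
            and self.folded == other.folded
            and (
                (self.effective_length is None and other.effective_length is None)
                or (
                    self.effective_length is not None
                    and other.effective_length is not None
                    and self.effective_length == other.effective_length
                )
            )
            and np.array_equal(self.counts, other.counts)
        )

    def copy(self) -> "JointSFS":
        return JointSFS(
            self.counts.copy(), self.n1, self.n2, self.effective_length, self.folded
        )

    def __repr__(self) -> str:
        return (
            f"JointSFS(n1={self.n1}, n2={self.n2}, "
            f"S={self.n_polymorphic:.1f}, folded={self.folded})"
        )


@dataclass
class TestResult:
    """A named test statistic with its degrees of freedom and p-value."""

    __test__ = False  # not a pytest class despite the name

    name: str
    statistic: float
    df: object  # float or tuple of floats
    p_value: float

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass
class FstResult:
    theta: float
    per_locus: dict = field(default_factory=dict)
    n_permutations: int = 0
    p_value: Optional[float] = None


@dataclass
class FilterReport:
    """Counts of SNPs removed by each RAD filtering rule."""

    n_input: int = 0
    removed_blacklist: int = 0
    removed_excess_snps: int = 0
    removed_hwe: int = 0
    removed_not_first: int = 0
    retained: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def check(self) -> None:
        removed = (
            self.removed_blacklist
            + self.removed_excess_snps
            + self.removed_hwe
            + self.removed_not_first
        )
        if removed + self.retained != self.n_input:
            raise AssertionError("filter report does not balance")


@dataclass
class InferenceConfig:
    """Settings for the composite-likelihood demographic fit."""

    mu: float = 7.5e-9  # substitutions per site per generation
    ecm_rounds: int = 50
    sims_start: int = 100_000
    sims_end: int = 250_000
    sims_step: int = 5_000
    n_starts: int = 5
    n_bootstrap: int = 50
    seed: int = 0
    monomorphic: bool = True  # include the monomorphic class in the likelihood
    coord_evals: int = 8  # likelihood evaluations per coordinate line search
    polish_rounds: int = 0  # extra small-step rounds on the best start
    # start racing: run n_screen random starts through the first
    # screen_rounds rounds at screen_sims simulations, continue only the
    # n_starts best (0 disables screening)
    n_screen: int = 0
    screen_rounds: int = 5
    screen_sims: Optional[int] = None  # default: sims_start // 2
    # minimum composite-lnL gain to accept a coordinate/block move; anchors
    # the search against Monte-Carlo noise drift along flat ridges
    accept_tol: float = 0.5

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if self.sims_start > self.sims_end:
            raise ValueError("sims_start must be <= sims_end")

    def sims_for_round(self, r: int) -> int:
        """Simulation count for ECM round ``r`` (0-based), increasing schedule."""
        return min(self.sims_start + r * self.sims_step, self.sims_end)


@dataclass
class FitResult:
    """Outcome of one composite-likelihood fit."""

    model_id: str
    params: dict  # name -> value, demographic units
    lnl: float
    n_free: int
    seed: int = 0
    n_sims: int = 0
    ci: dict = field(default_factory=dict)  # name -> (lo, hi), 2.5/97.5 percentiles
    obs_id: Optional[str] = None

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free - 2.0 * self.lnl
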