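"""Demographic models: demes, timed events, and the crater-lake model family.

Time runs in generations before present; sizes are diploid individuals.
Growth rates are forward-time exponential rates per generation, so a deme
with current size ``N0`` and growth ``r`` had size ``N0 * exp(-r * t)`` at
``t`` generations ago.  The migration matrix entry ``m[i][j]`` is the
forward-time per-generation probability that an allele in deme ``i``
descends from deme ``j`` one generation earlier (equivalently, the
backward-time rate at which a lineage in ``i`` jumps to ``j``).

Models are compiled to a piecewise-constant-parameter epoch table consumed
by the coalescent engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = [
    "Deme",
    "SizeChange",
    "AdmixturePulse",
    "DemeFounding",
    "MigrationChange",
    "DemographicModel",
    "EpochTable",
    "crater_colonization_model",
    "CRATER_MLE",
]


@dataclass
class Deme:
    name: str
    size: float  # current diploid size
    growth: float = 0.0  # forward exponential growth rate per generation

    def __post_init__(self) -> None:
        if not self.size > 0:
            raise ValueError(f"deme size must be > 0, got {self.size}")


@dataclass
class SizeChange:
    """At ``time`` generations ago, set ``deme``'s size (and growth for all
    older times)."""

    time: float
    deme: str
    size: float
    growth: float = 0.0


@dataclass
class AdmixturePulse:
    """At ``time``, ``dest`` instantaneously received ``proportion`` of its
    gene pool from ``source`` (forward-time description)."""

    time: float
    source: str
    dest: str
    proportion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("admixture proportion must be in [0, 1]")


@dataclass
class DemeFounding:
    """``deme`` was founded at ``time`` from ``ancestor``: backward in time
    all of its lineages merge into the ancestor and the deme ceases to
    exist at older times."""

    time: float
    deme: str
    ancestor: str


@dataclass
class MigrationChange:
    """Replace the full forward migration matrix for all times older than
    ``time``."""

    time: float
    matrix: Sequence[Sequence[float]]


@dataclass
class DemographicModel:
    demes: List[Deme]
    migration: Optional[Sequence[Sequence[float]]] = None
    events: List[object] = field(default_factory=list)
    sample_config: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = len(self.demes)
        if self.migration is None:
            self.migration = np.zeros((d, d))
        self.migration = np.asarray(self.migration, dtype=float)
        if self.migration.shape != (d, d):
            raise ValueError("migration matrix shape mismatch")
        if (self.migration < 0).any() or (self.migration >= 1).any():
            raise ValueError("migration entries must be in [0, 1)")
        if any(e.time < 0 for e in self.events):
            raise ValueError("event times must be >= 0")
        self.events = sorted(self.events, key=lambda e: e.time)

    def deme_index(self, name: str) -> int:
        for i, d in enumerate(self.demes):
            if d.name == name:
                return i
        raise KeyError(f"no deme named {name!r}")

    @property
    def n_demes(self) -> int:
        return len(self.demes)


class EpochTable:
    """Piecewise representation of a model for the coalescent engine.

    Attributes (K epochs, D demes):

    * ``times``: (K+1,) epoch boundaries, times[0] == 0, times[-1] == inf
    * ``n_start``: (K, D) diploid size at the younger edge of each epoch
    * ``growth``: (K, D) forward growth rate within the epoch
    * ``mig``: (K, D, D) backward lineage jump rates (diagonal zero)
    * ``moves``: list, per interior boundary k (time ``times[k]``), of
      (from_deme, to_deme, probability) lineage moves applied when the
      engine crosses that boundary going backward.
    * ``alive``: (K, D) whether the deme exists in the epoch
    """

    def __init__(self, model: DemographicModel):
        D = model.n_demes
        times = sorted({0.0} | {float(e.time) for e in model.events})
        K = len(times)
        self.times = np.array(times + [np.inf])
        self.n_start = np.zeros((K, D))
        self.growth = np.zeros((K, D))
        self.mig = np.zeros((K, D, D))
        self.alive = np.ones((K, D), dtype=bool)
        self.moves: List[List[tuple]] = [[] for _ in range(K + 1)]

        size = np.array([d.size for d in model.demes], dtype=float)
        growth = np.array([d.growth for d in model.demes], dtype=float)
        mig = np.array(model.migration, dtype=float).copy()
        np.fill_diagonal(mig, 0.0)
        alive = np.ones(D, dtype=bool)

        events_at = {t: [] for t in times}
        for e in model.events:
            events_at[float(e.time)].append(e)

        for k, t in enumerate(times):
            # apply events at this boundary (affect epoch k and older)
            for e in events_at[t]:
                if isinstance(e, SizeChange):
                    i = model.deme_index(e.deme)
                    size[i] = e.size
                    growth[i] = e.growth
                elif isinstance(e, AdmixturePulse):
                    s = model.deme_index(e.source)
                    d_ = model.deme_index(e.dest)
                    self.moves[k].append((d_, s, float(e.proportion)))
                elif isinstance(e, DemeFounding):
                    i = model.deme_index(e.deme)
                    a = model.deme_index(e.ancestor)
                    # size at founding time from the younger epoch's trajectory
                    self.moves[k].append((i, a, 1.0))
                    alive = alive.copy()
                    alive[i] = False
                    mig[i, :] = 0.0
                    mig[:, i] = 0.0
                elif isinstance(e, MigrationChange):
                    mig = np.asarray(e.matrix, dtype=float).copy()
                    np.fill_diagonal(mig, 0.0)
                else:
                    raise TypeError(f"unknown event type {type(e)}")
            if k == 0:
                self.n_start[0] = size
            else:
                # size at the start (younger edge) of epoch k is the size at
                # boundary time t following the *previous* epoch's trajectory,
                # unless a SizeChange reset it at this boundary.
                dt = t - times[k - 1]
                carried = self.n_start[k - 1] * np.exp(-self.growth[k - 1] * dt)
                reset = np.zeros(D, dtype=bool)
                for e in events_at[t]:
                    if isinstance(e, SizeChange):
                        reset[model.deme_index(e.deme)] = True
                self.n_start[k] = np.where(reset, size, carried)
                size = self.n_start[k].copy()
            self.growth[k] = growth
            self.mig[k] = mig
            self.alive[k] = alive
            if not (self.n_start[k][alive] > 0).all():
                raise ValueError("deme size must remain > 0 after events")

        # sanity: the final (oldest) epoch must allow everything to coalesce
        self.n_demes = D
        self.n_epochs = K

    def size_at(self, deme: int, t: float) -> float:
        """Diploid size of ``deme`` at ``t`` generations before present."""
        k = int(np.searchsorted(self.times, t, side="right")) - 1
        k = min(k, self.n_epochs - 1)
        return float(
            self.n_start[k, deme] * math.exp(-self.growth[k, deme] * (t - self.times[k]))
        )


# Maximum-likelihood point estimates of the winning colonization model:
# a source lake that went through a bottleneck followed by exponential
# recovery, a crater lake founded from it by a handful of individuals with
# exponential growth since, one later admixture pulse from the source, and
# continuous low-level migration source -> crater.
CRATER_MLE = dict(
    n_anc=20_439.0,  # ancestral (pre-bottleneck) source size
    n_bneck=1_556.0,  # source size right after the bottleneck
    t_bneck=2_080.0,  # generations ago
    n_source_now=260_429.0,
    n_founder=32.0,  # crater founder size
    t_col=797.0,  # colonization time, generations ago
    n_crater_now=19_460.0,
    t_admix=507.0,  # admixture pulse time
    admix_prop=0.323,  # proportion of crater gene pool replaced
    mig=8.95e-5,  # per-allele per-generation migration probability into crater
)


def crater_colonization_model(
    n_anc: float,
    n_bneck: float,
    t_bneck: float,
    n_source_now: float,
    n_founder: float,
    t_col: float,
    n_crater_now: float,
    t_admix: float = 0.0,
    admix_prop: float = 0.0,
    mig: float = 0.0,
    samples: tuple = (50, 50),
    source_bottlegrowth: bool = True,
    crater_growth: bool = True,
) -> DemographicModel:
    """Build the two-deme crater-lake colonization model.

    Exponential growth rates are derived from the sizes at the two bounding
    times of each growth phase (e.g. the crater grows from ``n_founder`` at
    ``t_col`` to ``n_crater_now`` at present).  Structure toggles turn the
    bottlegrowth / growth / admixture / migration components off to produce
    the nested model family used for model comparison.

    Ordering ``t_admix < t_col < t_bneck`` is required whenever the
    corresponding components are active.
    """
    if admix_prop > 0 and not (0 < t_admix < t_col):
        raise ValueError("need 0 < t_admix < t_col for an admixture pulse")
    if source_bottlegrowth and not (t_col < t_bneck):
        raise ValueError("need t_col < t_bneck")

    if crater_growth:
        r_crater = math.log(n_crater_now / n_founder) / t_col
        crater = Deme("crater", n_crater_now, r_crater)
    else:
        crater = Deme("crater", n_crater_now, 0.0)

    if source_bottlegrowth:
        r_source = math.log(n_source_now / n_bneck) / t_bneck
        source = Deme("source", n_source_now, r_source)
    else:
        source = Deme("source", n_anc, 0.0)

    events: List[object] = []
    if admix_prop > 0:
        events.append(AdmixturePulse(t_admix, "source", "crater", admix_prop))
    if not crater_growth:
        # fixed founder size takes effect at colonization regardless
        if abs(n_crater_now - n_founder) > 0:
            events.append(SizeChange(t_col, "crater", n_founder))
    events.append(DemeFounding(t_col, "crater", "source"))
    if source_bottlegrowth:
        events.append(SizeChange(t_bneck, "source", n_anc, 0.0))

    mig_matrix = np.zeros((2, 2))
    if mig > 0:
        # crater receives alleles from the source: backward, crater lineages
        # jump to the source at rate mig
        mig_matrix[0, 1] = mig

    return DemographicModel(
        demes=[crater, source],
        migration=mig_matrix,
        events=events,
        sample_config={"crater": samples[0], "source": samples[1]},
    )
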