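"""Forward-time karyomorph-frequency dynamics and dispersal reachability.

Random mating, non-overlapping generations, autosomal karyomorphs, equal sex
contribution and no selfing.  Each generation: parents pair at random, each
parent contributes a gamete from its genotype's segregation distribution,
zygotes are viability-filtered and the survivors renormalized (fecundity
compensation).

Two census models:

* deterministic (infinite N): mating-pair frequencies are ``f_a * f_b``.
  When a state carries integer *counts* (e.g. a freshly arrived single
  migrant), pairs are drawn without replacement of individuals, so a
  singleton class cannot mate with itself — this is what restricts a type IV
  migrant's F1 in a type I population to {I, II, III, IV}.
* finite-N stochastic: the next generation's N individuals are sampled
  multinomially from the expected offspring distribution, with an explicit
  integer seed (no global RNG state).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .karyo_model import Karyomorph
from .segregation import (
    ParameterError,
    SegregationParams,
    ViabilityMap,
    apply_viability,
    cross,
    gametes_for_genotype,
    union_distribution,
)


@dataclass(frozen=True)
class PopulationState:
    """Karyomorph composition of one generation.

    ``counts`` (integers summing to the census size) marks a finite, exactly
    known population; ``freqs`` alone describes the deterministic
    infinite-N limit.
    """

    generation: int
    freqs: dict[Karyomorph, float]
    counts: dict[Karyomorph, int] | None = None
    extinct: bool = False

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ParameterError("generation must be >= 0")
        if not self.extinct:
            total = sum(self.freqs.values())
            if any(f < 0 for f in self.freqs.values()) or abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"frequencies must be >= 0 and sum to 1, got sum {total}"
                )
        if self.counts is not None:
            n = sum(self.counts.values())
            if n <= 0 or any(c < 0 for c in self.counts.values()):
                raise ParameterError("counts must be non-negative with positive total")

    @classmethod
    def from_counts(cls, counts: Mapping[Karyomorph, int], generation: int = 0) -> "PopulationState":
        n = sum(counts.values())
        freqs = {k: c / n for k, c in counts.items() if c > 0}
        return cls(generation=generation, freqs=freqs,
                   counts={k: int(c) for k, c in counts.items() if c > 0})

    @property
    def size(self) -> int | None:
        return None if self.counts is None else sum(self.counts.values())

    def support(self) -> set[Karyomorph]:
        return {k for k, f in self.freqs.items() if f > 0}


def migrant_state(
    migrant: Karyomorph, resident: Karyomorph, n_residents: int
) -> PopulationState:
    """Generation-0 state: one migrant among ``n_residents`` residents."""
    if n_residents < 1:
        raise ParameterError("need at least one resident")
    counts = {resident: n_residents}
    counts[migrant] = counts.get(migrant, 0) + 1
    return PopulationState.from_counts(counts)


def _pair_weights(state: PopulationState) -> dict[tuple[Karyomorph, Karyomorph], float]:
    """Unordered mating-pair probabilities.

    With integer counts, individuals pair without replacement
    (``n_a * n_b`` for a != b, ``n_a * (n_a - 1)`` within a class); in the
    frequency-only limit this reduces to ``f_a * f_b``.
    """
    if state.counts is not None:
        n = state.counts
        total = sum(n.values())
        if total < 2:
            raise ParameterError("a finite population needs >= 2 individuals to mate")
        denom = total * (total - 1)
        weights = {}
        for a in n:
            for b in n:
                w = n[a] * (n[b] - (1 if a == b else 0)) / denom
                if w > 0:
                    weights[(a, b)] = w
        return weights
    return {
        (a, b): fa * fb
        for a, fa in state.freqs.items()
        for b, fb in state.freqs.items()
        if fa * fb > 0
    }


def expected_offspring(
    state: PopulationState,
    params: SegregationParams,
    viability: ViabilityMap,
) -> tuple[dict[Karyomorph, float], float]:
    """Expected next-generation distribution and pre-normalization surviving mass."""
    gamete_dists = {k: gametes_for_genotype(k, params) for k in state.freqs}
    zygotes: dict[Karyomorph, float] = {}
    for (a, b), w in _pair_weights(state).items():
        for k, p in union_distribution(gamete_dists[a], gamete_dists[b]).items():
            zygotes[k] = zygotes.get(k, 0.0) + w * p
    return apply_viability(zygotes, viability, renormalize=True)


def step(
    state: PopulationState,
    params: SegregationParams,
    viability: ViabilityMap,
    rng: np.random.Generator | None = None,
) -> PopulationState:
    """Advance one generation.

    Deterministic when ``rng`` is None; otherwise the next generation keeps
    the census size and is sampled multinomially.  Total inviability yields a
    flagged (``extinct``) state rather than an exception.
    """
    dist, mass = expected_offspring(state, params, viability)
    if mass <= 0.0:
        return PopulationState(
            generation=state.generation + 1, freqs={}, counts=None, extinct=True
        )
    if rng is None:
        return PopulationState(generation=state.generation + 1, freqs=dist)
    if state.size is None:
        raise ParameterError("finite-N sampling requires a state with counts")
    karyos = sorted(dist)
    probs = np.array([dist[k] for k in karyos])
    draws = rng.multinomial(state.size, probs / probs.sum())
    counts = {k: int(c) for k, c in zip(karyos, draws) if c > 0}
    return PopulationState.from_counts(counts, generation=state.generation + 1)


def simulate(
    init: PopulationState,
    params: SegregationParams,
    viability: ViabilityMap | None = None,
    generations: int = 1,
    seed: int | None = None,
    mode: str = "det",
) -> list[PopulationState]:
    """Run ``generations`` steps, returning the trajectory including ``init``.

    ``mode="finite"`` requires an explicit integer seed and a counts-bearing
    initial state; the run is reproducible bit-for-bit from the seed.
    """
    viability = viability or ViabilityMap.default()
    if mode not in ("det", "finite"):
        raise ParameterError(f"mode must be 'det' or 'finite', got {mode!r}")
    rng = None
    if mode == "finite":
        if seed is None:
            raise ParameterError("finite-N simulation requires an explicit seed")
        rng = np.random.default_rng(seed)
    states = [init]
    for _ in range(generations):
        if states[-1].extinct:
            break
        states.append(step(states[-1], params, viability, rng=rng))
    return states


def reachable_types(
    migrant: Karyomorph,
    resident: Karyomorph,
    params: SegregationParams,
    viability: ViabilityMap | None = None,
    generations: int = 1,
) -> list[set[Karyomorph]]:
    """Set-valued dispersal recursion: which karyomorphs can appear per generation.

    F1 is the viable offspring of migrant x resident (a lone migrant cannot
    self); each later generation is the viable offspring of all pairs from
    the previous set together with the resident type.
    """
    if generations < 1:
        raise ParameterError("generations must be >= 1")
    viability = viability or ViabilityMap.default()
    sets: list[set[Karyomorph]] = []
    current = cross(migrant, resident, params, viability).support()
    sets.append(set(current))
    for _ in range(1, generations):
        pool = current | {resident}
        nxt: set[Karyomorph] = set()
        for a in pool:
            for b in pool:
                nxt |= cross(a, b, params, viability).support()
        sets.append(nxt)
        current = nxt
    return sets


def summarize_trajectory(states: Sequence[PopulationState]) -> pd.DataFrame:
    """Per-generation frequency table with the heterozygote fraction.

    One row per generation; karyomorph columns (labels) plus
    ``het_fraction``, the summed frequency of focally heterozygous
    karyomorphs (any heteromorphic homolog slot).
    """
    if not states:
        raise ParameterError("trajectory must contain at least one state")
    labels = sorted({k.label for s in states for k in s.freqs})
    rows = []
    for s in states:
        row: dict[str, object] = {"generation": s.generation, "extinct": s.extinct}
        by_label = {k.label: f for k, f in s.freqs.items()}
        for lab in labels:
            row[lab] = by_label.get(lab, 0.0)
        row["het_fraction"] = sum(
            f for k, f in s.freqs.items() if k.is_heterozygous
        )
        rows.append(row)
    return pd.DataFrame(rows)
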