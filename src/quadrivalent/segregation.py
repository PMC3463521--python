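"""Quadrivalent segregation, gamete and offspring enumeration, viability-filtered crosses.

A translocation heterozygote (karyomorph IV, MT/mSt) forms a quadrivalent of
the four focal chromosomes at meiosis I.  Three segregation modes produce six
gamete classes:

=========== ==================== =========================
mode        gametes              genic balance
=========== ==================== =========================
alternate   {M,m}, {T,St}        balanced
adjacent-1  {M,St}, {m,T}        unbalanced (dup/def)
adjacent-2  {M,T}, {m,St}        unbalanced (dup/def)
=========== ==================== =========================

All other genotypes have at most one heteromorphic homolog slot, so no
quadrivalent forms: they segregate as independent bivalents, one chromosome
per slot with equal probability ("trivial" mode).

Fusing gametes enumerates offspring karyomorphs: all six gamete classes give
19 karyologically distinct multisets, the four alternate+adjacent-1 gametes
give the nine Roman types I-IX.  Crosses convolve two parental gamete
distributions, apply per-karyomorph viability, and renormalize over the
surviving mass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .karyo_model import (
    CHR1_CODES,
    CHR6_CODES,
    Karyomorph,
    ROMAN_LABELS,
    _sort_codes,
)

PROBABILITY_TOL = 1e-9

MODES = ("alternate", "adjacent1", "adjacent2", "trivial")


class ParameterError(ValueError):
    """Segregation-mode or viability parameters violate their constraints."""


@dataclass(frozen=True)
class Gamete:
    """An unordered pair of focal chromosomes with segregation-mode provenance."""

    chromosomes: tuple[str, str]
    mode: str = "trivial"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"unknown segregation mode {self.mode!r}")
        object.__setattr__(self, "chromosomes", _sort_codes(self.chromosomes))

    @classmethod
    def of(cls, a: str, b: str, mode: str = "trivial") -> "Gamete":
        return cls((a, b), mode)

    @property
    def balanced(self) -> bool:
        """Genically balanced: one full chr-1 + chr-6 complement ({M,m} or {T,St})."""
        return set(self.chromosomes) in ({"M", "m"}, {"T", "St"})

    def __str__(self) -> str:  # pragma: no cover
        return "/".join(self.chromosomes)


ALTERNATE_GAMETES = (Gamete.of("M", "m", "alternate"), Gamete.of("T", "St", "alternate"))
ADJACENT1_GAMETES = (Gamete.of("M", "St", "adjacent1"), Gamete.of("m", "T", "adjacent1"))
ADJACENT2_GAMETES = (Gamete.of("M", "T", "adjacent2"), Gamete.of("m", "St", "adjacent2"))

SIX_GAMETES = ALTERNATE_GAMETES + ADJACENT1_GAMETES + ADJACENT2_GAMETES
FOUR_GAMETES = ALTERNATE_GAMETES + ADJACENT1_GAMETES


@dataclass(frozen=True)
class SegregationParams:
    """Probabilities of the three quadrivalent segregation modes."""

    p_alt: float
    p_adj1: float
    p_adj2: float = 0.0

    def __post_init__(self) -> None:
        for name, p in (("p_alt", self.p_alt), ("p_adj1", self.p_adj1), ("p_adj2", self.p_adj2)):
            if p < 0:
                raise ParameterError(f"{name} must be >= 0, got {p}")
        total = self.p_alt + self.p_adj1 + self.p_adj2
        if abs(total - 1.0) > PROBABILITY_TOL:
            raise ParameterError(
                f"segregation-mode probabilities must sum to 1 "
                f"(tolerance {PROBABILITY_TOL}), got {total}"
            )


def all_offspring_karyomorphs() -> frozenset[Karyomorph]:
    """The 19 karyologically distinct offspring of a heterozygote selfing."""
    return frozenset(enumerate_offspring(SIX_GAMETES))


@dataclass(frozen=True)
class ViabilityMap:
    """Per-karyomorph zygote-to-adult viability in [0, 1].

    The default encodes the observed lethal set: types I-V viable, the four
    anticipated-but-absent balanced types (VI, VII, VIII, IX) and every
    genically unbalanced multiset inviable.
    """

    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"viability of {label} must lie in [0, 1], got {v}")

    @classmethod
    def default(cls) -> "ViabilityMap":
        vals = {k.label: 0.0 for k in all_offspring_karyomorphs()}
        for label in ("I", "II", "III", "IV", "V"):
            vals[label] = 1.0
        return cls(vals)

    @classmethod
    def all_viable(cls) -> "ViabilityMap":
        vals = {k.label: 1.0 for k in all_offspring_karyomorphs()}
        return cls(vals)

    def __getitem__(self, key: "Karyomorph | str") -> float:
        label = key.label if isinstance(key, Karyomorph) else key
        try:
            return self.values[label]
        except KeyError:
            raise ParameterError(f"viability undefined for karyomorph {label!r}") from None

    def with_overrides(self, **overrides: float) -> "ViabilityMap":
        vals = dict(self.values)
        vals.update(overrides)
        return ViabilityMap(vals)


def _slots(k: Karyomorph) -> tuple[tuple[str, ...], tuple[str, ...]]:
    return (
        tuple(c for c in k.codes if c in CHR1_CODES),
        tuple(c for c in k.codes if c in CHR6_CODES),
    )


def gametes_for_genotype(
    k: Karyomorph, params: SegregationParams | None = None
) -> dict[Gamete, float]:
    """Gamete distribution of a genotype.

    Type IV (both slots heteromorphic) forms the quadrivalent: each mode's
    two gametes receive (mode weight)/2.  Focal homozygotes transmit their
    single gamete with probability 1.  Every other genotype segregates as
    independent bivalents: one chromosome per homolog slot, uniformly (a
    slot left empty by an unbalanced constitution contributes a same-slot
    pair instead).
    """
    chr1, chr6 = _slots(k)
    if _sort_codes(chr1) == ("M", "T") and _sort_codes(chr6) == ("m", "St"):
        if params is None:
            raise ParameterError(
                "segregation-mode probabilities are required for the "
                "translocation heterozygote (type IV)"
            )
        dist: dict[Gamete, float] = {}
        for weight, pair in (
            (params.p_alt, ALTERNATE_GAMETES),
            (params.p_adj1, ADJACENT1_GAMETES),
            (params.p_adj2, ADJACENT2_GAMETES),
        ):
            for g in pair:
                if weight > 0:
                    dist[g] = dist.get(g, 0.0) + weight / 2.0
        return dist

    if chr1 and chr6:
        combos = [(a, b) for a in chr1 for b in chr6]
    else:
        full = chr1 or chr6  # all four chromosomes in one slot
        combos = [pair for pair in itertools.combinations(full, 2)]
    dist = {}
    p = 1.0 / len(combos)
    for a, b in combos:
        g = Gamete.of(a, b)
        dist[g] = dist.get(g, 0.0) + p
    return dist


def enumerate_offspring(gametes: Iterable[Gamete]) -> set[Karyomorph]:
    """Distinct karyomorph multisets from all unordered gamete pairings
    (self-pairings included).

    Karyologically identical multisets from different pairings collapse,
    e.g. {M,m}+{T,St}, {M,St}+{m,T} and {M,T}+{m,St} all yield MT/mSt.
    """
    pool = list(dict.fromkeys(gametes))
    if not pool:
        raise ParameterError("gamete set must be non-empty")
    out: set[Karyomorph] = set()
    for g1, g2 in itertools.combinations_with_replacement(pool, 2):
        out.add(Karyomorph.from_codes(g1.chromosomes + g2.chromosomes))
    return out


def union_distribution(
    d1: Mapping[Gamete, float], d2: Mapping[Gamete, float]
) -> dict[Karyomorph, float]:
    """Zygote distribution from random union of two gamete distributions."""
    out: dict[Karyomorph, float] = {}
    for g1, p1 in d1.items():
        for g2, p2 in d2.items():
            k = Karyomorph.from_codes(g1.chromosomes + g2.chromosomes)
            out[k] = out.get(k, 0.0) + p1 * p2
    return out


def apply_viability(
    zygotes: Mapping[Karyomorph, float],
    viability: ViabilityMap,
    renormalize: bool = True,
) -> tuple[dict[Karyomorph, float], float]:
    """Filter a zygote distribution by viability.

    Returns ``(distribution, surviving_mass)``; with ``renormalize`` the
    distribution sums to 1 over survivors (empty when nothing survives).
    """
    survived = {k: p * viability[k] for k, p in zygotes.items() if p * viability[k] > 0.0}
    mass = sum(survived.values())
    if renormalize and mass > 0:
        survived = {k: p / mass for k, p in survived.items()}
    return survived, mass


@dataclass(frozen=True)
class CrossResult:
    """Offspring karyomorph distribution of a single cross."""

    distribution: dict[Karyomorph, float]
    surviving_mass: float

    @property
    def sterile(self) -> bool:
        """All conceivable offspring are inviable."""
        return self.surviving_mass <= 0.0

    def support(self) -> set[Karyomorph]:
        return set(self.distribution)

    def labels(self) -> dict[str, float]:
        return {k.label: p for k, p in sorted(self.distribution.items())}


def cross(
    a: Karyomorph,
    b: Karyomorph,
    params: SegregationParams | None = None,
    viability: ViabilityMap | None = None,
    renormalize: bool = True,
) -> CrossResult:
    """Offspring distribution of a x b under segregation ``params`` and viability.

    The distribution is the random union of the two parental gamete
    distributions, viability-filtered and (by default) renormalized over the
    surviving mass.  A cross whose offspring are all inviable is signalled
    through ``CrossResult.sterile``, not an exception.
    """
    viability = viability or ViabilityMap.default()
    zygotes = union_distribution(
        gametes_for_genotype(a, params), gametes_for_genotype(b, params)
    )
    dist, mass = apply_viability(zygotes, viability, renormalize=renormalize)
    return CrossResult(distribution=dist, surviving_mass=mass)
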