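"""Chromosome and karyomorph representation for a reciprocal-translocation polymorphism.

The polymorphism involves a mutual exchange between chromosome 1 (large
metacentric, M) and chromosome 6 (small metacentric, m): nearly the whole
short arm of chromosome 1 is exchanged with a small segment of chromosome 6,
producing a large telocentric translocated chromosome 1 (T) and a large
subtelocentric translocated chromosome 6 (St).  A karyomorph is the multiset
of the four "focal" chromosomes occupying the chromosome-1 and chromosome-6
homolog slots; the nine balanced combinations carry Roman labels I-IX
(I = MM/mm normal, IV = MT/mSt translocation heterozygote,
IX = TT/StSt translocation homozygote).

The 5S rDNA locus sits near the chromosome-1 centromere and is retained on
both M and T, so a FISH signal is a homology marker that pins a chromosome
into the chr-1 slot regardless of its morphology.

This module classifies centromere position (Levan arm-ratio nomenclature)
and size class from morphometric measurements, canonicalizes karyomorph
labels, and calls a whole cell's karyomorph from its 26 measurement records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

# --- alphabet -------------------------------------------------------------

FOCAL_CODES: tuple[str, ...] = ("M", "T", "m", "St")
CHR1_CODES = frozenset({"M", "T"})  # carry the 5S rDNA marker
CHR6_CODES = frozenset({"m", "St"})
_CODE_ORDER = {"M": 0, "T": 1, "m": 2, "St": 3}

#: diploid chromosome number of the species
DIPLOID_NUMBER = 26
N_PAIRS = DIPLOID_NUMBER // 2


class CentromereClass(str, Enum):
    """Levan (1964) centromere-position class, ordered by arm ratio."""

    metacentric = "metacentric"
    submetacentric = "submetacentric"
    subtelocentric = "subtelocentric"
    telocentric = "telocentric"

    @property
    def index(self) -> int:
        return _CENTROMERE_ORDER[self]


_CENTROMERE_ORDER = {
    CentromereClass.metacentric: 0,
    CentromereClass.submetacentric: 1,
    CentromereClass.subtelocentric: 2,
    CentromereClass.telocentric: 3,
}

# Levan arm-ratio cut points, half-open intervals, lower bound inclusive:
# [1.0, 1.7) metacentric, [1.7, 3.0) submetacentric, [3.0, 7.0)
# subtelocentric, [7.0, inf) telocentric.
LEVAN_BOUNDARIES: tuple[tuple[float, CentromereClass], ...] = (
    (1.7, CentromereClass.metacentric),
    (3.0, CentromereClass.submetacentric),
    (7.0, CentromereClass.subtelocentric),
    (math.inf, CentromereClass.telocentric),
)

#: default large/small relative-length cutoff (percent of haploid complement);
#: separates the largest small chromosome (6.09) from the smallest large one
#: (8.19) in both reference idiograms.
DEFAULT_SIZE_CUTOFF = 7.0

#: arm ratio above which a homolog *within an identified focal pair* is called
#: translocated (T in the chr-1 slot, St in the chr-6 slot).  Anything beyond
#: the metacentric range in a focal pair is the rearranged homolog; using the
#: metacentric/submetacentric boundary keeps the call >4.8 SD away from every
#: reference mean, which exact Levan classes would not (T sits ~1 SD from the
#: telocentric boundary).
TRANSLOCATED_AR_THRESHOLD = 1.7


class MeasurementError(ValueError):
    """A single measurement violates its physical constraints."""


class DomainError(ValueError):
    """A chromosome code outside the focal alphabet."""


class MalformedCellError(ValueError):
    """A cell's record set cannot represent a 2n = 26 karyotype."""


class AmbiguityError(ValueError):
    """Focal-pair assignment is ambiguous; ``candidates`` names the options."""

    def __init__(self, message: str, candidates: Sequence[int] = ()):
        super().__init__(message)
        self.candidates = tuple(candidates)


# --- elementary classifiers ----------------------------------------------

def classify_centromere(arm_ratio: float) -> CentromereClass:
    """Classify centromere position from the arm ratio (long/short arm).

    Uses Levan cut points 1.7, 3.0 and 7.0 with half-open intervals
    (lower bound inclusive).  ``arm_ratio`` must be >= 1.
    """
    if not math.isfinite(arm_ratio) and arm_ratio != math.inf:
        raise MeasurementError(f"arm ratio must be a number, got {arm_ratio!r}")
    if arm_ratio < 1.0:
        raise MeasurementError(
            f"arm ratio must be >= 1 (long arm / short arm), got {arm_ratio}"
        )
    for upper, klass in LEVAN_BOUNDARIES:
        if arm_ratio < upper:
            return klass
    return CentromereClass.telocentric  # arm_ratio == inf


def classify_size(relative_length: float, cutoff: float = DEFAULT_SIZE_CUTOFF) -> str:
    """Return ``"large"`` or ``"small"`` from relative length (percent).

    ``large`` iff relative_length >= cutoff.
    """
    if not relative_length > 0:
        raise MeasurementError(
            f"relative length must be positive, got {relative_length}"
        )
    return "large" if relative_length >= cutoff else "small"


# --- types ----------------------------------------------------------------

@dataclass(frozen=True)
class FocalChromosome:
    """One member of the translocation quadrivalent."""

    code: str

    def __post_init__(self) -> None:
        if self.code not in FOCAL_CODES:
            raise DomainError(
                f"unknown focal chromosome code {self.code!r}; "
                f"alphabet is {FOCAL_CODES}"
            )

    @property
    def carries_5S(self) -> bool:
        """True for the chromosome-1 complement (M and T carry the 5S locus)."""
        return self.code in CHR1_CODES


@dataclass(frozen=True)
class MeasurementRecord:
    """One chromosome's morphometrics within one metaphase cell.

    ``relative_length`` is on the percent-of-haploid-complement scale
    (the 26 records of a cell sum to ~200).
    """

    cell_id: str
    chrom_index: int
    homolog_id: int
    relative_length: float
    arm_ratio: float
    has_5S_signal: bool | None = None

    def __post_init__(self) -> None:
        if not self.relative_length > 0:
            raise MeasurementError(
                f"cell {self.cell_id} chrom {self.chrom_index}-{self.homolog_id}: "
                f"relative length must be positive, got {self.relative_length}"
            )
        if self.arm_ratio < 1.0:
            raise MeasurementError(
                f"cell {self.cell_id} chrom {self.chrom_index}-{self.homolog_id}: "
                f"arm ratio must be >= 1, got {self.arm_ratio}"
            )
        if not 1 <= int(self.chrom_index) <= N_PAIRS:
            raise MeasurementError(
                f"chrom_index must be in 1..{N_PAIRS}, got {self.chrom_index}"
            )
        if int(self.homolog_id) not in (1, 2):
            raise MeasurementError(f"homolog_id must be 1 or 2, got {self.homolog_id}")


# Roman labels of the nine balanced karyomorphs, keyed by
# (sorted chr-1 pair, sorted chr-6 pair).
ROMAN_GRID: dict[tuple[tuple[str, str], tuple[str, str]], str] = {
    (("M", "M"), ("m", "m")): "I",
    (("M", "M"), ("m", "St")): "II",
    (("M", "T"), ("m", "m")): "III",
    (("M", "T"), ("m", "St")): "IV",
    (("M", "T"), ("St", "St")): "V",
    (("M", "M"), ("St", "St")): "VI",
    (("T", "T"), ("m", "m")): "VII",
    (("T", "T"), ("m", "St")): "VIII",
    (("T", "T"), ("St", "St")): "IX",
}
_ROMAN_TO_PAIRS = {v: k for k, v in ROMAN_GRID.items()}
ROMAN_LABELS = tuple(_ROMAN_TO_PAIRS)


def _sort_codes(codes: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(codes, key=_CODE_ORDER.__getitem__))


@dataclass(frozen=True, order=True)
class Karyomorph:
    """A multiset of exactly four focal chromosomes, canonically ordered.

    ``balanced`` is True iff exactly two chromosomes carry the 5S/chr-1
    complement (and hence two the chr-6 complement); only balanced
    karyomorphs get Roman labels, all others use the systematic label
    (codes joined in canonical order, e.g. ``"MMTm"``).
    """

    codes: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.codes) != 4:
            raise DomainError(f"a karyomorph has exactly 4 chromosomes, got {self.codes}")
        for c in self.codes:
            if c not in FOCAL_CODES:
                raise DomainError(f"unknown code {c!r} in {self.codes}")
        object.__setattr__(self, "codes", _sort_codes(self.codes))

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "Karyomorph":
        return cls(tuple(codes))  # type: ignore[arg-type]

    @classmethod
    def from_label(cls, label: str) -> "Karyomorph":
        """Parse a Roman (I-IX) or systematic (e.g. ``MmStSt``) label."""
        if label in _ROMAN_TO_PAIRS:
            chr1, chr6 = _ROMAN_TO_PAIRS[label]
            return cls.from_codes(chr1 + chr6)
        codes: list[str] = []
        i = 0
        while i < len(label):
            if label.startswith("St", i):
                codes.append("St")
                i += 2
            elif label[i] in ("M", "T", "m"):
                codes.append(label[i])
                i += 1
            else:
                raise DomainError(f"cannot parse karyomorph label {label!r}")
        return cls.from_codes(codes)

    @property
    def chr1_codes(self) -> tuple[str, ...]:
        return tuple(c for c in self.codes if c in CHR1_CODES)

    @property
    def chr6_codes(self) -> tuple[str, ...]:
        return tuple(c for c in self.codes if c in CHR6_CODES)

    @property
    def balanced(self) -> bool:
        return len(self.chr1_codes) == 2

    @property
    def label(self) -> str:
        if self.balanced:
            return ROMAN_GRID[(self.chr1_codes, self.chr6_codes)]
        return "".join(self.codes)

    @property
    def is_heterozygous(self) -> bool:
        """True if either homolog slot is heteromorphic (unbalanced count too)."""
        if not self.balanced:
            return True
        a, b = self.chr1_codes
        c, d = self.chr6_codes
        return a != b or c != d

    @property
    def n_translocated(self) -> int:
        """Number of translocated chromosomes (T or St) among the four."""
        return sum(1 for c in self.codes if c in ("T", "St"))

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


def karyomorph_from_codes(
    chr1_pair: Sequence[str], chr6_pair: Sequence[str]
) -> Karyomorph:
    """Build a karyomorph from the two homolog pairs; order is irrelevant."""
    if len(chr1_pair) != 2 or len(chr6_pair) != 2:
        raise DomainError("each homolog slot takes exactly two chromosome codes")
    return Karyomorph.from_codes(tuple(chr1_pair) + tuple(chr6_pair))


# --- whole-cell classification --------------------------------------------

@dataclass(frozen=True)
class KaryoConfig:
    """Tunables for morphometric karyotyping.

    rl_sum_tol
        Acceptable deviation of the per-cell relative-length sum (on the
        per-haploid-complement scale, i.e. sum over 26 chromosomes divided
        by two) from ``rl_sum_target``; set to ``None`` to skip the check.
        The check exists to catch wrong-scale input (e.g. fractions
        instead of percent); published heteromorphic idiograms normalize
        over different entry sets, shifting the raw sum by up to ~20
        percent, hence the generous default.
    normalize_rl
        Rescale the cell's relative lengths to the target scale before size
        classification, making size calls independent of the input scale.
    infer_slots
        If no 5S flags are present, identify the chr-1 pair by morphology
        (largest pair of metacentric/telocentric large chromosomes) instead
        of trusting ``chrom_index``.
    """

    size_cutoff: float = DEFAULT_SIZE_CUTOFF
    rl_sum_target: float = 100.0
    rl_sum_tol: float | None = 25.0
    normalize_rl: bool = True
    translocated_ar_threshold: float = TRANSLOCATED_AR_THRESHOLD
    infer_slots: bool = False
    ambiguity_margin: float = 1.0


@dataclass(frozen=True)
class ClassifiedCell:
    """Result of :func:`karyotype_from_measurements`."""

    cell_id: str
    karyomorph: Karyomorph
    table: pd.DataFrame = field(compare=False)

    @property
    def label(self) -> str:
        return self.karyomorph.label


def _pairs_by_index(records: Sequence[MeasurementRecord]) -> dict[int, list[MeasurementRecord]]:
    pairs: dict[int, list[MeasurementRecord]] = {}
    for rec in records:
        pairs.setdefault(int(rec.chrom_index), []).append(rec)
    return pairs


def _infer_chr1_pair(
    pairs: Mapping[int, Sequence[MeasurementRecord]], config: KaryoConfig
) -> int:
    """Morphology-based chr-1 pair identification (no 5S flags available).

    Candidate pairs have both members metacentric or (sub)telocentric and
    large; the pair with the largest mean relative length wins.  A runner-up
    within ``ambiguity_margin`` RL percent triggers :class:`AmbiguityError`.
    """
    acceptable = {
        CentromereClass.metacentric,
        CentromereClass.subtelocentric,
        CentromereClass.telocentric,
    }
    scored: list[tuple[float, int]] = []
    for idx, members in pairs.items():
        classes = [classify_centromere(m.arm_ratio) for m in members]
        sizes = [classify_size(m.relative_length, config.size_cutoff) for m in members]
        if all(c in acceptable for c in classes) and all(s == "large" for s in sizes):
            mean_rl = sum(m.relative_length for m in members) / len(members)
            scored.append((mean_rl, idx))
    if not scored:
        raise AmbiguityError(
            "no homolog pair matches the chr-1 morphology "
            "(large metacentric/telocentric)"
        )
    scored.sort(reverse=True)
    if len(scored) > 1 and scored[0][0] - scored[1][0] < config.ambiguity_margin:
        cands = [idx for _, idx in scored[:2]]
        raise AmbiguityError(
            f"chr-1 pair ambiguous between chromosome pairs {cands} "
            f"(mean RL {scored[0][0]:.2f} vs {scored[1][0]:.2f})",
            candidates=cands,
        )
    return scored[0][1]


def _infer_chr6_pair(
    pairs: Mapping[int, Sequence[MeasurementRecord]],
    chr1_idx: int,
    config: KaryoConfig,
) -> int:
    """Chr-6 pair: any pair containing a subtelocentric (St-like) member,
    else the largest remaining small-metacentric pair."""
    st_pairs: list[int] = []
    small_met: list[tuple[float, int]] = []
    for idx, members in pairs.items():
        if idx == chr1_idx:
            continue
        classes = [classify_centromere(m.arm_ratio) for m in members]
        sizes = [classify_size(m.relative_length, config.size_cutoff) for m in members]
        if any(c is CentromereClass.subtelocentric for c in classes):
            st_pairs.append(idx)
        elif all(c is CentromereClass.metacentric for c in classes) and all(
            s == "small" for s in sizes
        ):
            mean_rl = sum(m.relative_length for m in members) / len(members)
            small_met.append((mean_rl, idx))
    if len(st_pairs) == 1:
        return st_pairs[0]
    if len(st_pairs) > 1:
        raise AmbiguityError(
            f"chr-6 pair ambiguous: several pairs contain subtelocentric members "
            f"{sorted(st_pairs)}",
            candidates=sorted(st_pairs),
        )
    if not small_met:
        raise AmbiguityError("no candidate chr-6 pair (small metacentric) found")
    small_met.sort(reverse=True)
    return small_met[0][1]


def karyotype_from_measurements(
    records: Sequence[MeasurementRecord], config: KaryoConfig | None = None
) -> ClassifiedCell:
    """Call the karyomorph of one cell from its 26 measurement records.

    Every chromosome is classified by centromere position and size; the four
    focal chromosomes are located (5S flags force the flagged pair into the
    chr-1 slot; otherwise the pairing given by ``chrom_index`` — or pure
    morphology when ``config.infer_slots`` — is used) and coded M/T and m/St
    by arm ratio within their pair.  Returns the karyomorph together with the
    full per-chromosome classification table.
    """
    config = config or KaryoConfig()
    records = list(records)
    if len(records) != DIPLOID_NUMBER:
        raise MalformedCellError(
            f"a cell must have exactly {DIPLOID_NUMBER} chromosomes, "
            f"got {len(records)}"
        )
    cell_ids = {r.cell_id for r in records}
    if len(cell_ids) != 1:
        raise MalformedCellError(f"records mix several cells: {sorted(cell_ids)}")
    cell_id = records[0].cell_id

    pairs = _pairs_by_index(records)
    if sorted(pairs) != list(range(1, N_PAIRS + 1)) or any(
        len(v) != 2 for v in pairs.values()
    ):
        raise MalformedCellError(
            f"cell {cell_id}: expected chromosome pairs 1..{N_PAIRS} with two "
            f"homologs each, got "
            f"{{{', '.join(f'{k}: {len(v)}' for k, v in sorted(pairs.items()))}}}"
        )

    raw_sum = sum(r.relative_length for r in records) / 2.0
    if config.rl_sum_tol is not None and abs(raw_sum - config.rl_sum_target) > config.rl_sum_tol:
        raise MalformedCellError(
            f"cell {cell_id}: per-haploid relative-length sum {raw_sum:.2f} "
            f"outside {config.rl_sum_target} +/- {config.rl_sum_tol}"
        )
    scale = (config.rl_sum_target / raw_sum) if config.normalize_rl else 1.0
    if scale != 1.0:
        records = [replace(r, relative_length=r.relative_length * scale) for r in records]
        pairs = _pairs_by_index(records)

    # locate the chr-1 pair
    flagged = [r for r in records if r.has_5S_signal]
    if flagged:
        flagged_pairs = {int(r.chrom_index) for r in flagged}
        if len(flagged) != 2 or len(flagged_pairs) != 1:
            raise AmbiguityError(
                f"cell {cell_id}: 5S signals must mark exactly one homolog pair, "
                f"found {len(flagged)} signals on pairs {sorted(flagged_pairs)}",
                candidates=sorted(flagged_pairs),
            )
        chr1_idx = flagged_pairs.pop()
    elif config.infer_slots:
        chr1_idx = _infer_chr1_pair(pairs, config)
    else:
        chr1_idx = 1
    if config.infer_slots and not any(r.has_5S_signal for r in pairs[chr1_idx]):
        chr6_idx = _infer_chr6_pair(pairs, chr1_idx, config)
    elif chr1_idx != 6:
        chr6_idx = 6
    else:
        chr6_idx = _infer_chr6_pair(pairs, chr1_idx, config)

    thr = config.translocated_ar_threshold
    chr1_codes = tuple(
        "T" if r.arm_ratio >= thr else "M" for r in pairs[chr1_idx]
    )
    chr6_codes = tuple(
        "St" if r.arm_ratio >= thr else "m" for r in pairs[chr6_idx]
    )
    karyomorph = karyomorph_from_codes(chr1_codes, chr6_codes)

    code_of: dict[tuple[int, int], str] = {}
    for rec, code in zip(pairs[chr1_idx], chr1_codes):
        code_of[(rec.chrom_index, rec.homolog_id)] = code
    for rec, code in zip(pairs[chr6_idx], chr6_codes):
        code_of[(rec.chrom_index, rec.homolog_id)] = code

    rows = []
    for r in sorted(records, key=lambda r: (r.chrom_index, r.homolog_id)):
        rows.append(
            {
                "cell_id": r.cell_id,
                "chrom_index": r.chrom_index,
                "homolog_id": r.homolog_id,
                "relative_length": r.relative_length,
                "arm_ratio": r.arm_ratio,
                "centromere_class": classify_centromere(r.arm_ratio).value,
                "size_class": classify_size(r.relative_length, config.size_cutoff),
                "focal_code": code_of.get((r.chrom_index, r.homolog_id), ""),
                "has_5S_signal": r.has_5S_signal,
            }
        )
    table = pd.DataFrame(rows)
    return ClassifiedCell(cell_id=cell_id, karyomorph=karyomorph, table=table)
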