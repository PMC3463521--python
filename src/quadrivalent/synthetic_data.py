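"""Seeded generators for every input the pipeline consumes.

Three generators mirror the three observed data layers:

* :func:`generate_cells` — per-cell chromosome morphometrics (relative
  length, arm ratio) drawn from truncated normals around a reference
  idiogram's means and SDs, with relative lengths renormalized per cell and
  5S flags set on the chromosome-1 homologs;
* :func:`generate_counts` — population karyomorph count tables drawn from
  the viability-filtered random-gamete-union distribution;
* :func:`generate_lengths` — heteromorphic-chromosome length tables with a
  lognormal per-cell size factor (metaphase cells vary ~2x in total length)
  and additive measurement noise, built to conserve S_het = S_norm up to
  noise.

All generators take an explicit integer seed and are byte-reproducible.
The noise model is Gaussian and independent across chromosomes; real
metaphase measurements correlate within a cell (condensation gradients),
which is captured only through the per-cell scale factor.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .karyo_model import CHR1_CODES, DIPLOID_NUMBER, Karyomorph
from .segregation import (
    Gamete,
    ParameterError,
    ViabilityMap,
    apply_viability,
    union_distribution,
)
from .inference import GametePoolParams

_IDIOGRAM_RESOURCE = "table5_idiogram.csv"
#: per-cell relative lengths are rescaled to this sum over the 26
#: chromosomes (percent-of-haploid-complement scale).
RL_CELL_SUM = 200.0


def _idiogram_frame() -> pd.DataFrame:
    ref = importlib.resources.files("quadrivalent") / "data" / _IDIOGRAM_RESOURCE
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, dtype={"focal_code": "string"})
    df["focal_code"] = df["focal_code"].fillna("")
    return df


@dataclass(frozen=True)
class IdiogramEntry:
    chrom_index: int
    homolog_id: int
    rl_mean: float
    rl_sd: float
    ar_mean: float
    ar_sd: float
    focal_code: str = ""

    def __post_init__(self) -> None:
        if self.rl_mean <= 0 or self.ar_mean < 1:
            raise ParameterError("idiogram means must satisfy RL > 0, AR >= 1")
        if self.rl_sd < 0 or self.ar_sd < 0:
            raise ParameterError("idiogram SDs must be >= 0")


@dataclass(frozen=True)
class IdiogramSpec:
    """Mean +/- SD morphometrics for each of the 26 chromosomes of a karyomorph."""

    entries: tuple[IdiogramEntry, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != DIPLOID_NUMBER:
            raise ParameterError(
                f"an idiogram spec needs {DIPLOID_NUMBER} chromosome entries, "
                f"got {len(self.entries)}"
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IdiogramSpec":
        entries = tuple(
            IdiogramEntry(
                int(r.chrom_index), int(r.homolog_id),
                float(r.rl_mean), float(r.rl_sd),
                float(r.ar_mean), float(r.ar_sd),
                str(r.focal_code),
            )
            for r in df.itertuples()
        )
        return cls(entries)

    def entry(self, chrom_index: int, homolog_id: int) -> IdiogramEntry:
        for e in self.entries:
            if e.chrom_index == chrom_index and e.homolog_id == homolog_id:
                return e
        raise ParameterError(
            f"idiogram spec missing chromosome {chrom_index}-{homolog_id}"
        )


def reference_idiogram(karyotype: str) -> IdiogramSpec:
    """The packaged measured idiogram for karyomorph ``"I"`` or ``"IV"``."""
    df = _idiogram_frame()
    sub = df[df["karyotype"] == karyotype]
    if sub.empty:
        raise ParameterError(
            f"no packaged idiogram for karyotype {karyotype!r} (have I and IV)"
        )
    return IdiogramSpec.from_frame(sub)


def idiogram_for(k: Karyomorph) -> IdiogramSpec:
    """Compose an idiogram for any balanced karyomorph.

    Type I uses its own measured column; every other balanced type is
    assembled from the type IV column, substituting the focal homolog
    moments (M = 1-1, T = 1-2, m = 6-1, St = 6-2) according to the
    karyomorph's codes.  Per-cell renormalization absorbs the two columns'
    slightly different length scales.
    """
    if not k.balanced:
        raise ParameterError(
            f"idiograms are defined for balanced karyomorphs only, got {k.label}"
        )
    if k.label == "I":
        return reference_idiogram("I")
    base = reference_idiogram("IV")
    code_entry = {
        "M": base.entry(1, 1),
        "T": base.entry(1, 2),
        "m": base.entry(6, 1),
        "St": base.entry(6, 2),
    }
    entries = []
    for e in base.entries:
        if e.chrom_index == 1:
            code = k.chr1_codes[e.homolog_id - 1]
        elif e.chrom_index == 6:
            code = k.chr6_codes[e.homolog_id - 1]
        else:
            entries.append(e)
            continue
        src = code_entry[code]
        entries.append(
            IdiogramEntry(
                e.chrom_index, e.homolog_id,
                src.rl_mean, src.rl_sd, src.ar_mean, src.ar_sd, code,
            )
        )
    return IdiogramSpec(tuple(entries))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cells(
    k: Karyomorph,
    spec: IdiogramSpec | None = None,
    n_cells: int = 1,
    seed: int = 0,
    cell_prefix: str | None = None,
) -> pd.DataFrame:
    """Simulate per-cell measurement records for ``n_cells`` cells of karyomorph ``k``.

    Relative lengths are truncated-normal (> 0) at the spec's moments and
    renormalized so each cell sums to 200 (percent of one haploid
    complement); arm ratios are truncated-normal (>= 1).  Chromosome-1
    homologs get ``has_5S_signal = True``.  Output columns match the
    measurement CSV schema.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    spec = spec or idiogram_for(k)
    rng = np.random.default_rng(seed)
    prefix = cell_prefix or f"{k.label}_cell"

    rl = np.column_stack(
        [_truncated_normal(rng, e.rl_mean, e.rl_sd, 0.0, n_cells) for e in spec.entries]
    )
    ar = np.column_stack(
        [_truncated_normal(rng, e.ar_mean, e.ar_sd, 1.0, n_cells) for e in spec.entries]
    )
    rl *= RL_CELL_SUM / rl.sum(axis=1, keepdims=True)

    rows = []
    for i in range(n_cells):
        cid = f"{prefix}{i:04d}"
        for j, e in enumerate(spec.entries):
            rows.append(
                {
                    "cell_id": cid,
                    "chrom_index": e.chrom_index,
                    "homolog_id": e.homolog_id,
                    "relative_length": rl[i, j],
                    "arm_ratio": ar[i, j],
                    "has_5S_signal": e.focal_code in CHR1_CODES,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimScenario:
    """Study design for synthetic population count tables."""

    gamete_pool: GametePoolParams
    population_sizes: tuple[int, ...]
    seed: int
    viability: ViabilityMap | None = None

    def __post_init__(self) -> None:
        if not self.population_sizes or any(n < 1 for n in self.population_sizes):
            raise ParameterError("population sizes must be positive")


def zygote_distribution_from_pool(
    pool: GametePoolParams, viability: ViabilityMap | None = None
) -> dict[Karyomorph, float]:
    """Viability-filtered random-union karyomorph distribution of a gamete pool."""
    gametes = {
        Gamete.of("M", "m"): pool.f1,
        Gamete.of("T", "St"): pool.f2,
        Gamete.of("M", "St"): pool.f3,
        Gamete.of("m", "T"): pool.f4,
    }
    gametes = {g: p for g, p in gametes.items() if p > 0}
    zygotes = union_distribution(gametes, gametes)
    dist, mass = apply_viability(zygotes, viability or ViabilityMap.default())
    if mass <= 0:
        raise ParameterError("gamete pool yields no viable offspring")
    return dist


def generate_counts(scenario: SimScenario) -> pd.DataFrame:
    """Draw population x sex x karyomorph count tables under a scenario.

    Individuals are multinomial in the viability-filtered random-union
    distribution; sexes are assigned independently 50/50.  Output matches
    the counts CSV schema (nonzero rows only).
    """
    rng = np.random.default_rng(scenario.seed)
    dist = zygote_distribution_from_pool(scenario.gamete_pool, scenario.viability)
    karyos = sorted(dist)
    probs = np.array([dist[k] for k in karyos])
    rows = []
    for p_idx, n in enumerate(scenario.population_sizes, start=1):
        draws = rng.multinomial(n, probs / probs.sum())
        for k, c in zip(karyos, draws):
            if c == 0:
                continue
            males = int(rng.binomial(int(c), 0.5))
            for sex, cnt in (("male", males), ("female", int(c) - males)):
                if cnt > 0:
                    rows.append(
                        {
                            "population_id": f"pop{p_idx}",
                            "sex": sex,
                            "karyomorph": k.label,
                            "count": cnt,
                        }
                    )
    return pd.DataFrame(rows, columns=["population_id", "sex", "karyomorph", "count"])


#: default homolog lengths (micrometres) for synthetic length tables; chosen
#: in the range of measured karyomorph-IV cells and exactly length-conserving
#: (1-2 + 6-2 = 1-1 + 6-1), i.e. the null of the conservation test.
DEFAULT_BASE_LENGTHS: Mapping[str, float] = {
    "1-1": 6.5, "1-2": 4.2, "6-1": 2.5, "6-2": 4.8,
}


def generate_lengths(
    n_cells: int,
    base_lengths_um: Mapping[str, float] | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
    scale_sd: float = 0.25,
) -> pd.DataFrame:
    """Simulate a heteromorphic-chromosome length table (wide, one row per cell).

    Each cell scales every base length by a shared lognormal factor
    (sigma = ``scale_sd``) and adds independent Gaussian noise
    (``noise_sd`` micrometres); lengths are floored at 0.05 um.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    base = dict(base_lengths_um or DEFAULT_BASE_LENGTHS)
    missing = [c for c in ("1-1", "1-2", "6-1", "6-2") if c not in base]
    if missing:
        raise ParameterError(f"base lengths missing chromosomes {missing}")
    rng = np.random.default_rng(seed)
    scale = rng.lognormal(mean=0.0, sigma=scale_sd, size=n_cells) if scale_sd > 0 else np.ones(n_cells)
    data = {}
    for chrom in ("1-1", "1-2", "6-1", "6-2"):
        noise = rng.normal(0.0, noise_sd, size=n_cells) if noise_sd > 0 else 0.0
        data[chrom] = np.maximum(base[chrom] * scale + noise, 0.05)
    df = pd.DataFrame(data)
    df.index = pd.Index([str(i + 1) for i in range(n_cells)], name="cell_id")
    return df
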