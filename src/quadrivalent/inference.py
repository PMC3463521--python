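"""Frequency tables, gamete-pool maximum likelihood, and the arm-length conservation test.

The population-genetic model: adults release gametes into a common pool with
frequencies ``f1..f4`` for the four occurring classes {M,m}, {T,St}, {M,St},
{m,T}; zygotes form by random union, so pre-selection karyomorph
probabilities are

    I: f1^2          II: 2 f1 f3      III: 2 f1 f4
    IV: 2 f1 f2 + 2 f3 f4             V:  2 f2 f3
    VI: f3^2         VII: f4^2        VIII: 2 f2 f4      IX: f2^2

(type IV arises both from the two balanced gametes and from the two
adjacent-1 gametes, hence its two terms).  Viability filtering restricts and
renormalizes this distribution over the surviving types; observed karyomorph
counts are multinomial in the renormalized probabilities, and the gamete-pool
frequencies are estimated by maximizing that likelihood over the 3-simplex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .karyo_model import ROMAN_LABELS
from .segregation import ParameterError, ViabilityMap

VIABLE_LABELS = ("I", "II", "III", "IV", "V")
GAMETE_NAMES = ("M/m", "T/St", "M/St", "m/T")

#: heteromorphic-length-table chromosome identifiers: the two chromosome-1
#: homologs (1-1 normal M, 1-2 translocated T) and the two chromosome-6
#: homologs (6-1 normal m, 6-2 translocated St).
LENGTH_CHROMS = ("1-1", "1-2", "6-1", "6-2")


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


# --- frequency tables -----------------------------------------------------

def _round_half_up(x: Fraction, decimals: int = 1) -> float:
    q = Fraction(10) ** decimals
    return float(math.floor(x * q + Fraction(1, 2)) / q)


def frequency_table(counts: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Per-population and pooled karyomorph frequencies, in percent.

    ``counts`` has columns population_id, sex, karyomorph, count; sexes are
    pooled.  Frequencies are computed as exact rationals and rounded half-up
    to ``decimals`` for the report, matching the printed style of published
    frequency tables.  A zero-total population is flagged (``flagged``
    column) rather than raising.
    """
    if counts.empty or int(counts["count"].sum()) == 0:
        raise InsufficientDataError("need at least one nonzero karyomorph count")
    labels = sorted(
        counts["karyomorph"].unique(), key=lambda s: (s not in ROMAN_LABELS, ROMAN_LABELS.index(s) if s in ROMAN_LABELS else 0, s)
    )
    grouped = counts.groupby(["population_id", "karyomorph"], sort=False)["count"].sum()
    pops = list(dict.fromkeys(counts["population_id"]))
    rows = []
    pooled: dict[str, int] = {lab: 0 for lab in labels}
    for pop in pops:
        sub = grouped.loc[pop] if pop in grouped.index.get_level_values(0) else pd.Series(dtype=int)
        total = int(sub.sum())
        row: dict[str, object] = {"population_id": pop, "total": total, "flagged": total == 0}
        for lab in labels:
            c = int(sub.get(lab, 0))
            pooled[lab] += c
            row[lab] = (
                float("nan") if total == 0 else _round_half_up(Fraction(100 * c, total), decimals)
            )
        rows.append(row)
    grand = sum(pooled.values())
    pooled_row: dict[str, object] = {"population_id": "pooled", "total": grand, "flagged": False}
    for lab in labels:
        pooled_row[lab] = _round_half_up(Fraction(100 * pooled[lab], grand), decimals)
    rows.append(pooled_row)
    return pd.DataFrame(rows).set_index("population_id")


# --- gamete-pool likelihood -----------------------------------------------

@dataclass(frozen=True)
class GametePoolParams:
    """Pool frequencies of the gametes {M,m}, {T,St}, {M,St}, {m,T}."""

    f1: float
    f2: float
    f3: float
    f4: float

    def __post_init__(self) -> None:
        fs = self.as_tuple()
        if any(f < -1e-12 for f in fs):
            raise ParameterError(f"gamete frequencies must be >= 0, got {fs}")
        if abs(sum(fs) - 1.0) > 1e-6:
            raise ParameterError(f"gamete frequencies must sum to 1, got {sum(fs)}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.f1, self.f2, self.f3, self.f4)


def zygote_probabilities(f: Sequence[float]) -> dict[str, float]:
    """Pre-selection karyomorph probabilities under random gamete union."""
    f1, f2, f3, f4 = f
    return {
        "I": f1 * f1,
        "II": 2 * f1 * f3,
        "III": 2 * f1 * f4,
        "IV": 2 * f1 * f2 + 2 * f3 * f4,
        "V": 2 * f2 * f3,
        "VI": f3 * f3,
        "VII": f4 * f4,
        "VIII": 2 * f2 * f4,
        "IX": f2 * f2,
    }


def _viable_probs(f: np.ndarray, viability: ViabilityMap, labels: Sequence[str]) -> np.ndarray:
    zyg = zygote_probabilities(f)
    weighted = {lab: p * viability[lab] for lab, p in zyg.items()}
    mass = sum(weighted.values())
    if mass <= 0:
        return np.zeros(len(labels))
    return np.array([weighted.get(lab, 0.0) / mass for lab in labels])


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood gamete-pool estimate from karyomorph counts."""

    estimates: GametePoolParams
    log_likelihood: float
    expected_counts: dict[str, float]
    converged: bool
    boundary: bool
    n: int

    def summary(self) -> str:
        lines = [
            "gamete-pool ML fit (n = %d)" % self.n,
            "  " + "  ".join(
                f"{name} = {v:.4f}"
                for name, v in zip(GAMETE_NAMES, self.estimates.as_tuple())
            ),
            f"  log-likelihood = {self.log_likelihood:.4f}"
            + ("  [boundary]" if self.boundary else ""),
        ]
        return "\n".join(lines)


def fit_gamete_pool(
    observed: Mapping[str, int] | pd.Series,
    viability: ViabilityMap | None = None,
    n_starts: int = 16,
) -> FitResult:
    """Fit gamete-pool frequencies to observed karyomorph counts.

    The multinomial log-likelihood (frequency form, no combinatorial
    coefficient, hence always <= 0) is maximized over the 3-simplex with
    SLSQP from multiple deterministic starts.  Non-convergence is flagged,
    with the best point found still reported; an optimum on the simplex
    boundary sets ``boundary``.
    """
    viability = viability or ViabilityMap.default()
    obs = dict(observed)
    for lab in obs:
        if lab not in ROMAN_LABELS:
            raise ParameterError(f"unknown karyomorph label {lab!r} in observed counts")
        if obs[lab] < 0:
            raise ParameterError(f"negative count for {lab}")
    labels = [lab for lab in ROMAN_LABELS if viability[lab] > 0]
    extra = {lab for lab, c in obs.items() if c > 0 and lab not in labels}
    if extra:
        raise ParameterError(
            f"observed counts include karyomorphs with zero viability: {sorted(extra)}"
        )
    counts = np.array([float(obs.get(lab, 0)) for lab in labels])
    total = int(counts.sum())
    if total == 0:
        raise InsufficientDataError("all observed counts are zero")

    def nll(x: np.ndarray) -> float:
        f = np.append(x, 1.0 - x.sum())
        if np.any(f < 0):
            return 1e12
        p = _viable_probs(f, viability, labels)
        if np.any((p <= 0) & (counts > 0)):
            return 1e12
        with np.errstate(divide="ignore"):
            return float(-np.sum(counts * np.log(np.clip(p, 1e-300, None))))

    rng = np.random.default_rng(0)  # fixed: fitting is deterministic
    starts = [
        np.array([0.25, 0.25, 0.25]),
        np.array([0.94, 0.02, 0.02]),
        np.array([0.02, 0.94, 0.02]),
        np.array([0.02, 0.02, 0.94]),
        np.array([0.02, 0.02, 0.02]),
        np.array([0.7, 0.2, 0.05]),
    ]
    while len(starts) < n_starts:
        starts.append(rng.dirichlet(np.ones(4))[:3])

    best = None
    any_converged = False
    cons = ({"type": "ineq", "fun": lambda x: 1.0 - x.sum()},)
    for x0 in starts:
        res = optimize.minimize(
            nll,
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * 3,
            constraints=cons,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)

    x = np.clip(best.x, 0.0, 1.0)
    f = np.append(x, max(0.0, 1.0 - x.sum()))
    f = f / f.sum()
    p = _viable_probs(f, viability, labels)
    log_lik = float(np.sum(counts[counts > 0] * np.log(p[counts > 0])))
    return FitResult(
        estimates=GametePoolParams(*f),
        log_likelihood=log_lik,
        expected_counts={lab: total * pi for lab, pi in zip(labels, p)},
        converged=any_converged,
        boundary=bool(np.any(f < 1e-6)),
        n=total,
    )


# --- arm-length conservation ----------------------------------------------

@dataclass(frozen=True)
class ArmConservationResult:
    """Paired comparison of heteromorphic vs doubled-normal chromosome length."""

    mean_het_sum: float
    mean_norm_sum: float
    t_statistic: float
    p_value: float
    n_cells: int

    @property
    def conserved(self) -> bool:
        """No significant length change at the 5% level."""
        return self.p_value > 0.05


def arm_conservation_test(lengths: pd.DataFrame) -> ArmConservationResult:
    """Test whether the translocation conserves total chromosome length.

    ``lengths`` is a wide table (one row per cell) with micrometre columns
    ``1-1``, ``1-2``, ``6-1``, ``6-2``.  Per cell the four heteromorphic
    chromosomes are summed (S_het) and compared with twice the two normal
    homologs (S_norm = 2 x (1-1 + 6-1)) by a two-sided paired t-test: under
    a reciprocal exchange without loss the two sums estimate the same
    quantity, so p > 0.05 supports a balanced exchange.
    """
    missing = [c for c in LENGTH_CHROMS if c not in lengths.columns]
    if missing:
        raise ParameterError(f"length table lacks columns {missing}")
    if len(lengths) < 2:
        raise InsufficientDataError(
            f"paired t-test needs >= 2 cells, got {len(lengths)}"
        )
    if (lengths[list(LENGTH_CHROMS)] <= 0).any().any():
        raise ParameterError("chromosome lengths must be positive")
    s_het = lengths[list(LENGTH_CHROMS)].sum(axis=1)
    s_norm = 2.0 * (lengths["1-1"] + lengths["6-1"])
    if np.allclose(s_het, s_norm):
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_rel(s_het, s_norm)
    return ArmConservationResult(
        mean_het_sum=float(s_het.mean()),
        mean_norm_sum=float(s_norm.mean()),
        t_statistic=float(t_stat),
        p_value=float(p_val),
        n_cells=len(lengths),
    )
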