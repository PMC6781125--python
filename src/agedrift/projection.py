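"""Deterministic Leslie-matrix machinery and the genotype-expanded projection.

The scalar Leslie matrix has newborn recruitment ``m_x`` across the first
row (newborns are censused at birth, so a mother of age x contributes
``m_x`` daughters to next year's newborn class) and the survival
probabilities ``P_x`` on the subdiagonal. With this birth-pulse convention
the dominant eigenvalue is exactly 1 whenever the schedule is normalized
to ``R0 = Σ l_x m_x = 1``, and the stable age distribution is proportional
to survivorship ``l_x``.

The genotype-expanded system tracks female counts per age class for the
three genotypes AA, AB, BB at one biallelic locus. Each year the newborn
class is rebuilt in Hardy–Weinberg proportions (p², 2pq, q²) at the allele
frequency produced by random union of parental gametes, weighted by the
effective fecundities ``f_x = P_{x-1} m_x``; older classes advance with
(possibly genotype-specific) survival.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .life_tables import LifeTable
from .fecundity import FecunditySchedule

__all__ = [
    "GenotypeState",
    "build_leslie",
    "stable_age_distribution",
    "newborn_allele_freq",
    "project_genotypes",
]

GENOTYPES = ("AA", "AB", "BB")


@dataclass(frozen=True)
class GenotypeState:
    """Per-age-class, per-genotype female counts at one time step.

    ``counts`` has shape (3, k): rows AA, AB, BB; columns age classes 1..k.
    """

    t: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != 3:
            raise ValueError("counts must have shape (3, k)")
        if (c < 0).any():
            raise ValueError("genotype counts must be non-negative")

    @property
    def class_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def newborn_p(self) -> float:
        """Frequency of allele A among the newborn class."""
        nb = self.counts[:, 0]
        tot = nb.sum()
        if tot == 0:
            return np.nan
        return float((2 * nb[0] + nb[1]) / (2 * tot))

    @property
    def newborn_het(self) -> float:
        """Expected heterozygosity 2p(1-p) of the newborn class."""
        p = self.newborn_p
        return float(2 * p * (1 - p))


def build_leslie(lt: LifeTable, fs: FecunditySchedule) -> np.ndarray:
    """k×k Leslie matrix: recruitment m_x in the first row, P_x below it."""
    fs._check(lt)
    L = np.zeros((lt.k, lt.k))
    L[0, :] = fs.m
    if lt.k > 1:
        L[np.arange(1, lt.k), np.arange(lt.k - 1)] = lt.P
    return L


def stable_age_distribution(
    L: np.ndarray,
    N_total: float = 1000.0,
    iterations: int = 100,
    tol: float = 1e-12,
    max_iterations: int = 50_000,
) -> np.ndarray:
    """Stable per-class counts from repeated projection of a uniform start.

    At least ``iterations`` multiplications are applied; iteration then
    continues until the normalized vector is a fixed point to ``tol``
    (sup-norm), because schedules concentrated at late ages damp their
    transients slowly and a fixed cycle count would leave a visible
    remnant of the uniform start in the newborn class. The result is
    rescaled to sum to ``N_total``; for a normalized schedule it is the
    dominant eigenvector, proportional to survivorship.
    """
    k = L.shape[0]
    if N_total <= 0:
        raise ValueError("N_total must be positive")
    v = np.full(k, 1.0 / k)
    for i in range(max_iterations):
        w = L @ v
        s = w.sum()
        if s <= 0:
            raise ValueError("population collapsed to zero during projection")
        w = w / s
        if i >= iterations - 1 and np.abs(w - v).max() < tol:
            v = w
            break
        v = w
    else:
        raise ValueError("stable age distribution did not converge")
    return v * N_total


def newborn_allele_freq(
    state: GenotypeState, lt: LifeTable, fs: FecunditySchedule
) -> float:
    """Allele-A frequency among next year's newborns under random mating.

    p = (Σ f_x n_{x,AA} + ½ Σ f_x n_{x,AB}) / b, with b the
    fecundity-weighted parental total — Mendelian segregation of the
    gametes contributed by each breeding class.
    """
    f = fs.effective(lt)
    b = float(f @ state.class_totals)
    if b <= 0:
        raise ValueError("no births: effective fecundity-weighted parent count is zero")
    num = float(f @ state.counts[0] + 0.5 * (f @ state.counts[1]))
    return min(1.0, max(0.0, num / b))


def project_genotypes(
    state: GenotypeState,
    lt: LifeTable,
    fs: FecunditySchedule,
    survival: np.ndarray | None = None,
) -> GenotypeState:
    """One deterministic year of the genotype-expanded projection.

    Older classes advance with ``survival`` (shape (3, k-1), defaulting to
    the life table's P replicated across genotypes); the newborn class is
    rebuilt at Hardy–Weinberg proportions using the parental allele
    frequency. Summed over genotypes this reproduces the scalar Leslie
    projection exactly when survival is genotype-independent.
    """
    fs._check(lt)
    if survival is None:
        survival = np.tile(lt.P, (3, 1))
    survival = np.asarray(survival, dtype=float)
    if survival.shape != (3, lt.k - 1):
        raise ValueError("survival must have shape (3, k-1)")
    p = newborn_allele_freq(state, lt, fs)
    b = float(fs.m @ state.class_totals)
    q = 1.0 - p
    new = np.empty_like(state.counts)
    new[:, 0] = b * np.array([p * p, 2 * p * q, q * q])
    new[:, 1:] = state.counts[:, :-1] * survival
    return GenotypeState(t=state.t + 1, counts=new)
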