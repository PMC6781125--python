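"""Survivorship life tables on one-year age classes.

A :class:`LifeTable` stores survivorship ``l_x`` — the probability of
surviving from birth to the beginning of age class ``x`` — over ``k``
one-year classes. Classes are numbered 1..k with the newborn class as
class 1 carrying ``l = 1``; arrays are stored 0-based, so ``l[0]`` is the
newborn class. Per-class survival ``P[i] = l[i+1] / l[i]`` has length
``k - 1``; individuals surviving the last class die (no loop-back), which
keeps every projection finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "from_counts",
    "build_type2",
    "build_type3",
    "mortality_gap",
    "read_life_table",
    "write_life_table",
]

_L_TOL = 1e-9


@dataclass(frozen=True)
class LifeTable:
    """Survivorship schedule over integer one-year age classes.

    Parameters
    ----------
    l
        Survivorship to each class relative to newborns; non-increasing,
        ``l[0] == 1``.
    n
        Optional per-class female counts; if given, ``l == n / n[0]``.
    annotations
        Extra per-class columns carried through CSV round-trips.
    """

    l: np.ndarray
    n: np.ndarray | None = None
    annotations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        l = np.asarray(self.l, dtype=float)
        object.__setattr__(self, "l", l)
        if l.ndim != 1 or l.size < 1:
            raise ValueError("survivorship must be a non-empty 1-d array")
        if not np.isfinite(l).all() or (l < 0).any():
            raise ValueError("survivorship values must be finite and non-negative")
        if abs(l[0] - 1.0) > _L_TOL:
            raise ValueError(f"newborn-class survivorship must be 1, got {l[0]!r}")
        rises = np.nonzero(np.diff(l) > _L_TOL)[0]
        if rises.size:
            rows = ", ".join(str(i + 1) for i in rises[:5])
            raise ValueError(
                f"survivorship must be non-increasing; it rises after class {rows}"
            )
        if self.n is not None:
            n = np.asarray(self.n, dtype=float)
            object.__setattr__(self, "n", n)
            if n.shape != l.shape:
                raise ValueError("counts and survivorship lengths differ")
            if not np.allclose(l, n / n[0], atol=_L_TOL):
                raise ValueError("counts are inconsistent with survivorship (l != n/n0)")

    @property
    def k(self) -> int:
        """Number of age classes."""
        return self.l.size

    @property
    def ages(self) -> np.ndarray:
        """Class labels 1..k (years)."""
        return np.arange(1, self.k + 1)

    @property
    def P(self) -> np.ndarray:
        """Per-class survival probabilities, length ``k - 1``.

        ``P[i]`` is the probability of surviving from class ``i+1`` to
        class ``i+2``; zero wherever the source class is already empty.
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(self.l[:-1] > 0, self.l[1:] / self.l[:-1], 0.0)
        return np.clip(p, 0.0, 1.0)


def from_counts(counts) -> LifeTable:
    """Build a life table from per-age female cohort counts (``l_x = n_x/n_0``)."""
    n = np.asarray(counts, dtype=float)
    if n.size == 0:
        raise ValueError("empty count vector")
    if (n < 0).any():
        raise ValueError("counts must be non-negative")
    if n[0] <= 0:
        raise ValueError("newborn count must be positive")
    if (np.diff(n) > _L_TOL * n[0]).any():
        raise ValueError("counts increase with age; a closed cohort cannot grow")
    return LifeTable(l=n / n[0], n=n)


def build_type2(k: int, mortality: float = 0.1) -> LifeTable:
    """Constant-mortality (Type-II) survivorship: ``l_{x+1} = (1 - mortality) l_x``."""
    if not 0.0 < mortality < 1.0:
        raise ValueError("mortality must lie strictly between 0 and 1")
    if k < 2:
        raise ValueError("need at least two age classes")
    return LifeTable(l=(1.0 - mortality) ** np.arange(k))


def build_type3(k: int, exponent: float = 2.126) -> LifeTable:
    """Power-law (Type-III) survivorship ``l_x = x**-exponent``.

    The power law is undefined at age 0, so the curve is anchored with the
    newborn class at x = 1 (``l_1 = 1``).
    """
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    if k < 2:
        raise ValueError("need at least two age classes")
    x = np.arange(1, k + 1, dtype=float)
    return LifeTable(l=x ** (-exponent))


def mortality_gap(lt: LifeTable) -> np.ndarray:
    """Per-class death fractions ``d_x = l_x - l_{x+1}``, with ``l_{k+1} = 0``."""
    l_ext = np.append(lt.l, 0.0)
    return l_ext[:-1] - l_ext[1:]


def read_life_table(path) -> LifeTable:
    """Read a life-table CSV with an ``age`` column and ``l`` or ``n``.

    Unknown columns are preserved as annotations; ``m`` (fecundity) rides
    along the same way.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "age" not in cols:
        raise ValueError(f"{path}: missing required 'age' column")
    if "l" not in cols and "n" not in cols:
        raise ValueError(f"{path}: need a survivorship column 'l' or a count column 'n'")
    for c in df.columns:
        if not np.issubdtype(df[c].dtype, np.number):
            raise ValueError(f"{path}: column {c!r} contains non-numeric cells")
    df = df.sort_values(cols["age"]).reset_index(drop=True)
    extra = {
        name: df[orig].to_numpy(dtype=float)
        for name, orig in cols.items()
        if name not in ("age", "l", "n")
    }
    if "l" in cols:
        l = df[cols["l"]].to_numpy(dtype=float)
        rises = np.nonzero(np.diff(l) > _L_TOL)[0]
        if rises.size:
            bad = ", ".join(str(int(df[cols["age"]].iloc[i + 1])) for i in rises[:5])
            raise ValueError(f"{path}: survivorship increases at age(s) {bad}")
        n = df[cols["n"]].to_numpy(dtype=float) if "n" in cols else None
        return LifeTable(l=l, n=n, annotations=extra)
    lt = from_counts(df[cols["n"]].to_numpy(dtype=float))
    return LifeTable(l=lt.l, n=lt.n, annotations=extra)


def write_life_table(lt: LifeTable, path) -> None:
    """Write a life table as CSV (columns: age, l, optional n, annotations)."""
    data: dict[str, np.ndarray] = {"age": lt.ages, "l": lt.l}
    if lt.n is not None:
        data["n"] = lt.n
    data.update(lt.annotations)
    pd.DataFrame(data).to_csv(path, index=False)
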