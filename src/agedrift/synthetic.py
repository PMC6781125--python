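"""Synthetic life tables emulating the classic survivorship-curve families.

The generators produce the curve shapes the analysis contrasts, with no
external data: a modern Type-I (near-flat survival through the
reproductive span, Gompertz-like senescent decline after a late onset), a
pre-industrial Type-I (the same senescent pattern plus an
exponentially-decaying juvenile mortality spike), a Type-II (constant
yearly mortality, log-linear survivorship), and a Type-III power law.
Hazards are per-year death probabilities; parameters are deterministic by
default, with opt-in multiplicative jitter for robustness checks.
"""

from __future__ import annotations

import numpy as np

from . import life_tables
from .life_tables import LifeTable

__all__ = [
    "make_type1_modern",
    "make_type1_preindustrial",
    "make_fixture",
    "FAMILIES",
]


def _from_hazard(hazard: np.ndarray, jitter: float, seed) -> LifeTable:
    if jitter > 0:
        rng = np.random.default_rng(seed)
        hazard = hazard * rng.lognormal(0.0, jitter, hazard.size)
    q = np.clip(hazard, 0.0, 1.0)
    l = np.concatenate(([1.0], np.cumprod(1.0 - q[:-1])))
    return LifeTable(l=l)


def make_type1_modern(
    k: int = 101,
    background: float = 0.002,
    senescent_onset: float = 60.0,
    senescent_scale: float = 0.01,
    senescent_rate: float = 0.12,
    jitter: float = 0.0,
    seed=None,
) -> LifeTable:
    """Modern Type-I table: low flat hazard, steep Gompertz rise after onset.

    Defaults give survivorship above 0.9 through the childbearing years
    (age 27 mean) and near-zero survival by the last class — the
    industrial-era human pattern.
    """
    if senescent_onset >= k:
        raise ValueError("senescent onset must fall inside the age range")
    x = np.arange(1, k + 1, dtype=float)
    hazard = background + senescent_scale * np.exp(
        senescent_rate * (x - senescent_onset)
    ) * (x >= senescent_onset)
    lt = _from_hazard(hazard, jitter, seed)
    assert (np.diff(lt.l) <= 0).all()
    return lt


def make_type1_preindustrial(
    k: int = 101,
    juvenile_hazard: float = 0.22,
    juvenile_decay: float = 0.5,
    jitter: float = 0.0,
    seed=None,
    **modern_params,
) -> LifeTable:
    """Pre-industrial Type-I table: juvenile mortality spike, then plateau.

    Identical to :func:`make_type1_modern` apart from an added juvenile
    hazard ``juvenile_hazard · exp(-juvenile_decay · (x - 1))``; with the
    spike at zero it reduces to the modern family exactly. Emulates
    hunter-gatherer / pre-industrial survivorship: heavy early-childhood
    mortality followed by a long plateau and late decline.
    """
    base = make_type1_modern(k=k, jitter=0.0, **modern_params)
    x = np.arange(1, k + 1, dtype=float)
    base_hazard = np.append(1.0 - base.P, 1.0)
    hazard = base_hazard + juvenile_hazard * np.exp(-juvenile_decay * (x - 1.0))
    return _from_hazard(hazard, jitter, seed)


def _make_rectangular(k: int) -> LifeTable:
    return LifeTable(l=np.ones(k))


FAMILIES = (
    "type1_modern",
    "type1_preindustrial",
    "type2",
    "type3",
    "rectangular",
    "exponential",
)


def make_fixture(family: str, k: int = 101, **params) -> LifeTable:
    """Dispatch a named survivorship family.

    ``rectangular`` (everyone survives to the wall, closed-form e0 = k,
    H ≈ 0) and ``exponential`` (alias of the constant-mortality Type-II,
    closed-form e0 → 1/mortality, H → 1) exist for analytic tests.
    """
    if family == "type1_modern":
        return make_type1_modern(k=k, **params)
    if family == "type1_preindustrial":
        return make_type1_preindustrial(k=k, **params)
    if family in ("type2", "exponential"):
        return life_tables.build_type2(k=k, **({"mortality": 0.1} | params))
    if family == "type3":
        return life_tables.build_type3(k=k, **({"exponent": 2.126} | params))
    if family == "rectangular":
        return _make_rectangular(k)
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
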