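"""Age-specific fecundity schedules tied to a life table.

``m_x`` is the per-year rate at which a female of age class ``x`` produces
daughters. Schedules are normalized so the net reproductive rate
``R0 = Σ l_x m_x = 1``, which keeps the projected population stationary.
The effective fecundity under a birth-pulse model is ``f_x = P_{x-1} m_x``
(survive into class x, then breed there), with survival into the newborn
class taken as 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .life_tables import LifeTable

__all__ = ["FecunditySchedule", "gaussian_schedule", "normalize", "shift_schedule"]


@dataclass(frozen=True)
class FecunditySchedule:
    """Per-age daughter production rates.

    Parameters
    ----------
    m
        Birth rates per female per year, one entry per age class.
    shift
        Signed displacement (years) already applied to the schedule.
    mean, sd
        Parameters of the generating Gaussian, if the schedule was built
        from one; shifting re-evaluates the density instead of rolling
        the array.
    """

    m: np.ndarray
    shift: float = 0.0
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        object.__setattr__(self, "m", m)
        if m.ndim != 1 or m.size == 0:
            raise ValueError("m must be a non-empty 1-d array")
        if (m < 0).any() or not np.isfinite(m).all():
            raise ValueError("birth rates must be finite and non-negative")

    def effective(self, lt: LifeTable) -> np.ndarray:
        """Effective fecundities ``f_x = P_{x-1} m_x`` (birth-pulse)."""
        self._check(lt)
        P_into = np.concatenate(([1.0], lt.P))
        return P_into * self.m

    def _check(self, lt: LifeTable) -> None:
        if self.m.size != lt.k:
            raise ValueError(
                f"schedule length {self.m.size} does not match life table k={lt.k}"
            )


def gaussian_schedule(
    lt: LifeTable, mean: float = 27.0, sd: float = 7.0
) -> FecunditySchedule:
    """Gaussian-shaped fecundity over integer ages, normalized to R0 = 1.

    The default mimics a modern human schedule: births centred at age 27
    with spread 7 years, truncated to the table's age range.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    m = stats.norm.pdf(lt.ages.astype(float), loc=mean, scale=sd)
    return normalize(lt, FecunditySchedule(m=m, mean=mean, sd=sd))


def normalize(lt: LifeTable, fs: FecunditySchedule) -> FecunditySchedule:
    """Rescale ``m`` so that ``Σ l_x m_x = 1`` (stationary population)."""
    fs._check(lt)
    r0 = float(lt.l @ fs.m)
    if r0 <= 0:
        raise ValueError("schedule has no reproductive overlap with surviving ages")
    return replace(fs, m=fs.m / r0)


def shift_schedule(lt: LifeTable, fs: FecunditySchedule, delta: float) -> FecunditySchedule:
    """Displace the reproductive distribution by ``delta`` years.

    Gaussian-built schedules are re-evaluated at the shifted mean (a smooth
    translation of the underlying curve); tabulated schedules are rolled by
    whole years. Mass falling outside classes 1..k is truncated and the
    result re-normalized, so the generation time moves monotonically with
    ``delta`` but not necessarily by exactly ``delta`` near the boundaries.
    """
    fs._check(lt)
    if abs(delta) >= lt.k:
        raise ValueError("shift exceeds the age range")
    if delta == 0:
        return fs
    if fs.mean is not None and fs.sd is not None:
        m = stats.norm.pdf(lt.ages.astype(float), loc=fs.mean + delta, scale=fs.sd)
        out = FecunditySchedule(
            m=m, shift=fs.shift + delta, mean=fs.mean + delta, sd=fs.sd
        )
    else:
        step = int(round(delta))
        m = np.zeros_like(fs.m)
        if step > 0:
            m[step:] = fs.m[: fs.m.size - step]
        else:
            m[:step] = fs.m[-step:]
        out = FecunditySchedule(m=m, shift=fs.shift + step)
    if float(lt.l @ out.m) <= 0:
        raise ValueError("shift leaves no reproductive mass inside the age range")
    return normalize(lt, out)
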