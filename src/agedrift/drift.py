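"""Stochastic simulation of genetic drift on an age-structured population.

Two sources of allele-frequency noise act each year. First, the fixed
number of newborns ``Nnb`` (the newborn class of the stable age
distribution) is drawn from a multinomial over the Hardy–Weinberg genotype
probabilities (p², 2pq, q²) at the parental allele frequency — random
union of gametes. Second, survivors of each age-class transition are a
random subsample of the class: either independent binomial thinning per
genotype (default) or a "faithful" two-part cull in which a deterministic
``P_x`` fraction keeps its genotypes and the remainder is redrawn
multinomially from the class's current genotype frequencies.

Viability selection against the recessive homozygote reduces BB survival
by a factor (1 - s) on transitions out of reproductive-age classes.

Census structure is held stationary: class totals start at the stable age
distribution and the newborn count never changes, so drift acts on allele
frequencies rather than on population size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .life_tables import LifeTable
from .fecundity import FecunditySchedule, shift_schedule
from .projection import build_leslie, stable_age_distribution

__all__ = [
    "SimulationConfig",
    "TrajectoryResult",
    "resample_newborns",
    "cull_age_class",
    "apply_selection",
    "heterozygosity",
    "run_simulation",
    "summarize",
    "fit_retention",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of one drift experiment.

    ``p0`` is the initial frequency of the B allele (the one selection
    acts against when ``s > 0``); ``shift`` displaces the fecundity
    schedule in years before anything else happens.
    """

    N_total: int = 1000
    years: int = 1000
    replicates: int = 1000
    p0: float = 0.5
    s: float = 0.0
    shift: float = 0.0
    seed: int | None = None
    het_mode: str = "expected"
    cull_mode: str = "binomial"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("s must lie in [0, 1]")
        if self.years < 1 or self.replicates < 1:
            raise ValueError("years and replicates must be at least 1")
        if self.het_mode not in ("expected", "observed"):
            raise ValueError("het_mode must be 'expected' or 'observed'")
        if self.cull_mode not in ("binomial", "faithful"):
            raise ValueError("cull_mode must be 'binomial' or 'faithful'")


@dataclass
class TrajectoryResult:
    """Replicate heterozygosity trajectories and their summaries."""

    het: np.ndarray                     # (replicates, years)
    final_p: np.ndarray                 # realized B-allele frequency among the last newborns
    fixation_times: np.ndarray          # year of loss of variation, NaN if never
    config: SimulationConfig
    Nnb: int
    T: float
    rng_algorithm: str = "PCG64"
    meta: dict = field(default_factory=dict)

    @property
    def mean_het(self) -> np.ndarray:
        return self.het.mean(axis=0)

    @property
    def final(self) -> np.ndarray:
        return self.het[:, -1]

    def final_summary(self) -> dict:
        """Final-time distribution summary (boxplot-style, with notch)."""
        f = self.final
        q1, med, q3 = np.percentile(f, [25, 50, 75])
        iqr = q3 - q1
        return {
            "mean": float(f.mean()),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "iqr": float(iqr),
            "notch": float(1.58 * iqr / np.sqrt(f.size)),
        }


def resample_newborns(p: float, Nnb: int, rng: np.random.Generator) -> np.ndarray:
    """One multinomial draw of Nnb newborn genotypes at HW proportions."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    q = 1.0 - p
    return rng.multinomial(Nnb, (p * p, 2 * p * q, q * q))


def cull_age_class(
    counts: np.ndarray,
    P_x,
    rng: np.random.Generator,
    cull_mode: str = "binomial",
) -> np.ndarray:
    """Survivors of one age-class transition for one class's genotype counts.

    ``P_x`` may be a scalar or per-genotype length-3 vector (selection).
    """
    counts = np.asarray(counts)
    P = np.broadcast_to(np.asarray(P_x, dtype=float), (3,))
    if (P < 0).any() or (P > 1).any():
        raise ValueError("survival probabilities must lie in [0, 1]")
    if cull_mode == "binomial":
        return rng.binomial(counts.astype(np.int64), P)
    if cull_mode != "faithful":
        raise ValueError(f"unknown cull mode {cull_mode!r}")
    total = counts.sum()
    if total == 0:
        return np.zeros(3, dtype=np.int64)
    expected = P * counts
    new_total = int(round(expected.sum()))
    kept = np.floor(expected).astype(np.int64)
    remainder = new_total - int(kept.sum())
    if remainder > 0:
        kept += rng.multinomial(remainder, counts / total)
    return kept


def apply_selection(
    P: np.ndarray, s: float, reproductive_mask: np.ndarray
) -> np.ndarray:
    """Genotype-specific survival matrix (3, k-1) with BB reduced by (1-s).

    The reduction applies only to transitions out of reproductive-age
    classes (``reproductive_mask`` over source classes 1..k-1); AA and AB
    are untouched.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must lie in [0, 1]")
    out = np.tile(np.asarray(P, dtype=float), (3, 1))
    mask = np.asarray(reproductive_mask, dtype=bool)[: out.shape[1]]
    out[2, mask] *= 1.0 - s
    if (out < 0).any() or (out > 1).any():
        raise ValueError("selection pushed a survival probability outside [0, 1]")
    return out


def heterozygosity(newborn_counts: np.ndarray, het_mode: str = "expected") -> float:
    """Heterozygosity of the newborn class.

    ``expected``: 2p(1-p) at the realized newborn allele frequency;
    ``observed``: the heterozygote (AB) fraction.
    """
    nb = np.asarray(newborn_counts, dtype=float)
    tot = nb.sum()
    if tot == 0:
        return 0.0
    if het_mode == "expected":
        p = (2 * nb[0] + nb[1]) / (2 * tot)
        return float(2 * p * (1 - p))
    if het_mode == "observed":
        return float(nb[1] / tot)
    raise ValueError(f"unknown het mode {het_mode!r}")


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder integer apportionment of `total` over `weights`."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("cannot apportion over zero weights")
    quota = w / w.sum() * total
    base = np.floor(quota).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(quota - base))
        base[order[:short]] += 1
    return base


def _initial_counts(
    stable: np.ndarray, N_total: int, p: float
) -> tuple[np.ndarray, int]:
    """Integer (3, k) genotype counts at HW(p) on the stable distribution."""
    Nnb = int(round(stable[0]))
    if Nnb < 1:
        raise ValueError("stable newborn class rounds to zero individuals")
    class_n = np.empty(stable.size, dtype=np.int64)
    class_n[0] = Nnb
    if stable.size > 1:
        class_n[1:] = _apportion(stable[1:], N_total - Nnb)
    q = 1.0 - p
    hw = np.array([p * p, 2 * p * q, q * q])
    counts = np.empty((3, stable.size), dtype=np.int64)
    for x in range(stable.size):
        counts[:, x] = _apportion(hw, int(class_n[x])) if class_n[x] else 0
    return counts, Nnb


def run_simulation(
    lt: LifeTable, fs: FecunditySchedule, config: SimulationConfig
) -> TrajectoryResult:
    """Replicated yearly drift simulation; see module docstring for the cycle.

    Each year: parental allele frequency among prospective newborns →
    multinomial draw of the fixed newborn class → stochastic cull of every
    older transition (with selection if configured) → record newborn
    heterozygosity. Replicates use independent RNG streams spawned from
    the root seed. Once a replicate loses all variation it is absorbed and
    records zero heterozygosity thereafter.
    """
    if config.shift != 0.0:
        fs = shift_schedule(lt, fs, config.shift)
    L = build_leslie(lt, fs)
    stable = stable_age_distribution(L, N_total=config.N_total, iterations=100)
    from .demography import net_reproduction

    _, T, _ = net_reproduction(lt, fs)
    p_init = 1.0 - config.p0  # track allele A; p0 is the B-allele frequency
    init_counts, Nnb = _initial_counts(stable, config.N_total, p_init)
    f_eff = fs.effective(lt)
    if fs.m.max() <= 0:
        raise ValueError("all-zero fecundity schedule")
    repro_mask = fs.m > 1e-3 * fs.m.max()
    P_sel = apply_selection(lt.P, config.s, repro_mask) if lt.k > 1 else None

    het = np.zeros((config.replicates, config.years))
    final_p = np.empty(config.replicates)
    fix_time = np.full(config.replicates, np.nan)
    streams = np.random.SeedSequence(config.seed).spawn(config.replicates)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        n = init_counts.copy()
        for t in range(config.years):
            den = float(f_eff @ n.sum(axis=0))
            # clamp: roundoff in the two dot products can leave p just outside [0, 1]
            p = min(1.0, max(0.0, float(f_eff @ n[0] + 0.5 * (f_eff @ n[1])) / den))
            newborns = resample_newborns(p, Nnb, rng)
            if lt.k > 1:
                if config.cull_mode == "binomial":
                    surv = rng.binomial(n[:, :-1], P_sel)
                else:
                    surv = np.column_stack(
                        [
                            cull_age_class(n[:, x], P_sel[:, x], rng, "faithful")
                            for x in range(lt.k - 1)
                        ]
                    )
                n = np.concatenate([newborns[:, None], surv], axis=1)
            else:
                n = newborns[:, None]
            het[r, t] = heterozygosity(newborns, config.het_mode)
            final_p[r] = (2 * newborns[2] + newborns[1]) / (2 * Nnb)
            a_copies = 2 * n[0].sum() + n[1].sum()
            if a_copies == 0 or a_copies == 2 * n.sum():
                fix_time[r] = t + 1
                break  # absorbed: remaining years stay at zero heterozygosity
    return TrajectoryResult(
        het=het,
        final_p=final_p,
        fixation_times=fix_time,
        config=config,
        Nnb=Nnb,
        T=T,
        meta={"stable_newborn": float(stable[0]), "config": asdict(config)},
    )


def fit_retention(mean_het: np.ndarray) -> tuple[float, float]:
    """Per-step heterozygosity retention rate and the implied effective size.

    Fits the geometric decay H_{t+1} = H_t (1 - 1/2Ne) by least squares on
    log H_t; returns (retention rate, implied Ne). Requires at least two
    positive points and a genuinely declining series.
    """
    h = np.asarray(mean_het, dtype=float)
    t = np.arange(h.size)
    pos = h > 0
    if pos.sum() < 2:
        raise ValueError("need at least two positive heterozygosity values")
    slope, _, _, _, _ = sps.linregress(t[pos], np.log(h[pos]))
    rho = float(np.exp(slope))
    ne = np.inf if rho >= 1.0 else 1.0 / (2.0 * (1.0 - rho))
    return rho, ne


def summarize(results: dict[str, TrajectoryResult]) -> pd.DataFrame:
    """Comparison table across named runs.

    One row per run: final-time boxplot statistics, the fitted per-year
    heterozygosity retention rate, and the effective size implied by
    H_{t+1} = H_t(1 - 1/2Ne).
    """
    rows = []
    for name, res in results.items():
        row = {"run": name, "Nnb": res.Nnb, "T": res.T}
        row.update(res.final_summary())
        try:
            rho, ne = fit_retention(res.mean_het)
        except ValueError:
            rho, ne = np.nan, np.nan
        row["retention"] = rho
        row["implied_Ne"] = ne
        rows.append(row)
    return pd.DataFrame(rows)
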