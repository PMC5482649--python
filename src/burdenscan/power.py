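"""Simulation-based discovery power for single variants and gene burdens.

A variant (or gene) is parameterised by its population frequency and the
per-allele (per-carrier) relative risk RR. Under a rare-disease model the
case frequency follows from the control frequency p0 as

    p1 = RR * p0 / (1 - p0 + RR * p0)

Each replicate draws case and control allele (or carrier) counts binomially
and applies the same test used in the analysis proper: the two-sided Fisher
exact test for single variants, the exact one-sided mid-P burden test for
genes. Power is the fraction of replicates reaching the supplied significance
threshold; 10,000 replicates is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerPoint",
    "risk_allele_frequency",
    "single_variant_power",
    "burden_power",
    "power_grid",
]


@dataclass(frozen=True)
class PowerPoint:
    """One evaluated (frequency, RR) power cell."""

    frequency: float
    rr: float
    n_case: int
    n_control: int
    alpha: float
    B: int
    power: float
    mc_se: float
    kind: str  # "single_variant" | "burden"


def risk_allele_frequency(p0: float, rr: float) -> float:
    """Case frequency implied by control frequency p0 and relative risk RR.

    Kept as a separate function so an alternative mapping (e.g. odds-ratio
    based) can be substituted in one place.
    """
    if not 0 < p0 < 1:
        raise ValueError("control frequency must lie in (0, 1)")
    if rr < 0:
        raise ValueError("relative risk must be non-negative")
    p1 = rr * p0 / (1 - p0 + rr * p0)
    if p1 >= 1:
        raise ValueError("relative risk too large for this frequency")
    return p1


@lru_cache(maxsize=100_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    from .single_variant import fisher_two_sided

    return fisher_two_sided(a, b, c, d)[0]


def single_variant_power(
    maf: float,
    rr: float,
    n_case: int,
    n_control: int,
    alpha: float,
    B: int = 10_000,
    seed: int = 0,
) -> PowerPoint:
    """Power of the two-sided Fisher allele test at a (MAF, RR) point.

    Per replicate, case and control minor-allele counts are drawn binomially
    at frequencies p1 and p0 = ``maf`` over 2*n alleles each; power is the
    fraction of replicates with Fisher P <= ``alpha``.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("MAF must lie in (0, 0.5]")
    p1 = risk_allele_frequency(maf, rr)
    rng = np.random.default_rng(seed)
    na, nu = 2 * n_case, 2 * n_control
    a = rng.binomial(na, p1, size=B)
    c = rng.binomial(nu, maf, size=B)
    pairs, counts = np.unique(np.stack([a, c], axis=1), axis=0, return_counts=True)
    hits = 0
    for (ai, ci), k in zip(pairs, counts):
        if _fisher_p(int(ai), na - int(ai), int(ci), nu - int(ci)) <= alpha:
            hits += int(k)
    power = hits / B
    return PowerPoint(
        frequency=maf, rr=rr, n_case=n_case, n_control=n_control,
        alpha=alpha, B=B, power=power,
        mc_se=math.sqrt(max(power * (1 - power), 0.0) / B),
        kind="single_variant",
    )


def burden_power(
    carrier_freq: float,
    rr: float,
    n_case: int,
    n_control: int,
    alpha: float,
    B: int = 10_000,
    seed: int = 0,
) -> PowerPoint:
    """Power of the exact mid-P burden test at a (carrier fraction, RR) point.

    Per replicate, carrier-sample counts are drawn binomially — controls at
    c0 = ``carrier_freq``, cases at the RR-mapped c1 — every carrier holding
    one qualifying allele, and the exact one-sided mid-P is computed from the
    hypergeometric permutation null.
    """
    if not 0 < carrier_freq < 1:
        raise ValueError("carrier frequency must lie in (0, 1)")
    c1 = risk_allele_frequency(carrier_freq, rr)
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n_case, c1, size=B)
    x0 = rng.binomial(n_control, carrier_freq, size=B)
    K = x1 + x0
    N = n_case + n_control
    # weight-1 null: carriers in cases ~ Hypergeom(N, K, n_case)
    p = stats.hypergeom.sf(x1, N, K, n_case) + 0.5 * stats.hypergeom.pmf(
        x1, N, K, n_case
    )
    power = float(np.mean(p <= alpha))
    return PowerPoint(
        frequency=carrier_freq, rr=rr, n_case=n_case, n_control=n_control,
        alpha=alpha, B=B, power=power,
        mc_se=math.sqrt(max(power * (1 - power), 0.0) / B),
        kind="burden",
    )


def power_grid(
    freq_list: list[float],
    rr_list: list[float],
    n_case: int,
    n_control: int,
    alpha: float,
    B: int = 10_000,
    seed: int = 0,
    kind: str = "single_variant",
) -> pd.DataFrame:
    """Evaluate power over the Cartesian (frequency, RR) grid.

    Each cell gets a distinct child seed derived from ``seed`` so the grid is
    reproducible as a whole.
    """
    if not freq_list or not rr_list:
        raise ValueError("frequency and RR grids must be non-empty")
    fn = single_variant_power if kind == "single_variant" else burden_power
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(freq_list) * len(rr_list))
    i = 0
    for f in freq_list:
        for rr in rr_list:
            cell_seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            pt = fn(f, rr, n_case, n_control, alpha, B, cell_seed)
            rows.append(pt.__dict__)
    return pd.DataFrame(rows)
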