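"""Power analysis and effect-size arithmetic for the trial design.

The fixed-effects F-test power convention used throughout: for an ANCOVA (or
any fixed-effects contrast) with numerator df ``u``, denominator df
``v = N - k - c`` and Cohen's effect size f², the test statistic under the
alternative follows a noncentral F distribution with noncentrality
``lambda = f^2 * N_total``.  This matches the G*Power "F tests, fixed effects"
family; Cohen's-tables and chi-square-limit conventions differ in the third
decimal and are not used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from scipy import optimize, stats

from ._errors import InputError

__all__ = [
    "PowerSpec",
    "EffectSizeInput",
    "pooled_sd",
    "cohens_d",
    "se_to_sd",
    "ncf_power",
    "required_n_per_group",
    "sensitivity_f2",
    "f2_to_f_to_d",
]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of an a priori power computation for a fixed-effects F test."""

    f: float
    groups: int = 3
    covariates: int = 1
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if self.f < 0:
            raise InputError("effect size f must be nonnegative")
        if not (0 < self.alpha < 1):
            raise InputError("alpha must lie in (0, 1)")
        if not (self.alpha < self.target_power < 1):
            raise InputError("target power must lie in (alpha, 1)")
        if self.groups < 2 or self.covariates < 0:
            raise InputError("need k >= 2 groups and c >= 0 covariates")

    @property
    def f2(self) -> float:
        return self.f**2

    @property
    def u(self) -> int:
        return self.groups - 1


@dataclass(frozen=True)
class EffectSizeInput:
    """Mean difference plus per-group baseline SDs and sizes for Cohen's d."""

    mean_difference: float
    sd_a: float
    n_a: int
    sd_b: float
    n_b: int

    def __post_init__(self) -> None:
        if self.sd_a <= 0 or self.sd_b <= 0:
            raise InputError("standard deviations must be positive")
        if self.n_a < 2 or self.n_b < 2:
            raise InputError("group sizes must be at least 2")

    def d(self) -> float:
        return cohens_d(
            self.mean_difference,
            pooled_sd(self.sd_a, self.n_a, self.sd_b, self.n_b),
        )


def pooled_sd(sd_a: float, n_a: int, sd_b: float, n_b: int) -> float:
    """Bias-weighted pooled SD: sqrt(((n_a-1)sd_a² + (n_b-1)sd_b²)/(n_a+n_b-2))."""
    if n_a <= 1 or n_b <= 1:
        raise InputError("each group needs n >= 2 for a pooled SD")
    if sd_a <= 0 or sd_b <= 0:
        raise InputError("standard deviations must be positive")
    return math.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))


def cohens_d(mean_difference: float, pooled: float) -> float:
    """Standardized mean difference d = Δ / pooled SD."""
    if pooled <= 0:
        raise InputError("pooled SD must be positive")
    return mean_difference / pooled


def se_to_sd(se: float, n: int) -> float:
    """Recover a group SD from a reported standard error: sd = se·sqrt(n)."""
    if se <= 0 or n < 1:
        raise InputError("need se > 0 and n >= 1")
    return se * math.sqrt(n)


def _check_df_alpha(u: float, v: float, alpha: float) -> None:
    if u < 1 or v < 1:
        raise InputError("degrees of freedom must be at least 1")
    if not (0 < alpha < 1):
        raise InputError("alpha must lie in (0, 1)")


def ncf_power(f2: float, u: int, v: int, N_total: int, alpha: float = 0.05) -> float:
    """Power of the fixed-effects F test at effect size f².

    P(F'(u, v, λ) > F_crit(1-α; u, v)) with λ = f²·N_total, via the
    noncentral-F survival function.
    """
    _check_df_alpha(u, v, alpha)
    if f2 < 0:
        raise InputError("f2 must be nonnegative")
    lam = f2 * N_total
    fcrit = stats.f.isf(alpha, u, v)
    if lam == 0:
        return alpha
    return float(stats.ncf.sf(fcrit, u, v, lam))


def required_n_per_group(
    f: float,
    k: int = 3,
    c: int = 1,
    alpha: float = 0.05,
    target_power: float = 0.80,
    max_total: int = 100_000,
) -> tuple[int, int]:
    """Smallest total N (and per-group n, rounded up) reaching target power.

    Denominator df is v = N - k - c; noncentrality λ = f²·N.
    """
    spec = PowerSpec(f, k, c, alpha, target_power)  # validates
    if f == 0:
        raise InputError("power never exceeds alpha at f = 0")
    u = spec.u
    for N in range(k + c + 2, max_total + 1):
        if ncf_power(spec.f2, u, N - k - c, N, alpha) >= target_power:
            return N, math.ceil(N / k)
    raise InputError(f"target power unreachable below N = {max_total}")


def sensitivity_f2(
    u: int, v: int, alpha: float = 0.05, target_power: float = 0.80
) -> float:
    """Smallest detectable f² at given dfs (post hoc sensitivity analysis).

    Solves ncf_power(f2, u, v, u+v+1, alpha) = target_power by bisection to
    1e-6 in f².
    """
    _check_df_alpha(u, v, alpha)
    if not (alpha < target_power < 1):
        raise InputError("target power must lie in (alpha, 1)")
    N = u + v + 1
    g = lambda f2: ncf_power(f2, u, v, N, alpha) - target_power
    hi = 1e-3
    while g(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise InputError("sensitivity search failed to bracket the root")
    return float(optimize.brentq(g, 0.0, hi, xtol=1e-6))


def f2_to_f_to_d(f2: float) -> tuple[float, float]:
    """Convert f² to Cohen's f and to d under the two-group contrast d = 2f."""
    if f2 < 0:
        raise InputError("f2 must be nonnegative")
    f = math.sqrt(f2)
    return f, 2.0 * f
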