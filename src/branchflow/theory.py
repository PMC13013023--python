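"""Scaling theory for power loss in asymmetric branching networks.

Signals in dendrites and glial processes attenuate passively; modelling
each branch segment as a cylindrical ohmic wire, the resistance of a
level-k segment is R_k = rho * l_k / (pi * r_k^2). With all physical
constants absorbed (rho/pi == 1), R = l / r^2 in relative units.

For a hierarchy whose level-j junctions have mean/half-difference radius
scale factors (beta_mean_j, |beta_diff_j|) and length scale factors
(gamma_mean_j, |gamma_diff_j|), the dissipated power of unit current
injected at the tips is the recursion

    P = R_N,TOT * sum_{k=0}^{N} prod_{j=k}^{N-1} B_j,

    B_j = (beta_mean_j + |beta_diff_j|)^2 / (gamma_mean_j + |gamma_diff_j|)
        + (beta_mean_j - |beta_diff_j|)^2 / (gamma_mean_j - |gamma_diff_j|)

where the empty product (k = N) is 1 and R_N,TOT is the total terminal
resistance. Each bracket term is a daughter's conductance ratio
beta_i^2 / gamma_i relative to its parent: beta1 (the +|..| pair) is the
longer-and-possibly-wider daughter, beta2/gamma2 the shorter one. The
default pairs the second term with gamma_mean - |gamma_diff|; set
``second_denominator="plus"`` to evaluate the variant that reuses
gamma_mean + |gamma_diff| in both terms.

This module evaluates the recursion as written; it makes no claim that the
sum equals a series-parallel reduction of any particular explicit tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScaleSchedule",
    "beta_pair",
    "branch_resistance",
    "power_loss",
    "level_brackets",
]


def beta_pair(beta_mean: float, beta_diff: float) -> tuple[float, float]:
    """Recover (beta1, beta2) from the mean/half-difference parametrization.

    beta1 = beta_mean + |beta_diff|, beta2 = beta_mean - |beta_diff|; the
    absolute value makes the construction insensitive to the sign
    convention of the stored half-difference.

    Raises
    ------
    ValueError
        If beta_mean <= |beta_diff| (beta2 would be non-positive).
    """
    d = abs(beta_diff)
    if beta_mean <= d:
        raise ValueError(
            f"beta_mean ({beta_mean}) must exceed |beta_diff| ({d}); "
            "the smaller ratio would be non-positive"
        )
    return beta_mean + d, beta_mean - d


def branch_resistance(path_length: float, mean_radius: float) -> float:
    """Ohmic resistance l / r^2 of a cylindrical segment (units of rho/pi)."""
    if mean_radius <= 0:
        raise ValueError(f"mean_radius must be positive, got {mean_radius}")
    return path_length / mean_radius**2


@dataclass
class ScaleSchedule:
    """Per-level scale factors for the power-loss recursion.

    ``levels`` holds one row (beta_mean, beta_diff_abs, gamma_mean,
    gamma_diff_abs) per junction level j = 0..N-1; ``terminal_resistance``
    is R_N,TOT, the lumped resistance of the terminal (level-N) segments.
    Half-differences are stored as magnitudes; negative inputs are
    absolute-valued on validation.
    """

    levels: list[tuple[float, float, float, float]]
    terminal_resistance: float = 1.0

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def validated(self) -> "ScaleSchedule":
        if self.terminal_resistance <= 0:
            raise ValueError(
                f"terminal_resistance must be positive, got {self.terminal_resistance}"
            )
        levels = []
        for j, (bm, bd, gm, gd) in enumerate(self.levels):
            bd, gd = abs(bd), abs(gd)
            if bm - bd <= 0:
                raise ValueError(f"level {j}: beta_mean - |beta_diff| = {bm - bd} <= 0")
            if gm - gd <= 0:
                raise ValueError(f"level {j}: gamma_mean - |gamma_diff| = {gm - gd} <= 0")
            levels.append((bm, bd, gm, gd))
        return ScaleSchedule(levels=levels, terminal_resistance=self.terminal_resistance)

    @classmethod
    def uniform(
        cls,
        n_levels: int,
        beta_mean: float,
        beta_diff: float = 0.0,
        gamma_mean: float = 1.0,
        gamma_diff: float = 0.0,
        terminal_resistance: float = 1.0,
    ) -> "ScaleSchedule":
        """Schedule with identical scale factors at every level."""
        return cls(
            levels=[(beta_mean, beta_diff, gamma_mean, gamma_diff)] * n_levels,
            terminal_resistance=terminal_resistance,
        )


def level_brackets(schedule: ScaleSchedule, second_denominator: str = "minus") -> np.ndarray:
    """Per-level bracket values B_j of the power-loss recursion."""
    if second_denominator not in ("minus", "plus"):
        raise ValueError("second_denominator must be 'minus' or 'plus'")
    sched = schedule.validated()
    out = np.empty(sched.n_levels)
    for j, (bm, bd, gm, gd) in enumerate(sched.levels):
        den2 = gm - gd if second_denominator == "minus" else gm + gd
        out[j] = (bm + bd) ** 2 / (gm + gd) + (bm - bd) ** 2 / den2
    return out


def power_loss(schedule: ScaleSchedule, second_denominator: str = "minus") -> float:
    """Evaluate the power-loss recursion for a schedule of N levels.

    Returns R_N,TOT * sum_{k=0}^{N} prod_{j=k}^{N-1} B_j (empty product
    = 1), in units of I0^2 * resistance. Linear in terminal_resistance;
    N = 0 returns the terminal resistance itself.
    """
    sched = schedule.validated()
    brackets = level_brackets(sched, second_denominator)
    total = 1.0  # the k = N term
    prod = 1.0
    for j in range(sched.n_levels - 1, -1, -1):
        prod *= brackets[j]
        total += prod
    return sched.terminal_resistance * total
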