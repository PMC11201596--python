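"""Effect-size calibration for planted cohorts.

Links the generator's knobs to the prediction performance CPM can attain,
so a cohort can be calibrated to a target cross-validated r before it is
simulated.

With i.i.d. frames, the sample correlation of an edge whose population
value is rho has sampling SD approximately ``sd = (1 - rho^2)/sqrt(F - 1)``
over F frames. A planted edge's observed value across subjects is

    e_i = base + sign * effect * severity_i + noise_i,

so its correlation with severity is ``effect / sqrt(effect^2 + sd^2)`` —
that is what edge selection has to detect.

The strength predictor of one polarity sums the m planted edges of that
sign plus, at selection threshold alpha, about ``k = alpha/2 * E_null``
false-positive null edges, each contributing pure frame noise. Its
correlation with severity is therefore

    c = m * effect / sqrt(m^2 * effect^2 + (m + k) * sd^2),

and the population ceiling on the combined two-predictor prediction r is
``R = sqrt(c_pos^2 + c_neg^2)`` (the two strengths share only the severity
signal). Inverting R for the effect size calibrates a cohort; a Monte-Carlo
check of these closed forms lives in the test suite.
"""

from __future__ import annotations

import math

from .errors import ParameterError

__all__ = [
    "edge_sampling_sd",
    "expected_edge_severity_r",
    "expected_network_corr",
    "expected_prediction_r",
    "effect_for_prediction_r",
    "effect_for_edge_severity_r",
]


def edge_sampling_sd(base: float, frames: int) -> float:
    """Approximate SD of a sample correlation around rho=base over F frames."""
    if frames < 4:
        raise ParameterError("need at least 4 frames")
    return (1.0 - base**2) / math.sqrt(frames - 1)


def expected_edge_severity_r(effect: float, base: float, frames: int) -> float:
    """Population correlation between one planted edge's sample r and severity."""
    sd = edge_sampling_sd(base, frames)
    return effect / math.sqrt(effect**2 + sd**2)


def _null_edges_per_polarity(n_nodes: int | None, n_planted: int, p_threshold: float) -> float:
    if n_nodes is None:
        return 0.0
    n_edges = n_nodes * (n_nodes - 1) // 2
    return 0.5 * p_threshold * max(n_edges - n_planted, 0)


def expected_network_corr(
    effect: float, base: float, frames: int, m_planted: int, k_null: float
) -> float:
    """Correlation of one polarity's strength sum with severity."""
    if m_planted < 0 or k_null < 0:
        raise ParameterError("edge counts must be non-negative")
    if m_planted == 0:
        return 0.0
    sd = edge_sampling_sd(base, frames)
    num = m_planted * effect
    return num / math.sqrt(num**2 + (m_planted + k_null) * sd**2)


def expected_prediction_r(
    effect: float,
    base: float,
    frames: int,
    m_pos: int,
    m_neg: int,
    n_nodes: int | None = None,
    p_threshold: float = 0.01,
) -> float:
    """Population ceiling on combined-network CPM prediction r.

    ``n_nodes=None`` ignores false-positive dilution (an idealized
    selection that keeps exactly the planted edges).
    """
    if m_pos + m_neg < 1:
        raise ParameterError("need at least one planted edge")
    k = _null_edges_per_polarity(n_nodes, m_pos + m_neg, p_threshold)
    c_pos = expected_network_corr(effect, base, frames, m_pos, k)
    c_neg = expected_network_corr(effect, base, frames, m_neg, k)
    return min(1.0, math.sqrt(c_pos**2 + c_neg**2))


def effect_for_prediction_r(
    target_r: float,
    base: float,
    frames: int,
    m_pos: int,
    m_neg: int,
    n_nodes: int | None = None,
    p_threshold: float = 0.01,
) -> float:
    """Effect size whose prediction ceiling equals ``target_r`` (bisection)."""
    if not 0.0 < target_r < 1.0:
        raise ParameterError("target_r must lie in (0, 1)")
    if m_pos + m_neg < 1:
        raise ParameterError("need at least one planted edge")
    lo, hi = 0.0, (1.0 - abs(base)) / 3.0  # respect the 3-SD safety margin
    if expected_prediction_r(hi, base, frames, m_pos, m_neg, n_nodes, p_threshold) < target_r:
        raise ParameterError(
            f"target_r={target_r} unreachable within the correlation safety margin"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = expected_prediction_r(mid, base, frames, m_pos, m_neg, n_nodes, p_threshold)
        if r < target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def effect_for_edge_severity_r(target_r: float, base: float, frames: int) -> float:
    """Effect size giving a per-edge severity correlation of ``target_r``."""
    if not 0.0 < target_r < 1.0:
        raise ParameterError("target_r must lie in (0, 1)")
    sd = edge_sampling_sd(base, frames)
    return sd * target_r / math.sqrt(1.0 - target_r**2)
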