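"""Renkin-Crone conversion between tracer uptake rate K1 and blood flow.

First-pass extraction of a diffusible tracer falls with flow:

    E(F) = 1 - alpha * exp(-beta / F),        K1 = F * E(F)

K1(F) is strictly increasing for alpha < 1 (dK1/dF >= 1 - alpha > 0), so
flow is recovered from a fitted K1 by bisection.  Attenuation-corrected
(AC) and non-attenuation-corrected (NAC) reconstructions each carry their
own calibrated (alpha, beta) preset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FlowModelParams",
    "FlowMetrics",
    "AC",
    "NAC",
    "extraction_fraction",
    "k1_from_flow",
    "flow_from_k1",
    "compute_flow_metrics",
]

_FLOW_UPPER = 20.0  # ml/min/g; physiologic flows are far below this
_BISECT_TOL = 1e-8


@dataclass(frozen=True)
class FlowModelParams:
    """Renkin-Crone parameters for one reconstruction variant."""

    alpha: float
    beta: float  # ml/min/g
    variant: str = "custom"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


#: Calibrated presets for 99mTc-sestamibi CZT quantification.
AC = FlowModelParams(alpha=0.879, beta=0.337, variant="AC")
NAC = FlowModelParams(alpha=0.814, beta=0.065, variant="NAC")

PRESETS = {"AC": AC, "NAC": NAC}


def extraction_fraction(flow: float, fm: FlowModelParams) -> float:
    """First-pass extraction E(F) = 1 - alpha exp(-beta/F), for flow > 0."""
    if flow <= 0:
        raise ValueError("flow must be > 0")
    return 1.0 - fm.alpha * np.exp(-fm.beta / flow)


def k1_from_flow(flow: float, fm: FlowModelParams) -> float:
    """Uptake rate K1 = F * E(F); K1(0) = 0, strictly increasing in F."""
    if flow < 0:
        raise ValueError("flow must be >= 0")
    if flow == 0:
        return 0.0
    return flow * extraction_fraction(flow, fm)


def flow_from_k1(k1: float, fm: FlowModelParams) -> float:
    """Invert K1 = F * E(F) for flow by bisection on [1e-6, 20] ml/min/g.

    Monotonicity of K1(F) guarantees the bracket; absolute tolerance 1e-8.
    """
    if k1 < 0:
        raise ValueError("K1 must be >= 0")
    if k1 == 0:
        return 0.0
    lo, hi = 1e-6, _FLOW_UPPER
    if k1 > k1_from_flow(hi, fm):
        raise ValueError(f"K1={k1} exceeds the model range (flow > {hi} ml/min/g)")
    if k1 <= k1_from_flow(lo, fm):
        return lo
    while hi - lo > _BISECT_TOL:
        mid = 0.5 * (lo + hi)
        if k1_from_flow(mid, fm) < k1:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class FlowMetrics:
    """Rest/stress flow with derived reserve (MFR) and difference (FD)."""

    rest_mbf: float  # ml/min/g
    stress_mbf: float  # ml/min/g
    mfr: float  # dimensionless, stress/rest
    fd: float  # ml/min/g, stress - rest (may be negative)
    variant: str
    region_label: str = "global"


def compute_flow_metrics(
    rest_mbf: float,
    stress_mbf: float,
    variant: str = "NAC",
    region_label: str = "global",
) -> FlowMetrics:
    """Myocardial flow reserve (stress/rest) and flow difference (stress - rest)."""
    if rest_mbf <= 0:
        raise ValueError("rest MBF must be > 0 to form a ratio")
    if stress_mbf < 0:
        raise ValueError("stress MBF must be >= 0")
    return FlowMetrics(
        rest_mbf=rest_mbf,
        stress_mbf=stress_mbf,
        mfr=stress_mbf / rest_mbf,
        fd=stress_mbf - rest_mbf,
        variant=variant,
        region_label=region_label,
    )
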