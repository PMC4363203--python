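"""qPCR ΔCt fold-enrichment arithmetic and western-blot ratio arithmetic.

ChIP-qPCR enrichment follows the classical three-step ΔCt scheme with an
amplification efficiency of exactly 2 per cycle:

1.  ΔCt = Ct_input - Ct_IP, with well-to-well spread combined in
    quadrature: s_ΔCt = sqrt(s_input² + s_IP²).
2.  Fold change FC = 2^ΔCt; its error by first-order (delta-method)
    propagation E = FC · ln2 · s_ΔCt.
3.  Fold enrichment = FC_IP / FC_mock, with relative errors of the two
    fold changes combined in quadrature.

The propagation in step 2 is the standard first-order form and is kept in
one function so an alternative (e.g. exact log-normal) is a one-line swap.
Ct means and standard deviations use the sample (n-1) estimator over the
wells of a triplicate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

_ROLES = ("input", "mock", "IP")


@dataclass
class QtPcrSample:
    """Ct wells for one target x condition (role: input, mock or IP)."""

    role: str
    ct_values: np.ndarray

    def __post_init__(self):
        if self.role not in _ROLES:
            raise InvalidInputError(f"role must be one of {_ROLES}, got {self.role!r}")
        self.ct_values = np.asarray(self.ct_values, dtype=float)
        if self.ct_values.size < 2:
            raise InvalidInputError("need at least 2 wells per sample")

    @property
    def ct_mean(self) -> float:
        return float(self.ct_values.mean())

    @property
    def ct_sd(self) -> float:
        return float(self.ct_values.std(ddof=1))


@dataclass
class EnrichmentResult:
    """Fold enrichment of an IP over its mock IP, with propagated error."""

    delta_ct: float
    delta_ct_sd: float
    fold_change: float
    fold_error: float
    fold_enrichment: float
    fold_enrichment_error: float


def delta_ct(ip: QtPcrSample, input_: QtPcrSample) -> tuple[float, float]:
    """ΔCt = Ct_input - Ct_IP and its quadrature-combined sd."""
    d = input_.ct_mean - ip.ct_mean
    sd = math.hypot(input_.ct_sd, ip.ct_sd)
    return d, sd


def fold_change(dct: float, dct_sd: float) -> tuple[float, float]:
    """Linear-scale fold change FC = 2^ΔCt and first-order error."""
    fc = 2.0 ** dct
    return fc, fc * math.log(2.0) * dct_sd


def fold_enrichment(
    fc_ip: tuple[float, float], fc_mock: tuple[float, float]
) -> tuple[float, float]:
    """FC_IP / FC_mock with relative errors combined in quadrature."""
    (f_ip, e_ip), (f_m, e_m) = fc_ip, fc_mock
    if f_m <= 0:
        raise InvalidInputError("mock fold change must be > 0")
    ratio = f_ip / f_m
    err = ratio * math.hypot(e_ip / f_ip if f_ip else 0.0, e_m / f_m)
    return ratio, err


def analyze_qtpcr(
    ip: QtPcrSample, mock: QtPcrSample, input_: QtPcrSample
) -> EnrichmentResult:
    """Run steps 1-3 for one target and return the full result."""
    d_ip, s_ip = delta_ct(ip, input_)
    d_m, s_m = delta_ct(mock, input_)
    fc_ip = fold_change(d_ip, s_ip)
    fc_m = fold_change(d_m, s_m)
    fe, fe_err = fold_enrichment(fc_ip, fc_m)
    return EnrichmentResult(
        delta_ct=d_ip,
        delta_ct_sd=s_ip,
        fold_change=fc_ip[0],
        fold_error=fc_ip[1],
        fold_enrichment=fe,
        fold_enrichment_error=fe_err,
    )


def wb_relative_abundance(
    signal_target: float, signal_h4: float, ref_target: float, ref_h4: float
) -> float:
    """Target/H4 ratio in a cell line over the same ratio in the reference.

    Standardizing against the co-loaded core histone H4 cancels loading
    differences; dividing by the reference line's ratio puts abundance on
    a fold-over-reference scale.
    """
    if signal_h4 <= 0 or ref_h4 <= 0 or ref_target <= 0:
        raise InvalidInputError("denominators must be > 0")
    return (signal_target / signal_h4) / (ref_target / ref_h4)


def wb_fold_ratio(
    band_a: float, bg_a: float, input_a: float,
    band_b: float, bg_b: float, input_b: float,
) -> float:
    """Background-corrected, input-adjusted fold ratio between two IPs.

    ((band_a - bg_a)/input_a) / ((band_b - bg_b)/input_b); a negative
    background-corrected signal floors at 0 with a warning.
    """
    if input_a <= 0 or input_b <= 0:
        raise InvalidInputError("input signals must be > 0")
    ca = band_a - bg_a
    cb = band_b - bg_b
    if ca < 0 or cb < 0:
        warnings.warn("negative background-corrected signal floored at 0")
        ca, cb = max(ca, 0.0), max(cb, 0.0)
    if cb == 0:
        raise InvalidInputError("denominator IP signal is 0 after correction")
    return (ca / input_a) / (cb / input_b)
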