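"""Log-parabola contrast sensitivity function (CSF) and its key attributes.

The CSF relates contrast sensitivity ``S`` (the reciprocal of contrast
threshold) to spatial frequency ``sf`` (cycles per degree, cpd).  We use the
standard three-parameter log-parabola,

    log10 S(sf) = log10(peakCS) - 4 log10(2) * ((log10 sf - log10 peakSF) / b)^2,

where ``peakCS`` is the peak sensitivity, ``peakSF`` the spatial frequency at
the peak, and ``b`` the full width at half maximum of the parabola measured in
log10-SF units (decades).  The 4·log10(2) scaling makes S drop to peakCS/2
exactly at log10(peakSF) ± b/2.

Observers respond in a two-alternative orientation-discrimination task; the
probability of a correct response at contrast ``c`` is the Weibull-family
psychometric function

    p(r=1 | θ, sf, c) = g + (1 - g - λ/2) * (1 - exp(-(c·S(sf,θ))^β)),

with fixed guess rate g = 0.5, lapse rate λ = 0.04 and slope β = 2, so the
achievable range is (0.5, 0.98].

Five scalar attributes summarise a fitted CSF: peak-CS, peak-SF, bandwidth
(FWHM), cutoff-SF (the high-frequency point where S = 1, an acuity proxy) and
AULCSF (area under the log CSF over the tested SF range, a "window of
visibility" summary).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "LOG_PEAK_CS_BOUNDS",
    "LOG_PEAK_SF_BOUNDS",
    "LOG_BANDWIDTH_BOUNDS",
    "PARAM_BOUNDS",
    "PARAM_NAMES",
    "CSFParams",
    "PsychometricConstants",
    "DEFAULT_CONSTANTS",
    "CSFAttributes",
    "sensitivity",
    "log_sensitivity",
    "p_correct",
    "log_likelihood",
    "cutoff_sf",
    "aulcsf",
    "derive_attributes",
    "bandwidth_octaves",
]

LOG4LOG2 = 4.0 * math.log10(2.0)

# Truncation boxes for the three log10 parameters (shared by the uniform BIP
# prior, the parameter grids, and the HBM hyperpriors).
LOG_PEAK_CS_BOUNDS = (math.log10(1.05), math.log10(1050.0))
LOG_PEAK_SF_BOUNDS = (math.log10(0.1), math.log10(5.0))
LOG_BANDWIDTH_BOUNDS = (math.log10(1.0), math.log10(9.0))
PARAM_BOUNDS = np.array(
    [LOG_PEAK_CS_BOUNDS, LOG_PEAK_SF_BOUNDS, LOG_BANDWIDTH_BOUNDS]
)
PARAM_NAMES = ("log_peak_cs", "log_peak_sf", "log_bandwidth")


@dataclass(frozen=True)
class CSFParams:
    """One observer's CSF on the log10 scale.

    Attributes
    ----------
    log_peak_cs : float
        log10 of peak contrast sensitivity (dimensionless).
    log_peak_sf : float
        log10 of peak spatial frequency (log10 cpd).
    log_bandwidth : float
        log10 of the FWHM bandwidth, itself expressed in log10-SF decades.
    """

    log_peak_cs: float
    log_peak_sf: float
    log_bandwidth: float

    def __post_init__(self) -> None:
        vec = np.array([self.log_peak_cs, self.log_peak_sf, self.log_bandwidth])
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"non-finite CSF parameters: {vec}")
        if np.any(vec < PARAM_BOUNDS[:, 0] - 1e-12) or np.any(
            vec > PARAM_BOUNDS[:, 1] + 1e-12
        ):
            raise ValueError(
                f"CSF parameters {vec} outside truncation bounds {PARAM_BOUNDS}"
            )

    @classmethod
    def from_linear(
        cls, peak_cs: float, peak_sf: float, bandwidth: float
    ) -> "CSFParams":
        """Build from linear peak sensitivity, peak SF (cpd) and bandwidth (decades)."""
        return cls(math.log10(peak_cs), math.log10(peak_sf), math.log10(bandwidth))

    @classmethod
    def unchecked(
        cls, log_peak_cs: float, log_peak_sf: float, log_bandwidth: float
    ) -> "CSFParams":
        """Construct without the truncation-box check (e.g. to evaluate the
        model at a hypothetical peak_cs < 1, where cutoff-SF is undefined)."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "log_peak_cs", float(log_peak_cs))
        object.__setattr__(obj, "log_peak_sf", float(log_peak_sf))
        object.__setattr__(obj, "log_bandwidth", float(log_bandwidth))
        return obj

    def as_array(self) -> np.ndarray:
        return np.array([self.log_peak_cs, self.log_peak_sf, self.log_bandwidth])

    @property
    def peak_cs(self) -> float:
        return 10.0 ** self.log_peak_cs

    @property
    def peak_sf(self) -> float:
        return 10.0 ** self.log_peak_sf

    @property
    def bandwidth(self) -> float:
        """FWHM in log10-SF decades."""
        return 10.0 ** self.log_bandwidth


@dataclass(frozen=True)
class PsychometricConstants:
    """Fixed (not fitted) constants of the psychometric function."""

    guess_rate: float = 0.5
    lapse_rate: float = 0.04
    slope: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.guess_rate < 1.0):
            raise ValueError("guess_rate must lie in (0, 1)")
        if not (0.0 <= self.lapse_rate < 1.0):
            raise ValueError("lapse_rate must lie in [0, 1)")
        if self.slope <= 0.0:
            raise ValueError("slope must be positive")


DEFAULT_CONSTANTS = PsychometricConstants()


@dataclass(frozen=True)
class CSFAttributes:
    """The five key CSF attributes on their natural (linear) scales.

    ``cutoff_sf`` is NaN (with ``cutoff_defined=False``) when the CSF never
    reaches sensitivity 1, i.e. peak_cs < 1.
    """

    peak_cs: float
    peak_sf: float
    bandwidth_fwhm: float
    cutoff_sf: float
    aulcsf: float
    cutoff_defined: bool = True


def log_sensitivity(params: CSFParams, sf) -> np.ndarray:
    """log10 contrast sensitivity at spatial frequency ``sf`` (cpd)."""
    sf = np.asarray(sf, dtype=float)
    if np.any(sf <= 0.0):
        raise ValueError("spatial frequency must be positive")
    z = (np.log10(sf) - params.log_peak_sf) / params.bandwidth
    return params.log_peak_cs - LOG4LOG2 * z * z


def sensitivity(params: CSFParams, sf) -> np.ndarray:
    """Linear contrast sensitivity at spatial frequency ``sf`` (cpd)."""
    return 10.0 ** log_sensitivity(params, sf)


def p_correct(
    params: CSFParams,
    sf,
    contrast,
    consts: PsychometricConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Probability of a correct response for stimulus (sf, contrast).

    Strictly increasing in contrast; bounded in (g, 1 - λ/2).
    """
    contrast = np.asarray(contrast, dtype=float)
    if np.any(contrast <= 0.0) or np.any(contrast > 1.0):
        raise ValueError("contrast must lie in (0, 1]")
    s = sensitivity(params, sf)
    g, lam, beta = consts.guess_rate, consts.lapse_rate, consts.slope
    return g + (1.0 - g - lam / 2.0) * (1.0 - np.exp(-((contrast * s) ** beta)))


def p_response(params, sf, contrast, response, consts=DEFAULT_CONSTANTS):
    """Probability of the observed response (1 = correct, 0 = incorrect)."""
    p1 = p_correct(params, sf, contrast, consts)
    response = np.asarray(response)
    return np.where(response == 1, p1, 1.0 - p1)


def log_likelihood(params: CSFParams, trials, consts=DEFAULT_CONSTANTS) -> float:
    """Summed log probability of a set of Bernoulli trials under ``params``.

    ``trials`` is a pandas DataFrame (or mapping of arrays) with columns
    ``sf``, ``contrast`` and ``response`` (0/1).  Returns 0.0 with a warning
    for an empty trial set.
    """
    sf = np.asarray(trials["sf"], dtype=float)
    contrast = np.asarray(trials["contrast"], dtype=float)
    response = np.asarray(trials["response"])
    if sf.size == 0:
        warnings.warn("log_likelihood of an empty trial set is 0", stacklevel=2)
        return 0.0
    if not np.all(np.isin(response, (0, 1))):
        raise ValueError("responses must be 0 or 1")
    return float(np.sum(np.log(p_response(params, sf, contrast, response, consts))))


def cutoff_sf(params: CSFParams) -> float:
    """High-frequency cutoff: the larger root of S(sf) = 1, in cpd.

    Closed form: log10(cutoff) = log10(peakSF) + b * sqrt(log10(peakCS) / (4 log10 2)).
    Returns NaN when peak_cs < 1 (the curve never reaches sensitivity 1).
    """
    if params.log_peak_cs < 0.0:
        return float("nan")
    offset = params.bandwidth * math.sqrt(params.log_peak_cs / LOG4LOG2)
    return 10.0 ** (params.log_peak_sf + offset)


def _unit_crossings(params: CSFParams) -> tuple[float, float]:
    """The two roots of S(sf) = 1 in cpd (requires peak_cs >= 1)."""
    offset = params.bandwidth * math.sqrt(max(params.log_peak_cs, 0.0) / LOG4LOG2)
    return 10.0 ** (params.log_peak_sf - offset), 10.0 ** (params.log_peak_sf + offset)


def aulcsf(params: CSFParams, sf_lo: float = 0.5, sf_hi: float = 16.0) -> float:
    """Area under the log CSF over [sf_lo, sf_hi] cpd.

    Integrates max(log10 S, 0) with respect to log10(sf), so the result is 0
    exactly when peak_cs <= 1.  The default range is the tested SF range
    0.5–16 cpd.  Adaptive quadrature to relative tolerance 1e-6; the integrand
    is restricted to the interval where it is positive (between the two unit
    crossings), on which it is smooth.
    """
    if not (0.0 < sf_lo < sf_hi):
        raise ValueError("require 0 < sf_lo < sf_hi")
    if params.log_peak_cs <= 0.0:
        return 0.0
    lo_root, hi_root = _unit_crossings(params)
    a = math.log10(max(sf_lo, lo_root))
    b = math.log10(min(sf_hi, hi_root))
    if b <= a:
        return 0.0

    def integrand(u: float) -> float:
        z = (u - params.log_peak_sf) / params.bandwidth
        return params.log_peak_cs - LOG4LOG2 * z * z

    val, _ = integrate.quad(integrand, a, b, epsrel=1e-6, epsabs=1e-12)
    return float(max(val, 0.0))


def derive_attributes(
    params: CSFParams, sf_lo: float = 0.5, sf_hi: float = 16.0
) -> CSFAttributes:
    """Compute the five key CSF attributes from a fitted parameter triplet."""
    cut = cutoff_sf(params)
    return CSFAttributes(
        peak_cs=params.peak_cs,
        peak_sf=params.peak_sf,
        bandwidth_fwhm=params.bandwidth,
        cutoff_sf=cut,
        aulcsf=aulcsf(params, sf_lo, sf_hi),
        cutoff_defined=not math.isnan(cut),
    )


def bandwidth_octaves(bandwidth_decades: float) -> float:
    """Convert an FWHM bandwidth from log10-SF decades to octaves."""
    return bandwidth_decades / math.log10(2.0)
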