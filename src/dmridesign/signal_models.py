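"""Noise-free forward models for direction-averaged diffusion MRI.

Two generative models are provided, both returning the normalised signal
``S(b)/S0`` at a set of diffusion weightings (b-values, s/mm^2):

* the bi-exponential intravoxel incoherent motion (IVIM) model, which splits
  the signal into a perfusing compartment with volume fraction ``f`` and
  pseudo-diffusivity ``D_fast``, and a tissue compartment with diffusivity
  ``D_slow``::

      S(b)/S0 = f * exp(-b * (D_fast + D_slow)) + (1 - f) * exp(-b * D_slow)

* the mono-exponential apparent-diffusion-coefficient (ADC) model::

      S(b)/S0 = exp(-b * ADC)

All diffusivities are expressed in mm^2/s internally; configuration files may
use the common 1e-3 mm^2/s convention, which is converted once at load time
(see :mod:`dmridesign.config`).  The fast-compartment exponent carries the
``D_fast + D_slow`` sum; with typical tissue values (``D_fast`` two to three
orders of magnitude above ``D_slow``) the difference from ``exp(-b*D_fast)``
is negligible, but the summed form is this package's definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputValidationError

__all__ = [
    "AcquisitionProtocol",
    "IVIMParams",
    "ADCParams",
    "ivim_signal",
    "adc_signal",
    "ivim_curve",
    "adc_curve",
]


def _validate_b_values(b_values) -> np.ndarray:
    b = np.atleast_1d(np.asarray(b_values, dtype=float))
    if b.ndim != 1:
        raise InputValidationError("b_values must be a one-dimensional array")
    if not np.all(np.isfinite(b)):
        raise InputValidationError("b_values must be finite")
    if np.any(b < 0):
        raise InputValidationError("b_values must be non-negative")
    return b


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Measurement design: b-value scheme plus effective SNR.

    Parameters
    ----------
    b_values : array-like
        Diffusion weightings in s/mm^2.  Must contain b = 0 (the
        normalisation point) and at least three values in total.
    snr : float
        Effective signal-to-noise ratio at b = 0 (dimensionless, > 0).
        "Effective" means after ROI averaging: acquisition factors such as
        TE, TR, repetitions and ROI size are absorbed into this single
        number.  ``numpy.inf`` is accepted and means noise-free.
    """

    b_values: np.ndarray
    snr: float

    def __post_init__(self) -> None:
        b = _validate_b_values(self.b_values)
        if b.size < 3:
            raise InputValidationError(
                "protocol needs at least 3 b-values (normalisation point plus "
                f"a fittable curve); got {b.size}"
            )
        if not np.any(b == 0):
            raise InputValidationError(
                "protocol must include b = 0 for signal normalisation"
            )
        snr = float(self.snr)
        if np.isnan(snr) or snr <= 0:
            raise InputValidationError(f"snr must be > 0, got {snr}")
        b.setflags(write=False)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "snr", snr)

    @property
    def n_measurements(self) -> int:
        return int(self.b_values.size)

    @property
    def b0_index(self) -> int:
        """Index of the (first) b = 0 measurement."""
        return int(np.flatnonzero(self.b_values == 0)[0])


@dataclass(frozen=True)
class IVIMParams:
    """IVIM tissue parameters.

    Attributes
    ----------
    f : float
        Perfusion (fast-compartment) volume fraction, in [0, 1].
    d_slow : float
        Diffusivity of non-perfusing water, mm^2/s, >= 0.
    d_fast : float
        Pseudo-diffusivity of perfusing water, mm^2/s, >= 0.
    """

    f: float
    d_slow: float
    d_fast: float

    def __post_init__(self) -> None:
        for name in ("f", "d_slow", "d_fast"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise InputValidationError(f"{name} must be finite, got {v}")
            object.__setattr__(self, name, v)
        if not 0.0 <= self.f <= 1.0:
            raise InputValidationError(f"f must lie in [0, 1], got {self.f}")
        if self.d_slow < 0 or self.d_fast < 0:
            raise InputValidationError(
                f"diffusivities must be >= 0, got d_slow={self.d_slow}, "
                f"d_fast={self.d_fast}"
            )

    def as_dict(self) -> dict[str, float]:
        return {"f": self.f, "d_slow": self.d_slow, "d_fast": self.d_fast}


@dataclass(frozen=True)
class ADCParams:
    """Mono-exponential model parameter: apparent diffusion coefficient, mm^2/s."""

    adc: float

    def __post_init__(self) -> None:
        v = float(self.adc)
        if not np.isfinite(v) or v < 0:
            raise InputValidationError(f"adc must be finite and >= 0, got {v}")
        object.__setattr__(self, "adc", v)

    def as_dict(self) -> dict[str, float]:
        return {"adc": self.adc}


# Parameter names per model identifier, in canonical column order.
MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "ivim": ("f", "d_slow", "d_fast"),
    "adc": ("adc",),
}


def ivim_curve(b: np.ndarray, f: float, d_slow: float, d_fast: float) -> np.ndarray:
    """Raw IVIM kernel without argument validation (hot path for fitting)."""
    return f * np.exp(-b * (d_fast + d_slow)) + (1.0 - f) * np.exp(-b * d_slow)


def adc_curve(b: np.ndarray, adc: float) -> np.ndarray:
    """Raw mono-exponential kernel without argument validation."""
    return np.exp(-b * adc)


def ivim_signal(params: IVIMParams, b_values) -> np.ndarray:
    """Evaluate the normalised IVIM signal S(b)/S0.

    Parameters
    ----------
    params : IVIMParams
        Tissue parameters (validated on construction).
    b_values : array-like
        Diffusion weightings, s/mm^2, finite and >= 0.

    Returns
    -------
    numpy.ndarray
        One value per b-value, each in (0, 1]; exactly 1 at b = 0.
    """
    b = _validate_b_values(b_values)
    return ivim_curve(b, params.f, params.d_slow, params.d_fast)


def adc_signal(params: ADCParams, b_values) -> np.ndarray:
    """Evaluate the normalised mono-exponential signal S(b)/S0 = exp(-b*ADC)."""
    b = _validate_b_values(b_values)
    return adc_curve(b, params.adc)


def model_signal(model: str, params: dict[str, float], b_values: np.ndarray) -> np.ndarray:
    """Evaluate a named model ("ivim" or "adc") from a parameter mapping."""
    if model == "ivim":
        return ivim_signal(IVIMParams(**params), b_values)
    if model == "adc":
        return adc_signal(ADCParams(**params), b_values)
    raise InputValidationError(f"unknown model {model!r}; expected 'ivim' or 'adc'")
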