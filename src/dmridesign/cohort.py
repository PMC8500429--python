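"""Synthetic cohort generation: parameter draws, Rician noise, normalisation.

This is the data-synthesis stage of the assessment pipeline.  Each simulated
subject is one mean-ROI signal: per-subject tissue parameters are drawn from
the tissue characterisation (independent Gaussians per parameter, truncated
to the physical domain by rejection), the noise-free signal is evaluated at
the protocol b-values, every measurement — including b = 0 — is corrupted
independently with Rician noise at sigma = S0/SNR, and the signal is then
normalised by the subject's own measured noisy b = 0 value, mimicking
real-world processing where the true S0 is unknown.

Rician corruption of a noise-free magnitude S is

    S_noisy = sqrt( N(S, sigma^2)^2 + N(0, sigma^2)^2 )

i.e. the magnitude of a complex Gaussian perturbation, which produces the
characteristic positive "noise floor" at low signal levels.

Randomness is handled with a single root seed per cohort, spawned into
independent sub-streams (one parameter stream and one noise stream per
tissue) via :class:`numpy.random.SeedSequence`, so cohorts are exactly
reproducible and streams cannot alias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputValidationError
from .signal_models import (
    MODEL_PARAMS,
    ADCParams,
    AcquisitionProtocol,
    IVIMParams,
    adc_curve,
    ivim_curve,
)

__all__ = [
    "TissueDistribution",
    "CohortSpec",
    "SubjectRecord",
    "draw_tissue_parameters",
    "add_rician_noise",
    "synthesize_cohort",
    "cohort_to_frame",
    "cohort_from_frame",
]

# Physical bounds enforced on parameter draws, per model parameter.
_PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "f": (0.0, 1.0),
    "d_slow": (0.0, np.inf),
    "d_fast": (0.0, np.inf),
    "adc": (0.0, np.inf),
}

# A draw batch whose acceptance rate falls below this floor indicates a
# distribution essentially outside the physical domain.
_MIN_ACCEPTANCE = 1e-3


@dataclass(frozen=True)
class TissueDistribution:
    """Gaussian parameter distribution characterising one tissue type.

    Parameters are drawn independently per subject from N(mean, sd^2) and
    rejected (redrawn) when they violate physical bounds (f outside [0, 1],
    negative diffusivities), so the effective marginal is a truncated
    Gaussian.  An sd of 0 gives a degenerate (point-mass) parameter.
    """

    label: str
    model: str
    param_means: dict[str, float]
    param_sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.model not in MODEL_PARAMS:
            raise ConfigurationError(
                f"tissue {self.label!r}: unknown model {self.model!r}; "
                f"expected one of {sorted(MODEL_PARAMS)}"
            )
        expected = set(MODEL_PARAMS[self.model])
        if set(self.param_means) != expected or set(self.param_sds) != expected:
            raise ConfigurationError(
                f"tissue {self.label!r}: parameter names must be exactly "
                f"{sorted(expected)}; got means={sorted(self.param_means)}, "
                f"sds={sorted(self.param_sds)}"
            )
        for name, mu in self.param_means.items():
            if not np.isfinite(mu):
                raise ConfigurationError(
                    f"tissue {self.label!r}: mean of {name} must be finite"
                )
        for name, sd in self.param_sds.items():
            if not np.isfinite(sd) or sd < 0:
                raise ConfigurationError(
                    f"tissue {self.label!r}: sd of {name} must be finite and >= 0"
                )

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_PARAMS[self.model]


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic two-tissue cohort."""

    tissues: tuple[TissueDistribution, TissueDistribution]
    n_per_tissue: int
    protocol: AcquisitionProtocol
    seed: int

    def __post_init__(self) -> None:
        if len(self.tissues) != 2:
            raise ConfigurationError("a cohort requires exactly two tissues")
        if self.tissues[0].label == self.tissues[1].label:
            raise ConfigurationError(
                f"tissue labels must be distinct, got {self.tissues[0].label!r} twice"
            )
        if int(self.n_per_tissue) < 2:
            raise ConfigurationError("n_per_tissue must be >= 2")
        object.__setattr__(self, "n_per_tissue", int(self.n_per_tissue))
        object.__setattr__(self, "seed", int(self.seed))
        object.__setattr__(self, "tissues", tuple(self.tissues))


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated subject: label, drawn ground truth, normalised noisy signal."""

    tissue_label: str
    true_params: IVIMParams | ADCParams
    signal: np.ndarray


def _param_object(model: str, values: dict[str, float]) -> IVIMParams | ADCParams:
    return IVIMParams(**values) if model == "ivim" else ADCParams(**values)


def draw_tissue_parameters(
    dist: TissueDistribution, n: int, rng: np.random.Generator
) -> list[IVIMParams | ADCParams]:
    """Draw ``n`` physically valid parameter sets from a tissue distribution.

    Each parameter is drawn from its Gaussian independently; a draw is
    accepted only if every parameter satisfies its physical bounds, otherwise
    the whole set is redrawn (rejection sampling, so marginals are truncated
    Gaussians and parameters stay independent given acceptance).

    Raises
    ------
    ConfigurationError
        If the acceptance probability is so low (< 0.1%) that the
        distribution is effectively outside the physical domain.
    """
    if n < 1:
        raise InputValidationError(f"n must be >= 1, got {n}")
    names = dist.param_names
    means = np.array([dist.param_means[p] for p in names])
    sds = np.array([dist.param_sds[p] for p in names])
    lo = np.array([_PARAM_BOUNDS[p][0] for p in names])
    hi = np.array([_PARAM_BOUNDS[p][1] for p in names])

    accepted = np.empty((0, len(names)))
    n_proposed = 0
    while accepted.shape[0] < n:
        batch = max(n - accepted.shape[0], 1000)
        draws = rng.normal(means, sds, size=(batch, len(names)))
        ok = np.all((draws >= lo) & (draws <= hi), axis=1)
        n_proposed += batch
        accepted = np.vstack([accepted, draws[ok]])
        if n_proposed >= 1000 and accepted.shape[0] / n_proposed < _MIN_ACCEPTANCE:
            raise ConfigurationError(
                f"tissue {dist.label!r}: acceptance rate "
                f"{accepted.shape[0] / n_proposed:.2e} below {_MIN_ACCEPTANCE}; "
                "distribution lies essentially outside the physical domain"
            )
    accepted = accepted[:n]
    return [
        _param_object(dist.model, dict(zip(names, row))) for row in accepted
    ]


def add_rician_noise(
    signal: np.ndarray, snr: float, rng: np.random.Generator
) -> np.ndarray:
    """Corrupt a noise-free normalised signal with element-wise Rician noise.

    sigma = 1/SNR (the input is normalised, so S0 = 1).  ``snr = numpy.inf``
    returns the input unchanged.
    """
    s = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(s)) or np.any(s < 0):
        raise InputValidationError("signal must be finite and non-negative")
    snr = float(snr)
    if np.isnan(snr) or snr <= 0:
        raise InputValidationError(f"snr must be > 0, got {snr}")
    sigma = 0.0 if np.isinf(snr) else 1.0 / snr
    real = rng.normal(s, sigma)
    imag = rng.normal(0.0, sigma, size=s.shape)
    return np.hypot(real, imag)


def _noise_free_curves(dist: TissueDistribution, params: Sequence, b: np.ndarray) -> np.ndarray:
    out = np.empty((len(params), b.size))
    if dist.model == "ivim":
        for i, p in enumerate(params):
            out[i] = ivim_curve(b, p.f, p.d_slow, p.d_fast)
    else:
        for i, p in enumerate(params):
            out[i] = adc_curve(b, p.adc)
    return out


def synthesize_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Simulate a full two-tissue cohort (pipeline data-synthesis stage).

    For each tissue: draw ``n_per_tissue`` parameter sets, evaluate the
    generative model at the protocol b-values, corrupt every measurement with
    Rician noise at sigma = 1/SNR, and divide each subject's samples by their
    measured noisy b = 0 value.  Deterministic given ``spec.seed``.
    """
    proto = spec.protocol
    b = proto.b_values
    b0 = proto.b0_index
    streams = np.random.SeedSequence(spec.seed).spawn(2 * len(spec.tissues))
    records: list[SubjectRecord] = []
    for t_idx, dist in enumerate(spec.tissues):
        param_rng = np.random.default_rng(streams[2 * t_idx])
        noise_rng = np.random.default_rng(streams[2 * t_idx + 1])
        params = draw_tissue_parameters(dist, spec.n_per_tissue, param_rng)
        clean = _noise_free_curves(dist, params, b)
        noisy = add_rician_noise(clean, proto.snr, noise_rng)
        normalised = noisy / noisy[:, b0][:, None]
        for p, sig in zip(params, normalised):
            sig = np.asarray(sig)
            sig.setflags(write=False)
            records.append(SubjectRecord(dist.label, p, sig))
    return records


def cohort_to_frame(cohort: Sequence[SubjectRecord], protocol: AcquisitionProtocol) -> pd.DataFrame:
    """Flatten a cohort to a table: one row per subject.

    Columns: ``subject``, ``tissue``, ``true_<param>`` for each generative
    parameter, and ``b<value>`` per measurement.  Round-trips through CSV via
    :func:`cohort_from_frame`.
    """
    rows = []
    for i, rec in enumerate(cohort):
        row: dict[str, object] = {"subject": i, "tissue": rec.tissue_label}
        for name, val in rec.true_params.as_dict().items():
            row[f"true_{name}"] = val
        for bval, s in zip(protocol.b_values, rec.signal):
            row[f"b{bval:g}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_from_frame(frame: pd.DataFrame, protocol: AcquisitionProtocol) -> list[SubjectRecord]:
    """Inverse of :func:`cohort_to_frame`."""
    sig_cols = [f"b{bv:g}" for bv in protocol.b_values]
    true_cols = [c for c in frame.columns if c.startswith("true_")]
    model = "ivim" if "true_f" in frame.columns else "adc"
    records = []
    for _, row in frame.iterrows():
        params = {c[len("true_"):]: float(row[c]) for c in true_cols}
        sig = row[sig_cols].to_numpy(dtype=float)
        sig.setflags(write=False)
        records.append(SubjectRecord(str(row["tissue"]), _param_object(model, params), sig))
    return records
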