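"""Covariate model mapping patient characteristics to individual PK parameters.

The final covariate model for IV magnesium in preeclampsia takes the form

    CL_i = tvCL * (CCR_i/ref_CCR)^dCLdCCR * (BMI_i/ref_BMI)^dCLdBMI
               * (1 + dCLdfurosemide * FURO_i) * exp(etaCL_i)
    V_i  = tvV  * (1 + dVdfurosemide * FURO_i) * exp(etaV_i)

with continuous covariates entering as power functions of a normalized value
and categorical covariates as proportional shifts.  Proportional
coefficients are stored signed, so a printed factor ``(1 - 0.16*furo)``
corresponds to a coefficient of -0.16.  Between-subject random effects are
log-normal with a diagonal covariance (no CL--V correlation term).

Beyond the fixed final-model equations this module also provides the generic
:class:`CovariateEffect` building block used by the stepwise covariate
search, where any covariate may be attached to CL or V in either functional
form.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .pk_core import PKParameters


class ModelValidityError(ValueError):
    """A covariate factor became non-positive for the given inputs."""


@dataclass(frozen=True)
class Covariates:
    """Patient-level covariates. Units: CCR ml/min, BMI kg/m2, albumin g/L,
    calcium g/L, age years; drug flags and ADR are 0/1."""

    CCR: float
    BMI: float
    furosemide: int = 0
    age: float | None = None
    albumin: float | None = None
    calcium: float | None = None
    labetalol: int = 0
    nifedipine: int = 0
    ADR: int = 0

    def __post_init__(self) -> None:
        if not self.CCR > 0:
            raise ValueError(f"CCR must be > 0, got {self.CCR}")
        if not self.BMI > 0:
            raise ValueError(f"BMI must be > 0, got {self.BMI}")
        for name in ("furosemide", "labetalol", "nifedipine", "ADR"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")


@dataclass(frozen=True)
class ThetaVector:
    """Fixed effects of the final model (typical values and covariate
    coefficients).  ``ref_CCR``/``ref_BMI`` are the normalization constants
    the power terms divide by; they default to 51 to match the published
    form of the equations and are deliberately easy to override (a more
    conventional choice is the study median, CCR ~182 and BMI ~29)."""

    tvCL: float = 2.98
    tvV: float = 25.07
    dCLdCCR: float = 0.39
    dCLdBMI: float = -0.54
    dCLdfurosemide: float = -0.16
    dVdfurosemide: float = -0.25
    ref_CCR: float = 51.0
    ref_BMI: float = 51.0

    def __post_init__(self) -> None:
        if not self.tvCL > 0:
            raise ValueError("tvCL must be > 0")
        if not self.tvV > 0:
            raise ValueError("tvV must be > 0")
        for name in ("dCLdfurosemide", "dVdfurosemide"):
            if abs(getattr(self, name)) >= 1:
                raise ValueError(f"|{name}| must be < 1 so factors stay positive")


@dataclass(frozen=True)
class EtaVector:
    etaCL: float = 0.0
    etaV: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.etaCL) and np.isfinite(self.etaV)):
            raise ValueError("etas must be finite")


@dataclass(frozen=True)
class OmegaMatrix:
    """Diagonal between-subject variance matrix (variances of etaCL, etaV)."""

    omega2CL: float = 0.082
    omega2V: float = 0.023

    def __post_init__(self) -> None:
        if self.omega2CL < 0 or self.omega2V < 0:
            raise ValueError("omega2 values must be >= 0")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate attachment for the stepwise search: ``covariate`` acts
    on ``parameter`` ("CL" or "V") through ``form`` ("power" for continuous,
    "proportional" for categorical); ``reference`` is the power-form
    normalization constant."""

    parameter: str
    covariate: str
    form: str
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in ("CL", "V"):
            raise ValueError("parameter must be 'CL' or 'V'")
        if self.form not in ("power", "proportional"):
            raise ValueError("form must be 'power' or 'proportional'")
        if self.form == "power" and (self.reference is None or self.reference <= 0):
            raise ValueError("power form requires a positive reference")

    @property
    def name(self) -> str:
        """Coefficient name in the field's d<param>d<covariate> convention."""
        return f"d{self.parameter}d{self.covariate}"


def covariate_term(form: str, value, coefficient: float, reference: float | None = None):
    """Multiplicative covariate factor.

    power:        (value / reference) ** coefficient
    proportional: 1 + coefficient * value   (value normally 0/1)
    """
    value = np.asarray(value, dtype=float)
    if form == "power":
        if reference is None or reference <= 0:
            raise ValueError("power form requires a positive reference")
        if np.any(value <= 0):
            raise ValueError("power form requires a positive covariate value")
        factor = (value / reference) ** coefficient
    elif form == "proportional":
        factor = 1.0 + coefficient * value
    else:
        raise ValueError(f"unknown covariate form {form!r}")
    if np.any(factor <= 0):
        raise ModelValidityError(
            f"covariate factor must stay positive (form={form}, coef={coefficient})"
        )
    return factor if factor.ndim else float(factor)


def final_model_effects(
    ref_CCR: float = 51.0, ref_BMI: float = 51.0
) -> tuple[CovariateEffect, ...]:
    """The four covariate attachments of the final model."""
    return (
        CovariateEffect("CL", "CCR", "power", ref_CCR),
        CovariateEffect("CL", "BMI", "power", ref_BMI),
        CovariateEffect("CL", "furosemide", "proportional"),
        CovariateEffect("V", "furosemide", "proportional"),
    )


def typical_values(theta: ThetaVector, cov: Covariates) -> tuple[float, float]:
    """Typical (eta = 0) clearance and volume for a patient's covariates."""
    cl = (
        theta.tvCL
        * covariate_term("power", cov.CCR, theta.dCLdCCR, theta.ref_CCR)
        * covariate_term("power", cov.BMI, theta.dCLdBMI, theta.ref_BMI)
        * covariate_term("proportional", cov.furosemide, theta.dCLdfurosemide)
    )
    v = theta.tvV * covariate_term("proportional", cov.furosemide, theta.dVdfurosemide)
    return float(cl), float(v)


def individual_params(
    theta: ThetaVector,
    cov: Covariates,
    eta: EtaVector = EtaVector(),
    baseline: float = 0.0,
) -> PKParameters:
    """Individual parameters: typical values scaled by exp(eta)."""
    cl_typ, v_typ = typical_values(theta, cov)
    return PKParameters(
        CL=cl_typ * float(np.exp(eta.etaCL)),
        V=v_typ * float(np.exp(eta.etaV)),
        baseline=baseline,
    )
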