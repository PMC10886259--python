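"""Model parameters for the tumor-immune radioembolization/ICI system.

The four-compartment model tracks targeted tumor cells (inside the
Y90-perfused territory), non-targeted tumor cells (outside it),
radiation-inactivated tumor cells that persist and present antigen, and
circulating lymphocytes.  All rate constants are per day; cell
compartments are absolute counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, radiosensitivities and PK constants of the model.

    Defaults are the published values for hepatocellular carcinoma; the
    per-patient quantities (``alpha_T``, ``q``, ``delta_durva``) hold the
    population means and are overridden per virtual subject.

    Attributes
    ----------
    a : float
        Exponential tumor growth rate (1/d).
    f : float
        Lymphocyte decay rate (1/d).
    r : float
        Decay rate of inactivated (radiation-killed) tumor cells (1/d).
    omega1 : float
        Baseline immune kill efficiency (1/d).
    omega2 : float
        Tumor -> lymphocyte recruitment constant (1/d).
    omega3 : float
        Inactivated-tumor -> lymphocyte recruitment constant (1/d).
    g : float
        Geometric saturation constant (cells).
    s : float
        Constant lymphocyte supply (cells/d).
    alpha_beta_ratio : float
        Tumor alpha/beta ratio of the linear-quadratic model (Gy).
    alpha_T : float
        Tumor LQ alpha (1/Gy); population mean.
    alpha_L : float
        Lymphocyte radiosensitivity (1/Gy), linear survival model.
    C_max : float
        ICI maximum concentration scale (mg/kg).
    t_half_ici : float
        ICI (durvalumab) elimination half-life (d).
    delta_durva : float
        Dimensionless ICI effectiveness; population mean.
    t_half_y90 : float
        Y90 physical half-life (d); also the effective half-life since
        the source is never removed.
    q : float
        Dimensionless Y90 effectiveness scaling physical to effective
        dose; population mean.
    k : float
        Unit conversion, J per MeV.
    E_mean : float
        Mean energy emitted per nuclear transition (MeV/dis).
    tumor_density : float
        Tumor cell density (cells/cc).
    """

    a: float = 0.01
    f: float = 0.033
    r: float = 0.14
    omega1: float = 0.119
    omega2: float = 0.003
    omega3: float = 0.009
    g: float = 7.330e10
    s: float = 1.470e8
    alpha_beta_ratio: float = 10.0
    alpha_T: float = 0.148
    alpha_L: float = 0.737
    C_max: float = 10.0
    t_half_ici: float = 21.0
    delta_durva: float = 0.12
    t_half_y90: float = 2.6
    q: float = 0.12
    k: float = 1.6022e-13
    E_mean: float = 0.9267
    tumor_density: float = 1.0e9

    def __post_init__(self) -> None:
        positive = (
            "a", "f", "r", "omega1", "omega2", "omega3", "g", "s",
            "alpha_beta_ratio", "alpha_T", "alpha_L", "C_max",
            "t_half_ici", "t_half_y90", "k", "E_mean", "tumor_density",
        )
        for name in positive:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")
        for name in ("delta_durva", "q"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"parameter {name!r} must lie in [0, 1], got {value!r}")

    @property
    def beta_T(self) -> float:
        """Tumor LQ beta (1/Gy^2), derived as alpha_T / (alpha/beta)."""
        return self.alpha_T / self.alpha_beta_ratio

    @property
    def lymphocyte_steady_state(self) -> float:
        """Tumor-free lymphocyte equilibrium s/f (cells)."""
        return self.s / self.f

    def with_(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


DEFAULT_PARAMETERS = ModelParameters()
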