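"""Material and electroporation parameters of the single-cell model.

The cell is a prolate spheroid of conductive cytoplasm inside a conductive
extracellular bath; the membrane enters only through a thin-layer (contact
impedance) boundary condition, so the parameter set is: bulk conductivities
and relative permittivities for the two volumes, the passive membrane
conductivity and permittivity, the membrane thickness, and the constants of
the asymptotic pore-density equation (creation-rate density ``alpha``,
characteristic voltage ``V_ep``, equilibrium density ``N0``, electroporation
constant ``q``, single-pore radius ``r_p``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = ["MaterialParams", "default_params", "pore_conductivity", "EPS0"]

#: Vacuum permittivity, F/m (CODATA).
EPS0 = 8.8541878128e-12


def pore_conductivity(sigma_e: float, sigma_i: float) -> float:
    """Effective conductivity of a single aqueous pore, S/m.

    The pore spans the membrane and connects media of conductivity
    ``sigma_i`` and ``sigma_e``; its effective conductivity is the
    logarithmic mean

        sigma_p = (sigma_e - sigma_i) / ln(sigma_e / sigma_i)

    which lies strictly between the two bulk values.  For equal inputs the
    continuous limit (their common value) is returned.

    Raises
    ------
    ValueError
        If either conductivity is not strictly positive.
    """
    if sigma_e <= 0.0 or sigma_i <= 0.0:
        raise ValueError(
            f"conductivities must be > 0, got sigma_e={sigma_e}, sigma_i={sigma_i}"
        )
    if sigma_e == sigma_i:
        return float(sigma_e)
    return (sigma_e - sigma_i) / math.log(sigma_e / sigma_i)


@dataclass(frozen=True)
class MaterialParams:
    """Electrical and electroporation parameters of the cell model.

    Attributes
    ----------
    eps_i, eps_e, eps_m :
        Relative permittivities of the intracellular space, the
        extracellular space and the membrane (dimensionless).
    sigma_i, sigma_e :
        Bulk conductivities of cytoplasm and bath, S/m.
    sigma_m0 :
        Conductivity of the non-electroporated membrane, S/m.
    r_p :
        Radius of a single pore, m (fixed; no pore growth is modelled).
    alpha :
        Pore creation-rate density, m^-2 s^-1.
    V_ep :
        Characteristic electroporation voltage, V.
    N0 :
        Equilibrium pore density at zero transmembrane voltage, m^-2.
    q :
        Electroporation constant (dimensionless).
    d_m :
        Membrane thickness, m.
    eps0 :
        Vacuum permittivity, F/m.
    sigma_p_override :
        If not None, pins the pore conductivity to the given value instead
        of the logarithmic mean of ``sigma_e`` and ``sigma_i``.
    """

    eps_i: float = 80.0
    eps_e: float = 80.0
    eps_m: float = 5.0
    sigma_i: float = 0.3
    sigma_e: float = 1.0
    sigma_m0: float = 0.3e-6
    r_p: float = 0.76e-9
    alpha: float = 1e9
    V_ep: float = 0.258
    N0: float = 1.5e9
    q: float = 1.46
    d_m: float = 10e-9
    eps0: float = EPS0
    sigma_p_override: float | None = None

    def __post_init__(self) -> None:
        positive = (
            "eps_i", "eps_e", "eps_m", "sigma_i", "sigma_e", "sigma_m0",
            "r_p", "alpha", "V_ep", "N0", "q", "d_m", "eps0",
        )
        for name in positive:
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.sigma_p_override is not None and self.sigma_p_override <= 0.0:
            raise ValueError("sigma_p_override must be > 0 when given")

    @property
    def sigma_p(self) -> float:
        """Pore conductivity, S/m (logarithmic mean unless overridden)."""
        if self.sigma_p_override is not None:
            return self.sigma_p_override
        return pore_conductivity(self.sigma_e, self.sigma_i)

    @property
    def c_m(self) -> float:
        """Specific membrane capacitance eps0*eps_m/d_m, F/m^2."""
        return self.eps0 * self.eps_m / self.d_m

    # -- config serialization ------------------------------------------------

    def to_config(self) -> dict:
        """Serialize to a plain ``material:`` config mapping."""
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "sigma_p_override" and v is None:
                continue
            out[f.name] = v
        return out

    @classmethod
    def from_config(cls, section: dict | None) -> "MaterialParams":
        """Build from a ``material:`` config section.

        Missing keys fall back to the defaults; unknown keys raise.
        """
        section = dict(section or {})
        known = {f.name for f in fields(cls)}
        unknown = set(section) - known
        if unknown:
            raise ValueError(
                f"unknown material parameter(s): {sorted(unknown)}; "
                f"expected a subset of {sorted(known)}"
            )
        return cls(**section)

    def with_(self, **kwargs) -> "MaterialParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_params() -> MaterialParams:
    """The default parameter set used throughout the numerical study."""
    return MaterialParams()
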