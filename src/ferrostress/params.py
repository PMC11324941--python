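"""Physical parameters of the magneto-poro-elastic tumor model.

Every constant used anywhere in the pipeline lives in :class:`ParamSet`:
poroelastic moduli, Starling exchange coefficients, power-law blood
rheology, magnet/ferrofluid permeabilities and the 2D geometry scalars
(tumor disk, capillary ring, feeder vessels, tissue rectangle).

Two scalars required by Starling's law are not part of the published
value set and carry implementer defaults, loudly marked as such:

* ``P_L`` — lymphatic hydrostatic pressure, default 0 Pa (lymphatics
  drain at ambient/gauge pressure, the standard convention);
* ``pi_B`` — blood colloid osmotic pressure, default 2666 Pa (typical
  plasma oncotic pressure, ~20 mmHg).

Both are ordinary config keys and can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import yaml

REGIONS = ("tumor", "healthy")

#: vacuum magnetic permeability (H/m)
MU_0 = 4.0e-7 * math.pi

#: ferrofluid volume fraction at which the tabulated mixture
#: permeability (1.3) applies; anchors the linear mixing rule
PHI_REF = 0.5


class ParamError(ValueError):
    """Raised when a parameter value violates a model invariant."""


def _region_map(tumor: float, healthy: float) -> dict:
    return {"tumor": tumor, "healthy": healthy}


@dataclass
class ParamSet:
    """Validated physical parameter set (SI units throughout).

    Region-dependent coefficients are ``{"tumor": ..., "healthy": ...}``
    maps; the lymph filtration coefficient is zero in the tumor because
    tumor tissue lacks functional lymphatics (source-only region).
    """

    # porous-medium volume fractions
    eps_i: float = 0.5        # interstitial fluid fraction
    eps_t: float = 0.5        # solid (cells + matrix) fraction

    # densities (kg/m^3)
    rho_i: float = 1020.0
    rho_B: float = 1060.0
    rho_t: float = 1045.0

    # interstitial fluid
    mu_i: float = 1.32        # dynamic viscosity (Pa s)
    k_over_mu_i: dict = field(
        default_factory=lambda: _region_map(30e-15, 6.41e-15)
    )                          # hydraulic conductivity (m^2/Pa/s)

    # drained linear-elastic moduli (Pa), identical in both regions
    lam: float = 91192.0
    mu_lame: float = 2026.5

    # Starling transvascular exchange
    LpS_over_V: dict = field(
        default_factory=lambda: _region_map(42.2e-8, 18.9e-9)
    )                          # blood filtration coefficient (1/Pa/s)
    LpLSL_over_V: dict = field(
        default_factory=lambda: _region_map(0.0, 1.0e-7)
    )                          # lymph filtration coefficient (1/Pa/s)
    delta_B: dict = field(default_factory=lambda: _region_map(0.82, 0.91))
    pi_i: dict = field(default_factory=lambda: _region_map(1999.83, 1333.0))
    pi_B: float = 2666.0      # implementer default, see module docstring
    P_L: float = 0.0          # implementer default, see module docstring

    # vascular boundary pressures (Pa, gauge)
    P_inlet: float = 2080.0
    P_outlet: float = 0.0

    # power-law blood rheology: mu_B = m_pl * gamma_dot**(n_pl - 1)
    m_pl: float = 0.035
    n_pl: float = 0.6

    # magnetics
    mu_r_magnet: float = 1.0
    mu_r_ferrofluid: float = 1.3   # mixture value at phi_ff = PHI_REF
    mu_0: float = MU_0
    phi_ff: float = 0.5

    # geometry scalars (m)
    d_t: float = 0.01         # tumor diameter
    R_t: float = 0.005        # tumor radius
    d_c: float = 0.00025      # capillary-ring thickness
    d_a: float = 0.0015       # feeder-vessel width
    L_t: float = 0.025        # tissue rectangle length (x)
    W_t: float = 0.02         # tissue rectangle width (y)

    def __post_init__(self):
        self.validate()

    # -- validation --------------------------------------------------

    def validate(self) -> None:
        if not 0.0 < self.eps_i < 1.0:
            raise ParamError(f"eps_i must lie in (0, 1), got {self.eps_i}")
        if abs(self.eps_i + self.eps_t - 1.0) > 1e-12:
            raise ParamError(
                f"eps_i + eps_t must equal 1, got {self.eps_i + self.eps_t}"
            )
        if not 0.0 < self.n_pl <= 1.0:
            raise ParamError(f"n_pl must lie in (0, 1], got {self.n_pl}")
        if self.lam <= 0 or self.mu_lame <= 0:
            raise ParamError("Lame parameters lam, mu_lame must be positive")
        if self.m_pl <= 0:
            raise ParamError("power-law consistency m_pl must be positive")
        if not 0.0 <= self.phi_ff <= 1.0:
            raise ParamError(f"phi_ff must lie in [0, 1], got {self.phi_ff}")
        if self.mu_i <= 0:
            raise ParamError("mu_i must be positive")
        for name in ("LpS_over_V", "LpLSL_over_V", "k_over_mu_i",
                     "delta_B", "pi_i"):
            m = getattr(self, name)
            missing = [r for r in REGIONS if r not in m]
            if missing:
                raise ParamError(f"{name} missing regions {missing}")
        for r in REGIONS:
            if self.LpS_over_V[r] < 0 or self.LpLSL_over_V[r] < 0:
                raise ParamError("filtration coefficients must be >= 0")
            if self.k_over_mu_i[r] <= 0:
                raise ParamError("hydraulic conductivity must be positive")
            if not 0.0 < self.delta_B[r] <= 1.0:
                raise ParamError(
                    f"delta_B[{r}] must lie in (0, 1], got {self.delta_B[r]}"
                )
        if self.LpLSL_over_V["tumor"] != 0.0:
            raise ParamError(
                "lymph filtration coefficient must be zero in the tumor "
                "(tumor tissue has no functional lymphatics)"
            )
        for name in ("d_t", "R_t", "d_c", "d_a", "L_t", "W_t"):
            if getattr(self, name) <= 0:
                raise ParamError(f"geometry scalar {name} must be positive")

    # -- config round trip -------------------------------------------

    def to_config(self) -> dict:
        """Flatten to a plain ``key -> number`` mapping."""
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, dict):
                for r in REGIONS:
                    out[f"{f.name}.{r}"] = v[r]
            else:
                out[f.name] = v
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=True)

    def copy(self, **overrides) -> "ParamSet":
        return replace(self, **overrides)


def _apply_overrides(cfg: dict) -> ParamSet:
    scalar = {f.name: f for f in fields(ParamSet)}
    kwargs: dict = {}
    region_kwargs: dict = {}
    for key, value in cfg.items():
        if "." in key:
            base, _, region = key.partition(".")
            if base not in scalar or region not in REGIONS:
                raise ParamError(f"unknown config key: {key!r}")
            region_kwargs.setdefault(base, {})[region] = float(value)
        elif key in scalar:
            kwargs[key] = float(value)
        else:
            raise ParamError(f"unknown config key: {key!r}")
    p = ParamSet.__new__(ParamSet)
    defaults = ParamSet()
    for f in fields(ParamSet):
        if f.name in region_kwargs:
            merged = dict(getattr(defaults, f.name))
            merged.update(region_kwargs[f.name])
            setattr(p, f.name, merged)
        elif f.name in kwargs:
            setattr(p, f.name, kwargs[f.name])
        else:
            v = getattr(defaults, f.name)
            setattr(p, f.name, dict(v) if isinstance(v, dict) else v)
    p.validate()
    return p


def load_params(config_path=None) -> ParamSet:
    """Load a :class:`ParamSet`, optionally overridden by a flat YAML file.

    Keys absent from the file keep their defaults; unknown keys and
    invariant violations raise :class:`ParamError`.
    """
    if config_path is None:
        return ParamSet()
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParamError("config must be a flat key -> number mapping")
    return _apply_overrides(cfg)


def stress_scale(p: ParamSet) -> float:
    """Pressure/stress scale ``2*mu + lam`` (Pa).

    Used to nondimensionalize interstitial pressure (Pi* = Pi/(2mu+lam))
    and von Mises stress (sigma* = sigma/(2mu+lam)).
    """
    return 2.0 * p.mu_lame + p.lam


def effective_permeability(p: ParamSet, phi_ff: float) -> float:
    """Relative permeability of the blood + ferrofluid mixture.

    Linear mixing rule ``mu_r = 1 + phi_ff * chi_p`` with the particle
    susceptibility contribution ``chi_p`` anchored so that the mixture
    value equals ``p.mu_r_ferrofluid`` at the reference volume fraction
    ``PHI_REF`` (1.3 at phi_ff = 0.5, hence chi_p = 0.6).  Plasma alone
    (phi_ff = 0) is non-magnetic.
    """
    if not 0.0 <= phi_ff <= 1.0:
        raise ParamError(f"phi_ff must lie in [0, 1], got {phi_ff}")
    chi_p = (p.mu_r_ferrofluid - 1.0) / PHI_REF
    return 1.0 + phi_ff * chi_p
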