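"""Physical core: optical depth, the Beer–Lambert forward model, gravimetry.

The measurement principle: at 2.55 THz a leaf attenuates light almost entirely
through its water, so the optical depth

    tau = ln(I0 / I_Tr)

obeys Beer–Lambert, tau = alpha * d_w, where alpha is the water absorption
coefficient (~500 cm^-1 in this spectral region) and d_w is the *effective
water thickness*: the leaf's water volume spread over its projected area,
d_w = M_w / (rho_w * L_A). Eliminating d_w gives the working forward model

    tau = (K * M_w + C0) / L_A,        K = alpha / rho_w,

where the intercept C0 (cm^2, entering as tau*L_A = C1*M_w + C0) absorbs
residual absorption/scattering by dry matter. With C0 = 0 this is the pure
water-slab model.

Intensities are unitless detector counts; no radiometric calibration is
attempted. All functions accept scalars or numpy arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    DomainError,
    GravimetryError,
    InvalidIntensityError,
    NegativeOpticalDepthWarning,
    ProtocolError,
)

__all__ = [
    "SPECIES_CODES",
    "SMALL_LEAF_SPECIES",
    "PhysicalConstants",
    "ForwardModelParams",
    "TransmissionRecord",
    "LeafRecord",
    "average_incident",
    "aggregate_transmission",
    "optical_depth",
    "tau_from_transmission",
    "forward_tau",
    "invert_tau",
    "effective_water_thickness",
    "water_mass",
    "specific_leaf_area",
    "validate_protocol",
]

#: Species codes of the six broadleaf species the study design covers:
#: Corylus avellana, Ostrya carpinifolia, Quercus suber, Vitis vinifera,
#: Quercus ilex, Laurus nobilis.
SPECIES_CODES = ("C_A", "O_C", "Q_S", "V_V", "Q_I", "L_N")

#: Species whose leaves are too small for the full four-point transmission
#: protocol; two points are measured instead.
SMALL_LEAF_SPECIES = frozenset({"Q_S"})


def _check_positive_intensity(value, name: str) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise InvalidIntensityError(
            f"{name} must be strictly positive and finite, got {value!r}"
        )


@dataclass(frozen=True)
class PhysicalConstants:
    """Water optics constants at the 2.55 THz operating point.

    alpha
        Water absorption coefficient, cm^-1. ~500 cm^-1 at 2.55 THz.
    rho_w
        Density of liquid water, mg cm^-3 (~1000).
    """

    alpha: float = 500.0
    rho_w: float = 1000.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.rho_w <= 0:
            raise DomainError("alpha and rho_w must be strictly positive")

    @property
    def K(self) -> float:
        """Implied forward-model slope alpha/rho_w, cm^2 mg^-1."""
        return self.alpha / self.rho_w


@dataclass(frozen=True)
class ForwardModelParams:
    """Slope/intercept of the linear attenuation model.

    K
        Slope, cm^2 mg^-1 (the fitted C1, or alpha/rho_w for pure water).
    C0
        Intercept in tau*L_A space, cm^2; residual dry-matter absorption.
        Stored here so tau = (K*M_w + C0)/L_A covers both the zero-intercept
        and the intercept form with one code path.
    """

    K: float
    C0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.K) or self.K <= 0:
            raise DomainError(f"slope K must be strictly positive, got {self.K}")


@dataclass(frozen=True)
class TransmissionRecord:
    """Raw intensity readings for one leaf.

    The protocol takes the incident beam intensity twice (before and after
    the leaf measurements) and the transmitted intensity at four points on
    the adaxial blade — two points for small-leaved species.
    """

    I0_before: float
    I0_after: float
    I_tr_points: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "I_tr_points", tuple(float(x) for x in self.I_tr_points))
        _check_positive_intensity(self.I0_before, "I0_before")
        _check_positive_intensity(self.I0_after, "I0_after")
        if len(self.I_tr_points) not in (2, 4):
            raise ProtocolError(
                f"expected 2 or 4 transmission points, got {len(self.I_tr_points)}"
            )
        for x in self.I_tr_points:
            _check_positive_intensity(x, "transmitted intensity")

    @property
    def n_points(self) -> int:
        return len(self.I_tr_points)


@dataclass
class LeafRecord:
    """One leaf's identity, masses (mg), area (cm^2) and optical depth.

    fresh_mass and dry_mass come from the gravimetric protocol (weigh
    immediately, oven-dry at 105 °C, reweigh 24 h later); water mass and
    specific leaf area are derived.
    """

    species_code: str
    leaf_id: str
    fresh_mass: float
    dry_mass: float
    leaf_area: float | None = None
    tau: float | None = None
    plant_id: str | None = None
    image_path: str | None = None

    def __post_init__(self) -> None:
        if self.species_code not in SPECIES_CODES:
            raise DomainError(
                f"unknown species code {self.species_code!r}; expected one of {SPECIES_CODES}"
            )
        if not (np.isfinite(self.fresh_mass) and np.isfinite(self.dry_mass)):
            raise DomainError("masses must be finite")
        if self.dry_mass <= 0:
            raise DomainError(f"dry mass must be positive, got {self.dry_mass}")
        if self.dry_mass > self.fresh_mass:
            raise GravimetryError(
                f"dry mass {self.dry_mass} exceeds fresh mass {self.fresh_mass}"
            )
        if self.leaf_area is not None and self.leaf_area <= 0:
            raise DomainError(f"leaf area must be positive, got {self.leaf_area}")

    @property
    def water_mass(self) -> float:
        """M_w = fresh - dry, mg."""
        return self.fresh_mass - self.dry_mass

    @property
    def sla(self) -> float:
        """Specific leaf area L_A / dry mass, cm^2 mg^-1."""
        if self.leaf_area is None:
            raise DomainError("leaf area is not set; cannot compute SLA")
        return self.leaf_area / self.dry_mass

    @property
    def tau_la(self) -> float:
        """The calibration response tau * L_A, cm^2."""
        if self.tau is None or self.leaf_area is None:
            raise DomainError("tau and leaf area must both be set")
        return self.tau * self.leaf_area


def average_incident(i0_before, i0_after):
    """Mean of the incident-beam readings taken before and after the leaf."""
    _check_positive_intensity(i0_before, "I0_before")
    _check_positive_intensity(i0_after, "I0_after")
    return (np.asarray(i0_before, dtype=float) + np.asarray(i0_after, dtype=float)) / 2.0


def aggregate_transmission(points: Sequence[float]):
    """Mean of the per-point transmitted intensities (2 or 4 points)."""
    pts = np.asarray(list(points), dtype=float)
    if pts.size not in (2, 4):
        raise ProtocolError(f"expected 2 or 4 transmission points, got {pts.size}")
    _check_positive_intensity(pts, "transmitted intensity")
    return float(pts.mean())


def optical_depth(i0_mean, itr_mean):
    """tau = ln(I0 / I_Tr).

    A transmitted intensity above the incident one yields tau < 0; that is
    physically possible under source drift or detector noise, so it is
    flagged with :class:`NegativeOpticalDepthWarning` rather than raised.
    """
    _check_positive_intensity(i0_mean, "I0")
    _check_positive_intensity(itr_mean, "I_Tr")
    tau = np.log(np.asarray(i0_mean, dtype=float) / np.asarray(itr_mean, dtype=float))
    if np.any(tau < 0):
        warnings.warn(
            "transmitted intensity exceeds incident intensity; optical depth < 0",
            NegativeOpticalDepthWarning,
            stacklevel=2,
        )
    if tau.ndim == 0:
        return float(tau)
    return tau


def tau_from_transmission(rec: TransmissionRecord, method: str = "pooled") -> float:
    """Per-leaf optical depth from a raw transmission record.

    method="pooled" (default): intensities are averaged before the log,
    tau = ln(mean I0 / mean I_Tr), mirroring how the protocol defines I0 and
    I_Tr as averages. method="per_point": mean of ln(mean I0 / I_Tr,i)
    across points. By concavity of the log the pooled value never exceeds
    the per-point mean.
    """
    i0 = average_incident(rec.I0_before, rec.I0_after)
    if method == "pooled":
        return optical_depth(i0, aggregate_transmission(rec.I_tr_points))
    if method == "per_point":
        return float(np.mean([optical_depth(i0, x) for x in rec.I_tr_points]))
    raise ValueError(f"unknown method {method!r}; expected 'pooled' or 'per_point'")


def forward_tau(m_w, l_a, params: ForwardModelParams):
    """Forward model tau = (K*M_w + C0) / L_A."""
    m_w = np.asarray(m_w, dtype=float)
    l_a = np.asarray(l_a, dtype=float)
    if np.any(m_w < 0):
        raise DomainError("water mass must be non-negative")
    if np.any(l_a <= 0):
        raise DomainError("leaf area must be strictly positive")
    out = (params.K * m_w + params.C0) / l_a
    return float(out) if out.ndim == 0 else out


def invert_tau(tau, l_a, params: ForwardModelParams):
    """Algebraic inverse of :func:`forward_tau`: M_w = (tau*L_A - C0)/K."""
    l_a = np.asarray(l_a, dtype=float)
    if np.any(l_a <= 0):
        raise DomainError("leaf area must be strictly positive")
    out = (np.asarray(tau, dtype=float) * l_a - params.C0) / params.K
    return float(out) if out.ndim == 0 else out


def effective_water_thickness(m_w, l_a, constants: PhysicalConstants = PhysicalConstants()):
    """d_w = M_w / (rho_w * L_A): thickness (cm) of an equivalent pure-water slab."""
    m_w = np.asarray(m_w, dtype=float)
    l_a = np.asarray(l_a, dtype=float)
    if np.any(m_w < 0):
        raise DomainError("water mass must be non-negative")
    if np.any(l_a <= 0):
        raise DomainError("leaf area must be strictly positive")
    out = m_w / (constants.rho_w * l_a)
    return float(out) if out.ndim == 0 else out


def water_mass(fresh, dry):
    """M_w = fresh - dry, mg (oven-drying gravimetry)."""
    fresh = np.asarray(fresh, dtype=float)
    dry = np.asarray(dry, dtype=float)
    if np.any(dry <= 0) or np.any(fresh <= 0):
        raise DomainError("masses must be strictly positive")
    if np.any(dry > fresh):
        raise GravimetryError("dry mass exceeds fresh mass")
    out = fresh - dry
    return float(out) if out.ndim == 0 else out


def specific_leaf_area(l_a, dry):
    """SLA = L_A / dry mass, cm^2 mg^-1; low SLA flags thick/waxy leaves."""
    l_a = np.asarray(l_a, dtype=float)
    dry = np.asarray(dry, dtype=float)
    if np.any(l_a <= 0) or np.any(dry <= 0):
        raise DomainError("leaf area and dry mass must be strictly positive")
    out = l_a / dry
    return float(out) if out.ndim == 0 else out


def validate_protocol(species_code: str, n_points: int, strict: bool = True) -> None:
    """Check the point count against the species' protocol.

    Four transmission points per leaf, except two for species flagged
    small-leaved (Q. suber). With strict=False any valid count (2 or 4)
    passes for any species.
    """
    if n_points not in (2, 4):
        raise ProtocolError(f"n_points must be 2 or 4, got {n_points}")
    if not strict:
        return
    expected = 2 if species_code in SMALL_LEAF_SPECIES else 4
    if n_points != expected:
        raise ProtocolError(
            f"species {species_code} expects {expected} transmission points, got {n_points}"
        )
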