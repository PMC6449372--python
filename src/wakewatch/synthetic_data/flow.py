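"""Steady channel flow with a log-law vertical structure.

The vertical profile of horizontal current speed over a rough bed follows the
law of the wall,

    u(h) = (u* / kappa) * ln(h / z0),   z0 <= h <= H,

where ``u*`` is the bed friction velocity, ``kappa`` the von Karman constant,
``z0`` the bed roughness length, ``h`` height above the bed and ``H`` the
water depth.  Below ``z0`` the profile is clamped to u(z0) = 0 (documented
clamp), and negative values are clipped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FlowFieldConfig", "FlowField", "UniformFlowField", "generate_flow_field"]


@dataclass
class FlowFieldConfig:
    """Configuration of a steady, unidirectional open-channel flow.

    Parameters
    ----------
    channel_length : m, streamwise extent of the domain.
    water_depth : m.
    u_star : m s-1, bed friction velocity.
    z0 : m, bed roughness length.
    kappa : von Karman constant (0.41).
    horizontal_dispersion_scaling : dimensionless multiplier applied to the
        horizontal dispersion field (default 1.0).
    vertical_dispersion : m2 s-1, constant vertical dispersion (default 0.01).
    horizontal_dispersion : m2 s-1, constant horizontal dispersion before
        scaling (a full eddy-viscosity field may be attached to the resulting
        :class:`FlowField` instead).
    """

    channel_length: float = 5000.0
    water_depth: float = 25.0
    u_star: float = 0.1
    z0: float = 0.001
    kappa: float = 0.41
    horizontal_dispersion_scaling: float = 1.0
    vertical_dispersion: float = 0.01
    horizontal_dispersion: float = 0.01

    def validate(self) -> None:
        if not (self.z0 > 0 and self.z0 < self.water_depth):
            raise ValueError(
                f"roughness length z0={self.z0} must satisfy 0 < z0 < depth="
                f"{self.water_depth}"
            )
        if self.u_star < 0:
            raise ValueError(f"friction velocity u*={self.u_star} must be >= 0")
        if self.vertical_dispersion < 0 or self.horizontal_dispersion < 0:
            raise ValueError("dispersion coefficients must be >= 0")
        if self.channel_length <= 0 or self.water_depth <= 0:
            raise ValueError("channel_length and water_depth must be > 0")


@dataclass
class FlowField:
    """Steady unidirectional flow over ``0 <= x <= channel_length``.

    Two vertical conventions coexist in the field and both are exposed:
    ``speed_at_height(h)`` takes height above the bed (the natural log-law
    coordinate), while ``velocity(x, z)`` takes depth below the surface (the
    coordinate in which particles are released and reflected).
    """

    config: FlowFieldConfig = field(default_factory=FlowFieldConfig)

    @property
    def depth(self) -> float:
        return self.config.water_depth

    def speed_at_height(self, h):
        """Log-law speed at height ``h`` above the bed; h < z0 clamps to z0."""
        cfg = self.config
        h = np.maximum(np.asarray(h, dtype=float), cfg.z0)
        u = (cfg.u_star / cfg.kappa) * np.log(h / cfg.z0)
        return np.maximum(u, 0.0)

    def velocity(self, x, z):
        """Horizontal speed at depth ``z`` below the surface (m s-1)."""
        h = self.depth - np.asarray(z, dtype=float)
        return self.speed_at_height(h)

    def horizontal_dispersion(self, x, z):
        """Dh(x, z), m2 s-1: scaled constant unless a field is attached."""
        cfg = self.config
        base = cfg.horizontal_dispersion_scaling * cfg.horizontal_dispersion
        return np.broadcast_to(base, np.broadcast(np.asarray(x), np.asarray(z)).shape).copy()

    @property
    def vertical_dispersion(self) -> float:
        return self.config.vertical_dispersion

    def depth_averaged_speed(self) -> float:
        """Analytic depth average of the log profile over [z0, H]."""
        cfg = self.config
        H, z0 = cfg.water_depth, cfg.z0
        # (1/H) * int_{z0}^{H} (u*/k) ln(h/z0) dh = (u*/k)(ln(H/z0) - 1 + z0/H)
        return max(
            (cfg.u_star / cfg.kappa) * (np.log(H / z0) - 1.0 + z0 / H), 0.0
        )


def generate_flow_field(config: FlowFieldConfig) -> FlowField:
    """Build a steady log-law channel flow from its configuration."""
    config.validate()
    return FlowField(config=config)


@dataclass
class UniformFlowField(FlowField):
    """Depth-uniform flow, handy for analytic transit-time checks."""

    speed: float = 1.0

    def speed_at_height(self, h):
        return np.broadcast_to(float(self.speed), np.asarray(h, dtype=float).shape).copy()

    def velocity(self, x, z):
        shape = np.broadcast(np.asarray(x), np.asarray(z)).shape
        return np.broadcast_to(float(self.speed), shape).copy()

    def depth_averaged_speed(self) -> float:
        return float(self.speed)
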