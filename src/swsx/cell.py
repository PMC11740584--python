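"""Unit-cell geometry: metric tensors, d-spacings and orthogonalization.

All resolution bookkeeping in the package goes through ``d_spacing`` /
``s_from_d`` so that the reciprocal-space metric is defined in exactly one
place.  The convention used throughout is ``s = sin(theta)/lambda = 1/(2d)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = ["UnitCell", "d_spacing", "s_from_d"]


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell (lengths in Angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180)")
        # reject degenerate metrics (e.g. alpha+beta+gamma >= 360)
        if np.linalg.det(self.metric) <= 0:
            raise ValueError("cell angles give a non-positive-definite metric")

    @cached_property
    def metric(self) -> np.ndarray:
        """Direct-space metric tensor G (3x3)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @cached_property
    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G* = G^-1."""
        return np.linalg.inv(self.metric)

    @cached_property
    def volume(self) -> float:
        return float(np.sqrt(np.linalg.det(self.metric)))

    @cached_property
    def orthogonalization(self) -> np.ndarray:
        """Matrix O mapping fractional to Cartesian coordinates (PDB convention)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = self.volume / (a * b * c)
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, c * v / sg],
            ]
        )

    @cached_property
    def recip_basis(self) -> np.ndarray:
        """Matrix A whose product A @ h gives the reciprocal vector in 1/Angstrom."""
        return np.linalg.inv(self.orthogonalization).T

    def d(self, hkl) -> np.ndarray | float:
        return d_spacing(self, hkl)

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def d_spacing(cell: UnitCell, hkl) -> np.ndarray | float:
    """Resolution d (Angstrom) of one or many Miller indices.

    ``hkl`` may be a length-3 sequence or an (N, 3) array.  Raises
    ``ValueError`` on the zero index triple.
    """
    h = np.asarray(hkl, dtype=float)
    scalar = h.ndim == 1
    h = np.atleast_2d(h)
    inv_d2 = np.einsum("ni,ij,nj->n", h, cell.reciprocal_metric, h)
    if np.any(inv_d2 <= 0):
        raise ValueError("d-spacing undefined for the (0,0,0) index")
    d = 1.0 / np.sqrt(inv_d2)
    return float(d[0]) if scalar else d


def s_from_d(d) -> np.ndarray | float:
    """sin(theta)/lambda from resolution: s = 1/(2d)."""
    return 0.5 / np.asarray(d) if np.ndim(d) else 0.5 / d
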