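"""Point-group symmetry on Miller indices.

Canonical unique keys are defined as the lexicographically greatest index over
all point-group images (and over the Friedel mate when Friedel merging is on),
which avoids hand-coded asymmetric-unit boundary tables.  Operator presets for
the point groups 1, 2, 222, 422, 622 and 23 are extracted from the rotation
parts of representative space groups via gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import gemmi
import numpy as np

__all__ = ["PointGroup", "point_group", "to_asu", "POINT_GROUP_PRESETS"]

# representative (primitive, symmorphic) space group per shipped point group
POINT_GROUP_PRESETS = {
    "1": "P1",
    "2": "P2",
    "222": "P222",
    "422": "P422",
    "622": "P622",
    "23": "P23",
}


@dataclass(frozen=True)
class PointGroup:
    """A point group acting on (h,k,l) by integer 3x3 matrices.

    ``ops`` has shape (n_ops, 3, 3); ``ops[i] @ h`` is the image of the column
    vector h.  ``friedel`` records whether -h is adjoined when building merged
    unique keys (set per call in :func:`to_asu`, stored here as the default).
    """

    name: str
    ops: np.ndarray = field(repr=False)
    friedel: bool = True

    def __post_init__(self) -> None:
        ops = np.asarray(self.ops, dtype=int)
        object.__setattr__(self, "ops", ops)
        if ops.ndim != 3 or ops.shape[1:] != (3, 3):
            raise ValueError("ops must have shape (n, 3, 3)")
        dets = np.round(np.linalg.det(ops)).astype(int)
        if not np.all(np.abs(dets) == 1):
            raise ValueError("all operators must have determinant +/-1")
        if not any(np.array_equal(m, np.eye(3, dtype=int)) for m in ops):
            raise ValueError("point group must contain the identity")
        # closure check
        keys = {m.tobytes() for m in ops}
        for m1 in ops:
            for m2 in ops:
                if (m1 @ m2).tobytes() not in keys:
                    raise ValueError("operator set is not closed under multiplication")

    @property
    def n_ops(self) -> int:
        return len(self.ops)

    def multiplicity(self, with_friedel: bool = True) -> int:
        return self.n_ops * (2 if with_friedel else 1)


@lru_cache(maxsize=None)
def point_group(name: str) -> PointGroup:
    """Return a shipped point-group preset by name ('1', '2', '222', '422', '622', '23')."""
    if name not in POINT_GROUP_PRESETS:
        raise ValueError(
            f"unknown point group {name!r}; shipped presets: "
            + ", ".join(sorted(POINT_GROUP_PRESETS))
        )
    sg = gemmi.SpaceGroup(POINT_GROUP_PRESETS[name])
    basis = np.eye(3, dtype=int)
    mats = []
    for op in sg.operations():
        # column j of M is the image of the j-th reciprocal basis vector
        cols = [op.apply_to_hkl(tuple(int(x) for x in basis[j])) for j in range(3)]
        mats.append(np.array(cols, dtype=int).T)
    uniq = {m.tobytes(): m for m in mats}
    return PointGroup(name=name, ops=np.stack(list(uniq.values())))


def _lex_rank(images: np.ndarray) -> np.ndarray:
    """Scalar rank such that lexicographic order on (h,k,l) is preserved."""
    m = int(np.abs(images).max(initial=0)) + 1
    base = 2 * m + 1
    h, k, l = images[..., 0], images[..., 1], images[..., 2]
    return ((h + m) * base + (k + m)) * base + (l + m)


def _orbit_rep(pg: PointGroup, hkl: np.ndarray) -> np.ndarray:
    """Lexicographically greatest image of each row of hkl under pg.ops."""
    images = np.einsum("oij,nj->noi", pg.ops, hkl)
    rank = _lex_rank(images)
    best = np.argmax(rank, axis=1)
    return images[np.arange(len(hkl)), best]


def to_asu(
    pg: PointGroup, hkl, friedel_merge: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Map Miller indices to canonical asymmetric-unit representatives.

    With ``friedel_merge`` on, the representative is the lexicographic maximum
    over the orbit of h and of -h, and the sign is always +1.  With it off,
    the representative is taken over the orbit of h alone and
    ``friedel_sign`` is -1 iff the orbit of -h carries the greater
    representative (i.e. h belongs to the "minus" branch of its Bijvoet pair).

    Accepts a single (3,) index or an (N, 3) array; returns (asu, sign) with
    matching leading shape.
    """
    h = np.asarray(hkl, dtype=int)
    scalar = h.ndim == 1
    h = np.atleast_2d(h)
    if np.any(np.all(h == 0, axis=1)):
        raise ValueError("the (0,0,0) index has no asymmetric-unit representative")
    rep_plus = _orbit_rep(pg, h)
    rep_minus = _orbit_rep(pg, -h)
    sign = np.where(_lex_rank(rep_plus) >= _lex_rank(rep_minus), 1, -1)
    if friedel_merge:
        asu = np.where(sign[:, None] > 0, rep_plus, rep_minus)
        sign = np.ones(len(h), dtype=int)
    else:
        asu = rep_plus
    if scalar:
        return asu[0], int(sign[0])
    return asu, sign


def bijvoet_key(pg: PointGroup, hkl) -> tuple[np.ndarray, np.ndarray]:
    """Friedel-folded unique key plus the Bijvoet branch sign of each index.

    The key is shared by both mates of a Bijvoet pair; the sign separates
    them (+1 for the branch containing the key itself, -1 for its mate,
    +1 for centric reflections where the branches coincide).
    """
    h = np.asarray(hkl, dtype=int)
    scalar = h.ndim == 1
    h = np.atleast_2d(h)
    rep_plus = _orbit_rep(pg, h)
    rep_minus = _orbit_rep(pg, -h)
    plus_wins = _lex_rank(rep_plus) >= _lex_rank(rep_minus)
    key = np.where(plus_wins[:, None], rep_plus, rep_minus)
    sign = np.where(plus_wins, 1, -1)
    if scalar:
        return key[0], int(sign[0])
    return key, sign


def is_centric(pg: PointGroup, hkl) -> np.ndarray:
    """True where -h lies in the proper-rotation orbit of h."""
    h = np.atleast_2d(np.asarray(hkl, dtype=int))
    return _lex_rank(_orbit_rep(pg, h)) == _lex_rank(_orbit_rep(pg, -h))
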