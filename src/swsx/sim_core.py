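"""Ground-truth intensity generation and small-wedge rotation-data simulation.

The simulator emulates the statistical structure of SWSX campaigns: many
randomly oriented 1-10 degree wedges per structure, per-crystal scale and
B-factor variation, Poisson photon noise proportional to dose per unit
rotation angle, a multiplicative systematic error shared within each frame,
and (optionally) weak Bijvoet differences and polymorph mixtures with a
prescribed intensity correlation.

Ground truth comes in two modes:

``wilson``
    acentric intensities drawn i.i.d. exponential with mean
    ``C * exp(-2 * B_true * s**2)`` (ideal Wilson statistics);
``model``
    intensities ``|F|**2`` from a toy atomic model with constant per-atom
    scattering strength ``f0`` and optional anomalous corrections ``f'``,
    ``f''``, which makes Bijvoet differences and calculated phases exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .cell import UnitCell, d_spacing, s_from_d
from .symmetry import PointGroup, bijvoet_key, is_centric, point_group

__all__ = [
    "Atom",
    "GroundTruth",
    "PolymorphSet",
    "WedgePlan",
    "WedgeDataset",
    "structure_factors",
    "generate_ground_truth",
    "make_polymorphs",
    "predict_wedge",
    "simulate_wedges",
    "enumerate_hkl_sphere",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """Toy atom: constant scattering strength, no s-dependent form factor."""

    frac_xyz: tuple[float, float, float]
    z_electrons: float
    f_prime: float = 0.0
    f_dblprime: float = 0.0
    b_iso: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.b_iso < 0:
            raise ValueError("b_iso must be non-negative")
        if self.f_dblprime < 0:
            raise ValueError("f_dblprime must be non-negative")


@dataclass
class GroundTruth:
    """True (I+, I-) intensities on the canonical unique reflection set.

    ``table`` is indexed 0..n-1 with columns h, k, l (the Friedel-folded
    canonical key), d, s, centric, i_plus, i_minus.
    """

    cell: UnitCell
    pointgroup: PointGroup
    d_min: float
    mode: str
    table: pd.DataFrame
    model: list[Atom] | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._lookup: dict | None = None

    @property
    def n_unique(self) -> int:
        return len(self.table)

    @property
    def n_unique_anomalous(self) -> int:
        """Count of Friedel-separated uniques (centrics counted once)."""
        cen = int(self.table["centric"].sum())
        return 2 * (len(self.table) - cen) + cen

    def _key_codes(self, h, k, l) -> np.ndarray:
        m = int(max(np.abs(self.table[["h", "k", "l"]]).max().max(), 1)) + 1
        base = 2 * m + 1
        return ((np.asarray(h) + m) * base + (np.asarray(k) + m)) * base + (
            np.asarray(l) + m
        )

    def intensities(self, keys: np.ndarray, signs: np.ndarray) -> np.ndarray:
        """True intensity for Friedel-folded keys with Bijvoet branch signs.

        Unknown keys (outside the table, e.g. beyond d_min) return NaN.
        """
        tab = self.table
        codes = self._key_codes(tab["h"].values, tab["k"].values, tab["l"].values)
        order = np.argsort(codes)
        sorted_codes = codes[order]
        q = self._key_codes(keys[:, 0], keys[:, 1], keys[:, 2])
        pos = np.searchsorted(sorted_codes, q)
        pos = np.clip(pos, 0, len(sorted_codes) - 1)
        found = sorted_codes[pos] == q
        idx = order[pos]
        ip = tab["i_plus"].values[idx]
        im = tab["i_minus"].values[idx]
        out = np.where(np.asarray(signs) > 0, ip, im)
        return np.where(found, out, np.nan)


@dataclass
class PolymorphSet:
    """Polymorph mixture: intensity sets sharing one cell / point group."""

    members: list[GroundTruth]
    target_cc: float
    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if len(p) != len(self.members):
            raise ValueError("one proportion per member required")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("proportions must sum to 1")
        self.proportions = p

    @property
    def cell(self) -> UnitCell:
        return self.members[0].cell

    @property
    def pointgroup(self) -> PointGroup:
        return self.members[0].pointgroup

    @property
    def d_min(self) -> float:
        return self.members[0].d_min


@dataclass(frozen=True)
class WedgePlan:
    """Acquisition parameters for one wedge.

    dose_total is the absorbed dose per crystal (Gy); n0 converts
    (dose per degree x true intensity) into expected photon counts and is a
    free beamline calibration.  sigma_sys is the s.d. of the multiplicative
    log-normal systematic error shared by all observations on a frame.
    """

    wedge_deg: float = 5.0
    frame_deg: float = 0.2
    dose_total: float = 1.0e7
    wavelength: float = 1.0
    n0: float = 2.5e-4
    sigma_sys: float = 0.03
    bg_rate: float = 1.0
    damage_beta: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.wedge_deg <= 360:
            raise ValueError("wedge_deg must lie in (0, 360]")
        n = self.wedge_deg / self.frame_deg
        if abs(n - round(n)) > 1e-6:
            raise ValueError("frame_deg must divide wedge_deg")
        if self.dose_total < 0:
            raise ValueError("dose_total must be non-negative")
        if self.sigma_sys < 0:
            raise ValueError("sigma_sys must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.wedge_deg / self.frame_deg))


@dataclass
class WedgeDataset:
    """Observations from one crystal's wedge plus acquisition metadata.

    ``observations`` columns: h, k, l (as measured), kh, kk, kl (canonical
    Friedel-folded key), sign (Bijvoet branch), s, d, i_obs, sigma, frame,
    phi.
    """

    wedge_id: str
    cell: UnitCell
    pointgroup_name: str
    plan: WedgePlan
    observations: pd.DataFrame
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    polymorph_id: int = 0
    d_min: float | None = None
    # simulation ground truth (NaN for real data)
    true_ln_g: float = float("nan")
    true_b: float = float("nan")

    def __post_init__(self) -> None:
        r = np.asarray(self.orientation, dtype=float)
        if r.shape != (3, 3) or np.abs(r @ r.T - np.eye(3)).max() > 1e-8:
            raise ValueError("orientation must be a 3x3 orthonormal matrix")
        self.orientation = r

    @property
    def pointgroup(self) -> PointGroup:
        return point_group(self.pointgroup_name)

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def with_observations(self, obs: pd.DataFrame) -> "WedgeDataset":
        return replace(self, observations=obs.reset_index(drop=True))


# ---------------------------------------------------------------------------
# structure factors and ground truth
# ---------------------------------------------------------------------------


def structure_factors(
    model: Sequence[Atom],
    cell: UnitCell,
    hkl_list,
    b_overall: float = 0.0,
    anomalous: bool = True,
):
    """Complex F(+h) and F(-h) for a toy atomic model.

    F(h) = sum_j occ_j (f0_j + f'_j + i f''_j) exp(2 pi i h.x_j)
           exp(-(b_iso_j + b_overall) s^2),   s = 1/(2 d).

    F(-h) is computed by an independent summation (not conjugation), so
    Bijvoet differences arise only from f'' > 0.  With ``anomalous=False``
    the f' and f'' terms are dropped (used for calculated phases).
    """
    if len(model) == 0:
        raise ValueError("structure_factors requires a non-empty model")
    hkl = np.atleast_2d(np.asarray(hkl_list, dtype=int))
    s2 = s_from_d(d_spacing(cell, hkl)) ** 2  # (N,)
    xyz = np.array([a.frac_xyz for a in model])  # (M,3)
    occ = np.array([a.occupancy for a in model])
    biso = np.array([a.b_iso for a in model])
    if anomalous:
        f = np.array([a.z_electrons + a.f_prime + 1j * a.f_dblprime for a in model])
    else:
        f = np.array([a.z_electrons + 0.0j for a in model])
    dw = np.exp(-np.outer(s2, biso + b_overall))  # (N,M)
    coef = occ * f  # (M,)

    def _sum(sign: int) -> np.ndarray:
        phase = np.exp(2j * np.pi * (sign * hkl) @ xyz.T)  # (N,M)
        return (phase * dw) @ coef

    return _sum(+1), _sum(-1)


def random_symmetric_model(
    pointgroup: PointGroup | str,
    n_light: int = 120,
    f_light: float = 7.0,
    b_iso: float = 8.0,
    n_anom: int = 1,
    f_anom: float = 16.0,
    f_dblprime: float = 0.243,
    seed: int = 0,
) -> tuple[list[Atom], list[tuple[float, float, float]]]:
    """Random protein-like toy model obeying the point-group symmetry.

    ``n_light`` light atoms (mean protein scattering strength ~7 e-) and
    ``n_anom`` anomalous scatterers (defaults model an S atom at 1 A
    wavelength, f'' = 0.243 e-) are placed at random general positions and
    expanded over the point-group rotations, so simulated intensities
    respect the symmetry exactly.  Returns (atoms, anomalous_sites) where
    the sites are the unexpanded anomalous positions (one per orbit).
    """
    import gemmi

    from .symmetry import POINT_GROUP_PRESETS

    pg = point_group(pointgroup) if isinstance(pointgroup, str) else pointgroup
    sg = gemmi.SpaceGroup(POINT_GROUP_PRESETS[pg.name])
    ops = list(sg.operations())
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    sites: list[tuple[float, float, float]] = []

    def expand(xyz, f0, fpp):
        for op in ops:
            x, y, z = op.apply_to_xyz(list(xyz))
            atoms.append(
                Atom(
                    frac_xyz=(x % 1.0, y % 1.0, z % 1.0),
                    z_electrons=f0,
                    f_dblprime=fpp,
                    b_iso=b_iso,
                )
            )

    for _ in range(n_light):
        expand(rng.random(3), f_light, 0.0)
    for _ in range(n_anom):
        xyz = tuple(rng.random(3))
        sites.append(xyz)
        expand(xyz, f_anom, f_dblprime)
    return atoms, sites


def enumerate_hkl_sphere(cell: UnitCell, d_min: float) -> np.ndarray:
    """All Miller indices (both Friedel hemispheres) with d >= d_min."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hmax = int(np.floor(cell.a / d_min)) + 1
    kmax = int(np.floor(cell.b / d_min)) + 1
    lmax = int(np.floor(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    inv_d2 = np.einsum("ni,ij,nj->n", hkl.astype(float), cell.reciprocal_metric, hkl.astype(float))
    return hkl[inv_d2 <= 1.0 / d_min**2 + 1e-12]


def _unique_keys(cell: UnitCell, pg: PointGroup, d_min: float) -> pd.DataFrame:
    hkl = enumerate_hkl_sphere(cell, d_min)
    keys, _ = bijvoet_key(pg, hkl)
    df = pd.DataFrame(keys, columns=["h", "k", "l"]).drop_duplicates(ignore_index=True)
    kk = df[["h", "k", "l"]].values
    df["d"] = d_spacing(cell, kk)
    df["s"] = s_from_d(df["d"].values)
    df["centric"] = is_centric(pg, kk)
    return df


def generate_ground_truth(
    cell: UnitCell,
    pointgroup: PointGroup | str,
    d_min: float,
    mode: str = "wilson",
    params: dict | None = None,
    seed: int = 0,
    model: Sequence[Atom] | None = None,
    max_reflections: int = 2_000_000,
) -> GroundTruth:
    """Enumerate the unique reflection set to d_min and assign true intensities.

    params (wilson mode): C (mean intensity scale, default 1.0), B_true
    (overall Wilson B in A^2, default 0) and bijvoet_ratio (s.d. of the
    relative Bijvoet difference, default 0; applied to acentrics only).
    """
    pg = point_group(pointgroup) if isinstance(pointgroup, str) else pointgroup
    params = dict(params or {})
    n_sphere = len(enumerate_hkl_sphere(cell, d_min))
    if n_sphere > max_reflections:
        raise ValueError(
            f"{n_sphere} reflections to d_min={d_min} exceeds the cap of {max_reflections}"
        )
    df = _unique_keys(cell, pg, d_min)
    rng = np.random.default_rng(seed)
    if mode == "wilson":
        c_scale = float(params.get("C", 1.0))
        b_true = float(params.get("B_true", 0.0))
        ratio = float(params.get("bijvoet_ratio", 0.0))
        mean = c_scale * np.exp(-2.0 * b_true * df["s"].values ** 2)
        i_mean = rng.exponential(mean)
        delta = rng.normal(0.0, 1.0, size=len(df)) * ratio * i_mean
        delta[df["centric"].values] = 0.0
        df["i_plus"] = np.clip(i_mean + 0.5 * delta, 0.0, None)
        df["i_minus"] = np.clip(i_mean - 0.5 * delta, 0.0, None)
    elif mode == "model":
        if not model:
            raise ValueError("mode='model' requires a non-empty atom list")
        b_overall = float(params.get("b_overall", 0.0))
        keys = df[["h", "k", "l"]].values
        f_plus, f_minus = structure_factors(model, cell, keys, b_overall=b_overall)
        df["i_plus"] = np.abs(f_plus) ** 2
        df["i_minus"] = np.abs(f_minus) ** 2
        model = list(model)
    else:
        raise ValueError("mode must be 'wilson' or 'model'")
    return GroundTruth(
        cell=cell, pointgroup=pg, d_min=d_min, mode=mode, table=df, model=model, params=params
    )


def make_polymorphs(
    gt: GroundTruth,
    n_poly: int,
    target_cc: float,
    proportions=None,
    seed: int = 0,
) -> PolymorphSet:
    """Build a mixture of polymorphs with prescribed intensity correlation.

    Each new member is constructed in complex-amplitude space as
    F2 = rho' F1 + sqrt(1 - rho'^2) F_indep with rho' = sqrt(target_cc);
    for circular complex Gaussian amplitudes the intensity correlation then
    equals |rho'|^2 = target_cc.  The relative Bijvoet signal of the parent
    is carried over unchanged.
    """
    if not 0.0 <= target_cc <= 1.0:
        raise ValueError("target_cc must lie in [0, 1]")
    if n_poly < 1:
        raise ValueError("n_poly must be >= 1")
    if proportions is None:
        proportions = np.full(n_poly, 1.0 / n_poly)
    rng = np.random.default_rng(seed)
    members = [gt]
    tab = gt.table
    i1 = 0.5 * (tab["i_plus"].values + tab["i_minus"].values)
    rel_ano = np.divide(
        tab["i_plus"].values - tab["i_minus"].values,
        i1,
        out=np.zeros_like(i1),
        where=i1 > 0,
    )
    # local mean intensity profile for the independent component
    mu = _shell_mean_profile(tab["s"].values, i1)
    rho = np.sqrt(target_cc)
    for _ in range(1, n_poly):
        if target_cc == 1.0:
            members.append(replace(gt, table=tab.copy()))
            continue
        phase1 = np.exp(2j * np.pi * rng.random(len(tab)))
        f1 = np.sqrt(i1) * phase1
        f_ind = np.sqrt(mu / 2.0) * (
            rng.normal(size=len(tab)) + 1j * rng.normal(size=len(tab))
        )
        i2 = np.abs(rho * f1 + np.sqrt(1.0 - rho**2) * f_ind) ** 2
        new = tab.copy()
        new["i_plus"] = np.clip(i2 * (1.0 + 0.5 * rel_ano), 0.0, None)
        new["i_minus"] = np.clip(i2 * (1.0 - 0.5 * rel_ano), 0.0, None)
        members.append(replace(gt, table=new))
    return PolymorphSet(members=members, target_cc=target_cc, proportions=proportions)


def _shell_mean_profile(s: np.ndarray, i: np.ndarray, n_shells: int = 20) -> np.ndarray:
    """Smooth per-reflection mean intensity by resolution shell."""
    order = np.argsort(s)
    edges = np.quantile(s, np.linspace(0, 1, n_shells + 1))
    edges[-1] += 1e-9
    idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_shells - 1)
    means = np.array([i[idx == j].mean() if np.any(idx == j) else np.nan for j in range(n_shells)])
    # fill empty shells with the global mean
    means = np.where(np.isfinite(means), means, np.nanmean(i))
    del order
    return means[idx]


# ---------------------------------------------------------------------------
# rotation-method prediction
# ---------------------------------------------------------------------------


def predict_wedge(
    cell: UnitCell,
    orientation: np.ndarray,
    wavelength: float,
    phi_start: float,
    wedge_deg: float,
    d_min: float,
    frame_deg: float = 0.2,
    hkl: np.ndarray | None = None,
) -> pd.DataFrame:
    """Reflections crossing the Ewald sphere within a rotation wedge.

    Geometry: spindle axis +z, incident beam along +x with wavevector
    s0 = (1/lambda, 0, 0); a reflection h diffracts at spindle angle phi when
    |Rz(phi) R A h + s0| = 1/lambda.  Returns a DataFrame with columns
    h, k, l, phi (deg) and frame; every symmetry image and both Friedel
    mates are reported independently.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if wedge_deg <= 0:
        raise ValueError("wedge_deg must be positive")
    if hkl is None:
        hkl = enumerate_hkl_sphere(cell, d_min)
    q0 = (np.asarray(orientation) @ cell.recip_basis @ hkl.T).T  # (N,3)
    qx, qy = q0[:, 0], q0[:, 1]
    rho = np.hypot(qx, qy)
    c = -0.5 * wavelength * np.einsum("ni,ni->n", q0, q0)
    ok = rho > 0
    ratio = np.where(ok, np.clip(c / np.where(ok, rho, 1.0), -1.0, 1.0), 2.0)
    sol = np.abs(ratio) <= 1.0
    sol &= np.abs(c) <= rho  # exact feasibility (pre-clip)
    alpha = np.arccos(np.where(sol, ratio, 0.0))
    delta = np.arctan2(qy, qx)
    start = np.radians(phi_start)
    span = np.radians(wedge_deg)
    rows = []
    for branch in (+1, -1):
        phi = -delta + branch * alpha
        rel = np.mod(phi - start, 2.0 * np.pi)
        hit = sol & (rel < span)
        if branch == -1:
            # alpha == 0 would duplicate the +1 branch (tangential touch)
            hit &= alpha > 1e-12
        phi_deg = np.degrees(start + rel[hit])
        frame = np.floor(np.degrees(rel[hit]) / frame_deg).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "h": hkl[hit, 0],
                    "k": hkl[hit, 1],
                    "l": hkl[hit, 2],
                    "phi": phi_deg,
                    "frame": frame,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["frame", "h", "k", "l"], ignore_index=True)


# ---------------------------------------------------------------------------
# wedge simulation
# ---------------------------------------------------------------------------


def simulate_wedges(
    polyset: PolymorphSet,
    n_wedges: int,
    plan: WedgePlan,
    seed: int = 0,
    sigma_g: float = 0.3,
    sigma_b: float = 3.0,
    id_prefix: str = "w",
) -> list[WedgeDataset]:
    """Simulate SWSX wedge datasets from a polymorph mixture.

    Per wedge: a uniform random orientation, a polymorph drawn by the mixture
    proportions, a relative scale ln g ~ N(0, sigma_g^2) and relative
    B ~ |N(0, sigma_b^2)|.  Expected counts for an observation at resolution
    s on frame f are

        lam = n0 * (dose_total / wedge_deg) * g
              * exp(-2 (B + damage_beta * D_f) s^2) * I_true

    with D_f the dose accumulated to the middle of frame f; raw counts are
    Poisson(lam + bg_rate) and i_obs = (counts - bg_rate) * exp(eta) with a
    per-frame systematic factor eta ~ N(0, sigma_sys^2).  sigma applies the
    standard one-count floor: sqrt(max(counts + bg_rate, 1)) * exp(eta).
    """
    if n_wedges < 1:
        raise ValueError("n_wedges must be >= 1")
    rng = np.random.default_rng(seed)
    cell = polyset.cell
    pg = polyset.pointgroup
    d_min = polyset.d_min
    hkl_all = enumerate_hkl_sphere(cell, d_min)
    dose_per_deg = plan.dose_total / plan.wedge_deg
    wedges: list[WedgeDataset] = []
    for j in range(n_wedges):
        orientation = Rotation.random(rng=rng).as_matrix()
        poly_id = int(rng.choice(len(polyset.members), p=polyset.proportions))
        ln_g = float(rng.normal(0.0, sigma_g))
        b_j = float(abs(rng.normal(0.0, sigma_b)))
        pred = predict_wedge(
            cell, orientation, plan.wavelength, 0.0, plan.wedge_deg, d_min,
            frame_deg=plan.frame_deg, hkl=hkl_all,
        )
        hkl_obs = pred[["h", "k", "l"]].values
        keys, signs = bijvoet_key(pg, hkl_obs)
        d = d_spacing(cell, hkl_obs)
        s = s_from_d(d)
        i_true = polyset.members[poly_id].intensities(keys, signs)
        valid = np.isfinite(i_true)
        pred = pred[valid].reset_index(drop=True)
        keys, signs, d, s, i_true = (
            keys[valid], signs[valid], d[valid], s[valid], i_true[valid]
        )
        frame = pred["frame"].values
        dose_f = plan.dose_total * (frame + 0.5) / plan.n_frames
        b_eff = b_j + plan.damage_beta * dose_f
        lam = plan.n0 * dose_per_deg * np.exp(ln_g) * np.exp(-2.0 * b_eff * s**2) * i_true
        counts = rng.poisson(lam + plan.bg_rate).astype(float)
        eta = rng.normal(0.0, plan.sigma_sys, size=plan.n_frames)[frame] if plan.sigma_sys > 0 else np.zeros(len(frame))
        scale = np.exp(eta)
        i_obs = (counts - plan.bg_rate) * scale
        sigma = np.sqrt(np.maximum(counts + plan.bg_rate, 1.0)) * scale
        obs = pd.DataFrame(
            {
                "h": pred["h"].values,
                "k": pred["k"].values,
                "l": pred["l"].values,
                "kh": keys[:, 0],
                "kk": keys[:, 1],
                "kl": keys[:, 2],
                "sign": signs,
                "s": s,
                "d": d,
                "i_obs": i_obs,
                "sigma": sigma,
                "frame": frame,
                "phi": pred["phi"].values,
            }
        )
        wedges.append(
            WedgeDataset(
                wedge_id=f"{id_prefix}{j:04d}",
                cell=cell,
                pointgroup_name=pg.name,
                plan=plan,
                observations=obs,
                orientation=orientation,
                polymorph_id=poly_id,
                d_min=d_min,
                true_ln_g=ln_g,
                true_b=b_j,
            )
        )
    return wedges
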