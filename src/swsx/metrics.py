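"""Quality and information metrics on merged reflection data.

Covers resolution-shell binning (equal volume in 1/d^3), half-dataset
correlation CC1/2 and the d_min at its 50% crossing, per-shell <I/sigma>,
Wilson-B estimation with an over-sharpening check, a Kullback-Leibler
information-gain metric (bits of structural information per observation,
simplified acentric Wilson-prior model), and anomalous difference Fourier
peak heights from Bijvoet differences with model phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell import UnitCell, s_from_d
from .scale_merge import MergedDataset
from .sim_core import Atom, structure_factors
from .symmetry import PointGroup, is_centric

__all__ = [
    "ShellStats",
    "MetricsReport",
    "make_shells",
    "cc_half",
    "dmin_at_cchalf",
    "mean_i_over_sigma",
    "wilson_b",
    "information_gain",
    "anomalous_peak",
]


@dataclass
class ShellStats:
    """Per-shell statistics; shells partition resolution by equal 1/d^3 volume."""

    d_lo: np.ndarray  # coarse boundary of each shell (A)
    d_hi: np.ndarray  # fine boundary (A)
    center_invd2: np.ndarray
    n_unique: np.ndarray
    multiplicity: np.ndarray
    cc_half: np.ndarray | None = None
    mean_i_over_sigma: np.ndarray | None = None
    d_min_cc50: float | None = None
    no_signal: bool = False

    @property
    def n_shells(self) -> int:
        return len(self.d_lo)


@dataclass
class MetricsReport:
    wilson_b: float | None = None
    wilson_intercept: float | None = None
    over_sharpening: bool = False
    info_gain_total: float | None = None
    info_gain_per_reflection: float | None = None
    anom_peak_sigma: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# shells
# ---------------------------------------------------------------------------


def make_shells(d: np.ndarray, n_shells: int = 10) -> tuple[ShellStats, np.ndarray]:
    """Equal-volume shells over the resolution range of ``d``.

    Returns the shell table and the shell index of every input reflection.
    """
    d = np.asarray(d, dtype=float)
    u = 1.0 / d**3
    edges = np.linspace(u.min(), u.max(), n_shells + 1)
    edges[-1] *= 1.0 + 1e-12
    idx = np.clip(np.searchsorted(edges, u, side="right") - 1, 0, n_shells - 1)
    d_lo = edges[:-1] ** (-1.0 / 3.0)
    d_hi = edges[1:] ** (-1.0 / 3.0)
    center_invd2 = (0.5 * (edges[:-1] + edges[1:])) ** (2.0 / 3.0)
    n_unique = np.bincount(idx, minlength=n_shells)
    return (
        ShellStats(
            d_lo=d_lo,
            d_hi=d_hi,
            center_invd2=center_invd2,
            n_unique=n_unique,
            multiplicity=np.zeros(n_shells),
        ),
        idx,
    )


# ---------------------------------------------------------------------------
# CC1/2
# ---------------------------------------------------------------------------


def cc_half(
    merged: MergedDataset,
    n_shells: int = 10,
    seed: int = 0,
    n_splits: int = 1,
    min_unique: int = 3,
) -> ShellStats:
    """Half-dataset correlation per resolution shell.

    For every unique with >= 2 kept observations the (scaled) observations
    are randomly split into two halves; CC1/2 is the Pearson correlation of
    the half means across the uniques of each shell, averaged over
    ``n_splits`` seeded splits.  Shells with fewer than ``min_unique``
    usable uniques report NaN.
    """
    obs = merged.scaled_obs[merged.scaled_obs["kept"]]
    if len(obs) < 2:
        raise ValueError("cc_half requires observations")
    codes = obs["code"].values
    x = obs["i_scaled"].values
    n_codes = int(codes.max()) + 1
    n_u = np.bincount(codes, minlength=n_codes)
    if not np.any(n_u >= 2):
        raise ValueError("no unique reflection has two observations")
    d_of_code = np.full(n_codes, np.nan)
    d_of_code[codes] = obs["d"].values
    shells, _ = make_shells(obs["d"].values, n_shells)
    u_edges = np.linspace(
        (1.0 / obs["d"].values ** 3).min(), (1.0 / obs["d"].values ** 3).max(), n_shells + 1
    )
    u_edges[-1] *= 1.0 + 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        shell_of_code = np.clip(
            np.searchsorted(u_edges, 1.0 / d_of_code**3, side="right") - 1, 0, n_shells - 1
        )

    rng = np.random.default_rng(seed)
    acc = np.full((n_splits, n_shells), np.nan)
    usable = n_u >= 2
    for split in range(n_splits):
        r = rng.random(len(obs))
        order = np.lexsort((r, codes))
        c_sorted = codes[order]
        pos_in_group = np.arange(len(obs)) - np.searchsorted(c_sorted, c_sorted)
        half = pos_in_group < (n_u[c_sorted] // 2)
        sum1 = np.bincount(c_sorted[half], weights=x[order][half], minlength=n_codes)
        cnt1 = np.bincount(c_sorted[half], minlength=n_codes)
        sum2 = np.bincount(c_sorted[~half], weights=x[order][~half], minlength=n_codes)
        cnt2 = np.bincount(c_sorted[~half], minlength=n_codes)
        ok = (cnt1 > 0) & (cnt2 > 0) & usable
        for b in range(n_shells):
            sel = ok & (shell_of_code == b)
            if sel.sum() < min_unique:
                continue
            m1 = sum1[sel] / cnt1[sel]
            m2 = sum2[sel] / cnt2[sel]
            if m1.std() == 0 or m2.std() == 0:
                continue
            acc[split, b] = np.corrcoef(m1, m2)[0, 1]
    with np.errstate(invalid="ignore"):
        shells.cc_half = np.nanmean(acc, axis=0)
    mult = np.zeros(n_shells)
    for b in range(n_shells):
        sel = usable & (shell_of_code == b)
        if sel.any():
            mult[b] = n_u[sel].mean()
    shells.multiplicity = mult
    return shells


def dmin_at_cchalf(shells: ShellStats, level: float = 0.5) -> float:
    """Resolution where CC1/2 crosses ``level``, interpolated linearly in 1/d^2.

    Scanning from low to high resolution: the first adjacent defined shell
    pair bracketing the level fixes the crossing.  If CC1/2 never drops
    below the level the finest shell boundary is returned; if it is below
    already in the first shell the coarsest boundary is returned and
    ``shells.no_signal`` is set.
    """
    if shells.cc_half is None:
        raise ValueError("run cc_half first")
    cc = np.asarray(shells.cc_half, dtype=float)
    centers = np.asarray(shells.center_invd2, dtype=float)
    defined = np.isfinite(cc)
    if defined.sum() < 2:
        raise ValueError("need at least two shells with defined CC1/2")
    cc = cc[defined]
    centers = centers[defined]
    if cc[0] < level:
        shells.no_signal = True
        shells.d_min_cc50 = float(shells.d_lo[0])
        return shells.d_min_cc50
    for i in range(len(cc) - 1):
        if cc[i] >= level > cc[i + 1]:
            frac = (cc[i] - level) / (cc[i] - cc[i + 1])
            inv_d2 = centers[i] + frac * (centers[i + 1] - centers[i])
            shells.d_min_cc50 = float(1.0 / np.sqrt(inv_d2))
            return shells.d_min_cc50
    shells.d_min_cc50 = float(shells.d_hi[-1])
    return shells.d_min_cc50


def mean_i_over_sigma(merged: MergedDataset, n_shells: int = 10) -> ShellStats:
    """Arithmetic mean of i_mean/sigma_mean per shell."""
    tab = merged.table
    if len(tab) == 0:
        raise ValueError("empty merged dataset")
    shells, idx = make_shells(tab["d"].values, n_shells)
    ios = tab["i_mean"].values / tab["sigma_mean"].values
    out = np.full(n_shells, np.nan)
    for b in range(n_shells):
        sel = idx == b
        if sel.any():
            out[b] = ios[sel].mean()
    shells.mean_i_over_sigma = out
    mult = np.zeros(n_shells)
    for b in range(n_shells):
        sel = idx == b
        if sel.any():
            mult[b] = tab["n_obs"].values[sel].mean()
    shells.multiplicity = mult
    return shells


# ---------------------------------------------------------------------------
# Wilson B
# ---------------------------------------------------------------------------


def wilson_b(
    merged: MergedDataset,
    n_shells: int = 10,
    fit_range: tuple[float, float] | None = None,
    b_floor: float = 8.0,
) -> tuple[float, float, bool]:
    """Wilson B from the slope of ln<I> vs s^2 (weighted by shell size).

    Returns (B, intercept, over_sharpening).  The over-sharpening flag is
    raised when B falls below ``b_floor`` (default 8 A^2, emulating a
    cross-check against typical temperature factors at comparable
    resolution).  By default the fit uses the upper half of the s^2 range.
    """
    tab = merged.table
    shells, idx = make_shells(tab["d"].values, n_shells)
    s2 = s_from_d(tab["d"].values) ** 2
    mean_i = np.full(shells.n_shells, np.nan)
    mean_s2 = np.full(shells.n_shells, np.nan)
    n = np.zeros(shells.n_shells)
    for b in range(shells.n_shells):
        sel = idx == b
        if sel.any():
            mean_i[b] = tab["i_mean"].values[sel].mean()
            mean_s2[b] = s2[sel].mean()
            n[b] = sel.sum()
    ok = np.isfinite(mean_i) & (mean_i > 0)
    if fit_range is None:
        lo = np.nanmin(mean_s2) + 0.5 * (np.nanmax(mean_s2) - np.nanmin(mean_s2))
        ok &= mean_s2 >= lo
    else:
        ok &= (mean_s2 >= fit_range[0]) & (mean_s2 <= fit_range[1])
    if ok.sum() < 4:
        raise ValueError("need at least four usable shells for the Wilson fit")
    w = n[ok]
    xfit, yfit = mean_s2[ok], np.log(mean_i[ok])
    sw = w.sum()
    xm = (w * xfit).sum() / sw
    ym = (w * yfit).sum() / sw
    slope = (w * (xfit - xm) * (yfit - ym)).sum() / (w * (xfit - xm) ** 2).sum()
    intercept = ym - slope * xm
    b_est = -0.5 * slope
    return float(b_est), float(intercept), bool(b_est < b_floor)


# ---------------------------------------------------------------------------
# information gain
# ---------------------------------------------------------------------------


def information_gain(
    merged: MergedDataset,
    n_shells: int = 10,
    quadrature_n: int = 2000,
) -> tuple[float, float]:
    """KL divergence (bits) from the Wilson prior to the intensity posterior.

    Simplified acentric model: prior p(J) = exp(-J) on the normalized true
    intensity J = I/<I>_shell, Gaussian likelihood
    N(i_obs; J <I>_shell, sigma), posterior by normalized product on a
    trapezoid grid over [0, J_up] with J_up = max(10, (i_obs+6 sigma)/<I>).
    The prior is renormalized on the same interval so the per-reflection
    gain is an exact KL divergence (>= 0).  Returns (total, mean) bits.
    """
    tab = merged.table
    if np.any(tab["sigma_mean"].values <= 0):
        raise ValueError("non-positive sigma in merged data")
    shells, idx = make_shells(tab["d"].values, n_shells)
    mean_i = np.array(
        [
            tab["i_mean"].values[idx == b].mean() if (idx == b).any() else np.nan
            for b in range(shells.n_shells)
        ]
    )
    pos = tab["i_mean"].values[tab["i_mean"].values > 0]
    fallback = pos.mean() if len(pos) else float(np.mean(tab["sigma_mean"].values))
    mean_i = np.where(np.isfinite(mean_i) & (mean_i > 0), mean_i, fallback)
    sig_ref = mean_i[idx]
    i_obs = tab["i_mean"].values
    sigma = tab["sigma_mean"].values
    j_up = np.maximum(10.0, (i_obs + 6.0 * sigma) / sig_ref)
    # per-reflection grid: J = t * j_up, t in [0, 1]
    t = np.linspace(0.0, 1.0, quadrature_n)
    gains = np.empty(len(tab))
    chunk = max(1, int(4e6 // quadrature_n))
    for lo in range(0, len(tab), chunk):
        hi = min(lo + chunk, len(tab))
        J = np.outer(j_up[lo:hi], t)  # (m, n)
        z = (i_obs[lo:hi, None] - J * sig_ref[lo:hi, None]) / sigma[lo:hi, None]
        log_q = -J - 0.5 * z * z
        log_q -= log_q.max(axis=1, keepdims=True)
        q = np.exp(log_q)
        norm = np.trapezoid(q, J, axis=1)
        q /= norm[:, None]
        # prior renormalized on [0, J_up]
        p = np.exp(-J) / (1.0 - np.exp(-j_up[lo:hi, None]))
        with np.errstate(divide="ignore", invalid="ignore"):
            integrand = np.where(q > 0, q * np.log2(q / p), 0.0)
        gains[lo:hi] = np.trapezoid(integrand, J, axis=1)
    gains = np.maximum(gains, 0.0)
    return float(gains.sum()), float(gains.mean())


# ---------------------------------------------------------------------------
# anomalous difference Fourier
# ---------------------------------------------------------------------------


def anomalous_peak(
    merged: MergedDataset,
    model: list[Atom],
    cell: UnitCell,
    pointgroup: PointGroup,
    site: tuple[float, float, float],
    grid_factor: float = 3.0,
    min_pairs: int = 50,
) -> float:
    """Anomalous difference Fourier peak height (sigma units) at ``site``.

    Coefficients dF(h) = |F+| - |F-| with |F| = sqrt(max(I, 0)) and phase
    phi_calc(h) - 90 deg from the (non-anomalous) model structure factors;
    the map is synthesized by Hermitian summation on a grid with spacing
    <= d_min/grid_factor (evaluated exactly via FFT), centric reflections
    excluded.  The peak height is (rho(site) - mean rho) / rms rho, with the
    site density evaluated by direct summation at the exact coordinates.
    """
    if not merged.anomalous:
        raise ValueError("anomalous_peak requires a Friedel-separated merge")
    tab = merged.table
    plus = tab[tab["sign"] > 0].set_index(["kh", "kk", "kl"])
    minus = tab[tab["sign"] < 0].set_index(["kh", "kk", "kl"])
    common = plus.index.intersection(minus.index)
    if len(common) < min_pairs:
        raise ValueError(f"only {len(common)} Bijvoet pairs; need >= {min_pairs}")
    keys = np.array(list(common))
    centric = is_centric(pointgroup, keys)
    keys = keys[~centric]
    ip = plus.loc[common, "i_mean"].values[~centric]
    im = minus.loc[common, "i_mean"].values[~centric]
    dF = np.sqrt(np.maximum(ip, 0.0)) - np.sqrt(np.maximum(im, 0.0))
    # expand over the proper rotations; dF is invariant, phases follow the model
    ops = pointgroup.ops
    all_h = np.concatenate([keys @ m.T for m in ops])
    all_df = np.tile(dF, len(ops))
    uniq, first = np.unique(all_h, axis=0, return_index=True)
    all_h, all_df = uniq, all_df[first]
    f_calc, _ = structure_factors(model, cell, all_h, anomalous=False)
    phi_c = np.angle(f_calc)
    coef = all_df * np.exp(1j * (phi_c - 0.5 * np.pi))
    d_min = float(tab["d"].min())
    hmax = int(np.abs(all_h).max())
    n_grid = max(int(np.ceil(grid_factor * max(cell.a, cell.b, cell.c) / d_min)), 2 * hmax + 2)
    grid = np.zeros((n_grid, n_grid, n_grid), dtype=complex)
    hi = np.mod(all_h, n_grid)
    grid[hi[:, 0], hi[:, 1], hi[:, 2]] += coef
    hneg = np.mod(-all_h, n_grid)
    grid[hneg[:, 0], hneg[:, 1], hneg[:, 2]] += np.conj(coef)
    # rho(x) = sum_h C(h) exp(-2 pi i h.x); fftn applies exactly that kernel
    rho = np.fft.fftn(grid).real
    site = np.asarray(site, dtype=float)
    phase_site = np.exp(-2j * np.pi * (all_h @ site))
    rho_site = float(2.0 * np.real(np.sum(coef * phase_site)))
    return float((rho_site - rho.mean()) / rho.std())
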