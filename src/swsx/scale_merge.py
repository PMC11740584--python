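"""Three-run relative scaling and merging of wedge datasets.

The protocol mirrors multi-wedge merging practice: fit per-wedge relative
scales ln g_j and relative B_j against a lowest-B reference (run01), reject
outlier frames by a robust MAD rule and re-scale (run02), reject anomalous
wedge sets by their correlation to the leave-one-out consensus and re-scale
(run03), then merge with inverse-variance weights and per-reflection outlier
rejection against the weighted median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .symmetry import to_asu  # noqa: F401  (part of this module's surface)
from .sim_core import GroundTruth, WedgeDataset

__all__ = [
    "ScalingModel",
    "MergedDataset",
    "to_asu",
    "fit_wedge_scales",
    "reject_outlier_frames",
    "reject_outlier_wedges",
    "merge",
    "merging_stats",
    "three_run_merge",
    "ThreeRunResult",
]


@dataclass
class ScalingModel:
    """Per-wedge relative scale and B against a lowest-B reference wedge."""

    wedge_ids: list[str]
    ln_g: np.ndarray
    b_rel: np.ndarray
    reference_id: str
    n_iter: int
    converged: bool
    excluded: list[str] = field(default_factory=list)

    def params_for(self, wedge_id: str) -> tuple[float, float]:
        j = self.wedge_ids.index(wedge_id)
        return float(self.ln_g[j]), float(self.b_rel[j])


@dataclass
class MergedDataset:
    """Unique-reflection table plus global merging statistics.

    ``table`` columns: kh, kk, kl, sign (Bijvoet branch; always +1 when
    Friedel-merged), s, d, i_mean, sigma_mean, n_obs.  ``scaled_obs`` keeps
    the scaled observations that went into the merge (with their unique-key
    code) for downstream statistics such as CC1/2.
    """

    table: pd.DataFrame
    anomalous: bool
    scaled_obs: pd.DataFrame = field(repr=False, default=None)
    stats: dict = field(default_factory=dict)

    @property
    def n_unique(self) -> int:
        return len(self.table)

    @property
    def multiplicity(self) -> float:
        return float(self.table["n_obs"].sum() / max(len(self.table), 1))


# ---------------------------------------------------------------------------
# pooling helpers
# ---------------------------------------------------------------------------


def _pool(wedges: list[WedgeDataset], anomalous: bool) -> pd.DataFrame:
    frames = []
    for j, w in enumerate(wedges):
        df = w.observations[
            ["kh", "kk", "kl", "sign", "s", "d", "i_obs", "sigma", "frame"]
        ].copy()
        df["wedge"] = j
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)
    if anomalous:
        key_cols = ["kh", "kk", "kl", "sign"]
    else:
        key_cols = ["kh", "kk", "kl"]
    codes, _ = pd.factorize(pd.MultiIndex.from_frame(pooled[key_cols]), sort=True)
    pooled["code"] = codes
    return pooled


def _apply_scales(pooled: pd.DataFrame, ln_g: np.ndarray, b_rel: np.ndarray):
    w = pooled["wedge"].values
    fac = np.exp(-ln_g[w] + 2.0 * b_rel[w] * pooled["s"].values ** 2)
    return pooled["i_obs"].values * fac, pooled["sigma"].values * fac


def _group_wmean(codes, values, weights, n_codes):
    sw = np.bincount(codes, weights=weights * values, minlength=n_codes)
    w = np.bincount(codes, weights=weights, minlength=n_codes)
    with np.errstate(invalid="ignore", divide="ignore"):
        return sw / w, w


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


def fit_wedge_scales(
    wedges: list[WedgeDataset],
    max_iter: int = 60,
    i_over_sigma_min: float = 3.0,
    n_min: int = 10,
    tol: float = 1e-6,
) -> ScalingModel:
    """Iterative relative scaling: ln(I_j / I_merged) ~ ln g_j - 2 b_j s^2.

    Alternates (1) inverse-variance merging with the current scales and
    (2) per-wedge weighted least squares on strong common reflections, then
    re-references so the wedge with the lowest fitted B carries (0, 0).
    Wedges with fewer than ``n_min`` usable reflections are flagged
    unscalable and excluded with a warning.
    """
    if len(wedges) < 2:
        raise ValueError("scaling requires at least two wedges")
    pooled = _pool(wedges, anomalous=False)
    n_codes = int(pooled["code"].max()) + 1
    n_w = len(wedges)
    codes = pooled["code"].values
    widx = pooled["wedge"].values
    s2 = pooled["s"].values ** 2
    i_raw = pooled["i_obs"].values
    sig = pooled["sigma"].values

    strong = i_raw > i_over_sigma_min * sig
    mult = np.bincount(codes, minlength=n_codes)
    usable = strong & (mult[codes] >= 2)
    n_usable = np.bincount(widx[usable], minlength=n_w)
    excluded = n_usable < n_min
    if excluded.any():
        bad = [wedges[j].wedge_id for j in np.flatnonzero(excluded)]
        warnings.warn(f"wedges excluded as unscalable (<{n_min} strong common): {bad}")
    if (~excluded).sum() < 2:
        raise ValueError("fewer than two scalable wedges")

    ln_g = np.zeros(n_w)
    b_rel = np.zeros(n_w)
    active_obs = usable & ~excluded[widx]
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        fac = np.exp(-ln_g[widx] + 2.0 * b_rel[widx] * s2)
        x = i_raw * fac
        wls = 1.0 / (sig * fac) ** 2
        keep = ~excluded[widx]
        merged, _ = _group_wmean(codes[keep], x[keep], wls[keep], n_codes)
        ok = active_obs & (merged[codes] > 0) & (i_raw > 0)
        y = np.log(i_raw[ok] / merged[codes[ok]])
        wt = (i_raw[ok] / sig[ok]) ** 2
        xs = s2[ok]
        wj = widx[ok]
        sw = np.bincount(wj, weights=wt, minlength=n_w)
        sx = np.bincount(wj, weights=wt * xs, minlength=n_w)
        sy = np.bincount(wj, weights=wt * y, minlength=n_w)
        sxx = np.bincount(wj, weights=wt * xs * xs, minlength=n_w)
        sxy = np.bincount(wj, weights=wt * xs * y, minlength=n_w)
        det = sw * sxx - sx * sx
        good = (~excluded) & (det > 0)
        slope = np.where(good, (sw * sxy - sx * sy) / np.where(det > 0, det, 1.0), 0.0)
        inter = np.where(good, (sy - slope * sx) / np.where(sw > 0, sw, 1.0), 0.0)
        new_ln_g = np.where(good, inter, ln_g)
        new_b = np.where(good, -0.5 * slope, b_rel)
        # re-reference to the lowest fitted B (ties: most observations)
        cand = np.flatnonzero(~excluded)
        order = sorted(cand, key=lambda j: (new_b[j], -len(wedges[j].observations)))
        jref = order[0]
        new_ln_g = new_ln_g - new_ln_g[jref]
        new_b = new_b - new_b[jref]
        delta = max(
            np.abs(new_ln_g[~excluded] - ln_g[~excluded]).max(initial=0.0),
            np.abs(new_b[~excluded] - b_rel[~excluded]).max(initial=0.0),
        )
        ln_g, b_rel = new_ln_g, new_b
        if delta < tol:
            converged = True
            break
    return ScalingModel(
        wedge_ids=[w.wedge_id for w in wedges],
        ln_g=ln_g,
        b_rel=b_rel,
        reference_id=wedges[jref].wedge_id,
        n_iter=n_iter,
        converged=converged,
        excluded=[wedges[j].wedge_id for j in np.flatnonzero(excluded)],
    )


# ---------------------------------------------------------------------------
# outlier rejection (run02 / run03)
# ---------------------------------------------------------------------------


def reject_outlier_frames(
    wedges: list[WedgeDataset],
    scaling: ScalingModel,
    merged: MergedDataset | None = None,
    k_mad: float = 3.5,
) -> tuple[list[WedgeDataset], pd.DataFrame]:
    """Drop frames whose median |I_scaled - I_merged|/sigma is a MAD outlier.

    The frame statistic is compared against median + k_mad * MAD over all
    frames of all wedges; ``k_mad=inf`` rejects nothing.
    """
    pooled = _pool(wedges, anomalous=False)
    n_codes = int(pooled["code"].max()) + 1
    x, sig_s = _apply_scales(pooled, scaling.ln_g, scaling.b_rel)
    codes = pooled["code"].values
    wls = 1.0 / sig_s**2
    mval, _ = _group_wmean(codes, x, wls, n_codes)
    resid = np.abs(x - mval[codes]) / sig_s
    df = pd.DataFrame(
        {"wedge": pooled["wedge"].values, "frame": pooled["frame"].values, "resid": resid}
    )
    stat = df.groupby(["wedge", "frame"])["resid"].median()
    med = float(stat.median())
    mad = 1.4826 * float((stat - med).abs().median())  # normalized MAD (~sigma)
    cutoff = med + k_mad * mad
    rejected = stat[stat > cutoff] if np.isfinite(cutoff) else stat.iloc[0:0]
    report = stat.reset_index().rename(columns={"resid": "frame_stat"})
    report["rejected"] = report.set_index(["wedge", "frame"]).index.isin(rejected.index)
    report["wedge_id"] = [wedges[j].wedge_id for j in report["wedge"]]
    out = []
    for j, w in enumerate(wedges):
        bad_frames = {f for (wj, f) in rejected.index if wj == j}
        if bad_frames:
            w = w.with_observations(
                w.observations[~w.observations["frame"].isin(bad_frames)]
            )
        out.append(w)
    return out, report[["wedge_id", "frame", "frame_stat", "rejected"]]


def reject_outlier_wedges(
    wedges: list[WedgeDataset],
    scaling: ScalingModel,
    merged: MergedDataset | None = None,
    cc_min: float = 0.8,
) -> tuple[list[WedgeDataset], pd.DataFrame]:
    """Drop wedges whose CC against the leave-one-out consensus is < cc_min."""
    pooled = _pool(wedges, anomalous=False)
    n_codes = int(pooled["code"].max()) + 1
    x, sig_s = _apply_scales(pooled, scaling.ln_g, scaling.b_rel)
    codes = pooled["code"].values
    widx = pooled["wedge"].values
    wls = 1.0 / sig_s**2
    sw = np.bincount(codes, weights=wls * x, minlength=n_codes)
    wsum = np.bincount(codes, weights=wls, minlength=n_codes)
    ccs = np.full(len(wedges), np.nan)
    for j in range(len(wedges)):
        mine = widx == j
        w_loo = wsum[codes[mine]] - wls[mine]
        valid = w_loo > 0
        if valid.sum() < 3:
            continue
        loo = (sw[codes[mine]][valid] - (wls[mine] * x[mine])[valid]) / w_loo[valid]
        xv = x[mine][valid]
        if np.std(xv) == 0 or np.std(loo) == 0:
            continue
        ccs[j] = float(np.corrcoef(xv, loo)[0, 1])
    rejected = np.where(np.isnan(ccs), False, ccs < cc_min)
    report = pd.DataFrame(
        {
            "wedge_id": [w.wedge_id for w in wedges],
            "cc_loo": ccs,
            "rejected": rejected,
        }
    )
    kept = [w for w, r in zip(wedges, rejected) if not r]
    return kept, report


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def _group_weighted_median(codes, values, weights, n_codes):
    """Per-group weighted median: first value whose cumulative weight >= half."""
    order = np.lexsort((values, codes))
    c, v, w = codes[order], values[order], weights[order]
    tot = np.bincount(c, weights=w, minlength=n_codes)
    cum = np.cumsum(w)
    starts = np.searchsorted(c, np.arange(n_codes))
    base = np.concatenate([[0.0], cum])[starts]
    within = cum - base[c]  # cumulative weight inside each group
    at_half = within >= 0.5 * tot[c] - 1e-12
    idx = np.flatnonzero(at_half)
    med = np.full(n_codes, np.nan)
    groups, first_pos = np.unique(c[idx], return_index=True)
    med[groups] = v[idx[first_pos]]
    return med


def merge(
    wedges: list[WedgeDataset],
    scaling: ScalingModel,
    anomalous: bool = False,
    reject_k: float = 4.0,
) -> MergedDataset:
    """Inverse-variance merge of scaled observations.

    Observations are scaled by exp(-ln_g + 2 b s^2); within each unique key
    (Bijvoet branches kept separate when ``anomalous``) observations further
    than ``reject_k`` * sigma from the weighted median are rejected, then the
    weighted mean and sigma_merged = (sum 1/sigma^2)^(-1/2) are reported.
    """
    idx_of = {wid: j for j, wid in enumerate(scaling.wedge_ids)}
    keep_w = [w for w in wedges if w.wedge_id not in scaling.excluded]
    pooled = _pool(keep_w, anomalous=anomalous)
    ln_g = np.array([scaling.ln_g[idx_of[w.wedge_id]] for w in keep_w])
    b_rel = np.array([scaling.b_rel[idx_of[w.wedge_id]] for w in keep_w])
    x, sig_s = _apply_scales(pooled, ln_g, b_rel)
    codes = pooled["code"].values
    n_codes = int(codes.max()) + 1
    wls = 1.0 / sig_s**2
    if np.isfinite(reject_k):
        med = _group_weighted_median(codes, x, wls, n_codes)
        kept = np.abs(x - med[codes]) <= reject_k * sig_s
    else:
        kept = np.ones(len(x), dtype=bool)
    i_mean, wsum = _group_wmean(codes[kept], x[kept], wls[kept], n_codes)
    n_obs = np.bincount(codes[kept], minlength=n_codes)
    present = n_obs > 0
    key_cols = ["kh", "kk", "kl", "sign"] if anomalous else ["kh", "kk", "kl"]
    firsts = pooled.loc[~pooled["code"].duplicated()].sort_values("code")
    table = firsts[key_cols + ["s", "d"]].reset_index(drop=True)
    if not anomalous:
        table["sign"] = 1
    table["i_mean"] = i_mean[firsts["code"].values]
    table["sigma_mean"] = 1.0 / np.sqrt(np.maximum(wsum[firsts["code"].values], 1e-300))
    table["n_obs"] = n_obs[firsts["code"].values]
    table = table[present[firsts["code"].values]].reset_index(drop=True)
    table = table[["kh", "kk", "kl", "sign", "s", "d", "i_mean", "sigma_mean", "n_obs"]]
    scaled_obs = pd.DataFrame(
        {
            "code": codes,
            "i_scaled": x,
            "sigma_scaled": sig_s,
            "wedge": pooled["wedge"].values,
            "frame": pooled["frame"].values,
            "s": pooled["s"].values,
            "d": pooled["d"].values,
            "kept": kept,
        }
    )
    return MergedDataset(table=table, anomalous=anomalous, scaled_obs=scaled_obs)


def merging_stats(merged: MergedDataset, n_possible: int | GroundTruth) -> dict:
    """Completeness, multiplicity and R_merge / R_meas / R_pim.

    ``n_possible`` is the count of possible uniques to d_min (or a
    GroundTruth whose unique set defines it).  R statistics use the
    unweighted mean within each unique and exclude multiplicity-1 uniques;
    with no multiplicity >= 2 data they are reported as None.
    """
    if merged.n_unique == 0:
        raise ValueError("empty merged dataset")
    if isinstance(n_possible, GroundTruth):
        n_possible = (
            n_possible.n_unique_anomalous if merged.anomalous else n_possible.n_unique
        )
    obs = merged.scaled_obs[merged.scaled_obs["kept"]]
    codes = obs["code"].values
    x = obs["i_scaled"].values
    n_codes = int(codes.max()) + 1
    n_u = np.bincount(codes, minlength=n_codes)
    mean = np.bincount(codes, weights=x, minlength=n_codes) / np.maximum(n_u, 1)
    multi = n_u[codes] >= 2
    stats: dict[str, float | None] = {}
    if multi.any():
        dev = np.abs(x - mean[codes])
        n_here = n_u[codes].astype(float)
        denom = x[multi].sum()
        stats["r_merge"] = 100.0 * dev[multi].sum() / denom
        stats["r_meas"] = 100.0 * (dev[multi] * np.sqrt(n_here[multi] / (n_here[multi] - 1))).sum() / denom
        stats["r_pim"] = 100.0 * (dev[multi] * np.sqrt(1.0 / (n_here[multi] - 1))).sum() / denom
    else:
        stats["r_merge"] = stats["r_meas"] = stats["r_pim"] = None
    stats["completeness"] = 100.0 * merged.n_unique / n_possible
    stats["multiplicity"] = merged.multiplicity
    stats["n_unique"] = merged.n_unique
    stats["n_obs"] = int(merged.table["n_obs"].sum())
    merged.stats.update(stats)
    return stats


# ---------------------------------------------------------------------------
# full protocol
# ---------------------------------------------------------------------------


@dataclass
class ThreeRunResult:
    merged: MergedDataset
    scaling: ScalingModel
    wedges: list[WedgeDataset]
    frame_report: pd.DataFrame
    wedge_report: pd.DataFrame


def three_run_merge(
    wedges: list[WedgeDataset],
    anomalous: bool = False,
    k_mad: float = 3.5,
    cc_min: float = 0.8,
    reject_k: float = 4.0,
    **fit_kwargs,
) -> ThreeRunResult:
    """run01 scale/merge, run02 frame rejection, run03 wedge rejection."""
    scaling = fit_wedge_scales(wedges, **fit_kwargs)
    wedges2, frame_report = reject_outlier_frames(wedges, scaling, k_mad=k_mad)
    wedges2 = [w for w in wedges2 if w.n_obs > 0]
    scaling2 = fit_wedge_scales(wedges2, **fit_kwargs)
    wedges3, wedge_report = reject_outlier_wedges(wedges2, scaling2, cc_min=cc_min)
    if len(wedges3) < 2:
        wedges3 = wedges2
    scaling3 = fit_wedge_scales(wedges3, **fit_kwargs)
    merged = merge(wedges3, scaling3, anomalous=anomalous, reject_k=reject_k)
    return ThreeRunResult(
        merged=merged,
        scaling=scaling3,
        wedges=wedges3,
        frame_report=frame_report,
        wedge_report=wedge_report,
    )
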