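"""Dual regression, band-limited spectral statistics, and sign-flip
permutation inference with TFCE-based family-wise error correction.

Dual regression follows group-ICA practice: stage 1 spatially regresses each
volume onto all group maps jointly, giving per-run component time courses
(variance-normalized so stage-2 betas are comparable across subjects);
stage 2 temporally regresses each target voxel's series onto all time
courses jointly, giving subject-specific connectivity maps. Condition
differences are tested voxelwise with a paired t statistic whose null
distribution is built by sign-flipping subject difference maps; family-wise
error is controlled with the max-statistic distribution of the TFCE-enhanced
images.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as spstats

from .io import derive_seed
from .physio import HP_FLOOR, band_fraction_psd, cohens_d_from_summary, welch_psd
from .types import ComponentSet, FrequencyBand, Mask, PairedTestResult, StatMapResult, VolumeSeries

logger = logging.getLogger("micacardio")

__all__ = [
    "SubjectMaps",
    "dual_regression",
    "dual_regression_maps",
    "stage1_time_courses",
    "band_fraction_tc",
    "band_power_table",
    "spectral_change_test",
    "tfce",
    "paired_permutation_map_test",
]

BIG_T = 100.0  # stand-in t for zero-variance voxels with non-zero mean


@dataclass
class SubjectMaps:
    """Per-subject, per-condition stage-2 beta maps on a target mask."""

    betas: dict  # subject -> condition -> (k, V_target) array
    target: Mask
    k: int
    subjects: list[str] = field(default_factory=list)
    conditions: tuple[str, str] = ("Rest", "LBNP")

    def __post_init__(self) -> None:
        if not self.subjects:
            self.subjects = sorted(self.betas)
        for s in self.subjects:
            for cond in self.conditions:
                if cond not in self.betas[s]:
                    raise ValueError(f"subject {s} lacks condition {cond}")
                if not np.isfinite(self.betas[s][cond]).all():
                    raise ValueError(f"non-finite betas for subject {s}/{cond}")

    def diff_matrix(self, component: int) -> np.ndarray:
        """(n_subjects, V_target) matrix of LBNP - Rest betas for one component."""
        rest, lbnp = self.conditions
        return np.stack(
            [self.betas[s][lbnp][component] - self.betas[s][rest][component] for s in self.subjects]
        )

    def condition_matrix(self, component: int, condition: str) -> np.ndarray:
        return np.stack([self.betas[s][condition][component] for s in self.subjects])


def _parse_run_meta(run: VolumeSeries) -> tuple[str, str]:
    """Default subject/condition metadata from run ids like ``sub03_LBNP_06``."""
    parts = run.run_id.split("_")
    if len(parts) >= 2 and parts[1] in ("LBNP", "Rest"):
        return parts[0], parts[1]
    raise ValueError(
        f"cannot infer subject/condition from run id {run.run_id!r}; pass them explicitly"
    )


def stage1_time_courses(run: VolumeSeries, group_maps: ComponentSet, normalize: bool = True) -> np.ndarray:
    """Stage-1 spatial regression: per-volume multiple regression on all maps.

    Returns the (T, k) time-course matrix; columns are variance-normalized
    when ``normalize`` so downstream betas are comparable across subjects.
    """
    from .mica import _extract_normalized

    maps = group_maps.maps  # (k, V)
    if np.linalg.matrix_rank(maps) < maps.shape[0]:
        raise ValueError("group maps are rank deficient (duplicate components?)")
    y = _extract_normalized(run, group_maps.mask)  # (T, V)
    design = np.vstack([np.ones(maps.shape[1]), maps]).T  # (V, 1 + k)
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)  # (1 + k, T)
    tc = coef[1:].T  # (T, k)
    if normalize:
        tc = tc - tc.mean(axis=0)
        sd = tc.std(axis=0)
        sd[sd == 0] = 1.0
        tc = tc / sd
    return tc


def _stage2_betas(run: VolumeSeries, tc: np.ndarray, target: Mask) -> np.ndarray:
    """Stage-2 temporal regression of each target voxel onto all time courses."""
    target.check_grid(run)
    y = run.data[target.data].T  # (T, V_target)
    y = y - y.mean(axis=0)
    design = np.column_stack([np.ones(len(tc)), tc])  # (T, 1 + k)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)  # (1 + k, V_target)
    return coef[1:]  # (k, V_target)


def dual_regression_maps(
    runs: list[VolumeSeries], group_maps: ComponentSet, target: Mask
) -> np.ndarray:
    """Per-run stage-2 beta maps, (n_runs, k, V_target); no aggregation."""
    out = []
    for run in runs:
        tc = stage1_time_courses(run, group_maps)
        out.append(_stage2_betas(run, tc, target))
    return np.stack(out)


def dual_regression(
    runs: list[VolumeSeries],
    group_maps: ComponentSet,
    target: Mask,
    subjects: list[str] | None = None,
    conditions: list[str] | None = None,
) -> SubjectMaps:
    """Two-stage dual regression with run-to-subject aggregation.

    Runs of the same subject and condition are averaged (arithmetic mean);
    the subject is the unit of later permutation inference. Subject and
    condition labels default to parsing the ``sub<id>_<cond>_...`` run ids.
    """
    if subjects is None or conditions is None:
        meta = [_parse_run_meta(r) for r in runs]
        subjects = [m[0] for m in meta]
        conditions = [m[1] for m in meta]
    betas_by: dict[str, dict[str, list[np.ndarray]]] = {}
    for run, subj, cond in zip(runs, subjects, conditions):
        tc = stage1_time_courses(run, group_maps)
        beta = _stage2_betas(run, tc, target)
        betas_by.setdefault(subj, {}).setdefault(cond, []).append(beta)
    averaged = {
        s: {c: np.mean(stack, axis=0) for c, stack in conds.items()}
        for s, conds in betas_by.items()
    }
    return SubjectMaps(betas=averaged, target=target, k=group_maps.k)


# ---------------------------------------------------------------------------
# Band-limited spectral statistics of component time courses


def band_fraction_tc(
    tc: np.ndarray, tr: float, band: FrequencyBand, hp_floor: float = HP_FLOOR
) -> float:
    """Fractional band power of a component time course (fALFF-style).

    Welch PSD of the detrended series; band-integrated power divided by the
    total power above the high-pass floor (0.005 Hz default, matching the
    imaging preprocessing high-pass).
    """
    tc = np.asarray(tc, dtype=float)
    fs = 1.0 / tr
    if band.hi >= fs / 2:
        raise ValueError(
            f"band reaches {band.hi:.3f} Hz but Nyquist is {fs / 2:.3f} Hz at tr={tr} s"
        )
    if len(tc) * tr < 5.0 / band.centre:
        raise ValueError("time course too short for the requested band")
    f, p = welch_psd(tc, fs)
    return band_fraction_psd(f, p, band, hp_floor)


def band_power_table(
    runs: list[VolumeSeries],
    group_maps: ComponentSet,
    bands: dict[str, FrequencyBand],
    subjects: list[str] | None = None,
    conditions: list[str] | None = None,
    hp_floor: float = HP_FLOOR,
) -> pd.DataFrame:
    """Per (subject, condition, component, band) fractional band power.

    Stage-1 time courses are extracted per run; fractions of runs sharing a
    subject and condition are averaged so the table holds one row per cell.
    """
    if subjects is None or conditions is None:
        meta = [_parse_run_meta(r) for r in runs]
        subjects = [m[0] for m in meta]
        conditions = [m[1] for m in meta]
    rows = []
    for run, subj, cond in zip(runs, subjects, conditions):
        tc = stage1_time_courses(run, group_maps)
        for comp in range(group_maps.k):
            for band_name, band in bands.items():
                rows.append(
                    {
                        "subject": subj,
                        "condition": cond,
                        "component": comp,
                        "band": band_name,
                        "fraction": band_fraction_tc(tc[:, comp], run.tr, band, hp_floor),
                    }
                )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["subject", "condition", "component", "band"], as_index=False)["fraction"]
        .mean()
        .sort_values(["component", "band", "subject", "condition"])
        .reset_index(drop=True)
    )


def _signflip_t(diffs: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """Paired t statistics of sign-flipped differences, vectorized over flips."""
    n = diffs.shape[0]
    means = flips @ diffs / n
    msq = (diffs**2).sum(axis=0) / n  # flip-invariant second moment, per voxel
    var = (msq - means**2) * n / (n - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0  # 0/0: flat differences
    t[np.isinf(t)] = np.sign(means[np.isinf(t)]) * BIG_T
    return t


def _all_sign_flips(n: int) -> np.ndarray:
    out = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    return out


def spectral_change_test(
    table: pd.DataFrame,
    component: int,
    band: str,
    n_perm: int = 10000,
    seed: int = 0,
    method: str = "signflip",
) -> PairedTestResult:
    """Non-parametric paired test of LBNP vs Rest fractional band power.

    The paired t statistic on subject differences is referred to its
    sign-flip permutation distribution — exhaustively (all 2^n flips) when
    n <= 12 or 2^n <= n_perm, else ``n_perm`` random flips. A Wilcoxon
    signed-rank alternative is available via ``method='wilcoxon'``.
    """
    cell = table[(table["component"] == component) & (table["band"] == band)]
    pivot = cell.pivot(index="subject", columns="condition", values="fraction").dropna()
    if len(pivot) < 3:
        raise ValueError("need at least 3 subjects with both conditions")
    rest = pivot["Rest"].to_numpy()
    lbnp = pivot["LBNP"].to_numpy()
    n = len(rest)
    diffs = lbnp - rest
    summaries = dict(
        n=n,
        df=n - 1,
        mean_rest=float(rest.mean()),
        mean_lbnp=float(lbnp.mean()),
        sd_rest=float(np.std(rest, ddof=1)),
        sd_lbnp=float(np.std(lbnp, ddof=1)),
    )
    d = cohens_d_from_summary(
        summaries["mean_rest"], summaries["mean_lbnp"], summaries["sd_rest"], summaries["sd_lbnp"]
    )
    if np.all(diffs == 0):
        return PairedTestResult(t=0.0, p=1.0, d=0.0, method="signflip", **summaries)
    if method == "wilcoxon":
        stat, p = spstats.wilcoxon(lbnp, rest)
        return PairedTestResult(t=float(stat), p=float(p), d=d, method="wilcoxon", **summaries)
    t_obs = float(_signflip_t(diffs.reshape(-1, 1), np.ones((1, n)))[0, 0])
    if 2**n <= max(n_perm, 2**min(n, 12)):
        flips = _all_sign_flips(n)
        t_perm = _signflip_t(diffs.reshape(-1, 1), flips).ravel()
        p = float((np.abs(t_perm) >= abs(t_obs) - 1e-12).sum() / len(flips))
    else:
        rng = np.random.default_rng(derive_seed(seed, "spectral", component, band))
        flips = rng.choice((1.0, -1.0), size=(n_perm, n))
        t_perm = _signflip_t(diffs.reshape(-1, 1), flips).ravel()
        p = float((1 + (np.abs(t_perm) >= abs(t_obs) - 1e-12).sum()) / (n_perm + 1))
    return PairedTestResult(t=t_obs, p=p, d=d, method="signflip", **summaries)


# ---------------------------------------------------------------------------
# Threshold-free cluster enhancement


def _tfce_one_sided(
    vol: np.ndarray, mask: np.ndarray, H: float, E: float, dh: float | None, structure: np.ndarray
) -> np.ndarray:
    vals = np.where(mask, vol, 0.0)
    vals = np.where(vals > 0, vals, 0.0)
    out = np.zeros_like(vals)
    vmax = vals.max()
    if vmax <= 0:
        return out
    if dh is None:
        dh = vmax / 100.0
    n_steps = int(np.floor(vmax / dh + 1e-9))
    for i in range(1, n_steps + 1):
        h = i * dh
        sup = vals >= h
        labels, n_lab = ndimage.label(sup, structure=structure)
        if n_lab == 0:
            continue
        sizes = np.bincount(labels.ravel())
        enh = (sizes.astype(float) ** E) * (h**H) * dh
        enh[0] = 0.0
        out += enh[labels]
    return out


def tfce(
    stat_map: np.ndarray,
    mask: Mask | np.ndarray,
    H: float = 2.0,
    E: float = 0.5,
    dh: float | None = None,
    connectivity: int = 26,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a voxelwise statistic map.

    TFCE(v) = sum over thresholds h = dh, 2dh, ... <= max of
    e(v, h)^E * h^H * dh, with e(v, h) the voxel count of the connected
    component containing v at threshold h. Defaults are the canonical
    H = 2, E = 0.5, 26-connectivity, dh = max/100. Negative values are
    enhanced symmetrically on the negated map and returned with negative
    sign, so the output is signed like the input.
    """
    if dh is not None and dh <= 0:
        raise ValueError("dh must be positive")
    mask_data = mask.data if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    # crop to the mask bounding box: clusters cannot leave the mask support
    sl = ndimage.find_objects(mask_data.astype(np.int8))[0]
    sub_map = np.asarray(stat_map, dtype=float)[sl]
    sub_mask = mask_data[sl]
    pos = _tfce_one_sided(sub_map, sub_mask, H, E, dh, structure)
    neg = _tfce_one_sided(-sub_map, sub_mask, H, E, dh, structure)
    out = np.zeros(mask_data.shape, dtype=float)
    out[sl] = pos - neg
    return out


# ---------------------------------------------------------------------------
# Paired permutation map test with FWE correction


def paired_permutation_map_test(
    maps: SubjectMaps,
    component: int,
    n_perm: int = 500,
    seed: int = 0,
    use_tfce: bool = True,
    H: float = 2.0,
    E: float = 0.5,
    dh: float | None = None,
    connectivity: int = 26,
    one_sample: bool = False,
    condition: str = "LBNP",
) -> StatMapResult:
    """Sign-flip max-statistic paired test of connectivity change.

    Computes the voxelwise paired t map of (LBNP - Rest) betas for one
    component, enhances it (and its negation) with TFCE, and refers each
    voxel's enhanced value to the permutation distribution of the image-wide
    maximum enhanced statistic under subject-level sign flips:
    p_fwe(v) = (1 + #{perm max >= observed(v)}) / (n_perm + 1). When
    2^n_subjects <= n_perm the enumeration is exhaustive and
    p_fwe(v) = #{flip max >= observed(v)} / 2^n (the identity flip counts).
    With ``one_sample`` the signs of single-condition maps are flipped
    instead (supplementary-style one-sample test).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse FWE estimate", stacklevel=2)
    if one_sample:
        diffs = maps.condition_matrix(component, condition)
    else:
        diffs = maps.diff_matrix(component)
    n = diffs.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    target = maps.target

    def enhance(t_flat: np.ndarray) -> np.ndarray:
        """Per-voxel enhanced statistic used for both tails (max of the two)."""
        if not use_tfce:
            return np.abs(t_flat)
        vol = np.zeros(target.data.shape)
        vol[target.data] = t_flat
        enh = tfce(vol, target, H=H, E=E, dh=dh, connectivity=connectivity)
        return np.abs(enh)[target.data]

    t_obs = _signflip_t(diffs, np.ones((1, n)))[0]
    obs_enh = enhance(t_obs)

    exhaustive = 2**n <= n_perm
    if exhaustive:
        flips = _all_sign_flips(n)
    else:
        rng = np.random.default_rng(derive_seed(seed, "permmap", component))
        flips = rng.choice((1.0, -1.0), size=(n_perm, n))
    t_perm = _signflip_t(diffs, flips)
    max_stats = np.empty(len(flips))
    for i in range(len(flips)):
        max_stats[i] = enhance(t_perm[i]).max() if t_perm[i].any() else 0.0
    max_sorted = np.sort(max_stats)
    n_ge = len(max_sorted) - np.searchsorted(max_sorted, obs_enh - 1e-12, side="left")
    if exhaustive:
        p_fwe = n_ge / len(flips)
        n_reported = len(flips)
    else:
        p_fwe = (1.0 + n_ge) / (n_perm + 1.0)
        n_reported = n_perm
    p_fwe = np.minimum(np.maximum(p_fwe, 1.0 / (n_reported + 1)), 1.0)

    vol_t = np.zeros(target.data.shape)
    vol_t[target.data] = t_obs
    tfce_signed = tfce(vol_t, target, H=H, E=E, dh=dh, connectivity=connectivity)[target.data] \
        if use_tfce else t_obs
    return StatMapResult(
        t_map=t_obs,
        tfce_map=tfce_signed,
        p_fwe=p_fwe,
        n_permutations=n_reported,
        seed=int(seed),
        target=target,
    )
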