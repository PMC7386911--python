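"""Masked spatial ICA, reproducibility-driven model-order selection,
component specificity filtering, and winner-take-all segmentation.

The decomposition is spatial ICA of the temporally concatenated,
voxelwise-variance-normalized runs restricted to an anatomical mask:
sources are the spatial maps (independent over voxels), mixing columns are
their time courses. Model order is chosen by split-half reproducibility:
ICA is run on random half-samples, components are matched by Hungarian
sorting of the spatial cross-correlation matrix, and the dimensionality
maximising the mean matched |r| — among dimensionalities that converged on
every split — is selected.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io import derive_seed
from .types import ComponentSet, LabelMap, Mask, ReproducibilityCurve, TissuePriors, VolumeSeries

logger = logging.getLogger("micacardio")

__all__ = [
    "masked_ica",
    "crosscorr",
    "hungarian_match",
    "reproducibility",
    "select_dim",
    "specificity_scores",
    "filter_unspecific",
    "segment",
    "mixture_threshold",
]


def _extract_normalized(run: VolumeSeries, mask: Mask, voxel_norm: bool = False) -> np.ndarray:
    """In-mask (T, V) data, demeaned per voxel and variance-normalized per run.

    By default the run is scaled by one global factor (the overall in-mask
    standard deviation), which preserves the spatial amplitude profile of the
    sources; ``voxel_norm`` switches to per-voxel unit variance (MELODIC
    style), which equalises voxel amplitudes but flattens source profiles.
    """
    mask.check_grid(run)
    y = run.data[mask.data].T.astype(float)  # (T, V)
    y = y - y.mean(axis=0)
    if voxel_norm:
        sd = y.std(axis=0)
        sd[sd == 0] = 1.0
        return y / sd
    scale = y.std()
    return y / scale if scale > 0 else y


def masked_ica(
    runs: list[VolumeSeries],
    mask: Mask,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    voxel_norm: bool = False,
) -> ComponentSet:
    """Spatial ICA of the concatenated runs inside the mask.

    Runs are individually variance-normalized per voxel and temporally
    concatenated; the concatenated matrix is reduced to ``k`` dimensions and
    unmixed by fixed-point negentropy maximisation with the tanh contrast
    (FastICA). Maps are z-scored across voxels; per-run mixing time courses
    are recovered by least-squares projection of the normalized run data onto
    the maps. ``converged`` reports whether the fixed-point iteration met
    ``tol`` within ``max_iter``.
    """
    if not runs:
        raise ValueError("need at least one run")
    total_t = sum(r.n_volumes for r in runs)
    if k >= total_t:
        raise ValueError(f"k={k} must be smaller than the {total_t} concatenated volumes")
    if k > mask.n_voxels:
        raise ValueError(f"k={k} exceeds the {mask.n_voxels} in-mask voxels")
    if k < 1:
        raise ValueError("k must be >= 1")
    per_run = [_extract_normalized(r, mask, voxel_norm) for r in runs]
    y = np.vstack(per_run)  # (T_total, V)

    ica = FastICA(
        n_components=k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(y.T)  # (V, k): spatial maps
    converged = ica.n_iter_ < max_iter

    maps = sources.T  # (k, V)
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = (maps - mu) / sd
    # canonical orientation: heavier z tail positive (ICA signs are arbitrary,
    # but winner-take-all segmentation needs positively signed source peaks)
    flip = np.sign(np.sum(maps**3, axis=1))
    flip[flip == 0] = 1.0
    maps = maps * flip[:, None]

    pinv = np.linalg.pinv(maps)  # (V, k)
    mixing = [yr @ pinv for yr in per_run]
    return ComponentSet(
        maps=maps,
        mixing=mixing,
        mask=mask,
        converged=bool(converged),
        seed=int(seed),
        run_ids=[r.run_id for r in runs],
    )


def crosscorr(a: ComponentSet, b: ComponentSet) -> np.ndarray:
    """Pearson correlations of all map pairs over in-mask voxels, (k_a, k_b)."""
    if not np.array_equal(a.mask.data, b.mask.data):
        raise ValueError("component sets live on different masks")
    return _rowwise_corr(a.maps, b.maps)


def _rowwise_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xs = (x - x.mean(axis=1, keepdims=True))
    ys = (y - y.mean(axis=1, keepdims=True))
    xs /= np.sqrt((xs**2).sum(axis=1, keepdims=True))
    ys /= np.sqrt((ys**2).sum(axis=1, keepdims=True))
    return xs @ ys.T


def hungarian_match(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-to-one component matching maximising the summed |correlation|.

    Rectangular matrices are padded to square with -1 score entries so dummy
    assignments are never preferred. Returns ``(assignment, matched_r,
    signs)`` where ``assignment[i]`` is the column matched to row ``i`` (-1
    for a dummy match), ``matched_r`` the |corr| at the assigned cells, and
    ``signs`` the retained correlation signs for map alignment (ICA signs are
    arbitrary).
    """
    corr = np.asarray(corr, dtype=float)
    n_a, n_b = corr.shape
    n = max(n_a, n_b)
    score = np.full((n, n), -1.0)
    score[:n_a, :n_b] = np.abs(corr)
    rows, cols = linear_sum_assignment(score, maximize=True)
    assignment = np.full(n_a, -1, dtype=int)
    matched_r = np.zeros(n_a)
    signs = np.ones(n_a)
    for r, c in zip(rows, cols):
        if r < n_a and c < n_b:
            assignment[r] = c
            matched_r[r] = abs(corr[r, c])
            signs[r] = 1.0 if corr[r, c] >= 0 else -1.0
    return assignment, matched_r, signs


# ---------------------------------------------------------------------------
# Split-half reproducibility and dimensionality selection


def _group_runs_by_subject(runs, subjects):
    if subjects is None:
        subjects = [r.run_id for r in runs]
    if len(subjects) != len(runs):
        raise ValueError("subjects must parallel runs")
    by_subj: dict[str, list[int]] = {}
    for i, s in enumerate(subjects):
        by_subj.setdefault(str(s), []).append(i)
    for s in by_subj:  # canonical within-subject run order (run-order invariance)
        by_subj[s].sort(key=lambda i: runs[i].run_id)
    return by_subj


def reproducibility(
    runs: list[VolumeSeries],
    mask: Mask,
    dims: list[int],
    n_splits: int = 30,
    seed: int = 0,
    subjects: list[str] | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> ReproducibilityCurve:
    """Split-half reproducibility of masked ICA across dimensionalities.

    For each dimensionality K and each of ``n_splits`` random subject-level
    half-splits, ICA is run on each half, components are Hungarian-matched on
    their spatial cross-correlations, and the mean matched |r| is recorded.
    Splits where either half failed to converge do not enter the mean/sd
    (non-convergence is penalised through ``n_converged``). Results are
    invariant to the order of ``runs``: subjects are canonicalised by sorted
    id and all split randomness derives from ``seed`` alone.
    """
    if len(runs) < 4:
        raise ValueError("need at least 4 runs so both halves are non-empty")
    if any(k < 1 for k in dims):
        raise ValueError("dims must be >= 1")
    by_subj = _group_runs_by_subject(runs, subjects)
    subj_ids = sorted(by_subj)
    if len(subj_ids) < 2:
        raise ValueError("need at least 2 subjects to split")

    rng = np.random.default_rng(derive_seed(seed, "repro-splits"))
    mean_r = []
    sd_r = []
    n_conv = []
    split_assignments = [rng.permutation(len(subj_ids)) for _ in range(n_splits)]
    for k in dims:
        rs = []
        for s_i, perm in enumerate(split_assignments):
            half = len(subj_ids) // 2
            ids_a = [subj_ids[i] for i in perm[:half]]
            ids_b = [subj_ids[i] for i in perm[half:]]
            runs_a = [runs[i] for sid in sorted(ids_a) for i in by_subj[sid]]
            runs_b = [runs[i] for sid in sorted(ids_b) for i in by_subj[sid]]
            set_a = masked_ica(runs_a, mask, k, seed=derive_seed(seed, "split", s_i, "a", k),
                               max_iter=max_iter, tol=tol)
            set_b = masked_ica(runs_b, mask, k, seed=derive_seed(seed, "split", s_i, "b", k),
                               max_iter=max_iter, tol=tol)
            if not (set_a.converged and set_b.converged):
                continue
            _, matched, _ = hungarian_match(crosscorr(set_a, set_b))
            rs.append(float(matched.mean()))
        n_conv.append(len(rs))
        mean_r.append(float(np.mean(rs)) if rs else float("nan"))
        sd_r.append(float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0)
        logger.info("reproducibility K=%d: mean_r=%.3f (%d/%d converged)",
                    k, mean_r[-1], n_conv[-1], n_splits)
    return ReproducibilityCurve(dims=list(dims), mean_r=mean_r, sd_r=sd_r,
                                n_converged=n_conv, n_splits=n_splits)


def select_dim(curve: ReproducibilityCurve, min_converged_frac: float = 1.0) -> int:
    """Dimensionality maximising mean reproducibility among fully converged K.

    K values whose converged-split fraction falls below ``min_converged_frac``
    are excluded; ties break toward the smaller K.
    """
    best_k = None
    best_r = -np.inf
    for k, r, nc in sorted(zip(curve.dims, curve.mean_r, curve.n_converged)):
        if curve.n_splits and nc / curve.n_splits < min_converged_frac:
            continue
        if not np.isfinite(r):
            continue
        if r > best_r:
            best_k, best_r = k, r
    if best_k is None:
        raise ValueError("no dimensionality satisfies the convergence requirement")
    return int(best_k)


# ---------------------------------------------------------------------------
# Specificity filtering


def specificity_scores(
    components: ComponentSet,
    runs: list[VolumeSeries],
    cuboid: Mask,
    priors: TissuePriors,
) -> np.ndarray:
    """Tissue-specificity quotient per component from unmasked dual regression.

    Stage-1 dual regression of each run on the component maps yields per-run
    time courses; stage-2 regression onto the cuboid volume (brainstem +
    hypothalamus surrogate) yields per-component activation maps. The score is
    the activation-weighted grey+white matter probability over the
    activation-weighted CSF probability, with activation the group-mean
    absolute stage-2 beta. A component with zero CSF-weighted activation gets
    the +inf sentinel (maximally specific).
    """
    from .stats import dual_regression_maps

    betas = dual_regression_maps(runs, components, cuboid)  # (n_runs, k, V_cuboid)
    activation = np.abs(betas).mean(axis=0)  # (k, V)
    gm_wm = (priors.gm + priors.wm)[cuboid.data]
    csf = priors.csf[cuboid.data]
    num = activation @ gm_wm
    den = activation @ csf
    scores = np.full(components.k, np.inf)
    nonzero = den > 0
    scores[nonzero] = num[nonzero] / den[nonzero]
    return scores


def filter_unspecific(scores: np.ndarray) -> tuple[list[int], list[int]]:
    """Exclude components whose quotient is below mean - 1 SD.

    +inf sentinels participate as the largest finite score so a single
    empty-CSF component cannot mask genuinely low quotients.
    """
    scores = np.asarray(scores, dtype=float)
    finite = np.isfinite(scores)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite scores")
    mapped = scores.copy()
    mapped[~finite] = scores[finite].max()
    thresh = mapped.mean() - np.std(mapped, ddof=1)
    excluded = [int(i) for i in np.flatnonzero(mapped < thresh)]
    kept = [int(i) for i in range(len(scores)) if i not in excluded]
    return kept, excluded


# ---------------------------------------------------------------------------
# Winner-take-all segmentation


def segment(components: ComponentSet, kept: list[int]) -> LabelMap:
    """Label each mask voxel with the kept component of highest z-value.

    Labels are 1-based component indices (label = component index + 1);
    voxels where every kept component has z <= 0 stay background (0). Exact
    ties go to the lowest component index.
    """
    if not kept:
        raise ValueError("kept component list is empty")
    kept = sorted(kept)
    z = components.maps[kept]  # (n_kept, V)
    best = np.argmax(z, axis=0)  # first occurrence wins ties -> lowest id
    best_z = z[best, np.arange(z.shape[1])]
    labels_flat = np.array([kept[b] + 1 for b in best], dtype=np.int32)
    labels_flat[best_z <= 0] = 0
    labels = np.zeros(components.mask.data.shape, dtype=np.int32)
    labels[components.mask.data] = labels_flat
    return LabelMap(labels=labels, affine=components.mask.affine)


# ---------------------------------------------------------------------------
# Mixture-model thresholding of component maps


def mixture_threshold(
    zvals: np.ndarray, seed: int = 0, z_fallback: float = 2.3
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-mixture posterior thresholding of a z-map at p > 0.5.

    Fits 1-, 2- and 3-class Gaussian mixtures (null plus positive and
    optional negative tail classes) to the z histogram by EM, selects the
    model by BIC, and returns the posterior probability of belonging to a
    non-null class together with its > 0.5 thresholding. The null class is
    the one with mean closest to zero. EM failure or a degenerate map falls
    back to |z| > ``z_fallback`` with a logged warning.

    Returns ``(survived, posterior)``.
    """
    from sklearn.mixture import GaussianMixture

    z = np.asarray(zvals, dtype=float).ravel()
    if len(z) < 50:
        raise ValueError("need at least 50 voxels")
    if np.std(z) < 1e-12:
        warnings.warn("degenerate map; falling back to |z| threshold", stacklevel=2)
        survived = np.abs(z) > z_fallback
        return survived, survived.astype(float)
    X = z.reshape(-1, 1)
    best = None
    best_bic = np.inf
    try:
        for n_comp in (1, 2, 3):
            gmm = GaussianMixture(
                n_components=n_comp,
                covariance_type="full",
                n_init=2,
                max_iter=500,
                random_state=int(seed),
                reg_covar=1e-6,
            ).fit(X)
            if not gmm.converged_:
                continue
            bic = gmm.bic(X)
            if bic < best_bic:
                best, best_bic = gmm, bic
    except Exception:  # EM blow-up on pathological maps
        best = None
    if best is None:
        warnings.warn("mixture EM did not converge; falling back to |z| threshold", stacklevel=2)
        survived = np.abs(z) > z_fallback
        return survived, survived.astype(float)
    if best.n_components == 1:
        posterior = np.zeros(len(z))
    else:
        resp = best.predict_proba(X)
        null_class = int(np.argmin(np.abs(best.means_.ravel())))
        posterior = 1.0 - resp[:, null_class]
    return posterior > 0.5, posterior
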