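"""Domain containers shared by every stage of the pipeline.

All imaging types live on a common voxel grid; no resampling is performed
anywhere in the package — masks and priors must match the functional grid
exactly, because group statistics are only meaningful on a shared template
grid and registration/resampling is treated as preprocessing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "VolumeSeries",
    "Mask",
    "TissuePriors",
    "PhysioTrace",
    "DesignBlocks",
    "RealignmentTrack",
    "BeatSeries",
    "FrequencyBand",
    "PairedTestResult",
    "ComponentSet",
    "ReproducibilityCurve",
    "LabelMap",
    "StatMapResult",
    "SelectionResult",
]

TRACE_KINDS = ("pulse", "bp", "respiration")


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine is not invertible")
    return affine


@dataclass
class VolumeSeries:
    """A 4D BOLD series (x, y, z, t) with repetition time and affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, T)
        Voxel intensities in arbitrary BOLD units.
    tr : float
        Repetition time in seconds per volume.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform. Must be invertible.
    run_id : str
        Label identifying the run (used for subject/condition bookkeeping).
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray
    run_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"VolumeSeries needs 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("VolumeSeries needs at least 2 time points")
        if not (self.tr > 0):
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not np.isfinite(self.data).all():
            raise ValueError("VolumeSeries contains non-finite values")
        self.affine = _check_affine(self.affine)

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class Mask:
    """A boolean 3D region of interest on the functional grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("Mask must be 3D")
        if not self.data.any():
            raise ValueError("Mask has no true voxels")
        self.affine = _check_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_grid(self, other) -> None:
        if self.data.shape != tuple(np.shape(other.data)[:3]):
            raise ValueError(
                f"grid mismatch: mask {self.data.shape} vs {np.shape(other.data)[:3]}"
            )


@dataclass
class TissuePriors:
    """Probabilistic grey-matter / white-matter / CSF maps in [0, 1]."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.gm = np.asarray(self.gm, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float)
        self.csf = np.asarray(self.csf, dtype=float)
        for name, arr in (("gm", self.gm), ("wm", self.wm), ("csf", self.csf)):
            if arr.ndim != 3:
                raise ValueError(f"{name} prior must be 3D")
            if arr.min() < 0 or arr.max() > 1 + 1e-6:
                raise ValueError(f"{name} prior values must lie in [0, 1]")
        if self.gm.shape != self.wm.shape or self.gm.shape != self.csf.shape:
            raise ValueError("tissue priors must share one grid")
        if (self.gm + self.wm + self.csf).max() > 1 + 1e-6:
            raise ValueError("tissue priors sum to more than 1 at some voxel")
        self.affine = _check_affine(self.affine)


@dataclass
class PhysioTrace:
    """A uniformly sampled physiological signal with explicit validity flags.

    Dropouts are encoded in ``valid`` rather than with sentinel values, so
    downstream cleaning knows exactly where they were.
    """

    samples: np.ndarray
    fs: float
    kind: str
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("PhysioTrace samples must be 1D")
        if not (self.fs > 0):
            raise ValueError("fs must be positive")
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"kind must be one of {TRACE_KINDS}, got {self.kind!r}")
        if self.valid is None:
            self.valid = np.ones(self.samples.shape, dtype=bool)
        self.valid = np.asarray(self.valid).astype(bool)
        if self.valid.shape != self.samples.shape:
            raise ValueError("valid flags must match sample count")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class DesignBlocks:
    """Ordered, alternating LBNP / Rest blocks in seconds."""

    blocks: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("design must contain at least one block")
        prev_end = -np.inf
        prev_label = None
        clean = []
        for label, start, end in self.blocks:
            if label not in ("LBNP", "Rest"):
                raise ValueError(f"unknown block label {label!r}")
            if not (end > start):
                raise ValueError("block end must exceed start")
            if start < prev_end:
                raise ValueError("blocks must be non-overlapping and increasing")
            if label == prev_label:
                raise ValueError("block labels must alternate")
            clean.append((label, float(start), float(end)))
            prev_end, prev_label = end, label
        self.blocks = clean

    def label_at(self, t: float) -> str | None:
        for label, start, end in self.blocks:
            if start <= t < end:
                return label
        return None

    def condition_mask(self, times: np.ndarray, label: str) -> np.ndarray:
        out = np.zeros(len(times), dtype=bool)
        for lab, start, end in self.blocks:
            if lab == label:
                out |= (times >= start) & (times < end)
        return out


@dataclass
class RealignmentTrack:
    """One rigid 4x4 transform per volume, as produced by motion correction."""

    matrices: np.ndarray

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1:] != (4, 4):
            raise ValueError("RealignmentTrack needs an (n, 4, 4) array")
        rot = self.matrices[:, :3, :3]
        gram = np.einsum("nij,nkj->nik", rot, rot)
        if not np.allclose(gram, np.eye(3), atol=1e-6):
            raise ValueError("rotation parts must be orthonormal (tol 1e-6)")

    def __len__(self) -> int:
        return len(self.matrices)


@dataclass
class BeatSeries:
    """Event times with a per-beat scalar (interbeat interval or systolic BP).

    ``insert_beat`` / ``delete_beat`` are the manual-review hook of the
    semi-automated beat detection: callers may correct the detector output
    before any beat-to-beat series is derived.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "beat"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1D")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("beat times must be strictly increasing")
        if len(self.values) and not np.isfinite(self.values).all():
            raise ValueError("beat values must be finite")

    def __len__(self) -> int:
        return len(self.times)

    def insert_beat(self, time: float, value: float = np.nan) -> "BeatSeries":
        idx = int(np.searchsorted(self.times, time))
        times = np.insert(self.times, idx, time)
        values = np.insert(self.values, idx, value)
        return BeatSeries(times, np.nan_to_num(values), self.kind)

    def delete_beat(self, index: int) -> "BeatSeries":
        return BeatSeries(
            np.delete(self.times, index), np.delete(self.values, index), self.kind
        )


@dataclass(frozen=True)
class FrequencyBand:
    """A spectral band given as centre +/- half-width in Hz."""

    centre: float
    half_width: float

    def __post_init__(self) -> None:
        if not (self.centre - self.half_width > 0):
            raise ValueError("band lower edge must be positive")

    @property
    def lo(self) -> float:
        return self.centre - self.half_width

    @property
    def hi(self) -> float:
        return self.centre + self.half_width


@dataclass
class PairedTestResult:
    """Paired comparison record: t, df, two-sided p, Cohen's d, and summaries."""

    t: float
    df: int
    p: float
    d: float
    n: int
    mean_rest: float
    mean_lbnp: float
    sd_rest: float
    sd_lbnp: float
    method: str = "t"

    def __post_init__(self) -> None:
        if self.df != self.n - 1:
            raise ValueError("df must equal n - 1")
        if not (0 <= self.p <= 1):
            raise ValueError("p must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "t": float(self.t),
            "df": int(self.df),
            "p": float(self.p),
            "d": float(self.d),
            "n": int(self.n),
            "mean_rest": float(self.mean_rest),
            "mean_lbnp": float(self.mean_lbnp),
            "sd_rest": float(self.sd_rest),
            "sd_lbnp": float(self.sd_lbnp),
            "method": self.method,
        }


@dataclass
class ComponentSet:
    """K spatial components on a mask plus per-run mixing time courses.

    ``maps`` holds z-scored loadings over the in-mask voxels (row = component);
    ``mixing`` holds one (T, K) time-course matrix per input run, recovered by
    projection of that run's normalized data onto the maps.
    """

    maps: np.ndarray  # (k, V) z-valued
    mixing: list[np.ndarray]  # per run (T, k)
    mask: Mask
    converged: bool
    seed: int
    run_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be (k, V)")
        if self.maps.shape[0] < 1:
            raise ValueError("need at least one component")
        if self.maps.shape[1] != self.mask.n_voxels:
            raise ValueError("map columns must equal in-mask voxel count")
        for m in self.mixing:
            if m.shape[1] != self.k:
                raise ValueError("mixing column count must equal k")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def map_volume(self, i: int) -> np.ndarray:
        """Return component ``i`` as a full 3D volume (zeros outside mask)."""
        vol = np.zeros(self.mask.data.shape, dtype=float)
        vol[self.mask.data] = self.maps[i]
        return vol

    def map_volumes(self) -> np.ndarray:
        """All components stacked as a 4D (x, y, z, k) array."""
        out = np.zeros(self.mask.data.shape + (self.k,), dtype=float)
        for i in range(self.k):
            out[..., i][self.mask.data] = self.maps[i]
        return out


@dataclass
class ReproducibilityCurve:
    """Split-half reproducibility as a function of ICA dimensionality."""

    dims: list[int]
    mean_r: list[float]
    sd_r: list[float]
    n_converged: list[int]
    n_splits: int

    def __post_init__(self) -> None:
        n = len(self.dims)
        if not (len(self.mean_r) == len(self.sd_r) == len(self.n_converged) == n):
            raise ValueError("curve fields must have equal length")
        for r in self.mean_r:
            if np.isfinite(r) and not (-1 - 1e-9 <= r <= 1 + 1e-9):
                raise ValueError("mean_r must lie in [-1, 1]")


@dataclass
class LabelMap:
    """Winner-take-all segmentation; 0 marks background / excluded territory."""

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        self.affine = _check_affine(self.affine)


@dataclass
class StatMapResult:
    """Voxelwise paired test with TFCE enhancement and FWE-corrected p-values."""

    t_map: np.ndarray  # (V_target,)
    tfce_map: np.ndarray  # signed enhanced statistic
    p_fwe: np.ndarray  # family-wise corrected p per voxel
    n_permutations: int
    seed: int
    target: Mask | None = None

    def __post_init__(self) -> None:
        lo = 1.0 / (self.n_permutations + 1)
        if self.p_fwe.size and (self.p_fwe.min() < lo - 1e-12 or self.p_fwe.max() > 1 + 1e-12):
            raise ValueError("p_fwe out of admissible range")

    @property
    def min_p(self) -> float:
        return float(self.p_fwe.min()) if self.p_fwe.size else 1.0

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_fwe <= alpha


@dataclass
class SelectionResult:
    """Dual-criterion verdict per component plus provenance.

    A component counts as cardiovascular iff it shows a significant spectral
    change in at least one band AND a significant connectivity change in at
    least one target.
    """

    components: list[int]
    spectral: dict  # comp -> {band_name: PairedTestResult}
    fc_significant: dict  # comp -> bool
    fc_summary: dict  # comp -> {target: {"min_p": float, "n_sig": int}}
    cardiovascular: dict  # comp -> bool
    alpha_spec: float
    alpha_fwe: float
    provenance: dict = field(default_factory=dict)

    def selected(self) -> list[int]:
        return [c for c in self.components if self.cardiovascular[c]]

    def to_dict(self) -> dict:
        return {
            "components": list(self.components),
            "spectral": {
                str(c): {b: r.to_dict() for b, r in self.spectral[c].items()}
                for c in self.components
            },
            "fc_significant": {str(c): bool(self.fc_significant[c]) for c in self.components},
            "fc_summary": {str(c): self.fc_summary.get(c, {}) for c in self.components},
            "cardiovascular": {str(c): bool(self.cardiovascular[c]) for c in self.components},
            "selected": self.selected(),
            "alpha_spec": self.alpha_spec,
            "alpha_fwe": self.alpha_fwe,
            "provenance": self.provenance,
        }
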