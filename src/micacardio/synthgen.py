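"""Phantom imaging and physiological data with known ground truth.

The generator emulates the statistical structure the analysis assumes:
spatially compact sources inside a small anatomical mask whose time courses
carry condition-modulated oscillations at the Mayer-wave (~0.1 Hz) and
respiratory (~0.28 Hz) frequencies plus noise; a CSF-locked nuisance source;
pulse plethysmography with respiratory sinus arrhythmia; continuous blood
pressure with Mayer waves, dropouts and outlier spikes. Every injected
effect is recorded in a :class:`GroundTruth` manifest so recovery can be
asserted exactly.

All generators are pure functions of (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import derive_seed
from .types import DesignBlocks, Mask, PhysioTrace, RealignmentTrack, TissuePriors, VolumeSeries

__all__ = ["PhantomSpec", "GroundTruth", "make_phantom", "make_physio", "make_realign", "default_mask"]

LF_HZ = 0.1  # Mayer-wave band centre
HF_HZ = 0.28  # respiratory band centre


@dataclass
class SourceAmplitudes:
    """Per-source oscillation gains by condition (arbitrary BOLD units)."""

    baseline: float = 0.2  # slow drift amplitude
    lf_gain_rest: float = 1.0
    lf_gain_lbnp: float = 1.0
    hf_gain_rest: float = 1.0
    hf_gain_lbnp: float = 1.0


@dataclass
class Coupling:
    """Condition-dependent directed shared signal from source a into b's core.

    At weight ``w`` source a's stochastic time-course component is expressed
    in the *core* of source b's territory (a blob at b's centre with 0.6 x
    its radius, orthogonalized against all source maps). The profile is
    deliberately not in the span of the source maps: a joint stage-2 dual
    regression partials out anything lying exactly in that span, so only
    such off-profile shared signal is — and should be — visible as a
    functional-connectivity change of component a at b's territory, while no
    stage-1 time course (and hence no spectral fraction) is affected.
    """

    a: int
    b: int
    w_rest: float = 0.0
    w_lbnp: float = 0.9


@dataclass
class PhantomSpec:
    """Desk-scale mimicry of the real 2 mm / 1.23 s / 4 x 233-volume protocol.

    Defaults: 24x24x12 grid, an ellipsoidal mask of ~600 voxels, k_true = 8
    Gaussian-blob sources (truncated at 2 sigma), 4 runs x 240 volumes at
    tr = 1.25 s with alternating LBNP/Rest labels starting with LBNP.
    """

    grid: tuple[int, int, int] = (24, 24, 12)
    tr: float = 1.25
    n_volumes: int = 240
    n_runs: int = 4
    k_true: int = 8
    centres: list[tuple[float, float, float]] | None = None
    radii: list[float] | None = None
    amplitudes: list[SourceAmplitudes] | None = None
    couplings: list[Coupling] = field(default_factory=list)
    noise_sd: float = 0.5  # imaging noise, in map-peak units
    tc_noise_sd: float = 1.0  # stochastic part of each source time course
    run_cv: float = 0.15  # per-run heterogeneity of gains/amplitudes/noise
    csf_source: bool = True  # last source is CSF-locked
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.n_runs % 2:
            raise ValueError("n_runs must be even (alternating conditions)")
        if self.centres is None:
            self.centres = _default_centres(self.grid, self.k_true)
        if self.radii is None:
            self.radii = [1.0] * self.k_true
        if self.amplitudes is None:
            self.amplitudes = default_amplitudes(self.k_true)
        if len(self.centres) != self.k_true or len(self.radii) != self.k_true:
            raise ValueError("centres/radii must have k_true entries")
        if len(self.amplitudes) != self.k_true:
            raise ValueError("amplitude table must have k_true entries")
        for amp in self.amplitudes:
            for g in (amp.lf_gain_rest, amp.lf_gain_lbnp, amp.hf_gain_rest, amp.hf_gain_lbnp):
                if g < 0:
                    raise ValueError("gains must be non-negative")
        for c in self.couplings:
            if not (0 <= c.a < self.k_true and 0 <= c.b < self.k_true and c.a != c.b):
                raise ValueError("coupling indices out of range")

    @property
    def conditions(self) -> list[str]:
        return ["LBNP" if i % 2 == 0 else "Rest" for i in range(self.n_runs)]


def default_amplitudes(k_true: int) -> list[SourceAmplitudes]:
    """Default study conditions: two dual-criterion sources, one spectral-only
    source, one coupling-only source, the rest null.

    Source 0: HF power reduced under LBNP (mimics vagal withdrawal) + coupled.
    Source 1: LF power increased under LBNP (mimics Mayer-wave gain) + coupled.
    Source 2: HF reduction only (spectral criterion without connectivity).
    Source 3: coupling only (connectivity criterion without spectral change).
    """
    amps = [SourceAmplitudes() for _ in range(k_true)]
    if k_true >= 1:
        amps[0] = SourceAmplitudes(hf_gain_rest=1.5, hf_gain_lbnp=0.5)
    if k_true >= 2:
        amps[1] = SourceAmplitudes(lf_gain_rest=0.8, lf_gain_lbnp=1.2)
    if k_true >= 3:
        amps[2] = SourceAmplitudes(hf_gain_rest=1.5, hf_gain_lbnp=0.5)
    return amps


def default_couplings(k_true: int) -> list[Coupling]:
    """Mutual pair (0, 1) plus the coupling-only source 3 projecting into 0.

    All injections land in the core territories of the dual-criterion
    sources 0 and 1, keeping shared-signal energy away from the null
    sources' territories.
    """
    out = []
    if k_true >= 2:
        out.append(Coupling(0, 1))
        out.append(Coupling(1, 0))
    if k_true >= 4:
        out.append(Coupling(3, 0))
    return out


@dataclass
class GroundTruth:
    """Everything the generator injected, for exact recovery assertions."""

    source_maps: np.ndarray | None = None  # (k, nx, ny, nz)
    time_courses: list[np.ndarray] | None = None  # per run (T, k)
    conditions: list[str] | None = None
    spectral_change_sources: list[dict] | None = None  # {source, band, direction}
    coupled_pairs: list[tuple[int, int]] | None = None
    csf_source: int | None = None
    beat_times: np.ndarray | None = None
    dropout_indices: np.ndarray | None = None
    spike_indices: np.ndarray | None = None

    def to_manifest(self) -> dict:
        out: dict = {}
        if self.conditions is not None:
            out["conditions"] = list(self.conditions)
        if self.spectral_change_sources is not None:
            out["spectral_change_sources"] = self.spectral_change_sources
        if self.coupled_pairs is not None:
            out["coupled_pairs"] = [list(p) for p in self.coupled_pairs]
        if self.csf_source is not None:
            out["csf_source"] = int(self.csf_source)
        if self.beat_times is not None:
            out["beat_times"] = [float(t) for t in self.beat_times]
        if self.dropout_indices is not None:
            out["dropout_indices"] = [int(i) for i in self.dropout_indices]
        if self.spike_indices is not None:
            out["spike_indices"] = [int(i) for i in self.spike_indices]
        return out


# ---------------------------------------------------------------------------
# Imaging phantom


def default_mask(grid: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal mask (~600 voxels at the default 24x24x12 grid)."""
    nx, ny, nz = grid
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 6.0, 6.0, 4.0
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _default_centres(grid, k_true):
    """Blob centres on two staggered rings inside the mask.

    With the default sigma = 1.0 (truncation radius 2) every blob voxel stays
    inside the default ellipsoidal mask and adjacent cross-ring blobs overlap
    by roughly 15 % of their volume — the partial-overlap regime masked ICA
    must handle (neighbouring nuclei abut).
    """
    nx, ny, nz = grid
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    centres = []
    for i in range(k_true):
        ring = i % 2
        ang = 2 * np.pi * (i // 2) / max((k_true + 1) // 2, 1) + (np.pi / 4) * ring
        z = cz + (0.7 if ring else -0.7)
        centres.append((cx + 3.0 * np.cos(ang), cy + 3.0 * np.sin(ang), z))
    return centres


def _blob(grid, centre, sigma):
    """Gaussian blob truncated at 2 sigma, peak 1."""
    nx, ny, nz = grid
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    d2 = (x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2
    blob = np.exp(-0.5 * d2 / sigma**2)
    blob[d2 > (2 * sigma) ** 2] = 0.0
    return blob


def _source_time_course(amp, cond, rng, t, noise_sd):
    """drift + condition-gated LF/HF sinusoids + white noise.

    The noise is rescaled per condition so the total time-course variance
    equals its Rest-condition value: an injected band-power change then
    alters the spectral *composition* of the source without altering its
    amplitude, and must not register as a connectivity change
    (total-variance differences would shift dual-regression betas across a
    source's whole territory). Returns ``(tc, unit_noise)``; the latter is
    the standardized stochastic component used for coupling injections.
    """
    lf_gain = amp.lf_gain_lbnp if cond == "LBNP" else amp.lf_gain_rest
    hf_gain = amp.hf_gain_lbnp if cond == "LBNP" else amp.hf_gain_rest
    phi, psi = rng.uniform(0, 2 * np.pi, 2)
    tc = amp.baseline * np.cos(2 * np.pi * 0.01 * t + rng.uniform(0, 2 * np.pi))
    tc = tc + lf_gain * np.sin(2 * np.pi * LF_HZ * t + phi)
    tc = tc + hf_gain * np.sin(2 * np.pi * HF_HZ * t + psi)
    sin_var_rest = (amp.lf_gain_rest**2 + amp.hf_gain_rest**2) / 2.0
    sin_var_cond = (lf_gain**2 + hf_gain**2) / 2.0
    noise_var = max(noise_sd**2 + sin_var_rest - sin_var_cond, 0.01 * noise_sd**2)
    unit_noise = rng.standard_normal(len(t))
    return tc + np.sqrt(noise_var) * unit_noise, unit_noise


def make_phantom(spec: PhantomSpec) -> tuple[list[VolumeSeries], Mask, TissuePriors, GroundTruth]:
    """Generate phantom runs, mask, tissue priors and the ground-truth manifest.

    Each run's in-mask data is sum_k map_k(v) * tc_k(t) plus white imaging
    noise (which also fills the out-of-mask background). Runs alternate
    LBNP/Rest; consecutive (LBNP, Rest) pairs form one synthetic subject.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, "phantom"))
    affine = np.eye(4)
    mask_data = default_mask(spec.grid)
    mask = Mask(data=mask_data, affine=affine)

    maps = np.stack([_blob(spec.grid, c, r) for c, r in zip(spec.centres, spec.radii)])
    for i in range(spec.k_true):
        if not mask_data[maps[i] > 0].all():
            raise ValueError(f"source {i} extends outside the mask")

    priors, csf_idx = _make_priors(spec, mask_data, maps, affine)

    t = np.arange(spec.n_volumes) * spec.tr
    runs: list[VolumeSeries] = []
    tcs: list[np.ndarray] = []
    conditions = spec.conditions
    # Coupling injection profiles: a core blob (0.6 x radius) at each source's
    # centre, orthogonalized against the span of all source maps (plus
    # intercept) over the mask voxels. Orthogonality keeps the injected
    # shared signal out of every stage-1 time-course estimate, so coupling
    # changes connectivity (stage-2 partial betas) without touching any
    # component's spectral content.
    flat = maps.reshape(spec.k_true, -1)
    cores = np.stack(
        [_blob(spec.grid, c, 0.6 * r) for c, r in zip(spec.centres, spec.radii)]
    ).reshape(spec.k_true, -1)
    in_mask = mask_data.ravel()
    design = np.vstack([np.ones(int(in_mask.sum())), flat[:, in_mask]]).T
    cores_perp = np.zeros_like(cores)
    for k in range(spec.k_true):
        coef, *_ = np.linalg.lstsq(design, cores[k, in_mask], rcond=None)
        cores_perp[k, in_mask] = cores[k, in_mask] - design @ coef

    def jitter(rng, n=1):
        if spec.run_cv <= 0:
            return np.ones(n)
        return np.clip(1.0 + rng.normal(0.0, spec.run_cv, size=n), 0.5, 1.5)

    for r_i, cond in enumerate(conditions):
        run_rng = np.random.default_rng(derive_seed(spec.seed, "run", r_i))
        # per-run physiological heterogeneity: each source's oscillation
        # gains, noise level and overall amplitude fluctuate around the
        # cohort values (condition contrasts are preserved multiplicatively)
        j_lf = jitter(run_rng, spec.k_true)
        j_hf = jitter(run_rng, spec.k_true)
        j_noise = jitter(run_rng, spec.k_true)
        j_amp = jitter(run_rng, spec.k_true)
        tc = np.empty((spec.n_volumes, spec.k_true))
        unit_noise = np.empty((spec.n_volumes, spec.k_true))
        for k in range(spec.k_true):
            a = spec.amplitudes[k]
            amp_k = SourceAmplitudes(
                baseline=a.baseline,
                lf_gain_rest=a.lf_gain_rest * j_lf[k],
                lf_gain_lbnp=a.lf_gain_lbnp * j_lf[k],
                hf_gain_rest=a.hf_gain_rest * j_hf[k],
                hf_gain_lbnp=a.hf_gain_lbnp * j_hf[k],
            )
            tc_k, unit_noise[:, k] = _source_time_course(
                amp_k, cond, run_rng, t, spec.tc_noise_sd * j_noise[k]
            )
            tc[:, k] = tc_k * j_amp[k]
        data_flat = flat.T @ tc.T  # (V_grid, T)
        for c in spec.couplings:
            w = (c.w_lbnp if cond == "LBNP" else c.w_rest) * jitter(run_rng)[0]
            if w == 0:
                continue
            amp = w * spec.tc_noise_sd
            data_flat += amp * np.outer(cores_perp[c.b], unit_noise[:, c.a])
        data = data_flat.reshape(spec.grid + (spec.n_volumes,))
        if spec.noise_sd > 0:
            data = data + spec.noise_sd * run_rng.standard_normal(data.shape)
        subject = r_i // 2
        runs.append(
            VolumeSeries(
                data=data, tr=spec.tr, affine=affine, run_id=f"sub{subject:02d}_{cond}_{r_i:02d}"
            )
        )
        tcs.append(tc)

    truth = GroundTruth(
        source_maps=maps,
        time_courses=tcs,
        conditions=conditions,
        spectral_change_sources=_spectral_changes(spec),
        coupled_pairs=[(c.a, c.b) for c in spec.couplings if c.w_rest != c.w_lbnp],
        csf_source=csf_idx,
    )
    return runs, mask, priors, truth


def _spectral_changes(spec: PhantomSpec) -> list[dict]:
    out = []
    for k, amp in enumerate(spec.amplitudes):
        if amp.lf_gain_rest != amp.lf_gain_lbnp:
            out.append(
                {"source": k, "band": "LF",
                 "direction": "up" if amp.lf_gain_lbnp > amp.lf_gain_rest else "down"}
            )
        if amp.hf_gain_rest != amp.hf_gain_lbnp:
            out.append(
                {"source": k, "band": "HF",
                 "direction": "up" if amp.hf_gain_lbnp > amp.hf_gain_rest else "down"}
            )
    return out


def _make_priors(spec, mask_data, maps, affine):
    """GM inside the mask, a WM shell around it, CSF locked to the last source.

    If ``csf_source`` is set, the last source's exact support gets csf ~0.9
    (so 100 % of its map mass lies on CSF voxels) without bleeding into
    neighbouring sources' territory.
    """
    grid = spec.grid
    gm = np.zeros(grid)
    wm = np.zeros(grid)
    csf = np.zeros(grid)
    gm[mask_data] = 0.85

    from scipy.ndimage import binary_dilation

    shell = binary_dilation(mask_data, iterations=2) & ~mask_data
    wm[shell] = 0.7

    csf_idx = None
    if spec.csf_source:
        csf_idx = spec.k_true - 1
        region = _blob(grid, spec.centres[csf_idx], spec.radii[csf_idx]) > 0
        csf[region] = 0.9
        gm[region] = 0.05
        wm[region] = 0.0
    return TissuePriors(gm=gm, wm=wm, csf=csf, affine=affine), csf_idx


# ---------------------------------------------------------------------------
# Physiological phantom


def make_physio(
    duration: float,
    fs: float,
    hr_bpm: float = 60.0,
    rsa_depth: float = 0.08,
    mayer_depth: float = 4.0,
    dropout_rate: float = 0.0,
    spike_rate: float = 0.0,
    condition_blocks: DesignBlocks | None = None,
    seed: int = 0,
    resp_hz: float = HF_HZ,
    rsa_lbnp_factor: float = 0.5,
    mayer_lbnp_factor: float = 2.0,
    bp_noise_sd: float = 2.0,
    ibi_jitter_sd: float = 0.0,
) -> tuple[PhysioTrace, PhysioTrace, PhysioTrace, GroundTruth]:
    """Generate pulse, blood-pressure and respiration traces.

    The pulse is a train of Gaussian systolic upstrokes whose instantaneous
    rate is modulated at the respiratory frequency (respiratory sinus
    arrhythmia, depth ``rsa_depth``, reduced by ``rsa_lbnp_factor`` during
    LBNP blocks). Blood pressure is a beat-synchronous systolic envelope
    (120/80 mmHg nominal) plus a 0.1 Hz Mayer oscillation of amplitude
    ``mayer_depth`` mmHg (scaled by ``mayer_lbnp_factor`` during LBNP), with
    dropout runs and +100 mmHg outlier spikes injected at the stated rates
    (events per second). Beat-to-beat systolic jitter of fixed standard
    deviation ``bp_noise_sd`` mmHg provides the amplitude-independent
    variability floor against which a Mayer-depth change alters the LF power
    *fraction* (a pure sinusoid's fractional power is scale-invariant).
    True beat times and corrupted sample indices are recorded in the
    returned :class:`GroundTruth`.
    """
    if fs < 25:
        raise ValueError("fs must be >= 25 Hz")
    if not (40 <= hr_bpm <= 120):
        raise ValueError("hr_bpm must lie in [40, 120]")
    rng = np.random.default_rng(derive_seed(seed, "physio"))
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    def rsa_at(tt: float) -> float:
        depth = rsa_depth
        if condition_blocks is not None and condition_blocks.label_at(tt) == "LBNP":
            depth = rsa_depth * rsa_lbnp_factor
        return depth

    # beat times: integrate instantaneous rate; stop short of the trace end so
    # every true beat has a fully supported, detectable pulse waveform
    beat_times = []
    ti = 0.5
    base_ibi = 60.0 / hr_bpm
    while ti < duration - 0.5:
        beat_times.append(ti)
        ibi = base_ibi * (1.0 - rsa_at(ti) * np.sin(2 * np.pi * resp_hz * ti))
        if ibi_jitter_sd > 0:
            ibi += rng.normal(0.0, ibi_jitter_sd)
        ti += max(ibi, 0.3)
    beat_times = np.array(beat_times)

    # pulse: Gaussian upstroke at each beat
    pulse = np.zeros(n)
    sigma = 0.08
    for bt in beat_times:
        lo = max(0, int((bt - 4 * sigma) * fs))
        hi = min(n, int((bt + 4 * sigma) * fs) + 1)
        pulse[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - bt) / sigma) ** 2)

    # blood pressure: diastolic floor + pulse-pressure bump + Mayer wave
    mayer_amp = np.full(n, mayer_depth)
    if condition_blocks is not None:
        lbnp = condition_blocks.condition_mask(t, "LBNP")
        mayer_amp[lbnp] = mayer_depth * mayer_lbnp_factor
    mayer = mayer_amp * np.sin(2 * np.pi * LF_HZ * t)
    # per-beat systolic jitter, piecewise constant over beat intervals
    sbp_noise = np.zeros(n)
    if bp_noise_sd > 0 and len(beat_times) > 1:
        offsets = rng.normal(0.0, bp_noise_sd, size=len(beat_times))
        edges = np.searchsorted(t, beat_times)
        for b in range(len(beat_times)):
            hi = edges[b + 1] if b + 1 < len(beat_times) else n
            sbp_noise[edges[b]:hi] = offsets[b]
    bp = 80.0 + (40.0 + mayer + sbp_noise) * pulse

    resp = np.sin(2 * np.pi * resp_hz * t)

    valid = np.ones(n, dtype=bool)
    dropout_idx: list[int] = []
    n_dropouts = rng.poisson(dropout_rate * duration)
    for _ in range(n_dropouts):
        start = rng.integers(0, n)
        length = int(rng.uniform(0.2, 1.0) * fs)
        sl = slice(start, min(n, start + length))
        valid[sl] = False
        bp[sl] = 0.0
        dropout_idx.extend(range(sl.start, sl.stop))

    spike_idx: list[int] = []
    n_spikes = rng.poisson(spike_rate * duration)
    if n_spikes:
        candidates = np.flatnonzero(valid)
        picks = rng.choice(candidates, size=min(n_spikes, len(candidates)), replace=False)
        bp[picks] += 100.0
        spike_idx = sorted(int(i) for i in picks)

    truth = GroundTruth(
        beat_times=beat_times,
        dropout_indices=np.array(sorted(set(dropout_idx)), dtype=int),
        spike_indices=np.array(spike_idx, dtype=int),
    )
    return (
        PhysioTrace(samples=pulse, fs=fs, kind="pulse"),
        PhysioTrace(samples=bp, fs=fs, kind="bp", valid=valid),
        PhysioTrace(samples=resp, fs=fs, kind="respiration"),
        truth,
    )


# ---------------------------------------------------------------------------
# Motion phantom


def make_realign(n_volumes: int, motion_sd: float, seed: int = 0) -> RealignmentTrack:
    """Random-walk rigid track: translation steps ~ N(0, motion_sd^2) per axis."""
    if motion_sd < 0:
        raise ValueError("motion_sd must be >= 0")
    rng = np.random.default_rng(derive_seed(seed, "realign"))
    mats = np.tile(np.eye(4), (n_volumes, 1, 1))
    trans = np.cumsum(rng.normal(0.0, motion_sd, size=(n_volumes, 3)), axis=0)
    trans[0] = 0.0  # first volume is the reference
    mats[:, :3, 3] = trans
    return RealignmentTrack(matrices=mats)
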