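"""Synthetic moving water-fat thorax phantom and dual-echo acquisition simulator.

The phantom is a desk-scale stand-in for the thorax: a water body with
vessel-like water-only tubes, a subcutaneous fat layer, a liver compartment
below a diaphragm interface and a heart blob above it.  Respiratory motion is
a foot-head translation of the sub-diaphragm compartment with a linear decay
to zero at the chest wall; the heart compartment moves at 0.57x the diaphragm
displacement (the hepatic-to-cardiac motion ratio used throughout the
reconstruction).  This motion model is analytically known, so every pipeline
stage can be scored against ground truth.

The acquisition emulates an ECG-triggered dual-echo spoiled gradient echo:
per heartbeat window, a ky=kz=0 self-navigator line followed by a center-out
sweep of phase-encode points; both echoes are sampled per line.  The readout
dimension is simulated in hybrid space (already inverse-transformed), so
k-space "lines" are (ky, kz) samples of 1D readout profiles, matching how the
self-gating stage consumes them.  The Fourier convention is centered and
orthonormal along both phase axes (adjoint = inverse).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .motion_estimation import DeformationFieldSet, LinearWarp

__all__ = [
    "FatSpectralModel",
    "PhantomGroundTruth",
    "BreathingTrace",
    "AcquisitionParams",
    "KSpaceSet",
    "make_phantom",
    "make_breathing_trace",
    "simulate_acquisition",
    "ground_truth_fields",
    "phantom_at_displacement",
    "cfft2",
    "icfft2",
]

_PHASE_AXES = (-2, -1)


def cfft2(img: np.ndarray) -> np.ndarray:
    """Centered orthonormal FT along the two phase-encode axes (ky, kz)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=_PHASE_AXES), axes=_PHASE_AXES, norm="ortho"),
        axes=_PHASE_AXES,
    )


def icfft2(ksp: np.ndarray) -> np.ndarray:
    """Inverse (= adjoint) of :func:`cfft2`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=_PHASE_AXES), axes=_PHASE_AXES, norm="ortho"),
        axes=_PHASE_AXES,
    )


# ---------------------------------------------------------------------------
# Spectral model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FatSpectralModel:
    """Two-echo fat signal evolution.

    ``dfat[i]`` is the complex factor multiplying the fat image at echo i:
    dfat_i = sum_s alpha_s * exp(2j*pi*dfs_s*TE_i) over spectral peaks s.
    The default constants are the empirically calibrated values for
    TE = 2.8/6.5 ms; if an explicit peak list ``peaks`` (frequency shift in
    Hz, weight) is supplied, dfat is recomputed from it so the simulator and
    the reconstruction share one self-consistent model.
    """

    echo_times: tuple = (2.8e-3, 6.5e-3)
    dfat: tuple = (0.70 - 0.37j, -0.58 - 0.20j)
    peaks: tuple | None = None

    def __post_init__(self):
        if self.peaks is not None:
            peaks = tuple((float(f), float(a)) for f, a in self.peaks)
            total = sum(a for _, a in peaks)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"peak weights must sum to 1, got {total}")
            dfat = tuple(
                complex(sum(a * np.exp(2j * np.pi * f * te) for f, a in peaks))
                for te in self.echo_times
            )
            object.__setattr__(self, "peaks", peaks)
            object.__setattr__(self, "dfat", dfat)
        if len(self.dfat) != len(self.echo_times):
            raise ValueError("dfat must have one entry per echo time")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


@dataclass
class PhantomGroundTruth:
    """Known water/fat volumes, phase fields, coil maps and motion geometry."""

    water: np.ndarray
    fat: np.ndarray
    phase_fields: list  # unit-modulus complex field per echo (b1, b2)
    coil_maps: np.ndarray  # [n_coils, nx, ny, nz]
    voxel_size: float  # mm, isotropic
    motion_amplitude: float = 0.0  # mm
    diaphragm_roi: tuple = ()
    body_mask: np.ndarray | None = None
    motion_weight: np.ndarray | None = None  # foot-head motion shape field
    heart_mask: np.ndarray | None = None

    @property
    def grid_shape(self) -> tuple:
        return self.water.shape

    @property
    def n_coils(self) -> int:
        return self.coil_maps.shape[0]


def make_phantom(
    grid_shape=(64, 64, 32),
    voxel_size: float = 3.0,
    seed: int = 0,
    n_coils: int = 4,
) -> PhantomGroundTruth:
    """Build the moving water-fat thorax phantom.

    Axis 0 is the readout / foot-head direction.  The object contains a water
    body, a peripheral fat layer, a brighter liver compartment below the
    diaphragm, a heart ellipsoid, and several thin (<=3 voxel) water-only
    tubes running head-foot that probe vessel sharpness.  Phase fields are
    derived from one smooth synthetic off-resonance map evaluated at both
    echo times, so the inter-echo phasor b2*conj(b1) is spatially smooth.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if min(grid_shape) < 16:
        raise ValueError("each grid dimension must be >= 16 voxels")
    nx, ny, nz = grid_shape
    rng = np.random.default_rng(seed)
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    ry, rz = 0.42 * ny, 0.40 * nz
    ell = ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
    body = ell <= 1.0
    inner = ell <= 0.80  # fat shell occupies 0.80 < ell <= 1

    water = np.zeros(grid_shape)
    fat = np.zeros(grid_shape)
    water[inner] = 0.45
    fat[body & ~inner] = 0.90

    # diaphragm interface: liver below (low x), thorax above
    x_d = int(round(0.35 * nx))
    dome = x_d + np.round(
        2.5 * np.exp(-(((y - cy) / (0.3 * ny)) ** 2 + ((z - cz) / (0.3 * nz)) ** 2))
    ).astype(int)
    liver = inner & (x < dome)
    water[liver] = 0.75

    # heart ellipsoid in the upper thorax
    hc = (int(0.62 * nx), int(0.42 * ny), int(0.5 * nz))
    hr = (0.16 * nx, 0.18 * ny, 0.26 * nz)
    heart = (
        ((x - hc[0]) / hr[0]) ** 2
        + ((y - hc[1]) / hr[1]) ** 2
        + ((z - hc[2]) / hr[2]) ** 2
    ) <= 1.0
    heart &= inner
    water[heart] = 0.85

    # thin water-only vessels along the readout direction
    n_vessels = 5
    for _ in range(n_vessels):
        vy = rng.uniform(cy - 0.28 * ny, cy + 0.28 * ny)
        vz = rng.uniform(cz - 0.28 * nz, cz + 0.28 * nz)
        rad = rng.uniform(0.6, 1.4)  # voxels; diameter <= ~3
        tube = ((y - vy) ** 2 + (z - vz) ** 2) <= rad**2
        tube &= inner
        water[tube] = 1.0
        fat[tube] = 0.0

    # mild parenchymal texture: real tissue is not piecewise constant, and
    # featureless interiors leave non-rigid registration unconstrained
    tex = gaussian_filter(rng.standard_normal(grid_shape), 1.5)
    tex = 1.0 + 0.18 * tex / max(np.abs(tex).max(), 1e-12)
    water *= tex
    fat *= tex

    # mild smoothing for realistic edges, then re-impose support and positivity
    water = gaussian_filter(water, 0.6)
    fat = gaussian_filter(fat, 0.6)
    water[~body] = 0.0
    fat[~body] = 0.0
    np.clip(water, 0.0, None, out=water)
    np.clip(fat, 0.0, None, out=fat)

    # smooth off-resonance (Hz) and receive phase -> unit phasors per echo
    f0 = gaussian_filter(rng.standard_normal(grid_shape), 6.0)
    f0 *= 30.0 / max(np.abs(f0).max(), 1e-12)  # ~+-30 Hz, plausible at 0.55 T
    rx = gaussian_filter(rng.standard_normal(grid_shape), 8.0)
    rx *= 0.8 / max(np.abs(rx).max(), 1e-12)
    te = FatSpectralModel().echo_times
    phase_fields = [np.exp(1j * (2 * np.pi * f0 * t + rx)) for t in te]

    # smooth complex coil maps: Gaussian lobes around the (y, z) perimeter
    coil_maps = np.zeros((n_coils,) + grid_shape, dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        py, pz = cy + 0.75 * ry * np.cos(ang), cz + 0.75 * rz * np.sin(ang)
        mag = np.exp(-(((y - py) / (0.6 * ny)) ** 2 + ((z - pz) / (0.6 * nz)) ** 2))
        ph = 0.5 * np.cos(ang) * (y - cy) / ny + 0.5 * np.sin(ang) * (z - cz) / nz
        coil_maps[c] = mag * np.exp(1j * ph)

    # foot-head motion shape: rigid below the diaphragm, linear decay above,
    # heart compartment scaled to 0.57x the diaphragm excursion
    w_shape = np.clip((nx - 1.0 - x) / max(nx - 1.0 - x_d, 1), 0.0, 1.0)
    w_shape[x <= x_d] = 1.0
    w_shape = w_shape * 1.0
    w_shape[heart] = 0.57

    dy = int(np.round(cy))
    dz = int(np.round(cz))
    diaphragm_roi = (
        (max(x_d - 1, 0), min(x_d + 2, nx)),
        (dy - 1, dy + 2),
        (dz - 1, dz + 2),
    )
    return PhantomGroundTruth(
        water=water,
        fat=fat,
        phase_fields=phase_fields,
        coil_maps=coil_maps,
        voxel_size=float(voxel_size),
        diaphragm_roi=diaphragm_roi,
        body_mask=body,
        motion_weight=w_shape,
        heart_mask=heart,
    )


# ---------------------------------------------------------------------------
# Breathing traces
# ---------------------------------------------------------------------------


@dataclass
class BreathingTrace:
    """Diaphragm foot-head position (mm) at each heartbeat window.

    Positive displacement = inspiration.  ``amplitude_mm`` is the half
    peak-to-peak excursion, so a regular trace spans [-A, +A].
    """

    times: np.ndarray
    displacement: np.ndarray
    pattern: str
    seed: int
    amplitude_mm: float
    period_s: float = 3.8
    heart_rate_bpm: float = 60.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.times.shape != self.displacement.shape:
            raise ValueError("times and displacement must have the same length")

    def __len__(self) -> int:
        return self.times.size


_PATTERNS = ("regular", "irregular", "drifting")


def make_breathing_trace(
    pattern: str,
    n_windows: int,
    amplitude_mm: float,
    seed: int = 0,
    heart_rate_bpm: float = 60.0,
    period_s: float = 3.8,
) -> BreathingTrace:
    """Generate a per-heartbeat diaphragm trace.

    regular   -- periodic breathing with an end-expiratory plateau;
    irregular -- per-cycle amplitude and end-expiratory baseline jitter;
    drifting  -- regular breathing plus a monotone baseline drift.

    The sampled trace is affinely rescaled to span exactly [-A, +A], so the
    peak-to-peak excursion equals 2*amplitude_mm by construction.
    """
    if pattern not in _PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; valid: {_PATTERNS}")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if amplitude_mm <= 0:
        raise ValueError("amplitude_mm must be > 0")
    rng = np.random.default_rng(seed)
    rr = 60.0 / heart_rate_bpm
    t = np.arange(n_windows) * rr
    # raised-cosine shape with exponent > 1: the trace dwells near -A,
    # emulating the expiratory plateau of quiet breathing
    plateau_p = 1.6

    def _cycle_shape(phase):
        return 2.0 * ((1.0 - np.cos(phase)) / 2.0) ** plateau_p - 1.0

    if pattern == "regular":
        d = amplitude_mm * _cycle_shape(2 * np.pi * t / period_s)
    else:
        # integrate a jittered instantaneous frequency cycle by cycle
        n_cycles = int(np.ceil(t[-1] / period_s)) + 2 if n_windows > 1 else 2
        cyc_period = period_s * (1.0 + 0.15 * rng.standard_normal(n_cycles))
        cyc_period = np.clip(cyc_period, 0.5 * period_s, 1.5 * period_s)
        cyc_amp = 1.0 + 0.30 * rng.standard_normal(n_cycles)
        cyc_amp = np.clip(cyc_amp, 0.4, 1.6)
        cyc_base = 0.15 * rng.standard_normal(n_cycles)
        edges = np.concatenate([[0.0], np.cumsum(cyc_period)])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_cycles - 1)
        phase = 2 * np.pi * (t - edges[idx]) / cyc_period[idx]
        d = amplitude_mm * (cyc_amp[idx] * (_cycle_shape(phase) + 1.0) / 2.0 * 2.0
                            - 1.0 + cyc_base[idx])
        if pattern == "drifting":
            d = d + amplitude_mm * 0.5 * t / max(t[-1], 1e-9)
    if n_windows > 1 and d.max() > d.min():
        d = (d - d.min()) / (d.max() - d.min()) * 2 * amplitude_mm - amplitude_mm
    return BreathingTrace(
        times=t,
        displacement=d,
        pattern=pattern,
        seed=seed,
        amplitude_mm=float(amplitude_mm),
        period_s=float(period_s),
        heart_rate_bpm=float(heart_rate_bpm),
    )


# ---------------------------------------------------------------------------
# Acquisition parameters and the k-space container
# ---------------------------------------------------------------------------


@dataclass
class AcquisitionParams:
    """Sequence parameters; defaults mirror the dual-echo protocol.

    ``t2prep_scale`` is a scalar contrast factor standing in for the 40 ms
    T2-preparation (no Bloch simulation: the pipeline never uses
    sequence-level amplitudes).  ``noise_sigma`` is the complex-Gaussian
    k-space noise std relative to the peak coil-weighted image signal.
    """

    tr: float = 9.1e-3
    flip_deg: float = 15.0
    nsegments: int = 16
    heart_rate_bpm: float = 60.0
    noise_sigma: float = 0.03
    t2prep_scale: float = 1.0

    def __post_init__(self):
        if self.nsegments < 2:
            raise ValueError("nsegments must be >= 2")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class KSpaceSet:
    """Annotated dual-echo Cartesian k-space lines grouped by heartbeat window.

    ``data`` has shape [line, echo, readout, coil]; ``ky``/``kz`` are signed
    centered grid indices (DC at 0); ``window`` maps lines to acquisition
    windows; ``time`` is seconds per line.
    """

    data: np.ndarray
    ky: np.ndarray
    kz: np.ndarray
    window: np.ndarray
    time: np.ndarray
    coil_maps: np.ndarray
    grid_shape: tuple
    voxel_size: float
    params: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self):
        self.ky = np.asarray(self.ky, dtype=int)
        self.kz = np.asarray(self.kz, dtype=int)
        self.window = np.asarray(self.window, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        self.grid_shape = tuple(int(g) for g in self.grid_shape)

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_windows(self) -> int:
        return int(self.window.max()) + 1 if self.n_lines else 0

    @property
    def n_coils(self) -> int:
        return self.data.shape[3]

    def center_lines(self, echo: int = 1) -> np.ndarray:
        """The first ky=kz=0 line of each window: [window, readout, coil]."""
        out = []
        for w in range(self.n_windows):
            idx = np.where((self.window == w) & (self.ky == 0) & (self.kz == 0))[0]
            if idx.size == 0:
                raise ValueError(f"window {w} has no ky=kz=0 self-navigator line")
            first = idx[np.argmin(self.time[idx])]
            out.append(self.data[first, echo])
        return np.stack(out)

    def window_times(self) -> np.ndarray:
        return np.array(
            [self.time[self.window == w].min() for w in range(self.n_windows)]
        )

    def grid_indices(self) -> tuple:
        """(iy, iz) array indices on the centered k-grid (DC at n//2)."""
        _, ny, nz = self.grid_shape
        return self.ky + ny // 2, self.kz + nz // 2


# ---------------------------------------------------------------------------
# Ground-truth fields and the forward simulation
# ---------------------------------------------------------------------------


def _displacement_field(phantom: PhantomGroundTruth, d_mm: float) -> np.ndarray:
    """Warp field (mm) that displaces the object by +d_mm foot-head.

    The warp convention is out(r) = vol(r + u(r)), so shifting tissue by +d
    requires u = -d * shape(r).
    """
    f = np.zeros((3,) + phantom.grid_shape)
    f[0] = -d_mm * phantom.motion_weight
    return f


def ground_truth_fields(
    phantom: PhantomGroundTruth,
    state_displacements_mm,
    reference_state: int = 0,
) -> DeformationFieldSet:
    """Exact per-state deformation fields from the phantom's motion model.

    ``state_displacements_mm`` is the representative diaphragm displacement of
    each motion state (e.g. the per-bin mean of the breathing trace).  Fields
    map the reference state's coordinates to each state.
    """
    disp = np.asarray(state_displacements_mm, dtype=float)
    fields = np.stack(
        [
            _displacement_field(phantom, d - disp[reference_state])
            for d in disp
        ]
    )
    return DeformationFieldSet(
        fields=fields,
        reference_state=int(reference_state),
        roi_box=None,
        voxel_size=phantom.voxel_size,
    )


def phantom_at_displacement(phantom: PhantomGroundTruth, d_mm: float):
    """Ground-truth (water, fat) warped to diaphragm displacement d_mm.

    Motion-compensated reconstructions recover the object in their reference
    motion state, so recovery metrics must compare against the truth
    expressed in that state, not at the neutral position.
    """
    if d_mm == 0.0:
        return phantom.water.copy(), phantom.fat.copy()
    warp = LinearWarp(_displacement_field(phantom, d_mm), phantom.voxel_size)
    return warp.forward(phantom.water), warp.forward(phantom.fat)


def simulate_acquisition(
    phantom: PhantomGroundTruth,
    spectral: FatSpectralModel,
    trace: BreathingTrace,
    schedule,
    params: AcquisitionParams | None = None,
    seed: int = 0,
) -> KSpaceSet:
    """Simulate the self-gated dual-echo acquisition of the moving phantom.

    Per window the object (water and fat) is warped by the window's diaphragm
    displacement through the phantom's motion model, the two echo images
    C * (w + dfat_i * f) * b_i are formed, Fourier-transformed along the phase
    axes, and the scheduled (ky, kz) lines are sampled for both echoes.
    Complex Gaussian noise of std noise_sigma x peak signal is added
    independently per sample.
    """
    params = params or AcquisitionParams()
    windows = schedule.windows
    if len(windows) != len(trace):
        raise ValueError(
            f"schedule has {len(windows)} windows but trace has {len(trace)}"
        )
    nx, ny, nz = phantom.grid_shape
    n_coils = phantom.n_coils
    n_echo = spectral.n_echoes
    n_lines = sum(len(w) for w in windows)

    data = np.empty((n_lines, n_echo, nx, n_coils), dtype=complex)
    ky = np.empty(n_lines, dtype=int)
    kz = np.empty(n_lines, dtype=int)
    win = np.empty(n_lines, dtype=int)
    tim = np.empty(n_lines, dtype=float)

    scale = params.t2prep_scale
    peak = 0.0
    pos = 0
    for w_idx, lines in enumerate(windows):
        d = trace.displacement[w_idx]
        if d == 0.0:
            ww, wf = phantom.water, phantom.fat
        else:
            warp = LinearWarp(_displacement_field(phantom, d), phantom.voxel_size)
            ww = warp.forward(phantom.water)
            wf = warp.forward(phantom.fat)
        for i in range(n_echo):
            img = scale * (ww + spectral.dfat[i] * wf) * phantom.phase_fields[i]
            coil_img = phantom.coil_maps * img[None]
            peak = max(peak, float(np.abs(coil_img).max()))
            ksp = cfft2(coil_img)  # [coil, nx, ny, nz]
            for s_idx, (lky, lkz) in enumerate(lines):
                iy, iz = lky + ny // 2, lkz + nz // 2
                data[pos + s_idx, i] = ksp[:, :, iy, iz].T
        for s_idx, (lky, lkz) in enumerate(lines):
            ky[pos + s_idx] = lky
            kz[pos + s_idx] = lkz
            win[pos + s_idx] = w_idx
            tim[pos + s_idx] = trace.times[w_idx] + s_idx * params.tr
        pos += len(lines)

    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sigma = params.noise_sigma * peak
        noise = sigma / np.sqrt(2.0) * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
        data = data + noise

    return KSpaceSet(
        data=data,
        ky=ky,
        kz=kz,
        window=win,
        time=tim,
        coil_maps=phantom.coil_maps.copy(),
        grid_shape=phantom.grid_shape,
        voxel_size=phantom.voxel_size,
        params=params,
    )
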