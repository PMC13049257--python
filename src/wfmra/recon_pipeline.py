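"""The four-stage reconstruction: respiratory-resolved CS, motion-compensated
CG-SENSE, image-based two-point Dixon with error-phasor smoothing, and the
final motion-corrected model-based water-fat reconstruction.

Stage 1 (respiratory-resolved) reconstructs one second-echo image per motion
state with spatial TV per state plus TV along the state dimension, solved by
L-BFGS; it exists solely to feed the motion-field estimation.  Stage 2 solves
the motion-compensated SENSE normal equations per echo by conjugate
gradients, giving sharp echo images.  Stage 3 separates them per voxel into
real-valued water/fat plus unit-modulus error phasors b1, b2 (closed-form
two-root solve; the true/swapped labeling is resolved by spatial smoothness
of the inter-echo phasor), and the phasors are Gaussian-smoothed while
preserving unit modulus and the voxelwise b2*conj(b1) difference.  Stage 4
re-solves for (w, f) directly against k-space through the full water-fat
encoding operator, with T and B held fixed, warm-started from stage 3.

Nonsmooth |.|_1 TV terms are smoothed with a Charbonnier penalty
sqrt(|d|^2 + eps^2), eps = 1e-6 x the dynamic range of the initializer, so
the L-BFGS solver sees a differentiable objective.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import convolve1d
from scipy.optimize import minimize

from .encoding_operators import (
    EncodingContext,
    apply_moco,
    apply_resolved,
    apply_waterfat,
    split_kspace_by_state,
)
from .fixtures_phantom import FatSpectralModel, KSpaceSet
from .motion_estimation import (
    DeformationFieldSet,
    RegistrationConfig,
    intra_bin_refine,
    register_states,
)
from .self_gating import (
    MotionBinning,
    bin_windows,
    extract_surrogate,
    pick_reference_state,
    scale_surrogate_mm,
)

__all__ = [
    "ReconConfig",
    "PipelineConfig",
    "EchoImages",
    "PhasorField",
    "WaterFatResult",
    "PipelineResult",
    "resp_resolved_recon",
    "moco_echo_recon",
    "dixon_candidates",
    "image_based_dixon",
    "smooth_phasors",
    "model_based_waterfat",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------


@dataclass
class ReconConfig:
    """Regularization weights and iteration counts for all stages.

    Defaults: lambda_tv_resolved = lambda_tvt = 0.001 with 15 L-BFGS
    iterations for the respiratory-resolved stage; 10 CG iterations for the
    motion-compensated echo reconstruction; lambda_tv_w = lambda_tv_f =
    0.0007 with 10 L-BFGS iterations for the final model-based stage.
    """

    lambda_tv_resolved: float = 0.001
    lambda_tvt: float = 0.001
    iters_resolved: int = 15
    cg_iters: int = 10
    cg_tol: float = 1e-12
    lambda_tv_w: float = 0.0007
    lambda_tv_f: float = 0.0007
    iters_final: int = 10
    tv_epsilon_rel: float = 1e-6

    def __post_init__(self):
        for lam in (self.lambda_tv_resolved, self.lambda_tvt,
                    self.lambda_tv_w, self.lambda_tv_f):
            if lam < 0:
                raise ValueError("regularization weights must be >= 0")
        if min(self.iters_resolved, self.cg_iters, self.iters_final) < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.tv_epsilon_rel <= 0:
            raise ValueError("tv_epsilon_rel must be > 0")


@dataclass
class PipelineConfig:
    """Pipeline-level knobs on top of :class:`ReconConfig`."""

    recon: ReconConfig = field(default_factory=ReconConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    m_states: int = 4
    gating_echo: int = 1  # second echo feeds the PCA surrogate
    refine_intra_bin: bool = True
    cardiac_scale: float = 0.57
    roi_box: tuple | None = None
    liver_roi: tuple | None = None
    decay_sigma: float = 3.0


@dataclass
class EchoImages:
    """Per-echo complex volumes (motion-corrected), plus solver diagnostics."""

    echoes: list
    residual_traces: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def n_echoes(self) -> int:
        return len(self.echoes)


@dataclass
class PhasorField:
    """Unit-modulus error phasors per echo."""

    b1: np.ndarray
    b2: np.ndarray

    def __post_init__(self):
        for b in (self.b1, self.b2):
            mod = np.abs(b)
            if not np.allclose(mod, 1.0, atol=1e-6):
                raise ValueError("phasors must be unit-modulus")

    def inter_echo(self) -> np.ndarray:
        return self.b2 * np.conj(self.b1)


@dataclass
class WaterFatResult:
    """Real-valued water and fat volumes plus the error phasors."""

    water: np.ndarray
    fat: np.ndarray
    phasors: PhasorField
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.iscomplexobj(self.water) or np.iscomplexobj(self.fat):
            raise ValueError("water and fat must be real-valued")


@dataclass
class PipelineResult:
    waterfat: WaterFatResult
    echoes: EchoImages
    resolved: np.ndarray | None = None
    surrogate: object = None
    binning: MotionBinning | None = None
    fields: DeformationFieldSet | None = None
    report: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Charbonnier-smoothed total variation
# ---------------------------------------------------------------------------


def charbonnier_tv(x: np.ndarray, eps: float, axes) -> tuple:
    """sum over axes of sum(sqrt(|D_a x|^2 + eps^2) - eps), with gradient.

    Anisotropic (per-axis) forward differences, non-periodic boundaries.
    Works for real or complex arrays; the gradient matches the real-pair
    parameterization of complex inputs componentwise.
    """
    val = 0.0
    grad = np.zeros_like(x)
    for a in axes:
        d = np.diff(x, axis=a)
        mag = np.sqrt(np.abs(d) ** 2 + eps**2)
        val += float((mag - eps).sum())
        g = d / mag
        sl_lo = [slice(None)] * x.ndim
        sl_hi = [slice(None)] * x.ndim
        sl_lo[a] = slice(None, -1)
        sl_hi[a] = slice(1, None)
        grad[tuple(sl_hi)] += g
        grad[tuple(sl_lo)] -= g
    return val, grad


def _pack(x: np.ndarray) -> np.ndarray:
    if np.iscomplexobj(x):
        return np.concatenate([x.real.ravel(), x.imag.ravel()])
    return x.ravel().astype(float)


def _unpack(v: np.ndarray, shape, is_complex: bool) -> np.ndarray:
    if is_complex:
        n = v.size // 2
        return (v[:n] + 1j * v[n:]).reshape(shape)
    return v.reshape(shape)


def _lbfgs(fun_grad, x0: np.ndarray, maxiter: int):
    """L-BFGS driver recording the objective at every accepted iterate.

    Memory 10; stops early on insufficient objective decrease (scipy ftol).
    Returns (x, trace, warnings).
    """
    is_complex = np.iscomplexobj(x0)
    shape = x0.shape

    def f(v):
        x = _unpack(v, shape, is_complex)
        val, grad = fun_grad(x)
        return val, _pack(grad)

    trace = []

    def cb(vk):
        trace.append(f(vk)[0])

    v0 = _pack(x0)
    trace.append(f(v0)[0])
    res = minimize(
        f,
        v0,
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={
            "maxiter": maxiter,
            "maxcor": 10,
            "ftol": 1e-14,
            "gtol": 1e-14,
            "maxls": 40,
        },
    )
    warnings = []
    if not res.success and "ABNORMAL" in str(res.message):
        warnings.append(f"L-BFGS line search failed: {res.message}")
    x = _unpack(res.x, shape, is_complex)
    # keep the best evaluated iterate if the last callback value is stale
    if trace and res.fun < trace[-1]:
        trace.append(float(res.fun))
    return x, trace, warnings


def _data_misfit(pred, data):
    """sum_m ||pred_m - data_m||^2 and the per-state residuals."""
    val = 0.0
    resid = []
    for p, d in zip(pred, data):
        r = p - d
        resid.append(r)
        val += float(np.vdot(r, r).real)
    return val, resid


# ---------------------------------------------------------------------------
# Stage 1: respiratory-resolved reconstruction
# ---------------------------------------------------------------------------


def _density_compensated_adjoint(kdata_states, ctx: EncodingContext):
    """Zero-filled reconstruction that AVERAGES duplicate line measurements.

    The plain adjoint sums the many repeats of the center line, which scales
    DC by the repeat count and wastes the first solver iterations undoing
    it; averaging gives an initializer already on the right intensity scale.
    """
    from .fixtures_phantom import icfft2

    nx, ny, nz = ctx.grid_shape
    out = np.empty((ctx.n_states,) + ctx.grid_shape, dtype=complex)
    for m, (iy, iz) in enumerate(ctx.state_lines):
        kgrid = np.zeros((ctx.n_coils, nx, ny, nz), dtype=complex)
        counts = np.zeros((ny, nz))
        np.add.at(counts, (iy, iz), 1.0)
        vals = np.ascontiguousarray(kdata_states[m].transpose(2, 1, 0))
        np.add.at(kgrid, (slice(None), slice(None), iy, iz), vals)
        kgrid /= np.maximum(counts, 1.0)[None, None]
        img = icfft2(kgrid)
        csum = np.maximum((np.abs(ctx.coil_maps) ** 2).sum(axis=0), 1e-12)
        out[m] = (np.conj(ctx.coil_maps) * img).sum(axis=0) / csum
    return out


def resp_resolved_recon(kdata_states, ctx: EncodingContext,
                        config: ReconConfig | None = None):
    """Per-state CS reconstruction of the second echo.

    Minimizes  sum_m ||E_m s_m - k_m||^2 + lam_TV * TV_x(s) + lam_TVT * TV_t(s)
    over the per-state image stack s with ``iters_resolved`` L-BFGS
    iterations.  TV_x acts per state along the three spatial axes, TV_t along
    the state axis; both are Charbonnier-smoothed.
    """
    config = config or ReconConfig()
    for m, (iy, _) in enumerate(ctx.state_lines):
        if iy.size == 0:
            raise ValueError(f"motion state {m} has an empty sampling mask")
    x0 = _density_compensated_adjoint(kdata_states, ctx)
    eps = config.tv_epsilon_rel * max(float(np.abs(x0).max()), 1e-30)
    lam_x, lam_t = config.lambda_tv_resolved, config.lambda_tvt

    def fun(s):
        pred = apply_resolved(s, ctx, "forward")
        val, resid = _data_misfit(pred, kdata_states)
        grad = 2.0 * apply_resolved(resid, ctx, "adjoint")
        if lam_x > 0:
            v, g = charbonnier_tv(s, eps, axes=(1, 2, 3))
            val += lam_x * v
            grad += lam_x * g
        if lam_t > 0 and s.shape[0] > 1:
            v, g = charbonnier_tv(s, eps, axes=(0,))
            val += lam_t * v
            grad += lam_t * g
        return val, grad

    s, trace, warnings = _lbfgs(fun, x0, config.iters_resolved)
    return s, {"objective": trace, "warnings": warnings}


# ---------------------------------------------------------------------------
# Stage 2: motion-compensated CG-SENSE
# ---------------------------------------------------------------------------


def moco_echo_recon(kdata_echo_states, ctx: EncodingContext,
                    config: ReconConfig | None = None) -> EchoImages:
    """Conjugate-gradient solution of the motion-compensated normal equations,
    one echo at a time.  The data residual ||E x - k|| is recorded per
    iteration and is non-increasing by the CG energy-norm property; if it
    ever increases (numerical breakdown) the last good iterate is returned
    with a warning.
    """
    config = config or ReconConfig()
    echoes, traces, warnings = [], [], []
    for i, kdata in enumerate(kdata_echo_states):
        b = apply_moco(kdata, ctx, "adjoint")
        x = np.zeros_like(b)
        r = b.copy()
        p = r.copy()
        rs = float(np.vdot(r, r).real)

        def data_resid(xx):
            pred = apply_moco(xx, ctx, "forward")
            return np.sqrt(sum(float(np.vdot(pp - dd, pp - dd).real)
                               for pp, dd in zip(pred, kdata)))

        trace = [data_resid(x)]
        best = x
        for _ in range(config.cg_iters):
            ap = apply_moco(apply_moco(p, ctx, "forward"), ctx, "adjoint")
            denom = float(np.vdot(p, ap).real)
            if denom <= 0:
                warnings.append(f"echo {i}: CG curvature breakdown")
                break
            alpha = rs / denom
            x = x + alpha * p
            r = r - alpha * ap
            rs_new = float(np.vdot(r, r).real)
            res = data_resid(x)
            if res > trace[-1] * (1 + 1e-12):
                warnings.append(f"echo {i}: residual increased; keeping best iterate")
                break
            best = x
            trace.append(res)
            if np.sqrt(rs_new) <= config.cg_tol * np.sqrt(float(np.vdot(b, b).real)):
                break
            p = r + (rs_new / rs) * p
            rs = rs_new
        echoes.append(best)
        traces.append(trace)
    return EchoImages(echoes=echoes, residual_traces=traces, warnings=warnings)


# ---------------------------------------------------------------------------
# Stage 3: image-based two-point Dixon
# ---------------------------------------------------------------------------


def dixon_candidates(s1, s2, spectral: FatSpectralModel):
    """Closed-form per-voxel candidate solutions of the real-valued model.

    The model  s_i = (w + dfat_i f) b_i  with real w, f and |b_i| = 1 gives
    |s_i|^2 = w^2 + 2 Re(dfat_i) w f + |dfat_i|^2 f^2 for both echoes:
    eliminating w^2 leaves a quadratic in f^2 whose two roots are the true
    and the swapped interpretation.  Returns arrays (w, f, b1, b2), each with
    a leading candidate axis of length 2 (f >= 0 gauge per candidate).
    """
    d1, d2 = spectral.dfat
    a1, a2 = d1.real, d2.real
    D1, D2 = abs(d1) ** 2, abs(d2) ** 2
    if abs(a1 - a2) < 1e-12:
        raise ValueError("degenerate spectral model: Re(dfat) equal across echoes")
    s1 = np.asarray(s1, dtype=complex)
    s2 = np.asarray(s2, dtype=complex)
    m1 = np.abs(s1) ** 2
    m2 = np.abs(s2) ** 2
    alpha = (m1 - m2) / (2.0 * (a1 - a2))
    beta = (D1 - D2) / (2.0 * (a1 - a2))
    A2 = beta**2 - 2 * a1 * beta + D1
    A1 = 2 * alpha * (a1 - beta) - m1
    A0 = alpha**2
    disc = np.clip(A1**2 - 4 * A2 * A0, 0.0, None)
    sq = np.sqrt(disc)
    # numerically stable quadratic roots (avoid catastrophic cancellation)
    q = -0.5 * (A1 + np.where(A1 >= 0, 1.0, -1.0) * sq)
    safe_q = np.where(np.abs(q) > 0, q, 1.0)
    r_big = q / A2
    r_small = np.where(np.abs(q) > 0, A0 / safe_q, 0.0)
    roots = np.stack([np.minimum(r_big, r_small), np.maximum(r_big, r_small)])
    scale = np.sqrt(np.maximum(m1, m2))
    tiny = 1e-9 * max(float(scale.max()), 1e-30)

    w_c = np.empty_like(roots)
    f_c = np.empty_like(roots)
    b1_c = np.empty(roots.shape, dtype=complex)
    b2_c = np.empty(roots.shape, dtype=complex)
    for k in range(2):
        v = np.clip(roots[k], 0.0, None)
        f = np.sqrt(v)
        wf = alpha - beta * v
        # signed sqrt form: stable where f -> 0 (wf/f would amplify error)
        w2 = np.clip(m1 - 2 * a1 * wf - D1 * v, 0.0, None)
        w = np.where(wf >= 0, 1.0, -1.0) * np.sqrt(w2)
        w, f = _newton_polish(w, f, m1, m2, a1, a2, D1, D2)
        neg = f < 0  # re-impose the f >= 0 candidate gauge after polishing
        w = np.where(neg, -w, w)
        f = np.where(neg, -f, f)
        # w and f are proton-density magnitudes: the error phasors absorb all
        # phase, so negative w (a noise-level sign read off w*f when either
        # component vanishes) is clamped to the physical branch
        w = np.abs(w)
        for b_out, s, d in ((b1_c, s1, d1), (b2_c, s2, d2)):
            den = w + d * f
            safe = np.abs(den) > tiny
            b = np.where(safe, s / np.where(safe, den, 1.0), 1.0)
            mod = np.abs(b)
            b_out[k] = np.where(mod > tiny, b / np.where(mod > tiny, mod, 1.0), 1.0)
        w_c[k], f_c[k] = w, f
    return w_c, f_c, b1_c, b2_c


def _newton_polish(w, f, m1, m2, a1, a2, D1, D2, n_steps: int = 2):
    """Vectorized Newton refinement of the magnitude system
    |w + dfat_i f|^2 = m_i, sharpening the closed-form roots to ~machine
    precision.  Singular Jacobians (degenerate voxels) keep the input."""
    for _ in range(n_steps):
        g1 = w**2 + 2 * a1 * w * f + D1 * f**2 - m1
        g2 = w**2 + 2 * a2 * w * f + D2 * f**2 - m2
        j11 = 2 * (w + a1 * f)
        j12 = 2 * (a1 * w + D1 * f)
        j21 = 2 * (w + a2 * f)
        j22 = 2 * (a2 * w + D2 * f)
        det = j11 * j22 - j12 * j21
        ok = np.abs(det) > 1e-30
        det_s = np.where(ok, det, 1.0)
        dw = (g1 * j22 - g2 * j12) / det_s
        df = (g2 * j11 - g1 * j21) / det_s
        w = np.where(ok, w - dw, w)
        f = np.where(ok, f - df, f)
    return w, f


def _region_grow_labels(q_c, conf, mask):
    """Confidence-seeded growth choosing the candidate whose inter-echo
    phasor best matches the already-labeled neighbour."""
    import heapq

    shape = mask.shape
    labels = np.zeros(shape, dtype=np.int8)
    visited = ~mask
    if not mask.any():
        return labels
    seed = np.unravel_index(np.argmax(np.where(mask, conf, -np.inf)), shape)
    heap = [(-conf[seed], seed)]
    visited[seed] = True
    labels[seed] = 0
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while heap:
        _, idx = heapq.heappop(heap)
        q_here = q_c[labels[idx]][idx]
        for off in offsets:
            nb = (idx[0] + off[0], idx[1] + off[1], idx[2] + off[2])
            if not all(0 <= nb[a] < shape[a] for a in range(3)):
                continue
            if visited[nb]:
                continue
            visited[nb] = True
            d0 = abs(q_c[0][nb] - q_here)
            d1 = abs(q_c[1][nb] - q_here)
            labels[nb] = 0 if d0 <= d1 else 1
            heapq.heappush(heap, (-conf[nb], nb))
    return labels


def _icm_polish(labels, q_c, mask, n_sweeps: int = 4):
    """Iterated-conditional-modes sweeps: relabel each voxel to the candidate
    closest to the local mean inter-echo phasor (checkerboard updates)."""
    kernel = np.array([1.0, 0.0, 1.0])
    ix, iy, iz = np.indices(labels.shape)
    parity = (ix + iy + iz) % 2
    for sweep in range(n_sweeps):
        q_sel = np.where(labels.astype(bool), q_c[1], q_c[0]) * mask
        wsum = mask.astype(float)
        num = q_sel.copy()
        den = wsum.copy()
        for a in range(3):
            num = num + convolve1d(q_sel, kernel, axis=a, mode="constant")
            den = den + convolve1d(wsum, kernel, axis=a, mode="constant")
        # exclude the voxel itself from its neighbourhood mean
        num = num - q_sel
        den = np.clip(den - wsum, 1e-12, None)
        q_avg = num / den
        new = (np.abs(q_c[1] - q_avg) < np.abs(q_c[0] - q_avg)).astype(np.int8)
        upd = mask & (parity == sweep % 2)
        labels = np.where(upd, new, labels)
    return labels


def image_based_dixon(
    echoes: EchoImages,
    spectral: FatSpectralModel | None = None,
    mask_rel: float = 1e-3,
) -> WaterFatResult:
    """Voxelwise two-point water-fat separation with smoothness labeling.

    Solves the exactly determined real-valued system per voxel (two analytic
    candidate roots, true and swapped), then selects the per-voxel labeling
    that makes the inter-echo phasor b2*conj(b1) spatially smooth, via
    confidence-seeded region growing polished by iterated conditional modes.
    Voxels with (near-)zero signal in both echoes are gauge-fixed to
    w = f = 0, b = 1.  The global two-point swap ambiguity is resolved by the
    convention that the volume-integrated water signal is >= the fat signal.
    """
    spectral = spectral or FatSpectralModel()
    s1, s2 = echoes.echoes[0], echoes.echoes[1]
    w_c, f_c, b1_c, b2_c = dixon_candidates(s1, s2, spectral)
    mag = np.abs(s1) + np.abs(s2)
    mask = mag > mask_rel * float(mag.max())

    q_c = b2_c * np.conj(b1_c)
    labels = _region_grow_labels(q_c, mag, mask)
    labels = _icm_polish(labels, q_c, mask, n_sweeps=4)

    sel = labels.astype(bool)
    w = np.where(sel, w_c[1], w_c[0])
    f = np.where(sel, f_c[1], f_c[0])
    b1 = np.where(sel, b1_c[1], b1_c[0])
    b2 = np.where(sel, b2_c[1], b2_c[0])
    w = np.where(mask, w, 0.0)
    f = np.where(mask, f, 0.0)
    b1 = np.where(mask, b1, 1.0)
    b2 = np.where(mask, b2, 1.0)

    if f[mask].sum() > w[mask].sum():  # global swap gauge: water-dominant body
        sel = ~sel
        w = np.where(mask, np.where(sel, w_c[1], w_c[0]), 0.0)
        f = np.where(mask, np.where(sel, f_c[1], f_c[0]), 0.0)
        b1 = np.where(mask, np.where(sel, b1_c[1], b1_c[0]), 1.0)
        b2 = np.where(mask, np.where(sel, b2_c[1], b2_c[0]), 1.0)

    return WaterFatResult(
        water=w.real.astype(float),
        fat=f.real.astype(float),
        phasors=PhasorField(b1=b1, b2=b2),
        provenance={"stage": "image_based_dixon"},
    )


def smooth_phasors(phasors: PhasorField, sigma: float = 1.0,
                   radius: int = 4) -> PhasorField:
    """Gaussian-smooth b1 as a complex field and renormalize to unit modulus;
    b2 is rebuilt as smoothed-b1 times the ORIGINAL voxelwise b2*conj(b1), so
    the inter-echo difference is preserved exactly.  Voxels where the
    smoothed phasor cancels (phase singularities) keep their original value.
    """
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    delta = phasors.inter_echo()
    b1s = phasors.b1.astype(complex)
    for a in range(b1s.ndim):
        b1s = convolve1d(b1s, kernel, axis=a, mode="nearest")
    mod = np.abs(b1s)
    tiny = 1e-12
    b1_new = np.where(mod > tiny, b1s / np.where(mod > tiny, mod, 1.0), phasors.b1)
    return PhasorField(b1=b1_new, b2=b1_new * delta)


# ---------------------------------------------------------------------------
# Stage 4: model-based water-fat reconstruction
# ---------------------------------------------------------------------------


def model_based_waterfat(
    kdata_echo_states,
    ctx: EncodingContext,
    init: WaterFatResult,
    config: ReconConfig | None = None,
) -> WaterFatResult:
    """Minimize  sum_i sum_m ||E_m,i(w,f) - k_m,i||^2
                 + lam_w TV(w) + lam_f TV(f)
    over real (w, f) with ``iters_final`` L-BFGS iterations.  The motion
    fields T and error phasors B live in the context and stay fixed
    throughout; (w, f) start from the image-based Dixon result.
    """
    config = config or ReconConfig()
    if ctx.phasors is None:
        raise ValueError("context must carry smoothed error phasors B")
    shape = init.water.shape
    x0 = np.stack([init.water, init.fat])
    eps = config.tv_epsilon_rel * max(float(np.abs(x0).max()), 1e-30)
    lam_w, lam_f = config.lambda_tv_w, config.lambda_tv_f

    def data_term(w, f):
        pred = apply_waterfat(w, f, ctx, "forward")
        val = 0.0
        resid = []
        for i in range(len(pred)):
            v, r = _data_misfit(pred[i], kdata_echo_states[i])
            val += v
            resid.append(r)
        return val, resid

    def fun(x):
        w, f = x[0], x[1]
        val, resid = data_term(w, f)
        gw, gf = apply_waterfat(resid, None, ctx, "adjoint")
        grad = 2.0 * np.stack([gw, gf])
        if lam_w > 0:
            v, g = charbonnier_tv(w, eps, axes=(0, 1, 2))
            val += lam_w * v
            grad[0] += lam_w * g
        if lam_f > 0:
            v, g = charbonnier_tv(f, eps, axes=(0, 1, 2))
            val += lam_f * v
            grad[1] += lam_f * g
        return val, grad

    data0 = data_term(x0[0], x0[1])[0]
    x, trace, warnings = _lbfgs(fun, x0, config.iters_final)
    data1 = data_term(x[0], x[1])[0]
    return WaterFatResult(
        water=x[0],
        fat=x[1],
        phasors=PhasorField(b1=ctx.phasors[0], b2=ctx.phasors[1]),
        provenance={
            "stage": "model_based_waterfat",
            "objective": trace,
            "data_term_init": data0,
            "data_term_final": data1,
            "warnings": warnings,
        },
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_pipeline(
    kset: KSpaceSet,
    config: PipelineConfig | None = None,
    mode: str = "selfgated",
    spectral: FatSpectralModel | None = None,
    truth_fields: DeformationFieldSet | None = None,
) -> PipelineResult:
    """Execute the full reconstruction chain on an acquisition.

    mode="selfgated" runs surrogate extraction -> binning ->
    respiratory-resolved recon -> motion fields (B-spline registration, or
    ``truth_fields`` injected to decouple registration error from
    reconstruction error) -> intra-bin refinement -> motion-compensated
    CG-SENSE -> image-based Dixon + phasor smoothing -> model-based
    water-fat.  mode="gated-no-moco" skips gating and motion entirely
    (single state, identity motion) but uses the identical Dixon and
    model-based stages, mirroring how navigator-gated scans are processed.
    """
    config = config or PipelineConfig()
    spectral = spectral or FatSpectralModel()
    report = {"mode": mode, "timings": {}, "traces": {}, "warnings": []}
    t_all = time.perf_counter()

    def tic():
        return time.perf_counter()

    if mode == "gated-no-moco":
        binning = None
        zero = DeformationFieldSet(
            fields=np.zeros((1, 3) + kset.grid_shape),
            reference_state=0,
            voxel_size=kset.voxel_size,
        )
        ctx = EncodingContext.from_kspace(
            kset, None, fields=zero, spectral=spectral
        )
        kdata = [split_kspace_by_state(kset, None, echo=i) for i in range(2)]
        surrogate = None
        fields = zero
        resolved = None
    elif mode == "selfgated":
        t0 = tic()
        center = kset.center_lines(echo=config.gating_echo)
        surrogate = extract_surrogate(center, times=kset.window_times())
        binning = bin_windows(surrogate, config.m_states)
        ref = pick_reference_state(surrogate, binning)
        report["timings"]["self_gating"] = tic() - t0

        t0 = tic()
        ctx_res = EncodingContext.from_kspace(kset, binning)
        k2 = split_kspace_by_state(kset, binning, echo=1)
        resolved, info = resp_resolved_recon(k2, ctx_res, config.recon)
        report["traces"]["resolved_objective"] = info["objective"]
        report["warnings"] += info["warnings"]
        report["timings"]["resp_resolved"] = tic() - t0

        t0 = tic()
        if truth_fields is not None:
            fields = truth_fields
        else:
            fields = register_states(
                np.abs(resolved),
                config.registration,
                roi_box=config.roi_box,
                reference_state=ref,
                voxel_size=kset.voxel_size,
                decay_sigma=config.decay_sigma,
            )
            report["warnings"] += fields.warnings
        report["timings"]["motion_fields"] = tic() - t0

        liver_roi = config.liver_roi
        if liver_roi is not None:
            try:
                surrogate = scale_surrogate_mm(surrogate, fields, liver_roi,
                                               binning)
                report["respiratory_range_mm"] = surrogate.range_mm
            except ValueError as exc:
                report["warnings"].append(f"surrogate calibration skipped: {exc}")
            if config.refine_intra_bin:
                fields, binning = intra_bin_refine(
                    fields, binning, surrogate, liver_roi,
                    cardiac_scale=config.cardiac_scale,
                    voxel_size=kset.voxel_size,
                )
        ctx = EncodingContext.from_kspace(
            kset, binning, fields=fields, spectral=spectral
        )
        kdata = [split_kspace_by_state(kset, binning, echo=i) for i in range(2)]
    else:
        raise ValueError("mode must be 'selfgated' or 'gated-no-moco'")

    t0 = tic()
    echoes = moco_echo_recon(kdata, ctx, config.recon)
    report["traces"]["cg_residuals"] = echoes.residual_traces
    report["warnings"] += echoes.warnings
    report["timings"]["moco_echoes"] = tic() - t0

    t0 = tic()
    wf0 = image_based_dixon(echoes, spectral)
    smoothed = smooth_phasors(wf0.phasors)
    report["timings"]["image_dixon"] = tic() - t0

    t0 = tic()
    ctx_wf = replace(ctx, phasors=(smoothed.b1, smoothed.b2))
    ctx_wf._warps = ctx._warps  # reuse cached warp stencils
    final = model_based_waterfat(kdata, ctx_wf, wf0, config.recon)
    report["traces"]["model_based_objective"] = final.provenance["objective"]
    report["warnings"] += final.provenance.get("warnings", [])
    report["timings"]["model_based"] = tic() - t0
    report["timings"]["total"] = tic() - t_all

    return PipelineResult(
        waterfat=final,
        echoes=echoes,
        resolved=resolved,
        surrogate=surrogate,
        binning=binning,
        fields=fields,
        report=report,
    )
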