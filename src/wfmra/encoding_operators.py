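"""The three linear/affine MR encoding operators and their exact adjoints.

All reconstruction stages share these operator chains:

* respiratory-resolved:   E_m s_m       = P_m F C s_m          (one image per state)
* motion-compensated:     E_moco,m s    = P_m F T_m C s        (one image, warped per state)
* water-fat model:        E_m,i(w, f)   = E_moco,m,i (b_i o (w + dfat_i f))

with F the centered orthonormal Fourier transform along the two phase-encode
axes, C the coil sensitivities, P_m the per-state line sampling, T_m the
trilinear warp to motion state m, b_i the unit-modulus error phasor of echo i
and dfat_i the complex fat evolution factor.  The warp acts on the
coil-weighted image (T after C), matching the operator order of the
motion-compensated encoding.

The water-fat adjoint returns the REAL parts of the phasor-weighted
back-projections: w and f are modeled as real-valued with a common phase, and
taking the real part is the exact adjoint of embedding real images into
complex space -- required for gradient correctness of the model-based stage.

K-space data is held as one array per state of shape [n_lines, readout,
coil]; repeated lines (the per-window center line, overlapping patterns) are
legitimate duplicate measurements and the adjoint scatter-adds them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixtures_phantom import FatSpectralModel, KSpaceSet, cfft2, icfft2
from .motion_estimation import DeformationFieldSet, LinearWarp

__all__ = [
    "EncodingContext",
    "apply_resolved",
    "apply_moco",
    "apply_waterfat",
    "split_kspace_by_state",
    "operator_norm",
]


@dataclass
class EncodingContext:
    """Everything the encoding chains need: coils, per-state lines, warps.

    ``state_lines`` holds, per motion state, the (iy, iz) array indices of
    its acquired lines on the centered k-grid (DC at n//2).  ``fields`` and
    ``phasors`` are optional; operators that need them raise if absent.
    """

    coil_maps: np.ndarray  # [n_coils, nx, ny, nz]
    grid_shape: tuple
    state_lines: list  # per state: (iy array, iz array)
    fields: DeformationFieldSet | None = None
    spectral: FatSpectralModel | None = None
    phasors: tuple | None = None  # (b1, b2)
    voxel_size: float = 1.0
    _warps: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if self.coil_maps.ndim != 4:
            raise ValueError("coil_maps must be [n_coils, nx, ny, nz]")

    @property
    def n_states(self) -> int:
        return len(self.state_lines)

    @property
    def n_coils(self) -> int:
        return self.coil_maps.shape[0]

    def warp(self, m: int) -> LinearWarp | None:
        """Cached per-state warp operator (None = identity)."""
        if self.fields is None:
            return None
        if not self._warps:
            self._warps = [None] * self.n_states
        if self._warps[m] is None:
            f = self.fields.fields[m]
            if not np.any(f):
                self._warps[m] = "identity"
            else:
                self._warps[m] = LinearWarp(f, voxel_size=self.voxel_size)
        w = self._warps[m]
        return None if w == "identity" else w

    @classmethod
    def from_kspace(
        cls,
        kset: KSpaceSet,
        binning=None,
        fields: DeformationFieldSet | None = None,
        spectral: FatSpectralModel | None = None,
        phasors=None,
    ) -> "EncodingContext":
        """Build per-state line index sets from an acquisition and a binning.

        Without a binning all lines form a single state.  The per-state masks
        are disjoint by construction (each window belongs to exactly one
        state) and their union is the acquired line set.
        """
        iy, iz = kset.grid_indices()
        if binning is None:
            states = [np.arange(kset.n_lines)]
        else:
            line_state = binning.assignment[kset.window]
            n_states = int(binning.m)
            states = [np.where(line_state == m)[0] for m in range(n_states)]
        state_lines = [(iy[s], iz[s]) for s in states]
        return cls(
            coil_maps=kset.coil_maps,
            grid_shape=kset.grid_shape,
            state_lines=state_lines,
            fields=fields,
            spectral=spectral,
            phasors=phasors,
            voxel_size=kset.voxel_size,
        )


def split_kspace_by_state(kset: KSpaceSet, binning=None, echo: int = 0) -> list:
    """Measured data of one echo, split per motion state.

    Returns one array [n_lines_m, readout, coil] per state, ordered exactly
    like the context built by :meth:`EncodingContext.from_kspace` with the
    same binning.
    """
    if binning is None:
        return [kset.data[:, echo]]
    line_state = binning.assignment[kset.window]
    return [
        kset.data[line_state == m, echo] for m in range(int(binning.m))
    ]


def _gather(ksp: np.ndarray, iy, iz) -> np.ndarray:
    """[coil, nx, ny, nz] k-grid -> [n_lines, nx, coil] line samples."""
    return ksp[:, :, iy, iz].transpose(2, 1, 0)


def _scatter(lines: np.ndarray, iy, iz, n_coils, grid_shape) -> np.ndarray:
    """Exact transpose of :func:`_gather` (duplicates accumulate)."""
    nx, ny, nz = grid_shape
    kgrid = np.zeros((n_coils, nx, ny, nz), dtype=complex)
    vals = np.ascontiguousarray(lines.transpose(2, 1, 0))  # [coil, nx, n_lines]
    np.add.at(kgrid, (slice(None), slice(None), iy, iz), vals)
    return kgrid


def apply_resolved(images, ctx: EncodingContext, direction: str = "forward"):
    """Respiratory-resolved encoding: per state, P_m F C s_m.

    forward: ``images`` [n_states, nx, ny, nz] -> list of per-state line
    arrays [n_lines_m, nx, coil].  adjoint: the conjugate-transpose chain.
    """
    if direction == "forward":
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        if images.shape[0] != ctx.n_states:
            raise ValueError(
                f"state axis mismatch: {images.shape[0]} images for "
                f"{ctx.n_states} states"
            )
        if images.shape[1:] != ctx.grid_shape:
            raise ValueError(
                f"image grid {images.shape[1:]} != context grid {ctx.grid_shape}"
            )
        out = []
        for m, (iy, iz) in enumerate(ctx.state_lines):
            coil_img = ctx.coil_maps * images[m][None]
            out.append(_gather(cfft2(coil_img), iy, iz))
        return out
    if direction == "adjoint":
        out = np.zeros((ctx.n_states,) + ctx.grid_shape, dtype=complex)
        for m, (iy, iz) in enumerate(ctx.state_lines):
            kgrid = _scatter(images[m], iy, iz, ctx.n_coils, ctx.grid_shape)
            out[m] = (np.conj(ctx.coil_maps) * icfft2(kgrid)).sum(axis=0)
        return out
    raise ValueError("direction must be 'forward' or 'adjoint'")


def apply_moco(image, ctx: EncodingContext, direction: str = "forward"):
    """Motion-compensated encoding: per state, P_m F T_m C s.

    forward: single image [nx, ny, nz] -> per-state line arrays.  The warp
    acts on the coil-weighted image; the adjoint uses the warp transpose
    (exact transpose of the trilinear interpolation, not the inverse warp).
    """
    if ctx.fields is None:
        raise ValueError("context has no motion fields; use apply_resolved")
    if direction == "forward":
        image = np.asarray(image)
        if image.shape != ctx.grid_shape:
            raise ValueError(
                f"image grid {image.shape} != context grid {ctx.grid_shape}"
            )
        out = []
        coil_img = ctx.coil_maps * image[None]
        for m, (iy, iz) in enumerate(ctx.state_lines):
            warp = ctx.warp(m)
            warped = coil_img if warp is None else warp.forward(coil_img)
            out.append(_gather(cfft2(warped), iy, iz))
        return out
    if direction == "adjoint":
        acc = np.zeros((ctx.n_coils,) + ctx.grid_shape, dtype=complex)
        for m, (iy, iz) in enumerate(ctx.state_lines):
            kgrid = _scatter(image[m], iy, iz, ctx.n_coils, ctx.grid_shape)
            back = icfft2(kgrid)
            warp = ctx.warp(m)
            acc += back if warp is None else warp.adjoint(back)
        return (np.conj(ctx.coil_maps) * acc).sum(axis=0)
    raise ValueError("direction must be 'forward' or 'adjoint'")


def apply_waterfat(w, f, ctx: EncodingContext, direction: str = "forward"):
    """Water-fat model encoding and its real-projected adjoint.

    forward: real (w, f) -> nested list [echo][state] of line arrays, where
    echo i transmits b_i o (w + dfat_i f) through the motion-compensated
    chain.  adjoint: residual-shaped data -> (grad_w, grad_f), the REAL parts
    of conj(b_i)- and conj(dfat_i b_i)-weighted back-projections, summed over
    echoes.  The adjoint identity holds over the real inner product.
    """
    if ctx.phasors is None:
        raise ValueError(
            "context has no error phasors B; run image_based_dixon first"
        )
    if ctx.spectral is None:
        raise ValueError("context has no spectral model")
    b = ctx.phasors
    d = ctx.spectral.dfat
    if direction == "forward":
        w = np.asarray(w, dtype=float)
        f = np.asarray(f, dtype=float)
        return [
            apply_moco(b[i] * (w + d[i] * f), ctx, "forward")
            for i in range(len(d))
        ]
    if direction == "adjoint":
        gw = np.zeros(ctx.grid_shape)
        gf = np.zeros(ctx.grid_shape)
        for i in range(len(d)):
            g = apply_moco(w[i], ctx, "adjoint")  # w carries the data here
            gw += np.real(np.conj(b[i]) * g)
            gf += np.real(np.conj(d[i]) * np.conj(b[i]) * g)
        return gw, gf
    raise ValueError("direction must be 'forward' or 'adjoint'")


def operator_norm(ctx: EncodingContext, which: str = "moco", n_iter: int = 20,
                  seed: int = 0) -> float:
    """Largest singular value of an encoding chain by power iteration."""
    rng = np.random.default_rng(seed)
    if which == "resolved":
        x = rng.standard_normal((ctx.n_states,) + ctx.grid_shape) + 1j * (
            rng.standard_normal((ctx.n_states,) + ctx.grid_shape)
        )
        fwd = lambda v: apply_resolved(v, ctx, "forward")
        adj = lambda k: apply_resolved(k, ctx, "adjoint")
    elif which == "moco":
        x = rng.standard_normal(ctx.grid_shape) + 1j * rng.standard_normal(
            ctx.grid_shape
        )
        fwd = lambda v: apply_moco(v, ctx, "forward")
        adj = lambda k: apply_moco(k, ctx, "adjoint")
    else:
        raise ValueError("which must be 'resolved' or 'moco'")
    sigma = 0.0
    for _ in range(n_iter):
        y = adj(fwd(x))
        sigma = np.sqrt(np.linalg.norm(y) / max(np.linalg.norm(x), 1e-300))
        x = y / max(np.linalg.norm(y), 1e-300)
    return float(sigma)
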