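"""Variable-density Poisson-disk phase-encode patterns and center-out schedules.

The acquisition distributes (ky, kz) phase-encode points as an overlay of
several (default three) variable-density Poisson-disk patterns with differing
random seeds.  Every pattern fully samples the central core (normalized
radius <= central_fraction, default 5%), enforces a minimum sampling density
in the periphery, crops the k-space corners to the inscribed ellipse, and
excludes an asymmetric partial-Fourier region (fraction 0.875 kept per phase
axis, on the positive side).

Normalized radius on the anisotropic grid is
r = sqrt((ky/(n_ky/2))^2 + (kz/(n_kz/2))^2); corner cropping keeps r <= 1.

For acquisition, the points are split by normalized radius into
nsegments - 1 equal-count bins; each heartbeat window acquires the ky=kz=0
self-navigator line followed by one line per bin in center-out order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingPattern",
    "AcquisitionSchedule",
    "generate_pattern",
    "build_schedule",
    "verify_pattern",
]


@dataclass
class SamplingPattern:
    """Phase-encode point multiset with per-point pattern index.

    ``ky``/``kz`` are signed centered grid indices; ``pattern`` in
    {1..n_patterns}.  Points of the fully sampled core are present in every
    pattern, so they appear with multiplicity n_patterns.
    """

    ky: np.ndarray
    kz: np.ndarray
    pattern: np.ndarray
    grid_shape: tuple  # (n_ky, n_kz)
    central_fraction: float
    min_density: float
    partial_fourier: float
    seeds: tuple
    density_amp: float = 0.0
    density_exponent: float = 2.0
    rejection_scale: float = 1.0

    def __post_init__(self):
        self.ky = np.asarray(self.ky, dtype=int)
        self.kz = np.asarray(self.kz, dtype=int)
        self.pattern = np.asarray(self.pattern, dtype=int)

    @property
    def n_points(self) -> int:
        return self.ky.size

    @property
    def n_patterns(self) -> int:
        return int(self.pattern.max()) if self.n_points else 0

    def radii(self) -> np.ndarray:
        return _norm_radius(self.ky, self.kz, self.grid_shape)

    def density(self, r) -> np.ndarray:
        """Target sampling density (per pattern, per unit normalized area)."""
        r = np.asarray(r, dtype=float)
        return self.density_amp * np.clip(1.0 - r, 0.0, None) ** self.density_exponent + self.min_density

    def rejection_radius(self, r) -> np.ndarray:
        """Poisson-disk exclusion distance at normalized radius r."""
        return self.rejection_scale / np.sqrt(self.density(r))


@dataclass
class AcquisitionSchedule:
    """Per-heartbeat line ordering: each window starts with (0, 0) and then
    acquires one line per radial bin in center-out (non-decreasing radius)
    order."""

    windows: list  # list of list of (ky, kz)
    radial_bin_edges: np.ndarray
    grid_shape: tuple

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def noncenter_lines(self) -> list:
        """All scheduled lines except the per-window leading (0, 0)."""
        out = []
        for w in self.windows:
            out.extend(w[1:])
        return out


def _norm_radius(ky, kz, grid_shape):
    ky_max, kz_max = grid_shape[0] / 2.0, grid_shape[1] / 2.0
    return np.sqrt((np.asarray(ky) / ky_max) ** 2 + (np.asarray(kz) / kz_max) ** 2)


def _eligible_grid(grid_shape, partial_fourier):
    """All in-ellipse, in-partial-Fourier (ky, kz) points and their radii."""
    n_ky, n_kz = grid_shape
    ky = np.arange(-(n_ky // 2), n_ky - n_ky // 2)
    kz = np.arange(-(n_kz // 2), n_kz - n_kz // 2)
    KY, KZ = np.meshgrid(ky, kz, indexing="ij")
    r = _norm_radius(KY, KZ, grid_shape)
    cut_y = int(round((1.0 - partial_fourier) * n_ky))
    cut_z = int(round((1.0 - partial_fourier) * n_kz))
    keep = (r <= 1.0) & (KY >= -(n_ky // 2) + cut_y) & (KZ >= -(n_kz // 2) + cut_z)
    return KY[keep], KZ[keep], r[keep]


def generate_pattern(
    grid_shape,
    n_patterns: int = 3,
    central_fraction: float = 0.05,
    min_density: float | None = None,
    density_exponent: float = 2.0,
    target_lines: int | None = None,
    partial_fourier: float = 0.875,
    seeds=None,
) -> SamplingPattern:
    """Generate the overlaid variable-density Poisson-disk patterns.

    The peripheral target density follows A*(1-r)^p + min_density with A
    calibrated so the total point count (all patterns, core included) lands
    within +-2% of ``target_lines``.  Dart throwing with a radius-dependent
    exclusion distance realizes each pattern; a pair of candidate points at
    radii r1, r2 is accepted only if their distance exceeds the rejection
    radius evaluated at (r1+r2)/2.

    ``min_density`` defaults to 4% of the fully sampled density.  Units are
    samples per unit normalized-k-space area, per pattern.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    ky_all, kz_all, r_all = _eligible_grid(grid_shape, partial_fourier)
    cell_area = 1.0 / (grid_shape[0] / 2.0) / (grid_shape[1] / 2.0)
    full_density = 1.0 / cell_area
    if min_density is None:
        min_density = 0.04 * full_density
    if seeds is None:
        seeds = tuple(range(n_patterns))
    seeds = tuple(int(s) for s in seeds)
    if len(seeds) != n_patterns:
        raise ValueError("need one seed per pattern")

    core = r_all <= central_fraction
    n_core = int(core.sum())
    periph = ~core
    periph_area = float(periph.sum()) * cell_area

    if central_fraction >= 1.0 or not periph.any():
        # degenerate fully sampled limit
        ky = np.tile(ky_all, n_patterns)
        kz = np.tile(kz_all, n_patterns)
        pat = np.repeat(np.arange(1, n_patterns + 1), ky_all.size)
        return SamplingPattern(
            ky, kz, pat, grid_shape, central_fraction, min_density,
            partial_fourier, seeds, density_amp=0.0,
            density_exponent=density_exponent,
        )

    if target_lines is None:
        target_lines = n_patterns * n_core + int(
            round(0.35 * n_patterns * periph.sum())
        )
    if target_lines < n_patterns * n_core:
        raise ValueError(
            f"target_lines={target_lines} below mandatory core total "
            f"{n_patterns * n_core}"
        )
    periph_target = (target_lines - n_patterns * n_core) / n_patterns
    floor_expected = min_density * periph_area
    if periph_target < floor_expected * 0.98:
        raise ValueError(
            "infeasible target: minimum peripheral density alone requires "
            f">= {n_patterns * (n_core + floor_expected):.0f} total lines"
        )
    # calibrate the density amplitude A from the discrete area integral
    shape_int = float(
        (np.clip(1.0 - r_all[periph], 0, None) ** density_exponent).sum()
    ) * cell_area
    amp = max((periph_target - floor_expected) / max(shape_int, 1e-12), 0.0)

    def density(r):
        return amp * np.clip(1.0 - r, 0.0, None) ** density_exponent + min_density

    kyp, kzp, rp = ky_all[periph], kz_all[periph], r_all[periph]
    u_all = np.stack([kyp / (grid_shape[0] / 2.0), kzp / (grid_shape[1] / 2.0)], 1)
    rho = density(rp)
    prob = rho / rho.sum()
    per_pattern = int(round(periph_target))

    ky_out, kz_out, pat_out = [], [], []
    rejection_scale = 0.75 / np.sqrt(1.0)  # refined by the retry loop below
    for p in range(n_patterns):
        rng = np.random.default_rng(seeds[p])
        proposals = rng.choice(rp.size, size=min(60 * max(per_pattern, 1), 200_000),
                               p=prob)
        scale = 0.75
        best = None
        for _ in range(6):
            sel = _dart_throw(u_all, rp, proposals, density, scale, per_pattern,
                              central_fraction)
            if best is None or len(sel) > len(best[0]):
                best = (sel, scale)
            if len(sel) >= per_pattern:
                break
            scale *= 0.82  # saturated below target: tighten the packing
        sel, scale = best
        sel = np.asarray(sel[:per_pattern], dtype=int)
        # per-annulus floor top-up (rarely needed; keeps every annulus >= floor)
        sel = _floor_topup(sel, u_all, rp, density, scale, min_density,
                           cell_area, rng, central_fraction)
        ky_out.append(np.concatenate([ky_all[core], kyp[sel]]))
        kz_out.append(np.concatenate([kz_all[core], kzp[sel]]))
        pat_out.append(np.full(n_core + sel.size, p + 1))
        rejection_scale = scale

    ky = np.concatenate(ky_out)
    kz = np.concatenate(kz_out)
    pat = np.concatenate(pat_out)
    total = ky.size
    if abs(total - target_lines) > 0.02 * target_lines:
        raise RuntimeError(
            f"pattern generation realized {total} lines for target "
            f"{target_lines} (>2% off); adjust min_density or target_lines"
        )
    return SamplingPattern(
        ky, kz, pat, grid_shape, central_fraction, float(min_density),
        partial_fourier, seeds, density_amp=float(amp),
        density_exponent=density_exponent, rejection_scale=float(rejection_scale),
    )


def _dart_throw(u_all, r_all, proposals, density, scale, target, central_fraction):
    """Sequential dart throwing with pair-mean-radius exclusion distance."""
    accepted = []
    acc_u = np.empty((0, 2))
    acc_r = np.empty(0)
    taken = set()
    for cand in proposals:
        if len(accepted) >= target:
            break
        if cand in taken:
            continue
        u = u_all[cand]
        r = r_all[cand]
        if acc_r.size:
            mean_r = 0.5 * (acc_r + r)
            dmin2 = ((acc_u - u) ** 2).sum(1)
            rej = scale / np.sqrt(density(mean_r))
            if np.any(dmin2 < rej**2):
                continue
        accepted.append(int(cand))
        taken.add(int(cand))
        acc_u = np.vstack([acc_u, u])
        acc_r = np.append(acc_r, r)
    return accepted


def _floor_topup(sel, u_all, r_all, density, scale, min_density, cell_area,
                 rng, central_fraction, n_annuli: int = 6):
    """Add in-annulus points (respecting spacing) where density < floor."""
    sel = list(sel)
    edges = np.linspace(central_fraction, 1.0, n_annuli + 1)
    for lo, hi in zip(edges[:-1], edges[1:]):
        ann = (r_all >= lo) & (r_all < hi)
        n_cells = int(ann.sum())
        if n_cells == 0:
            continue
        area = n_cells * cell_area
        need = int(np.ceil(min_density * area))
        have = int(np.sum((r_all[np.asarray(sel, int)] >= lo)
                          & (r_all[np.asarray(sel, int)] < hi))) if sel else 0
        if have >= need:
            continue
        cand_pool = np.where(ann)[0]
        rng.shuffle(cand_pool)
        taken = set(sel)
        acc_u = u_all[np.asarray(sel, int)] if sel else np.empty((0, 2))
        acc_r = r_all[np.asarray(sel, int)] if sel else np.empty(0)
        for cand in cand_pool:
            if have >= need:
                break
            if int(cand) in taken:
                continue
            u, r = u_all[cand], r_all[cand]
            if acc_r.size:
                mean_r = 0.5 * (acc_r + r)
                if np.any(((acc_u - u) ** 2).sum(1)
                          < (scale / np.sqrt(density(mean_r))) ** 2):
                    continue
            sel.append(int(cand))
            taken.add(int(cand))
            acc_u = np.vstack([acc_u, u])
            acc_r = np.append(acc_r, r)
            have += 1
    return np.asarray(sel, dtype=int)


def build_schedule(
    pattern: SamplingPattern,
    nsegments: int,
    n_windows: int | None = None,
    seed: int = 0,
) -> AcquisitionSchedule:
    """Distribute the pattern's points over per-heartbeat windows.

    Points are split by normalized radius into nsegments-1 equal-count radial
    bins; each window draws one line (without replacement, seeded) from each
    bin and orders them center-out after the leading (0, 0) self-navigator
    line.  Bins are exhausted as evenly as possible: once a bin runs dry a
    window fills its remaining slots from the bins with the most lines left,
    so only the trailing window can be short.
    """
    if nsegments < 2:
        raise ValueError("nsegments must be >= 2")
    n_bins = nsegments - 1
    n_pts = pattern.n_points
    min_windows = int(np.ceil(n_pts / n_bins))
    if n_windows is None:
        n_windows = min_windows
    if n_pts > n_windows * n_bins:
        raise ValueError(
            f"{n_pts} points cannot be scheduled in {n_windows} windows of "
            f"{n_bins} non-center lines; need n_windows >= {min_windows}"
        )
    radii = pattern.radii()
    order = np.argsort(radii, kind="stable")
    bins = [list(chunk) for chunk in np.array_split(order, n_bins)]
    edges = np.array(
        [radii[b[-1]] if b else np.nan for b in bins]
    )  # upper radius of each of the nsegments-1 bins
    rng = np.random.default_rng(seed)
    for b in bins:
        rng.shuffle(b)

    windows = []
    for _ in range(n_windows):
        drawn = []
        for b in bins:
            if b:
                drawn.append(b.pop())
        while len(drawn) < n_bins and any(bins):
            richest = max(range(n_bins), key=lambda i: len(bins[i]))
            if not bins[richest]:
                break
            drawn.append(bins[richest].pop())
        drawn.sort(key=lambda i: radii[i])
        lines = [(0, 0)] + [(int(pattern.ky[i]), int(pattern.kz[i])) for i in drawn]
        windows.append(lines)
    return AcquisitionSchedule(
        windows=windows, radial_bin_edges=edges, grid_shape=pattern.grid_shape
    )


def verify_pattern(
    pattern: SamplingPattern,
    binning=None,
    schedule: AcquisitionSchedule | None = None,
    point_states=None,
    n_annuli: int = 6,
    central_region: float = 0.40,
) -> dict:
    """Report coverage and density diagnostics for a pattern.

    Returns per-annulus realized density (per pattern), the core coverage
    fraction, several candidate total-acceleration definitions (the printed
    in-vivo accelerations admit more than one reading, so all are reported
    rather than asserting one), and -- when a motion binning is supplied
    either as a per-point state array (``point_states``) or as a
    MotionBinning plus the schedule that maps points to windows -- the
    per-state acceleration within the central ``central_region`` of the
    normalized radius.
    """
    grid_shape = pattern.grid_shape
    ky_all, kz_all, r_all = _eligible_grid(grid_shape, pattern.partial_fourier)
    cell_area = 1.0 / (grid_shape[0] / 2.0) / (grid_shape[1] / 2.0)
    radii = pattern.radii()
    n_patterns = max(pattern.n_patterns, 1)

    core_grid = {(int(a), int(b)) for a, b in
                 zip(ky_all[r_all <= pattern.central_fraction],
                     kz_all[r_all <= pattern.central_fraction])}
    coverage = []
    for p in range(1, n_patterns + 1):
        pts = {(int(a), int(b)) for a, b in
               zip(pattern.ky[pattern.pattern == p],
                   pattern.kz[pattern.pattern == p])}
        covered = len(core_grid & pts)
        coverage.append(covered / len(core_grid) if core_grid else 1.0)

    edges = np.linspace(pattern.central_fraction, 1.0, n_annuli + 1)
    ann_density = np.zeros((n_patterns, n_annuli))
    for j, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        area = float(((r_all >= lo) & (r_all < hi)).sum()) * cell_area
        if area == 0:
            ann_density[:, j] = np.nan
            continue
        for p in range(1, n_patterns + 1):
            sel = (pattern.pattern == p) & (radii >= lo) & (radii < hi)
            ann_density[p - 1, j] = sel.sum() / area

    distinct = len({(int(a), int(b)) for a, b in zip(pattern.ky, pattern.kz)})
    full_grid = grid_shape[0] * grid_shape[1]
    report = {
        "core_coverage": np.array(coverage),
        "annulus_edges": edges,
        "annulus_density": ann_density,
        "min_density": pattern.min_density,
        "n_points": pattern.n_points,
        "n_distinct": distinct,
        "acceleration_candidates": {
            "full_grid_over_multiset": full_grid / pattern.n_points,
            "full_grid_over_distinct": full_grid / distinct,
            "elliptical_pf_over_multiset": r_all.size / pattern.n_points,
            "elliptical_pf_over_distinct": r_all.size / distinct,
        },
    }

    if point_states is None and binning is not None and schedule is not None:
        # map scheduled non-center lines to their window's motion state
        states = []
        pts = []
        for w_idx, lines in enumerate(schedule.windows):
            st = int(binning.assignment[w_idx])
            for line in lines[1:]:
                pts.append(line)
                states.append(st)
        pts = np.asarray(pts)
        point_states = np.asarray(states)
        r_pts = _norm_radius(pts[:, 0], pts[:, 1], grid_shape)
    elif point_states is not None:
        point_states = np.asarray(point_states)
        r_pts = radii
    if point_states is not None:
        central = r_pts <= central_region
        total_central = int(central.sum())
        n_states = int(point_states.max()) + 1
        accel = np.array([
            total_central / max(int((central & (point_states == m)).sum()), 1)
            for m in range(n_states)
        ])
        report["per_bin_central_acceleration"] = accel
        grid_central = int((r_all <= central_region).sum())
        report["per_bin_central_acceleration_vs_grid"] = np.array([
            grid_central / max(int((central & (point_states == m)).sum()), 1)
            for m in range(n_states)
        ])
    return report
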