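"""Serial-section alignment on downsampled density rasters.

Each marker slide carries a point pattern of positive-cell coordinates at
full scanning resolution (0.2 µm/pixel).  To align a stack of serial
sections we rasterize each pattern to a working image of roughly
500 × 500 pixels, estimate a rigid transform (normalized cross-correlation,
multi-start rotation grid plus local refinement) followed by a
diffusion-regularized demons displacement field, and then transfer the
full-resolution coordinates through the field by bilinear interpolation —
equivalent to upsampling the deformation field to the original image size.

Transform convention
--------------------
Estimated transforms are *resampling maps* ``T`` from fixed-frame working
coordinates to moving-frame coordinates, i.e. ``moving(T(x)) ≈ fixed(x)``.
:func:`align_to_reference` therefore registers with ``moving`` = the
reference raster and ``fixed`` = the slide raster, so that ``T`` pushes the
slide's cell coordinates directly into the reference frame without any
field inversion.  Composition order is fixed: the demons displacement is
applied first, then the rigid part — ``T(x) = R(x + u(x))`` — matching the
rigid-then-nonrigid estimation order (the demons field refines the
rigidly-aligned pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "MarkerPointPattern",
    "RasterGrid",
    "RigidTransform",
    "DeformationField",
    "RegistrationResult",
    "rasterize",
    "register_rigid",
    "register_nonrigid",
    "upsample_and_transform",
    "align_to_reference",
]


@dataclass
class MarkerPointPattern:
    """One marker slide's detected-cell coordinates, in µm.

    ``points`` holds every detected cell; the boolean ``positive`` mask
    separates marker-positive cells (used for density quantification) from
    negative ones (which still carry tissue structure that registration
    exploits).  Omitting the mask means all cells are positive.
    """

    marker: str
    points: np.ndarray  # (n, 2) µm
    slide_extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax µm
    resolution: float = 0.2  # µm per full-resolution pixel
    positive: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.positive is None:
            self.positive = np.ones(len(self.points), dtype=bool)
        else:
            self.positive = np.asarray(self.positive, dtype=bool).reshape(-1)
            if len(self.positive) != len(self.points):
                raise ValueError("positive mask length must match point count")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def n_positive(self) -> int:
        return int(self.positive.sum())

    def positive_pattern(self) -> "MarkerPointPattern":
        """Subpattern of marker-positive cells only."""
        return MarkerPointPattern(
            self.marker, self.points[self.positive], self.slide_extent, self.resolution
        )

    def with_points(self, points: np.ndarray) -> "MarkerPointPattern":
        return MarkerPointPattern(
            self.marker, points, self.slide_extent, self.resolution, self.positive.copy()
        )


@dataclass(frozen=True)
class RasterGrid:
    """Mapping between slide µm coordinates and working-raster pixels."""

    origin: tuple[float, float]  # µm of pixel-(0, 0) corner
    scale: float  # µm per working pixel
    side: int  # pixels per side

    def to_px(self, pts_um: np.ndarray) -> np.ndarray:
        p = np.asarray(pts_um, dtype=float)
        return (p - np.asarray(self.origin)) / self.scale

    def to_um(self, pts_px: np.ndarray) -> np.ndarray:
        return np.asarray(pts_px, dtype=float) * self.scale + np.asarray(self.origin)


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about the raster centre plus translation, working pixels."""

    rotation_deg: float
    shift: tuple[float, float]  # (dx, dy) px
    center: tuple[float, float]  # rotation centre, px

    def apply(self, pts_px: np.ndarray) -> np.ndarray:
        p = np.asarray(pts_px, dtype=float).reshape(-1, 2)
        th = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.asarray(self.center)
        return (p - c) @ rot.T + c + np.asarray(self.shift)

    def inverse(self) -> "RigidTransform":
        th = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        s = -rot.T @ np.asarray(self.shift)
        return RigidTransform(-self.rotation_deg, (s[0], s[1]), self.center)

    @classmethod
    def identity(cls, side: int) -> "RigidTransform":
        c = (side - 1) / 2.0
        return cls(0.0, (0.0, 0.0), (c, c))


@dataclass
class DeformationField:
    """Rigid component plus a dense working-scale displacement grid.

    ``u`` has shape (side, side, 2) holding (dx, dy) in working pixels on
    the fixed-frame grid.  The composed map is ``T(x) = rigid(x + u(x))``.
    """

    rigid: RigidTransform
    u: np.ndarray
    grid: RasterGrid
    moving_id: str = ""
    fixed_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement grid contains non-finite values")

    def apply_px(self, pts_px: np.ndarray) -> tuple[np.ndarray, int]:
        """Map fixed-frame px points through demons-then-rigid.

        Returns transformed points and the number of points that fell
        outside the field domain (nearest-edge extrapolated).
        """
        p = np.asarray(pts_px, dtype=float).reshape(-1, 2)
        hi = self.grid.side - 1
        outside = int(np.sum((p < 0).any(axis=1) | (p > hi).any(axis=1)))
        # map_coordinates indexes (row=y, col=x); clamp = nearest-edge
        coords = np.vstack([p[:, 1], p[:, 0]])
        dx = ndimage.map_coordinates(self.u[..., 0], coords, order=1, mode="nearest")
        dy = ndimage.map_coordinates(self.u[..., 1], coords, order=1, mode="nearest")
        return self.rigid.apply(p + np.column_stack([dx, dy])), outside

    def save_npz(self, path) -> None:
        """Persist as a 2-band float raster plus transform metadata."""
        np.savez_compressed(
            path,
            dx=self.u[..., 0], dy=self.u[..., 1],
            rigid=np.array([self.rigid.rotation_deg, *self.rigid.shift, *self.rigid.center]),
            grid=np.array([*self.grid.origin, self.grid.scale, self.grid.side]),
            ids=np.array([self.moving_id, self.fixed_id]),
        )

    @classmethod
    def load_npz(cls, path) -> "DeformationField":
        with np.load(path, allow_pickle=False) as data:
            rigid = RigidTransform(
                float(data["rigid"][0]),
                (float(data["rigid"][1]), float(data["rigid"][2])),
                (float(data["rigid"][3]), float(data["rigid"][4])),
            )
            grid = RasterGrid(
                origin=(float(data["grid"][0]), float(data["grid"][1])),
                scale=float(data["grid"][2]),
                side=int(data["grid"][3]),
            )
            u = np.stack([data["dx"], data["dy"]], axis=-1)
            ids = data["ids"]
            return cls(rigid, u, grid, moving_id=str(ids[0]), fixed_id=str(ids[1]))


@dataclass
class RegistrationResult:
    field: DeformationField
    score_before: float
    score_after: float
    transformed: MarkerPointPattern | None = None
    n_extrapolated: int = 0
    is_reference: bool = False


def _square_extent(extent: tuple[float, float, float, float]) -> tuple[float, float, float]:
    """Square bounding box (origin x, origin y, side) centred on the extent."""
    xmin, ymin, xmax, ymax = extent
    side = max(xmax - xmin, ymax - ymin)
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    return cx - side / 2.0, cy - side / 2.0, side


def rasterize(
    pattern: MarkerPointPattern,
    target_side: int = 500,
    sigma: float = 3.0,
) -> tuple[np.ndarray, RasterGrid]:
    """Density raster of a point pattern on a square working grid.

    A 2-D histogram of point counts over ``target_side`` bins spanning the
    (squared) slide extent, Gaussian-smoothed with ``sigma`` working pixels.
    Before smoothing the image sums to the point count; smoothing preserves
    total mass up to boundary truncation.
    """
    if target_side < 64:
        raise ValueError("target_side must be >= 64 pixels")
    ox, oy, side_um = _square_extent(pattern.slide_extent)
    grid = RasterGrid(origin=(ox, oy), scale=side_um / target_side, side=target_side)
    if pattern.n == 0:
        warnings.warn(f"rasterize: empty pattern {pattern.marker!r}", stacklevel=2)
        return np.zeros((target_side, target_side)), grid
    px = grid.to_px(pattern.points)
    img, _, _ = np.histogram2d(
        px[:, 1], px[:, 0], bins=target_side, range=[[0, target_side], [0, target_side]]
    )
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma)
    return img, grid


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-shape images."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _resample_rigid(moving: np.ndarray, t: RigidTransform) -> np.ndarray:
    """Sample ``moving`` at T(x) over the fixed grid (output(x)=moving(T(x)))."""
    th = np.deg2rad(t.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    # affine_transform works in (row, col) = (y, x) order
    rot_rc = np.array([[rot[1, 1], rot[1, 0]], [rot[0, 1], rot[0, 0]]])
    c = np.array([t.center[1], t.center[0]])
    shift = np.array([t.shift[1], t.shift[0]])
    offset = c + shift - rot_rc @ c
    return ndimage.affine_transform(moving, rot_rc, offset=offset, order=1, mode="constant", cval=0.0)


def _fft_shift(moving: np.ndarray, fixed: np.ndarray) -> tuple[float, float]:
    """Translation (dx, dy) maximizing correlation of moving shifted onto fixed."""
    fa = np.fft.rfft2(moving - moving.mean())
    fb = np.fft.rfft2(fixed - fixed.mean())
    corr = np.fft.irfft2(fa * np.conj(fb), s=moving.shape)
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    n = moving.shape[0]
    dy = iy if iy <= n // 2 else iy - n
    dx = ix if ix <= n // 2 else ix - n
    # corr peak at (dy, dx) means moving(x + d) matches fixed(x): T-shift = +d
    return float(dx), float(dy)


def register_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    rotation_range: float = 12.0,
    rotation_step: float = 2.0,
) -> tuple[RigidTransform, float]:
    """Estimate the rigid resampling map maximizing NCC.

    Coarse search: rotation grid at quarter scale with FFT translation per
    rotation; refinement: Nelder–Mead on (rotation, dx, dy) at full working
    scale.  Returns the transform and its NCC score.  A flat image yields
    the identity with a warning.
    """
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed images must share a shape")
    side = moving.shape[0]
    ident = RigidTransform.identity(side)
    if moving.std() == 0 or fixed.std() == 0:
        warnings.warn("register_rigid: flat image, returning identity", stacklevel=2)
        return ident, _ncc(moving, fixed)

    # --- coarse: quarter-scale rotation grid + FFT translation
    f = max(1, side // 128)
    mv_small = ndimage.zoom(moving, 1.0 / f, order=1)
    fx_small = ndimage.zoom(fixed, 1.0 / f, order=1)
    best = (0.0, 0.0, 0.0)
    best_score = -np.inf
    csmall = (mv_small.shape[0] - 1) / 2.0
    for rot_deg in np.arange(-rotation_range, rotation_range + 1e-9, rotation_step):
        t_small = RigidTransform(rot_deg, (0.0, 0.0), (csmall, csmall))
        rotated = _resample_rigid(mv_small, t_small)
        dx, dy = _fft_shift(rotated, fx_small)
        t_try = RigidTransform(rot_deg, (dx, dy), (csmall, csmall))
        score = _ncc(_resample_rigid(mv_small, t_try), fx_small)
        if score > best_score:
            best_score = score
            best = (rot_deg, dx * f, dy * f)

    # --- refine at half scale (cheap), then polish at working scale
    mv_half = ndimage.zoom(moving, 0.5, order=1)
    fx_half = ndimage.zoom(fixed, 0.5, order=1)
    chalf = (mv_half.shape[0] - 1) / 2.0

    def neg_ncc_half(params: np.ndarray) -> float:
        t = RigidTransform(params[0], (params[1] / 2.0, params[2] / 2.0), (chalf, chalf))
        return -_ncc(_resample_rigid(mv_half, t), fx_half)

    res = optimize.minimize(
        neg_ncc_half,
        x0=np.array(best),
        method="Nelder-Mead",
        options={"xatol": 0.01, "fatol": 1e-7, "maxiter": 120},
    )
    cand = RigidTransform(res.x[0], (res.x[1], res.x[2]), ident.center)
    cand_score = _ncc(_resample_rigid(moving, cand), fixed)
    id_score = _ncc(moving, fixed)
    if cand_score >= id_score:
        return cand, float(cand_score)
    return ident, float(id_score)


def register_nonrigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    window_sizes: tuple[int, ...] = (200, 120, 80),
    max_search: float = 15.0,
    smooth_windows: float = 0.8,
    min_weight: float = 0.05,
) -> np.ndarray:
    """Smooth displacement estimation by regularized local block matching.

    Iterates coarse-to-fine over ``window_sizes``: at each pass, the fixed
    image is covered by half-overlapping windows, each window's
    displacement is estimated by the (subpixel) peak of the zero-mean local
    cross-correlation against the current warped moving image, and the
    sparse block displacements are merged into a dense field by
    correlation-weighted Gaussian regression over the block grid — a
    smoothness regularization that suppresses unreliable blocks (weight
    below ``min_weight`` of the best block is ignored).  Local correlation
    is insensitive to regional intensity differences between serial-section
    markers, which defeats plain intensity-matching updates.

    The pass is accepted only if the NCC dissimilarity (1 - NCC) does not
    increase; a diverging pass returns the best-so-far field with a
    warning.  Returns ``u`` of shape (side, side, 2) in working pixels on
    the fixed grid (``moving(x + u(x)) ≈ fixed(x)``); the caller is
    expected to have applied the rigid step already.
    """
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed images must share a shape")
    side = moving.shape[0]
    u = np.zeros((side, side, 2))
    best_err = 1.0 - _ncc(moving, fixed)
    for w in window_sizes:
        warped = _warp(moving, u)
        du = _block_match_field(warped, fixed, int(w), max_search, smooth_windows, min_weight)
        cand = u + du
        err = 1.0 - _ncc(_warp(moving, cand), fixed)
        if err <= best_err + 1e-12:
            u = cand
            best_err = err
        else:
            warnings.warn("register_nonrigid: divergence, returning best-so-far", stacklevel=2)
            break
    return u


def _warp(img: np.ndarray, u: np.ndarray) -> np.ndarray:
    n = img.shape[0]
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    coords = np.vstack([(yy + u[..., 1]).ravel(), (xx + u[..., 0]).ravel()])
    return ndimage.map_coordinates(img, coords, order=1, mode="nearest").reshape(n, n)


def _subpixel_peak(corr: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Separable parabola refinement of an integer correlation peak."""
    def refine(cm: float, c0: float, cp: float) -> float:
        denom = cm - 2 * c0 + cp
        if denom >= 0:
            return 0.0
        return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))

    dy = dx = 0.0
    if 0 < iy < corr.shape[0] - 1:
        dy = refine(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    if 0 < ix < corr.shape[1] - 1:
        dx = refine(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
    return dx, dy


def _block_match_field(
    moving: np.ndarray,
    fixed: np.ndarray,
    window: int,
    max_search: float,
    smooth_windows: float,
    min_weight: float,
) -> np.ndarray:
    """One block-matching pass: dense incremental displacement field."""
    side = moving.shape[0]
    stride = max(window // 2, 1)
    centers = np.arange(window // 2, side - window // 2 + 1, stride)
    if len(centers) == 0:
        centers = np.array([side // 2])
    nb = len(centers)
    disp = np.zeros((nb, nb, 2))
    weight = np.zeros((nb, nb))
    half = window // 2
    for bi, cy in enumerate(centers):
        for bj, cx in enumerate(centers):
            fy, fx_ = slice(cy - half, cy + half), slice(cx - half, cx + half)
            f_patch = fixed[fy, fx_]
            m_patch = moving[fy, fx_]
            fs, ms = f_patch.std(), m_patch.std()
            if fs == 0 or ms == 0:
                continue
            a = m_patch - m_patch.mean()
            b = f_patch - f_patch.mean()
            corr = np.fft.irfft2(
                np.fft.rfft2(a) * np.conj(np.fft.rfft2(b)), s=a.shape
            )
            corr = np.fft.fftshift(corr)
            c0 = window // 2
            r = int(min(max_search, c0 - 1))
            sub = corr[c0 - r : c0 + r + 1, c0 - r : c0 + r + 1]
            iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
            ddx, ddy = _subpixel_peak(sub, iy, ix)
            disp[bi, bj] = (ix - r + ddx, iy - r + ddy)
            weight[bi, bj] = max(sub[iy, ix] / (window * window * ms * fs), 0.0)
    if weight.max() <= 0:
        return np.zeros((side, side, 2))
    weight[weight < min_weight * weight.max()] = 0.0
    # correlation-weighted Gaussian regression over the block grid
    sw = ndimage.gaussian_filter(weight, smooth_windows, mode="nearest")
    coarse = np.zeros((nb, nb, 2))
    for k in range(2):
        num = ndimage.gaussian_filter(weight * disp[..., k], smooth_windows, mode="nearest")
        coarse[..., k] = np.where(sw > 1e-12, num / np.maximum(sw, 1e-12), 0.0)
    # interpolate block-centre values to the full grid (edge-extended)
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    pos = (np.clip((yy - centers[0]) / stride, 0, nb - 1),
           np.clip((xx - centers[0]) / stride, 0, nb - 1))
    du = np.zeros((side, side, 2))
    for k in range(2):
        du[..., k] = ndimage.map_coordinates(coarse[..., k], pos, order=1, mode="nearest")
    return du


def upsample_and_transform(
    field: DeformationField, pattern: MarkerPointPattern
) -> tuple[MarkerPointPattern, int]:
    """Transfer full-resolution cell coordinates through the working field.

    The working-scale displacement grid is bilinearly interpolated at each
    full-resolution coordinate (the continuous equivalent of upsampling the
    field to the original image size), the demons displacement applied, then
    the rigid part; µm↔pixel conversion uses the raster grid.  Points
    outside the field domain are nearest-edge extrapolated and counted.
    """
    px = field.grid.to_px(pattern.points)
    out_px, n_extrap = field.apply_px(px)
    if n_extrap:
        warnings.warn(
            f"upsample_and_transform: {n_extrap} point(s) outside field domain, "
            "nearest-edge extrapolated",
            stacklevel=2,
        )
    return pattern.with_points(field.grid.to_um(out_px)), n_extrap


def register_pair(
    moving_img: np.ndarray,
    fixed_img: np.ndarray,
    grid: RasterGrid,
    moving_id: str = "",
    fixed_id: str = "",
    nonrigid: bool = True,
    **nonrigid_kwargs,
) -> tuple[DeformationField, float, float]:
    """Rigid-then-nonrigid registration of one raster pair.

    Returns the composed deformation field plus NCC before and after.  The
    accepted result never scores below the identity transform.
    """
    rigid, rigid_score = register_rigid(moving_img, fixed_img)
    score_before = _ncc(moving_img, fixed_img)
    aligned = _resample_rigid(moving_img, rigid)
    if nonrigid:
        u = register_nonrigid(aligned, fixed_img, **nonrigid_kwargs)
        score_after = _ncc(_warp(aligned, u), fixed_img)
        if score_after < rigid_score:  # demons must not undo the rigid fit
            u = np.zeros_like(u)
            score_after = rigid_score
    else:
        u = np.zeros((grid.side, grid.side, 2))
        score_after = rigid_score
    field = DeformationField(rigid=rigid, u=u, grid=grid, moving_id=moving_id, fixed_id=fixed_id)
    return field, float(score_before), float(score_after)


def align_to_reference(
    slides: list[MarkerPointPattern],
    reference_index: int | None = None,
    target_side: int = 500,
    sigma: float = 3.0,
    nonrigid: bool = True,
    **nonrigid_kwargs,
) -> list[RegistrationResult]:
    """Register every slide of a serial-section stack to the reference slide.

    ``reference_index`` defaults to the middle slide (index ``len // 2``,
    i.e. index 3 of a 7-slide stack).  Each non-reference slide's raster is
    the *fixed* image and the reference raster the *moving* image, so the
    estimated map transfers the slide's cell coordinates into the reference
    frame (see module docstring).  The reference slide gets an identity
    result.
    """
    if len(slides) == 0:
        raise ValueError("empty slide list")
    if reference_index is None:
        reference_index = len(slides) // 2
    if not 0 <= reference_index < len(slides):
        raise ValueError(f"reference_index {reference_index} out of range")
    ref = slides[reference_index]
    ref_img, grid = rasterize(ref, target_side=target_side, sigma=sigma)
    results: list[RegistrationResult] = []
    for i, slide in enumerate(slides):
        if i == reference_index:
            ident = DeformationField(
                rigid=RigidTransform.identity(target_side),
                u=np.zeros((target_side, target_side, 2)),
                grid=grid,
                moving_id=ref.marker,
                fixed_id=slide.marker,
            )
            score = _ncc(ref_img, ref_img)
            results.append(
                RegistrationResult(ident, score, score, transformed=slide, is_reference=True)
            )
            continue
        slide_img, _ = rasterize(slide, target_side=target_side, sigma=sigma)
        field, before, after = register_pair(
            ref_img, slide_img, grid,
            moving_id=ref.marker, fixed_id=slide.marker,
            nonrigid=nonrigid, **nonrigid_kwargs,
        )
        transformed, n_extrap = upsample_and_transform(field, slide)
        results.append(RegistrationResult(field, before, after, transformed, n_extrap))
    return results
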