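"""Synthetic serial-section cohorts with known ground truth.

The generator emulates the data layout of a tumor immune-profiling study:
per patient, one tumor-core annotation plus one positive-cell point pattern
per marker (default CD3, CD4, CD8, CD19, CD163, CK), small per-slide
misalignments standing in for serial-section cutting/mounting shifts, and a
clinical record whose event times are tied to immune densities by a
proportional-hazards model.  Every planted quantity (misalignment transform,
pre-misalignment densities, log hazard ratios) is retained so downstream
stages can be tested by parameter recovery.

Spatial model: a Thomas cluster process — Poisson parents, Gaussian-scattered
offspring — restricted to tumor core plus invasive-margin band, with the
offspring thinned so the realized intensity in the band is ``im_enrichment``
times the core intensity.  By default the lymphocyte markers are enriched
about two-fold in the margin while macrophages (CD163) and tumor cells (CK)
are not.  Cluster parents are shared across the markers of one patient so
serial sections exhibit the common tissue architecture that intensity-based
registration relies on.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

from .regions import RegionAnnotation, build_im_band
from .registration import MarkerPointPattern
from .stats import SurvivalRecord

__all__ = [
    "TumorGeometry",
    "CohortSpec",
    "MisalignmentTransform",
    "SyntheticPatient",
    "generate_geometry",
    "simulate_point_pattern",
    "apply_misalignment",
    "generate_survival",
    "generate_patient",
    "generate_cohort",
]

# section order: CK cut in the middle of the stack, so the middle-slide
# registration reference is the dense tumor-cell slide
DEFAULT_MARKERS = ("CD3", "CD4", "CD8", "CK", "CD19", "CD163")
IMMUNE_MARKERS = ("CD3", "CD4", "CD8", "CD19", "CD163")

# order-of-magnitude density choices (cells/mm^2 in the tumor core); the
# relative IM enrichment, not the absolute scale, is what the analysis sees
DEFAULT_BASE_INTENSITY = {
    "CD3": 800.0,
    "CD4": 500.0,
    "CD8": 400.0,
    "CD19": 150.0,
    "CD163": 300.0,
    "CK": 2000.0,
}
DEFAULT_IM_ENRICHMENT = {
    "CD3": 2.0,
    "CD4": 2.0,
    "CD8": 2.0,
    "CD19": 2.0,
    "CD163": 1.0,  # macrophages evenly distributed between core and margin
    "CK": 1.0,
}


@dataclass(frozen=True)
class TumorGeometry:
    """Tumor-core polygon on a slide; the invasive front is its boundary."""

    tc_polygon: Polygon
    slide_extent: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not (self.tc_polygon.is_valid and self.tc_polygon.is_simple):
            raise ValueError("tumor-core polygon must be simple and valid")
        xmin, ymin, xmax, ymax = self.slide_extent
        bx = self.tc_polygon.bounds
        if bx[0] < xmin or bx[1] < ymin or bx[2] > xmax or bx[3] > ymax:
            raise ValueError("tumor-core polygon extends beyond the slide extent")

    @property
    def if_polyline(self):
        return self.tc_polygon.exterior

    def annotation(self, im_width: float = 100.0) -> RegionAnnotation:
        return RegionAnnotation.from_polygon(self.tc_polygon, im_width=im_width)


@dataclass
class CohortSpec:
    """All knobs of the synthetic cohort, with study-scale defaults."""

    n_patients: int = 68
    markers: tuple[str, ...] = DEFAULT_MARKERS
    resolution: float = 0.2  # µm per full-resolution pixel
    slide_extent: tuple[float, float, float, float] = (0.0, 0.0, 2000.0, 2000.0)
    im_width: float = 100.0
    base_intensity: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_INTENSITY))
    im_enrichment: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_IM_ENRICHMENT))
    # Thomas cluster process
    parent_rate: float = 100.0  # parents per mm^2
    offspring_sigma: float = 40.0  # µm
    shared_parents: bool = True
    # marker-negative tissue nuclei: one pattern per patient, carried by
    # every serial section (thinned and jittered per slide) the way the
    # same cells recur across adjacent 4 µm sections
    tissue_intensity: float = 2500.0  # nuclei per mm^2
    tissue_keep_prob: float = 0.85
    tissue_jitter_um: float = 2.0
    # geometry
    semi_axis_range: tuple[float, float] = (500.0, 700.0)
    perturb_amplitude: float = 0.12
    # per-slide misalignment
    max_rotation_deg: float = 5.0
    max_translation_um: float = 30.0
    warp_amplitude_um: float = 15.0
    warp_wavelength_um: tuple[float, float] = (1000.0, 3000.0)
    # survival
    baseline_hazard_dfs: float = 0.0054  # per month
    baseline_hazard_os: float = 0.0032
    log_hr: dict[str, float] = field(default_factory=lambda: {"TC-CD3": -0.7})
    censoring_rate: float = 0.2
    admin_horizon_months: float = 120.0
    survival_model: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.0
    metastasis_given_recurrence: float = 0.74
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.base_intensity.values()):
            raise ValueError("intensities must be >= 0")
        if any(v <= 0 for v in self.im_enrichment.values()):
            raise ValueError("im_enrichment must be > 0")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring rate must be in [0, 1)")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.baseline_hazard_dfs < 0 or self.baseline_hazard_os < 0:
            raise ValueError("baseline hazards must be >= 0")

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class MisalignmentTransform:
    """Exact forward transform planted on one slide.

    Rotation about ``center`` then translation, then a smooth warp that is
    a sum of low-frequency sinusoidal displacement components:
    ``d(x) = sum_k a_k * sin(2π (f_k · x) + φ_k)`` per axis.
    """

    rotation_deg: float
    translation: tuple[float, float]
    center: tuple[float, float]
    warp_x: tuple[tuple[float, float, float, float], ...] = ()  # (amp, fx, fy, phase)
    warp_y: tuple[tuple[float, float, float, float], ...] = ()

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float).reshape(-1, 2)
        if self.rotation_deg != 0:
            th = np.deg2rad(self.rotation_deg)
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            c = np.asarray(self.center)
            out = (p - c) @ rot.T + c
        else:
            out = p.copy()
        out += np.asarray(self.translation)
        dx = np.zeros(len(out))
        dy = np.zeros(len(out))
        for amp, fx, fy, phase in self.warp_x:
            dx += amp * np.sin(2 * np.pi * (fx * out[:, 0] + fy * out[:, 1]) + phase)
        for amp, fx, fy, phase in self.warp_y:
            dy += amp * np.sin(2 * np.pi * (fx * out[:, 0] + fy * out[:, 1]) + phase)
        out[:, 0] += dx
        out[:, 1] += dy
        return out

    @property
    def is_identity(self) -> bool:
        return (
            self.rotation_deg == 0
            and self.translation == (0.0, 0.0)
            and not self.warp_x
            and not self.warp_y
        )


@dataclass
class SyntheticPatient:
    patient_id: str
    geometry: TumorGeometry
    slides: dict[str, MarkerPointPattern]  # observed (misaligned) patterns
    true_slides: dict[str, MarkerPointPattern]  # pre-misalignment ground truth
    transforms: dict[str, MisalignmentTransform]
    true_densities: dict[str, float]
    clinical: SurvivalRecord | None = None


def generate_geometry(spec: CohortSpec, rng: np.random.Generator, max_retries: int = 20) -> TumorGeometry:
    """Random blob-like simple polygon: radially perturbed ellipse.

    Regenerates internally on the (rare) self-intersecting draw and fails
    after ``max_retries`` attempts.
    """
    xmin, ymin, xmax, ymax = spec.slide_extent
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    for _ in range(max_retries):
        a = rng.uniform(*spec.semi_axis_range)
        b = rng.uniform(*spec.semi_axis_range)
        theta = np.linspace(0, 2 * np.pi, 181)[:-1]
        r_mod = np.ones_like(theta)
        for k in range(2, 6):
            amp = spec.perturb_amplitude * rng.uniform(0, 1) / np.sqrt(max(k - 1, 1))
            r_mod += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
        xs = cx + a * r_mod * np.cos(theta)
        ys = cy + b * r_mod * np.sin(theta)
        poly = Polygon(np.column_stack([xs, ys]))
        if not (poly.is_valid and poly.is_simple):
            continue
        bx = poly.bounds
        if bx[0] < xmin or bx[1] < ymin or bx[2] > xmax or bx[3] > ymax:
            continue
        return TumorGeometry(tc_polygon=poly, slide_extent=spec.slide_extent)
    raise RuntimeError(f"could not generate a simple polygon in {max_retries} attempts")


def _thomas_parents(
    domain: BaseGeometry, parent_rate_mm2: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson parents over the domain bounds dilated by 3 sigma."""
    xmin, ymin, xmax, ymax = domain.bounds
    xmin, ymin, xmax, ymax = xmin - 3 * sigma, ymin - 3 * sigma, xmax + 3 * sigma, ymax + 3 * sigma
    area_mm2 = (xmax - xmin) * (ymax - ymin) / 1e6
    n = rng.poisson(parent_rate_mm2 * area_mm2)
    return np.column_stack([rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)])


def simulate_point_pattern(
    geometry: TumorGeometry,
    marker: str,
    base_intensity: float,
    im_enrichment: float,
    spec: CohortSpec,
    rng: np.random.Generator,
    parents: np.ndarray | None = None,
) -> MarkerPointPattern:
    """Thomas cluster pattern over TC ∪ IM with margin enrichment.

    Offspring are generated at the peak intensity and thinned by the local
    intensity ratio, so the point count in any region is Poisson around
    intensity × area and the realized IM/TC density ratio (on disjoint
    core/band regions) matches ``im_enrichment`` in expectation.
    """
    if base_intensity < 0:
        raise ValueError("intensity must be >= 0")
    annotation = geometry.annotation(spec.im_width)
    band = build_im_band(annotation, extent=geometry.slide_extent)
    domain = geometry.tc_polygon.union(band)
    if domain.area == 0:
        warnings.warn("zero-area domain: empty pattern", stacklevel=2)
        return MarkerPointPattern(marker, np.empty((0, 2)), geometry.slide_extent, spec.resolution)
    lam_max = base_intensity * max(1.0, im_enrichment)  # cells/mm^2
    if lam_max == 0:
        return MarkerPointPattern(marker, np.empty((0, 2)), geometry.slide_extent, spec.resolution)
    if parents is None:
        parents = _thomas_parents(domain, spec.parent_rate, spec.offspring_sigma, rng)
    if len(parents) == 0:
        return MarkerPointPattern(marker, np.empty((0, 2)), geometry.slide_extent, spec.resolution)
    bxmin, bymin, bxmax, bymax = domain.bounds
    gen_area_mm2 = (
        (bxmax - bxmin + 6 * spec.offspring_sigma)
        * (bymax - bymin + 6 * spec.offspring_sigma)
        / 1e6
    )
    mu = lam_max * gen_area_mm2 / len(parents)  # offspring per parent at peak intensity
    counts = rng.poisson(mu, size=len(parents))
    total = int(counts.sum())
    if total == 0:
        return MarkerPointPattern(marker, np.empty((0, 2)), geometry.slide_extent, spec.resolution)
    centers = np.repeat(parents, counts, axis=0)
    pts = centers + rng.normal(0.0, spec.offspring_sigma, size=(total, 2))
    # location-dependent thinning: band at enrichment, core at 1, outside at 0
    import shapely

    in_tc = shapely.intersects_xy(geometry.tc_polygon, pts[:, 0], pts[:, 1])
    in_band = shapely.intersects_xy(band, pts[:, 0], pts[:, 1])
    ratio = np.where(
        in_band, im_enrichment * base_intensity, np.where(in_tc, base_intensity, 0.0)
    ) / lam_max
    keep = rng.uniform(size=total) < ratio
    pts = pts[keep]
    xmin, ymin, xmax, ymax = geometry.slide_extent
    inside = (pts[:, 0] >= xmin) & (pts[:, 0] <= xmax) & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax)
    return MarkerPointPattern(marker, pts[inside], geometry.slide_extent, spec.resolution)


def sample_misalignment(spec: CohortSpec, rng: np.random.Generator) -> MisalignmentTransform:
    """Draw a random per-slide misalignment within the spec bounds."""
    xmin, ymin, xmax, ymax = spec.slide_extent
    center = ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)
    rot = rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg)
    ang = rng.uniform(0, 2 * np.pi)
    mag = rng.uniform(0, spec.max_translation_um)
    trans = (mag * np.cos(ang), mag * np.sin(ang))

    def comps() -> tuple[tuple[float, float, float, float], ...]:
        n = rng.integers(2, 5)
        amps = rng.dirichlet(np.ones(n)) * spec.warp_amplitude_um
        out = []
        for ai in amps:
            wl = rng.uniform(*spec.warp_wavelength_um)
            direction = rng.uniform(0, 2 * np.pi)
            out.append(
                (float(ai), float(np.cos(direction) / wl), float(np.sin(direction) / wl),
                 float(rng.uniform(0, 2 * np.pi)))
            )
        return tuple(out)

    return MisalignmentTransform(
        rotation_deg=float(rot), translation=trans, center=center,
        warp_x=comps(), warp_y=comps(),
    )


def apply_misalignment(
    pattern: MarkerPointPattern,
    transform: MisalignmentTransform | None = None,
    spec: CohortSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MarkerPointPattern, MisalignmentTransform]:
    """Apply (or sample and apply) a misalignment; returns the ground truth.

    Raises if the displaced pattern leaves the slide extent, which signals
    a warp amplitude inconsistent with the configured slide.
    """
    if transform is None:
        if spec is None or rng is None:
            raise ValueError("either a transform or (spec, rng) must be given")
        transform = sample_misalignment(spec, rng)
    moved = transform.apply(pattern.points)
    if len(moved):
        xmin, ymin, xmax, ymax = pattern.slide_extent
        if (
            moved[:, 0].min() < xmin or moved[:, 0].max() > xmax
            or moved[:, 1].min() < ymin or moved[:, 1].max() > ymax
        ):
            raise ValueError("misalignment pushes the pattern outside the slide extent")
    return pattern.with_points(moved), transform


STAGE_MARGINALS = {
    "I": 0.22, "IIA": 0.25, "IIB": 0.21, "IIIA": 0.16, "IIIB": 0.08, "IIIC": 0.08,
}
AGE_MARGINALS = {"<40": 11 / 68, "40-50": 18 / 68, ">50": 39 / 68}


def _sample_covariates(rng: np.random.Generator) -> dict:
    stage = rng.choice(list(STAGE_MARGINALS), p=list(STAGE_MARGINALS.values()))
    age = rng.choice(list(AGE_MARGINALS), p=list(AGE_MARGINALS.values()))
    return {
        "stage": str(stage),
        "age_group": str(age),
        "tumor_size_cm": float(np.round(rng.lognormal(np.log(2.5), 0.4), 1)),
        "grade": int(rng.choice([2, 3], p=[18 / 68, 50 / 68])),
        "ki67_pct": float(np.round(rng.uniform(5, 80), 0)),
        "p53_positive": int(rng.uniform() < 0.5),
        "basal_like": int(rng.uniform() < 0.6),
    }


def generate_survival(
    true_densities: dict[str, float],
    spec: CohortSpec,
    rng: np.random.Generator,
    patient_id: str = "p0",
    standardization: dict[str, tuple[float, float]] | None = None,
    covariates: dict | None = None,
) -> SurvivalRecord:
    """Exponential (or Weibull) proportional-hazards event times.

    The linear predictor is ``sum(log_hr[k] * z_k)`` over the configured
    prognostic parameters, with ``z`` the density standardized by the
    cohort mean/sd in ``standardization`` (raw values are used unchanged
    when no standardization is supplied).  Relapse and death are
    independent exponentials sharing the linear predictor; DFS is the
    first of relapse/death, censoring is independent (administrative
    horizon plus an exponential with rate set from ``censoring_rate``).
    """
    if not all(np.isfinite(v) for v in true_densities.values()):
        raise ValueError("densities must be finite")
    lp = 0.0
    for key, beta in spec.log_hr.items():
        if key not in true_densities:
            continue
        v = true_densities[key]
        if standardization and key in standardization:
            m, s = standardization[key]
            v = (v - m) / s if s > 0 else 0.0
        lp += beta * v

    def draw_time(h0: float) -> float:
        if h0 == 0:
            return np.inf
        rate = h0 * np.exp(lp)
        e = rng.exponential(1.0)
        if spec.survival_model == "weibull":
            return float((e / rate) ** (1.0 / spec.weibull_shape))
        return float(e / rate)

    t_relapse = draw_time(spec.baseline_hazard_dfs)
    t_death = draw_time(spec.baseline_hazard_os)
    if spec.censoring_rate > 0:
        rate_c = spec.baseline_hazard_dfs * spec.censoring_rate / (1 - spec.censoring_rate)
        c = min(spec.admin_horizon_months, float(rng.exponential(1.0 / rate_c)))
    else:
        c = spec.admin_horizon_months
    dfs_time = min(t_relapse, t_death, c)
    dfs_event = min(t_relapse, t_death) <= c
    os_time = min(t_death, c)
    os_event = t_death <= c
    recurrence = t_relapse <= min(t_death, c)
    metastasis = bool(recurrence and rng.uniform() < spec.metastasis_given_recurrence)
    cov = covariates if covariates is not None else _sample_covariates(rng)
    return SurvivalRecord(
        patient_id=patient_id,
        dfs_months=round(dfs_time, 1),
        dfs_event=bool(dfs_event),
        os_months=round(os_time, 1),
        os_event=bool(os_event),
        recurrence=bool(recurrence),
        metastasis=metastasis,
        **cov,
    )


def _true_region_densities(
    patterns: dict[str, MarkerPointPattern], geometry: TumorGeometry, im_width: float
) -> dict[str, float]:
    from .quantify import region_density

    annotation = geometry.annotation(im_width)
    band = build_im_band(annotation, extent=geometry.slide_extent)
    tc = geometry.tc_polygon
    union = tc.union(band)
    out: dict[str, float] = {}
    for marker, pat in patterns.items():
        out[f"TC-{marker}"] = region_density(pat, tc)
        out[f"IM-{marker}"] = region_density(pat, band)
        out[f"TC+IM-{marker}"] = region_density(pat, union)
    return out


def generate_patient(
    spec: CohortSpec, rng: np.random.Generator, patient_id: str = "patient_000"
) -> SyntheticPatient:
    """One patient: geometry, true and misaligned slides, true densities.

    The clinical record is attached at cohort level (survival depends on
    cohort-standardized densities).
    """
    geometry = generate_geometry(spec, rng)
    parents = None
    if spec.shared_parents:
        annotation = geometry.annotation(spec.im_width)
        band = build_im_band(annotation, extent=geometry.slide_extent)
        domain = geometry.tc_polygon.union(band)
        parents = _thomas_parents(domain, spec.parent_rate, spec.offspring_sigma, rng)
    tissue = simulate_point_pattern(
        geometry, "tissue", spec.tissue_intensity, 1.0, spec, rng, parents=parents
    )
    true_slides: dict[str, MarkerPointPattern] = {}
    slides: dict[str, MarkerPointPattern] = {}
    transforms: dict[str, MisalignmentTransform] = {}
    for marker in spec.markers:
        pos = simulate_point_pattern(
            geometry, marker,
            spec.base_intensity.get(marker, 0.0),
            spec.im_enrichment.get(marker, 1.0),
            spec, rng, parents=parents,
        )
        # negative cells: this section's copy of the shared tissue nuclei
        keep = rng.uniform(size=tissue.n) < spec.tissue_keep_prob
        neg = tissue.points[keep] + rng.normal(0, spec.tissue_jitter_um, size=(int(keep.sum()), 2))
        pat = MarkerPointPattern(
            marker,
            np.vstack([pos.points, neg]),
            geometry.slide_extent,
            spec.resolution,
            positive=np.r_[np.ones(pos.n, bool), np.zeros(len(neg), bool)],
        )
        true_slides[marker] = pat
        moved, t = apply_misalignment(pat, spec=spec, rng=rng)
        slides[marker] = moved
        transforms[marker] = t
    true_densities = _true_region_densities(
        {m: p.positive_pattern() for m, p in true_slides.items()}, geometry, spec.im_width
    )
    return SyntheticPatient(
        patient_id=patient_id,
        geometry=geometry,
        slides=slides,
        true_slides=true_slides,
        transforms=transforms,
        true_densities=true_densities,
    )


@dataclass
class Cohort:
    spec: CohortSpec
    patients: list[SyntheticPatient]

    @property
    def clinical(self) -> list[SurvivalRecord]:
        return [p.clinical for p in self.patients]


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Full cohort: spatial data for every patient, then survival linked to
    cohort-standardized true densities."""
    root = np.random.default_rng(spec.seed)
    seeds = root.spawn(spec.n_patients + 1)
    patients = [
        generate_patient(spec, seeds[i], patient_id=f"patient_{i:03d}")
        for i in range(spec.n_patients)
    ]
    std: dict[str, tuple[float, float]] = {}
    for key in spec.log_hr:
        vals = np.array([p.true_densities.get(key, np.nan) for p in patients])
        std[key] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
    surv_rng = seeds[-1]
    for p in patients:
        p.clinical = generate_survival(
            p.true_densities, spec, surv_rng, patient_id=p.patient_id, standardization=std
        )
    return Cohort(spec=spec, patients=patients)
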