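"""Seeded synthetic cohort generator.

Emulates the structure of the study data: one latent uterus-like shape
per image, four manual contours differing by a smooth observer
perturbation, quality ratings 1-3, and one semiautomated ("ags") contour
attempt per observer whose corruption and failure probability depend on
image quality.  Every artifact is reproducible bit-exactly from
(config, master_seed); per-image and per-contour generators are derived
with counter-based seed sequences so any subset can be regenerated in
isolation.

The generative distributions are artifact conventions calibrated to
reported scales (median interobserver MSSD ~3.2 mm, ~19% failure rate,
6/18/11 rating mix), not a model of patient anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import sph_harm_y

from .errors import GenerationError, ValidationError
from .geometry import SurfaceContour, _signed_volume, volume_centroid
from .metrics import mssd
from .primitives import icosphere

__all__ = [
    "UterusShapeParams",
    "ObserverModel",
    "AGSErrorModel",
    "CohortConfig",
    "CohortImage",
    "Cohort",
    "random_shape_params",
    "generate_true_shape",
    "perturb_contour",
    "simulate_ags",
    "build_cohort",
    "calibrate_sigma",
    "DEFAULT_SIGMA_OBS",
]

# Observer radial amplitude (mm) giving a cohort median directed MSSD of
# ~3.2 mm at the default correlation length / edge boost (set from
# calibrate_sigma at the defaults).
DEFAULT_SIGMA_OBS = 1.9

_SHAPE_RANGES = {
    "body_length": (60.0, 100.0),
    "fundal_width": (30.0, 60.0),
    "cervix_length": (20.0, 35.0),
    "cervix_radius": (8.0, 15.0),
    "anteversion_deg": (0.0, 90.0),
}


@dataclass
class UterusShapeParams:
    body_length: float = 80.0
    fundal_width: float = 45.0
    cervix_length: float = 27.0
    cervix_radius: float = 11.0
    anteversion_deg: float = 30.0
    seed: int = 0

    def validate(self):
        for name in ("body_length", "fundal_width", "cervix_length", "cervix_radius"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0.0 <= self.anteversion_deg <= 90.0):
            raise ValidationError("anteversion_deg must be in [0, 90]")
        return self


@dataclass
class ObserverModel:
    """Smooth radial perturbation emulating interobserver variability."""

    sigma_obs: float = DEFAULT_SIGMA_OBS
    correlation_length: float = 25.0
    edge_boost: float = 1.8
    seed: int = 0

    def validate(self):
        if self.sigma_obs < 0:
            raise ValidationError("sigma_obs must be >= 0")
        if self.correlation_length <= 0:
            raise ValidationError("correlation_length must be > 0")
        if self.edge_boost < 1:
            raise ValidationError("edge_boost must be >= 1")
        return self


@dataclass
class AGSErrorModel:
    """Quality-dependent corruption and failure model for the emulated
    semiautomated segmentations.

    Rating-3 failure probability must be 0 (failures only occur on
    degraded images).  ``extrusion_width`` controls how thick the
    shadow-artifact protrusions are.
    """

    failure_prob: dict = field(default_factory=lambda: {1: 0.5, 2: 0.2, 3: 0.0})
    corruption_mm: dict = field(default_factory=lambda: {1: 5.0, 2: 3.5, 3: DEFAULT_SIGMA_OBS})
    extrusion_rate: dict = field(default_factory=lambda: {1: 2.0, 2: 1.0, 3: 0.0})
    extrusion_length: float = 22.0
    extrusion_width: float = 6.0
    correlation_length: float = 25.0
    edge_boost: float = 1.8
    seed: int = 0

    def validate(self):
        for r in (1, 2, 3):
            p = self.failure_prob.get(r)
            if p is None or not (0.0 <= p <= 1.0):
                raise ValidationError(f"failure_prob[{r}] must be in [0,1]")
            if self.corruption_mm.get(r, 0.0) < 0:
                raise ValidationError("corruption amplitudes must be >= 0")
            if self.extrusion_rate.get(r, 0.0) < 0:
                raise ValidationError("extrusion rates must be >= 0")
        if self.failure_prob[3] != 0.0:
            raise ValidationError("rating-3 failure probability must be 0")
        return self


def random_shape_params(rng: np.random.Generator, seed: int = 0) -> UterusShapeParams:
    draws = {k: float(rng.uniform(*v)) for k, v in _SHAPE_RANGES.items()}
    return UterusShapeParams(seed=seed, **draws)


# ---------------------------------------------------------------------------
# true shape


def generate_true_shape(params: UterusShapeParams,
                        subdivisions: int = 3, **labels) -> SurfaceContour:
    """Watertight pear-shaped mesh: a superellipsoid body blended (radial
    union) with a tapered cervical capsule pointing inferior, bent
    anteriorly by ``anteversion_deg``.  Deterministic given params."""
    params.validate()
    base = icosphere(1.0, subdivisions)
    u = base.vertices  # unit directions

    bl, fw = params.body_length, params.fundal_width
    semi = np.array([fw / 2.0, 0.8 * fw / 2.0, 0.55 * bl])
    center = np.array([0.0, 0.0, 0.45 * bl])
    r_body = _superellipsoid_radius(u, center, semi, exponent=2.5)
    r_cervix = _capsule_radius(u, params.cervix_length, params.cervix_radius)
    r = np.maximum(r_body, r_cervix)

    # small smooth asymmetry so distinct seeds give distinct anatomy
    rng = np.random.default_rng(np.random.SeedSequence((int(params.seed), 0x5A)))
    bump = _spherical_harmonic_field(u, rng, max_degree=3, degree_scale=2.0)
    r = r * (1.0 + 0.02 * bump)

    v = r[:, None] * u
    v = _bend_anterior(v, np.deg2rad(params.anteversion_deg))
    mesh = SurfaceContour(v, base.faces, **labels)
    try:
        mesh.validate()
    except Exception as exc:  # pragma: no cover - defensive
        raise GenerationError(f"shape generation failed: {exc}") from exc
    return mesh


def _superellipsoid_radius(u, center, semi, exponent):
    """Radial exit distance from the origin along directions ``u`` for a
    convex superellipsoid |x/a|^e + |y/b|^e + |z/c|^e = 1 (origin must be
    interior).  Solved by bisection; f(t) is convex with f(0) < 0."""
    if np.sum(np.abs(center / semi) ** exponent) >= 1.0:
        raise GenerationError("origin not inside body superellipsoid")

    def f(t):
        p = t[:, None] * u - center
        return np.sum(np.abs(p / semi) ** exponent, axis=1) - 1.0

    hi = np.full(len(u), float(np.sum(np.abs(center)) + semi.max() * 2.0))
    return _bisect_root(f, hi)


def _capsule_radius(u, length, radius):
    """Radial exit distance for a capsule from the origin to
    (0, 0, -length) with the given radius."""
    def f(t):
        p = t[:, None] * u
        s = np.clip(-p[:, 2], 0.0, length)
        q = p - s[:, None] * np.array([0.0, 0.0, -1.0])
        return np.linalg.norm(q, axis=1) - radius

    hi = np.full(len(u), length + radius + 1.0)
    return _bisect_root(f, hi)


def _bisect_root(f, hi, iters=60):
    lo = np.zeros_like(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        neg = f(mid) < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    return 0.5 * (lo + hi)


def _bend_anterior(v, alpha):
    """Circular-arc bend tilting the superior end anteriorly by ``alpha``
    radians.  Cross-sections are carried rigidly along the arc, so the
    enclosed volume is preserved to first order."""
    if alpha < 1e-9:
        return v
    zmin, zmax = v[:, 2].min(), v[:, 2].max()
    span = zmax - zmin
    R = span / alpha
    phi = alpha * (v[:, 2] - zmin) / span
    y, out = v[:, 1], v.copy()
    out[:, 1] = R - (R - y) * np.cos(phi)
    out[:, 2] = zmin + (R - y) * np.sin(phi)
    return out


# ---------------------------------------------------------------------------
# perturbation fields


def _spherical_harmonic_field(u, rng, max_degree=6, degree_scale=4.0):
    """Zero-mean smooth random field on directions ``u``: real spherical
    harmonics to ``max_degree`` with Gaussian degree damping, normalized
    to unit standard deviation over the vertices."""
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    vals = np.zeros(len(u))
    for ell in range(max_degree + 1):
        w = np.exp(-((ell / degree_scale) ** 2))
        for m in range(ell + 1):
            y = sph_harm_y(ell, m, theta, phi)
            if m == 0:
                vals += w * rng.standard_normal() * y.real
            else:
                a, b = rng.standard_normal(2)
                vals += w * np.sqrt(2.0) * (a * y.real + b * y.imag)
    sd = vals.std()
    if sd < 1e-12:
        return np.zeros(len(u))
    return vals / sd


def _vertex_normals(v, f):
    tv = v[f]
    fn = np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0])
    out = np.zeros_like(v)
    for k in range(3):
        np.add.at(out, f[:, k], fn)
    norms = np.linalg.norm(out, axis=1)
    norms[norms < 1e-12] = 1.0
    return out / norms[:, None]


def _edge_weight(v, edge_boost):
    """Weight >= 1 emphasising the lateral (left-right) extremes and the
    base of the cervix, where real observers disagree most."""
    if edge_boost <= 1.0:
        return np.ones(len(v))
    c = v.mean(axis=0)
    d = v - c
    rx = np.abs(d[:, 0]) / (np.abs(d[:, 0]).max() + 1e-12)
    span = float(v[:, 2].max() - v[:, 2].min())
    t = (v[:, 2] - v[:, 2].min()) / (span + 1e-12)
    cervix_base = np.exp(-((t / 0.15) ** 2))
    g = np.clip(rx**2 + cervix_base, 0.0, 1.0)
    return 1.0 + (edge_boost - 1.0) * g


def perturb_contour(mesh: SurfaceContour, model: ObserverModel,
                    rng: np.random.Generator | None = None,
                    **labels) -> SurfaceContour:
    """Displace vertices along outward normals by a smooth correlated
    random field scaled by ``sigma_obs`` and the edge-boost weight.

    Topology is untouched, so the output stays closed; if the displaced
    surface turns inside out the amplitude is damped and retried.
    """
    model.validate()
    if rng is None:
        rng = np.random.default_rng(model.seed)
    meta = {
        "image_id": labels.get("image_id", mesh.image_id),
        "delineator": labels.get("delineator", mesh.delineator),
        "method": labels.get("method", mesh.method),
    }
    if model.sigma_obs == 0:
        out = SurfaceContour(mesh.vertices.copy(), mesh.faces, **meta)
        out._checked = mesh._checked
        return out
    center = volume_centroid(mesh)
    dirs = mesh.vertices - center
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    radius_scale = float(np.linalg.norm(mesh.vertices - center, axis=1).mean())
    degree_scale = max(np.pi * radius_scale / model.correlation_length, 0.5)
    fld = _spherical_harmonic_field(dirs, rng, max_degree=6,
                                    degree_scale=min(degree_scale, 8.0))
    disp = model.sigma_obs * fld * _edge_weight(mesh.vertices, model.edge_boost)
    normals = _vertex_normals(mesh.vertices, mesh.faces)

    ref_vol = _signed_volume(mesh.vertices, mesh.faces)
    amp = 1.0
    for _ in range(3):
        v = mesh.vertices + (amp * disp)[:, None] * normals
        vol = _signed_volume(v, mesh.faces)
        if vol > 0.25 * ref_vol:
            out = SurfaceContour(v, mesh.faces, **meta)
            out._checked = True  # topology/orientation unchanged, volume checked
            return out
        amp *= 0.5
    raise GenerationError("perturbation kept collapsing the surface")


def simulate_ags(mesh: SurfaceContour, rating: int, model: AGSErrorModel,
                 rng: np.random.Generator | None = None,
                 **labels) -> SurfaceContour | None:
    """One semiautomated segmentation attempt.

    Returns ``None`` on failure (Bernoulli with rating-dependent
    probability); otherwise a perturbed contour with rating-dependent
    amplitude plus Poisson-many protrusion artifacts along the normals,
    emulating shadow/speckle-driven errors.
    """
    if rating not in (1, 2, 3):
        raise ValidationError(f"rating must be 1, 2 or 3, got {rating!r}")
    model.validate()
    if rng is None:
        rng = np.random.default_rng(model.seed)
    if rng.random() < model.failure_prob[rating]:
        return None
    obs = ObserverModel(
        sigma_obs=model.corruption_mm[rating],
        correlation_length=model.correlation_length,
        edge_boost=model.edge_boost,
    )
    labels.setdefault("method", "ags")
    out = perturb_contour(mesh, obs, rng=rng, **labels)
    n_ext = int(rng.poisson(model.extrusion_rate.get(rating, 0.0)))
    if n_ext:
        v = out.vertices.copy()
        normals = _vertex_normals(v, out.faces)
        for _ in range(n_ext):
            j = int(rng.integers(len(v)))
            length = model.extrusion_length * (0.7 + 0.6 * rng.random())
            fall = np.exp(-(np.linalg.norm(v - v[j], axis=1)
                            / model.extrusion_width) ** 2)
            v = v + (length * fall)[:, None] * normals[j]
        out = SurfaceContour(v, out.faces, image_id=out.image_id,
                             delineator=out.delineator, method=out.method)
        if _signed_volume(v, out.faces) <= 0:
            raise GenerationError("extrusion inverted the surface")
        out._checked = True
    return out


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class CohortConfig:
    n_observers: int = 4
    rating_counts: dict = field(default_factory=lambda: {1: 6, 2: 18, 3: 11})
    n_excluded: int = 9
    observer: ObserverModel = field(default_factory=ObserverModel)
    ags: AGSErrorModel = field(default_factory=AGSErrorModel)
    mesh_subdivisions: int = 3
    session_disagreement_prob: float = 0.3

    @property
    def n_images(self) -> int:
        return int(sum(self.rating_counts.values()))

    def validate(self):
        if self.n_observers < 1:
            raise ValidationError("need at least one observer")
        if self.n_excluded < 0:
            raise ValidationError("n_excluded must be >= 0")
        if set(self.rating_counts) - {1, 2, 3}:
            raise ValidationError("rating_counts keys must be in {1,2,3}")
        if self.n_images < 1:
            raise ValidationError("need at least one retained image")
        self.observer.validate()
        self.ags.validate()
        return self

    def to_dict(self):
        d = asdict(self)
        d["n_images"] = self.n_images
        return d


@dataclass
class CohortImage:
    image_id: str
    final_rating: int
    session_ratings: tuple
    true_shape: SurfaceContour
    manual: dict  # observer -> SurfaceContour
    ags: dict  # observer -> SurfaceContour | None
    shape_params: UterusShapeParams


@dataclass
class Cohort:
    config: CohortConfig
    master_seed: int
    images: list
    excluded: list  # (image_id, session_ratings)

    @property
    def observers(self):
        return [f"obs{k + 1}" for k in range(self.config.n_observers)]


def _img_rng(master_seed, image_index, role, sub=0):
    return np.random.default_rng(
        np.random.SeedSequence((int(master_seed), int(image_index), int(role), int(sub)))
    )


def _session_pair(rating, rng, disagree_prob):
    """Two session ratings whose round-half-up mean equals ``rating``
    without triggering the zero-exclusion rule."""
    if rating > 1 and rng.random() < disagree_prob:
        pair = [rating, rating - 1]
        rng.shuffle(pair)
        return tuple(int(x) for x in pair)
    return (int(rating), int(rating))


def build_cohort(config: CohortConfig | None = None, master_seed: int = 0) -> Cohort:
    """Generate the full in-memory cohort.

    Default config: 35 retained images (rating mix 6/18/11), 9 excluded
    acquisitions, 4 observers, one manual contour and one ags attempt
    per observer per retained image.
    """
    config = (config or CohortConfig()).validate()
    rng = _img_rng(master_seed, 0xFFFF, 0)
    n_total = config.n_images + config.n_excluded
    ids = [f"img{k + 1:03d}" for k in range(n_total)]
    excluded_idx = set(
        rng.choice(n_total, size=config.n_excluded, replace=False).tolist()
    )
    ratings = [r for r, cnt in sorted(config.rating_counts.items()) for _ in range(cnt)]
    rng.shuffle(ratings)

    images, excluded = [], []
    pos = 0
    for idx, image_id in enumerate(ids):
        rrng = _img_rng(master_seed, idx, 3)
        if idx in excluded_idx:
            other = int(rrng.integers(0, 4))
            pair = [0, other]
            rrng.shuffle(pair)
            excluded.append((image_id, tuple(int(x) for x in pair)))
            continue
        rating = int(ratings[pos])
        pos += 1
        sessions = _session_pair(rating, rrng, config.session_disagreement_prob)

        srng = _img_rng(master_seed, idx, 0)
        params = random_shape_params(srng, seed=master_seed * 100000 + idx)
        true = generate_true_shape(params, subdivisions=config.mesh_subdivisions,
                                   image_id=image_id, delineator="truth",
                                   method="manual")
        manual, ags = {}, {}
        for k in range(config.n_observers):
            obs = f"obs{k + 1}"
            manual[obs] = perturb_contour(
                true, config.observer, rng=_img_rng(master_seed, idx, 1, k),
                image_id=image_id, delineator=obs, method="manual",
            )
            ags[obs] = simulate_ags(
                true, rating, config.ags, rng=_img_rng(master_seed, idx, 2, k),
                image_id=image_id, delineator=obs,
            )
        images.append(
            CohortImage(image_id, rating, sessions, true, manual, ags, params)
        )
    return Cohort(config, int(master_seed), images, excluded)


# ---------------------------------------------------------------------------
# calibration


def calibrate_sigma(
    target_median_mssd: float,
    correlation_length: float = 25.0,
    edge_boost: float = 1.8,
    levels=(0.5, 1.0, 2.0, 3.0, 4.5, 6.5, 9.0),
    n_shapes: int = 4,
    pairs_per_level: int = 4,
    seed: int = 0,
) -> float:
    """Invert the sigma -> median-MSSD response by Monte Carlo.

    Measures the median directed MSSD between independent perturbation
    pairs at each sigma level and interpolates the (monotone) response
    to return the sigma achieving ``target_median_mssd``.
    """
    if target_median_mssd <= 0:
        raise ValidationError("target median MSSD must be > 0")
    rng = np.random.default_rng(seed)
    shapes = [
        generate_true_shape(random_shape_params(rng, seed=seed * 1000 + s))
        for s in range(n_shapes)
    ]
    medians = []
    for sigma in levels:
        model = ObserverModel(sigma_obs=sigma, correlation_length=correlation_length,
                              edge_boost=edge_boost)
        vals = []
        for shape in shapes:
            for _ in range(pairs_per_level):
                a = perturb_contour(shape, model, rng=rng)
                b = perturb_contour(shape, model, rng=rng)
                vals.append(mssd(a, b))
        medians.append(float(np.median(vals)))
    medians = np.maximum.accumulate(medians)  # enforce monotone response
    lo, hi = medians[0], medians[-1]
    target = float(np.clip(target_median_mssd, lo, hi))
    return float(np.interp(target, medians, levels))
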