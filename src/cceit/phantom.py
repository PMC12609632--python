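"""Randomized 2D thorax phantom rasterized to complex-permittivity maps.

A transversal thorax slice is modelled as a combination of elliptic regions —
two lungs, heart, aorta and spine inside an elliptical body outline — each
carrying a complex permittivity ``eps = eps' + j*sigma/omega`` at the 100 MHz
excitation frequency.  Two lung pathologies can be painted as crescent-shaped
sub-regions of the pleural space: pneumothorax (air, low conductivity,
collecting anteriorly in the supine position) and pleural effusion (fluid,
high conductivity, collecting posteriorly).  Scenes of random ellipses are
also supported; they broaden the training distribution of the reconstructor.

Coordinates: field of view [-1, 1] x [-1, 1]; image row 0 is anterior, the x
axis points right; pixel centers sit at half-integer offsets (0-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConductivityMap",
    "EllipseRegion",
    "GridSpec",
    "PermittivityScene",
    "RejectedSample",
    "TISSUES",
    "TissueProperties",
    "VariabilityConfig",
    "assign_pathologies",
    "rasterize",
    "sample_random_ellipses",
    "sample_thorax",
    "template_scene",
    "uniform_scene",
]

EPS0 = 8.8541878128e-12  # F/m
DEFAULT_FREQUENCY = 100e6  # Hz


class RejectedSample(RuntimeError):
    """Raised when organ placement keeps overlapping after the retry budget."""


@dataclass(frozen=True)
class TissueProperties:
    """Electrical properties of one tissue at the excitation frequency."""

    name: str
    eps_rel: float  # relative permittivity, dimensionless, >= 1
    sigma: float  # conductivity, S/m, >= 0
    frequency: float = DEFAULT_FREQUENCY

    @property
    def complex_permittivity(self) -> complex:
        """Relative complex permittivity eps' + j*sigma/(omega*eps0)."""
        omega = 2.0 * np.pi * self.frequency
        return complex(self.eps_rel, self.sigma / (omega * EPS0))


# Dielectric properties at 100 MHz, from the standard tissue-property
# literature (Gabriel parametrization, rounded); editable by the user.
TISSUES: dict[str, TissueProperties] = {
    "background": TissueProperties("background", 66.0, 0.71),
    "lung": TissueProperties("lung", 31.6, 0.38),
    "heart": TissueProperties("heart", 90.8, 0.73),
    "aorta": TissueProperties("aorta", 76.8, 1.23),
    "spine": TissueProperties("spine", 15.3, 0.064),
    "air": TissueProperties("air", 1.0, 0.0),
    "pleural_fluid": TissueProperties("pleural_fluid", 70.0, 1.50),
}


@dataclass(frozen=True)
class _Ellipse:
    """Plain ellipse geometry: center, semi-axes, rotation (radians)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx = np.asarray(x) - self.center[0]
        dy = np.asarray(y) - self.center[1]
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (u / self.semi_axes[0]) ** 2 + (v / self.semi_axes[1]) ** 2 <= 1.0

    def boundary(self, n: int = 256) -> tuple[np.ndarray, np.ndarray]:
        th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        u = self.semi_axes[0] * np.cos(th)
        v = self.semi_axes[1] * np.sin(th)
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.center[0] + c * u - s * v, self.center[1] + s * u + c * v


@dataclass(frozen=True)
class EllipseRegion:
    """A painted elliptic region; an optional hole turns it into a crescent.

    ``z_order`` is the painter's priority: higher values are painted on top.
    A point belongs to the region iff it is inside ``geom`` and outside
    ``hole`` (crescent regions are how pleural pathologies are shaped).
    """

    geom: _Ellipse
    tissue: TissueProperties
    z_order: int
    name: str = ""
    hole: _Ellipse | None = None

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        inside = self.geom.contains(x, y)
        if self.hole is not None:
            inside &= ~self.hole.contains(x, y)
        return inside


@dataclass
class PermittivityScene:
    """Vector-geometry description of one slice, before rasterization."""

    body: _Ellipse
    regions: list[EllipseRegion]
    kind: str = "thorax"  # thorax | ellipses | uniform
    lung_labels: dict[str, str] = field(
        default_factory=lambda: {"left": "healthy", "right": "healthy"}
    )
    background: TissueProperties = TISSUES["background"]

    def to_json(self) -> str:
        def enc(e: _Ellipse | None):
            if e is None:
                return None
            return {"center": list(e.center), "semi_axes": list(e.semi_axes),
                    "rotation": e.rotation}

        return json.dumps({
            "kind": self.kind,
            "lung_labels": self.lung_labels,
            "body": enc(self.body),
            "background": self.background.name,
            "regions": [
                {"name": r.name, "tissue": r.tissue.name, "z_order": r.z_order,
                 "geom": enc(r.geom), "hole": enc(r.hole)}
                for r in self.regions
            ],
        })


@dataclass(frozen=True)
class GridSpec:
    """Image and solver raster resolutions over the [-1, 1]^2 field of view."""

    image_n: int = 64
    solver_n: int = 64
    extent: float = 1.0


@dataclass(frozen=True)
class ConductivityMap:
    """Rasterized conductivity image in S/m.

    Row 0 is anterior; pixels outside the body outline carry 0 S/m (air).
    Inside the body the unpainted background equals the reference tissue's
    conductivity.
    """

    values: np.ndarray  # (n, n) float, S/m
    pixel_size: float  # field-of-view units per pixel
    convention: str = "row0=anterior,x-right,half-integer pixel centers"


# --- template anatomy ---------------------------------------------------------
# Supine CT-derived layout: lungs lateral, heart anterior-left of center,
# aorta anterior-left of the spine, spine posterior.  Units: FOV in [-1, 1].
_TEMPLATE = {
    "body": _Ellipse((0.0, 0.0), (0.92, 0.74)),
    "lung_left": _Ellipse((-0.46, 0.06), (0.26, 0.40), 0.0),
    "lung_right": _Ellipse((0.46, 0.06), (0.26, 0.40), 0.0),
    "heart": _Ellipse((0.06, -0.30), (0.20, 0.16), 0.0),
    "aorta": _Ellipse((-0.10, 0.35), (0.06, 0.06), 0.0),
    "spine": _Ellipse((0.0, 0.55), (0.14, 0.11), 0.0),
}
_ORGAN_TISSUE = {
    "lung_left": "lung",
    "lung_right": "lung",
    "heart": "heart",
    "aorta": "aorta",
    "spine": "spine",
}


@dataclass(frozen=True)
class VariabilityConfig:
    """Per-organ jitter ranges for randomized thorax scenes.

    ``center_jitter`` is a uniform absolute shift (FOV units) applied to each
    coordinate; ``axis_jitter`` a uniform fractional change of each semi-axis;
    ``rotation_jitter`` a uniform rotation in radians.  All ranges are
    symmetric about the template value.
    """

    center_jitter: float = 0.05
    axis_jitter: float = 0.10
    rotation_jitter: float = 0.10
    max_retries: int = 100


def _regions_overlap(a: _Ellipse, b: _Ellipse, n_boundary: int = 256) -> bool:
    """Boundary-sampling overlap test (exact conic intersection is overkill
    at 64x64 resolution): any boundary point of one inside the other, or one
    center nested in the other."""
    ax, ay = a.boundary(n_boundary)
    if np.any(b.contains(ax, ay)):
        return True
    bx, by = b.boundary(n_boundary)
    if np.any(a.contains(bx, by)):
        return True
    return bool(
        b.contains(np.array(a.center[0]), np.array(a.center[1]))
        or a.contains(np.array(b.center[0]), np.array(b.center[1]))
    )


def _inside_body(e: _Ellipse, body: _Ellipse, n_boundary: int = 256) -> bool:
    bx, by = e.boundary(n_boundary)
    return bool(np.all(body.contains(bx, by)))


def template_scene() -> PermittivityScene:
    """The fixed standard-patient scene (zero jitter)."""
    regions = [
        EllipseRegion(_TEMPLATE[name], TISSUES[_ORGAN_TISSUE[name]], z_order=1,
                      name=name)
        for name in _ORGAN_TISSUE
    ]
    return PermittivityScene(body=_TEMPLATE["body"], regions=regions, kind="thorax")


def uniform_scene(tissue: TissueProperties | None = None) -> PermittivityScene:
    """Homogeneous scene used as a normalization reference."""
    t = tissue if tissue is not None else TISSUES["background"]
    return PermittivityScene(body=_TEMPLATE["body"], regions=[], kind="uniform",
                             lung_labels={}, background=t)


def sample_thorax(
    rng: np.random.Generator | int,
    variability: VariabilityConfig | None = None,
) -> PermittivityScene:
    """Draw a randomized thorax scene.

    Organ centers, semi-axes and rotations are jittered uniformly around the
    template; a draw is repeated (up to ``max_retries`` times) while any two
    organs overlap or an organ leaves the body outline, after which
    :class:`RejectedSample` is raised and the caller drops the sample.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cfg = variability if variability is not None else VariabilityConfig()

    for _ in range(cfg.max_retries):
        organs: dict[str, _Ellipse] = {}
        for name, tmpl in _TEMPLATE.items():
            if name == "body":
                continue
            cx = tmpl.center[0] + rng.uniform(-cfg.center_jitter, cfg.center_jitter)
            cy = tmpl.center[1] + rng.uniform(-cfg.center_jitter, cfg.center_jitter)
            rx = tmpl.semi_axes[0] * (1.0 + rng.uniform(-cfg.axis_jitter, cfg.axis_jitter))
            ry = tmpl.semi_axes[1] * (1.0 + rng.uniform(-cfg.axis_jitter, cfg.axis_jitter))
            rot = tmpl.rotation + rng.uniform(-cfg.rotation_jitter, cfg.rotation_jitter)
            organs[name] = _Ellipse((cx, cy), (rx, ry), rot)
        names = list(organs)
        ok = all(_inside_body(organs[n], _TEMPLATE["body"]) for n in names) and not any(
            _regions_overlap(organs[a], organs[b])
            for i, a in enumerate(names)
            for b in names[i + 1:]
        )
        if ok:
            regions = [
                EllipseRegion(organs[n], TISSUES[_ORGAN_TISSUE[n]], z_order=1, name=n)
                for n in names
            ]
            return PermittivityScene(body=_TEMPLATE["body"], regions=regions,
                                     kind="thorax")
    raise RejectedSample("organ overlap persisted after retry budget")


def _pleural_crescent(lung: _Ellipse, side: str) -> _Ellipse:
    """Hole ellipse whose complement within the lung forms the crescent.

    ``side='anterior'`` leaves an anterior crescent (pneumothorax), shifting
    the hole posteriorly; ``side='posterior'`` the opposite (effusion).
    Anterior is -y (image row 0).
    """
    shift = 0.30 * lung.semi_axes[1]
    dy = shift if side == "anterior" else -shift
    c, s = np.cos(lung.rotation), np.sin(lung.rotation)
    # shift along the lung's own minor/major frame y axis
    center = (lung.center[0] - s * dy, lung.center[1] + c * dy)
    axes = (0.88 * lung.semi_axes[0], 0.88 * lung.semi_axes[1])
    return _Ellipse(center, axes, lung.rotation)


def assign_pathologies(
    scene: PermittivityScene, rng: np.random.Generator | int
) -> PermittivityScene:
    """Independently draw pneumothorax and effusion for each lung (p = 1/2
    each), so the four states healthy / pneumothorax / effusion /
    hydropneumothorax are equiprobable at 25%.  Pathology regions are
    crescents clipped to the lung ellipse, painted above the lung."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    regions = list(scene.regions)
    labels = {}
    for side_name, organ in (("left", "lung_left"), ("right", "lung_right")):
        lung = next(r for r in regions if r.name == organ)
        pneumo = bool(rng.random() < 0.5)
        effusion = bool(rng.random() < 0.5)
        if pneumo:
            regions.append(EllipseRegion(
                geom=lung.geom, tissue=TISSUES["air"], z_order=2,
                name=f"pneumothorax_{side_name}",
                hole=_pleural_crescent(lung.geom, "anterior")))
        if effusion:
            regions.append(EllipseRegion(
                geom=lung.geom, tissue=TISSUES["pleural_fluid"], z_order=3,
                name=f"effusion_{side_name}",
                hole=_pleural_crescent(lung.geom, "posterior")))
        labels[side_name] = {
            (False, False): "healthy",
            (True, False): "pneumothorax",
            (False, True): "effusion",
            (True, True): "hydropneumothorax",
        }[(pneumo, effusion)]
    out = replace(scene)
    out.regions = regions
    out.lung_labels = labels
    return out


@dataclass(frozen=True)
class EllipseSceneConfig:
    """Ranges for random-ellipse scenes (uniform draws)."""

    count_range: tuple[int, int] = (1, 6)
    axis_range: tuple[float, float] = (0.08, 0.35)
    sigma_range: tuple[float, float] = (0.0, 1.5)
    eps_range: tuple[float, float] = (5.0, 90.0)


def sample_random_ellipses(
    rng: np.random.Generator | int,
    config: EllipseSceneConfig | None = None,
) -> PermittivityScene:
    """Random-ellipse scene; overlaps allowed, later ellipses paint on top."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cfg = config if config is not None else EllipseSceneConfig()
    body = _TEMPLATE["body"]
    k = int(rng.integers(cfg.count_range[0], cfg.count_range[1] + 1))
    regions = []
    for i in range(k):
        while True:  # centers uniform inside the body outline
            cx = rng.uniform(-body.semi_axes[0], body.semi_axes[0])
            cy = rng.uniform(-body.semi_axes[1], body.semi_axes[1])
            if body.contains(np.array(cx), np.array(cy)):
                break
        geom = _Ellipse(
            (float(cx), float(cy)),
            (rng.uniform(*cfg.axis_range), rng.uniform(*cfg.axis_range)),
            rng.uniform(0.0, np.pi),
        )
        tissue = TissueProperties(
            f"random_{i}", eps_rel=rng.uniform(*cfg.eps_range),
            sigma=rng.uniform(*cfg.sigma_range))
        regions.append(EllipseRegion(geom, tissue, z_order=i + 1, name=f"ellipse_{i}"))
    return PermittivityScene(body=body, regions=regions, kind="ellipses",
                             lung_labels={})


def _paint(scene: PermittivityScene, n: int, extent: float, attr: str) -> np.ndarray:
    """Rasterize one attribute (sigma / complex permittivity) at n x n."""
    coords = -extent + (np.arange(n) + 0.5) * (2.0 * extent / n)
    x, y = np.meshgrid(coords, coords)  # y varies along rows (row 0 anterior)
    inside = scene.body.contains(x, y)
    if attr == "sigma":
        out = np.zeros((n, n))
        out[inside] = scene.background.sigma
    else:
        out = np.full((n, n), TISSUES["air"].complex_permittivity, dtype=complex)
        out[inside] = scene.background.complex_permittivity
    for r in sorted(scene.regions, key=lambda r: r.z_order):
        mask = r.contains(x, y) & inside
        out[mask] = r.tissue.sigma if attr == "sigma" else r.tissue.complex_permittivity
    return out


def rasterize(
    scene: PermittivityScene, grid: GridSpec | None = None
) -> tuple[ConductivityMap, np.ndarray]:
    """Rasterize a scene to the 64x64 conductivity image and the solver-grid
    complex-permittivity field (pixel-center sampling, no anti-aliasing).

    Returns ``(ConductivityMap, eps_solver)`` where ``eps_solver`` is the
    ``solver_n x solver_n`` complex relative permittivity array.
    """
    g = grid if grid is not None else GridSpec()
    sigma = _paint(scene, g.image_n, g.extent, "sigma")
    eps = _paint(scene, g.solver_n, g.extent, "eps")
    return ConductivityMap(values=sigma, pixel_size=2.0 * g.extent / g.image_n), eps
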