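"""Elastic-band electrode displacement model.

A wearable EIT belt stretches when strapped onto the chest, shifting its 32
electrodes relative to each other; on top of the stretch the whole belt may be
rotated (global shift) and each electrode pad may sit slightly off its nominal
spot (local jitter).  The stretch is modelled by a monotone mapping
``f: [0, 1] -> [0, 1]`` of normalized arc-length position along the band,
built from a two-term sine curve rotated by pi/4 so that the endpoints are
fixed and, within a derived parameter box, the mapping is guaranteed to be
strictly increasing (electrodes never swap places).

The mapping is defined parametrically by

    x3(t) = t - S2(t),    y3(t) = t + S2(t),
    S2(t) = a1*(sin(pi t + b1) + (2t - 1) sin(b1)) + a2*(sin(2 pi t + b2) - sin(b2)),

and ``f(x)`` is obtained by solving ``x3(t) = x`` for ``t``.  The curve is a
one-to-one mapping iff ``|S2'(t)| < 1`` on [0, 1]; a conservative sufficient
box on the amplitudes is ``|a1| <= 1/(2(pi+1))``, ``|a2| <= 1/(4(pi+1))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "A1_MAX",
    "A2_MAX",
    "BandStretchParams",
    "DisplacementLevel",
    "ElectrodeLayout",
    "LEVELS",
    "LayoutError",
    "check_admissible",
    "sample_layout",
    "stretch_S",
    "stretch_S_deriv",
    "stretch_map",
    "truncated_normal",
]

#: Amplitude box guaranteeing a monotone mapping: |a1| <= A1_MAX, |a2| <= A2_MAX.
A1_MAX = 1.0 / (2.0 * (np.pi + 1.0))
A2_MAX = 1.0 / (4.0 * (np.pi + 1.0))


class LayoutError(RuntimeError):
    """Raised when no non-overlapping electrode layout could be drawn."""


@dataclass(frozen=True)
class BandStretchParams:
    """Four parameters of the band-stretch mapping family.

    ``a1``, ``a2`` are dimensionless amplitudes; ``b1``, ``b2`` phases in
    radians (only their value modulo 2*pi matters).
    """

    a1: float
    b1: float
    a2: float
    b2: float

    @property
    def is_identity(self) -> bool:
        return self.a1 == 0.0 and self.a2 == 0.0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a1, self.b1, self.a2, self.b2)


IDENTITY_STRETCH = BandStretchParams(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class DisplacementLevel:
    """Electrode disarrangement level.

    ``local_sd`` and ``global_sd`` are standard deviations of the truncated
    normal shift draws, in percent of the inter-electrode angle (2*pi/32).
    ``none`` also disables the band stretch.
    """

    name: str
    local_sd: float
    global_sd: float


LEVELS: dict[str, DisplacementLevel] = {
    "none": DisplacementLevel("none", 0.0, 0.0),
    "small": DisplacementLevel("small", 2.5, 7.5),
    "medium": DisplacementLevel("medium", 5.0, 12.5),
    "large": DisplacementLevel("large", 10.0, 50.0),
}


@dataclass(frozen=True)
class ElectrodeLayout:
    """Angular electrode positions on the sensor boundary after displacement."""

    n_electrodes: int
    centers: np.ndarray  # radians, strictly increasing modulo 2*pi
    arc_halfwidth: float  # radians
    normalized_positions: np.ndarray  # arc-length fraction in [0, 1], pre-shift

    def to_json_dict(self) -> dict:
        return {
            "n_electrodes": int(self.n_electrodes),
            "centers": [float(c) for c in self.centers],
            "arc_halfwidth": float(self.arc_halfwidth),
            "normalized_positions": [float(p) for p in self.normalized_positions],
        }


def equidistant_layout(n_electrodes: int = 32, coverage: float = 0.5) -> ElectrodeLayout:
    """Rigid-belt layout: electrode ``i`` at angle ``i * 2*pi/n``."""
    pitch = 2.0 * np.pi / n_electrodes
    return ElectrodeLayout(
        n_electrodes=n_electrodes,
        centers=np.arange(n_electrodes) * pitch,
        arc_halfwidth=coverage * pitch / 2.0,
        normalized_positions=np.arange(n_electrodes) / (n_electrodes - 1),
    )


def stretch_S(t, p: BandStretchParams):
    """The two-term stretch displacement S2(t); vanishes at t = 0 and t = 1."""
    t = np.asarray(t, dtype=float)
    return p.a1 * (np.sin(np.pi * t + p.b1) + (2.0 * t - 1.0) * np.sin(p.b1)) + p.a2 * (
        np.sin(2.0 * np.pi * t + p.b2) - np.sin(p.b2)
    )


def stretch_S_deriv(t, p: BandStretchParams):
    """dS2/dt, used for the monotonicity (one-to-one mapping) test."""
    t = np.asarray(t, dtype=float)
    return (
        p.a1 * np.pi * np.cos(np.pi * t + p.b1)
        + 2.0 * p.a1 * np.sin(p.b1)
        + 2.0 * np.pi * p.a2 * np.cos(2.0 * np.pi * t + p.b2)
    )


def check_admissible(
    p: BandStretchParams, mode: str = "derivative", n_grid: int = 20001
) -> tuple[bool, float]:
    """Test whether the stretch mapping is one-to-one.

    ``mode='box'`` applies the conservative amplitude box (sufficient, not
    necessary); ``mode='derivative'`` scans ``|S2'(t)|`` on a dense grid and
    requires the maximum to stay below 1 (the operative condition).  Returns
    ``(admissible, max_abs_derivative)`` where for box mode the reported value
    is the triangle-inequality bound ``|a1|(2+pi) + 2*pi*|a2|``.
    """
    if mode == "box":
        bound = abs(p.a1) * (2.0 + np.pi) + 2.0 * np.pi * abs(p.a2)
        ok = abs(p.a1) <= A1_MAX and abs(p.a2) <= A2_MAX
        return ok, float(bound)
    if mode == "derivative":
        t = np.linspace(0.0, 1.0, n_grid)
        m = float(np.max(np.abs(stretch_S_deriv(t, p))))
        return m < 1.0, m
    raise ValueError(f"unknown admissibility mode: {mode!r}")


def stretch_map(x, p: BandStretchParams, tol: float = 1e-12):
    """Evaluate the stretch mapping f(x) for x in [0, 1].

    Solves ``x3(t) = t - S2(t) = x`` by bisection (x3 is strictly increasing
    whenever ``|S2'| < 1``) and returns ``y3(t) = t + S2(t)``.  Accepts scalars
    or arrays.  Raises :class:`ValueError` for a non-admissible ``p`` —
    a band whose electrodes would overlap or swap is not physical.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1.0 + 1e-12):
        raise ValueError("stretch_map input must lie in [0, 1]")
    if p.is_identity:
        return x.copy() if x.ndim else float(x)
    ok, _ = check_admissible(p, mode="derivative")
    if not ok:
        raise ValueError("stretch parameters fail the |S2'| < 1 monotonicity test")
    xa = np.atleast_1d(x)
    lo = np.zeros_like(xa)
    hi = np.ones_like(xa)
    # ~50 halvings reach 1e-15 interval width; stop early once below tol.
    for _ in range(100):
        t = 0.5 * (lo + hi)
        x3 = t - stretch_S(t, p)
        below = x3 < xa
        lo = np.where(below, t, lo)
        hi = np.where(below, hi, t)
        if np.max(hi - lo) <= tol:
            break
    t = 0.5 * (lo + hi)
    y = t + stretch_S(t, p)
    y = np.clip(y, 0.0, 1.0)
    # endpoints are exact fixed points of the family
    y[xa <= 0.0] = 0.0
    y[xa >= 1.0] = 1.0
    return y if x.ndim else float(y[0])


def truncated_normal(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    """Draw N(0, sd) truncated to |x| <= sd, by rejection.

    The truncation point equals the standard deviation, so roughly 68% of
    proposals are accepted.  ``sd = 0`` returns zeros.
    """
    if sd == 0.0:
        return np.zeros(size)
    out = rng.normal(0.0, sd, size=size)
    bad = np.abs(out) > sd
    while np.any(bad):
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > sd
    return out


def sample_stretch_params(rng: np.random.Generator) -> BandStretchParams:
    """Uniform draw of (a1, a2) in the admissible box and phases in [0, 2*pi]."""
    return BandStretchParams(
        a1=rng.uniform(-A1_MAX, A1_MAX),
        b1=rng.uniform(0.0, 2.0 * np.pi),
        a2=rng.uniform(-A2_MAX, A2_MAX),
        b2=rng.uniform(0.0, 2.0 * np.pi),
    )


def _arcs_overlap(centers: np.ndarray, halfwidth: float) -> bool:
    c = np.sort(np.mod(centers, 2.0 * np.pi))
    gaps = np.diff(np.concatenate([c, [c[0] + 2.0 * np.pi]]))
    return bool(np.min(gaps) <= 2.0 * halfwidth)


def sample_layout(
    level: DisplacementLevel | str,
    rng: np.random.Generator | int,
    n_electrodes: int = 32,
    coverage: float = 0.5,
    max_local_retries: int = 100,
    max_stretch_retries: int = 100,
):
    """Draw one displaced electrode layout at the given disarrangement level.

    The three displacement sources compose additively in angle, in the order
    stretch -> global rotation -> local jitter.  Electrode ``i`` sits at
    normalized band position ``i/(n-1)``; the stretch maps that to ``f(i/(n-1))``
    over the band's angular span ``(n-1) * 2*pi/n`` (the closure gap between the
    last and first electrode is not stretched).  Global and local shifts are
    truncated-normal draws expressed in percent of the inter-electrode pitch.

    Local shifts are re-drawn (up to ``max_local_retries``) when electrode arcs
    overlap; if the stretch itself packs electrodes too densely for any jitter
    draw to fit, the stretch and global draws are re-drawn as well, up to
    ``max_stretch_retries``, after which :class:`LayoutError` is raised.

    Returns ``(layout, params, shifts)`` where ``shifts`` is a dict with the
    global shift and the 32 local shifts in percent units.
    """
    if isinstance(level, str):
        level = LEVELS[level]
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = n_electrodes
    pitch = 2.0 * np.pi / n
    halfwidth = coverage * pitch / 2.0
    if not 0.0 < coverage < 1.0:
        raise ValueError("electrode coverage must lie in (0, 1)")

    if level.name == "none":
        layout = equidistant_layout(n, coverage)
        shifts = {"global": 0.0, "local": np.zeros(n)}
        return layout, IDENTITY_STRETCH, shifts

    span = (n - 1) * pitch
    rigid = np.arange(n) / (n - 1)
    for _ in range(max_stretch_retries):
        params = sample_stretch_params(rng)
        pos = stretch_map(rigid, params)
        g = float(truncated_normal(rng, level.global_sd, 1)[0])
        base = span * pos + (g / 100.0) * pitch
        for _ in range(max_local_retries):
            local = truncated_normal(rng, level.local_sd, n)
            centers = base + (local / 100.0) * pitch
            if not _arcs_overlap(centers, halfwidth):
                layout = ElectrodeLayout(
                    n_electrodes=n,
                    centers=np.mod(centers, 2.0 * np.pi),
                    arc_halfwidth=halfwidth,
                    normalized_positions=pos,
                )
                return layout, params, {"global": g, "local": local}
    raise LayoutError(
        f"no overlap-free layout at level={level.name!r} after "
        f"{max_stretch_retries}x{max_local_retries} retries "
        "(arc coverage too large for this shift level)"
    )
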