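"""Finite-volume forward model for a screened 32-electrode capacitance sensor.

During a measurement, one electrode is driven at voltage U while every other
electrode and the screen are grounded; the potential obeys the generalized
Laplace equation ``div(eps grad phi) = 0``.  The equation is discretized on a
cell-centered Cartesian grid restricted to the body outline, with harmonic-mean
face permittivities (flux-conserving for discontinuous coefficients) and
Dirichlet values on the ring of outline-adjacent cells.

With all 32 excitation fields solved at a reference permittivity, the
reciprocity principle gives the sensitivity (Jacobian) of each mutual
capacitance to the permittivity of each image pixel,

    dC_AB / d eps_n = -(1/U^2) * sum_{cells in pixel n} grad(phi_A).grad(phi_B) * area,

and capacitance vectors follow from the linearization ``C = S @ eps``
(the reference capacitances are exactly ``S @ eps_ref``).  The measurement
vector holds all M = 32*31 = 992 ordered (excitation, sensing) pairs,
excitation-major; the (A,B) and (B,A) entries are equal by reciprocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .band import ElectrodeLayout, equidistant_layout
from .phantom import _Ellipse, _TEMPLATE

__all__ = [
    "MeasurementOrdering",
    "SensorMesh",
    "SensorMeshConfig",
    "build_sensor_mesh",
    "compute_sensitivity",
    "landweber_baseline",
    "simulate_capacitance",
    "solve_all_potentials",
    "solve_potential",
]

N_ELECTRODES = 32
M_MEASUREMENTS = N_ELECTRODES * (N_ELECTRODES - 1)  # 992


class MeasurementOrdering:
    """Excitation-major ordering of the 992 (A, B) pairs, self-pairs excluded."""

    def __init__(self, n_electrodes: int = N_ELECTRODES):
        self.n_electrodes = n_electrodes
        self.pairs = [(a, b) for a in range(n_electrodes)
                      for b in range(n_electrodes) if b != a]
        self.index = {p: i for i, p in enumerate(self.pairs)}

    def __len__(self) -> int:
        return len(self.pairs)

    def swapped(self) -> np.ndarray:
        """Index permutation mapping entry (A,B) to entry (B,A)."""
        return np.array([self.index[(b, a)] for a, b in self.pairs])

    def opposite_channels(self) -> np.ndarray:
        """Indices of diametrically opposite pairs (B = A + n/2 mod n)."""
        half = self.n_electrodes // 2
        return np.array([i for i, (a, b) in enumerate(self.pairs)
                         if (b - a) % self.n_electrodes == half])


ORDERING = MeasurementOrdering()


@dataclass(frozen=True)
class SensorMeshConfig:
    """Solver-grid geometry.  The body outline doubles as the sensor boundary:
    the band sits on the skin, so electrodes and screen are Dirichlet cells on
    the outline's inner ring."""

    solver_n: int = 64
    image_n: int = 64
    extent: float = 1.0
    outline: _Ellipse = field(default_factory=lambda: _TEMPLATE["body"])


@dataclass
class SensorMesh:
    """Classified solver grid: interior unknowns, per-electrode Dirichlet cells,
    screen cells, and the cell -> image-pixel aggregation map."""

    config: SensorMeshConfig
    inside: np.ndarray  # (n, n) bool, solved domain
    dirichlet: np.ndarray  # (n, n) bool, outline-adjacent ring
    electrode_of: np.ndarray  # (n, n) int, electrode id or -1 (screen/none)
    h: float  # cell size, FOV units

    @property
    def n(self) -> int:
        return self.config.solver_n

    @property
    def n_electrodes(self) -> int:
        return int(self.electrode_of.max()) + 1

    def electrode_cells(self, k: int) -> np.ndarray:
        return (self.electrode_of == k) & self.dirichlet

    def pixel_block(self) -> int:
        f, r = divmod(self.config.solver_n, self.config.image_n)
        if r != 0:
            raise ValueError("solver_n must be a multiple of image_n")
        return f


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return np.mod(a + np.pi, 2.0 * np.pi) - np.pi


def build_sensor_mesh(
    layout: ElectrodeLayout | None = None,
    config: SensorMeshConfig | None = None,
) -> SensorMesh:
    """Build the solver mesh for an electrode layout.

    Boundary (Dirichlet) cells are inside cells with at least one 4-neighbour
    outside the outline; a boundary cell belongs to electrode ``k`` when its
    polar angle lies within the electrode's arc, otherwise it is screen.
    Raises if any electrode maps to zero cells (grid too coarse) or the arcs
    are degenerate.
    """
    cfg = config if config is not None else SensorMeshConfig()
    lay = layout if layout is not None else equidistant_layout()
    if lay.arc_halfwidth <= 0.0:
        raise ValueError("electrode arc halfwidth must be positive")
    n = cfg.solver_n
    h = 2.0 * cfg.extent / n
    coords = -cfg.extent + (np.arange(n) + 0.5) * h
    x, y = np.meshgrid(coords, coords)
    inside = cfg.outline.contains(x, y)

    pad = np.pad(inside, 1, constant_values=False)
    has_out = (~pad[:-2, 1:-1] | ~pad[2:, 1:-1] | ~pad[1:-1, :-2] | ~pad[1:-1, 2:])
    dirichlet = inside & has_out

    ang = np.mod(np.arctan2(y, x), 2.0 * np.pi)
    electrode_of = np.full((n, n), -1, dtype=int)
    for k, c in enumerate(lay.centers):
        arc = np.abs(_wrap_angle(ang - c)) <= lay.arc_halfwidth
        hit = arc & dirichlet
        if electrode_of[hit].max(initial=-1) >= 0:
            raise ValueError("electrode arcs overlap on the mesh")
        electrode_of[hit] = k
        if not hit.any():
            raise ValueError(
                f"electrode {k} maps to zero boundary cells at {n}x{n}")
    return SensorMesh(config=cfg, inside=inside, dirichlet=dirichlet,
                      electrode_of=electrode_of, h=h)


def _assemble(inside: np.ndarray, dirichlet: np.ndarray, eps: np.ndarray):
    """Assemble the interior FVM system with eliminated Dirichlet cells.

    Returns (lu_factorization, unknown index map, neighbour lists) so that
    right-hand sides for many excitations reuse one factorization.
    """
    n = inside.shape[0]
    unknown = inside & ~dirichlet
    idx = -np.ones((n, n), dtype=int)
    idx[unknown] = np.arange(int(unknown.sum()))
    nu = int(unknown.sum())
    if nu == 0:
        raise ValueError("mesh has no interior unknowns")

    rows, cols, vals = [], [], []
    diag = np.zeros(nu, dtype=eps.dtype)
    # (row index of unknown, column index of Dirichlet neighbour, face weight)
    bc_terms: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    ui, uj = np.nonzero(unknown)
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ni, nj = ui + di, uj + dj
        ok = (ni >= 0) & (ni < n) & (nj >= 0) & (nj < n)
        ok[ok] &= inside[ni[ok], nj[ok]]
        a, b = eps[ui[ok], uj[ok]], eps[ni[ok], nj[ok]]
        w = 2.0 * a * b / (a + b)  # harmonic-mean face permittivity
        rsel = idx[ui[ok], uj[ok]]
        np.add.at(diag, rsel, -w)
        nb_unknown = unknown[ni[ok], nj[ok]]
        rows.append(rsel[nb_unknown])
        cols.append(idx[ni[ok], nj[ok]][nb_unknown])
        vals.append(w[nb_unknown])
        bc = ~nb_unknown
        bc_terms.append((rsel[bc], np.ravel_multi_index(
            (ni[ok][bc], nj[ok][bc]), (n, n)), w[bc]))
    rows.append(np.arange(nu))
    cols.append(np.arange(nu))
    vals.append(diag)
    A = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nu, nu))
    return splu(A), idx, bc_terms


def _solve_dirichlet(
    inside: np.ndarray,
    dirichlet: np.ndarray,
    dirichlet_values: np.ndarray,
    eps: np.ndarray,
) -> np.ndarray:
    """Solve div(eps grad phi) = 0 with the given Dirichlet data.

    ``dirichlet_values`` is an (n, n) array read on the Dirichlet cells.
    Exposed for geometries beyond the sensor (e.g. annulus verification).
    """
    lu, idx, bc_terms = _assemble(inside, dirichlet, eps)
    phi = _solve_with(lu, idx, bc_terms, inside, dirichlet, dirichlet_values)
    return phi


def _solve_with(lu, idx, bc_terms, inside, dirichlet, dirichlet_values):
    nu = int((inside & ~dirichlet).sum())
    dtype = np.result_type(dirichlet_values.dtype, np.float64)
    rhs = np.zeros(nu, dtype=dtype)
    flat_vals = dirichlet_values.ravel()
    for rsel, flat_nb, w in bc_terms:
        np.add.at(rhs, rsel, -w * flat_vals[flat_nb])
    sol = lu.solve(rhs.astype(lu.U.dtype, copy=False))
    phi = np.zeros(inside.shape, dtype=sol.dtype)
    phi[dirichlet] = dirichlet_values[dirichlet]
    phi[inside & ~dirichlet] = sol
    return phi


def solve_potential(
    mesh: SensorMesh, eps: np.ndarray, excitation: int, U: float = 1.0
) -> np.ndarray:
    """Potential field for one excitation electrode (U on its cells, 0 on the
    other electrodes and the screen).  ``eps`` is the (n, n) permittivity."""
    vals = np.zeros(mesh.inside.shape, dtype=np.asarray(eps).dtype)
    vals[mesh.electrode_cells(excitation)] = U
    return _solve_dirichlet(mesh.inside, mesh.dirichlet, vals, np.asarray(eps))


def solve_all_potentials(
    mesh: SensorMesh, eps: np.ndarray, U: float = 1.0
) -> np.ndarray:
    """All 32 excitation fields with one factorization; shape (32, n, n)."""
    eps = np.asarray(eps)
    lu, idx, bc_terms = _assemble(mesh.inside, mesh.dirichlet, eps)
    out = []
    for k in range(mesh.n_electrodes):
        vals = np.zeros(mesh.inside.shape, dtype=eps.dtype)
        vals[mesh.electrode_cells(k)] = U
        out.append(_solve_with(lu, idx, bc_terms, mesh.inside, mesh.dirichlet, vals))
    return np.stack(out)


def _masked_gradient(phi: np.ndarray, inside: np.ndarray, h: float):
    """Central differences where both neighbours lie inside, one-sided at the
    domain edge, zero where no inside neighbour exists along the axis."""
    grads = []
    for axis in (1, 0):  # d/dx (columns), d/dy (rows)
        fwd = np.roll(phi, -1, axis=axis)
        bwd = np.roll(phi, 1, axis=axis)
        m_f = np.roll(inside, -1, axis=axis) & inside
        m_b = np.roll(inside, 1, axis=axis) & inside
        # roll wraps around; edge rows/cols are outside for any sane outline
        g = np.zeros_like(phi)
        both = m_f & m_b
        g[both] = (fwd[both] - bwd[both]) / (2.0 * h)
        fo = m_f & ~m_b
        g[fo] = (fwd[fo] - phi[fo]) / h
        bo = m_b & ~m_f
        g[bo] = (phi[bo] - bwd[bo]) / h
        grads.append(g)
    gx, gy = grads
    return gx, gy


def compute_sensitivity(
    mesh: SensorMesh, fields: np.ndarray, U: float = 1.0,
    ordering: MeasurementOrdering = ORDERING,
) -> np.ndarray:
    """Sensitivity matrix S of shape (992, image_n^2) from the 32 solved
    fields, by the reciprocity principle; rows for (A,B) and (B,A) are equal
    by construction."""
    n = mesh.n
    f = mesh.pixel_block()
    img_n = mesh.config.image_n
    G = np.empty((fields.shape[0], 2, n, n), dtype=fields.dtype)
    for k in range(fields.shape[0]):
        gx, gy = _masked_gradient(fields[k], mesh.inside, mesh.h)
        G[k, 0], G[k, 1] = gx, gy
    G[:, :, ~mesh.inside] = 0.0
    Gf = G.reshape(fields.shape[0], 2, n * n)
    # all pairwise grad-dot-grad maps: (32, 32, cells)
    dots = np.einsum("aci,bci->abi", Gf, Gf)
    cellmaps = -(mesh.h ** 2 / U ** 2) * dots
    # aggregate solver cells into image pixels (f x f blocks)
    cm = cellmaps.reshape(fields.shape[0], fields.shape[0], img_n, f, img_n, f)
    pix = cm.sum(axis=(3, 5)).reshape(fields.shape[0], fields.shape[0], img_n * img_n)
    rows = [pix[a, b] for a, b in ordering.pairs]
    return np.stack(rows)


def capacitance_from_fields(
    mesh: SensorMesh, fields: np.ndarray, eps: np.ndarray,
    U: float = 1.0, ordering: MeasurementOrdering | None = None,
) -> np.ndarray:
    """Direct mutual capacitances from solved fields via the discrete energy
    form C_AB = -(1/U^2) sum_faces w_f(eps) dphi_A dphi_B, with the same
    harmonic-mean face weights the solver assembles.  Evaluated at the eps the
    fields were solved with, this is the nonlinear forward operator; its
    finite differences are the reference Jacobian for ``compute_sensitivity``.
    """
    if ordering is None:
        ordering = (ORDERING if fields.shape[0] == N_ELECTRODES
                    else MeasurementOrdering(fields.shape[0]))
    n = mesh.n
    ne = fields.shape[0]
    C = np.zeros(len(ordering.pairs), dtype=np.result_type(eps.dtype, fields.dtype))
    for axis in (0, 1):
        sl1 = (slice(0, n - 1), slice(None)) if axis == 0 else (slice(None), slice(0, n - 1))
        sl2 = (slice(1, n), slice(None)) if axis == 0 else (slice(None), slice(1, n))
        m = mesh.inside[sl1] & mesh.inside[sl2]
        a, b = eps[sl1][m], eps[sl2][m]
        w = 2.0 * a * b / (a + b)
        d = [fields[k][sl2][m] - fields[k][sl1][m] for k in range(ne)]
        for i, (A, B) in enumerate(ordering.pairs):
            C[i] += -(w * d[A] * d[B]).sum() / U ** 2
    return C


def sensitivity_for_layout(
    layout: ElectrodeLayout, config: SensorMeshConfig | None = None, U: float = 1.0
) -> np.ndarray:
    """Mesh + 32 uniform-reference solves + reciprocity, in one call.

    The reference is the uniform background: the field equation is homogeneous
    in eps, so a uniform reference admits a real-valued solve whose fields do
    not depend on the reference's value.
    """
    mesh = build_sensor_mesh(layout, config)
    eps = np.ones(mesh.inside.shape)
    fields = solve_all_potentials(mesh, eps, U=U)
    ordering = (ORDERING if layout.n_electrodes == N_ELECTRODES
                else MeasurementOrdering(layout.n_electrodes))
    return compute_sensitivity(mesh, fields, U=U, ordering=ordering)


def simulate_capacitance(
    S: np.ndarray, eps_pixels: np.ndarray,
    eps_ref: np.ndarray | complex | None = None,
    C_ref: np.ndarray | None = None,
) -> np.ndarray:
    """Linearized measurement vector ``C = S (eps - eps_ref) + C_ref``.

    With the default ``C_ref = S @ eps_ref`` this reduces to the plain linear
    model ``C = S @ eps``; both forms are exposed because a measured reference
    vector may replace the simulated one.
    """
    eps_pixels = np.asarray(eps_pixels).ravel()
    if eps_pixels.size != S.shape[1]:
        raise ValueError(
            f"permittivity vector length {eps_pixels.size} != {S.shape[1]}")
    if eps_ref is None:
        return S @ eps_pixels
    eps_ref = (np.full(S.shape[1], eps_ref)
               if np.isscalar(eps_ref) else np.asarray(eps_ref).ravel())
    if C_ref is None:
        C_ref = S @ eps_ref
    return S @ (eps_pixels - eps_ref) + C_ref


def landweber_baseline(
    C: np.ndarray, S: np.ndarray, iterations: int = 200,
    step: float | None = None, nonneg: bool = True,
) -> np.ndarray:
    """Iterative linear reconstruction x <- x + step * S^T (C - S x).

    A deterministic sanity-check baseline for the forward stack, not an
    imaging method of record.  ``step`` defaults to 1/||S||_2^2, inside the convergence bound;
    the residual must decrease monotonically or the iteration aborts.
    """
    S = np.real(S)
    C = np.real(np.asarray(C, dtype=float).ravel())
    if step is None:
        smax = np.linalg.norm(S, 2)
        step = 1.0 / (smax * smax)
    x = np.zeros(S.shape[1])
    prev = np.inf
    for it in range(iterations):
        r = C - S @ x
        rn = float(np.linalg.norm(r))
        if rn > prev * (1.0 + 1e-9):
            raise RuntimeError(f"Landweber diverged at iteration {it}")
        prev = rn
        x = x + step * (S.T @ r)
        if nonneg:
            np.maximum(x, 0.0, out=x)
    side = int(round(np.sqrt(S.shape[1])))
    return x.reshape(side, side)
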