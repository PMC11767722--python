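"""Image-based creeping-flow solver and wall-shear-stress operator.

The lumen geometry is taken directly from the binary mask: each lumen pixel is
a fluid cell of a marker-and-cell (MAC) staggered finite-difference grid, with
velocity components on cell faces and pressure at cell centers.  Rectangular
inlet/outlet port channels are attached flush to the two image borders along
the flow axis, widened to span the lumen's border footprint, so that a
developed parabolic profile enters the imaged chamber.

The solved equations are steady incompressible Stokes flow,

    mu * laplacian(u) = grad(p),   div(u) = 0,

with no-slip walls (enforced half a cell off the face by ghost reflection), a
prescribed parabolic inlet profile of given mean velocity, and a zero-traction
outlet.  At the velocities and length scales of a perfused microvascular
culture (U ~ 1e-4 m/s, L ~ 1e-4 m) the Reynolds number is ~1e-2, so neglecting
inertia changes nothing measurable; the linearity of Stokes flow is also what
makes the downstream dimensionless weights independent of the (unrecorded)
absolute inlet velocity.

Wall shear stress is the viscous tangential stress mu * |du_t/dn| evaluated at
each wall pixel by a one-sided difference along the inward wall normal, the
normal being the gradient of the Euclidean distance map.

Everything is assembled sparsely and solved with a direct factorization; a 2D
chamber of a few tens of thousands of lumen pixels solves in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.ndimage import map_coordinates
from scipy.sparse.linalg import spsolve

from .masks import LumenMask

__all__ = [
    "FlowConfig",
    "FlowDomain",
    "FlowField",
    "WallShearMap",
    "CrossSection",
    "NoPerfusionError",
    "build_domain",
    "solve_flow",
    "compute_wss",
    "edge_flux",
    "make_cross_section",
]


class NoPerfusionError(RuntimeError):
    """The lumen touches neither border along the flow axis: flow undefined."""


@dataclass
class FlowConfig:
    """Physical configuration of the perfusion.

    mu
        Dynamic viscosity, Pa s (culture medium ~ water).
    U_inlet
        Mean inlet velocity, m/s (typical capillary-scale perfusion).
    w_inlet
        Inlet width in metres used to normalize flow rates; when ``None`` the
        actual attached port width is used.
    d_ch
        Chamber extent along the flow direction (distance between the pillar
        rows bounding the chamber), metres.
    flow_axis
        ``"rows"``: perfusion from the top border to the bottom border;
        ``"cols"``: left to right.
    port_length_px
        Length of the attached inlet/outlet port channels in pixels.
    """

    mu: float = 1.0e-3
    U_inlet: float = 1.0e-4
    w_inlet: float | None = None
    d_ch: float = 2.0e-3
    flow_axis: Literal["rows", "cols"] = "rows"
    port_length_px: int = 20

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.U_inlet <= 0 or self.d_ch <= 0:
            raise ValueError("mu, U_inlet and d_ch must be positive")
        if self.w_inlet is not None and self.w_inlet <= 0:
            raise ValueError("w_inlet must be positive when given")
        if self.flow_axis not in ("rows", "cols"):
            raise ValueError("flow_axis must be 'rows' or 'cols'")


@dataclass
class FlowDomain:
    """Lumen geometry plus attached ports, in solver (canonical) orientation.

    The canonical orientation has the flow along axis 0, inlet at row 0.  When
    ``config.flow_axis == "cols"`` the mask is transposed internally and all
    exported fields are transposed back.
    """

    mask: LumenMask
    config: FlowConfig
    fluid: np.ndarray            # padded canonical bool grid (ports included)
    flow_fluid: np.ndarray       # subset of `fluid` on inlet-outlet components
    pad: int                     # port length (rows of padding top and bottom)
    transposed: bool
    inlet_cols: tuple[int, int]  # inclusive column span of the inlet port
    outlet_cols: tuple[int, int]
    no_flow: np.ndarray          # mask-frame bool grid of no-flow lumen pixels
    perfused: bool               # an inlet-outlet connected component exists

    @property
    def h(self) -> float:
        """Grid spacing in metres (= pixel size)."""
        return self.mask.pixel_size_m

    @property
    def port_width_m(self) -> float:
        j0, j1 = self.inlet_cols
        return (j1 - j0 + 1) * self.h

    @property
    def inlet_width_m(self) -> float:
        """Width used to normalize flow-rate ratios."""
        return self.config.w_inlet if self.config.w_inlet is not None else self.port_width_m

    def flow_lumen_mask(self) -> np.ndarray:
        """Mask-frame bool grid of flow-bearing lumen pixels."""
        return self.mask.pixels & ~self.no_flow

    def border_segments(self) -> tuple[int, int]:
        """Number of contiguous lumen runs on the inlet and outlet borders
        (the openings the attached ports feed/drain)."""
        m = _canon(self.mask.pixels, self.transposed)

        def runs(row: np.ndarray) -> int:
            padded = np.concatenate([[False], row, [False]])
            return int(np.count_nonzero(padded[1:] & ~padded[:-1]))

        return runs(m[0]), runs(m[-1])


@dataclass
class FlowField:
    """Steady velocity/pressure solution sampled at mask pixel centers."""

    vel_r: np.ndarray      # velocity along rows (axis 0) at pixel centers, m/s
    vel_c: np.ndarray      # velocity along cols (axis 1), m/s
    pressure: np.ndarray   # Pa, mask frame
    domain: FlowDomain
    config: FlowConfig
    inlet_flux: float      # m^2/s per unit depth
    outlet_flux: float
    max_div: float         # worst discrete divergence residual, 1/s
    zero_flow: bool = False

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vel_r, self.vel_c)


@dataclass
class WallShearMap:
    """Wall shear stress magnitude per wall pixel of the lumen mask."""

    wall_pixels: np.ndarray  # (N, 2) int row/col
    tau: np.ndarray          # (N,) Pa, >= 0
    normals: np.ndarray      # (N, 2) unit inward normals
    degenerate: np.ndarray   # (N,) bool, normal undefined -> tau forced to 0

    def label_index(self, shape: tuple[int, int]) -> np.ndarray:
        """Dense map pixel -> wall index (-1 off the wall)."""
        out = np.full(shape, -1, dtype=int)
        out[self.wall_pixels[:, 0], self.wall_pixels[:, 1]] = np.arange(len(self.tau))
        return out


@dataclass(frozen=True)
class CrossSection:
    """Straight sample segment spanning the local lumen width.

    points
        (N, 2) float pixel coordinates at ``step`` px spacing.
    tangent
        Unit vessel-axis direction the flux is measured along.
    step
        Sample spacing in pixels.
    """

    points: np.ndarray
    tangent: np.ndarray
    step: float


# ---------------------------------------------------------------------------
# Domain construction
# ---------------------------------------------------------------------------

def _canon(a: np.ndarray, transposed: bool) -> np.ndarray:
    return a.T if transposed else a


def build_domain(
    mask: LumenMask,
    config: FlowConfig,
    port_length_px: int | None = None,
) -> FlowDomain:
    """Attach inlet/outlet ports to the mask and partition the boundary.

    The inlet (outlet) port is a rectangle spanning the footprint of lumen
    pixels on the upstream (downstream) image border, extended
    ``port_length_px`` pixels outwards.  Lumen pixels with no face-connected
    path from inlet to outlet are flagged no-flow and excluded from the solve.

    Raises :class:`NoPerfusionError` if the lumen touches neither border.
    """
    transposed = config.flow_axis == "cols"
    m = _canon(mask.pixels, transposed)
    R, C = m.shape
    L = config.port_length_px if port_length_px is None else port_length_px
    if L < 1:
        raise ValueError("port_length_px must be >= 1")

    top = np.nonzero(m[0])[0]
    bot = np.nonzero(m[-1])[0]
    if top.size == 0 and bot.size == 0:
        raise NoPerfusionError(
            "no perfusion path: lumen touches neither border along the flow axis"
        )

    fluid = np.zeros((R + 2 * L, C), dtype=bool)
    fluid[L : L + R] = m
    inlet_cols = (int(top.min()), int(top.max())) if top.size else (0, -1)
    outlet_cols = (int(bot.min()), int(bot.max())) if bot.size else (0, -1)
    if top.size:
        fluid[:L, inlet_cols[0] : inlet_cols[1] + 1] = True
    if bot.size:
        fluid[L + R :, outlet_cols[0] : outlet_cols[1] + 1] = True

    # Face-connected (4-connectivity) components: flow passes only through
    # shared faces on a MAC grid, so diagonal-only links carry no flux.
    lab, _ = ndi.label(fluid, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    inlet_labels = set(np.unique(lab[0])) - {0}
    outlet_labels = set(np.unique(lab[-1])) - {0}
    keep = inlet_labels & outlet_labels
    perfused = bool(keep) and top.size > 0 and bot.size > 0
    flow_fluid = np.isin(lab, sorted(keep)) if perfused else np.zeros_like(fluid)

    no_flow_canon = m & ~flow_fluid[L : L + R]
    return FlowDomain(
        mask=mask,
        config=config,
        fluid=fluid,
        flow_fluid=flow_fluid,
        pad=L,
        transposed=transposed,
        inlet_cols=inlet_cols,
        outlet_cols=outlet_cols,
        no_flow=_canon(no_flow_canon, transposed).copy(),
        perfused=perfused,
    )


# ---------------------------------------------------------------------------
# Stokes solve
# ---------------------------------------------------------------------------

def _zero_field(domain: FlowDomain, config: FlowConfig) -> FlowField:
    shape = domain.mask.shape
    z = np.zeros(shape)
    return FlowField(
        vel_r=z,
        vel_c=z.copy(),
        pressure=z.copy(),
        domain=domain,
        config=config,
        inlet_flux=0.0,
        outlet_flux=0.0,
        max_div=0.0,
        zero_flow=True,
    )


def solve_flow(domain: FlowDomain, config: FlowConfig | None = None) -> FlowField:
    """Solve steady Stokes flow on the domain.

    Boundary conditions: parabolic inlet profile with prescribed mean
    ``U_inlet`` (discretely rescaled so the inlet flux is exactly
    ``U_inlet * port_width``), zero traction at the outlet, no-slip walls.
    Returns a zero field flagged ``zero_flow`` when the domain has no
    inlet-outlet path.
    """
    config = config or domain.config
    if not domain.perfused:
        return _zero_field(domain, config)

    fluid = domain.flow_fluid
    R, C = fluid.shape
    h = domain.h
    mu, U = config.mu, config.U_inlet
    j0, j1 = domain.inlet_cols
    wp = j1 - j0 + 1

    # v faces (axis-0 velocity), shape (R+1, C)
    above = np.zeros((R + 1, C), dtype=bool)
    above[1:] = fluid
    below = np.zeros((R + 1, C), dtype=bool)
    below[:-1] = fluid
    v_unknown = above & below
    v_unknown[R] |= fluid[R - 1]          # traction-free outlet faces
    v_exists = above | below
    v_dir = v_exists & ~v_unknown          # inlet + wall faces (Dirichlet)
    vval = np.zeros((R + 1, C))
    # Parabolic inlet profile, rescaled so the discrete flux is exact.
    xi = (np.arange(j0, j1 + 1) - j0 + 0.5) / wp
    prof = xi * (1.0 - xi)
    prof *= U * wp / prof.sum()
    vval[0, j0 : j1 + 1] = prof

    # u faces (axis-1 velocity), shape (R, C+1)
    left = np.zeros((R, C + 1), dtype=bool)
    left[:, 1:] = fluid
    right = np.zeros((R, C + 1), dtype=bool)
    right[:, :-1] = fluid
    u_unknown = left & right
    u_exists = left | right

    Nv = int(v_unknown.sum())
    Nu = int(u_unknown.sum())
    Np = int(fluid.sum())
    vid = np.full(v_unknown.shape, -1, dtype=np.int64)
    vid[v_unknown] = np.arange(Nv)
    uid = np.full(u_unknown.shape, -1, dtype=np.int64)
    uid[u_unknown] = Nv + np.arange(Nu)
    pid = np.full(fluid.shape, -1, dtype=np.int64)
    pid[fluid] = Nv + Nu + np.arange(Np)
    N = Nv + Nu + Np

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    rhs = np.zeros(N)

    def add(r: np.ndarray, c: np.ndarray, v: np.ndarray) -> None:
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        vals.append(np.asarray(v, dtype=float))

    def momentum(
        ii: np.ndarray,
        jj: np.ndarray,
        rr: np.ndarray,
        unknown: np.ndarray,
        exists: np.ndarray,
        idarr: np.ndarray,
        valarr: np.ndarray | None,
        axial_axis: int,
        shape: tuple[int, int],
    ) -> np.ndarray:
        """Laplacian stencil for one velocity component; returns diag."""
        diag = np.zeros(len(rr))
        H, W = shape
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ni, nj = ii + di, jj + dj
            inb = (ni >= 0) & (ni < H) & (nj >= 0) & (nj < W)
            axial = (di != 0) if axial_axis == 0 else (dj != 0)
            nis = np.clip(ni, 0, H - 1)
            njs = np.clip(nj, 0, W - 1)
            is_unknown = inb & unknown[nis, njs]
            is_dir = inb & exists[nis, njs] & ~unknown[nis, njs]
            is_ghost = ~inb | (inb & ~exists[nis, njs])
            # ghost reflection: wall half a cell away => v_nb = -v_f, except
            # past the outlet plane (zero normal gradient => v_nb = +v_f).
            downstream = (ni >= H) if axial_axis == 0 else False
            if axial_axis == 1 and di == 1:
                downstream = ni >= H
            ghost_minus = is_ghost & ~np.asarray(downstream)
            diag[is_unknown] -= 1.0
            diag[is_dir] -= 1.0
            diag[ghost_minus] -= 2.0
            # downstream ghost (+v) contributes net zero
            if is_unknown.any():
                add(rr[is_unknown], idarr[nis[is_unknown], njs[is_unknown]], np.ones(is_unknown.sum()))
            if valarr is not None and is_dir.any():
                np.subtract.at(rhs, rr[is_dir], valarr[nis[is_dir], njs[is_dir]])
        return diag

    # -- v momentum ---------------------------------------------------------
    vii, vjj = np.nonzero(v_unknown)
    vr = vid[vii, vjj]
    diag = momentum(vii, vjj, vr, v_unknown, v_exists, vid, vval, axial_axis=0, shape=(R + 1, C))
    add(vr, vr, diag)
    # pressure gradient: -(p'_below - p'_above)
    add(vr, pid[vii - 1, vjj], np.ones(Nv))
    interior = vii < R
    add(vr[interior], pid[vii[interior], vjj[interior]], -np.ones(int(interior.sum())))

    # -- u momentum ---------------------------------------------------------
    uii, ujj = np.nonzero(u_unknown)
    ur = uid[uii, ujj]
    diag = momentum(uii, ujj, ur, u_unknown, u_exists, uid, None, axial_axis=1, shape=(R, C + 1))
    add(ur, ur, diag)
    add(ur, pid[uii, ujj - 1], np.ones(Nu))
    add(ur, pid[uii, ujj], -np.ones(Nu))

    # -- continuity ---------------------------------------------------------
    ci, cj = np.nonzero(fluid)
    pr = pid[ci, cj]
    for fi, fj, sign, which in (
        (ci, cj, -1.0, "v"),
        (ci + 1, cj, 1.0, "v"),
        (ci, cj, -1.0, "u"),
        (ci, cj + 1, 1.0, "u"),
    ):
        if which == "v":
            unk = v_unknown[fi, fj]
            add(pr[unk], vid[fi[unk], fj[unk]], np.full(int(unk.sum()), sign))
            dirm = v_dir[fi, fj]
            if dirm.any():
                np.subtract.at(rhs, pr[dirm], sign * vval[fi[dirm], fj[dirm]])
        else:
            unk = u_unknown[fi, fj]
            add(pr[unk], uid[fi[unk], fj[unk]], np.full(int(unk.sum()), sign))
    # tiny pressure penalty for a safely non-singular factorization
    add(pr, pr, np.full(Np, -1e-12))

    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    ).tocsc()
    x = spsolve(A, rhs)

    vfull = np.array(vval)
    vfull[v_unknown] = x[:Nv]
    ufull = np.zeros((R, C + 1))
    ufull[u_unknown] = x[Nv : Nv + Nu]
    pfull = np.zeros((R, C))
    pfull[fluid] = x[Nv + Nu :] * mu / h  # undo the p' = p*h/mu scaling

    div = (vfull[1:] - vfull[:-1] + ufull[:, 1:] - ufull[:, :-1]) / h
    max_div = float(np.abs(div[fluid]).max()) if fluid.any() else 0.0

    v_cc = 0.5 * (vfull[:-1] + vfull[1:])
    u_cc = 0.5 * (ufull[:, :-1] + ufull[:, 1:])
    v_cc[~fluid] = 0.0
    u_cc[~fluid] = 0.0

    L = domain.pad
    Rm = domain.mask.shape[0] if not domain.transposed else domain.mask.shape[1]
    v_crop = v_cc[L : L + Rm]
    u_crop = u_cc[L : L + Rm]
    p_crop = pfull[L : L + Rm]

    inlet_flux = float(prof.sum() * h)
    outlet_flux = float(vfull[R].sum() * h)

    if domain.transposed:
        vel_r, vel_c = u_crop.T, v_crop.T
        p_crop = p_crop.T
    else:
        vel_r, vel_c = v_crop, u_crop

    return FlowField(
        vel_r=vel_r,
        vel_c=vel_c,
        pressure=p_crop,
        domain=domain,
        config=config,
        inlet_flux=inlet_flux,
        outlet_flux=outlet_flux,
        max_div=max_div,
    )


# ---------------------------------------------------------------------------
# Wall shear stress
# ---------------------------------------------------------------------------

def compute_wss(
    field: FlowField,
    domain: FlowDomain | None = None,
    config: FlowConfig | None = None,
) -> WallShearMap:
    """Wall shear stress at every wall pixel of the lumen mask.

    A wall pixel is a lumen pixel with a 4-connected background neighbor
    inside the image (image borders are open vessel ends, not walls).  The
    inward normal is the normalized gradient of the distance map; the
    tangential velocity at the pixel center, half a cell from the no-slip
    face, gives tau = mu * |u_t| / (h/2).  Isolated pixels with an undefined
    normal get tau = 0 and a degeneracy flag.
    """
    domain = domain or field.domain
    config = config or field.config
    m = domain.mask.pixels
    h = domain.h
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    interior = ndi.binary_erosion(m, structure=cross, border_value=1)
    wall = m & ~interior
    wi, wj = np.nonzero(wall)

    dmap = ndi.distance_transform_edt(m)
    gr, gc = np.gradient(dmap)
    nr, nc = gr[wi, wj], gc[wi, wj]
    norm = np.hypot(nr, nc)
    degenerate = norm < 1e-9
    norm[degenerate] = 1.0
    nr, nc = nr / norm, nc / norm

    vr = field.vel_r[wi, wj]
    vc = field.vel_c[wi, wj]
    vn = vr * nr + vc * nc
    tr, tc = vr - vn * nr, vc - vn * nc
    tau = config.mu * np.hypot(tr, tc) / (0.5 * h)
    tau[degenerate] = 0.0

    return WallShearMap(
        wall_pixels=np.column_stack([wi, wj]).astype(int),
        tau=tau,
        normals=np.column_stack([nr, nc]),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Edge flux
# ---------------------------------------------------------------------------

def make_cross_section(
    mask: LumenMask | np.ndarray,
    center_rc: tuple[float, float],
    tangent: tuple[float, float],
    step: float = 0.25,
    max_half_px: float | None = None,
) -> CrossSection:
    """Build a straight sample segment through ``center_rc`` spanning the lumen.

    The segment runs along the normal of the unit ``tangent`` (the skeleton
    direction), sampled every ``step`` pixels, trimmed to the lumen and, when
    ``max_half_px`` is given, to that half-length — callers pass the local
    half-width so a section near a junction does not run on into the joining
    vessel.
    """
    m = mask.pixels if isinstance(mask, LumenMask) else np.asarray(mask, dtype=bool)
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    n = np.array([-t[1], t[0]])
    c = np.asarray(center_rc, dtype=float)

    def inside(p: np.ndarray) -> bool:
        r, q = int(round(p[0])), int(round(p[1]))
        return 0 <= r < m.shape[0] and 0 <= q < m.shape[1] and bool(m[r, q])

    if not inside(c):
        raise ValueError("cross-section center is outside the lumen")
    pts = [c]
    for sgn in (1.0, -1.0):
        k = 1
        while max_half_px is None or k * step <= max_half_px:
            p = c + sgn * k * step * n
            if not inside(p):
                break
            pts.append(p)
            k += 1
    pts_arr = np.array(pts)
    order = np.argsort(pts_arr @ n)
    return CrossSection(points=pts_arr[order], tangent=t, step=step)


def edge_flux(field: FlowField, cross_section: CrossSection) -> float:
    """Signed flow rate through a cross-section, m^2/s per unit depth.

    Integrates the velocity component along the section tangent (the vessel
    axis) over the section by the rectangle rule at the sample spacing.
    Positive sign means flow along ``tangent``.
    """
    pts = cross_section.points
    t = cross_section.tangent
    h = field.domain.h
    vr = map_coordinates(field.vel_r, pts.T, order=1, mode="constant")
    vc = map_coordinates(field.vel_c, pts.T, order=1, mode="constant")
    along = vr * t[0] + vc * t[1]
    return float(along.sum() * cross_section.step * h)
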