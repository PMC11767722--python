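"""Synthetic lumen geometries and five-stage remodeling time-lapses.

Real inputs to this pipeline are microscope-derived binary masks of a
spontaneously formed microvascular network in a 2 mm (flow direction) x 3 mm
culture chamber.  This module replaces them with two kinds of synthetic data:

* **Toy geometries** with closed-form flow (straight channel, Y-branch,
  channel lattice, and a "bridge lattice" of two high-flow parallel channels
  joined by one perpendicular low-flow bridge — the canonical configuration of
  a preferentially pruned segment).
* **Stochastic time-lapses** that emulate the five morphological stages of
  long-term perfusion culture: an isotropic *meshwork* of random segments
  (area rising), directional *sprouting* along the flow axis (area rising,
  anisotropy rising), flow-coupled *remodeling* in which each frame removes
  the lowest-flow near-perpendicular segments found by actually solving the
  flow on the current mask (area falling), a *stable* stage with only +/-1 px
  wall jitter, and *erosion* by dilation growing in from the two port borders
  (area rising again).

The generator draws every stochastic choice from a single seeded RNG in a
fixed order, so a config (including its seed) fixes the mask sequence
bit-exactly.  Geometry is cartoon-level on purpose: segment widths are
log-normal around a 40 µm capillary scale, and no attempt is made to render
brightfield appearance or cell-scale behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as _line
from skimage.morphology import disk

from .flow import FlowConfig
from .masks import LumenMask, Stage, STAGE_ORDER

__all__ = [
    "ToyGeometrySpec",
    "TimelapseConfig",
    "TimelapseDataset",
    "PruningResult",
    "generate_toy_geometry",
    "generate_timelapse",
    "apply_pruning_event",
    "write_timelapse",
]


# ---------------------------------------------------------------------------
# Toy geometries
# ---------------------------------------------------------------------------

@dataclass
class ToyGeometrySpec:
    """Parametric toy lumen geometry.

    All toys are drawn with the flow running along image columns (left border
    = inlet) and must be solved with ``FlowConfig(flow_axis="cols")``.

    kind
        ``straight_channel`` | ``y_branch`` | ``lattice`` | ``bridge_lattice``.
    width_um
        Channel width per segment; must be at least 4 pixels to be resolvable.
    n_channels
        (horizontal, vertical) channel counts for ``lattice``.
    bridge_width_um
        Width of the perpendicular bridge of ``bridge_lattice`` (defaults to
        half the main-channel width).
    """

    kind: Literal["straight_channel", "y_branch", "lattice", "bridge_lattice"]
    width_um: float = 100.0
    image_shape_px: tuple[int, int] = (128, 256)
    pixel_size_um: float = 1.5625
    n_channels: tuple[int, int] = (3, 3)
    bridge_width_um: float | None = None

    @property
    def width_px(self) -> int:
        return int(round(self.width_um / self.pixel_size_um))

    def validate(self) -> None:
        if self.width_um < 4 * self.pixel_size_um:
            raise ValueError(
                f"width {self.width_um} um is below the 4-pixel resolvability "
                f"limit ({4 * self.pixel_size_um} um at {self.pixel_size_um} um/px)"
            )
        if min(self.image_shape_px) < self.width_px:
            raise ValueError("image too small for the requested channel width")


def _hband(m: np.ndarray, r_center: int, w: int, c0: int = 0, c1: int | None = None) -> None:
    r0 = r_center - w // 2
    m[max(0, r0) : r0 + w, c0 : m.shape[1] if c1 is None else c1] = True


def _vband(m: np.ndarray, c_center: int, w: int, r0: int = 0, r1: int | None = None) -> None:
    c0 = c_center - w // 2
    m[r0 : m.shape[0] if r1 is None else r1, max(0, c0) : c0 + w] = True


def _thick_line(m: np.ndarray, p0: tuple[int, int], p1: tuple[int, int], w: int) -> None:
    rr, cc = _line(p0[0], p0[1], p1[0], p1[1])
    stroke = np.zeros_like(m)
    ok = (rr >= 0) & (rr < m.shape[0]) & (cc >= 0) & (cc < m.shape[1])
    stroke[rr[ok], cc[ok]] = True
    if w > 1:
        stroke = ndi.binary_dilation(stroke, structure=disk(max(1, w // 2)))
    m |= stroke


def generate_toy_geometry(spec: ToyGeometrySpec) -> LumenMask:
    """Rasterize a toy geometry as a :class:`LumenMask`."""
    spec.validate()
    R, C = spec.image_shape_px
    w = spec.width_px
    m = np.zeros((R, C), dtype=bool)

    if spec.kind == "straight_channel":
        _hband(m, R // 2, w)
    elif spec.kind == "y_branch":
        xs = C // 3
        mid = R // 2
        dy = R // 4
        half = np.zeros_like(m)
        _hband(half, mid, w, 0, xs + w)
        _thick_line(half, (mid, xs), (mid - dy, C - 1), w)
        # extend the daughter to actually touch the outlet border
        half[:, -1] |= half[:, -2]
        m = half | half[::-1]
    elif spec.kind == "lattice":
        nh, nv = spec.n_channels
        rows = np.linspace(R * 0.2, R * 0.8, nh).astype(int)
        cols = np.linspace(C * 0.2, C * 0.8, nv).astype(int)
        for r in rows:
            _hband(m, int(r), w)
        for c in cols:
            _vband(m, int(c), w, int(rows.min()), int(rows.max()))
    elif spec.kind == "bridge_lattice":
        r1, r2 = R // 3, (2 * R) // 3
        _hband(m, r1, w)
        _hband(m, r2, w)
        bw = (
            int(round(spec.bridge_width_um / spec.pixel_size_um))
            if spec.bridge_width_um is not None
            else max(4, w // 2)
        )
        _vband(m, C // 2, bw, r1, r2)
    else:
        raise ValueError(f"unknown toy kind {spec.kind!r}")

    return LumenMask(m, spec.pixel_size_um)


# ---------------------------------------------------------------------------
# Time-lapse generator
# ---------------------------------------------------------------------------

def _default_durations() -> dict[Stage, int]:
    return {s: 4 for s in STAGE_ORDER}


@dataclass
class TimelapseConfig:
    """Study conditions of a synthetic remodeling time-lapse.

    The chamber defaults to the 2 mm (flow direction, image rows) x 3 mm
    (transverse, columns) culture geometry at 1.5625 µm/px (the full-chamber
    raster); tests and scaled-down runs pass a coarser ``pixel_size_um``.
    """

    stage_durations: dict[Stage, int] = field(default_factory=_default_durations)
    chamber_um: tuple[float, float] = (2000.0, 3000.0)
    pixel_size_um: float = 1.5625
    seed: int = 0
    initial_segment_count: int = 25
    free_segment_fraction: float = 0.4
    sprout_anisotropy: float = 0.8
    prune_fraction_per_frame: float = 0.1
    prune_rq_max: float = 0.1
    jitter_fraction: float = 0.05
    angle_max_deg: float = 45.0
    segment_width_um: float = 40.0
    min_object_px: int = 30
    flow: FlowConfig = field(default_factory=FlowConfig)
    days_per_frame: float = 1.0

    def __post_init__(self) -> None:
        for s, n in self.stage_durations.items():
            if n < 1:
                raise ValueError(f"stage {s} duration must be >= 1")
        if min(self.chamber_um) <= 0 or self.pixel_size_um <= 0:
            raise ValueError("chamber dimensions and pixel size must be positive")
        if not 0.0 <= self.sprout_anisotropy <= 1.0:
            raise ValueError("sprout_anisotropy must be in [0, 1]")
        if not 0.0 <= self.prune_fraction_per_frame <= 1.0:
            raise ValueError("prune_fraction_per_frame must be in [0, 1]")

    @property
    def image_shape_px(self) -> tuple[int, int]:
        return (
            int(round(self.chamber_um[0] / self.pixel_size_um)),
            int(round(self.chamber_um[1] / self.pixel_size_um)),
        )

    @property
    def n_frames(self) -> int:
        return sum(self.stage_durations.values())


@dataclass
class TimelapseDataset:
    """Ordered masks, ground-truth stage labels and provenance of one run."""

    masks: list[LumenMask]
    stage_labels: list[Stage]
    provenance: TimelapseConfig
    areas_px: list[int]


@dataclass
class PruningResult:
    """Outcome of one pruning event."""

    mask: LumenMask
    pruned_eids: list[int]
    warning: bool  # True when no prunable edge existed


def _sample_width_px(rng: np.random.Generator, cfg: TimelapseConfig) -> int:
    w_um = float(np.exp(rng.normal(np.log(cfg.segment_width_um), 0.35)))
    w_um = min(max(w_um, 4 * cfg.pixel_size_um), 2 * cfg.segment_width_um)
    return max(4, int(round(w_um / cfg.pixel_size_um)))


def _add_random_segment(
    m: np.ndarray, rng: np.random.Generator, cfg: TimelapseConfig,
    angle_mean: float | None, angle_spread: float,
    anchor_on_lumen: bool,
    length_range: tuple[float, float] = (150.0, 450.0),
) -> None:
    R, C = m.shape
    length = rng.uniform(*length_range) / cfg.pixel_size_um
    if angle_mean is None:
        theta = rng.uniform(0, np.pi)
    else:
        theta = angle_mean + rng.normal(0.0, angle_spread)
    if anchor_on_lumen and m.any():
        pts = np.argwhere(m)
        p0 = pts[rng.integers(len(pts))]
    else:
        p0 = np.array(
            [rng.uniform(0.1 * R, 0.9 * R), rng.uniform(0.1 * C, 0.9 * C)]
        ).astype(int)
    d = np.array([np.cos(theta), np.sin(theta)])
    sgn = 1 if rng.random() < 0.5 else -1
    p1 = (p0 + sgn * length * d).astype(int)
    p1 = np.clip(p1, [0, 0], [R - 1, C - 1])
    _thick_line(m, tuple(p0), tuple(p1), _sample_width_px(rng, cfg))


def _tidy(m: np.ndarray, min_object_px: int) -> np.ndarray:
    from .masks import remove_small_components

    return remove_small_components(m, min_object_px)


def generate_timelapse(config: TimelapseConfig) -> TimelapseDataset:
    """Run the five-stage generative model; deterministic given the seed.

    The remodeling stage is closed-loop: every remodeling frame analyzes the
    current mask with the full pipeline (flow solve + graph weighting) and
    erases the ``prune_fraction_per_frame`` of flow-bearing edges with the
    lowest flow-rate ratio among near-perpendicular, non-port-touching edges.
    Raises if remodeling is requested on a mask with no inlet-outlet path.
    """
    from .pipeline import analyze_frame  # lazy: pipeline imports this module

    rng = np.random.default_rng(config.seed)
    R, C = config.image_shape_px
    m = np.zeros((R, C), dtype=bool)
    flow = replace(config.flow, flow_axis="rows")

    masks: list[LumenMask] = []
    labels: list[Stage] = []
    areas: list[int] = []
    frame = 0

    def emit(stage: Stage) -> None:
        nonlocal frame
        mask = LumenMask(
            m.copy(),
            config.pixel_size_um,
            time_point=frame * config.days_per_frame,
            frame_id=frame,
        )
        masks.append(mask)
        labels.append(stage)
        areas.append(int(m.sum()))
        frame += 1

    # -- meshwork: isotropic random segment mesh, area rising ---------------
    # Most segments anchor on the existing lumen so vasculogenesis grows one
    # connected mesh; a fraction stay free-floating, the satellite cords that
    # never join the perfused network and will regress once flow matters.
    n_mesh = config.stage_durations.get(Stage.MESHWORK, 0)
    for i in range(n_mesh):
        count = config.initial_segment_count if i == 0 else max(
            3, config.initial_segment_count // 4
        )
        for j in range(count):
            anchored = not (i == 0 and j == 0) and (
                rng.random() >= config.free_segment_fraction
            )
            _add_random_segment(m, rng, config, None, 0.0, anchor_on_lumen=anchored)
        m = _tidy(m, config.min_object_px)
        emit(Stage.MESHWORK)

    # -- sprouting: directional growth along the flow axis ------------------
    n_sprout = config.stage_durations.get(Stage.SPROUTING, 0)
    spread = (1.0 - config.sprout_anisotropy) * (np.pi / 4) + 0.05
    for i in range(n_sprout):
        if i == 0:
            # main feedthrough channels spanning inlet to outlet, placed
            # inside the meshwork's column footprint so they perfuse it
            cols_occ = np.nonzero(m.any(axis=0))[0]
            lo = cols_occ.min() if len(cols_occ) else 0
            hi = cols_occ.max() if len(cols_occ) else C - 1
            lo, hi = max(lo, int(0.05 * C)), min(hi, int(0.95 * C))
            for _ in range(2):
                c = int(rng.uniform(lo, hi + 1))
                w = max(6, int(round(1.5 * config.segment_width_um / config.pixel_size_um)))
                _vband(m, c, w)
        n_new = max(5, config.initial_segment_count // 3)
        for _ in range(n_new):
            _add_random_segment(
                m, rng, config, 0.0, spread, anchor_on_lumen=True, length_range=(300.0, 700.0)
            )
        m = _tidy(m, config.min_object_px)
        emit(Stage.SPROUTING)

    # -- remodeling: closed-loop flow-dependent pruning ----------------------
    # Two flow-dependent processes per frame: the lowest-R_Q near-perpendicular
    # flow-bearing edges are pruned (the bridge phenomenon), and non-perfused
    # satellite lumens, lacking any shear stimulus, retract by erosion.
    n_remod = config.stage_durations.get(Stage.REMODELING, 0)
    for i in range(n_remod):
        if not (m[0].any() and m[-1].any()):
            raise RuntimeError(
                "remodeling requested on a mask with no inlet-outlet "
                "connected path: flow undefined"
            )
        if config.prune_fraction_per_frame == 0.0:
            emit(Stage.REMODELING)  # no-op pruning: frames repeat unchanged
            continue
        res = analyze_frame(
            LumenMask(m.copy(), config.pixel_size_um, frame_id=frame),
            flow_config=flow,
        )
        n_edges = sum(
            1 for _, _, _, d in res.weighted_graph.g.edges(keys=True, data=True)
            if not d.get("no_flow", True)
        )
        k = max(1, int(round(config.prune_fraction_per_frame * n_edges)))
        pruned = apply_pruning_event(
            res.mask,
            res.weighted_graph,
            k,
            angle_max_deg=config.angle_max_deg,
            min_object_px=config.min_object_px,
            max_rq=config.prune_rq_max,
        )
        m = pruned.mask.pixels.copy()
        no_flow = res.field.domain.no_flow if res.field is not None and res.field.domain is not None else None
        if no_flow is not None and no_flow.any():
            keepers = m & ~no_flow
            shrunk = ndi.binary_erosion(m & no_flow, structure=disk(2))
            m = keepers | shrunk
        m = _tidy(m, config.min_object_px)
        emit(Stage.REMODELING)

    # -- stable: boundary jitter only ----------------------------------------
    n_stable = config.stage_durations.get(Stage.STABLE, 0)
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    for _ in range(n_stable):
        interior = ndi.binary_erosion(m, structure=cross, border_value=1)
        wall = np.argwhere(m & ~interior)
        if len(wall):
            n_j = max(2, int(config.jitter_fraction * len(wall)))
            pick = wall[rng.choice(len(wall), size=min(n_j, len(wall)), replace=False)]
            half = len(pick) // 2
            # half erode by one pixel, half dilate by one pixel: area ~ constant
            for r, c in pick[:half]:
                m[r, c] = False
            for r, c in pick[half:]:
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < m.shape[0] and 0 <= cc < m.shape[1] and not m[rr, cc]:
                        m[rr, cc] = True
                        break
            m = _tidy(m, config.min_object_px)
        emit(Stage.STABLE)

    # -- erosion: dilation growing in from the two port borders --------------
    n_ero = config.stage_durations.get(Stage.EROSION, 0)
    for i in range(n_ero):
        band_half = max(2, (i + 1) * R // (2 * max(4, n_ero + 2)))
        band = np.zeros_like(m)
        band[:band_half] = True
        band[-band_half:] = True
        strip = max(1, 2 * (i + 1))
        m = m | (ndi.binary_dilation(m, structure=disk(2)) & band)
        m[:strip] = True
        m[-strip:] = True
        # the banded dilation halo can detach 1-2 px crumbs where a component
        # sits just outside the band; drop them
        m = _tidy(m, config.min_object_px)
        emit(Stage.EROSION)

    return TimelapseDataset(
        masks=masks, stage_labels=labels, provenance=config, areas_px=areas
    )


# ---------------------------------------------------------------------------
# Pruning events
# ---------------------------------------------------------------------------

def _is_port_touching(wg, u: int, v: int, d: dict, shape: tuple[int, int], flow_axis: str, margin: int = 3) -> bool:
    lim = shape[0] if flow_axis == "rows" else shape[1]
    ax = 0 if flow_axis == "rows" else 1
    for n in (u, v):
        c = wg.g.nodes[n]["coord"][ax]
        if c <= margin or c >= lim - 1 - margin:
            return True
    for p in d["chain"]:
        if p[ax] <= 0 or p[ax] >= lim - 1:
            return True
    return False


def _port_nodes(wg, shape: tuple[int, int], flow_axis: str, margin: int = 3):
    ax = 0 if flow_axis == "rows" else 1
    lim = shape[0] if flow_axis == "rows" else shape[1]
    inlet, outlet = [], []
    for n, dat in wg.g.nodes(data=True):
        c = dat["coord"][ax]
        if c <= margin:
            inlet.append(n)
        elif c >= lim - 1 - margin:
            outlet.append(n)
    return inlet, outlet


def apply_pruning_event(
    mask: LumenMask,
    graph,  # WeightedVesselGraph computed from `mask`
    k: int = 1,
    angle_max_deg: float = 45.0,
    min_object_px: int = 30,
    max_rq: float | None = None,
) -> PruningResult:
    """Erase the ``k`` lowest-flow prunable edges from the mask.

    Prunable edges are flow-bearing, not port-touching, and oriented within
    ``angle_max_deg`` of perpendicular to the flow axis; they are taken in
    order of increasing flow-rate ratio (ties broken by lower edge id), and a
    candidate whose removal would disconnect the inlet side from the outlet
    side of the graph is skipped.  ``max_rq`` restricts candidates to truly
    low-flow segments (pruning regresses lumens that lack flow, it does not
    sever flowing ones).  When no prunable edge exists the mask is returned
    unchanged with ``warning=True``.
    """
    from .network import orientation_deg  # local import to avoid cycle at import time

    if k < 1:
        raise ValueError("k must be >= 1")
    flow_axis = graph.config.flow_axis
    shape = mask.shape

    candidates = []
    for u, v, key, d in graph.g.edges(keys=True, data=True):
        if d.get("no_flow", True):
            continue
        if max_rq is not None and d["R_Q"] > max_rq:
            continue
        if _is_port_touching(graph, u, v, d, shape, flow_axis):
            continue
        ang = orientation_deg(
            d["chain"],
            coords=(graph.g.nodes[u]["coord"], graph.g.nodes[v]["coord"]),
        )
        # angle from the flow axis; perpendicular = 90 deg
        ang_from_axis = ang if flow_axis == "rows" else 90.0 - ang
        if abs(ang_from_axis - 90.0) > angle_max_deg:
            continue
        candidates.append((d["R_Q"], d["eid"], (u, v, key), d))
    candidates.sort(key=lambda t: (t[0], t[1]))

    import networkx as nx

    inlet_nodes, outlet_nodes = _port_nodes(graph, shape, flow_axis)
    flowing_nodes = {
        n
        for u, v, key, d in graph.g.edges(keys=True, data=True)
        if not d.get("no_flow", True)
        for n in (u, v)
    }

    def stays_connected(removed_keys) -> bool:
        """Ports must remain linked and no currently-perfused node may be
        stranded: a segment whose removal de-perfuses a whole region is not
        redundant and is never the one pruned."""
        h = graph.g.copy()
        h.remove_edges_from(removed_keys)
        reach: set = set()
        for p in inlet_nodes + outlet_nodes:
            if p in h and p not in reach:
                reach |= nx.node_connected_component(h, p)
        if inlet_nodes and outlet_nodes:
            if not any(b in nx.node_connected_component(h, a) for a in inlet_nodes for b in outlet_nodes if a in h and b in h):
                return False
        for n in flowing_nodes:
            if h.degree(n) >= 1 and n not in reach:
                return False
        return True

    # Nearest-chain partition of every lumen pixel: used to erase the full
    # extent of a pruned edge (the disc-radius regions leave unclaimed pixels
    # near junction clusters that would survive as stubs).
    from scipy.spatial import cKDTree

    chain_pts, chain_eid = [], []
    for _, _, _, d in graph.g.edges(keys=True, data=True):
        for p in d["chain"]:
            chain_pts.append(p)
            chain_eid.append(d["eid"])
    nearest_eid = None
    li = lj = None
    if chain_pts:
        tree = cKDTree(np.asarray(chain_pts, dtype=float))
        li, lj = np.nonzero(mask.pixels)
        _, idx = tree.query(np.column_stack([li, lj]).astype(float), k=1)
        nearest_eid = np.asarray(chain_eid)[idx]

    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    ax = 0 if flow_axis == "rows" else 1

    def mask_perfused(mm: np.ndarray) -> bool:
        first = np.take(mm, 0, axis=ax)
        last = np.take(mm, -1, axis=ax)
        if not (first.any() and last.any()):
            return False
        lab, _ = ndi.label(mm, structure=cross)
        return bool(
            (set(np.unique(np.take(lab, 0, axis=ax))) - {0})
            & (set(np.unique(np.take(lab, -1, axis=ax))) - {0})
        )

    m = mask.pixels.copy()
    pruned: list[int] = []
    removed_keys: list[tuple] = []
    labels = graph.region_labels
    for rq, eid, ekey, d in candidates:
        if len(pruned) >= k:
            break
        if inlet_nodes and outlet_nodes and not stays_connected(removed_keys + [ekey]):
            continue
        erase = labels == eid
        if nearest_eid is not None:
            unclaimed = (labels[li, lj] == -1) & (nearest_eid == eid)
            erase[li[unclaimed], lj[unclaimed]] = True
        trial = m & ~erase
        # the graph-level guard can miss a disconnection introduced by region
        # erasure; verify on the pixels themselves
        if not mask_perfused(trial):
            continue
        m = trial
        pruned.append(eid)
        removed_keys.append(ekey)

    if not pruned:
        return PruningResult(mask=mask, pruned_eids=[], warning=True)

    from .masks import remove_small_components

    m = remove_small_components(m, min_object_px)
    new_mask = LumenMask(
        m, mask.pixel_size_um, time_point=mask.time_point, frame_id=mask.frame_id
    )
    return PruningResult(mask=new_mask, pruned_eids=pruned, warning=False)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_timelapse(dataset: TimelapseDataset, directory: str | Path) -> None:
    """Write ``frame_####.tif`` masks plus a JSON sidecar with labels/config."""
    import json

    from .masks import write_mask

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, mask in enumerate(dataset.masks):
        write_mask(directory / f"frame_{i:04d}.tif", mask)
    cfg = dataset.provenance
    sidecar = {
        "stage_labels": [s.value for s in dataset.stage_labels],
        "areas_px": dataset.areas_px,
        "config": {
            "stage_durations": {s.value: n for s, n in cfg.stage_durations.items()},
            "chamber_um": list(cfg.chamber_um),
            "pixel_size_um": cfg.pixel_size_um,
            "seed": cfg.seed,
            "initial_segment_count": cfg.initial_segment_count,
            "sprout_anisotropy": cfg.sprout_anisotropy,
            "prune_fraction_per_frame": cfg.prune_fraction_per_frame,
            "days_per_frame": cfg.days_per_frame,
        },
    }
    (directory / "timelapse.json").write_text(json.dumps(sidecar, indent=1))
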