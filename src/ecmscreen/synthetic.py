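"""Synthetic fibrillar-matrix images and plate readouts with known ground truth.

Real decellularised-matrix images show major fibres linked by a mesh of fine
interconnecting fibrils; treatments that reorganise the matrix produce
sparser networks of thicker, less connected fibrils. This module emulates
both phenotypes as smooth polylines with Gaussian cross-sections on a noisy
background, and — crucially — returns the exact branch topology of the drawn
network, so the whole image pipeline can be validated without microscope
data.

A *branch* in the ground truth is an edge of the network graph: fibres are
cut at every pairwise intersection, and each stretch between consecutive
nodes (junctions or fibre endpoints) counts as one branch. This mirrors the
operational definition used by the image analysis (skeleton paths between
junctions/endpoints), so recovery is well-posed.

All randomness flows from a single ``numpy`` Generator seeded by the spec.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, MultiPoint, Point
from skimage.draw import line as draw_line

from .errors import ParameterError
from .io_imaging import WellImage

_NODE_TOL = 1.0  # px; cut positions closer than this merge into one node


@dataclass(frozen=True)
class FibrilSpec:
    """Parameters of one synthetic well image (native 16-bit count scale).

    Defaults emulate a densely meshed control matrix at desk scale: the well
    mosaic is generated at 512 px (the native acquisition geometry of
    2208 px is supported but not the default, to keep simulations light).
    ``fibre_intensity`` is the ridge amplitude *above* the background level;
    its default of 110 counts over a 100-count background reproduces the
    low-contrast regime of a faint fluorescent protein stain, the regime in
    which the default branch inclusion band (-50/+150 native counts around
    the marker mean) is meaningful.
    ``min_node_separation_px > 0`` enables rejection sampling so that all
    network nodes are well separated and crossings are steep — the regime in
    which per-branch recovery from the image alone is unambiguous.
    """

    n_major_fibres: int = 4
    major_width_px: float = 2.0
    n_mesh_fibres: int = 40
    mesh_width_px: float = 1.2
    fibre_intensity: float = 110.0
    background_level: float = 100.0
    noise_sigma: float = 6.0
    curvature: float = 30.0
    image_size: int = 512
    bit_depth: int = 16
    min_node_separation_px: float = 0.0
    min_crossing_angle_deg: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_major_fibres < 0 or self.n_mesh_fibres < 0:
            raise ParameterError("fibre counts must be >= 0")
        if self.noise_sigma < 0 or self.background_level < 0:
            raise ParameterError("background and noise must be >= 0")
        max_w = max(self.major_width_px, self.mesh_width_px)
        if self.image_size < max(16, int(8 * max_w)):
            raise ParameterError(
                f"image_size {self.image_size} too small for fibre width {max_w} (need >= {max(16, int(8 * max_w))})"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Exact topology of the drawn network."""

    segments: list[np.ndarray]  # one (n, 2) float array of (row, col) per fibre
    node_graph: nx.MultiGraph
    true_branch_count: int
    true_mask: np.ndarray


@dataclass(frozen=True)
class DoseResponseSpec:
    """Four-parameter-logistic plate readouts with multiplicative noise.

    The default curve emulates a pro-fibrotic stimulus titration (EC50 15
    in the concentration units of ``concentrations``); ``cv`` is the
    coefficient of variation of the lognormal noise on the ECM signal.
    """

    bottom: float = 100.0
    top: float = 1000.0
    ec50: float = 15.0
    hill: float = 1.2
    cv: float = 0.1
    concentrations: tuple[float, ...] = (0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)
    n_replicates: int = 4
    viability_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top <= self.bottom:
            raise ParameterError("top must exceed bottom")
        if self.ec50 <= 0:
            raise ParameterError("ec50 must be > 0")
        if self.cv < 0:
            raise ParameterError("cv must be >= 0")


# --- network sampling --------------------------------------------------------


def _bezier(p0: np.ndarray, p1: np.ndarray, ctrl: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * ctrl + t**2 * p1


def _sample_fibre(rng: np.random.Generator, p0: np.ndarray, p1: np.ndarray, curvature: float) -> np.ndarray:
    chord = p1 - p0
    length = float(np.hypot(*chord))
    perp = np.array([-chord[1], chord[0]]) / max(length, 1e-9)
    ctrl = (p0 + p1) / 2 + perp * rng.uniform(-curvature, curvature)
    return _bezier(p0, p1, ctrl, max(16, int(length)))


def _sample_major(rng: np.random.Generator, size: int, curvature: float) -> np.ndarray:
    # endpoints on opposite borders, horizontal-ish or vertical-ish at random
    lo, hi = 0.0, float(size - 1)
    a, b = rng.uniform(0.1 * size, 0.9 * size, 2)
    if rng.random() < 0.5:
        p0, p1 = np.array([a, lo]), np.array([b, hi])
    else:
        p0, p1 = np.array([lo, a]), np.array([hi, b])
    return _sample_fibre(rng, p0, p1, curvature)


def _point_at(seg: np.ndarray, frac: float) -> np.ndarray:
    d = np.r_[0.0, np.cumsum(np.hypot(*np.diff(seg, axis=0).T))]
    target = frac * d[-1]
    i = int(np.searchsorted(d, target))
    i = min(max(i, 1), len(seg) - 1)
    w = (target - d[i - 1]) / max(d[i] - d[i - 1], 1e-9)
    return seg[i - 1] * (1 - w) + seg[i] * w


def _mesh_fibre(rng: np.random.Generator, segs: list[np.ndarray], spec: FibrilSpec) -> np.ndarray:
    size = spec.image_size
    if spec.n_major_fibres >= 2:
        i, j = rng.choice(spec.n_major_fibres, size=2, replace=False)
        p0 = _point_at(segs[i], rng.uniform(0.1, 0.9))
        p1 = _point_at(segs[j], rng.uniform(0.1, 0.9))
    else:
        p0 = rng.uniform(0.1 * size, 0.9 * size, 2)
        p1 = rng.uniform(0.1 * size, 0.9 * size, 2)
    return _sample_fibre(rng, p0, p1, spec.curvature * 0.5)


def _separation_ok(segs: list[np.ndarray], spec: FibrilSpec) -> bool:
    graph, _ = _network_graph(segs)
    return (
        _min_node_separation(graph) >= spec.min_node_separation_px
        and _crossing_angles_ok(segs, spec.min_crossing_angle_deg)
    )


def _sample_network(rng: np.random.Generator, spec: FibrilSpec) -> list[np.ndarray]:
    """Sample majors then mesh connectors; with a separation constraint each
    fibre is accepted/rejected incrementally (up to 200 tries per fibre)."""
    constrained = spec.min_node_separation_px > 0
    tries = 200 if constrained else 1
    segs: list[np.ndarray] = []
    for _ in range(spec.n_major_fibres):
        for _attempt in range(tries):
            cand = _sample_major(rng, spec.image_size, spec.curvature)
            if not constrained or _separation_ok(segs + [cand], spec):
                segs.append(cand)
                break
        else:
            raise ParameterError(
                f"could not place a major fibre with node separation >= {spec.min_node_separation_px} px"
            )
    for _ in range(spec.n_mesh_fibres):
        for _attempt in range(tries):
            cand = _mesh_fibre(rng, segs, spec)
            if not constrained or _separation_ok(segs + [cand], spec):
                segs.append(cand)
                break
        else:
            raise ParameterError(
                f"could not place a mesh fibre with node separation >= {spec.min_node_separation_px} px"
            )
    return segs


def _network_graph(segments: list[np.ndarray]) -> tuple[nx.MultiGraph, int]:
    """Cut fibres at pairwise intersections and build the node/branch graph."""
    lines = [LineString(s) for s in segments]
    cuts: list[list[float]] = [[0.0, ln.length] for ln in lines]
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            inter = lines[i].intersection(lines[j])
            pts: list[Point] = []
            if isinstance(inter, Point):
                pts = [inter]
            elif isinstance(inter, MultiPoint):
                pts = list(inter.geoms)
            elif not inter.is_empty:
                # degenerate overlap: treat the overlap midpoint as one junction
                pts = [inter.centroid]
            # endpoint-on-fibre attachments can miss exact intersection by
            # floating point; snap endpoints within half a pixel
            for a, b in ((i, j), (j, i)):
                for frac in (0.0, 1.0):
                    end = lines[a].interpolate(frac, normalized=True)
                    if 0.0 < lines[b].distance(end) < 0.5 or (
                        lines[b].distance(end) == 0.0 and not any(p.distance(end) < _NODE_TOL for p in pts)
                    ):
                        pts.append(end)
            for p in pts:
                cuts[i].append(lines[i].project(p))
                cuts[j].append(lines[j].project(p))

    def node_key(p: Point) -> tuple[float, float]:
        return (round(p.x / _NODE_TOL) * _NODE_TOL, round(p.y / _NODE_TOL) * _NODE_TOL)

    graph = nx.MultiGraph()
    n_edges = 0
    for ln, pos in zip(lines, cuts):
        pos = sorted(pos)
        merged = [pos[0]]
        for q in pos[1:]:
            if q - merged[-1] > _NODE_TOL:
                merged.append(q)
        nodes = [node_key(ln.interpolate(q)) for q in merged]
        for a, b in zip(nodes[:-1], nodes[1:]):
            graph.add_edge(a, b)
            n_edges += 1
    return graph, n_edges


def _min_node_separation(graph: nx.MultiGraph) -> float:
    pts = np.array(list(graph.nodes))
    if len(pts) < 2:
        return np.inf
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def _crossing_angles_ok(segments: list[np.ndarray], min_deg: float) -> bool:
    lines = [LineString(s) for s in segments]
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            inter = lines[i].intersection(lines[j])
            pts = [inter] if isinstance(inter, Point) else (list(inter.geoms) if isinstance(inter, MultiPoint) else [])
            for p in pts:
                angs = []
                for ln in (lines[i], lines[j]):
                    q = ln.project(p)
                    p0 = ln.interpolate(max(q - 2.0, 0.0))
                    p1 = ln.interpolate(min(q + 2.0, ln.length))
                    angs.append(np.arctan2(p1.y - p0.y, p1.x - p0.x))
                diff = abs(angs[0] - angs[1]) % np.pi
                if min(diff, np.pi - diff) < np.deg2rad(min_deg):
                    return False
    return True


# --- rendering ---------------------------------------------------------------


def _stamp_polyline(canvas: np.ndarray, seg: np.ndarray) -> None:
    pts = np.clip(np.rint(seg).astype(int), 0, np.array(canvas.shape) - 1)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        canvas[rr, cc] = 1.0


def render_network(
    segments: list[np.ndarray],
    image_size: int,
    widths: list[float],
    fibre_intensity: float = 110.0,
    background_level: float = 100.0,
    noise_sigma: float = 6.0,
    bit_depth: int = 16,
    rng: np.random.Generator | None = None,
    well_id: str = "SYN",
) -> tuple[WellImage, GroundTruth]:
    """Rasterise a fibre network and return the image with its exact topology.

    Each fibre is drawn as its polyline centreline blurred to a Gaussian
    cross-section of the given width (sigma, px), scaled to
    ``fibre_intensity`` at the ridge; fibres combine by maximum so that
    crossings stay at the nominal intensity. Additive Gaussian noise on top
    of a flat background is clipped to the valid bit-depth range.
    """
    shape = (image_size, image_size)
    signal = np.zeros(shape, np.float64)
    centrelines = np.zeros(shape, bool)
    for seg, width in zip(segments, widths):
        stamp = np.zeros(shape, np.float64)
        _stamp_polyline(stamp, seg)
        centrelines |= stamp > 0
        # blur only a bounding box around the fibre for speed
        rr, cc = np.nonzero(stamp)
        pad = int(4 * width) + 2
        r0, r1 = max(rr.min() - pad, 0), min(rr.max() + pad + 1, image_size)
        c0, c1 = max(cc.min() - pad, 0), min(cc.max() + pad + 1, image_size)
        local = ndimage.gaussian_filter(stamp[r0:r1, c0:c1], sigma=width)
        peak = local.max()
        if peak > 0:
            np.maximum(signal[r0:r1, c0:c1], local / peak * fibre_intensity, out=signal[r0:r1, c0:c1])
    true_mask = (signal >= 0.5 * fibre_intensity) | centrelines

    graph, n_branches = _network_graph(segments) if segments else (nx.MultiGraph(), 0)

    img = signal + background_level
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sigma, shape)
    img = np.clip(np.rint(img), 0, 2**bit_depth - 1)
    pixels = img.astype(np.uint8 if bit_depth == 8 else np.uint16)
    well = WellImage(pixels=pixels, well_id=well_id)
    return well, GroundTruth(segments=segments, node_graph=graph, true_branch_count=n_branches, true_mask=true_mask)


def generate_fibril_image(spec: FibrilSpec, well_id: str = "SYN") -> tuple[WellImage, GroundTruth]:
    """Generate one synthetic well image plus ground truth, deterministically.

    With ``min_node_separation_px > 0`` fibres are placed one at a time and
    redrawn (all draws from the single seeded generator) until every pair of
    network nodes is at least that far apart and all crossings are steeper
    than ``min_crossing_angle_deg``.
    """
    rng = np.random.default_rng(spec.seed)
    segments: list[np.ndarray] = []
    if spec.n_major_fibres or spec.n_mesh_fibres:
        segments = _sample_network(rng, spec)
    widths = [spec.major_width_px] * min(spec.n_major_fibres, len(segments))
    widths += [spec.mesh_width_px] * (len(segments) - len(widths))
    return render_network(
        segments,
        image_size=spec.image_size,
        widths=widths,
        fibre_intensity=spec.fibre_intensity,
        background_level=spec.background_level,
        noise_sigma=spec.noise_sigma,
        bit_depth=spec.bit_depth,
        rng=rng,
        well_id=well_id,
    )


def generate_phenotype_pair(
    base: FibrilSpec, mesh_factor: float = 0.25, width_factor: float = 2.0
) -> tuple[FibrilSpec, FibrilSpec]:
    """Control spec plus a reorganised-matrix spec (sparser, thicker fibrils).

    The altered phenotype keeps the amount of signal comparable but changes
    its organisation: mesh fibre count scaled by ``mesh_factor`` (default
    x0.25) and fibre widths by ``width_factor`` (default x2), so by
    construction it has fewer junctions and fewer branches.
    """
    altered = dataclasses.replace(
        base,
        n_mesh_fibres=int(round(base.n_mesh_fibres * mesh_factor)),
        major_width_px=base.major_width_px * width_factor,
        mesh_width_px=base.mesh_width_px * width_factor,
    )
    return base, altered


def two_crossing_fibres_spec(image_size: int = 256) -> list[np.ndarray]:
    """Two straight fibres crossing once near the centre: 4 branches by hand.

    The crossing graph has one junction and four endpoints; each fibre is cut
    into two edges, giving a ground-truth branch count of exactly 4.
    """
    s = float(image_size - 1)
    a = np.array([[0.1 * s, 0.05 * s], [0.9 * s, 0.95 * s]])
    b = np.array([[0.85 * s, 0.1 * s], [0.15 * s, 0.9 * s]])
    return [a, b]


# --- plate readouts ----------------------------------------------------------


def four_pl_curve(x: np.ndarray, bottom: float, top: float, ec50: float, hill: float) -> np.ndarray:
    """Four-parameter logistic: y = bottom + (top - bottom) / (1 + (ec50/x)^hill)."""
    x = np.asarray(x, np.float64)
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


def generate_plate_readouts(spec: DoseResponseSpec) -> pd.DataFrame:
    """Simulate per-well ECM and viability signals along a 4PL titration.

    ``ecm_signal = 4PL(conc) * lognormal`` noise with unit median and
    coefficient of variation ``cv``; ``viability_signal`` is drawn near 1
    with coefficient ``viability_cv`` so that viability normalisation is a
    near-identity perturbation, as in a healthy assay plate.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    sigma = float(np.sqrt(np.log1p(spec.cv**2)))
    vsigma = float(np.sqrt(np.log1p(spec.viability_cv**2)))
    for conc in spec.concentrations:
        mu = four_pl_curve(np.array([conc]), spec.bottom, spec.top, spec.ec50, spec.hill)[0]
        for rep in range(spec.n_replicates):
            noise = float(np.exp(rng.normal(0.0, sigma))) if spec.cv > 0 else 1.0
            viab = float(np.exp(rng.normal(0.0, vsigma))) if spec.viability_cv > 0 else 1.0
            rows.append(
                {"concentration": conc, "replicate": rep, "ecm_signal": mu * noise, "viability_signal": viab}
            )
    return pd.DataFrame(rows)


# --- fixture persistence -----------------------------------------------------


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    """Persist segments, nodes and branch count as JSON (plain text)."""
    payload = {
        "true_branch_count": truth.true_branch_count,
        "nodes": [list(n) for n in truth.node_graph.nodes],
        "segments": [s.round(3).tolist() for s in truth.segments],
    }
    Path(path).write_text(json.dumps(payload))
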