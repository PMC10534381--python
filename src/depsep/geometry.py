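"""Parametric two-stage Y-channel lab-on-chip geometry.

The device is a planar microchannel network: two inlet branches (an upper
blood inlet carrying the cell sample and a lower, faster buffer inlet) merge
into a main channel whose upper wall carries an array of protruding
electrodes (the active stage).  A first Y-split sends the lower stream to
the WBC outlet; the upper stream passes through a short secondary channel
and a second Y-split dividing it between the CTC outlet (middle, horizontal)
and the PLT outlet (upper, vertical).

All coordinates are micrometres, x along the main channel, origin at the
lower-left corner of the device bounding box.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, box
from shapely.ops import unary_union

__all__ = [
    "LOCParams",
    "BoundarySegment",
    "LOCGeometry",
    "build_loc_geometry",
    "OUTLET_TAGS",
    "SPECIES_TARGET_OUTLET",
]

#: outlet tags in geometric order: upper (electrode side), middle, lower
OUTLET_TAGS = ("outlet_PLT", "outlet_CTC", "outlet_WBC")

#: fixed species -> designated outlet routing of the separator
SPECIES_TARGET_OUTLET = {"PLT": "outlet_PLT", "CTC": "outlet_CTC", "WBC": "outlet_WBC"}

# Footprint calibration: with all port lengths taken from their nominal
# values along the branch axes, the stage-2 outlets are extended by these
# amounts so the assembled default device (CW = 40 um) reproduces the
# published overall footprint of 919 um x 440 um exactly.
CTC_OUTLET_EXTENSION = 38.0812
PLT_OUTLET_EXTENSION = 59.0812

# The electrode array ends this fraction of CW upstream of the first
# Y-split entrance, leaving the upstream part of the main channel
# electrode-free for flow focusing.
ELECTRODE_END_CLEARANCE_FRAC = 0.5

_SQ2 = math.sqrt(2.0) / 2.0


class ParameterError(ValueError):
    """A device parameter violates its constraint; names the offending field."""


@dataclass(frozen=True)
class LOCParams:
    """Parametric device dimensions (micrometres / degrees).

    Defaults are the reference design dimensions: 190 um ports, a 500 um
    main channel, a 60 um secondary channel, 40 um channel width, 100 um
    depth (used only for volumetric throughput), 90 deg branch angles and
    40 um wide electrodes protruding 16 um with 40 um gaps.
    """

    inlet_length: float = 190.0
    main_channel_length: float = 500.0
    secondary_channel_length: float = 60.0
    channel_width: float = 40.0
    channel_depth: float = 100.0
    outlet_length: float = 190.0
    inlet_angle: float = 90.0
    outlet_angle: float = 90.0
    electrode_protrusion: float = 16.0
    electrode_width: float = 40.0
    electrode_gap: float = 40.0
    n_electrodes: int = 4

    def __post_init__(self) -> None:
        lengths = {
            "inlet_length": self.inlet_length,
            "main_channel_length": self.main_channel_length,
            "secondary_channel_length": self.secondary_channel_length,
            "channel_width": self.channel_width,
            "channel_depth": self.channel_depth,
            "outlet_length": self.outlet_length,
            "electrode_protrusion": self.electrode_protrusion,
            "electrode_width": self.electrode_width,
            "electrode_gap": self.electrode_gap,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ParameterError(f"{name} must be > 0, got {value}")
        if self.electrode_protrusion >= self.channel_width:
            raise ParameterError(
                "electrode_protrusion must be smaller than channel_width "
                f"({self.electrode_protrusion} >= {self.channel_width})"
            )
        if self.n_electrodes not in (2, 4):
            raise ParameterError(f"n_electrodes must be 2 or 4, got {self.n_electrodes}")
        array_len = (
            self.n_electrodes * self.electrode_width
            + (self.n_electrodes - 1) * self.electrode_gap
        )
        if array_len > self.main_channel_length:
            raise ParameterError(
                "electrode array does not fit in the main channel: "
                f"N*e + (N-1)*d = {array_len} > CL1 = {self.main_channel_length}"
            )
        for name in ("inlet_angle", "outlet_angle"):
            value = getattr(self, name)
            if not 0 < value < 180:
                raise ParameterError(f"{name} must be in (0, 180) degrees, got {value}")

    @property
    def electrode_array_length(self) -> float:
        return (
            self.n_electrodes * self.electrode_width
            + (self.n_electrodes - 1) * self.electrode_gap
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BoundarySegment:
    """A named straight boundary face: endpoints in um."""

    tag: str
    p0: tuple[float, float]
    p1: tuple[float, float]

    @property
    def length(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])

    def unit_tangent(self) -> tuple[float, float]:
        t = (self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])
        n = self.length
        return (t[0] / n, t[1] / n)


@dataclass
class LOCGeometry:
    """Tagged planar polygon of the device.

    ``polygon`` is a simple shapely polygon (CCW exterior).  ``segments``
    holds the named faces (inlet/outlet end faces, exposed electrode
    faces); every boundary edge not on a named face is a wall.
    ``port_directions`` maps port tags to the outward unit normal of the
    end face.
    """

    params: LOCParams
    polygon: Polygon
    segments: list[BoundarySegment]
    port_directions: dict[str, tuple[float, float]]
    junctions: dict[str, tuple[float, float]]

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds

    @property
    def area(self) -> float:
        return self.polygon.area

    def named_segment(self, tag: str) -> BoundarySegment:
        for seg in self.segments:
            if seg.tag == tag:
                return seg
        raise KeyError(tag)

    def electrode_segments(self, index: int) -> list[BoundarySegment]:
        tag = f"electrode_{index}"
        segs = [s for s in self.segments if s.tag == tag]
        if not segs:
            raise KeyError(tag)
        return segs

    @property
    def electrode_tags(self) -> list[str]:
        return [f"electrode_{i + 1}" for i in range(self.params.n_electrodes)]

    def electrode_corners(self) -> np.ndarray:
        """Corner points of the electrode notches (field singularities)."""
        corners = []
        for i in range(self.params.n_electrodes):
            for seg in self.electrode_segments(i + 1):
                corners.append(seg.p0)
                corners.append(seg.p1)
        return np.unique(np.asarray(corners), axis=0)

    def active_region_points(self, spacing: float) -> np.ndarray:
        """Points sampled along the active-stage boundary (electrode faces
        and the wall segments between adjacent electrodes), used for local
        mesh refinement where the DEP drive must be accurate."""
        segs = []
        n = self.params.n_electrodes
        for i in range(n):
            segs.extend(self.electrode_segments(i + 1))
        # wall gaps between adjacent electrodes (top wall level)
        by_el = [self.electrode_segments(i + 1) for i in range(n)]
        for a, b in zip(by_el[:-1], by_el[1:]):
            x_right = max(p[0] for s in a for p in (s.p0, s.p1))
            x_left = min(p[0] for s in b for p in (s.p0, s.p1))
            y_wall = max(p[1] for s in a for p in (s.p0, s.p1))
            segs.append(BoundarySegment("wall", (x_right, y_wall), (x_left, y_wall)))
        pts = []
        for s in segs:
            m = max(2, int(np.ceil(s.length / spacing)) + 1)
            t = np.linspace(0.0, 1.0, m)
            p0, p1 = np.asarray(s.p0), np.asarray(s.p1)
            pts.append(p0[None, :] + t[:, None] * (p1 - p0)[None, :])
        return np.vstack(pts)

    def contains(self, x: float, y: float) -> bool:
        return bool(shapely.contains_xy(self.polygon, x, y))

    def to_json(self) -> str:
        """Echo the geometry (parameters, tagged faces, vertices) as JSON."""
        data = {
            "params": self.params.to_dict(),
            "bounding_box": list(self.bounding_box),
            "area": self.area,
            "exterior": [list(p) for p in self.polygon.exterior.coords],
            "segments": [
                {"tag": s.tag, "p0": list(s.p0), "p1": list(s.p1)} for s in self.segments
            ],
        }
        return json.dumps(data, indent=1)


def _branch_rect(start, direction, length, width) -> Polygon:
    """Flat-capped rectangle of given width along a centreline segment."""
    end = (start[0] + direction[0] * length, start[1] + direction[1] * length)
    return LineString([start, end]).buffer(
        width / 2.0, cap_style="flat", join_style="mitre"
    )


def build_loc_geometry(params: LOCParams) -> LOCGeometry:
    """Assemble the tagged device polygon from :class:`LOCParams`.

    The inlet/outlet branch angles are measured between the two branches of
    each Y (90 deg by default, i.e. each branch at 45 deg to the local
    axis).  The electrode array is placed with its downstream edge half a
    channel width upstream of the first Y-split entrance.
    """
    cw = params.channel_width
    half = cw / 2.0
    il, ol = params.inlet_length, params.outlet_length
    cl1, cl2 = params.main_channel_length, params.secondary_channel_length

    # branch direction half-angles
    a_in = math.radians(params.inlet_angle) / 2.0
    a_out = math.radians(params.outlet_angle) / 2.0
    # unit vectors
    d_blood = (-math.cos(a_in), math.sin(a_in))      # upper inlet, up-left
    d_buffer = (-math.cos(a_in), -math.sin(a_in))    # lower inlet, down-left
    d_wbc = (math.cos(a_out), -math.sin(a_out))      # lower outlet, down-right
    d_sec = (math.cos(a_out), math.sin(a_out))       # secondary channel, up-right
    # second split symmetric about the secondary axis: rotate +-a_out
    ang_sec = math.atan2(d_sec[1], d_sec[0])
    d_ctc = (math.cos(ang_sec - a_out), math.sin(ang_sec - a_out))
    d_plt = (math.cos(ang_sec + a_out), math.sin(ang_sec + a_out))

    j1 = (0.0, 0.0)                       # inlet junction (origin shifted later)
    j2 = (cl1, 0.0)                       # first split
    j3 = (j2[0] + cl2 * d_sec[0], j2[1] + cl2 * d_sec[1])  # second split

    l_ctc = ol + CTC_OUTLET_EXTENSION
    l_plt = ol + PLT_OUTLET_EXTENSION

    parts = [
        _branch_rect(j1, d_blood, il, cw),
        _branch_rect(j1, d_buffer, il, cw),
        _branch_rect(j1, (1.0, 0.0), cl1, cw),
        _branch_rect(j2, d_wbc, ol, cw),
        _branch_rect(j2, d_sec, cl2, cw),
        _branch_rect(j3, d_ctc, l_ctc, cw),
        _branch_rect(j3, d_plt, l_plt, cw),
    ]
    channel = unary_union(parts)

    # electrode notches: rectangles cut into the upper wall of the main channel
    y_top = half
    pd = params.electrode_protrusion
    e, d = params.electrode_width, params.electrode_gap
    n = params.n_electrodes
    x_end = cl1 - ELECTRODE_END_CLEARANCE_FRAC * cw
    x_start = x_end - params.electrode_array_length
    if x_start < 0:
        raise ParameterError(
            "electrode array extends upstream of the main channel "
            f"(array start {x_start:.1f} < 0); shorten the array or lengthen CL1"
        )
    electrode_faces: list[BoundarySegment] = []
    notches = []
    for i in range(n):
        x0 = x_start + i * (e + d)
        x1 = x0 + e
        notches.append(box(x0, y_top - pd, x1, y_top + cw))
        tag = f"electrode_{i + 1}"
        yb = y_top - pd
        electrode_faces += [
            BoundarySegment(tag, (x0, y_top), (x0, yb)),      # upstream face
            BoundarySegment(tag, (x0, yb), (x1, yb)),         # bottom face
            BoundarySegment(tag, (x1, yb), (x1, y_top)),      # downstream face
        ]
    poly = channel.difference(unary_union(notches))
    if not isinstance(poly, Polygon):
        raise ParameterError("geometry is not a single connected polygon")
    poly = shapely.geometry.polygon.orient(poly, sign=1.0)  # CCW exterior

    # named end faces (port tag, tip centre, outward normal)
    def face(tag, j, direction, length):
        tip = (j[0] + direction[0] * length, j[1] + direction[1] * length)
        perp = (-direction[1], direction[0])
        p0 = (tip[0] - perp[0] * half, tip[1] - perp[1] * half)
        p1 = (tip[0] + perp[0] * half, tip[1] + perp[1] * half)
        return BoundarySegment(tag, p0, p1), direction

    ports = {}
    segments: list[BoundarySegment] = []
    for tag, j, dvec, length in [
        ("blood_inlet", j1, d_blood, il),
        ("buffer_inlet", j1, d_buffer, il),
        ("outlet_WBC", j2, d_wbc, ol),
        ("outlet_CTC", j3, d_ctc, l_ctc),
        ("outlet_PLT", j3, d_plt, l_plt),
    ]:
        seg, outward = face(tag, j, dvec, length)
        segments.append(seg)
        ports[tag] = outward
    segments += electrode_faces

    # shift so the bounding box starts at the origin
    minx, miny, _, _ = poly.bounds
    poly = shapely.affinity.translate(poly, -minx, -miny)

    def shift_seg(s: BoundarySegment) -> BoundarySegment:
        return BoundarySegment(
            s.tag,
            (s.p0[0] - minx, s.p0[1] - miny),
            (s.p1[0] - minx, s.p1[1] - miny),
        )

    segments = [shift_seg(s) for s in segments]
    junctions = {
        "inlet": (j1[0] - minx, j1[1] - miny),
        "split1": (j2[0] - minx, j2[1] - miny),
        "split2": (j3[0] - minx, j3[1] - miny),
    }

    if not poly.is_valid or not poly.is_simple:
        raise ParameterError("assembled polygon is not simple")

    return LOCGeometry(
        params=params,
        polygon=poly,
        segments=segments,
        port_directions=ports,
        junctions=junctions,
    )
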