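"""Nucleus and DNA geometry.

The nucleus is a sphere (default 1.5 µm diameter, radius 0.75 µm) centred at
the origin.  DNA is represented by straight segments, 2.6 nm wide, grouped
into *stacks* of parallel segments.  Each segment is a long narrow rectangle
whose two sides ("faces", front and back of the same rectangle plane) act as
uniform non-specific binding areas.  Target genes (TGs) are points on
segment centrelines, in the rectangle plane.

Within a stack, segments share an axial direction ``axis`` and are spaced
``spacing_nm`` apart along ``normal``.  The physical spacing is irrelevant to
intersegmental transfer, which is driven purely by the declared segment
adjacency graph; it only matters for 3D diffusion around the stack.

Surface coordinates of a DNA-bound TF are ``(segment, u, v, face)`` with
``u`` the axial position from the segment start and ``v ∈ [0, width]`` the
transverse position across the face (the centreline projects to
``v = width/2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import ModelConfig

__all__ = [
    "bp_to_nm",
    "nm_to_bp",
    "DNASegment",
    "TargetGene",
    "StackSpec",
    "GeometryLayout",
    "Geometry",
    "build_geometry",
    "surface_to_world",
    "world_to_surface",
]

DEFAULT_NUCLEUS_RADIUS = 0.75  # µm (1.5 µm diameter sphere)
DEFAULT_DNA_WIDTH_NM = 2.6
DEFAULT_RISE_PER_BP = 0.34  # nm, B-DNA


def bp_to_nm(n_bp: float, rise_per_bp: float = DEFAULT_RISE_PER_BP) -> float:
    """Convert a basepair count to a contour length in nm.

    Linear in ``n_bp`` (6 bp ≈ 2.0 nm, 150 bp ≈ 50 nm at the B-DNA rise).
    """
    if n_bp < 0:
        raise ValueError(f"basepair count must be >= 0, got {n_bp!r}")
    return n_bp * rise_per_bp


def nm_to_bp(length_nm: float, rise_per_bp: float = DEFAULT_RISE_PER_BP) -> float:
    if length_nm < 0:
        raise ValueError(f"length must be >= 0, got {length_nm!r}")
    return length_nm / rise_per_bp


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


@dataclass
class DNASegment:
    """One straight DNA segment inside a stack."""

    id: int
    length_bp: int
    stack: int
    index_in_stack: int
    origin: np.ndarray  # centreline start, µm
    axis: np.ndarray  # unit axial direction
    normal: np.ndarray  # unit face normal (stacking direction)
    width_nm: float = DEFAULT_DNA_WIDTH_NM

    @property
    def trans(self) -> np.ndarray:
        return np.cross(self.axis, self.normal)

    def length_um(self, rise_per_bp: float = DEFAULT_RISE_PER_BP) -> float:
        return bp_to_nm(self.length_bp, rise_per_bp) * 1e-3


@dataclass
class TargetGene:
    """A specific recognition site on a segment centreline."""

    id: int
    segment: int
    position_bp: float
    occupancy: int = 0


@dataclass
class StackSpec:
    """Layout of one stack of parallel DNA segments.

    ``length_bp`` may be a single int (uniform) or one length per segment.
    The stack is centred on ``center`` both axially and across the stacking
    direction.
    """

    n_segments: int
    length_bp: int | Sequence[int]
    spacing_nm: float = 10.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def lengths(self) -> list[int]:
        if np.isscalar(self.length_bp):
            return [int(self.length_bp)] * self.n_segments
        L = [int(x) for x in self.length_bp]
        if len(L) != self.n_segments:
            raise ValueError("one length per segment required")
        return L


@dataclass
class GeometryLayout:
    """Declarative layout: stacks plus TG placements (segment id, bp)."""

    stacks: list[StackSpec]
    tg: list[tuple[int, float]] = field(default_factory=list)
    nucleus_radius: float = DEFAULT_NUCLEUS_RADIUS
    width_nm: float = DEFAULT_DNA_WIDTH_NM


@dataclass
class Geometry:
    """Fully realised geometry: segments, TGs, IST graph and slide links."""

    nucleus_radius: float
    segments: list[DNASegment]
    tg_list: list[TargetGene]
    ist_adjacency: list[tuple[int, int]]
    slide_links: list[tuple[int, int]]
    width_nm: float
    rise_per_bp: float
    _stacks: list[StackSpec] = field(default_factory=list, repr=False)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def total_length_bp(self) -> int:
        return sum(s.length_bp for s in self.segments)

    def arrays(self) -> tuple:
        """Pack the geometry into a flat tuple of numpy arrays for the
        simulation kernel (cached).  See ``_kernel`` for the field order."""
        cached = getattr(self, "_arrays_cache", None)
        if cached is not None:
            return cached
        nseg = len(self.segments)
        nstk = len(self._stacks)
        w = self.width_nm * 1e-3
        half = 0.5 * w
        st_o = np.zeros((nstk, 3))
        st_a = np.zeros((nstk, 3))
        st_n = np.zeros((nstk, 3))
        st_t = np.zeros((nstk, 3))
        st_sp = np.zeros(nstk)
        st_seg0 = np.zeros(nstk, dtype=np.int64)
        st_m = np.zeros(nstk, dtype=np.int64)
        st_lo = np.zeros((nstk, 3))
        st_hi = np.zeros((nstk, 3))
        seg_stk = np.array([s.stack for s in self.segments], dtype=np.int64)
        seg_j = np.array([s.index_in_stack for s in self.segments], dtype=np.int64)
        seg_L = np.array(
            [s.length_um(self.rise_per_bp) for s in self.segments], dtype=float
        )
        # stack frames from first segment of each stack
        for k in range(nstk):
            members = [s for s in self.segments if s.stack == k]
            first = members[0]
            st_o[k] = first.origin
            st_a[k] = first.axis
            st_n[k] = first.normal
            st_t[k] = first.trans
            st_sp[k] = self._stacks[k].spacing_nm * 1e-3
            st_seg0[k] = first.id
            st_m[k] = len(members)
            pts = []
            for s in members:
                L = s.length_um(self.rise_per_bp)
                for uu in (0.0, L):
                    for vv in (-half, half):
                        pts.append(s.origin + uu * s.axis + vv * s.trans)
            pts = np.array(pts)
            st_lo[k] = pts.min(axis=0)
            st_hi[k] = pts.max(axis=0)
        slide_next = np.full(nseg, -1, dtype=np.int64)
        slide_prev = np.full(nseg, -1, dtype=np.int64)
        for i, j in self.slide_links:
            slide_next[i] = j
            slide_prev[j] = i
        # IST adjacency as CSR over segment ids
        neigh: list[list[int]] = [[] for _ in range(nseg)]
        for i, j in self.ist_adjacency:
            neigh[i].append(j)
            neigh[j].append(i)
        indptr = np.zeros(nseg + 1, dtype=np.int64)
        flat: list[int] = []
        for i in range(nseg):
            neigh[i].sort()
            flat.extend(neigh[i])
            indptr[i + 1] = len(flat)
        ist_indices = np.array(flat, dtype=np.int64)
        ntg = len(self.tg_list)
        tg_seg = np.array([t.segment for t in self.tg_list], dtype=np.int64)
        tg_u = np.array(
            [bp_to_nm(t.position_bp, self.rise_per_bp) * 1e-3 for t in self.tg_list]
        )
        tg_world = np.zeros((ntg, 3))
        for i, t in enumerate(self.tg_list):
            s = self.segments[t.segment]
            tg_world[i] = s.origin + tg_u[i] * s.axis
        # per-segment TG lists (id order preserved)
        s2t: list[list[int]] = [[] for _ in range(nseg)]
        for i, t in enumerate(self.tg_list):
            s2t[t.segment].append(i)
        s2t_indptr = np.zeros(nseg + 1, dtype=np.int64)
        s2t_flat: list[int] = []
        for i in range(nseg):
            s2t_flat.extend(s2t[i])
            s2t_indptr[i + 1] = len(s2t_flat)
        s2t_indices = np.array(s2t_flat, dtype=np.int64)
        if ntg:
            tg_lo = tg_world.min(axis=0)
            tg_hi = tg_world.max(axis=0)
        else:
            tg_lo = np.zeros(3)
            tg_hi = np.zeros(3)
        out = (
            float(self.nucleus_radius),
            float(half),
            float(w),
            st_o, st_a, st_n, st_t, st_sp, st_seg0, st_m, st_lo, st_hi,
            seg_stk, seg_j, seg_L,
            slide_next, slide_prev,
            indptr, ist_indices,
            tg_seg, tg_u, tg_world,
            s2t_indptr, s2t_indices,
            tg_lo, tg_hi,
        )
        self._arrays_cache = out
        return out

    def to_tsv(self, path) -> None:
        """Dump the segment table for inspection."""
        import pandas as pd

        rows = []
        for s in self.segments:
            rows.append(
                dict(
                    segment=s.id,
                    stack=s.stack,
                    length_bp=s.length_bp,
                    ox=s.origin[0], oy=s.origin[1], oz=s.origin[2],
                    ax=s.axis[0], ay=s.axis[1], az=s.axis[2],
                )
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_geometry(config: ModelConfig, layout: GeometryLayout) -> Geometry:
    """Realise a layout into a validated :class:`Geometry`.

    Raises a configuration error if any segment (including its faces) would
    extend beyond the nucleus sphere.  The IST adjacency is derived from
    ``config.ist_graph_kind`` within each stack; ``config.slide_linked``
    chains segment ends in stack order.
    """
    R = layout.nucleus_radius
    rise = config.rise_per_bp
    segments: list[DNASegment] = []
    slide_links: list[tuple[int, int]] = []
    adjacency: list[tuple[int, int]] = []
    sid = 0
    for k, stk in enumerate(layout.stacks):
        lengths = stk.lengths()
        axis = _unit(stk.axis)
        normal = _unit(stk.normal)
        if abs(float(np.dot(axis, normal))) > 1e-9:
            raise ValueError("stack axis and normal must be orthogonal")
        center = np.asarray(stk.center, dtype=float)
        sp = stk.spacing_nm * 1e-3
        m = stk.n_segments
        Lmax = bp_to_nm(max(lengths), rise) * 1e-3
        if Lmax > 2 * R:
            raise ValueError(
                f"segment of {max(lengths)} bp ({Lmax:.3f} µm) is longer than "
                f"the nucleus diameter ({2 * R:.3f} µm)"
            )
        start = center - 0.5 * Lmax * axis - 0.5 * (m - 1) * sp * normal
        first_id = sid
        for j in range(m):
            seg = DNASegment(
                id=sid,
                length_bp=lengths[j],
                stack=k,
                index_in_stack=j,
                origin=start + j * sp * normal,
                axis=axis,
                normal=normal,
                width_nm=layout.width_nm,
            )
            segments.append(seg)
            sid += 1
        ids = list(range(first_id, first_id + m))
        if config.slide_linked:
            slide_links.extend((ids[j], ids[j + 1]) for j in range(m - 1))
        if config.ist_graph_kind == "chain":
            adjacency.extend((ids[j], ids[j + 1]) for j in range(m - 1))
        elif config.ist_graph_kind == "complete":
            adjacency.extend(
                (ids[a], ids[b]) for a in range(m) for b in range(a + 1, m)
            )
    # validate containment: every corner of every segment inside the sphere
    half = 0.5 * layout.width_nm * 1e-3
    for s in segments:
        L = s.length_um(rise)
        for uu in (0.0, L):
            for vv in (-half, half):
                for nn in (-half, half):
                    p = s.origin + uu * s.axis + vv * s.trans + nn * s.normal
                    if np.linalg.norm(p) > R + 1e-12:
                        raise ValueError(
                            f"segment {s.id} extends outside the nucleus "
                            f"(|corner| = {np.linalg.norm(p):.4f} µm > R = {R} µm)"
                        )
    tgs: list[TargetGene] = []
    for i, (seg_id, pos_bp) in enumerate(layout.tg):
        if not 0 <= seg_id < len(segments):
            raise ValueError(f"TG {i}: unknown segment {seg_id}")
        if not 0 <= pos_bp <= segments[seg_id].length_bp:
            raise ValueError(
                f"TG {i}: position {pos_bp} bp outside segment of "
                f"{segments[seg_id].length_bp} bp"
            )
        tgs.append(TargetGene(id=i, segment=seg_id, position_bp=float(pos_bp)))
    return Geometry(
        nucleus_radius=R,
        segments=segments,
        tg_list=tgs,
        ist_adjacency=adjacency,
        slide_links=slide_links,
        width_nm=layout.width_nm,
        rise_per_bp=rise,
        _stacks=list(layout.stacks),
    )


def surface_to_world(
    geom: Geometry, segment: int, u_nm: float, v_nm: float, face: int
) -> np.ndarray:
    """Map surface coordinates (u, v in nm, face 0/1) to a 3D point in µm.

    ``face`` 0 is the +normal side of the rectangle plane, 1 the −normal
    side; both map to the same in-plane point (the face only determines the
    outward direction used when the TF leaves the surface).
    """
    s = geom.segments[segment]
    L_nm = bp_to_nm(s.length_bp, geom.rise_per_bp)
    if not 0.0 <= u_nm <= L_nm:
        raise ValueError(f"u = {u_nm} nm outside [0, {L_nm}] nm")
    if not 0.0 <= v_nm <= geom.width_nm:
        raise ValueError(f"v = {v_nm} nm outside [0, {geom.width_nm}] nm")
    if face not in (0, 1):
        raise ValueError("face must be 0 or 1")
    half = 0.5 * geom.width_nm * 1e-3
    return (
        s.origin
        + (u_nm * 1e-3) * s.axis
        + (v_nm * 1e-3 - half) * s.trans
    )


def world_to_surface(
    geom: Geometry, segment: int, face: int, point: np.ndarray
) -> tuple[float, float]:
    """Inverse of :func:`surface_to_world` on a given segment face.

    Returns (u_nm, v_nm) of the in-plane projection of ``point``.
    """
    s = geom.segments[segment]
    d = np.asarray(point, dtype=float) - s.origin
    u_nm = float(np.dot(d, s.axis)) * 1e3
    v_nm = float(np.dot(d, s.trans)) * 1e3 + 0.5 * geom.width_nm
    return u_nm, v_nm
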