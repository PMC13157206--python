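"""Structure cleaning applied before any distance analysis.

Duplicate vertices and degenerate (zero-area) contours are removed from
both members of every pair, so systems that perform this clean-up during
re-export are not penalised.  Cleaning is idempotent and never moves a
surviving vertex.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .model import PlanarContour, Structure

log = logging.getLogger(__name__)

DEFAULT_VERTEX_EPS = 1e-6  # mm
DEFAULT_AREA_EPS = 1e-6  # mm^2


@dataclass
class SliceGroup:
    """All contours of a structure sharing one slice position."""

    z: float
    contours: list[PlanarContour]

    @property
    def n_contours(self) -> int:
        return len(self.contours)


def remove_duplicate_vertices(c: PlanarContour, eps: float = DEFAULT_VERTEX_EPS) -> PlanarContour:
    """Drop consecutive vertices closer than ``eps`` (cyclically).

    The cyclic check covers a duplicated closing point (last == first).
    Vertex order is otherwise preserved; may return a contour with fewer
    than 3 vertices (degeneracy handled by :func:`remove_degenerate_contours`).
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    v = c.vertices
    if len(v) == 0:
        return c
    keep = [0]
    for i in range(1, len(v)):
        if np.linalg.norm(v[i] - v[keep[-1]]) >= eps:
            keep.append(i)
    # cyclic: last retained vertex may coincide with the first
    while len(keep) > 1 and np.linalg.norm(v[keep[-1]] - v[keep[0]]) < eps:
        keep.pop()
    return PlanarContour(v[keep], c.z, c.geometric_type)


def remove_degenerate_contours(
    s: Structure, area_eps: float = DEFAULT_AREA_EPS
) -> Structure:
    """Drop contours with < 3 distinct vertices or enclosed area below ``area_eps``.

    Survivors are untouched; each removal is logged.  The result may be an
    empty structure (flagged via a log warning).
    """
    kept: list[PlanarContour] = []
    for i, c in enumerate(s.contours):
        if c.n_vertices < 3:
            log.info(
                "%s: removed contour %d at z=%.3f (fewer than 3 vertices)", s.name, i, c.z
            )
            continue
        if c.area < area_eps:
            log.info(
                "%s: removed contour %d at z=%.3f (area %.3g < %.3g mm^2)",
                s.name, i, c.z, c.area, area_eps,
            )
            continue
        kept.append(c)
    if not kept and s.contours:
        log.warning("%s: all contours removed as degenerate", s.name)
    return replace(s, contours=kept)


def clean_structure(
    s: Structure,
    vertex_eps: float = DEFAULT_VERTEX_EPS,
    area_eps: float = DEFAULT_AREA_EPS,
) -> Structure:
    """Full clean: duplicate-vertex removal followed by degeneracy removal."""
    dedup = replace(s, contours=[remove_duplicate_vertices(c, vertex_eps) for c in s.contours])
    return remove_degenerate_contours(dedup, area_eps)


def group_by_slice(
    s: Structure, z_tol: float, dz: float | None = None
) -> list[SliceGroup]:
    """Cluster contours by slice position.

    Groups are sorted by ascending z and disjoint; each contour belongs to
    exactly one group whose representative z is the mean of its members.
    When ``dz`` is given, a pair of neighbouring groups separated by less
    than dz/2 (but more than ``z_tol``) triggers a mis-gridded-export
    warning.
    """
    if z_tol <= 0:
        raise ValueError("z_tol must be > 0")
    contours = sorted(s.contours, key=lambda c: c.z)
    groups: list[SliceGroup] = []
    for c in contours:
        if groups and abs(c.z - groups[-1].z) <= z_tol:
            g = groups[-1]
            members = g.contours + [c]
            groups[-1] = SliceGroup(float(np.mean([m.z for m in members])), members)
        else:
            groups.append(SliceGroup(c.z, [c]))
    if dz is not None:
        for g0, g1 in zip(groups, groups[1:]):
            gap = g1.z - g0.z
            if z_tol < gap < dz / 2:
                warnings.warn(
                    f"{s.name!r}: slices at z={g0.z:.4f} and z={g1.z:.4f} are "
                    f"{gap:.4f} mm apart (< dz/2): possible mis-gridded export",
                    stacklevel=2,
                )
    return groups


def match_slices(
    a: Structure, b: Structure, z_tol: float
) -> list[tuple[float, list[PlanarContour], list[PlanarContour]]]:
    """Pair up slice groups of two structures by z.

    Returns one entry per z present in either structure: ``(z, contours_a,
    contours_b)`` where either contour list may be empty (slice present in
    only one structure).
    """
    ga = group_by_slice(a, z_tol) if not a.is_empty else []
    gb = group_by_slice(b, z_tol) if not b.is_empty else []
    out: list[tuple[float, list[PlanarContour], list[PlanarContour]]] = []
    i = j = 0
    while i < len(ga) and j < len(gb):
        dzij = ga[i].z - gb[j].z
        if abs(dzij) <= z_tol:
            out.append((ga[i].z, ga[i].contours, gb[j].contours))
            i += 1
            j += 1
        elif dzij < 0:
            out.append((ga[i].z, ga[i].contours, []))
            i += 1
        else:
            out.append((gb[j].z, [], gb[j].contours))
            j += 1
    for g in ga[i:]:
        out.append((g.z, g.contours, []))
    for g in gb[j:]:
        out.append((g.z, [], g.contours))
    return out
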