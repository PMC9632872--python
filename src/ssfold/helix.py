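"""Helix-axis geometry from Cα traces (HELANAL-style local axes).

The local axis of a sliding window of four consecutive Cα atoms
(P_i, P_{i+1}, P_{i+2}, P_{i+3}) is the unit cross product of the two second
differences A = P_i − 2P_{i+1} + P_{i+2} and B = P_{i+1} − 2P_{i+2} + P_{i+3};
for a regular helix both second differences point toward the axis, so their
cross product is parallel to it.  Axes are oriented along the chain direction,
averaged into a global axis per segment, and two segments are compared by the
undirected line angle arccos|u·v| ∈ [0°, 90°] — antiparallel hairpin helices
therefore read as a small angle, matching how axial angles of helix hairpins
are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import StructureEnsemble, select_atoms

__all__ = ["HelixSegment", "local_axes", "global_axis", "interhelix_angle", "segment_from_ensemble"]


@dataclass
class HelixSegment:
    chain: str
    start_seq: int
    end_seq: int
    local_axes: np.ndarray  # (n_ca - 3, 3) unit vectors
    global_axis: np.ndarray  # unit 3-vector
    n_ca: int


def local_axes(ca_points) -> np.ndarray:
    """Unit local helix axes for every 4-Cα window, oriented along the chain."""
    pts = np.asarray(ca_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need at least 4 Cα points")
    axes = []
    for i in range(len(pts) - 3):
        a = pts[i] - 2 * pts[i + 1] + pts[i + 2]
        b = pts[i + 1] - 2 * pts[i + 2] + pts[i + 3]
        axis = np.cross(a, b)
        norm = np.linalg.norm(axis)
        if norm < 1e-8:
            raise ValueError(
                f"degenerate window {i}: collinear second differences (straight segment?)"
            )
        axis = axis / norm
        if np.dot(axis, pts[i + 3] - pts[i]) < 0:
            axis = -axis
        axes.append(axis)
    return np.array(axes)


def global_axis(axes) -> np.ndarray:
    """Unit-normalized mean of local axes."""
    axes = np.asarray(axes, dtype=float)
    if axes.ndim != 2 or len(axes) < 1:
        raise ValueError("need at least one local axis")
    mean = axes.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-6:
        raise ValueError("local axes cancel; split the segment at its kink")
    return mean / norm


def segment_from_ensemble(
    ensemble: StructureEnsemble,
    model_index: int,
    chain: str,
    start_seq: int,
    end_seq: int,
) -> HelixSegment:
    """Build a HelixSegment from the Cα trace of an author-numbered range."""
    seq_ids = [r.seq_id for r in ensemble.residues(model_index, chain)
               if start_seq <= r.seq_id <= end_seq]
    ca = select_atoms(ensemble, model_index, chain, seq_ids, ["CA"])
    axes = local_axes(ca)
    return HelixSegment(
        chain=chain,
        start_seq=start_seq,
        end_seq=end_seq,
        local_axes=axes,
        global_axis=global_axis(axes),
        n_ca=len(ca),
    )


def interhelix_angle(seg_a: HelixSegment, seg_b: HelixSegment) -> float:
    """Undirected angle (degrees, [0, 90]) between two segment axes."""
    u = seg_a.global_axis
    v = seg_b.global_axis
    cosang = abs(float(np.dot(u, v)))
    return float(np.degrees(np.arccos(min(1.0, cosang))))
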