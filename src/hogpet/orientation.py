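"""Orientation quantization of 3D gradients onto Platonic-solid face centers.

A gradient votes into histogram bins by projecting its unit direction onto
the face-center axes of a regular polyhedron (Eq.-style: q_hat = P g/|g|).
Projections are thresholded at the adjacent-face cosine t so that a gradient
exactly aligned with a face center votes in that bin alone, then the
surviving weights are rescaled to carry the gradient's full magnitude.

Half-orientation mode folds antipodal directions together by keeping one
face per antipodal pair and taking absolute projections, which makes the
resulting histograms invariant to intensity inversion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import NonFiniteDataError, UnsupportedPolyhedronError

__all__ = [
    "OrientationPolyhedron",
    "make_polyhedron",
    "quantize_gradient",
    "quantize_gradients",
    "N_FACES",
]

logger = logging.getLogger(__name__)

PHI = (1.0 + np.sqrt(5.0)) / 2.0

N_FACES = {
    "tetrahedron": 4,
    "hexahedron": 6,
    "octahedron": 8,
    "dodecahedron": 12,
    "icosahedron": 20,
}


def _cyclic(v: tuple[float, float, float]) -> list[tuple[float, float, float]]:
    a, b, c = v
    return [(a, b, c), (c, a, b), (b, c, a)]


def _icosahedron_faces() -> np.ndarray:
    """20 face-center directions = the vertices of the dual dodecahedron:
    (±1, ±1, ±1) plus cyclic permutations of (0, ±1/φ, ±φ)."""
    pts: list[tuple[float, float, float]] = []
    for sx in (1, -1):
        for sy in (1, -1):
            for sz in (1, -1):
                pts.append((sx, sy, sz))
    for sb in (1, -1):
        for sc in (1, -1):
            pts.extend(_cyclic((0.0, sb / PHI, sc * PHI)))
    return np.array(pts, dtype=np.float64)


def _dodecahedron_faces() -> np.ndarray:
    """12 face-center directions = the vertices of the dual icosahedron:
    cyclic permutations of (0, ±1, ±φ)."""
    pts: list[tuple[float, float, float]] = []
    for sb in (1, -1):
        for sc in (1, -1):
            pts.extend(_cyclic((0.0, float(sb), sc * PHI)))
    return np.array(pts, dtype=np.float64)


_FACE_BUILDERS = {
    "icosahedron": _icosahedron_faces,
    "dodecahedron": _dodecahedron_faces,
}


@dataclass
class OrientationPolyhedron:
    """Face-center matrix P, projection threshold t and orientation mode.

    Attributes
    ----------
    kind:
        Polyhedron name.
    P:
        (n_bins, 3) unit face-center directions actually used for voting
        (after antipodal folding when ``half`` is set).
    full_faces:
        (n_faces, 3) complete unit face set, kept for geometry export.
    half:
        Whether antipodal directions share a bin.
    t:
        Adjacent-face cosine: max dot product over distinct, non-antipodal
        face pairs of the full set.
    """

    kind: str
    P: np.ndarray
    full_faces: np.ndarray
    half: bool
    t: float
    fallback_count: int = field(default=0, compare=False)

    @property
    def n_bins(self) -> int:
        return self.P.shape[0]

    @property
    def n_faces(self) -> int:
        return self.full_faces.shape[0]

    def geometry_json(self) -> str:
        """Export face coordinates and threshold for cross-checking."""
        return json.dumps(
            {
                "kind": self.kind,
                "half": self.half,
                "threshold": self.t,
                "bin_directions": self.P.tolist(),
                "full_faces": self.full_faces.tolist(),
            },
            indent=2,
        )


def _adjacent_cosine(faces: np.ndarray) -> float:
    """Max pairwise dot product over distinct non-antipodal unit faces."""
    dots = faces @ faces.T
    n = faces.shape[0]
    best = -np.inf
    for i in range(n):
        for j in range(i + 1, n):
            if dots[i, j] > -1.0 + 1e-9:  # skip antipodal pairs
                best = max(best, dots[i, j])
    return float(best)


def _fold_antipodal(faces: np.ndarray) -> np.ndarray:
    """Keep one face per antipodal pair (the lexicographically larger one)."""
    kept: list[np.ndarray] = []
    used = np.zeros(faces.shape[0], dtype=bool)
    for i in range(faces.shape[0]):
        if used[i]:
            continue
        anti = np.argmin(faces @ faces[i])
        used[i] = used[anti] = True
        rep = faces[i] if tuple(faces[i]) >= tuple(faces[anti]) else faces[anti]
        kept.append(rep)
    return np.array(kept)


def make_polyhedron(
    kind: str, half: bool = True, recompute_half_threshold: bool = False
) -> OrientationPolyhedron:
    """Build an orientation quantizer for a dodecahedron or icosahedron.

    Parameters
    ----------
    kind:
        "dodecahedron" (12 faces) or "icosahedron" (20 faces). The other
        Platonic solids are valid orientation sets in principle but are not
        provided here.
    half:
        Fold antipodal directions into shared bins (n_bins = n_faces/2).
    recompute_half_threshold:
        If true, recompute the adjacency cosine on the folded face set
        instead of inheriting the full-set threshold.
    """
    if kind not in _FACE_BUILDERS:
        raise UnsupportedPolyhedronError(
            f"unsupported polyhedron {kind!r}; choose from {sorted(_FACE_BUILDERS)}"
        )
    faces = _FACE_BUILDERS[kind]()
    faces = faces / np.linalg.norm(faces, axis=1, keepdims=True)
    t = _adjacent_cosine(faces)
    P = faces
    if half:
        P = _fold_antipodal(faces)
        if recompute_half_threshold:
            t = _adjacent_cosine(P)
    return OrientationPolyhedron(kind=kind, P=P, full_faces=faces, half=half, t=t)


def quantize_gradients(g: np.ndarray, poly: OrientationPolyhedron) -> np.ndarray:
    """Quantize (N, 3) gradients into (N, n_bins) magnitude-carrying votes.

    For each nonzero gradient: project the unit direction onto the bin axes
    (absolute value in half mode), subtract the threshold t, clip at zero,
    and rescale so the vote's L2 norm equals the gradient magnitude. Zero
    gradients yield zero votes. If thresholding annihilates every bin for a
    nonzero gradient (not observed for these solids, but guarded), the full
    magnitude goes to the best-aligned bin (lowest index on ties) and the
    event is counted on ``poly.fallback_count``.
    """
    g = np.atleast_2d(np.asarray(g, dtype=np.float64))
    if not np.all(np.isfinite(g)):
        raise NonFiniteDataError("gradient contains non-finite values")
    norms = np.linalg.norm(g, axis=1)
    votes = np.zeros((g.shape[0], poly.n_bins))
    nz = norms > 0
    if not np.any(nz):
        return votes
    unit = g[nz] / norms[nz, None]
    qhat = unit @ poly.P.T
    if poly.half:
        qhat = np.abs(qhat)
    # Strictly-greater comparison with a tiny tolerance: a projection that
    # ties the adjacency cosine exactly (face-aligned gradient) must not
    # leak an O(eps) vote into the neighbouring bin.
    qthr = qhat - poly.t
    qthr[qthr <= 1e-12] = 0.0
    row = np.linalg.norm(qthr, axis=1)
    ok = row > 0
    out = np.zeros_like(qthr)
    out[ok] = qthr[ok] / row[ok, None]
    if np.any(~ok):
        # Degenerate: threshold wiped every projection; vote fully in argmax.
        idx = np.argmax(qhat[~ok], axis=1)
        out[np.flatnonzero(~ok), idx] = 1.0
        poly.fallback_count += int((~ok).sum())
        logger.warning("orientation fallback used for %d gradients", int((~ok).sum()))
    votes[nz] = out * norms[nz, None]
    return votes


def quantize_gradient(g: np.ndarray, poly: OrientationPolyhedron) -> np.ndarray:
    """Quantize a single 3-vector gradient into a length-n_bins vote."""
    return quantize_gradients(np.asarray(g, dtype=np.float64).reshape(1, 3), poly)[0]
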