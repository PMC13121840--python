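"""Echelon rotation and reference alignment of latent configurations.

Euclidean distances — and hence the LSIRM likelihood — are invariant under any
common orthogonal transformation of the person and item coordinates.  The
echelon rotation removes this indeterminacy deterministically: composed plane
(Givens) rotations zero the upper triangle of the leading item-coordinate
rows, so that item 1 loads only on dimension 1, item 2 on dimensions 1-2, and
so on (D(D-1)/2 zeros in total), mirroring echelon-structured factor loadings.
Reflection indeterminacy is removed by a per-dimension sign convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import orthogonal_procrustes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RotationRecord:
    """The orthogonal transformation applied on the right of W and Z.

    ``R`` is the composed plane rotation; ``angles`` lists each Givens angle
    with its (axis_a, axis_b) plane; ``sign_flips`` holds the per-dimension
    reflection (+1/-1) applied after rotating.
    """

    R: np.ndarray
    angles: tuple[tuple[int, int, float], ...] = ()
    sign_flips: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    @property
    def full_transform(self) -> np.ndarray:
        """Rotation and reflections combined: W_out = W @ full_transform."""
        return self.R * self.sign_flips[None, :]


def echelon_zero_pattern(D: int) -> list[tuple[int, int]]:
    """(row, col) positions of W fixed at zero: col > row for rows 0..D-2."""
    return [(j, d) for j in range(D - 1) for d in range(j + 1, D)]


def echelon_rotate(
    W: np.ndarray, Z: np.ndarray, anchor_items: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, RotationRecord]:
    """Rotate (W, Z) to the echelon-identified orientation.

    Parameters
    ----------
    W, Z
        Item (J x D) and person (N x D) coordinates.
    anchor_items
        Indices of the D-1 items carrying the zero constraints; defaults to
        the first D-1 items.  The sign convention additionally uses item D-1
        (0-based) for the last dimension.

    Returns
    -------
    (W', Z', RotationRecord) with W'[j, d] = 0 for d > j over the anchor rows,
    W'[d, d] >= 0 for d = 0..D-1, and all pairwise distances preserved.
    """
    W = np.array(W, dtype=np.float64)
    Z = np.array(Z, dtype=np.float64)
    J, D = W.shape
    if J < D:
        raise ValueError(f"need at least D={D} items, got J={J}")
    if anchor_items is None:
        anchor_items = np.arange(D)
    anchor_items = np.asarray(anchor_items, dtype=int)

    R = np.eye(D)
    angles: list[tuple[int, int, float]] = []
    # Zero entry (anchor j, column d) via a rotation in the (d-1, d) plane,
    # sweeping columns right-to-left; earlier anchors hold only zeros in the
    # touched columns, so their pattern survives.
    for j in range(D - 1):
        row = anchor_items[j]
        if not np.any(W[row]):
            logger.warning(
                "echelon rotation: anchor item %d has zero norm; angles "
                "undefined, identity used",
                row,
            )
            continue
        for d in range(D - 1, j, -1):
            a, b = d - 1, d
            x, y = W[row, a], W[row, b]
            if y == 0.0:  # target entry already zero
                continue
            r = np.hypot(x, y)
            c, s = x / r, y / r
            G = np.eye(D)
            G[a, a] = c
            G[b, b] = c
            G[a, b] = -s
            G[b, a] = s
            W = W @ G
            Z = Z @ G
            R = R @ G
            angles.append((a, b, float(np.arctan2(y, x))))

    # Reflection convention: diagonal of the anchor block nonnegative.
    flips = np.ones(D)
    for d in range(D):
        row = anchor_items[d] if d < len(anchor_items) else d
        if W[row, d] < 0:
            flips[d] = -1.0
    W = W * flips[None, :]
    Z = Z * flips[None, :]
    return W, Z, RotationRecord(R=R, angles=tuple(angles), sign_flips=flips)


def align_to_reference(
    W: np.ndarray, Z: np.ndarray, W_ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate/reflect (W, Z) to best match a reference item configuration.

    Solves the orthogonal Procrustes problem min_Q ||W Q - W_ref||_F over
    orthogonal Q (rotations and reflections, no scaling) and applies Q to
    both W and Z, preserving all distances.  Falls back to the echelon
    rotation when the cross-product matrix is rank deficient.
    """
    W = np.asarray(W, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    W_ref = np.asarray(W_ref, dtype=np.float64)
    if W.shape != W_ref.shape:
        raise ValueError(f"shape mismatch: {W.shape} vs {W_ref.shape}")
    M = W.T @ W_ref
    if np.linalg.matrix_rank(M) < W.shape[1]:
        logger.warning(
            "reference alignment: rank-deficient cross-product; "
            "falling back to echelon rotation"
        )
        Wr, Zr, _ = echelon_rotate(W, Z)
        return Wr, Zr
    Q, _ = orthogonal_procrustes(W, W_ref)
    return W @ Q, Z @ Q
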