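"""Per-channel importance of a learned projection, with scalp-map export.

The full map from vectorized trial features to the learned metric space is
the composition ``B = (Q s) A`` of the PCA conditioning (loadings ``Q`` and
total-variance scale ``s``) with the metric learner's matrix ``A``. Because
Euclidean distances in the projected space are invariant to any orthogonal
right-rotation of ``B``, the columns are first made canonical through the
SVD ``B = U D V^T``: the sorted projection ``B~ = U D`` orders the learned
dimensions by singular value and is unique up to sign (fixed here by making
the largest-magnitude entry of each left singular vector positive).

The *importance* of channel ``ch_k`` for projected dimension ``j`` is the
fraction of the squared norm of column ``j`` of ``B~`` carried by the rows
belonging to that channel:

    importance(ch_k, j) = sum_{i in I_k} B~_ij^2 / sum_{i'} B~_i'j^2

Each column of the per-dimension map therefore sums to one over channels;
the overall importance is the uniform average over the ``p`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCALP_COORDS_1020",
    "SortedProjection",
    "ImportanceMap",
    "compose_projection",
    "sort_projection",
    "channel_importance",
    "scalp_field",
    "topomap_export",
]

#: 2-D scalp positions (x = left->right, y = back->front) for the 21-channel
#: 10/20 layout, azimuthal-equidistant projection of the standard montage;
#: A1/A2 sit at the ear positions.
SCALP_COORDS_1020: dict[str, tuple[float, float]] = {
    "Fp1": (-0.546, 1.556), "Fp2": (0.547, 1.556),
    "F3": (-0.720, 0.761), "F4": (0.741, 0.776),
    "F7": (-1.463, 0.884), "F8": (1.461, 0.889),
    "Fz": (0.004, 0.722),
    "C3": (-0.789, -0.140), "C4": (0.808, -0.131), "Cz": (0.004, -0.091),
    "T3": (-1.650, -0.314), "T4": (1.655, -0.292),
    "T5": (-1.120, -1.136), "T6": (1.128, -1.128),
    "P3": (-0.580, -0.862), "P4": (0.601, -0.848), "Pz": (0.003, -0.776),
    "O1": (-0.378, -1.446), "O2": (0.384, -1.445),
    "A1": (-2.132, -0.619), "A2": (2.133, -0.622),
}


@dataclass
class SortedProjection:
    """SVD-canonicalized composite projection.

    ``B_tilde = U D`` with singular values descending; ``B_tilde @ Vt``
    reconstructs ``B``.
    """

    B: np.ndarray
    B_tilde: np.ndarray
    singular_values: np.ndarray
    Vt: np.ndarray


@dataclass
class ImportanceMap:
    """Per-channel importance, per projected dimension and overall."""

    per_dim: np.ndarray  # (n_channels, p)
    overall: np.ndarray  # (n_channels,)
    channels: tuple[str, ...]
    degenerate_dims: tuple[int, ...] = ()
    provenance: dict = field(default_factory=dict)


def compose_projection(pca, learner) -> np.ndarray:
    """Composite map ``B = (Q s) A`` from features to the learned space.

    ``pca`` is a fitted :class:`~eegmetric.features.TotalVariancePCA` (or
    ``None`` for no conditioning) and ``learner`` a fitted metric learner
    (or a bare ``A`` matrix).
    """
    A = learner if isinstance(learner, np.ndarray) else learner.A_
    if pca is None:
        return np.asarray(A, dtype=float)
    Q = pca.loading_matrix_
    if Q.shape[1] != A.shape[0]:
        raise ValueError(
            f"PCA output dimension {Q.shape[1]} does not match the learner "
            f"input dimension {A.shape[0]}"
        )
    return Q @ A


def sort_projection(B: np.ndarray) -> SortedProjection:
    """SVD sort: descending singular values, deterministic signs."""
    B = np.asarray(B, dtype=float)
    if B.ndim != 2:
        raise ValueError(f"B must be 2-D, got shape {B.shape}")
    if not np.any(B):
        raise ValueError("cannot sort an all-zero projection matrix")
    U, D, Vt = np.linalg.svd(B, full_matrices=False)
    # sign convention: largest-magnitude entry of each left singular vector
    # is positive, so repeated runs produce identical maps
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    return SortedProjection(B=B, B_tilde=U * D, singular_values=D, Vt=Vt)


def channel_importance(
    sp: SortedProjection, channel_index_map: dict[str, np.ndarray]
) -> ImportanceMap:
    """Eq.-style squared-weight fractions per channel and dimension.

    A dimension with zero singular value has no weight anywhere (0/0); it is
    assigned the uninformative uniform value 1/n_channels and flagged.
    """
    Bt = sp.B_tilde
    cols = np.concatenate([np.asarray(v) for v in channel_index_map.values()])
    if sorted(cols) != list(range(Bt.shape[0])):
        raise ValueError("channel_index_map must partition the rows of B_tilde")
    channels = tuple(channel_index_map)
    n_ch, p = len(channels), Bt.shape[1]
    sq = Bt**2
    denom = sq.sum(axis=0)
    per_dim = np.empty((n_ch, p))
    degenerate = []
    for j in range(p):
        if denom[j] <= 0:
            per_dim[:, j] = 1.0 / n_ch
            degenerate.append(j)
        else:
            for k, ch in enumerate(channels):
                per_dim[k, j] = sq[channel_index_map[ch], j].sum() / denom[j]
    return ImportanceMap(
        per_dim=per_dim,
        overall=per_dim.mean(axis=1),
        channels=channels,
        degenerate_dims=tuple(degenerate),
    )


def scalp_field(
    values: np.ndarray,
    channels: tuple[str, ...],
    resolution: int = 64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate per-channel values onto a 2-D scalp grid.

    Returns ``(grid_x, grid_y, field)``; points outside the convex hull of
    the electrodes are NaN. Raises if a channel has no known position.
    """
    from scipy.interpolate import griddata

    unknown = [c for c in channels if c not in SCALP_COORDS_1020]
    if unknown:
        raise ValueError(
            f"no scalp position for {unknown}; resolvable names: "
            f"{sorted(SCALP_COORDS_1020)}"
        )
    pos = np.array([SCALP_COORDS_1020[c] for c in channels])
    lim = 1.05 * np.abs(pos).max()
    gx, gy = np.meshgrid(
        np.linspace(-lim, lim, resolution), np.linspace(-lim, lim, resolution)
    )
    field = griddata(pos, np.asarray(values, dtype=float), (gx, gy), method="linear")
    return gx, gy, field


def topomap_export(imp: ImportanceMap, out_dir, stem: str = "importance") -> list[Path]:
    """Write the importance map as CSV plus rendered scalp images.

    One CSV holds the overall and per-dimension values; one PNG is rendered
    for the overall map and one per projected dimension.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = imp.per_dim.shape[1]
    table = pd.DataFrame({"channel": list(imp.channels), "overall": imp.overall})
    for j in range(p):
        table[f"dim_{j + 1}"] = imp.per_dim[:, j]
    csv_path = out_dir / f"{stem}.csv"
    table.to_csv(csv_path, index=False)
    written.append(csv_path)

    maps = [("overall", imp.overall)] + [
        (f"dim_{j + 1}", imp.per_dim[:, j]) for j in range(p)
    ]
    pos = np.array([SCALP_COORDS_1020[c] for c in imp.channels])
    for name, values in maps:
        gx, gy, field = scalp_field(values, imp.channels)
        fig, ax = plt.subplots(figsize=(4, 4))
        pc = ax.pcolormesh(gx, gy, field, shading="auto", cmap="viridis")
        ax.scatter(pos[:, 0], pos[:, 1], s=12, c="k", zorder=3)
        for (x, y), ch in zip(pos, imp.channels):
            ax.annotate(ch, (x, y), fontsize=6, ha="center", va="bottom")
        ax.set_aspect("equal")
        ax.set_axis_off()
        ax.set_title(f"importance — {name}")
        fig.colorbar(pc, ax=ax, shrink=0.75)
        png_path = out_dir / f"{stem}_{name}.png"
        fig.savefig(png_path, dpi=110, bbox_inches="tight")
        plt.close(fig)
        written.append(png_path)
    return written
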