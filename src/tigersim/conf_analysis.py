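"""Ensemble analysis: dPCA / distance-PCA free-energy landscapes.

The pipeline mirrors standard practice for replica-exchange ensembles:
dihedral angles are mapped to (cos, sin) pairs (dPCA, avoiding periodicity
artifacts) or inter-chain heavy-pair distances are z-scored; PCA reduces the
features; the first two principal components are histogrammed (30x30 bins by
default) and Boltzmann-inverted, ``dG = -kT ln(p / p_max)``, into a relative
free-energy landscape.  A mutant ensemble is *projected onto the reference
(wild-type) axes* — reusing the reference normalization statistics, mean and
components, and the reference bin edges — so both ensembles are drawn on one
comparable landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .constants import KB

__all__ = [
    "FeatureMatrix",
    "PrincipalAxes",
    "Landscape",
    "DisconnectedBasinsError",
    "dpca_features",
    "interchain_distance_features",
    "fit_pca",
    "project",
    "boltzmann_landscape",
    "barrier_height",
    "minimum_bin",
    "bin_occupancy",
    "plot_landscape",
]

DEFAULT_KT = KB * 280.0  # baseline temperature of the sampling protocols


@dataclass
class FeatureMatrix:
    """Frames x features with the normalization statistics used.

    ``raw`` holds the untransformed feature values; ``normalized`` applies
    the stored per-feature mean/std (identity when ``mean is None``).
    ``flags`` marks zero-variance features (kept, scaled by 1).
    """

    raw: np.ndarray
    kind: str = "generic"
    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    flags: np.ndarray | None = None

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2:
            raise ValueError("feature matrix must be 2D (frames x features)")
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def normalized(self) -> np.ndarray:
        if self.mean is None:
            return self.raw
        return (self.raw - self.mean) / self.std

    @property
    def n_frames(self) -> int:
        return self.raw.shape[0]

    @property
    def n_features(self) -> int:
        return self.raw.shape[1]


def dpca_features(dihedrals) -> FeatureMatrix:
    """Map each angle theta (degrees) to the pair (cos theta, sin theta).

    Columns are ordered (cos a1, sin a1, cos a2, sin a2, ...); no further
    normalization is applied.
    """
    ang = np.atleast_2d(np.asarray(dihedrals, dtype=float))
    if ang.size == 0:
        raise ValueError("empty dihedral input")
    rad = np.deg2rad(ang)
    out = np.empty((ang.shape[0], 2 * ang.shape[1]))
    out[:, 0::2] = np.cos(rad)
    out[:, 1::2] = np.sin(rad)
    return FeatureMatrix(raw=out, kind="dpca")


def interchain_distance_features(frames, chain_a, chain_b, normalize: bool = True,
                                 box_length=None, symmetrize: bool = False) -> FeatureMatrix:
    """One feature per (a in A, b in B) pair: the Euclidean distance (nm).

    With ``normalize`` each feature is z-scored by the ensemble mean and
    standard deviation (recorded in the matrix so a second ensemble can be
    normalized with *these* statistics); zero-variance features are kept,
    scaled by 1 and flagged.  ``symmetrize`` averages each feature with its
    chain-swapped partner (homodimer A<->B relabelling symmetry; off by
    default — chain labels are taken from topology).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:  # single frame
        frames = frames[None]
    chain_a = np.asarray(chain_a, dtype=int)
    chain_b = np.asarray(chain_b, dtype=int)
    if chain_a.size == 0 or chain_b.size == 0:
        raise ValueError("both chains must be non-empty")
    d = frames[:, chain_a, None, :] - frames[:, None, chain_b, :]
    if box_length is not None:
        d -= box_length * np.round(d / box_length)
    dist = np.sqrt(np.einsum("fabk,fabk->fab", d, d))
    if symmetrize:
        if chain_a.size != chain_b.size:
            raise ValueError("symmetrize requires equal-length chains")
        dist = 0.5 * (dist + dist.swapaxes(1, 2))
    raw = dist.reshape(frames.shape[0], -1)
    if not normalize:
        return FeatureMatrix(raw=raw, kind="interchain_distance")
    mean = raw.mean(axis=0)
    std = raw.std(axis=0)
    flags = std == 0.0
    std = np.where(flags, 1.0, std)
    return FeatureMatrix(raw=raw, kind="interchain_distance", mean=mean, std=std, flags=flags)


@dataclass
class PrincipalAxes:
    """Mean, orthonormal components and the fitting ensemble's normalization.

    Projecting a second ensemble through these axes uses the *stored*
    feature normalization and mean, never the new ensemble's own statistics.
    """

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features)
    explained_variance: np.ndarray
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None
    kind: str = "generic"

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "feature_mean": None if self.feature_mean is None else self.feature_mean.tolist(),
            "feature_std": None if self.feature_std is None else self.feature_std.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrincipalAxes":
        conv = lambda v: None if v is None else np.asarray(v, dtype=float)
        return cls(
            mean=conv(d["mean"]),
            components=conv(d["components"]),
            explained_variance=conv(d["explained_variance"]),
            feature_mean=conv(d.get("feature_mean")),
            feature_std=conv(d.get("feature_std")),
            kind=d.get("kind", "generic"),
        )


def fit_pca(features: FeatureMatrix, n_components: int) -> PrincipalAxes:
    """Mean-centred covariance eigendecomposition of the normalized features.

    Components are sorted by explained variance; the sign of each component
    is fixed so its largest-magnitude loading is positive.
    """
    x = features.normalized
    if n_components > x.shape[1]:
        raise ValueError("n_components exceeds feature count")
    if x.shape[0] <= n_components:
        raise ValueError("need more frames than components")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x)
    comps = pca.components_.copy()
    for row in comps:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return PrincipalAxes(
        mean=pca.mean_,
        components=comps,
        explained_variance=pca.explained_variance_.copy(),
        feature_mean=features.mean,
        feature_std=features.std,
        kind=features.kind,
    )


def project(features: FeatureMatrix, axes: PrincipalAxes) -> np.ndarray:
    """Scores (frames x components) of features on previously fitted axes.

    The raw features are normalized with the axes' stored statistics (not
    their own), centred by the axes' mean, then projected.
    """
    raw = features.raw
    if raw.shape[1] != axes.components.shape[1]:
        raise ValueError(
            f"feature dimensionality {raw.shape[1]} does not match axes "
            f"({axes.components.shape[1]})"
        )
    x = raw if axes.feature_mean is None else (raw - axes.feature_mean) / axes.feature_std
    return (x - axes.mean) @ axes.components.T


@dataclass
class Landscape:
    """Binned probability and Boltzmann-inverted dG over the first two PCs."""

    edges_x: np.ndarray
    edges_y: np.ndarray
    probability: np.ndarray  # (bins_x, bins_y), sums to 1 over unmasked bins
    delta_g: np.ndarray  # kcal/mol, min over unmasked = 0; masked bins = nan
    kt: float
    mask: np.ndarray  # True where the bin is empty
    n_frames: int = 0  # frames inside the axes range
    n_total: int = 0  # all frames offered (>= n_frames when a range is imposed)

    @property
    def axes_range(self):
        return ((self.edges_x[0], self.edges_x[-1]), (self.edges_y[0], self.edges_y[-1]))


class DisconnectedBasinsError(RuntimeError):
    """No unmasked 8-connected path joins the two requested bins."""


def boltzmann_landscape(scores, bins: int = 30, kt: float = DEFAULT_KT,
                        axes_range=None) -> Landscape:
    """Boltzmann inversion of the 2D histogram of the first two score columns.

    ``dG = -kT ln(p / p_max)`` referenced to the modal bin; empty bins are
    masked (nan), not pseudo-counted.  Pass ``axes_range`` so that a mutant
    landscape shares the reference bin edges.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("scores must have at least two columns")
    if scores.shape[0] < 1:
        raise ValueError("need at least one frame")
    if bins < 2:
        raise ValueError("need at least 2 bins per axis")
    hist, ex, ey = np.histogram2d(scores[:, 0], scores[:, 1], bins=bins, range=axes_range)
    total = hist.sum()
    mask = hist == 0
    if total == 0:
        # an imposed range can exclude every frame: fully masked landscape
        p = hist
        dg = np.full_like(hist, np.nan)
    else:
        p = hist / total
        with np.errstate(divide="ignore"):
            dg = -kt * np.log(p / p.max())
        dg[mask] = np.nan
    return Landscape(
        edges_x=ex, edges_y=ey, probability=p, delta_g=dg, kt=kt, mask=mask,
        n_frames=int(total), n_total=scores.shape[0],
    )


def minimum_bin(landscape: Landscape) -> tuple[int, int]:
    """Indices of the modal (dG = 0) bin."""
    idx = np.unravel_index(np.nanargmax(landscape.probability), landscape.probability.shape)
    return int(idx[0]), int(idx[1])


def bin_occupancy(landscape: Landscape, bin_idx, neighborhood: int = 0) -> float:
    """Probability mass in a bin (optionally including a square neighbourhood)."""
    i, j = bin_idx
    nb = landscape.probability[
        max(0, i - neighborhood) : i + neighborhood + 1,
        max(0, j - neighborhood) : j + neighborhood + 1,
    ]
    return float(nb.sum())


class _DisjointSet:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def barrier_height(landscape: Landscape, bin_a, bin_b) -> float:
    """Minimax-path barrier between two unmasked bins (kcal/mol).

    Over all 8-connected paths through unmasked bins, the minimum of the
    maximum dG along the path, minus dG at the start bin.  Implemented by
    adding bins in ascending dG to a union-find until the two bins connect.
    """
    dg = landscape.delta_g
    nx, ny = dg.shape
    a = (int(bin_a[0]), int(bin_a[1]))
    b = (int(bin_b[0]), int(bin_b[1]))
    for name, idx in (("A", a), ("B", b)):
        if not (0 <= idx[0] < nx and 0 <= idx[1] < ny):
            raise IndexError(f"bin {name} {idx} outside the grid")
        if landscape.mask[idx]:
            raise ValueError(f"bin {name} {idx} is masked (empty)")
    if a == b:
        return 0.0
    flat = lambda ij: ij[0] * ny + ij[1]
    order = sorted(
        ((dg[i, j], i, j) for i in range(nx) for j in range(ny) if not landscape.mask[i, j])
    )
    dsu = _DisjointSet(nx * ny)
    active = np.zeros((nx, ny), dtype=bool)
    for g, i, j in order:
        active[i, j] = True
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if 0 <= ni < nx and 0 <= nj < ny and active[ni, nj]:
                dsu.union(flat((i, j)), flat((ni, nj)))
        if active[a] and active[b] and dsu.find(flat(a)) == dsu.find(flat(b)):
            return float(g - dg[a])
    raise DisconnectedBasinsError(f"no unmasked path connects {a} and {b}")


def plot_landscape(landscape: Landscape, path=None, title: str | None = None,
                   highlight_bin=None):
    """Render the dG landscape as a heat map; saves to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    x, y = np.meshgrid(landscape.edges_x, landscape.edges_y, indexing="ij")
    pm = ax.pcolormesh(x, y, np.ma.masked_invalid(landscape.delta_g), cmap="viridis")
    fig.colorbar(pm, ax=ax, label=r"$\Delta G$ (kcal/mol)")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if highlight_bin is not None:
        i, j = highlight_bin
        cx = 0.5 * (landscape.edges_x[i] + landscape.edges_x[i + 1])
        cy = 0.5 * (landscape.edges_y[j] + landscape.edges_y[j + 1])
        ax.plot(cx, cy, "ro", markersize=10, fillstyle="none", markeredgewidth=2)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
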