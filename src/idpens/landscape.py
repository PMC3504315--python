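"""Two-dimensional free-energy landscapes and basin decomposition.

The free energy of a state along reaction coordinates (q, p) is estimated
from the joint probability distribution of an ensemble:

    G(q, p) = -kT ln P(q, p)

with P taken from a 2-D histogram, G shifted so its minimum over populated
bins is zero, and unpopulated bins masked (not set to +inf, so that no
infinities propagate into the basin search).  Basins are found by
steepest-descent assignment of every populated bin to its local minimum
over 8-neighborhoods, followed by watershed-style merging of minima whose
depth (lowest saddle minus basin minimum) falls below a threshold.

The operations are coordinate-agnostic: principal components, solvent
accessibility, or any other per-frame scalar can serve as an axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BOLTZMANN_KJ_PER_MOL_K",
    "FreeEnergySurface",
    "Basin",
    "BasinSet",
    "estimate_fel",
    "detect_basins",
    "assign_frames_to_basins",
]

#: Boltzmann constant in kJ/(mol K)
BOLTZMANN_KJ_PER_MOL_K = 0.0083145

UNASSIGNED = "unassigned"


@dataclass
class FreeEnergySurface:
    """Gridded free energies (kJ/mol); NaN marks unpopulated bins."""

    grid: np.ndarray  # (Nx, Ny), kJ/mol, NaN where unpopulated
    x_edges: np.ndarray
    y_edges: np.ndarray
    kT: float
    n_frames: int
    coordinates: tuple[str, str] = ("q1", "q2")

    @property
    def populated(self) -> np.ndarray:
        return ~np.isnan(self.grid)

    def probabilities(self) -> np.ndarray:
        """Re-exponentiated, renormalized bin probabilities (NaN where empty)."""
        p = np.exp(-self.grid / self.kT)
        p = p / np.nansum(p)
        return p

    def bin_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Map coordinates to flat (ix, iy) bin indices; -1 if out of range."""
        ix = np.searchsorted(self.x_edges, x, side="right") - 1
        iy = np.searchsorted(self.y_edges, y, side="right") - 1
        nx = len(self.x_edges) - 1
        ny = len(self.y_edges) - 1
        # points exactly on the upper edge belong to the last bin
        ix = np.where(np.asarray(x) == self.x_edges[-1], nx - 1, ix)
        iy = np.where(np.asarray(y) == self.y_edges[-1], ny - 1, iy)
        bad = (ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)
        out = np.stack([ix, iy], axis=-1)
        out[bad] = -1
        return out


@dataclass
class Basin:
    label: str
    bins: set[tuple[int, int]]
    min_bin: tuple[int, int]
    min_g: float
    population: float
    minor: bool = False
    frame_indices: np.ndarray | None = None


@dataclass
class BasinSet:
    basins: list[Basin]
    min_depth: float
    min_population: float

    def label_of_bin(self) -> dict[tuple[int, int], str]:
        out = {}
        for b in self.basins:
            for bb in b.bins:
                out[bb] = b.label
        return out

    def __len__(self) -> int:
        return len(self.basins)


def estimate_fel(
    x: np.ndarray,
    y: np.ndarray,
    bins: tuple[int, int] = (32, 32),
    temperature_K: float = 300.0,
    pad_fraction: float = 0.02,
    coordinates: tuple[str, str] = ("q1", "q2"),
) -> FreeEnergySurface:
    """Estimate G = -kT ln P over a 2-D histogram of (x, y).

    The grid spans [min, max] of each coordinate padded by ``pad_fraction``
    of the range; G is shifted so the global minimum is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("reaction coordinates contain non-finite values")
    nx, ny = int(bins[0]), int(bins[1])
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 bins per axis")

    def _edges(v: np.ndarray, n: int) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo
        if span == 0.0:
            span = max(abs(lo), 1.0)
            lo -= 0.5 * span
            hi += 0.5 * span
        pad = pad_fraction * span
        return np.linspace(lo - pad, hi + pad, n + 1)

    x_edges = _edges(x, nx)
    y_edges = _edges(y, ny)
    counts, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    kT = BOLTZMANN_KJ_PER_MOL_K * float(temperature_K)
    P = counts / x.size
    with np.errstate(divide="ignore"):
        G = -kT * np.log(P)
    G[counts == 0] = np.nan
    G -= np.nanmin(G)
    return FreeEnergySurface(G, x_edges, y_edges, kT, x.size, coordinates)


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _descend_labels(G: np.ndarray) -> dict[tuple[int, int], tuple[int, int]]:
    """Steepest-descent assignment: populated bin -> its local-minimum bin."""
    nx, ny = G.shape
    populated = ~np.isnan(G)

    def lowest_neighbor(b):
        i, j = b
        # strictly lower neighbors only; ties broken by bin index
        candidates = []
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if 0 <= ni < nx and 0 <= nj < ny and populated[ni, nj]:
                if G[ni, nj] < G[i, j]:
                    candidates.append((G[ni, nj], (ni, nj)))
        if not candidates:
            return b
        return min(candidates)[1]

    assignment: dict[tuple[int, int], tuple[int, int]] = {}
    for i in range(nx):
        for j in range(ny):
            if not populated[i, j]:
                continue
            path = []
            cur = (i, j)
            while cur not in assignment:
                path.append(cur)
                nxt = lowest_neighbor(cur)
                if nxt == cur:
                    assignment[cur] = cur
                    break
                cur = nxt
            root = assignment[cur] if cur in assignment else cur
            for b in path:
                assignment[b] = root
    return assignment


def detect_basins(
    fes: FreeEnergySurface,
    min_depth: float | None = None,
    min_population: float = 0.02,
) -> BasinSet:
    """Decompose a surface into basins around its local minima.

    Minima whose depth — lowest saddle to any adjacent basin minus the
    basin minimum — is below ``min_depth`` (default 1 kT) are merged into
    the neighbor across that saddle.  Basins whose population falls below
    ``min_population`` are flagged minor.  Labels A, B, C, ... are assigned
    by increasing basin minimum free energy.
    """
    if min_depth is None:
        min_depth = fes.kT
    G = fes.grid
    assignment = _descend_labels(G)
    basins: dict[tuple[int, int], set[tuple[int, int]]] = {}
    for b, root in assignment.items():
        basins.setdefault(root, set()).add(b)

    def saddles(root: tuple[int, int]):
        """(pass height, neighbor root) for each adjacent basin.

        A basin with no grid-adjacent neighbor (isolated across masked
        bins, e.g. outlier single-count bins) gets a *virtual* saddle to
        the basin with the closest bin: height = max G of the facing bin
        pair.  Deep, genuinely separated basins thus stay separate while
        sampling-noise islands can merge away.
        """
        out: dict[tuple[int, int], float] = {}
        for (i, j) in basins[root]:
            for di, dj in _NEIGHBORS:
                nb = (i + di, j + dj)
                if nb in assignment and assignment[nb] != root:
                    h = max(G[i, j], G[nb])
                    other = assignment[nb]
                    if other not in out or h < out[other]:
                        out[other] = h
        if not out and len(basins) > 1:
            own = np.array(sorted(basins[root]), dtype=float)
            best = None  # (distance, saddle height, other root)
            for other in sorted(basins):
                if other == root:
                    continue
                theirs = np.array(sorted(basins[other]), dtype=float)
                d2 = ((own[:, None, :] - theirs[None, :, :]) ** 2).sum(axis=2)
                k = np.unravel_index(np.argmin(d2), d2.shape)
                u = tuple(int(v) for v in own[k[0]])
                v = tuple(int(w) for w in theirs[k[1]])
                cand = (float(d2[k]), max(G[u], G[v]), other)
                if best is None or cand < best:
                    best = cand
            out[best[2]] = best[1]
        return out

    while len(basins) > 1:
        # find the shallowest basin below the depth threshold
        best = None  # (depth, root, target)
        for root in basins:
            sad = saddles(root)
            if not sad:
                continue
            target, h = min(sad.items(), key=lambda kv: (kv[1], kv[0]))
            depth = h - G[root]
            if depth < min_depth:
                if best is None or (depth, G[root], root) < (best[0], G[best[1]], best[1]):
                    best = (depth, root, target)
        if best is None:
            break
        _, root, target = best
        # merge into the neighbor across the lowest saddle; keep lower minimum
        keep = target if G[target] <= G[root] else root
        drop = root if keep is target else target
        basins[keep] |= basins[drop]
        del basins[drop]
        for b in assignment:
            if assignment[b] == drop:
                assignment[b] = keep

    roots = sorted(basins, key=lambda r: (G[r], r))
    out = []
    P = fes.probabilities()
    for k, root in enumerate(roots):
        label = _basin_label(k)
        pop = float(np.nansum([P[b] for b in basins[root]]))
        out.append(
            Basin(label, basins[root], root, float(G[root]), pop,
                  minor=pop < min_population)
        )
    return BasinSet(out, float(min_depth), float(min_population))


def _basin_label(k: int) -> str:
    # A..Z, then A1, B1, ...
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return letters[k % 26] + ("" if k < 26 else str(k // 26))


def assign_frames_to_basins(
    fes: FreeEnergySurface,
    basins: BasinSet,
    x: np.ndarray,
    y: np.ndarray,
) -> list[str]:
    """Per-frame basin label; frames in masked/out-of-range bins unassigned."""
    idx = fes.bin_of(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    label_of = basins.label_of_bin()
    labels = []
    for ix, iy in idx:
        if ix < 0:
            labels.append(UNASSIGNED)
        else:
            labels.append(label_of.get((int(ix), int(iy)), UNASSIGNED))
    for b in basins.basins:
        b.frame_indices = np.array(
            [i for i, lab in enumerate(labels) if lab == b.label], dtype=int
        )
    return labels
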