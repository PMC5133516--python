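"""Homozygosity intensity by a double-weight local polynomial model.

For each individual, the homozygosity indicator Y_i at ordered positions x_i
is smoothed with a locally weighted polynomial fit. At an anchor position x,
the coefficients minimise

    E(x) = sum_i K((x_i - x)/h) * L(MAF_i) * (Y_i - sum_j a_j (x_i - x)^j)^2

and the intensity estimate is lambda_hat(x) = a_0, clamped to [0, 1]. Two
weights enter: a cubic kernel K(u) = (1 - |u|^3)^3 on |u| < 1 that localises
the fit, and a locus weight L that down-weights rare variants (MAF < 0.05)
in proportion to MAF/0.05, because a common homozygote at a rare site carries
little information about runs of homozygosity.

Windows are nearest-neighbour: each anchor's window holds the k sites closest
in physical distance, with k = ceil(b/100 * m_c) for a chromosome with m_c
sites (b% = 5 by default), and the bandwidth h is set just beyond the k-th
neighbour distance so all members get a strictly positive kernel weight.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, compute_maf, homozygosity_indicator

RARE_MAF = 0.05

_H_SLACK = 1.0 + 1e-9  # h just beyond d_(k): k-th neighbour keeps |u| < 1


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window and fit configuration.

    b_percent : percentage of a chromosome's SNVs per window (default 5).
    degree : local polynomial order p (default 1, local linear).
    anchor_stride : evaluate at every ``anchor_stride``-th site (default 1).
    clamp : clamp the intercept estimate into [0, 1] (default True).
    """

    b_percent: float = 5.0
    degree: int = 1
    anchor_stride: int = 1
    clamp: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.b_percent <= 100:
            raise ValueError(f"b_percent must be in (0, 100], got {self.b_percent}")
        if self.degree < 0:
            raise ValueError(f"degree must be >= 0, got {self.degree}")
        if self.anchor_stride < 1:
            raise ValueError(f"anchor_stride must be >= 1, got {self.anchor_stride}")

    def window_size(self, m_c: int) -> int:
        return math.ceil(self.b_percent / 100.0 * m_c)


@dataclass
class Windows:
    """Nearest-neighbour windows over one chromosome's site positions.

    Members of window ``w`` are the contiguous index slice
    ``lo[w] .. hi[w]`` (inclusive); ``anchor[w]`` indexes the anchor site and
    ``h[w]`` its bandwidth in bp.
    """

    positions: np.ndarray
    anchor: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    h: np.ndarray
    k: int

    def __len__(self) -> int:
        return len(self.anchor)

    def members(self, w: int) -> np.ndarray:
        return np.arange(self.lo[w], self.hi[w] + 1)

    def span(self, w: int) -> tuple[float, float]:
        """Physical extent (bp) covered by window ``w``'s member sites."""
        return float(self.positions[self.lo[w]]), float(self.positions[self.hi[w]])


def build_windows(positions, spec: WindowSpec | None = None) -> Windows:
    """Construct nearest-neighbour windows at (strided) anchor SNVs.

    Each window holds the k sites with smallest physical distance to the
    anchor, ties broken toward the lower position. Because positions are
    sorted, members form a contiguous slice around the anchor; the bandwidth
    h is (1 + 1e-9) times the k-th neighbour distance so every member sits
    strictly inside the kernel support.
    """
    spec = spec or WindowSpec()
    x = np.asarray(positions, dtype=np.float64)
    m = len(x)
    if m < 2:
        raise ValueError("need at least 2 sites to build windows")
    if not np.all(np.diff(x) > 0):
        raise ValueError("positions must be strictly increasing")
    k = spec.window_size(m)
    if k > m:
        raise ValueError(
            f"window size k={k} exceeds the {m} sites on the chromosome; "
            "provide more sites or a smaller b_percent"
        )
    anchors = np.arange(0, m, spec.anchor_stride)
    lo = np.empty(len(anchors), dtype=np.int64)
    hi = np.empty(len(anchors), dtype=np.int64)
    h = np.empty(len(anchors), dtype=np.float64)
    for w, a in enumerate(anchors):
        i = j = a
        for _ in range(k - 1):
            d_left = x[a] - x[i - 1] if i > 0 else np.inf
            d_right = x[j + 1] - x[a] if j + 1 < m else np.inf
            if d_left <= d_right:  # tie -> lower position
                i -= 1
            else:
                j += 1
        lo[w], hi[w] = i, j
        d_k = max(x[a] - x[i], x[j] - x[a])
        h[w] = _H_SLACK * d_k if d_k > 0 else 1.0
    return Windows(positions=x, anchor=anchors, lo=lo, hi=hi, h=h, k=k)


def kernel_weight(u) -> np.ndarray | float:
    """Cubic kernel K(u) = (1 - |u|^3)^3 for |u| < 1, else 0 (tricube)."""
    u = np.abs(np.asarray(u, dtype=np.float64))
    w = np.where(u < 1.0, (1.0 - np.minimum(u, 1.0) ** 3) ** 3, 0.0)
    return w if w.ndim else float(w)


def locus_weight(maf) -> np.ndarray | float:
    """Rare-variant locus weight: 1 for MAF >= 0.05, else MAF/0.05.

    Undefined MAF (NaN, e.g. an all-missing site) gets weight 0, which
    removes the site from every fit.
    """
    maf = np.asarray(maf, dtype=np.float64)
    finite = maf[~np.isnan(maf)]
    if ((finite < 0) | (finite > 0.5)).any():
        bad = finite[(finite < 0) | (finite > 0.5)][0]
        raise ValueError(f"MAF must lie in [0, 0.5], got {bad}")
    w = np.where(np.isnan(maf), 0.0, np.minimum(maf / RARE_MAF, 1.0))
    return w if w.ndim else float(w)


@dataclass
class LocalPolyFit:
    """One window's fit: coefficients in the (x_i - x)^j basis."""

    alpha: np.ndarray
    intensity: float
    n_effective: int
    degree_used: int


def fit_local_polynomial(
    window_positions,
    anchor_position: float,
    h: float,
    y,
    site_weights,
    spec: WindowSpec | None = None,
) -> LocalPolyFit:
    """Weighted least-squares polynomial fit at one anchor (reference path).

    ``site_weights`` is the combined kernel x locus weight per member site.
    Missing responses (NaN) get zero weight. If fewer than degree + 1 sites
    carry positive weight, or the design is singular, the fit falls back to
    degree 0 (weighted mean); with no usable sites the intensity is NaN.
    """
    spec = spec or WindowSpec()
    x = np.asarray(window_positions, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    w = np.asarray(site_weights, dtype=np.float64).copy()
    w[np.isnan(y)] = 0.0
    usable = w > 0
    n_eff = int(usable.sum())
    u = (x - anchor_position) / h  # scaled offsets; alpha_0 is unaffected

    for degree in (spec.degree, 0):
        if n_eff < degree + 1:
            continue
        design = np.vander(u[usable], degree + 1, increasing=True)
        sw = np.sqrt(w[usable])
        coef, _, rank, _ = np.linalg.lstsq(design * sw[:, None], y[usable] * sw, rcond=None)
        if rank < degree + 1 and degree > 0:
            continue  # singular design: fall back to degree 0
        alpha = coef / h ** np.arange(degree + 1)  # back to (x_i - x)^j basis
        a0 = float(coef[0])
        if spec.clamp:
            a0 = min(max(a0, 0.0), 1.0)
        return LocalPolyFit(alpha=alpha, intensity=a0, n_effective=n_eff, degree_used=degree)
    return LocalPolyFit(
        alpha=np.full(spec.degree + 1, np.nan), intensity=np.nan,
        n_effective=n_eff, degree_used=-1,
    )


@dataclass
class HomozygosityProfile:
    """Per-individual homozygosity intensity at anchor SNVs, genome-wide.

    ``anchors`` has one row per anchor (chrom, pos); ``intensity`` is an
    (n_individuals x n_anchors) array in [0, 1] (NaN where a window was
    degenerate); ``individuals`` are IDs aligned to the rows.
    """

    anchors: pd.DataFrame
    intensity: np.ndarray = field(repr=False)
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.intensity[~np.isnan(self.intensity)]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("intensity values outside [0, 1]")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def for_chromosome(self, chrom) -> "HomozygosityProfile":
        mask = (self.anchors["chrom"] == chrom).to_numpy()
        return HomozygosityProfile(
            anchors=self.anchors.loc[mask].reset_index(drop=True),
            intensity=self.intensity[:, mask],
            individuals=self.individuals,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (individual, anchor)."""
        n, a = self.intensity.shape
        return pd.DataFrame(
            {
                "chrom": np.tile(self.anchors["chrom"].to_numpy(), n),
                "anchor_pos": np.tile(self.anchors["pos"].to_numpy(), n),
                "individual": np.repeat(self.individuals, a),
                "intensity": self.intensity.ravel(),
            }
        )

    def to_wide(self) -> pd.DataFrame:
        """Wide format: anchor rows, individual columns."""
        df = pd.DataFrame(
            self.intensity.T, columns=self.individuals,
        )
        df.insert(0, "chrom", self.anchors["chrom"].to_numpy())
        df.insert(1, "pos", self.anchors["pos"].to_numpy())
        return df

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "HomozygosityProfile":
        individuals = [c for c in df.columns if c not in ("chrom", "pos")]
        return cls(
            anchors=df[["chrom", "pos"]].reset_index(drop=True),
            intensity=df[individuals].to_numpy(dtype=np.float64).T,
            individuals=[str(c) for c in individuals],
        )


def _profile_chromosome(
    ind: np.ndarray,
    positions: np.ndarray,
    maf: np.ndarray,
    spec: WindowSpec,
    locus_weights: np.ndarray | None = None,
) -> tuple[Windows, np.ndarray]:
    """Vectorised intensity over one chromosome.

    The polynomial is fit in scaled offsets u = (x_i - x)/h, which leaves the
    intercept unchanged and keeps the moment matrices well conditioned. For
    each window the per-individual weighted moment sums S_q = sum w u^q over
    non-missing members are assembled by matrix products, and the normal
    equations are solved in closed form (degree <= 1) or batched (degree >= 2).
    """
    windows = build_windows(positions, spec)
    lw = locus_weight(maf) if locus_weights is None else np.asarray(locus_weights, float)
    n = ind.shape[0]
    p = spec.degree
    out = np.full((n, len(windows)), np.nan)
    mask_all = ~np.isnan(ind)
    y_all = np.where(mask_all, ind, 0.0)

    fell_back = False
    for w in range(len(windows)):
        sl = slice(windows.lo[w], windows.hi[w] + 1)
        u = (positions[sl] - positions[windows.anchor[w]]) / windows.h[w]
        wgt = kernel_weight(u) * lw[sl]
        pos_w = wgt > 0
        mask = mask_all[:, sl] & pos_w  # (n, k)
        y = y_all[:, sl]
        up = u[:, None] ** np.arange(2 * p + 1)  # (k, 2p+1)
        wup = wgt[:, None] * up
        S = mask.astype(np.float64) @ wup  # (n, 2p+1)
        T = (y * mask) @ wup[:, : p + 1]  # (n, p+1)
        n_eff = mask.sum(axis=1)

        est = np.full(n, np.nan)
        ok = n_eff >= p + 1
        if p == 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                est = np.where(S[:, 0] > 0, T[:, 0] / np.where(S[:, 0] > 0, S[:, 0], 1.0), np.nan)
        elif p == 1:
            det = S[:, 0] * S[:, 2] - S[:, 1] ** 2
            scale = S[:, 0] * S[:, 2]
            good = ok & (det > 1e-12 * np.maximum(scale, 1e-300))
            est[good] = (S[good, 2] * T[good, 0] - S[good, 1] * T[good, 1]) / det[good]
        else:
            idx = np.add.outer(np.arange(p + 1), np.arange(p + 1))
            A = S[:, idx]  # (n, p+1, p+1)
            good = ok.copy()
            if good.any():
                sol = np.full((n, p + 1), np.nan)
                try:
                    sol[good] = np.linalg.solve(A[good], T[good][:, :, None])[:, :, 0]
                except np.linalg.LinAlgError:
                    for i in np.where(good)[0]:
                        try:
                            sol[i] = np.linalg.solve(A[i], T[i])
                        except np.linalg.LinAlgError:
                            good[i] = False
                # reject ill-conditioned systems, mirroring the rank check
                cond_bad = good & ~np.isfinite(sol).all(axis=1)
                good &= ~cond_bad
                est[good] = sol[good, 0]

        if p >= 1:
            # degree-0 fallback where the full fit was degenerate
            fb = np.isnan(est) & (S[:, 0] > 0)
            if fb.any():
                fell_back = True
                est[fb] = T[fb, 0] / S[fb, 0]
        if spec.clamp:
            est = np.clip(est, 0.0, 1.0)
        out[:, w] = est

    if fell_back:
        warnings.warn(
            "degenerate window(s): fell back to degree-0 weighted mean",
            RuntimeWarning,
            stacklevel=3,
        )
    return windows, out


def estimate_profile(
    ind: np.ndarray,
    g: GenotypeMatrix,
    spec: WindowSpec | None = None,
    maf: np.ndarray | None = None,
    locus_weights: np.ndarray | None = None,
) -> HomozygosityProfile:
    """Estimate the homozygosity intensity profile for every individual.

    ``ind`` is the indicator matrix from :func:`homozygosity_indicator`
    aligned to ``g``'s sites. MAF is computed from ``g`` unless supplied.
    Passing ``locus_weights`` of all ones reproduces a classic single-weight
    local polynomial smoother.
    """
    spec = spec or WindowSpec()
    if ind.shape != g.calls.shape:
        raise ValueError("indicator matrix not aligned to genotype matrix")
    if maf is None:
        maf = compute_maf(g)
    anchor_frames = []
    blocks = []
    site_chrom = g.sites["chrom"].to_numpy()
    pos = g.sites["pos"].to_numpy(dtype=np.float64)
    for chrom in g.chromosomes():
        m = site_chrom == chrom
        lw = None if locus_weights is None else np.asarray(locus_weights, float)[m]
        windows, vals = _profile_chromosome(ind[:, m], pos[m], np.asarray(maf, float)[m], spec, lw)
        anchor_frames.append(
            pd.DataFrame({"chrom": chrom, "pos": pos[m][windows.anchor].astype(np.int64)})
        )
        blocks.append(vals)
    return HomozygosityProfile(
        anchors=pd.concat(anchor_frames, ignore_index=True),
        intensity=np.concatenate(blocks, axis=1),
        individuals=g.sample_ids,
    )
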