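"""Clustered association testing of homozygosity intensity against traits.

Phenotype preprocessing follows the blood-pressure conventions of family
hypertension studies: medicated individuals get +5 mm Hg DBP / +10 mm Hg SBP,
hypertension is ever-medicated or DBP > 90 or SBP > 140 (strict), and
quantitative BP is log-transformed then winsorised at the 1st/99th
percentiles before modelling.

The scan fits, window by window, a marginal regression of the response on
the window's homozygosity intensity with age and sex as covariates, using
generalized estimating equations (GEE) with pedigrees as clusters, an
exchangeable working correlation, and robust (sandwich) standard errors.
The identity link serves quantitative traits and expression; the logit link
serves binary hypertension status. P-values are Benjamini-Hochberg adjusted
across the genome-wide scan per response.

The GEE solver here is a direct implementation specialised to exchangeable
working correlation (solved via the Sherman-Morrison identity, so no
per-cluster matrix inversions), which keeps genome scans over many windows
and simulation replicates fast. Its conventions for the dispersion and
correlation moment estimators follow statsmodels' GEE, which the test suite
uses as an independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .intensity import HomozygosityProfile

DBP_MED_ADJUST = 5.0  # mm Hg added to DBP for medicated individuals
SBP_MED_ADJUST = 10.0  # mm Hg added to SBP
DBP_HTN_CUTOFF = 90.0  # strict: "exceeded"
SBP_HTN_CUTOFF = 140.0
DEFAULT_FDR_LEVEL = 0.05
DEFAULT_WINSOR_Q = 0.01


# ---------------------------------------------------------------------------
# Phenotype preprocessing


def adjust_medication(pheno: pd.DataFrame) -> pd.DataFrame:
    """Add 5/10 mm Hg to DBP/SBP of medicated individuals (idempotent).

    Individuals with a missing medication flag are excluded with a warning.
    A marker in ``DataFrame.attrs`` guards against double adjustment.
    """
    if "med" not in pheno.columns:
        raise ValueError("phenotype table lacks a 'med' column")
    out = pheno.copy()
    if out.attrs.get("med_adjusted"):
        return out
    missing = out["med"].isna()
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} individual(s) with missing medication flag",
            UserWarning,
            stacklevel=2,
        )
        out = out.loc[~missing].copy()
    medicated = out["med"].astype(float) > 0
    out.loc[medicated, "dbp"] = out.loc[medicated, "dbp"] + DBP_MED_ADJUST
    out.loc[medicated, "sbp"] = out.loc[medicated, "sbp"] + SBP_MED_ADJUST
    out.attrs["med_adjusted"] = True
    return out


def define_htn(pheno: pd.DataFrame) -> pd.DataFrame:
    """Flag hypertension: ever medicated, or DBP > 90, or SBP > 140 (strict).

    Must be applied to raw (pre-medication-adjustment) blood pressures.
    """
    if pheno.attrs.get("med_adjusted"):
        raise ValueError("define_htn requires pre-adjustment blood pressures")
    out = pheno.copy()
    med = out["med"].fillna(0).astype(float) > 0
    out["htn"] = (
        med | (out["dbp"] > DBP_HTN_CUTOFF) | (out["sbp"] > SBP_HTN_CUTOFF)
    ).astype(int)
    return out


def transform_bp(values, winsor_q: float = DEFAULT_WINSOR_Q, ids=None) -> np.ndarray:
    """Natural log then two-sided winsorisation at the ``winsor_q`` quantiles.

    Quantiles use linear interpolation (numpy default). Nonpositive values
    are rejected, naming the offending individual when ``ids`` is given.
    """
    v = np.asarray(values, dtype=np.float64)
    bad = np.where(v <= 0)[0]
    if bad.size:
        who = ids[bad[0]] if ids is not None else f"index {bad[0]}"
        raise ValueError(f"nonpositive blood pressure for {who}")
    logv = np.log(v)
    lo, hi = np.quantile(logv, [winsor_q, 1.0 - winsor_q])
    return np.clip(logv, lo, hi)


def prepare_phenotypes(pheno: pd.DataFrame, winsor_q: float = DEFAULT_WINSOR_Q) -> pd.DataFrame:
    """Full preprocessing chain: HTN flag, medication adjustment, BP transform.

    Returns a table with ``htn``, medication-adjusted ``dbp``/``sbp``, and
    log-winsorised ``dbp_t``/``sbp_t`` columns ready for association.
    """
    out = define_htn(pheno)
    out = adjust_medication(out)
    ids = out["id"].to_numpy() if "id" in out.columns else None
    out["dbp_t"] = transform_bp(out["dbp"].to_numpy(), winsor_q, ids)
    out["sbp_t"] = transform_bp(out["sbp"].to_numpy(), winsor_q, ids)
    return out


# ---------------------------------------------------------------------------
# FDR


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through).

    Missing entries are excluded from the number of tests m.
    """
    p = np.asarray(p_values, dtype=np.float64)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# GEE core


@dataclass
class GEEResult:
    """One GEE fit: coefficients, sandwich covariance, Wald inference."""

    params: np.ndarray
    cov: np.ndarray = field(repr=False)
    se: np.ndarray
    pvalues: np.ndarray
    alpha: float  # exchangeable working correlation
    scale: float
    n_obs: int
    n_clusters: int
    n_iter: int
    converged: bool


def _cluster_starts(groups: np.ndarray) -> np.ndarray:
    """Start indices of each cluster in a cluster-sorted array."""
    return np.concatenate(([0], np.where(groups[1:] != groups[:-1])[0] + 1))


def gee_fit(
    y,
    X,
    groups,
    link: str = "identity",
    maxiter: int = 100,
    tol: float = 1e-10,
) -> GEEResult:
    """Fit a marginal regression by GEE with exchangeable working correlation.

    ``link`` is ``"identity"`` (Gaussian variance) or ``"logit"`` (binomial
    variance). Clusters may appear in any order. Robust sandwich covariance;
    Wald p-values from the normal reference. With all-singleton clusters the
    exchangeable correlation is vacuous and the fit reduces to the
    independence GLM with HC0-type robust covariance.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    groups = np.asarray(groups)
    n, p = X.shape
    if link not in ("identity", "logit"):
        raise ValueError(f"unknown link {link!r}")

    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    starts = _cluster_starts(groups)
    n_c = np.diff(np.concatenate((starts, [n])))
    n_clusters = len(starts)
    n_pairs = float((n_c * (n_c - 1)).sum()) / 2.0
    alpha_lo = -0.999 / max(int(n_c.max()) - 1, 1)

    # independence-model start values
    if link == "identity":
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
    else:
        beta = np.zeros(p)
        for _ in range(25):
            mu = np.clip(expit(X @ beta), 1e-10, 1 - 1e-10)
            v = mu * (1 - mu)
            delta = np.linalg.solve((X * v[:, None]).T @ X, X.T @ (y - mu))
            beta = beta + delta
            if np.max(np.abs(delta)) < 1e-9:
                break

    alpha = 0.0
    scale = 1.0
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        eta = X @ beta
        if link == "identity":
            mu = eta
            var = np.ones(n)
            dmu = np.ones(n)
        else:
            mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
            var = mu * (1 - mu)
            dmu = var
        sd = np.sqrt(var)
        U = X * (dmu / sd)[:, None]
        rtil = (y - mu) / sd

        # dispersion and exchangeable correlation, statsmodels conventions
        ssr = float(rtil @ rtil)
        scale = ssr / max(n - p, 1)
        rs = np.add.reduceat(rtil, starts)
        ssr_c = np.add.reduceat(rtil * rtil, starts)
        denom = n_pairs - p
        if denom > 0 and scale > 0:
            alpha = float(((rs**2 - ssr_c) / 2.0).sum() / scale / denom)
            alpha = float(np.clip(alpha, alpha_lo, 0.9999))
        else:
            alpha = 0.0

        gamma = alpha / (1.0 - alpha + alpha * n_c)
        s = np.add.reduceat(U, starts, axis=0)  # (C, p) cluster column sums
        B = U.T @ U - np.einsum("c,cp,cq->pq", gamma, s, s)
        Ur = np.add.reduceat(U * rtil[:, None], starts, axis=0)
        G = Ur - gamma[:, None] * rs[:, None] * s  # per-cluster scores
        try:
            delta = np.linalg.solve(B, G.sum(axis=0))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular GEE design") from exc
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    # sandwich at the final estimate (B, G recomputed implicitly fresh above)
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular GEE design") from exc
    cov = Binv @ (G.T @ G) @ Binv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * norm.sf(np.abs(z))
    return GEEResult(
        params=beta, cov=cov, se=se, pvalues=pvals, alpha=alpha, scale=scale,
        n_obs=n, n_clusters=n_clusters, n_iter=it, converged=converged,
    )


# ---------------------------------------------------------------------------
# Window-wise association scan


@dataclass(frozen=True)
class ResponseSpec:
    """A response to scan: its name, link, and pre-transform."""

    name: str
    link: str = "identity"  # identity | logit
    transform: str = "none"  # none | log_winsor

    def __post_init__(self) -> None:
        if self.link not in ("identity", "logit"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.transform not in ("none", "log_winsor"):
            raise ValueError(f"unknown transform {self.transform!r}")


def response_spec(name: str) -> ResponseSpec:
    """Standard response configurations: DBP/SBP identity+log-winsor, HTN logit."""
    upper = name.upper()
    if upper in ("DBP", "SBP"):
        return ResponseSpec(name=upper, link="identity", transform="log_winsor")
    if upper == "HTN":
        return ResponseSpec(name=upper, link="logit", transform="none")
    return ResponseSpec(name=name)


ASSOC_COLUMNS = [
    "chrom", "pos", "response", "beta", "se", "p_value", "p_adjusted", "n", "status",
]


def gee_association(
    profile: HomozygosityProfile,
    response: ResponseSpec | str,
    pheno: pd.DataFrame,
    cluster_col: str = "ped",
    covariates: tuple[str, ...] = ("age", "sex"),
    fdr_level: float = DEFAULT_FDR_LEVEL,
    winsor_q: float = DEFAULT_WINSOR_Q,
) -> pd.DataFrame:
    """Window-wise GEE scan of a response on homozygosity intensity.

    ``pheno`` must carry ``id``, the cluster column, the covariates, and a
    column named after the response (case-insensitive). Individuals missing
    the response, a covariate, or the cluster label are dropped. Windows with
    no intensity variance are flagged untestable (p missing) and excluded
    from the FDR adjustment's test count; the same holds for non-converged
    fits. ``p_adjusted`` is BH-FDR across the scan.
    """
    if isinstance(response, str):
        response = response_spec(response)
    ph = pheno.copy()
    ph.columns = [str(c).lower() for c in ph.columns]
    rcol = response.name.lower()
    needed = ["id", cluster_col, rcol, *covariates]
    missing_cols = [c for c in needed if c not in ph.columns]
    if missing_cols:
        raise ValueError(f"phenotype table lacks columns {missing_cols}")
    ph = ph.drop_duplicates("id").set_index("id")
    ph = ph.reindex([str(i) for i in profile.individuals])
    keep = ph[needed[1:]].notna().all(axis=1).to_numpy()
    if keep.sum() < 2:
        raise ValueError("fewer than 2 individuals with complete data")

    yv = ph.loc[keep, rcol].to_numpy(dtype=np.float64)
    if response.transform == "log_winsor":
        yv = transform_bp(yv, winsor_q, ids=ph.index.to_numpy()[keep])
    clusters = ph.loc[keep, cluster_col].to_numpy()
    if len(np.unique(clusters)) < 2:
        raise ValueError("need at least 2 clusters for a clustered analysis")
    Z = ph.loc[keep, list(covariates)].to_numpy(dtype=np.float64)
    lam_all = profile.intensity[keep]

    rows = []
    for w in range(profile.n_anchors):
        lam = lam_all[:, w]
        ok = ~np.isnan(lam)
        chrom = profile.anchors["chrom"].iloc[w]
        pos = int(profile.anchors["pos"].iloc[w])
        lam_w, y_w, Z_w, cl_w = lam[ok], yv[ok], Z[ok], clusters[ok]
        if ok.sum() < Z.shape[1] + 2 or np.ptp(lam_w) == 0:
            rows.append((chrom, pos, response.name, np.nan, np.nan, np.nan,
                         np.nan, int(ok.sum()), "constant_intensity"))
            continue
        X = np.column_stack([np.ones(ok.sum()), lam_w, Z_w])
        try:
            fit = gee_fit(y_w, X, cl_w, link=response.link)
        except np.linalg.LinAlgError:
            rows.append((chrom, pos, response.name, np.nan, np.nan, np.nan,
                         np.nan, int(ok.sum()), "singular"))
            continue
        status = "ok" if fit.converged else "no_convergence"
        pv = fit.pvalues[1] if fit.converged else np.nan
        rows.append((chrom, pos, response.name, fit.params[1], fit.se[1], pv,
                     np.nan, int(ok.sum()), status))
    results = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    results["p_adjusted"] = fdr_adjust(results["p_value"].to_numpy())
    results.attrs["fdr_level"] = fdr_level
    return results


def significant_hd_regions(
    results: pd.DataFrame, alpha: float = DEFAULT_FDR_LEVEL
) -> pd.DataFrame:
    """Maximal runs of consecutive windows with adjusted p <= alpha.

    Region bounds are the first and last significant anchor positions,
    reported per chromosome and response.
    """
    rows = []
    for (chrom, resp), sub in results.groupby(["chrom", "response"], sort=False):
        sub = sub.sort_values("pos")
        sig = (sub["p_adjusted"] <= alpha).fillna(False).to_numpy()
        pos = sub["pos"].to_numpy()
        padj = sub["p_adjusted"].to_numpy()
        edges = np.diff(np.concatenate(([0], sig.astype(np.int8), [0])))
        for start, stop in zip(np.where(edges == 1)[0], np.where(edges == -1)[0]):
            rows.append(
                (chrom, resp, int(pos[start]), int(pos[stop - 1]),
                 float(np.nanmin(padj[start:stop])), stop - start)
            )
    return pd.DataFrame(
        rows, columns=["chrom", "response", "start_bp", "end_bp",
                       "min_p_adjusted", "n_windows"],
    )


# ---------------------------------------------------------------------------
# Expression regulation by a region of HD


REGULATION_COLUMNS = [
    "transcript", "beta", "se", "p_value", "p_adjusted", "fold_change", "n", "status",
]


def region_intensity(profile: HomozygosityProfile, region) -> np.ndarray:
    """Per-individual mean intensity over anchors inside a region.

    ``region`` is any mapping with ``chrom``, ``start_bp``, ``end_bp``.
    """
    inside = (
        (profile.anchors["chrom"] == region["chrom"])
        & (profile.anchors["pos"] >= region["start_bp"])
        & (profile.anchors["pos"] <= region["end_bp"])
    ).to_numpy()
    if not inside.any():
        raise ValueError("region contains no profile anchors")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(profile.intensity[:, inside], axis=1)


def expression_regulation(
    expr: pd.DataFrame,
    profile: HomozygosityProfile,
    region,
    pheno: pd.DataFrame,
    cluster_col: str = "ped",
    covariates: tuple[str, ...] = ("age", "sex"),
    fdr_level: float = DEFAULT_FDR_LEVEL,
    high_intensity: float = 0.9,
) -> pd.DataFrame:
    """Test each transcript's expression against a region's mean intensity.

    Identity-link GEE of expression on region intensity with age/sex
    adjustment and pedigree clusters; BH-FDR across transcripts. The
    reported fold change is log2 of mean expression in individuals whose
    region intensity is >= ``high_intensity`` over those below it (NaN when
    a group is empty); it is descriptive output for volcano plots, not part
    of the test.
    """
    lam = region_intensity(profile, region)
    ph = pheno.copy()
    ph.columns = [str(c).lower() for c in ph.columns]
    ph = ph.drop_duplicates("id").set_index("id")
    ph = ph.reindex([str(i) for i in profile.individuals])
    expr = expr.reindex(columns=[str(i) for i in profile.individuals])

    base = ph[[cluster_col, *covariates]].notna().all(axis=1).to_numpy()
    base &= ~np.isnan(lam)
    rows = []
    for transcript, evals in expr.iterrows():
        ev = evals.to_numpy(dtype=np.float64)
        ok = base & ~np.isnan(ev)
        n_used = int(ok.sum())
        if n_used < len(covariates) + 3 or np.ptp(ev[ok]) == 0 or np.ptp(lam[ok]) == 0:
            rows.append((transcript, np.nan, np.nan, np.nan, np.nan, np.nan,
                         n_used, "untestable"))
            continue
        hi = lam[ok] >= high_intensity
        mh, ml = ev[ok][hi].mean() if hi.any() else np.nan, ev[ok][~hi].mean() if (~hi).any() else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.log2(mh / ml) if (mh and ml and mh > 0 and ml > 0) else np.nan
        X = np.column_stack([
            np.ones(n_used), lam[ok],
            ph.loc[ok, list(covariates)].to_numpy(dtype=np.float64),
        ])
        try:
            fit = gee_fit(ev[ok], X, ph.loc[ok, cluster_col].to_numpy())
        except np.linalg.LinAlgError:
            rows.append((transcript, np.nan, np.nan, np.nan, np.nan, fc,
                         n_used, "singular"))
            continue
        rows.append((transcript, fit.params[1], fit.se[1], fit.pvalues[1],
                     np.nan, fc, n_used, "ok" if fit.converged else "no_convergence"))
    results = pd.DataFrame(rows, columns=REGULATION_COLUMNS)
    results["p_adjusted"] = fdr_adjust(results["p_value"].to_numpy())
    results.attrs["fdr_level"] = fdr_level
    return results
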