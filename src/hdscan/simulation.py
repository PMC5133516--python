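"""Synthetic pedigree genotypes, HD implantation, and operating-characteristic
experiments.

The generator emulates a family study: independent multi-generation
pedigrees, diploid genotypes gene-dropped from founder haplotypes (so
relatives share alleles identical by descent at the pedigree's kinship
rates), ordered positions on one chromosome, and a minor-allele-frequency
spectrum mixing common SNPs with rare variants (MAF < 0.05). A quantitative
trait Q1 is drawn from a normal distribution independently of every genotype
draw; trait-associated runs of homozygosity are implanted by the logistic
model

    Logit(p) = b0 + b1 * Q1

where p is each individual's probability that all genotypes in a target
region are replaced by homozygotes.

Separate, named random streams (genotypes, covariates, traits, implantation)
are spawned from one seed, so changing one ingredient never perturbs the
others. The type-1 experiment keeps genotypes fixed and redraws the trait
per replicate (one genotype data set, many simulated trait sets); the power
experiment redraws Q1 and re-implants per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .association import ResponseSpec, gee_association
from .genotype_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    GenotypeMatrix,
    compute_alt_freq,
    compute_maf,
    homozygosity_indicator,
)
from .intensity import RARE_MAF, WindowSpec, build_windows, estimate_profile

DEFAULT_Q1_MEAN = 10.0
DEFAULT_Q1_SD = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    The default design is 20 independent three-generation pedigrees of 44
    members each (a founding couple, 6 children married to 6 founder
    spouses, 5 grandchildren per union), 2,000 sites at ~50 kb mean spacing
    (a ~100 Mb chromosome), 30% rare sites with MAF uniform on
    (0.005, 0.05) and common sites uniform on (0.05, 0.5).
    """

    n_pedigrees: int = 20
    n_sib_g2: int = 6
    n_sib_g3: int = 5
    n_sites: int = 2000
    mean_spacing_bp: int = 50_000
    rare_fraction: float = 0.3
    rare_maf_range: tuple[float, float] = (0.005, 0.05)
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    chrom: str = "1"

    def __post_init__(self) -> None:
        if min(self.n_pedigrees, self.n_sib_g2, self.n_sib_g3, self.n_sites) < 1:
            raise ValueError("design counts must be positive")
        if not 0 <= self.rare_fraction <= 1:
            raise ValueError("rare_fraction must lie in [0, 1]")

    @property
    def pedigree_size(self) -> int:
        return 2 + 2 * self.n_sib_g2 + self.n_sib_g2 * self.n_sib_g3

    @property
    def n_individuals(self) -> int:
        return self.n_pedigrees * self.pedigree_size


def simulate_pedigree_structure(cfg: SimulationConfig) -> pd.DataFrame:
    """Three-generation pedigrees: id, ped, father, mother (NaN for founders)."""
    rows = []
    for p in range(cfg.n_pedigrees):
        ped = f"P{p:03d}"
        gp1, gp2 = f"{ped}_GP1", f"{ped}_GP2"
        rows.append((gp1, ped, None, None))
        rows.append((gp2, ped, None, None))
        for c in range(cfg.n_sib_g2):
            child = f"{ped}_C{c}"
            spouse = f"{ped}_S{c}"
            rows.append((child, ped, gp1, gp2))
            rows.append((spouse, ped, None, None))
            for gc in range(cfg.n_sib_g3):
                rows.append((f"{ped}_C{c}_G{gc}", ped, child, spouse))
    return pd.DataFrame(rows, columns=["id", "ped", "father", "mother"])


def simulate_genotypes(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    structure: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Gene-drop genotypes through the pedigrees.

    Founder haplotypes are Bernoulli(alt frequency) per site (Hardy-Weinberg
    in the founder population); each child inherits one randomly chosen
    allele per site from each parent. Sites are independent (no linkage),
    which is adequate for method evaluation because homozygous tracts enter
    only via implantation.
    """
    structure = structure if structure is not None else simulate_pedigree_structure(cfg)
    m = cfg.n_sites
    spacing = rng.integers(
        max(1, cfg.mean_spacing_bp // 2), cfg.mean_spacing_bp * 3 // 2 + 1, size=m
    )
    pos = 1_000_000 + np.cumsum(spacing)
    n_rare = int(round(cfg.rare_fraction * m))
    maf = np.empty(m)
    rare_idx = rng.choice(m, size=n_rare, replace=False)
    is_rare = np.zeros(m, dtype=bool)
    is_rare[rare_idx] = True
    maf[is_rare] = rng.uniform(*cfg.rare_maf_range, size=n_rare)
    maf[~is_rare] = rng.uniform(*cfg.common_maf_range, size=m - n_rare)
    alt_freq = maf  # alt is the minor allele

    ids = structure["id"].tolist()
    index = {i: k for k, i in enumerate(ids)}
    hap = np.zeros((len(ids), 2, m), dtype=np.int8)
    # founders first, then children in declaration order (parents precede kids)
    for k, row in enumerate(structure.itertuples(index=False)):
        if row.father is None or (isinstance(row.father, float) and np.isnan(row.father)):
            hap[k, 0] = rng.random(m) < alt_freq
            hap[k, 1] = rng.random(m) < alt_freq
        else:
            f, mo = index[row.father], index[row.mother]
            hap[k, 0] = np.take_along_axis(
                hap[f], rng.integers(0, 2, size=(1, m)), axis=0
            )[0]
            hap[k, 1] = np.take_along_axis(
                hap[mo], rng.integers(0, 2, size=(1, m)), axis=0
            )[0]
    calls = (hap[:, 0] + hap[:, 1]).astype(np.int8)  # dosage == genotype code

    sites = pd.DataFrame(
        {"chrom": cfg.chrom, "pos": pos.astype(np.int64), "ref": "A", "alt": "G"}
    )
    samples = structure[["id", "ped"]].copy()
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls)


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Age (years, uniform 20-80) and sex (0/1) for n individuals."""
    return pd.DataFrame(
        {"age": np.round(rng.uniform(20, 80, size=n), 1), "sex": rng.integers(0, 2, size=n)}
    )


def simulate_q1(
    n: int,
    mean: float = DEFAULT_Q1_MEAN,
    sd: float = DEFAULT_Q1_SD,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """I.i.d. normal trait draws, independent of all genotype streams."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.normal(mean, sd, size=n)


@dataclass(frozen=True)
class ImplantModel:
    """Logistic HD-implantation model Logit(p) = b0 + b1 * Q1 over a region."""

    b0: float
    b1: float
    chrom: str
    start_bp: int
    end_bp: int

    def replacement_probability(self, q1) -> np.ndarray:
        return expit(self.b0 + self.b1 * np.asarray(q1, dtype=np.float64))

    def __getitem__(self, key):  # mapping view for region helpers
        return {"chrom": self.chrom, "start_bp": self.start_bp, "end_bp": self.end_bp}[key]


def implant_hd(
    g: GenotypeMatrix,
    model: ImplantModel,
    q1: np.ndarray,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Implant a trait-associated homozygous tract.

    Each individual is replaced with probability p = expit(b0 + b1*Q1): all
    heterozygous calls inside the region become the homozygote of the site's
    major allele; homozygous calls are untouched, as are missing calls and
    every site outside the region. Returns the new matrix and the boolean
    replaced-individual mask.
    """
    in_region = (
        (g.sites["chrom"] == model.chrom)
        & (g.sites["pos"] >= model.start_bp)
        & (g.sites["pos"] <= model.end_bp)
    ).to_numpy()
    if not in_region.any():
        raise ValueError("implantation region covers no sites")
    p = model.replacement_probability(q1)
    replaced = rng.random(g.n_samples) < p
    calls = g.calls.copy()
    if replaced.any():
        alt_freq = compute_alt_freq(g)[in_region]
        major_hom = np.where(alt_freq > 0.5, HOM_ALT, HOM_REF).astype(np.int8)
        block = calls[np.ix_(replaced, np.where(in_region)[0])]
        het = block == HET
        block[het] = np.broadcast_to(major_hom, block.shape)[het]
        calls[np.ix_(replaced, np.where(in_region)[0])] = block
    out = GenotypeMatrix(sites=g.sites, samples=g.samples, calls=calls)
    return out, replaced


def place_region_by_rv_percentile(
    g: GenotypeMatrix, n_region_sites: int, percentile: float = 50.0
) -> ImplantModel:
    """Pick a candidate region whose local rare-variant fraction sits at a
    given percentile of same-sized blocks along the chromosome.

    Mirrors selecting target regions at the 10th/50th/90th percentiles of
    local rare-variant proportion. Returns an ImplantModel shell with b0, b1
    unset (0); use :func:`dataclasses.replace` to set them.
    """
    maf = compute_maf(g)
    rare = (maf < RARE_MAF).astype(float)
    m = g.n_sites
    if n_region_sites > m:
        raise ValueError("region larger than chromosome")
    stride = max(1, n_region_sites // 4)
    starts = np.arange(0, m - n_region_sites + 1, stride)
    fracs = np.array([rare[s : s + n_region_sites].mean() for s in starts])
    target = np.percentile(fracs, percentile)
    s = int(starts[np.argmin(np.abs(fracs - target))])
    pos = g.sites["pos"].to_numpy()
    return ImplantModel(
        b0=0.0, b1=0.0, chrom=str(g.sites["chrom"].iloc[s]),
        start_bp=int(pos[s]), end_bp=int(pos[s + n_region_sites - 1]),
    )


@dataclass
class ExperimentResult:
    """Summary of a type-1 or power experiment."""

    kind: str
    n_replicates: int
    per_replicate: np.ndarray = field(repr=False)
    mean: float
    mc_se: float
    params: dict = field(default_factory=dict)


def _spawn_streams(seed: int, n: int = 4) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def _scan_q1(profile, q1, samples, covariates, fdr_level):
    pheno = pd.DataFrame(
        {
            "id": samples["id"].astype(str),
            "ped": samples["ped"],
            "age": covariates["age"].to_numpy(),
            "sex": covariates["sex"].to_numpy(),
            "q1": q1,
        }
    )
    return gee_association(
        profile, ResponseSpec("Q1"), pheno, fdr_level=fdr_level
    )


def type1_experiment(
    cfg: SimulationConfig | None = None,
    n_replicates: int = 200,
    window_spec: WindowSpec | None = None,
    fdr_level: float = 0.05,
    q1_mean: float = DEFAULT_Q1_MEAN,
    q1_sd: float = DEFAULT_Q1_SD,
    seed: int = 0,
) -> ExperimentResult:
    """Type-1 error of the scan under a genotype-independent normal trait.

    One synthetic cohort is generated; per replicate a fresh trait is drawn
    and the full pipeline runs (intensity profile, GEE scan, BH-FDR). The
    per-replicate type-1 error is the fraction of testable windows declared
    significant; the experiment reports its mean and Monte-Carlo SE.
    """
    cfg = cfg or SimulationConfig()
    window_spec = window_spec or WindowSpec(anchor_stride=20)
    geno_rng, cov_rng, trait_rng, _ = _spawn_streams(seed)
    g = simulate_genotypes(cfg, geno_rng)
    covs = simulate_covariates(g.n_samples, cov_rng)
    profile = estimate_profile(homozygosity_indicator(g), g, window_spec)

    rates = np.empty(n_replicates)
    for r in range(n_replicates):
        q1 = simulate_q1(g.n_samples, q1_mean, q1_sd, rng=trait_rng)
        res = _scan_q1(profile, q1, g.samples, covs, fdr_level)
        testable = res["p_adjusted"].notna()
        rates[r] = (
            (res.loc[testable, "p_adjusted"] <= fdr_level).sum() / testable.sum()
            if testable.any()
            else 0.0
        )
    return ExperimentResult(
        kind="type1",
        n_replicates=n_replicates,
        per_replicate=rates,
        mean=float(rates.mean()),
        mc_se=float(rates.std(ddof=1) / np.sqrt(n_replicates)) if n_replicates > 1 else np.nan,
        params={"fdr_level": fdr_level, "q1_mean": q1_mean, "q1_sd": q1_sd,
                "n_individuals": g.n_samples, "n_sites": cfg.n_sites,
                "n_windows": profile.n_anchors, "seed": seed},
    )


def power_config() -> SimulationConfig:
    """A 500-individual design (25 pedigrees of 20) for power runs."""
    return SimulationConfig(n_pedigrees=25, n_sib_g2=3, n_sib_g3=4)


def power_experiment(
    cfg: SimulationConfig | None = None,
    b0: float = -10.0,
    b1: float = 1.0,
    region: ImplantModel | None = None,
    region_fraction: float = 0.1,
    n_replicates: int = 200,
    window_spec: WindowSpec | None = None,
    fdr_level: float = 0.05,
    q1_mean: float = DEFAULT_Q1_MEAN,
    q1_sd: float = DEFAULT_Q1_SD,
    seed: int = 0,
) -> ExperimentResult:
    """Power of the scan against an implanted trait-associated HD region.

    Per replicate: draw Q1, implant the region with per-individual
    replacement probability expit(b0 + b1*Q1), recompute MAF and the
    intensity profile from the implanted genotypes, run the GEE scan with
    BH-FDR, and record detection = at least one significant window whose
    member span overlaps the region. Power is the detected fraction.
    """
    cfg = cfg or power_config()
    window_spec = window_spec or WindowSpec(anchor_stride=20)
    geno_rng, cov_rng, trait_rng, implant_rng = _spawn_streams(seed)
    g = simulate_genotypes(cfg, geno_rng)
    covs = simulate_covariates(g.n_samples, cov_rng)
    if region is None:
        region = place_region_by_rv_percentile(
            g, max(1, int(round(region_fraction * cfg.n_sites)))
        )
    model = replace(region, b0=b0, b1=b1)

    pos = g.sites["pos"].to_numpy(dtype=np.float64)
    windows = build_windows(pos, window_spec)
    span_lo = pos[windows.lo]
    span_hi = pos[windows.hi]
    overlaps = (span_lo <= model.end_bp) & (span_hi >= model.start_bp)

    detected = np.zeros(n_replicates, dtype=bool)
    for r in range(n_replicates):
        q1 = simulate_q1(g.n_samples, q1_mean, q1_sd, rng=trait_rng)
        g_rep, _ = implant_hd(g, model, q1, implant_rng)
        profile = estimate_profile(homozygosity_indicator(g_rep), g_rep, window_spec)
        res = _scan_q1(profile, q1, g.samples, covs, fdr_level)
        sig = (res["p_adjusted"] <= fdr_level).fillna(False).to_numpy()
        detected[r] = bool((sig & overlaps).any())

    power = float(detected.mean())
    return ExperimentResult(
        kind="power",
        n_replicates=n_replicates,
        per_replicate=detected.astype(float),
        mean=power,
        mc_se=float(np.sqrt(power * (1 - power) / n_replicates)),
        params={"b0": b0, "b1": b1, "region": (model.chrom, model.start_bp, model.end_bp),
                "fdr_level": fdr_level, "q1_mean": q1_mean, "q1_sd": q1_sd,
                "n_individuals": g.n_samples, "n_sites": cfg.n_sites, "seed": seed},
    )


def power_grid(
    b0_values=(-25.0, -20.0, -15.0, -10.0),
    b1_values=(0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    **kwargs,
) -> pd.DataFrame:
    """Sweep the (b0, b1) grid of the implantation model; one row per cell."""
    rows = []
    for b0 in b0_values:
        for b1 in b1_values:
            res = power_experiment(b0=b0, b1=b1, **kwargs)
            rows.append((b0, b1, res.mean, res.mc_se, res.n_replicates))
    return pd.DataFrame(rows, columns=["b0", "b1", "power", "mc_se", "n_replicates"])
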