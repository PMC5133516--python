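"""Genotype, phenotype, and expression I/O.

Genotypes are held in a :class:`GenotypeMatrix`: an individuals x sites
matrix of diploid genotype codes over position-sorted variant sites, plus a
sample table carrying pedigree labels and covariates when available.
Coordinates are 1-based inclusive internally; BED exports elsewhere are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# genotype codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_CODE_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for many individuals over ordered variant sites.

    Parameters
    ----------
    sites : pandas.DataFrame
        One row per variant site with columns ``chrom, pos, ref, alt``;
        within each chromosome positions are strictly increasing.
    samples : pandas.DataFrame
        One row per individual with column ``id`` and optional ``ped``,
        ``sex``, ``age`` columns (covariates usually live in the phenotype
        table and are joined by ``id``).
    calls : numpy.ndarray
        ``int8`` array of shape ``(n_samples, n_sites)`` with values in
        ``{HOM_REF, HET, HOM_ALT, MISSING}``.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"invalid genotype code {self.calls[i, j]} at ({i}, {j})")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            # ties allowed only for biallelic splits of one multiallelic record
            if not np.all(np.diff(pos) >= 0):
                k = int(np.argmax(np.diff(pos) < 0))
                raise ValueError(
                    f"sites not sorted by position on {chrom}: "
                    f"pos {pos[k + 1]} follows {pos[k]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["id"].astype(str).tolist()

    def chromosomes(self) -> list:
        return list(self.sites["chrom"].drop_duplicates())

    def for_chromosome(self, chrom) -> "GenotypeMatrix":
        """View restricted to one chromosome (copies the call slice)."""
        mask = (self.sites["chrom"] == chrom).to_numpy()
        if not mask.any():
            raise KeyError(f"no sites on chromosome {chrom!r}")
        return GenotypeMatrix(
            sites=self.sites.loc[mask],
            samples=self.samples,
            calls=self.calls[:, mask],
        )


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-site minor allele frequency from the analyzed sample.

    Returns an array of length ``n_sites`` with ``maf = min(f, 1 - f)`` where
    ``f`` is the alternate-allele frequency among non-missing calls. Sites
    where every call is missing get NaN (excluded from locus weighting).
    """
    f = compute_alt_freq(g)
    return np.minimum(f, 1.0 - f)


def compute_alt_freq(g: GenotypeMatrix) -> np.ndarray:
    """Alternate-allele frequency per site; NaN where all calls are missing."""
    calls = g.calls
    nonmiss = (calls != MISSING).sum(axis=0)
    alt = (calls == HET).sum(axis=0) + 2 * (calls == HOM_ALT).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(nonmiss > 0, alt / (2.0 * nonmiss), np.nan)
    return f


def homozygosity_indicator(g: GenotypeMatrix) -> np.ndarray:
    """Homozygosity indicator matrix: 1.0 hom, 0.0 het, NaN missing.

    Shape matches ``g.calls``; the float encoding lets downstream weighted
    fits mask missing entries with NaN arithmetic.
    """
    ind = np.full(g.calls.shape, np.nan, dtype=np.float64)
    ind[(g.calls == HOM_REF) | (g.calls == HOM_ALT)] = 1.0
    ind[g.calls == HET] = 0.0
    return ind


# ---------------------------------------------------------------------------
# VCF input


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF 4.x (optionally gzipped) into a GenotypeMatrix.

    Multiallelic records are split into one biallelic site per ALT allele;
    a genotype carrying an allele not represented at the split site becomes
    missing so per-site allele frequencies stay well defined. Records must be
    position-sorted within each chromosome; the first violation is reported.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"{path}: VCF has no samples / no GT field")

    rows = []
    cols = []
    last: dict = {}
    for variant in vcf:
        chrom, pos = variant.CHROM, variant.POS
        if chrom in last and pos <= last[chrom]:
            raise ValueError(
                f"{path}: unsorted VCF at {chrom}:{pos} (previous {last[chrom]})"
            )
        last[chrom] = pos
        gts = variant.genotypes  # [a1, a2, phased] per sample
        if gts is None:
            raise ValueError(f"{path}: record {chrom}:{pos} lacks GT")
        for alt_index, alt in enumerate(variant.ALT, start=1):
            codes = np.empty(len(sample_ids), dtype=np.int8)
            for s, gt in enumerate(gts):
                a1, a2 = gt[0], gt[1]
                if a1 < 0 or a2 < 0:
                    codes[s] = MISSING
                elif {a1, a2} - {0, alt_index}:
                    codes[s] = MISSING  # carries an unrepresented allele
                else:
                    codes[s] = (a1 == alt_index) + (a2 == alt_index)
            rows.append((chrom, pos, variant.REF, alt))
            cols.append(codes)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    calls = np.array(cols, dtype=np.int8).T if cols else np.empty((len(sample_ids), 0), np.int8)
    samples = pd.DataFrame({"id": sample_ids})
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls)


# ---------------------------------------------------------------------------
# Genotype CSV dialect
#
# Header: CHROM,POS,REF,ALT,<id1>,<id2>,...   one row per biallelic site.
# Cells: the two alleles of a call, e.g. "AA", "AG", "GG"; "NN" = missing.
# gzip transparent via pandas (suffix .gz).


def read_genotype_csv(path: str, samples: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read the sites x individuals genotype CSV dialect.

    ``samples`` optionally supplies pedigree/covariate columns to attach
    (matched on ``id``); otherwise only IDs from the header are kept.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["CHROM", "POS", "REF", "ALT"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"{path}: first columns must be {required}, got {list(df.columns[:4])}")
    ids = list(df.columns[4:])
    sites = pd.DataFrame(
        {
            "chrom": df["CHROM"],
            "pos": df["POS"].astype(np.int64),
            "ref": df["REF"],
            "alt": df["ALT"],
        }
    )
    calls = np.empty((len(ids), len(df)), dtype=np.int8)
    ref = df["REF"].to_numpy()
    alt = df["ALT"].to_numpy()
    for j, col in enumerate(ids):
        cells = df[col].to_numpy()
        for i, cell in enumerate(cells):
            calls[j, i] = _decode_cell(cell, ref[i], alt[i], path, i, col)
    samp = pd.DataFrame({"id": ids})
    if samples is not None:
        samp = samp.merge(samples, on="id", how="left")
    return GenotypeMatrix(sites=sites, samples=samp, calls=calls)


def _decode_cell(cell, ref: str, alt: str, path, row: int, col: str) -> int:
    if not isinstance(cell, str) or len(cell) != 2:
        raise ValueError(f"{path}: malformed cell {cell!r} at row {row}, column {col!r}")
    if cell == "NN":
        return MISSING
    n_alt = 0
    for a in cell:
        if a == alt:
            n_alt += 1
        elif a != ref:
            raise ValueError(
                f"{path}: allele {a!r} at row {row}, column {col!r} "
                f"not in {{{ref}, {alt}}}"
            )
    return n_alt  # 0 hom_ref, 1 het, 2 hom_alt


def write_genotype_csv(g: GenotypeMatrix, path: str) -> None:
    """Write the CSV dialect read by :func:`read_genotype_csv` (round-trips)."""
    ref = g.sites["ref"].to_numpy()
    alt = g.sites["alt"].to_numpy()
    out = {
        "CHROM": g.sites["chrom"],
        "POS": g.sites["pos"],
        "REF": ref,
        "ALT": alt,
    }
    for j, sid in enumerate(g.sample_ids):
        codes = g.calls[j]
        cells = np.where(
            codes == MISSING,
            "NN",
            np.where(
                codes == HOM_REF,
                np.char.add(ref.astype(str), ref.astype(str)),
                np.where(
                    codes == HET,
                    np.char.add(ref.astype(str), alt.astype(str)),
                    np.char.add(alt.astype(str), alt.astype(str)),
                ),
            ),
        )
        out[sid] = cells
    pd.DataFrame(out).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Phenotypes and expression


PHENO_COLUMNS = ["ID", "PED", "AGE", "SEX", "DBP", "SBP", "MED"]


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read the phenotype CSV (ID, PED, AGE, SEX, DBP, SBP, MED).

    SEX is coded 0/1, MED is a 0/1 ever-medicated flag. Returns a DataFrame
    with lower-case column names (id, ped, age, sex, dbp, sbp, med).
    """
    df = pd.read_csv(path)
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype file lacks columns {missing}")
    df = df[PHENO_COLUMNS].rename(columns=str.lower)
    df["id"] = df["id"].astype(str)
    for c in ("dbp", "sbp"):
        if (df[c].dropna() <= 0).any():
            bad = df.loc[df[c] <= 0, "id"].iloc[0]
            raise ValueError(f"{path}: nonpositive {c.upper()} for individual {bad}")
    return df


def read_expression(path: str) -> pd.DataFrame:
    """Read the expression CSV: transcript rows, individual columns."""
    df = pd.read_csv(path, index_col=0)
    df.columns = df.columns.astype(str)
    df.index.name = "transcript"
    return df
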