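"""Triploid SNP genotypes: VCF input, two-stage filtering, IBS, clustering, PCA.

The clonal-lineage workflow is: read a freebayes-style VCF called with a
polyploid ploidy setting, drop low-confidence sites on their site annotations
(QUAL, QUAL/AO, strand and placement balance), build an alt-allele dosage
matrix, reduce it to a final SNP set (biallelic, polymorphic, MAF and mean
read-depth bounds), compute pairwise identity-by-state similarity generalized
to arbitrary ploidy, and cluster / ordinate the samples on 1 - IBS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "SiteRecord",
    "GenotypeTable",
    "SnpSetFilterParams",
    "IBSMatrix",
    "ClusterTree",
    "PcaResult",
    "VcfParseError",
    "PloidyMismatchError",
    "read_vcf",
    "site_quality_filter",
    "minor_allele_frequency",
    "snp_set_filter",
    "ibs_matrix",
    "hierarchical_cluster",
    "pca_genotypes",
    "genomewide_rescale",
]


class VcfParseError(ValueError):
    """Raised when a VCF file cannot be parsed."""


class PloidyMismatchError(ValueError):
    """Raised when a genotype's allele count disagrees with the declared ploidy."""


@dataclass
class SiteRecord:
    """One variant site with the annotations used by the site-quality filter."""

    chrom: str
    pos: int
    ref: str
    alt: tuple[str, ...]
    qual: float | None
    info: dict

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        ao = self.info.get("AO")
        saf, sar = self.info.get("SAF"), self.info.get("SAR")
        if ao is not None and ao < 0:
            raise ValueError("AO must be non-negative")
        if ao is not None and saf is not None and sar is not None and saf + sar > ao:
            raise ValueError(f"SAF + SAR = {saf + sar} exceeds AO = {ao} at {self.chrom}:{self.pos}")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def n_alt(self) -> int:
        return len(self.alt)


@dataclass
class GenotypeTable:
    """Samples x loci alt-allele dosage matrix with per-sample read depth.

    ``dosage`` holds alt-allele counts in ``{0..ploidy}`` as floats with NaN
    for missing genotypes; ``depth`` is the per-sample per-locus read depth
    (NaN allowed).  ``loci`` optionally carries per-locus metadata (at least
    ``n_alt`` when multiallelic sites may be present).
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray
    depth: np.ndarray
    ploidy: int = 3
    loci: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        n, m = len(self.sample_ids), len(self.locus_ids)
        if self.dosage.shape != (n, m):
            raise ValueError(f"dosage shape {self.dosage.shape} != ({n}, {m})")
        if self.depth.shape != (n, m):
            raise ValueError(f"depth shape {self.depth.shape} != ({n}, {m})")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > self.ploidy)
        if np.any(bad[~np.isnan(self.dosage)]):
            raise ValueError(f"dosages must lie in [0, {self.ploidy}]")
        if self.loci is not None and len(self.loci) != m:
            raise ValueError("loci metadata length does not match locus_ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.locus_ids)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        return GenotypeTable(
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.locus_ids[i] for i in keep],
            dosage=self.dosage[:, keep],
            depth=self.depth[:, keep],
            ploidy=self.ploidy,
            loci=None if self.loci is None else self.loci.iloc[np.flatnonzero(keep) if keep.dtype == bool else keep].reset_index(drop=True),
        )


@dataclass
class SnpSetFilterParams:
    """Final SNP-set selection: biallelic, polymorphic, MAF and depth bounds."""

    maf_min: float = 0.15
    depth_min: float = 10.0
    depth_max: float = 1000.0
    require_biallelic: bool = True
    require_polymorphic: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must not exceed depth_max")


@dataclass
class IBSMatrix:
    """Pairwise identity-by-state similarities in [0, 1] with shared-locus counts."""

    sample_ids: list[str]
    ibs: np.ndarray
    n_loci_used: np.ndarray

    @property
    def dissimilarity(self) -> np.ndarray:
        """1 - IBS, the clustering distance."""
        return 1.0 - self.ibs

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.ibs, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PcaResult:
    scores: pd.DataFrame
    variance_explained: np.ndarray  # percent, non-increasing


def read_vcf(path: str, ploidy: int = 3) -> tuple[list[SiteRecord], GenotypeTable]:
    """Read a VCF 4.x file into site records and an alt-allele dosage table.

    Dosage is the count of (first-)alt alleles in the genotype call; any
    partially or fully missing genotype becomes NaN.  A genotype whose allele
    count differs from ``ploidy`` raises :class:`PloidyMismatchError`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    sites: list[SiteRecord] = []
    dosage_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    n_alt: list[int] = []
    try:
        for i, var in enumerate(vcf):
            info = {}
            for key in ("AO", "SAF", "SAR", "RPR", "RPL"):
                val = var.INFO.get(key)
                if isinstance(val, tuple):
                    val = val[0]
                info[key] = val
            sites.append(
                SiteRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=tuple(var.ALT),
                    qual=var.QUAL,
                    info=info,
                )
            )
            n_alt.append(len(var.ALT))
            dos = np.full(len(samples), np.nan)
            for j, gt in enumerate(var.genotypes):
                alleles = gt[:-1]  # last element is the phasing flag
                if len(alleles) != ploidy:
                    raise PloidyMismatchError(
                        f"{var.CHROM}:{var.POS} sample {samples[j]}: genotype has "
                        f"{len(alleles)} alleles, expected ploidy {ploidy}"
                    )
                if any(a < 0 for a in alleles):
                    continue  # missing
                dos[j] = sum(1 for a in alleles if a == 1)
            dosage_rows.append(dos)
            dp = var.format("DP")
            if dp is None:
                depth_rows.append(np.full(len(samples), np.nan))
            else:
                dp = dp.astype(float).ravel()
                dp[dp < 0] = np.nan
                depth_rows.append(dp)
    except (PloidyMismatchError, VcfParseError):
        raise
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF record near line {len(sites) + 1} of the body: {exc}"
        ) from exc

    dosage = np.array(dosage_rows).T if dosage_rows else np.empty((len(samples), 0))
    depth = np.array(depth_rows).T if depth_rows else np.empty((len(samples), 0))
    table = GenotypeTable(
        sample_ids=samples,
        locus_ids=[s.locus_id for s in sites],
        dosage=dosage,
        depth=depth,
        ploidy=ploidy,
        loci=pd.DataFrame({"chrom": [s.chrom for s in sites],
                           "pos": [s.pos for s in sites],
                           "n_alt": n_alt}),
    )
    return sites, table


# site-quality rules, applied as strict inequalities in this order
_SITE_RULES = (
    ("qual", lambda q, i: q is not None and q > 1),
    ("qual_ao", lambda q, i: i.get("AO") not in (None, 0) and q / i["AO"] > 10),
    ("saf", lambda q, i: i.get("SAF") is not None and i["SAF"] > 0),
    ("sar", lambda q, i: i.get("SAR") is not None and i["SAR"] > 0),
    ("rpr", lambda q, i: i.get("RPR") is not None and i["RPR"] > 1),
    ("rpl", lambda q, i: i.get("RPL") is not None and i["RPL"] > 1),
)


def site_quality_filter(
    records: Iterable[SiteRecord], return_report: bool = False
) -> list[SiteRecord] | tuple[list[SiteRecord], pd.DataFrame]:
    """Keep sites with QUAL > 1, QUAL/AO > 10, SAF > 0, SAR > 0, RPR > 1, RPL > 1.

    Order is preserved.  A record missing one of the annotations is rejected
    with reason ``missing:<key>`` rather than silently kept; otherwise the
    reason names the first failing rule.
    """
    kept: list[SiteRecord] = []
    reasons: list[dict] = []
    for rec in records:
        reason = None
        for key in ("AO", "SAF", "SAR", "RPR", "RPL"):
            if rec.info.get(key) is None:
                reason = f"missing:{key}"
                break
        if reason is None and rec.qual is None:
            reason = "missing:QUAL"
        if reason is None:
            for name, rule in _SITE_RULES:
                if not rule(rec.qual, rec.info):
                    reason = name
                    break
        if reason is None:
            kept.append(rec)
        else:
            reasons.append({"locus_id": rec.locus_id, "reason": reason})
    if return_report:
        return kept, pd.DataFrame(reasons, columns=["locus_id", "reason"])
    return kept


def minor_allele_frequency(dosages: Sequence[float], ploidy: int = 3) -> float:
    """MAF from polyploid alt-allele dosages: min(f, 1 - f) with f = sum(d) / (ploidy * n)."""
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    if not ok.any():
        raise ValueError("MAF undefined: all dosages missing at this locus")
    f = d[ok].sum() / (ploidy * ok.sum())
    return float(min(f, 1.0 - f))


def snp_set_filter(
    table: GenotypeTable, params: SnpSetFilterParams | None = None
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Select the final SNP set and report a per-locus rejection reason table.

    Keeps loci that are biallelic, polymorphic, have MAF >= ``maf_min`` and a
    mean read depth per sample within ``[depth_min, depth_max]``.  The sample
    set and the relative locus order are unchanged.
    """
    params = params or SnpSetFilterParams()
    n_alt = (
        table.loci["n_alt"].to_numpy()
        if table.loci is not None and "n_alt" in table.loci
        else np.ones(table.n_loci, dtype=int)
    )
    reasons = []
    keep = np.zeros(table.n_loci, dtype=bool)
    for j in range(table.n_loci):
        col = table.dosage[:, j]
        ok = ~np.isnan(col)
        reason = None
        if params.require_biallelic and n_alt[j] != 1:
            reason = "multiallelic"
        elif not ok.any():
            reason = "all_missing"
        elif params.require_polymorphic and np.nanmin(col) == np.nanmax(col):
            reason = "monomorphic"
        elif minor_allele_frequency(col, table.ploidy) < params.maf_min:
            reason = "low_maf"
        else:
            mean_depth = np.nanmean(table.depth[:, j]) if ~np.all(np.isnan(table.depth[:, j])) else np.nan
            if np.isnan(mean_depth) or not (params.depth_min <= mean_depth <= params.depth_max):
                reason = "depth"
        keep[j] = reason is None
        reasons.append({"locus_id": table.locus_ids[j], "kept": reason is None, "reason": reason})
    report = pd.DataFrame(reasons)
    if not keep.any():
        warnings.warn("snp_set_filter removed every locus", UserWarning, stacklevel=2)
    return table.subset_loci(keep), report


def ibs_matrix(table: GenotypeTable) -> IBSMatrix:
    """Pairwise polyploid IBS: mean over shared loci of 1 - |d_i - d_j| / ploidy.

    Loci where either sample is missing are dropped pairwise; a pair with no
    shared loci gets a NaN similarity and a warning.
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples for an IBS matrix")
    if table.n_loci < 1:
        raise ValueError("need at least one locus for an IBS matrix")
    n = table.n_samples
    d = table.dosage
    ok = ~np.isnan(d)
    ibs = np.ones((n, n))
    nl = np.zeros((n, n), dtype=int)
    for i in range(n):
        nl[i, i] = ok[i].sum()
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            m = int(shared.sum())
            nl[i, j] = nl[j, i] = m
            if m == 0:
                warnings.warn(
                    f"samples {table.sample_ids[i]!r} and {table.sample_ids[j]!r} share no "
                    "non-missing loci; IBS entry set to NaN",
                    UserWarning,
                    stacklevel=2,
                )
                ibs[i, j] = ibs[j, i] = np.nan
                continue
            sim = 1.0 - np.abs(d[i, shared] - d[j, shared]) / table.ploidy
            ibs[i, j] = ibs[j, i] = float(sim.mean())
    return IBSMatrix(sample_ids=list(table.sample_ids), ibs=ibs, n_loci_used=nl)


@dataclass
class ClusterTree:
    """Agglomerative clustering of samples on a dissimilarity matrix."""

    linkage_matrix: np.ndarray
    labels: list[str]
    method: str

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels (1..k) from cutting the tree into ``k`` groups."""
        return hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths in dissimilarity units."""
        root = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"


def hierarchical_cluster(
    dissim: np.ndarray | pd.DataFrame | IBSMatrix,
    linkage: str = "average",
    labels: Sequence[str] | None = None,
) -> ClusterTree:
    """Agglomerative clustering of a symmetric dissimilarity matrix.

    Default linkage is UPGMA (``average``), the usual choice for SNP IBS
    dendrograms; any scipy linkage method tag is accepted.
    """
    if isinstance(dissim, IBSMatrix):
        labels = labels or dissim.sample_ids
        dissim = dissim.dissimilarity
    if isinstance(dissim, pd.DataFrame):
        labels = labels or list(dissim.index)
        dissim = dissim.to_numpy()
    dissim = np.asarray(dissim, dtype=float)
    if dissim.ndim != 2 or dissim.shape[0] != dissim.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(dissim, dissim.T, atol=1e-12, equal_nan=True):
        raise ValueError("dissimilarity matrix is not symmetric")
    if not np.allclose(np.diag(dissim), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    labels = list(labels) if labels is not None else [str(i) for i in range(dissim.shape[0])]
    condensed = squareform(dissim, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(linkage_matrix=Z, labels=labels, method=linkage)


def pca_genotypes(
    table: GenotypeTable, center: bool = True, scale: bool = False
) -> PcaResult:
    """PCA of the dosage matrix; missing dosages are imputed to the locus mean."""
    if table.n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    X = table.dosage.copy()
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    total = (S**2).sum()
    var_pct = 100.0 * (S**2) / total if total > 0 else np.zeros_like(S)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=table.sample_ids, columns=cols),
        variance_explained=var_pct,
    )


def genomewide_rescale(
    dissim_fraction: float, n_snps: int, genome_size: float, ndigits: int = 2
) -> tuple[int, float]:
    """Rescale a SNP-set dissimilarity fraction to genome-wide terms.

    Returns the implied number of differing SNPs (nearest integer) and the
    genome-wide dissimilarity as a percent of genome size, rounded to
    ``ndigits`` decimal places.
    """
    if not 0.0 <= dissim_fraction <= 1.0:
        raise ValueError("dissim_fraction must lie in [0, 1]")
    if n_snps <= 0 or genome_size <= 0:
        raise ValueError("n_snps and genome_size must be positive")
    snp_count = int(round(dissim_fraction * n_snps))
    percent = round(100.0 * snp_count / genome_size, ndigits)
    return snp_count, percent
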