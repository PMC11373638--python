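"""Genotype matrix container, VCF/TSV input-output, marker and individual
filtering, and LD-kNN imputation of missing dosages.

Genotypes are biallelic SNP dosages (count of the alternate allele, 0/1/2),
stored as a float matrix with ``nan`` marking missing calls.  Filtering follows
the conventional GBS pipeline order: individuals by call rate, then SNPs by
missingness, then SNPs by minor allele frequency on the retained individuals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "FilterParams",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "read_tsv",
    "write_tsv",
    "filter_genotypes",
    "ld_knni_impute",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNPs dosage matrix with SNP metadata.

    Parameters
    ----------
    individual_ids
        Unique identifiers, one per row of ``dosage``.
    snp_ids
        Unique identifiers, one per column of ``dosage``.
    chrom
        Chromosome label per SNP.
    pos_bp
        1-based physical position per SNP; must be sorted (non-decreasing)
        within each chromosome block.
    dosage
        ``(n_individuals, n_snps)`` float array, values in {0, 1, 2} or
        ``nan`` for a missing call.
    pos_cm
        Optional genetic position per SNP (centiMorgan).
    """

    individual_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    dosage: np.ndarray
    pos_cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.pos_cm is not None:
            self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        n, m = self.dosage.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos_bp) == m):
            raise ValueError("SNP metadata lengths do not match dosage columns")
        if len(set(self.snp_ids)) != m:
            raise ValueError("SNP ids are not unique")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids are not unique")
        for c in pd.unique(self.chrom):
            pos = self.pos_bp[self.chrom == c]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted within chromosome {c}")
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(self.dosage) & ~np.isin(self.dosage, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or nan")

    # -- basic properties -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def call_rate(self) -> np.ndarray:
        """Per-individual fraction of non-missing calls."""
        return 1.0 - self.missing_mask.mean(axis=1)

    def snp_missingness(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return self.missing_mask.mean(axis=0)

    def alt_allele_freq(self) -> np.ndarray:
        """Per-SNP alternate-allele frequency over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls."""
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)

    # -- manipulation -----------------------------------------------------

    def subset(self, ind_idx=None, snp_idx=None) -> "GenotypeMatrix":
        ind_idx = np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in ind_idx],
            snp_ids=[self.snp_ids[j] for j in snp_idx],
            chrom=self.chrom[snp_idx],
            pos_bp=self.pos_bp[snp_idx],
            dosage=self.dosage[np.ix_(ind_idx, snp_idx)].copy(),
            pos_cm=None if self.pos_cm is None else self.pos_cm[snp_idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return self.subset()

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos_bp, other.pos_bp)
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


@dataclass
class FilterParams:
    """Marker/individual quality thresholds (GBS pipeline defaults)."""

    min_maf: float = 0.03
    max_snp_missing: float = 0.10
    min_individual_call_rate: float = 0.80

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_snp_missing", "min_individual_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FilterReport:
    """Counts of individuals/SNPs removed at each filtering step."""

    individuals_removed_call_rate: int = 0
    snps_removed_missingness: int = 0
    snps_removed_maf: int = 0
    individuals_retained: int = 0
    snps_retained: int = 0
    removed_individual_ids: list[str] = field(default_factory=list)
    removed_snp_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


class EmptyMatrixError(ValueError):
    """All individuals or all SNPs were removed by filtering."""


def filter_genotypes(
    geno: GenotypeMatrix, params: FilterParams | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply call-rate, missingness and MAF filters in pipeline order.

    Order of application: (1) individuals with call rate below
    ``min_individual_call_rate`` are removed; (2) SNPs whose missingness among
    retained individuals exceeds ``max_snp_missing`` are removed; (3) SNPs
    whose MAF among retained individuals falls below ``min_maf`` are removed.
    The operation is idempotent.
    """
    params = params or FilterParams()
    keep_ind = np.flatnonzero(geno.call_rate() >= params.min_individual_call_rate)
    removed_inds = [i for k, i in enumerate(geno.individual_ids) if k not in set(keep_ind)]
    if keep_ind.size == 0:
        raise EmptyMatrixError("no individuals pass the call-rate filter")
    g1 = geno.subset(ind_idx=keep_ind)

    keep_miss = g1.snp_missingness() <= params.max_snp_missing
    n_removed_miss = int((~keep_miss).sum())
    g2 = g1.subset(snp_idx=np.flatnonzero(keep_miss))
    removed_snps = [s for s, k in zip(g1.snp_ids, keep_miss) if not k]

    keep_maf = g2.maf() >= params.min_maf
    n_removed_maf = int((~keep_maf).sum())
    removed_snps += [s for s, k in zip(g2.snp_ids, keep_maf) if not k]
    g3 = g2.subset(snp_idx=np.flatnonzero(keep_maf))
    if g3.n_snps == 0:
        raise EmptyMatrixError("no SNPs pass the missingness/MAF filters")

    report = FilterReport(
        individuals_removed_call_rate=len(removed_inds),
        snps_removed_missingness=n_removed_miss,
        snps_removed_maf=n_removed_maf,
        individuals_retained=g3.n_individuals,
        snps_retained=g3.n_snps,
        removed_individual_ids=removed_inds,
        removed_snp_ids=removed_snps,
    )
    return g3, report


# ---------------------------------------------------------------------------
# VCF and TSV input/output
# ---------------------------------------------------------------------------


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF v4.2 with GT fields (``./.`` missing).

    Alleles are written as placeholder REF=A / ALT=T: dosage files carry no
    nucleotide information and none is needed downstream.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=synpop\n")
        for c in pd.unique(geno.chrom):
            length = int(geno.pos_bp[geno.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individual_ids)
            + "\n"
        )
        for j in range(geno.n_snps):
            col = geno.dosage[:, j]
            gts = "\t".join(
                "./." if np.isnan(d) else gt_map[float(d)] for d in col
            )
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos_bp[j]}\t{geno.snp_ids[j]}"
                f"\tA\tT\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are skipped (a count is logged).  Genotypes are
    converted to alternate-allele dosages regardless of phasing.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error paths
        raise GenotypeParseError(f"cannot open VCF {path}: {exc}") from exc
    individual_ids = list(vcf.samples)
    snp_ids: list[str] = []
    chroms: list[str] = []
    pos: list[int] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    dose_of_gt_type = np.array([0.0, 1.0, np.nan, 2.0])
    for i, variant in enumerate(vcf):
        try:
            if len(variant.ALT) != 1:
                n_multi += 1
                continue
            snp_ids.append(variant.ID if variant.ID not in (None, ".") else
                           f"{variant.CHROM}_{variant.POS}")
            chroms.append(variant.CHROM)
            pos.append(variant.POS)
            rows.append(dose_of_gt_type[variant.gt_types])
        except Exception as exc:
            raise GenotypeParseError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc
    if n_multi:
        logger.info("skipped %d multi-allelic record(s) in %s", n_multi, path)
    if not rows:
        raise GenotypeParseError(f"no biallelic SNP records in {path}")
    dosage = np.vstack(rows).T  # individuals x SNPs
    return GenotypeMatrix(individual_ids, snp_ids, np.array(chroms, dtype=object),
                          np.array(pos), dosage)


def write_tsv(geno: GenotypeMatrix, path, map_path=None) -> None:
    """Write a dosage TSV (rows = individuals, columns = SNPs, missing = NA)
    and, optionally, the genetic map TSV (snp_id, chrom, pos_bp, pos_cM)."""
    df = pd.DataFrame(geno.dosage, index=geno.individual_ids, columns=geno.snp_ids)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="individual_id",
              float_format="%.0f")
    if map_path is not None:
        write_map_tsv(geno, map_path)


def write_map_tsv(geno: GenotypeMatrix, path) -> None:
    m = pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "chrom": geno.chrom,
            "pos_bp": geno.pos_bp,
            "pos_cM": np.full(geno.n_snps, np.nan) if geno.pos_cm is None else geno.pos_cm,
        }
    )
    m.to_csv(path, sep="\t", index=False)


def read_tsv(path, map_path=None) -> GenotypeMatrix:
    """Read a dosage TSV (with a ``individual_id`` index column) and a genetic
    map TSV carrying per-SNP chromosome and positions.

    Without a map file, all SNPs are placed on a single dummy chromosome at
    consecutive positions (sufficient for non-positional analyses).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:
        raise GenotypeParseError(f"cannot parse dosage TSV {path}: {exc}") from exc
    snp_ids = [str(c) for c in df.columns]
    if map_path is not None:
        m = pd.read_csv(map_path, sep="\t", dtype={"snp_id": str, "chrom": str})
        m = m.set_index("snp_id").loc[snp_ids]
        chrom = m["chrom"].to_numpy(dtype=object)
        pos_bp = m["pos_bp"].to_numpy(dtype=np.int64)
        pos_cm = m["pos_cM"].to_numpy(dtype=float) if "pos_cM" in m else None
        if pos_cm is not None and np.all(np.isnan(pos_cm)):
            pos_cm = None
    else:
        chrom = np.array(["0"] * len(snp_ids), dtype=object)
        pos_bp = np.arange(1, len(snp_ids) + 1)
        pos_cm = None
    return GenotypeMatrix([str(i) for i in df.index], snp_ids, chrom, pos_bp,
                          df.to_numpy(dtype=float), pos_cm=pos_cm)


# ---------------------------------------------------------------------------
# LD-kNN imputation
# ---------------------------------------------------------------------------


def _pairwise_complete_r2(dosage: np.ndarray, target: int) -> np.ndarray:
    """Squared Pearson correlation of every SNP with SNP ``target``, each pair
    computed over individuals where both calls are present (composite LD on
    unphased dosages)."""
    x = dosage[:, target]
    obs = ~np.isnan(dosage)
    vx = ~np.isnan(x)
    m = obs & vx[:, None]  # rows usable per column
    xf = np.where(np.isnan(x), 0.0, x)
    df = np.where(np.isnan(dosage), 0.0, dosage)
    n = m.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = (xf[:, None] * m).sum(axis=0)
        sy = (df * m).sum(axis=0)
        sxx = ((xf**2)[:, None] * m).sum(axis=0)
        syy = (df**2 * m).sum(axis=0)
        sxy = (xf[:, None] * df * m).sum(axis=0)
        cov = sxy - sx * sy / n
        varx = sxx - sx**2 / n
        vary = syy - sy**2 / n
        r2 = cov**2 / (varx * vary)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


def ld_knni_impute(
    geno: GenotypeMatrix, l: int = 30, k: int = 10, eps: float = 1e-6
) -> GenotypeMatrix:
    """Impute missing dosages by LD-kNN (nearest neighbours on high-LD markers).

    For each SNP ``s`` with missing calls, the ``l`` markers with the highest
    r² to ``s`` are selected (pairwise-complete composite LD).  For each
    missing cell ``(i, s)``, the distance from individual ``i`` to every
    individual with an observed call at ``s`` is the mean absolute dosage
    difference over those ``l`` markers (sites missing in either individual
    are ignored).  The imputed dosage is the inverse-distance-weighted mean of
    the ``k`` nearest neighbours' dosages at ``s``, rounded to the nearest
    integer in {0, 1, 2}.  A neighbour at distance zero receives weight
    ``1/eps``.  Ranking ties are broken by individual index.

    Observed cells are never altered.  A SNP with no observed call at all is
    left missing and reported via a warning.
    """
    if l < 1 or k < 1:
        raise ValueError("l and k must be >= 1")
    out = geno.dosage.copy()
    missing = np.isnan(geno.dosage)
    unimputable: list[str] = []
    for s in np.flatnonzero(missing.any(axis=0)):
        col_obs = ~missing[:, s]
        if not col_obs.any():
            unimputable.append(geno.snp_ids[s])
            continue
        r2 = _pairwise_complete_r2(geno.dosage, s)
        r2[s] = -np.inf  # never select the target itself
        n_pick = min(l, geno.n_snps - 1)
        # highest r2 first; index order breaks ties deterministically
        order = np.lexsort((np.arange(geno.n_snps), -r2))
        panel = order[:n_pick]
        sub = geno.dosage[:, panel]  # individuals x l
        donors = np.flatnonzero(col_obs)
        donor_sub = sub[donors]
        donor_obs = ~np.isnan(donor_sub)
        donor_vals = np.where(donor_obs, donor_sub, 0.0)
        for i in np.flatnonzero(missing[:, s]):
            qi = sub[i]
            qi_obs = ~np.isnan(qi)
            both = donor_obs & qi_obs[None, :]
            n_comp = both.sum(axis=1)
            diff = np.abs(donor_vals - np.where(qi_obs, qi, 0.0)[None, :]) * both
            with np.errstate(invalid="ignore"):
                dist = diff.sum(axis=1) / n_comp
            dist[n_comp == 0] = np.inf
            rank = np.lexsort((donors, dist))
            nearest = rank[: min(k, donors.size)]
            d_near = dist[nearest]
            w = 1.0 / np.maximum(d_near, eps)
            finite = np.isfinite(d_near)
            if not finite.any():
                # no overlapping markers with any donor: fall back to the
                # unweighted donor mean at s
                val = geno.dosage[donors, s].mean()
            else:
                w = np.where(finite, w, 0.0)
                val = np.sum(w * geno.dosage[donors[nearest], s]) / np.sum(w)
            out[i, s] = np.clip(np.rint(val), 0, 2)
    if unimputable:
        warnings.warn(
            f"{len(unimputable)} SNP(s) had no observed calls and were left "
            f"missing: {unimputable[:5]}...",
            stacklevel=2,
        )
    res = geno.copy()
    res.dosage = out
    return res
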