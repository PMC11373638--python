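"""Population-genetic characterization of SYN generations: Weir-Cockerham
Fst, Nei's (1972) standard genetic distance, Shannon's diversity index, PCA
population structure, and linkage-disequilibrium decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genio import GenotypeMatrix

__all__ = [
    "weir_cockerham_fst",
    "nei_distance",
    "shannon_index",
    "pca_structure",
    "ld_decay",
    "FstResult",
    "PCAResult",
    "LDResult",
    "diversity_summary",
    "NEI_D_CAP",
]

#: Sentinel reported for an infinite Nei distance (groups fixed for opposite
#: alleles at every locus); -ln of the identity floor used in the computation.
NEI_D_CAP = float(-np.log(1e-12))


def _as_label_series(labels, individual_ids: list[str]) -> pd.Series:
    s = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    s.index = s.index.astype(str)
    unknown = set(s.index) - set(individual_ids)
    if unknown:
        raise ValueError(f"labels reference unknown individuals: {sorted(unknown)[:5]}")
    return s.reindex(individual_ids)


def _group_counts(dosage: np.ndarray):
    """Per-SNP called-sample size, allele frequency and heterozygote
    frequency for one group of rows."""
    called = ~np.isnan(dosage)
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nansum(dosage, axis=0) / (2.0 * n)
        h = (dosage == 1).sum(axis=0) / n
    return n, p, h


@dataclass
class FstResult:
    per_snp: pd.Series          # theta per SNP; nan where skipped
    summary: dict               # min/max/mean over valid SNPs
    n_skipped: int
    focal_group: str


def weir_cockerham_fst(
    geno: GenotypeMatrix, labels, focal_group: str
) -> FstResult:
    """Per-SNP Weir-Cockerham theta for one group against the pooled rest.

    The estimator uses the classical variance components a (among
    populations), b (among individuals within populations) and c (within
    individuals) for two populations: the focal group and the pooled
    complement.  Negative per-SNP estimates are retained.  SNPs where either
    group has fewer than 2 called individuals, or where the denominator
    a + b + c is zero (monomorphic everywhere), are skipped and counted.
    """
    lab = _as_label_series(labels, geno.individual_ids)
    focal_rows = (lab == focal_group).to_numpy()
    other_rows = (lab != focal_group).to_numpy() & lab.notna().to_numpy()
    if focal_rows.sum() == 0 or other_rows.sum() == 0:
        raise ValueError(f"focal group {focal_group!r} or its complement is empty")

    r = 2.0
    n1, p1, h1 = _group_counts(geno.dosage[focal_rows])
    n2, p2, h2 = _group_counts(geno.dosage[other_rows])
    valid = (n1 >= 2) & (n2 >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(valid & (denom != 0), a / denom, np.nan)

    per_snp = pd.Series(theta, index=geno.snp_ids, name="theta")
    ok = per_snp.dropna()
    n_skipped = geno.n_snps - len(ok)
    summary = {
        "min": float(ok.min()) if len(ok) else np.nan,
        "max": float(ok.max()) if len(ok) else np.nan,
        "mean": float(ok.mean()) if len(ok) else np.nan,
        "n_snps": int(len(ok)),
    }
    return FstResult(per_snp, summary, n_skipped, focal_group)


def nei_distance(geno: GenotypeMatrix, labels) -> pd.DataFrame:
    """Pairwise Nei (1972) standard genetic distance between groups.

    ``D = -ln(Jxy / sqrt(Jx Jy))`` with gene identities averaged over loci
    computable in both groups.  Symmetric with a zero diagonal.  Fixation for
    opposite alleles at every locus gives infinite D, reported as
    :data:`NEI_D_CAP` with a warning.
    """
    lab = _as_label_series(labels, geno.individual_ids)
    groups = [g for g in pd.unique(lab.dropna())]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    freqs, counts = {}, {}
    for g in groups:
        rows = (lab == g).to_numpy()
        n, p, _ = _group_counts(geno.dosage[rows])
        freqs[g], counts[g] = p, n
    D = pd.DataFrame(0.0, index=groups, columns=groups)
    capped = False
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            both = (counts[g1] > 0) & (counts[g2] > 0)
            p1, p2 = freqs[g1][both], freqs[g2][both]
            jxy = float(np.mean(p1 * p2 + (1 - p1) * (1 - p2)))
            jx = float(np.mean(p1**2 + (1 - p1) ** 2))
            jy = float(np.mean(p2**2 + (1 - p2) ** 2))
            identity = jxy / np.sqrt(jx * jy)
            if identity <= 1e-12:
                capped = True
                d = NEI_D_CAP
            else:
                d = float(-np.log(identity))
            D.loc[g1, g2] = D.loc[g2, g1] = max(d, 0.0)
    if capped:
        warnings.warn(
            f"infinite Nei distance capped at {NEI_D_CAP:.2f} for fully "
            "differentiated group pair(s)",
            stacklevel=2,
        )
    return D


def shannon_index(geno: GenotypeMatrix, labels=None):
    """Shannon's diversity index per individual over its dosage proportions.

    For individual i with non-missing dosages d_s, ``q_s = d_s / sum(d)`` and
    ``H_i = -sum q_s ln q_s``; an individual heterozygous at all m SNPs
    attains the maximum ln(m).  With ``labels``, a per-group min/max/mean
    summary (the usual diversity-table layout) is returned alongside.
    """
    H = np.zeros(geno.n_individuals)
    for i in range(geno.n_individuals):
        d = geno.dosage[i]
        d = d[~np.isnan(d)]
        tot = d.sum()
        if tot == 0:
            warnings.warn(
                f"individual {geno.individual_ids[i]!r} has all-zero dosages; H set to 0",
                stacklevel=2,
            )
            continue
        q = d[d > 0] / tot
        H[i] = float(-(q * np.log(q)).sum())
    per_ind = pd.Series(H, index=geno.individual_ids, name="H")
    if labels is None:
        return per_ind
    lab = _as_label_series(labels, geno.individual_ids)
    rows = []
    for g, sub in per_ind.groupby(lab):
        rows.append({"group": g, "N": len(sub), "min": sub.min(),
                     "max": sub.max(), "mean": sub.mean()})
    return per_ind, pd.DataFrame(rows).set_index("group")


@dataclass
class PCAResult:
    coordinates: np.ndarray            # individuals x axes (scores)
    explained_variance_ratio: np.ndarray
    individual_ids: list[str]
    degenerate: bool = False

    def frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.individual_ids, columns=cols)


def pca_structure(geno: GenotypeMatrix, n_components: int | None = None) -> PCAResult:
    """Centered (unscaled) PCA of the individuals x SNP dosage matrix.

    Missing cells are mean-imputed per SNP before decomposition; columns are
    centered but not variance-scaled (the ``prcomp`` default).  Variance
    proportions sum to 1 over all axes.  A matrix of identical rows yields an
    explicit degenerate result with zero variance proportions.
    """
    if geno.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    X = geno.dosage.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_cells = np.isnan(X)
    X[nan_cells] = np.take(col_mean, np.where(nan_cells)[1])
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    var = S**2 / (geno.n_individuals - 1)
    total = var.sum()
    if total == 0:
        k = len(S) if n_components is None else min(n_components, len(S))
        return PCAResult(
            coordinates=np.zeros((geno.n_individuals, k)),
            explained_variance_ratio=np.zeros(k),
            individual_ids=list(geno.individual_ids),
            degenerate=True,
        )
    ratio = var / total
    scores = U * S
    if n_components is not None:
        scores = scores[:, :n_components]
        ratio = ratio[:n_components]
    return PCAResult(scores, ratio, list(geno.individual_ids))


@dataclass
class LDResult:
    distances_bp: np.ndarray
    r2: np.ndarray
    mean_r2: float
    decay_distance_bp: float
    smooth: np.ndarray           # (distance, fitted r2) sorted by distance
    n_pairs: int
    r2_threshold: float


def _pair_r2_complete(dosage: np.ndarray, j1: int, j2: int) -> float:
    x, y = dosage[:, j1], dosage[:, j2]
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return np.nan
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _ld_pairs(geno: GenotypeMatrix, max_dist_bp: float):
    """(distance, r2) for intra-chromosomal SNP pairs within the window;
    composite LD on dosages, pairwise-complete individuals."""
    dists, r2s = [], []
    complete = not np.isnan(geno.dosage).any()
    for c in pd.unique(geno.chrom):
        idx = np.flatnonzero(geno.chrom == c)
        if idx.size < 2:
            continue
        pos = geno.pos_bp[idx]
        sub = geno.dosage[:, idx]
        if complete:
            sd = sub.std(axis=0)
            poly = sd > 0
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(sub[:, poly], rowvar=False)
            ppos = pos[poly]
            jj, kk = np.triu_indices(poly.sum(), k=1)
            d = ppos[kk] - ppos[jj]
            keep = (d > 0) & (d <= max_dist_bp)
            dists.append(d[keep].astype(float))
            r2s.append(corr[jj[keep], kk[keep]] ** 2)
        else:
            for a in range(idx.size):
                for b in range(a + 1, idx.size):
                    d = pos[b] - pos[a]
                    if d <= 0 or d > max_dist_bp:
                        continue
                    r2 = _pair_r2_complete(sub, a, b)
                    if not np.isnan(r2):
                        dists.append(np.array([float(d)]))
                        r2s.append(np.array([r2]))
    if not dists:
        return np.array([]), np.array([])
    return np.concatenate(dists), np.concatenate(r2s)


def _decay_distance(smooth: np.ndarray, threshold: float) -> float:
    """Smallest distance at which the fitted curve is below the threshold,
    interpolated at the crossing; NaN if the curve never drops below."""
    d, f = smooth[:, 0], smooth[:, 1]
    below = f < threshold
    if not below.any():
        return np.nan
    i = int(np.argmax(below))
    if i == 0:
        return float(d[0])
    # linear interpolation of the crossing from above
    d0, d1, f0, f1 = d[i - 1], d[i], f[i - 1], f[i]
    if f0 == f1:
        return float(d1)
    return float(d0 + (f0 - threshold) * (d1 - d0) / (f0 - f1))


def ld_decay(
    geno: GenotypeMatrix,
    labels=None,
    max_dist_bp: float = 10_000_000,
    r2_threshold: float = 0.2,
    lowess_frac: float = 0.3,
):
    """LD decay per population: pairwise composite r² vs physical distance,
    a locally weighted smoothing curve, and the decay distance where the
    fitted curve first falls below ``r2_threshold``.

    Returns an :class:`LDResult`, or a dict keyed by group when ``labels``
    are given.
    """
    if labels is not None:
        lab = _as_label_series(labels, geno.individual_ids)
        out = {}
        for g in pd.unique(lab.dropna()):
            rows = np.flatnonzero((lab == g).to_numpy())
            out[str(g)] = ld_decay(
                geno.subset(ind_idx=rows),
                max_dist_bp=max_dist_bp,
                r2_threshold=r2_threshold,
                lowess_frac=lowess_frac,
            )
        return out
    if geno.n_individuals < 10:
        warnings.warn(
            f"population has only {geno.n_individuals} individuals; r2 "
            "estimates will be noisy",
            stacklevel=2,
        )
    d, r2 = _ld_pairs(geno, max_dist_bp)
    if d.size == 0:
        raise ValueError("no intra-chromosomal SNP pairs within the window")
    if d.size < 5:  # too few pairs to smooth; use the raw sorted points
        order = np.argsort(d)
        sm = np.column_stack([d[order], r2[order]])
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = lowess(r2, d, frac=lowess_frac, return_sorted=True)
    return LDResult(
        distances_bp=d,
        r2=r2,
        mean_r2=float(r2.mean()),
        decay_distance_bp=_decay_distance(sm, r2_threshold),
        smooth=sm,
        n_pairs=int(d.size),
        r2_threshold=r2_threshold,
    )


def diversity_summary(geno: GenotypeMatrix, labels) -> pd.DataFrame:
    """Diversity-table layout: per group N, Fst (min/max/mean of per-SNP
    theta vs the pooled remainder), Nei's D vs other groups (min/max/mean),
    and Shannon's H over individuals (min/max/mean)."""
    lab = _as_label_series(labels, geno.individual_ids)
    groups = [str(g) for g in pd.unique(lab.dropna())]
    D = nei_distance(geno, labels)
    _, h_summary = shannon_index(geno, labels)
    rows = []
    for g in groups:
        fst = weir_cockerham_fst(geno, labels, g)
        others = [o for o in groups if o != g]
        dvals = D.loc[g, others].to_numpy(dtype=float)
        rows.append(
            {
                "group": g,
                "N": int((lab == g).sum()),
                "Fst_min": fst.summary["min"],
                "Fst_max": fst.summary["max"],
                "Fst_mean": fst.summary["mean"],
                "D_min": float(dvals.min()),
                "D_max": float(dvals.max()),
                "D_mean": float(dvals.mean()),
                "H_min": float(h_summary.loc[g, "min"]),
                "H_max": float(h_summary.loc[g, "max"]),
                "H_mean": float(h_summary.loc[g, "mean"]),
            }
        )
    return pd.DataFrame(rows).set_index("group")
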