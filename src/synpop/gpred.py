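"""Ridge-regression BLUP genomic prediction with year fixed effects.

The model is the standard marker-effect mixed model

    y = X beta + Z u + eps,    u ~ N(0, sigma2_u I),  eps ~ N(0, sigma2_e I)

with ``y`` the stacked multi-year phenotype records of the training
population, ``X`` a one-column-per-year design of fixed year effects, and
``Z`` the column-centered marker dosages of each record's individual.  The
variance ratio ``lambda = sigma2_e / sigma2_u`` is found by REML on the
profiled likelihood after a single eigendecomposition of the genomic
relationship ``Z Z'`` projected off the fixed effects; ``beta`` and ``u``
then come from the mixed-model equations at the optimum.  The genomic
estimated breeding value of any genotyped individual is its centered dosage
row times ``u``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genio import GenotypeMatrix
from .stats import TukeyResult, tukey_hsd

logger = logging.getLogger(__name__)

__all__ = ["RRBLUPModel", "CVResult", "fit_rrblup", "cross_validate",
           "predict_populations", "PopulationPrediction"]


@dataclass
class RRBLUPModel:
    """A fitted ridge-regression BLUP model."""

    beta: pd.Series                 # fixed year effects, indexed by year
    u: np.ndarray                   # random marker effects
    lambda_: float                  # sigma2_e / sigma2_u
    sigma2_u: float
    sigma2_e: float
    snp_ids: list[str]
    center: np.ndarray              # training column means of the dosages
    years: list
    reml_loglik: float
    training_ids: list[str]

    def gebv(self, geno: GenotypeMatrix) -> pd.Series:
        """Genomic estimated breeding values (no fixed-effect part) for the
        individuals of ``geno``, on the SNP intersection with training."""
        common = [s for s in self.snp_ids if s in set(geno.snp_ids)]
        if not common:
            raise ValueError("no SNP overlap between model and target matrix")
        if len(common) < len(self.snp_ids):
            logger.info(
                "target matrix covers %d/%d training SNPs", len(common),
                len(self.snp_ids),
            )
        tr_pos = {s: j for j, s in enumerate(self.snp_ids)}
        tg_pos = {s: j for j, s in enumerate(geno.snp_ids)}
        jt = np.array([tr_pos[s] for s in common])
        jg = np.array([tg_pos[s] for s in common])
        dos = geno.dosage[:, jg]
        dos = np.where(np.isnan(dos), self.center[jt], dos)  # mean-impute
        vals = (dos - self.center[jt]) @ self.u[jt]
        return pd.Series(vals, index=geno.individual_ids, name="gebv")

    def predict(self, geno: GenotypeMatrix) -> pd.Series:
        """Predicted trait value: average year effect plus GEBV."""
        return self.gebv(geno) + float(self.beta.mean())


def _records(pheno: pd.DataFrame, trait: str | None) -> pd.DataFrame:
    df = pheno.copy()
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    if df.empty:
        raise ValueError("no phenotype records (after trait selection)")
    df["genotype_id"] = df["genotype_id"].astype(str)
    return df


def fit_rrblup(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    trait: str | None = None,
    lambda_: float | None = None,
) -> RRBLUPModel:
    """Fit the RR-BLUP model on phenotype records and marker dosages.

    ``pheno`` needs columns ``genotype_id, year, value`` (and optionally
    ``trait``).  Every phenotyped individual must be genotyped.  When
    ``lambda_`` is given, REML is skipped and the mixed-model equations are
    solved at that fixed variance ratio (used for limit checks).
    """
    df = _records(pheno, trait)
    ids = df["genotype_id"].tolist()
    geno_pos = {g: i for i, g in enumerate(geno.individual_ids)}
    missing = sorted(set(ids) - set(geno_pos))
    if missing:
        raise ValueError(f"phenotyped individuals not genotyped: {missing[:5]}")
    y = df["value"].to_numpy(dtype=float)
    n = y.size
    years = sorted(df["year"].unique().tolist())
    if len(years) > n:
        raise ValueError("more years than phenotype records")
    X = np.column_stack([(df["year"] == yr).to_numpy(float) for yr in years])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        empty = [yr for yr, col in zip(years, X.T) if col.sum() == 0]
        raise ValueError(f"singular year design matrix; empty/collinear year "
                         f"columns: {empty or years}")

    dos = geno.dosage[[geno_pos[g] for g in ids]]
    if np.isnan(dos).any():
        raise ValueError("training dosages contain missing calls; impute first")
    center = dos.mean(axis=0)
    Z = dos - center
    K = Z @ Z.T

    q = X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    P = np.eye(n) - X @ XtX_inv @ X.T

    if lambda_ is None:
        # REML on the projected spectrum (one eigendecomposition, 1-D search)
        M = P @ (K + np.eye(n)) @ P
        w, V = np.linalg.eigh((M + M.T) / 2.0)
        keep = w > 1e-8
        if keep.sum() != n - q:  # numerical guard; keep the n-q largest
            order = np.argsort(w)[::-1][: n - q]
            keep = np.zeros_like(w, dtype=bool)
            keep[order] = True
        xi = np.maximum(w[keep] - 1.0, 0.0)
        eta2 = (V[:, keep].T @ y) ** 2
        nq = n - q

        def neg_restricted_ll(log_delta: float) -> float:
            delta = np.exp(log_delta)
            denom = xi + delta
            ll = 0.5 * (
                nq * (np.log(nq / (2 * np.pi)) - 1.0 - np.log(np.sum(eta2 / denom)))
                - np.sum(np.log(denom))
            )
            return -ll

        res = minimize_scalar(
            neg_restricted_ll, bounds=(-25.0, 25.0), method="bounded",
            options={"xatol": 1e-10},
        )
        delta = float(np.exp(res.x))
        sigma2_u = float(np.sum(eta2 / (xi + delta)) / nq)
        sigma2_e = delta * sigma2_u
        loglik = -float(res.fun)
    else:
        delta = float(lambda_)
        sigma2_u = np.nan
        sigma2_e = np.nan
        loglik = np.nan

    # solve the mixed-model equations through the n-dimensional system
    H = K + delta * np.eye(n)
    Hinv_X = np.linalg.solve(H, X)
    Hinv_y = np.linalg.solve(H, y)
    beta = np.linalg.solve(X.T @ Hinv_X, X.T @ Hinv_y)
    u = Z.T @ np.linalg.solve(H, y - X @ beta)

    return RRBLUPModel(
        beta=pd.Series(beta, index=years, name="beta"),
        u=u,
        lambda_=delta,
        sigma2_u=sigma2_u,
        sigma2_e=sigma2_e,
        snp_ids=list(geno.snp_ids),
        center=center,
        years=years,
        reml_loglik=loglik,
        training_ids=sorted(set(ids)),
    )


@dataclass
class CVResult:
    """Per-replication cross-validation abilities and fold bookkeeping."""

    per_fold: pd.DataFrame       # columns: rep, fold, ability, n_validation
    assignments: pd.DataFrame    # columns: rep, genotype_id, fold
    folds: int

    @property
    def per_rep(self) -> pd.Series:
        return self.per_fold.groupby("rep")["ability"].mean()

    @property
    def mean_ability(self) -> float:
        return float(self.per_rep.mean())


def cross_validate(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    folds: int = 4,
    reps: int = 100,
    seed: int = 0,
    trait: str | None = None,
) -> CVResult:
    """Replicated k-fold cross-validation of predictive ability.

    Individuals (not records) are partitioned into ``folds`` folds per
    replication; each fold serves once as validation (with 4 folds this is
    the 75%/25% train/validation split).  Ability is the Pearson correlation
    between predicted GEBV and the year-adjusted observed mean (records minus
    the fitted year effect, averaged per individual) in the validation fold.
    """
    df = _records(pheno, trait)
    individuals = np.array(sorted(df["genotype_id"].unique()))
    if individuals.size < 2 * folds:
        raise ValueError("too few phenotyped individuals for cross-validation")
    rng = np.random.default_rng(seed)
    fold_rows, assign_rows = [], []
    for rep in range(reps):
        perm = rng.permutation(individuals)
        parts = np.array_split(perm, folds)
        for f, part in enumerate(parts):
            for g in part:
                assign_rows.append((rep, g, f))
        for f, part in enumerate(parts):
            val_ids = set(part)
            train_df = df[~df["genotype_id"].isin(val_ids)]
            model = fit_rrblup(train_df, geno, trait=trait)
            val_df = df[df["genotype_id"].isin(val_ids)].copy()
            adj = val_df["value"].to_numpy() - model.beta.reindex(
                val_df["year"]).to_numpy()
            val_df["adjusted"] = adj
            observed = val_df.groupby("genotype_id")["adjusted"].mean()
            preds = model.gebv(geno).reindex(observed.index)
            if observed.std(ddof=0) == 0 or preds.std(ddof=0) == 0:
                warnings.warn(
                    f"constant values in validation fold {f} of rep {rep}; "
                    "fold excluded",
                    stacklevel=2,
                )
                continue
            r = float(np.corrcoef(preds.to_numpy(), observed.to_numpy())[0, 1])
            fold_rows.append((rep, f, r, len(observed)))
    return CVResult(
        per_fold=pd.DataFrame(fold_rows, columns=["rep", "fold", "ability",
                                                  "n_validation"]),
        assignments=pd.DataFrame(assign_rows,
                                 columns=["rep", "genotype_id", "fold"]),
        folds=folds,
    )


@dataclass
class PopulationPrediction:
    predictions: pd.DataFrame    # columns: genotype_id, generation, predicted
    tukey: TukeyResult
    reps: int


def predict_populations(
    pheno: pd.DataFrame,
    geno_train: GenotypeMatrix,
    targets: dict[str, GenotypeMatrix],
    reps: int = 100,
    train_fraction: float = 0.75,
    alpha: float = 0.001,
    seed: int = 0,
    trait: str | None = None,
) -> PopulationPrediction:
    """Predict trait values of target generations from a trained model and
    compare generation means by Tukey HSD.

    Each replication refits the model on a random ``train_fraction`` subset
    of the phenotyped individuals; the reported prediction per individual is
    the mean over replications of (average year effect + GEBV).
    """
    if not targets:
        raise ValueError("no target populations given")
    df = _records(pheno, trait)
    individuals = np.array(sorted(df["genotype_id"].unique()))
    rng = np.random.default_rng(seed)
    sums: dict[str, pd.Series] = {}
    for _ in range(reps):
        n_tr = max(2, int(round(train_fraction * individuals.size)))
        sub = rng.choice(individuals, size=n_tr, replace=False)
        model = fit_rrblup(df[df["genotype_id"].isin(set(sub))], geno_train,
                           trait=trait)
        for gen_label, tgt in targets.items():
            p = model.predict(tgt)
            sums[gen_label] = sums.get(gen_label, 0.0) + p
    frames = []
    for gen_label, total in sums.items():
        mean_pred = total / reps
        frames.append(pd.DataFrame({
            "genotype_id": mean_pred.index,
            "generation": gen_label,
            "predicted": mean_pred.to_numpy(),
        }))
    predictions = pd.concat(frames, ignore_index=True)
    groups = {g: sub["predicted"].to_numpy()
              for g, sub in predictions.groupby("generation")}
    tk = tukey_hsd(groups, alpha=alpha)
    return PopulationPrediction(predictions=predictions, tukey=tk, reps=reps)
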