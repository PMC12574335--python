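"""Genomic prediction by RR-BLUP.

Marker effects solve the ridge system u = (W'W + lambda I)^-1 W'(y - ybar)
with the ridge parameter lambda = sigma_e^2 / sigma_u^2 estimated by REML on
the spectrum of W W'; GEBVs are W u.  Computation uses the equivalent n x n
kinship form, so cost scales with accessions rather than markers, and the
GBLUP identity is available as an independent cross-check.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .gwas import _null_reml


def _marker_matrix(geno) -> tuple[np.ndarray, list]:
    if isinstance(geno, GenotypeMatrix):
        d = geno.imputed()
        acc = list(geno.accessions)
    else:
        d = np.asarray(geno, dtype=float)
        acc = list(range(d.shape[0]))
    W = d - d.mean(axis=0)
    if np.allclose(W.var(axis=0).sum(), 0.0):
        raise ValueError("no marker variance")
    return W, acc


@dataclasses.dataclass
class RRBLUPResults:
    """Fitted marker effects and genomic breeding values."""

    marker_effects: np.ndarray
    gebv: pd.Series
    mu: float
    lambda_ridge: float
    sigma_u2: float
    sigma_e2: float

    def predict(self, geno, train_geno=None) -> pd.Series:
        """GEBVs for new accessions, centring markers as in training."""
        if isinstance(geno, GenotypeMatrix):
            d = geno.imputed()
            acc = list(geno.accessions)
        else:
            d = np.asarray(geno, dtype=float)
            acc = list(range(d.shape[0]))
        W = d - self._col_means
        return pd.Series(W @ self.marker_effects, index=acc,
                         name="gebv")

    _col_means: np.ndarray = dataclasses.field(default=None, repr=False)


class RRBLUP:
    """Ridge-regression BLUP of marker effects.

    Parameters
    ----------
    phenotype : Series or array
        Accession phenotypic values (typically BLUEs).
    geno : GenotypeMatrix or dosage array aligned with ``phenotype``.
    """

    def __init__(self, phenotype, geno):
        if isinstance(phenotype, pd.Series) and isinstance(
                geno, GenotypeMatrix):
            common = [a for a in geno.accessions if a in phenotype.index
                      and np.isfinite(phenotype[a])]
            idx = [geno.accessions.index(a) for a in common]
            geno = geno.take_accessions(idx)
            phenotype = phenotype.loc[common]
        self.geno = geno
        self.y = np.asarray(phenotype, dtype=float)
        self.index = (list(phenotype.index)
                      if isinstance(phenotype, pd.Series)
                      else list(range(len(self.y))))

    def fit(self) -> RRBLUPResults:
        W, acc = _marker_matrix(self.geno)
        if isinstance(self.geno, GenotypeMatrix):
            col_means = self.geno.imputed().mean(axis=0)
        else:
            col_means = np.asarray(self.geno, dtype=float).mean(axis=0)
        y = self.y
        n = len(y)
        K = W @ W.T
        X = np.ones((n, 1))
        su2, se2, U, w = _null_reml(y, X, K)
        lam = se2 / su2 if su2 > 0 else np.inf
        mu = float(np.mean(y))
        yc = y - mu
        # u = W'(WW' + lam I)^-1 yc  ==  (W'W + lam I)^-1 W' yc
        A = K + lam * np.eye(n)
        alpha = np.linalg.solve(A, yc)
        u = W.T @ alpha
        gebv = pd.Series(W @ u, index=self.index, name="gebv")
        res = RRBLUPResults(marker_effects=u, gebv=gebv, mu=mu,
                            lambda_ridge=float(lam), sigma_u2=float(su2),
                            sigma_e2=float(se2))
        res._col_means = col_means
        return res


def rrblup_fit(phenotype, geno) -> RRBLUPResults:
    """Fit RR-BLUP on the full data (effects + GEBVs for everyone)."""
    return RRBLUP(phenotype, geno).fit()


def gblup_gebv(phenotype, geno,
               lambda_ridge: float | None = None) -> pd.Series:
    """GEBVs via the kinship (GBLUP) formulation, g = K(K + lam/c I)^-1 yc
    with K = W W' / c.

    Algebraically identical to RR-BLUP at the same ridge parameter
    ``lambda_ridge`` (estimated by REML on K when omitted); kept as an
    independent route for equivalence checks.
    """
    W, acc = _marker_matrix(geno)
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    c = W.shape[1]
    K = W @ W.T / c
    if lambda_ridge is None:
        su2, se2, U, w = _null_reml(y, np.ones((n, 1)), K)
        lam = se2 / su2 if su2 > 0 else np.inf
    else:
        lam = float(lambda_ridge) / c
    yc = y - y.mean()
    g = K @ np.linalg.solve(K + lam * np.eye(n), yc)
    index = (list(phenotype.index) if isinstance(phenotype, pd.Series)
             else list(range(n)))
    return pd.Series(g, index=index, name="gebv")


@dataclasses.dataclass
class CvAccuracy:
    """Cross-validated prediction accuracy for one trait."""

    accuracy_r: float
    r2: float
    se_r: float
    per_rep_r: np.ndarray
    n_reps: int
    split_fraction: float
    seed: int


def cv_accuracy(phenotype, geno, split: float = 0.8, n_reps: int = 50,
                seed: int = 0) -> CvAccuracy:
    """Repeated hold-out cross-validation of genomic prediction accuracy.

    Per replicate the accessions are split ``split`` / ``1-split`` into
    training and testing, RR-BLUP is fit on the training set, and accuracy
    is the Pearson correlation between predicted GEBVs and observed
    phenotypes in the test set.  Reported r is the mean over replicates and
    r^2 its square.
    """
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(phenotype, pd.Series) and isinstance(geno, GenotypeMatrix):
        common = [a for a in geno.accessions if a in phenotype.index
                  and np.isfinite(phenotype[a])]
        idx = [geno.accessions.index(a) for a in common]
        d = geno.take_accessions(idx).imputed()
        y = phenotype.loc[common].to_numpy(dtype=float)
    else:
        d = np.asarray(geno, dtype=float)
        y = np.asarray(phenotype, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(n_reps):
        perm = rng.permutation(n)
        ntrain = int(round(split * n))
        train, test = perm[:ntrain], perm[ntrain:]
        fit = RRBLUP(y[train], d[train]).fit()
        Wtest = d[test] - d[train].mean(axis=0)
        pred = Wtest @ fit.marker_effects
        if np.std(pred) == 0 or np.std(y[test]) == 0:
            rs.append(0.0)
            continue
        rs.append(float(stats.pearsonr(pred, y[test])[0]))
    rs = np.asarray(rs)
    r = float(rs.mean())
    return CvAccuracy(accuracy_r=r, r2=r * r,
                      se_r=float(rs.std(ddof=1) / np.sqrt(n_reps))
                      if n_reps > 1 else 0.0,
                      per_rep_r=rs, n_reps=n_reps, split_fraction=split,
                      seed=seed)
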