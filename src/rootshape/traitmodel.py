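"""Mixed linear model for multi-environment trait records.

The observation model is

    y_ijkl = mu + g_i + e_j + (g x e)_ij + b_k(j) + p_l(jk) + eps_ijkl

with genotype either fixed (for BLUEs) or random (for sigma_g^2, BLUPs and
Cullis heritability), and environment, G x E, block-in-environment, plot and
residual random.  Variance components are estimated by REML: the residual
variance is profiled out of the restricted likelihood and the remaining
variance ratios are optimised on the log scale by Nelder-Mead, with each
evaluation a single sparse LU factorisation of the Henderson mixed-model
coefficient matrix.  BLUEs/BLUPs and prediction error variances come from
the same equations at the converged estimates.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu

logger = logging.getLogger(__name__)

RANDOM_TERMS = ("env", "gxe", "block", "plot")


def _indicator(codes: np.ndarray, n_levels: int) -> sparse.csc_matrix:
    n = len(codes)
    return sparse.csc_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels))


@dataclasses.dataclass
class TraitModelResults:
    """Converged mixed-model fit for one trait.

    Attributes
    ----------
    mu : float
        Intercept (mean of BLUEs for the fixed-genotype fit).
    blues : Series, optional
        Accession BLUEs (genotype fixed).
    blups : DataFrame, optional
        Accession BLUPs and their prediction error variance
        (genotype random; columns 'blup', 'pev').
    varcomp : dict
        Variance per source, including 'residual' (and 'g' when genotype
        is random).
    pev : float, optional
        Half the average pairwise variance of BLUP differences.
    loglik : float
        Restricted log-likelihood at the optimum.
    """

    trait: str
    genotype_as: str
    mu: float
    varcomp: dict
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    blues: pd.Series | None = None
    blups: pd.DataFrame | None = None
    pev: float | None = None
    dropped_terms: tuple = ()

    def cullis_h2(self) -> float:
        """Broad-sense heritability H^2 = 1 - PEV / sigma_g^2, in [0, 1]."""
        if self.genotype_as != "random":
            raise ValueError("H^2 needs a genotype-random fit")
        sg2 = self.varcomp.get("g", 0.0)
        if sg2 <= 0:
            return 0.0
        return float(np.clip(1.0 - self.pev / sg2, 0.0, 1.0))

    def variance_partition(self) -> pd.Series:
        """Each variance component as a share of the total (sums to 1)."""
        order = [k for k in ("g", "env", "gxe", "block", "plot", "residual")
                 if k in self.varcomp]
        v = np.array([self.varcomp[k] for k in order], dtype=float)
        total = v.sum()
        shares = v / total if total > 0 else np.zeros_like(v)
        return pd.Series(shares, index=order, name="share")

    def summary(self) -> str:
        lines = [
            f"Trait mixed model: {self.trait}",
            f"  genotype treated as: {self.genotype_as}",
            f"  observations: {self.n_obs}   converged: {self.converged} "
            f"({self.n_iter} evaluations)",
            f"  restricted log-likelihood: {self.loglik:.4f}",
            "  variance components:",
        ]
        for k, v in self.varcomp.items():
            lines.append(f"    {k:9s} {v:12.6f}")
        if self.genotype_as == "random":
            lines.append(f"  mean pairwise PEV: {self.pev:.6f}")
            lines.append(f"  Cullis H^2: {self.cullis_h2():.4f}")
        if self.dropped_terms:
            lines.append(f"  dropped terms: {', '.join(self.dropped_terms)}")
        return "\n".join(lines)


class RootTraitMixedModel:
    """REML mixed model for long-format phenotype records.

    Parameters
    ----------
    records : DataFrame
        Long format with columns accession, env, block, plot, trait, value.
    trait : str
        Trait name to model.
    genotype_as : {'fixed', 'random'}
        Fixed genotype yields BLUEs; random yields sigma_g^2, BLUPs, PEV.
    """

    def __init__(self, records: pd.DataFrame, trait: str,
                 genotype_as: str = "fixed"):
        if genotype_as not in ("fixed", "random"):
            raise ValueError("genotype_as must be 'fixed' or 'random'")
        sub = records[records["trait"] == trait]
        if len(sub) == 0:
            raise ValueError(f"trait {trait!r} not present in the records")
        self.trait = trait
        self.genotype_as = genotype_as
        self.records = sub.reset_index(drop=True)
        self._build()

    def _build(self):
        df = self.records
        self.y = df["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite trait values")
        n = len(df)

        acc_codes, self.accessions = pd.factorize(df["accession"])
        env_codes, envs = pd.factorize(df["env"])
        gxe_codes, _ = pd.factorize(
            df["accession"].astype(str) + "\x00" + df["env"].astype(str))
        blk_codes, blks = pd.factorize(
            df["env"].astype(str) + "\x00" + df["block"].astype(str))
        plot_codes, plots = pd.factorize(
            df["env"].astype(str) + "\x00" + df["block"].astype(str)
            + "\x00" + df["plot"].astype(str))

        dropped = []
        terms = {}
        if len(envs) >= 2:
            terms["env"] = _indicator(env_codes, env_codes.max() + 1)
            terms["gxe"] = _indicator(gxe_codes, gxe_codes.max() + 1)
        else:
            dropped += ["env", "gxe"]
        if len(blks) > len(envs):
            terms["block"] = _indicator(blk_codes, blk_codes.max() + 1)
        else:
            dropped.append("block")
        # plot is only identified with >1 root per plot
        counts = np.bincount(plot_codes)
        if counts.max() > 1 and len(plots) < n:
            terms["plot"] = _indicator(plot_codes, plot_codes.max() + 1)
        else:
            dropped.append("plot")
            logger.warning("plot effect confounded with residual "
                           "(single root per plot); dropped")
        self.dropped_terms = tuple(dropped)

        Zg = _indicator(acc_codes, acc_codes.max() + 1)
        if self.genotype_as == "fixed":
            self.X = Zg
            self.random_names = list(terms)
        else:
            self.X = sparse.csc_matrix(np.ones((n, 1)))
            terms = {"g": Zg, **terms}
            self.random_names = list(terms)
        self.Z_blocks = [terms[k] for k in self.random_names]
        self.q_sizes = np.array([Z.shape[1] for Z in self.Z_blocks])
        self.p = self.X.shape[1]
        self.n = n

        Z = sparse.hstack(self.Z_blocks, format="csc") if self.Z_blocks \
            else sparse.csc_matrix((n, 0))
        W = sparse.hstack([self.X, Z], format="csc")
        self.W = W
        self.C0 = (W.T @ W).tocsc()
        self.Wty = W.T @ self.y
        self.yty = float(self.y @ self.y)
        # diagonal template: 1/gamma_r goes on the rows of random block r
        self.block_slices = []
        off = self.p
        for q in self.q_sizes:
            self.block_slices.append(slice(off, off + q))
            off += q
        self.dim = off

    # ------------------------------------------------------------------
    def _assemble(self, gammas):
        d = np.zeros(self.dim)
        for sl, g in zip(self.block_slices, gammas):
            d[sl] = 1.0 / g
        return (self.C0 + sparse.diags(d)).tocsc()

    def _profiled_deviance(self, log_gammas, return_fit=False):
        gammas = np.exp(np.clip(log_gammas, -30.0, 30.0))
        C = self._assemble(gammas)
        try:
            lu = splu(C, permc_spec="COLAMD",
                      options=dict(SymmetricMode=True))
        except RuntimeError:
            return (np.inf, None) if return_fit else np.inf
        sol = lu.solve(self.Wty)
        ypy = self.yty - float(self.Wty @ sol)
        dof = self.n - self.p
        if ypy <= 0 or dof <= 0:
            return (np.inf, None) if return_fit else np.inf
        sigma2 = ypy / dof
        logdetC = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        logdetG = float(np.sum(self.q_sizes * np.log(gammas)))
        dev = (dof * (np.log(2 * np.pi * sigma2) + 1.0)
               + logdetC + logdetG)
        if return_fit:
            return dev, {"lu": lu, "sol": sol, "sigma2": sigma2,
                         "gammas": gammas}
        return dev

    def fit(self, maxiter: int = 400, tol: float = 1e-6,
            start: float = 0.3) -> TraitModelResults:
        """Minimise the profiled REML deviance and solve the MME.

        Non-convergence within ``maxiter`` evaluations is flagged on the
        result, not raised.
        """
        k = len(self.random_names)
        if k == 0:
            raise ValueError("no random terms; nothing to estimate")
        x0 = np.full(k, np.log(start))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                self._profiled_deviance, x0, method="Nelder-Mead",
                options=dict(maxiter=maxiter * k, fatol=tol, xatol=1e-4,
                             adaptive=k > 3))
        dev, fit = self._profiled_deviance(res.x, return_fit=True)
        sigma2 = fit["sigma2"]
        gammas = fit["gammas"]
        varcomp = {name: float(g * sigma2)
                   for name, g in zip(self.random_names, gammas)}
        # components at the lower optimiser boundary are genuine zeros
        varcomp = {k_: (0.0 if np.log(v / sigma2 + 1e-300) < -25 else v)
                   for k_, v in varcomp.items()}
        varcomp["residual"] = float(sigma2)
        sol = fit["sol"]

        out = TraitModelResults(
            trait=self.trait, genotype_as=self.genotype_as,
            mu=float("nan"), varcomp=varcomp, loglik=-0.5 * dev,
            converged=bool(res.success), n_iter=int(res.nfev),
            n_obs=self.n, dropped_terms=self.dropped_terms)

        if self.genotype_as == "fixed":
            blues = pd.Series(sol[:self.p], index=self.accessions,
                              name=self.trait)
            out.blues = blues
            out.mu = float(blues.mean())
        else:
            out.mu = float(sol[0])
            sl = self.block_slices[self.random_names.index("g")]
            u = sol[sl]
            # prediction error covariance = sigma2 * C^{-1} genotype block
            nacc = sl.stop - sl.start
            rhs = np.zeros((self.dim, nacc))
            rhs[sl, :] = np.eye(nacc)
            cinv = fit["lu"].solve(rhs)[sl, :]
            pec = sigma2 * 0.5 * (cinv + cinv.T)
            diag = np.diag(pec)
            if nacc > 1:
                # mean over i<j of Var(u_i - u_j) = pec_ii + pec_jj - 2 pec_ij
                npairs = nacc * (nacc - 1) / 2.0
                sum_diag_pairs = (nacc - 1) * diag.sum()
                sum_off = (pec.sum() - diag.sum()) / 2.0
                mean_pair = (sum_diag_pairs - 2.0 * sum_off) / npairs
            else:
                mean_pair = 2.0 * diag[0]
            out.pev = float(mean_pair / 2.0)
            out.blups = pd.DataFrame(
                {"blup": u, "pev": np.diag(pec)}, index=self.accessions)
        return out


def fit_trait_model(records: pd.DataFrame, trait: str,
                    genotype_as: str = "fixed", **kw) -> TraitModelResults:
    """Convenience wrapper: build and fit in one call."""
    return RootTraitMixedModel(records, trait, genotype_as).fit(**kw)


# ---------------------------------------------------------------------------
# Per-environment BLUEs and stability
# ---------------------------------------------------------------------------

def per_env_blues(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Accession x environment BLUE table.

    Within each environment the model reduces to genotype (fixed) plus
    block, plot and residual; accessions missing from an environment stay
    missing.
    """
    sub = records[records["trait"] == trait]
    if len(sub) == 0:
        raise ValueError(f"trait {trait!r} not present")
    cols = {}
    for env, env_df in sub.groupby("env"):
        env_df = env_df.copy()
        env_df["env"] = "single"
        model = RootTraitMixedModel(env_df, trait, genotype_as="fixed")
        cols[env] = model.fit().blues
    table = pd.DataFrame(cols)
    table.index.name = "accession"
    return table


@dataclasses.dataclass
class StabilityResult:
    """Finlay-Wilkinson regression per accession.

    ``table`` has columns fw_slope, fw_intercept, mse, n_env;
    ``environment_means`` is the per-environment mean over the accessions
    used.
    """

    table: pd.DataFrame
    environment_means: pd.Series


def fw_regression(per_env_table: pd.DataFrame,
                  complete_only: bool = True) -> StabilityResult:
    """Finlay-Wilkinson slopes: each accession's values regressed on the
    environment means (slope 1 = average sensitivity).

    ``complete_only`` restricts to accessions observed in every environment
    before computing the environment means, mirroring a complete-replication
    subset.
    """
    tab = per_env_table
    if complete_only:
        tab = tab.dropna(axis=0, how="any")
        if len(tab) == 0:
            raise ValueError("no accession is complete across environments")
    env_means = tab.mean(axis=0)
    rows = {}
    for acc, vals in tab.iterrows():
        ok = vals.notna()
        if ok.sum() < 2:
            continue
        x = env_means[ok].to_numpy(dtype=float)
        yv = vals[ok].to_numpy(dtype=float)
        slope, intercept = np.polyfit(x, yv, 1)
        resid = yv - (slope * x + intercept)
        rows[acc] = {"fw_slope": slope, "fw_intercept": intercept,
                     "mse": float(np.mean(resid ** 2)),
                     "n_env": int(ok.sum())}
    return StabilityResult(table=pd.DataFrame(rows).T,
                           environment_means=env_means)


def env_pair_correlations(per_env_table: pd.DataFrame):
    """Pearson correlations between environment pairs on shared accessions.

    Returns (matrix, average of the upper triangle).
    """
    corr = per_env_table.corr(method="pearson", min_periods=2)
    iu = np.triu_indices(corr.shape[0], k=1)
    vals = corr.to_numpy()[iu]
    avg = float(np.nanmean(vals)) if vals.size else float("nan")
    return corr, avg


def trait_correlations(blues_by_trait: pd.DataFrame) -> pd.DataFrame:
    """Trait x trait Pearson correlation of accession BLUEs."""
    return blues_by_trait.corr(method="pearson")
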