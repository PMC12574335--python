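"""Population structure: marker QC, LD pruning, PCA, admixture, distances.

The admixture model is the standard binomial mixture: dosage g_ij ~
Binomial(2, sum_k q_ik f_kj), maximised by multiplicative EM updates of the
ancestry proportions Q and population frequencies F.  Distances follow Nei
(1972); differentiation uses the Nei Gst ratio-of-sums estimator; trees are
neighbor-joining with deterministic tie-breaking.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

#: Cap for infinite Nei distances (no shared alleles at any locus).
NEI_INF_SENTINEL = -float(np.log(np.finfo(float).tiny))  # ~708


# ---------------------------------------------------------------------------
# Marker QC
# ---------------------------------------------------------------------------

def filter_markers(geno: GenotypeMatrix, min_per_hom_class: int = 5,
                   max_genotype_freq: float | None = None,
                   min_depth: float | None = None,
                   min_gq: float | None = None,
                   depth: np.ndarray | None = None,
                   gq: np.ndarray | None = None):
    """Apply GBS marker-quality rules.

    Rules (each optional): per-genotype depth/GQ minima (calls failing them
    become missing), at least ``min_per_hom_class`` individuals in each
    homozygous class, and removal of markers whose modal genotype frequency
    exceeds ``max_genotype_freq`` (default 1 - 5/N).

    Returns
    -------
    (filtered GenotypeMatrix, log dict with removal counts per rule)
    """
    n = geno.n_accessions
    if n < 6:
        raise ValueError("need at least 6 accessions for the QC rules")
    if max_genotype_freq is None:
        max_genotype_freq = 1.0 - 5.0 / n
    dosage = geno.dosage.copy()
    log = {"input": geno.n_markers}
    if min_depth is not None and depth is not None:
        dosage[depth < min_depth] = np.nan
    if min_gq is not None and gq is not None:
        dosage[gq < min_gq] = np.nan

    hom_ref = np.nansum(dosage == 0, axis=0)
    het = np.nansum(dosage == 1, axis=0)
    hom_alt = np.nansum(dosage == 2, axis=0)
    called = hom_ref + het + hom_alt

    fail_hom = (hom_ref < min_per_hom_class) | (hom_alt < min_per_hom_class)
    with np.errstate(invalid="ignore", divide="ignore"):
        modal = np.max(np.stack([hom_ref, het, hom_alt]), axis=0) / \
            np.where(called > 0, called, 1)
    fail_modal = modal > max_genotype_freq
    fail_uncalled = called == 0

    log["min_per_hom_class"] = int(fail_hom.sum())
    log["max_genotype_freq"] = int((fail_modal & ~fail_hom).sum())
    log["uncalled"] = int((fail_uncalled & ~fail_hom & ~fail_modal).sum())
    keep = ~(fail_hom | fail_modal | fail_uncalled)
    log["retained"] = int(keep.sum())
    if not keep.any():
        raise ValueError("all markers removed by the QC rules")
    out = geno.take_markers(np.where(keep)[0])
    out.dosage = dosage[:, keep]
    return out, log


# ---------------------------------------------------------------------------
# LD pruning and PCA
# ---------------------------------------------------------------------------

def _r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return 0.0
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(geno: GenotypeMatrix, window_kb: float = 50.0,
             step_kb: float = 5.0, r2_cutoff: float = 0.02) -> np.ndarray:
    """Greedy LD pruning: scanning markers in position order, a marker is
    dropped when its dosage r^2 with any retained marker within
    ``window_kb`` upstream exceeds ``r2_cutoff``.

    ``step_kb`` is accepted for interface compatibility with sliding-window
    tools; the positional scan visits every marker, which is the dense limit
    of stepping.  Returns the retained marker indices (into ``geno``).
    """
    window_bp = window_kb * 1000.0
    keep: list[int] = []
    chroms = geno.chrom.astype(str)
    for c in pd.unique(chroms):
        idx = np.where(chroms == c)[0]
        kept_c: list[int] = []
        for j in idx:
            drop = False
            for i in reversed(kept_c):
                if geno.pos[j] - geno.pos[i] > window_bp:
                    break
                if _r2(geno.dosage[:, i], geno.dosage[:, j]) > r2_cutoff:
                    drop = True
                    break
            if not drop:
                kept_c.append(j)
        keep.extend(kept_c)
    return np.array(sorted(keep), dtype=int)


def pca_genotypes(geno: GenotypeMatrix, n_components: int = 10):
    """PCA of the mean-imputed, column-centred dosage matrix.

    Returns (scores DataFrame indexed by accession, pct variance array);
    pct variance shares are of the total dosage variance, so they sum to at
    most 100%.
    """
    d = geno.imputed()
    dc = d - d.mean(axis=0)
    u, s, vt = np.linalg.svd(dc, full_matrices=False)
    total = float((s ** 2).sum())
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    pct = 100.0 * s[:k] ** 2 / total if total > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=geno.accessions, columns=cols), pct


# ---------------------------------------------------------------------------
# Admixture
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AdmixtureResults:
    """Converged admixture fit: Q (n x k), F (k x m), log-likelihood."""

    q: np.ndarray
    f: np.ndarray
    loglik: float
    k: int
    n_iter: int
    converged: bool
    seed: int
    loglik_path: np.ndarray
    cv_error: float | None = None

    def q_frame(self, accessions) -> pd.DataFrame:
        return pd.DataFrame(self.q, index=list(accessions),
                            columns=[f"pop{i + 1}" for i in range(self.k)])


class AdmixtureModel:
    """Binomial admixture mixture model fit by EM.

    Parameters
    ----------
    geno : GenotypeMatrix or ndarray
        Dosages in {0,1,2}; missing entries are mean-imputed unless a
        ``mask`` marks them excluded from the likelihood.
    k : int
        Number of ancestral populations.
    mask : ndarray of bool, optional
        True where the entry contributes to the likelihood (used by the
        cross-validation machinery).
    """

    def __init__(self, geno, k: int, mask: np.ndarray | None = None):
        if isinstance(geno, GenotypeMatrix):
            g = geno.imputed()
        else:
            g = np.asarray(geno, dtype=float)
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > g.shape[0]:
            raise ValueError("k exceeds the number of accessions")
        self.g = g
        self.k = k
        self.mask = np.ones(g.shape, dtype=bool) if mask is None \
            else np.asarray(mask, dtype=bool)

    def _loglik(self, q, f):
        p = np.clip(q @ f, 1e-10, 1 - 1e-10)
        ll = self.g * np.log(p) + (2.0 - self.g) * np.log(1.0 - p)
        return float(ll[self.mask].sum())

    def fit(self, seed: int = 0, max_iter: int = 2000, tol: float = 1e-4,
            n_restarts: int = 3) -> AdmixtureResults:
        """Run EM from ``n_restarts`` random starts, keep the best optimum.

        The log-likelihood is non-decreasing along every EM path; iteration
        stops when the per-iteration gain falls below ``tol``.
        """
        rng = np.random.default_rng(seed)
        g, k, w = self.g, self.k, self.mask.astype(float)
        n, m = g.shape
        obs_freq = np.average(g, axis=0, weights=np.maximum(
            w, 1e-12)) / 2.0
        best = None
        for _ in range(max(1, n_restarts)):
            q = rng.dirichlet(np.ones(k), size=n)
            f = np.clip(obs_freq + rng.normal(0, 0.05, size=(k, m)),
                        0.01, 0.99)
            path = []
            converged = False
            it = 0
            prev = -np.inf
            gw = g * w
            g2w = (2.0 - g) * w
            for it in range(1, max_iter + 1):
                p = np.clip(q @ f, 1e-10, 1 - 1e-10)
                a = gw / p          # n x m
                b = g2w / (1.0 - p)
                # EM responsibilities accumulated per population
                num_q = np.empty((n, k))
                num_f = np.empty((k, m))
                den_f = np.empty((k, m))
                for kk in range(k):
                    alt = a * f[kk][None, :]       # share of alt alleles
                    ref = b * (1.0 - f[kk])[None, :]
                    num_f[kk] = q[:, kk] @ alt
                    den_f[kk] = q[:, kk] @ ref
                    num_q[:, kk] = q[:, kk] * (alt.sum(axis=1)
                                               + ref.sum(axis=1))
                f = np.clip(num_f / np.maximum(num_f + den_f, 1e-12),
                            1e-6, 1 - 1e-6)
                denom = np.maximum(num_q.sum(axis=1, keepdims=True), 1e-12)
                q = num_q / denom
                ll = self._loglik(q, f)
                path.append(ll)
                if ll - prev < tol and it > 1:
                    converged = True
                    break
                prev = ll
            res = AdmixtureResults(q=q, f=f, loglik=path[-1], k=k,
                                   n_iter=it, converged=converged,
                                   seed=seed,
                                   loglik_path=np.array(path))
            if best is None or res.loglik > best.loglik:
                best = res
        return best


def admixture_cv(geno, k_range, n_folds: int = 5, seed: int = 0,
                 **fit_kw):
    """Entry-masked cross-validation over k.

    Genotype cells are partitioned into ``n_folds`` random folds; each fold
    is held out in turn, the model is fit on the remaining cells, and the
    held-out cells are scored by mean binomial deviance between the observed
    dosage and its fitted expectation 2 * sum_k q f.  Returns (DataFrame of
    cv_error per k, selected k).
    """
    if isinstance(geno, GenotypeMatrix):
        g = geno.imputed()
    else:
        g = np.asarray(geno, dtype=float)
    rng = np.random.default_rng(seed)
    folds = rng.integers(0, n_folds, size=g.shape)
    rows = []
    for k in k_range:
        errs = []
        for fold in range(n_folds):
            mask = folds != fold
            fit = AdmixtureModel(g, k, mask=mask).fit(
                seed=seed + 1000 * fold, **fit_kw)
            p = np.clip(fit.q @ fit.f, 1e-8, 1 - 1e-8)
            held = ~mask
            gh, ph = g[held], p[held]
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = np.where(gh > 0, gh * np.log(gh / (2 * ph)), 0.0)
                t2 = np.where(gh < 2,
                              (2 - gh) * np.log((2 - gh) / (2 - 2 * ph)),
                              0.0)
            errs.append(float(np.mean(2.0 * (t1 + t2))))
        rows.append({"k": int(k), "cv_error": float(np.mean(errs))})
    table = pd.DataFrame(rows)
    selected = int(table.loc[table["cv_error"].idxmin(), "k"])
    return table, selected


# ---------------------------------------------------------------------------
# Distances, trees, Fst
# ---------------------------------------------------------------------------

def _unit_frequencies(geno: GenotypeMatrix, unit: str):
    """Alternate-allele frequency vectors per accession or per group."""
    if unit == "accession":
        freqs = geno.dosage / 2.0
        labels = list(geno.accessions)
        return freqs, labels
    if unit == "group":
        groups = geno.group_array()
        labels = list(pd.unique(groups))
        freqs = np.vstack([
            np.nanmean(geno.dosage[groups == lab], axis=0) / 2.0
            for lab in labels])
        return freqs, labels
    raise ValueError("unit must be 'accession' or 'group'")


def nei_distance(geno: GenotypeMatrix, unit: str = "accession"):
    """Nei (1972) standard genetic distance matrix.

    D = -ln(Jxy / sqrt(Jx Jy)) over biallelic frequency profiles; infinite
    distances (no shared alleles) are capped at a large finite sentinel.
    Returns (matrix DataFrame, labels).
    """
    freqs, labels = _unit_frequencies(geno, unit)
    return nei_distance_from_freqs(freqs, labels)


def nei_distance_from_freqs(freqs: np.ndarray, labels):
    freqs = np.asarray(freqs, dtype=float)
    nunit, L = freqs.shape
    P = np.stack([freqs, 1.0 - freqs], axis=2)     # unit x locus x allele
    J = np.einsum("ila,jla->ij", P, P) / L
    diag = np.diag(J)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = J / np.sqrt(np.outer(diag, diag))
        D = -np.log(np.clip(ratio, 0.0, None))
    if np.isinf(D).any():
        logger.warning("infinite Nei distances capped at %.1f",
                       NEI_INF_SENTINEL)
        D[np.isinf(D)] = NEI_INF_SENTINEL
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    return pd.DataFrame(D, index=labels, columns=labels), labels


def nj_tree(distances) -> str:
    """Neighbor-joining (Saitou-Nei) tree in Newick format.

    Ties in the Q criterion break toward the lowest index pair; negative
    branch lengths are clamped to zero with the deficit transferred to the
    sister branch, preserving path lengths.
    """
    if isinstance(distances, pd.DataFrame):
        labels = [str(x) for x in distances.index]
        D = distances.to_numpy(dtype=float).copy()
    else:
        D = np.asarray(distances, dtype=float).copy()
        labels = [f"t{i}" for i in range(D.shape[0])]
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    nodes = list(labels)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index pair among minima
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ties = [(min(i, j), max(i, j)) for i, j in ties]
        i, j = sorted(set(ties))[0]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new_label = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([np.hstack([D[np.ix_(keep, keep)],
                                  dnew[keep, None]]),
                       np.hstack([dnew[keep], [0.0]])])
        nodes = [nodes[x] for x in keep] + [new_label]

    # terminal 3-star
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    v0 = max(0.0, 0.5 * (d01 + d02 - d12))
    v1 = max(0.0, 0.5 * (d01 + d12 - d02))
    v2 = max(0.0, 0.5 * (d02 + d12 - d01))
    return (f"({nodes[0]}:{v0:.10g},{nodes[1]}:{v1:.10g},"
            f"{nodes[2]}:{v2:.10g});")


def pairwise_fst(geno: GenotypeMatrix, groups=None,
                 corrected: bool = False,
                 method: str = "nei") -> pd.DataFrame:
    """Pairwise multilocus Fst between groups.

    ``method='nei'`` (default) is the Nei Gst ratio of sums: for each group
    pair, Ht = 1 - pbar^2 - qbar^2 from the unweighted mean frequency and
    Hs = the mean within-group expected heterozygosity; Fst =
    (sum Ht - sum Hs) / sum Ht over loci.  ``corrected`` applies the
    small-sample unbiased gene-diversity factor 2n/(2n-1) within groups.

    ``method='hudson'`` is the Hudson estimator (ratio of averages with
    sample-size-corrected numerator), which is consistent for the
    divergence parameter of an island/Balding-Nichols model; Gst between
    two demes instead converges to F/(2-F).
    """
    if groups is None:
        garr = geno.group_array()
    else:
        garr = np.asarray([groups[a] if isinstance(groups, dict) else g_
                           for a, g_ in zip(geno.accessions,
                                            np.broadcast_to(
                                                np.asarray(groups,
                                                           dtype=object),
                                                (geno.n_accessions,)))],
                          dtype=object)
    labels = list(pd.unique(garr))
    freqs, hets, sizes = {}, {}, {}
    for lab in labels:
        sub = geno.dosage[garr == lab]
        if sub.shape[0] < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 accessions")
        p = np.nanmean(sub, axis=0) / 2.0
        h = 2.0 * p * (1.0 - p)
        if corrected:
            nalle = 2.0 * np.sum(~np.isnan(sub), axis=0)
            h = h * nalle / np.maximum(nalle - 1.0, 1.0)
        freqs[lab], hets[lab] = p, h
        sizes[lab] = sub.shape[0]
    if method not in ("nei", "hudson"):
        raise ValueError("method must be 'nei' or 'hudson'")
    out = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            la, lb = labels[a], labels[b]
            p1, p2 = freqs[la], freqs[lb]
            if method == "nei":
                pbar = (p1 + p2) / 2.0
                ht = 1.0 - pbar ** 2 - (1.0 - pbar) ** 2
                hs = (hets[la] + hets[lb]) / 2.0
                ok = ht > 0
                fst = (ht[ok].sum() - hs[ok].sum()) / ht[ok].sum() \
                    if ok.any() else 0.0
            else:
                n1 = 2.0 * sizes[la]
                n2 = 2.0 * sizes[lb]
                num = ((p1 - p2) ** 2
                       - p1 * (1 - p1) / (n1 - 1.0)
                       - p2 * (1 - p2) / (n2 - 1.0))
                den = p1 * (1 - p2) + p2 * (1 - p1)
                ok = den > 0
                fst = num[ok].sum() / den[ok].sum() if ok.any() else 0.0
            fst = float(np.clip(fst, 0.0, 1.0))
            out.loc[la, lb] = fst
            out.loc[lb, la] = fst
    return out


def mean_pairwise_fst(geno: GenotypeMatrix, groups=None,
                      method: str = "nei") -> float:
    m = pairwise_fst(geno, groups, method=method)
    iu = np.triu_indices(m.shape[0], k=1)
    return float(np.nanmean(m.to_numpy()[iu]))
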