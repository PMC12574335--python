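"""Kinship mixed-model association scans and consensus QTL calling.

The scan is EMMAX-style: under the null model y = Xb + g + e with
g ~ N(0, sg^2 K) and e ~ N(0, se^2 I), the variance ratio is estimated once
per trait by REML on the spectrum of K; each marker is then tested by
generalized least squares in the eigenrotated space with a Wald t test.
K-LOCO repeats the null fit per chromosome with that chromosome left out of
the kinship.  Downstream utilities cover Bonferroni thresholds, the
observed-vs-expected -log10 p inflation slope, per-marker variance
explained, the two-model/two-panel consensus rule, and LD decay.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def vanraden_kinship(geno: GenotypeMatrix,
                     exclude_chromosome: str | None = None) -> pd.DataFrame:
    """VanRaden genomic relationship matrix.

    K = W W' / (2 sum_j p_j (1 - p_j)) with W the dosage matrix centred by
    2 p_j; monomorphic markers are skipped; ``exclude_chromosome``
    implements leave-one-chromosome-out.
    """
    keep = np.ones(geno.n_markers, dtype=bool)
    if exclude_chromosome is not None:
        keep &= geno.chrom.astype(str) != str(exclude_chromosome)
    d = geno.imputed()[:, keep]
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("fewer than 2 polymorphic markers for kinship")
    W = d[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = W @ W.T / denom
    return pd.DataFrame(K, index=geno.accessions, columns=geno.accessions)


# ---------------------------------------------------------------------------
# Null REML on the kinship spectrum
# ---------------------------------------------------------------------------

def _null_reml(y: np.ndarray, X: np.ndarray, K: np.ndarray,
               tol: float = 1e-10):
    """REML of V = sg^2 (K + delta I) via the eigendecomposition of K.

    Returns (sg2, se2, U, w) with U the eigenvectors and w the per-sample
    variance weights (eigenvalues + delta).
    """
    n, p = X.shape
    S, U = np.linalg.eigh(K)
    S = np.clip(S, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X

    def neg_restricted_ll(log_delta):
        delta = np.exp(log_delta)
        w = S + delta
        Xw = Xr / w[:, None]
        XtWX = Xr.T @ Xw
        try:
            beta = np.linalg.solve(XtWX, Xw.T @ yr)
        except np.linalg.LinAlgError:
            return np.inf
        r = yr - Xr @ beta
        ypy = float(r @ (r / w))
        if ypy <= 0:
            return np.inf
        sg2 = ypy / (n - p)
        sign, logdetX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return ((n - p) * np.log(sg2) + np.sum(np.log(w)) + logdetX
                + (n - p))

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(-10.0, 10.0),
                                   method="bounded",
                                   options={"xatol": tol})
    delta = float(np.exp(res.x))
    w = S + delta
    Xw = Xr / w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    r = yr - Xr @ beta
    sg2 = float(r @ (r / w)) / (n - p)
    se2 = sg2 * delta
    return sg2, se2, U, w


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GwasResults:
    """Per-marker association results for one model on one panel."""

    table: pd.DataFrame            # chrom, pos, beta, se, t, p, score
    model: str
    panel: str
    trait: str
    n: int
    varcomp: dict

    def inflation(self) -> float:
        return inflation_lambda(self.table["p"].to_numpy())

    def threshold(self, alpha: float = 0.05) -> float:
        return bonferroni_threshold(len(self.table), alpha)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        thr = self.threshold(alpha)
        return self.table[self.table["score"] >= thr]


class MixedLMScan:
    """Kinship mixed-linear-model genome scan.

    Parameters
    ----------
    phenotype : Series
        Accession-indexed trait values (typically BLUEs).
    geno : GenotypeMatrix
    kinship_mode : {'K', 'K-LOCO'}
    n_pcs : int
        Number of genotype principal components added as fixed covariates.
    """

    def __init__(self, phenotype: pd.Series, geno: GenotypeMatrix,
                 kinship_mode: str = "K", n_pcs: int = 0,
                 model: str | None = None, panel: str = "full",
                 trait: str | None = None):
        if kinship_mode not in ("K", "K-LOCO"):
            raise ValueError("kinship_mode must be 'K' or 'K-LOCO'")
        common = [a for a in geno.accessions if a in phenotype.index
                  and np.isfinite(phenotype[a])]
        if len(common) < 10:
            raise ValueError("fewer than 10 accessions with phenotype "
                             "and genotype")
        idx = [geno.accessions.index(a) for a in common]
        self.geno = geno.take_accessions(idx)
        self.y = phenotype.loc[common].to_numpy(dtype=float)
        self.kinship_mode = kinship_mode
        self.n_pcs = n_pcs
        self.model_name = model or (kinship_mode
                                    + ("+PC" if n_pcs else ""))
        self.panel = panel
        self.trait = trait or (phenotype.name or "trait")

        X = [np.ones((len(common), 1))]
        if n_pcs > 0:
            from .popgen import pca_genotypes
            scores, _ = pca_genotypes(self.geno, n_components=n_pcs)
            X.append(scores.to_numpy())
        self.X0 = np.hstack(X)

    def _scan_chunk(self, marker_idx, U, w, sg2, se2):
        """GLS per marker in the rotated space; Wald t with re-estimated
        scale, matching dense GLS at the null variance ratio."""
        d = self.geno.imputed()[:, marker_idx]
        yr = U.T @ self.y
        X0r = U.T @ self.X0
        rows = []
        sw = 1.0 / np.sqrt(w)
        yw = yr * sw
        X0w = X0r * sw[:, None]
        n, p0 = X0w.shape
        for jj, j in enumerate(marker_idx):
            xw = (U.T @ d[:, jj]) * sw
            Xf = np.hstack([X0w, xw[:, None]])
            XtX = Xf.T @ Xf
            try:
                XtX_inv = np.linalg.inv(XtX)
            except np.linalg.LinAlgError:
                logger.info("marker %s skipped: singular design",
                            self.geno.marker_ids[j])
                rows.append((np.nan,) * 4)
                continue
            beta = XtX_inv @ (Xf.T @ yw)
            resid = yw - Xf @ beta
            dof = n - p0 - 1
            s2 = float(resid @ resid) / dof
            v = s2 * XtX_inv[-1, -1]
            if not np.isfinite(v) or v <= 0:
                rows.append((np.nan,) * 4)
                continue
            se = float(np.sqrt(v))
            if se == 0:
                rows.append((np.nan,) * 4)
                continue
            t = float(beta[-1]) / se
            p = 2.0 * stats.t.sf(abs(t), dof)
            rows.append((float(beta[-1]), se, t, float(p)))
        return rows

    def fit(self) -> GwasResults:
        geno = self.geno
        chroms = geno.chrom.astype(str)
        out_rows = [None] * geno.n_markers
        varcomp = {}
        if self.kinship_mode == "K":
            K = vanraden_kinship(geno).to_numpy()
            sg2, se2, U, w = _null_reml(self.y, self.X0, K)
            varcomp = {"sigma_g2": sg2, "sigma_e2": se2}
            rows = self._scan_chunk(np.arange(geno.n_markers), U, w,
                                    sg2, se2)
            out_rows = rows
        else:
            for c in pd.unique(chroms):
                idx = np.where(chroms == c)[0]
                K = vanraden_kinship(geno, exclude_chromosome=c).to_numpy()
                sg2, se2, U, w = _null_reml(self.y, self.X0, K)
                varcomp[str(c)] = {"sigma_g2": sg2, "sigma_e2": se2}
                rows = self._scan_chunk(idx, U, w, sg2, se2)
                for j, r in zip(idx, rows):
                    out_rows[j] = r
        tab = pd.DataFrame(out_rows, columns=["beta", "se", "t", "p"])
        tab.insert(0, "pos", geno.pos)
        tab.insert(0, "chrom", chroms)
        with np.errstate(divide="ignore"):
            tab["score"] = -np.log10(tab["p"])
        return GwasResults(table=tab, model=self.model_name,
                           panel=self.panel, trait=self.trait,
                           n=len(self.y), varcomp=varcomp)


def mlm_scan(phenotype: pd.Series, geno: GenotypeMatrix,
             kinship_mode: str = "K", n_pcs: int = 0,
             **kw) -> GwasResults:
    """Convenience wrapper around :class:`MixedLMScan`."""
    return MixedLMScan(phenotype, geno, kinship_mode, n_pcs, **kw).fit()


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """-log10(alpha / n_markers)."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    return float(-np.log10(alpha / n_markers))


def inflation_lambda(p_values) -> float:
    """Slope of observed vs expected -log10 p (no intercept).

    Expected quantiles are the medians of the uniform order statistics
    (Beta(i, n+1-i) medians); lambda = 1 indicates calibrated tests.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    n = len(p)
    if n < 10:
        raise ValueError("need at least 10 p-values")
    obs = np.sort(-np.log10(p))
    i = np.arange(1, n + 1)
    expected = np.sort(-np.log10(stats.beta.median(i, n + 1 - i)))
    return float(np.sum(obs * expected) / np.sum(expected ** 2))


def marker_pve(dosage: np.ndarray, phenotype: np.ndarray) -> float:
    """Percent phenotypic variance explained by one marker.

    PVE = 100 * beta^2 Var(x) / Var(y) from the single-marker regression,
    capped at 100.
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    vx = x.var()
    if vx == 0:
        raise ValueError("monomorphic marker")
    vy = y.var()
    if vy == 0:
        return 0.0
    beta = np.cov(x, y, ddof=0)[0, 1] / vx
    return float(min(100.0, 100.0 * beta ** 2 * vx / vy))


# ---------------------------------------------------------------------------
# Consensus QTL
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class QtlCall:
    """A consensus QTL: co-located markers supported by >=2 models or by
    both panels."""

    chromosome: str
    position_bp: int
    traits: tuple
    models: tuple
    panels: tuple
    mean_score: float
    mean_pve: float | None
    members: tuple                 # (chrom, pos) of merged markers


def consensus_qtl(results, thresholds: dict, merge_radius_bp: int = 100_000,
                  alpha: float = 0.05, pve_by_marker: dict | None = None):
    """Apply the two-model / two-panel significance rule and merge calls.

    Parameters
    ----------
    results : iterable of GwasResults
        Labelled per-model, per-panel scan tables over shared coordinates.
    thresholds : dict
        panel -> -log10 significance threshold.
    merge_radius_bp : int
        Passing markers within this distance on a chromosome merge into one
        call (transitively).
    pve_by_marker : dict, optional
        (chrom, pos) -> PVE percent, averaged into the calls.

    Returns
    -------
    list of QtlCall, sorted by chromosome and position; output does not
    depend on the order of ``results``.
    """
    hits = {}
    for res in sorted(results, key=lambda r: (r.panel, r.model, r.trait)):
        thr = thresholds[res.panel]
        sig = res.table[res.table["score"] >= thr]
        for _, row in sig.iterrows():
            key = (str(row["chrom"]), int(row["pos"]))
            hits.setdefault(key, []).append(
                (res.model, res.panel, res.trait, float(row["score"])))

    passing = {}
    for key, entries in hits.items():
        models_by_panel = {}
        panels = set()
        for model, panel, trait, score in entries:
            models_by_panel.setdefault(panel, set()).add(model)
            panels.add(panel)
        ok = any(len(ms) >= 2 for ms in models_by_panel.values()) \
            or len(panels) >= 2
        if ok:
            passing[key] = entries

    # transitive merge within radius, per chromosome
    calls = []
    by_chrom = {}
    for (c, p) in passing:
        by_chrom.setdefault(c, []).append(p)
    for c in sorted(by_chrom):
        positions = sorted(by_chrom[c])
        cluster = [positions[0]]
        clusters = []
        for p in positions[1:]:
            if p - cluster[-1] <= merge_radius_bp:
                cluster.append(p)
            else:
                clusters.append(cluster)
                cluster = [p]
        clusters.append(cluster)
        for cl in clusters:
            entries = [e for p in cl for e in passing[(c, p)]]
            scores = [e[3] for e in entries]
            pves = None
            if pve_by_marker is not None:
                pv = [pve_by_marker[(c, p)] for p in cl
                      if (c, p) in pve_by_marker]
                pves = float(np.mean(pv)) if pv else None
            top = cl[int(np.argmax(
                [max(e[3] for e in passing[(c, p)]) for p in cl]))]
            calls.append(QtlCall(
                chromosome=c, position_bp=int(top),
                traits=tuple(sorted({e[2] for e in entries})),
                models=tuple(sorted({e[0] for e in entries})),
                panels=tuple(sorted({e[1] for e in entries})),
                mean_score=float(np.mean(scores)), mean_pve=pves,
                members=tuple((c, int(p)) for p in cl)))
    calls.sort(key=lambda q: (q.chromosome, q.position_bp))
    return calls


def qtl_table(calls) -> pd.DataFrame:
    rows = [{
        "chrom": q.chromosome, "pos": q.position_bp,
        "traits": ";".join(q.traits), "models": ";".join(q.models),
        "panels": ";".join(q.panels), "score": q.mean_score,
        "pve": q.mean_pve, "n_markers": len(q.members),
    } for q in calls]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay(geno: GenotypeMatrix, max_dist_bp: int = 2_000_000,
             bin_width_bp: int = 20_000, r2_target: float = 0.1):
    """Binned LD decay curve and the distance where it crosses a target r^2.

    Pairwise dosage r^2 within ``max_dist_bp`` is averaged per distance bin;
    the crossing distance is the first bin midpoint at which the monotone
    (non-increasing) envelope of the curve drops below ``r2_target``.

    Returns
    -------
    (curve DataFrame with bin_mid, mean_r2, n_pairs; crossing distance in
    bp or nan if the curve never drops below the target)
    """
    d = geno.imputed()
    dc = d - d.mean(axis=0)
    sd = dc.std(axis=0)
    chroms = geno.chrom.astype(str)
    nbins = int(np.ceil(max_dist_bp / bin_width_bp))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)
    for c in pd.unique(chroms):
        idx = np.where(chroms == c)[0]
        if len(idx) < 2:
            continue
        pos = geno.pos[idx]
        sub = dc[:, idx]
        ssd = sd[idx]
        for a in range(len(idx) - 1):
            if ssd[a] == 0:
                continue
            upper = np.searchsorted(pos, pos[a] + max_dist_bp,
                                    side="right")
            b = np.arange(a + 1, upper)
            b = b[ssd[b] > 0]
            if b.size == 0:
                continue
            r = (sub[:, a] @ sub[:, b]) / (len(sub) * ssd[a] * ssd[b])
            binno = ((pos[b] - pos[a]) // bin_width_bp).astype(int)
            binno = np.clip(binno, 0, nbins - 1)
            np.add.at(sums, binno, r ** 2)
            np.add.at(counts, binno, 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = (np.arange(nbins) + 0.5) * bin_width_bp
    # monotone non-increasing envelope over observed bins
    obs = ~np.isnan(mean_r2)
    smooth = np.full(nbins, np.nan)
    running = -np.inf
    for i in range(nbins - 1, -1, -1):
        if obs[i]:
            running = max(running, mean_r2[i])
            smooth[i] = running
    crossing = np.nan
    for i in range(nbins):
        if obs[i] and smooth[i] < r2_target:
            crossing = float(mids[i])
            break
    curve = pd.DataFrame({"bin_mid": mids, "mean_r2": mean_r2,
                          "smoothed_r2": smooth, "n_pairs": counts})
    return curve, crossing
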