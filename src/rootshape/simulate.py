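"""Synthetic data generation with known ground truth.

Three generators drive the pipeline's recovery tests:

* root silhouettes spanning the globose -> cylindrical -> conical ->
  unswollen-taproot continuum, rasterised from analytic width profiles;
* structured genotypes under the Balding-Nichols model with Dirichlet
  admixture;
* multi-environment phenotypes from the additive linear model
  ``y = mu + g + e + gxe + block(e) + plot(e,b) + residual`` with
  configurable variance components and causal QTL.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

FAMILIES = ("globose", "cylindrical", "conical", "taproot")

#: Variance components of the default simulated study: strong genotype signal
#: against equal smaller contributions from every non-genetic source.
DEFAULT_VARIANCES = {
    "g": 1.0, "env": 0.25, "gxe": 0.25,
    "block": 0.25, "plot": 0.25, "residual": 0.25,
}

#: Default trial design: a multi-environment RCBD with one plot (row) per
#: accession per block and several roots harvested per plot.
DEFAULT_DESIGN = {"n_environments": 4, "n_blocks": 3, "roots_per_plot": 6}


# ---------------------------------------------------------------------------
# Root silhouettes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ShapeParams:
    """Analytic description of a root silhouette.

    The half-width at fractional depth ``t`` (0 = crown, 1 = tip) is
    ``(max_width_mm / 2) * f(t)`` where ``f`` is the family profile:

    * ``globose`` -- raised-cosine bulge peaking at ``bulge_position``;
    * ``cylindrical`` -- constant width, optional elliptical tip cap over the
      final ``tip_cap_fraction`` of the length (0 gives a flat bottom);
    * ``conical`` -- linear taper from full width at the crown to zero;
    * ``taproot`` -- power-law taper ``(1-t)**taper_exponent`` on a narrow
      profile (width/length < 0.15).
    """

    length_mm: float
    max_width_mm: float
    family: str = "cylindrical"
    bulge_position: float = 0.5
    taper_exponent: float = 1.0
    tip_cap_fraction: float = 0.0

    def __post_init__(self):
        if self.length_mm <= 0 or self.max_width_mm <= 0:
            raise ValueError("length_mm and max_width_mm must be positive")
        if not 0.0 <= self.bulge_position <= 1.0:
            raise ValueError("bulge_position must lie in [0, 1]")
        if self.taper_exponent <= 0:
            raise ValueError("taper_exponent must be positive")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if (self.family == "taproot"
                and self.max_width_mm / self.length_mm >= 0.15):
            raise ValueError("taproot requires max_width/length < 0.15")

    # -- profile ---------------------------------------------------------
    def profile(self, t):
        """Normalised half-width f(t) in [0, 1] at fractional depth t."""
        t = np.asarray(t, dtype=float)
        if self.family == "globose":
            b = min(max(self.bulge_position, 1e-9), 1 - 1e-9)
            u = np.where(t <= b, 0.5 * t / b, 0.5 + 0.5 * (t - b) / (1 - b))
            return np.sin(np.pi * u) ** self.taper_exponent
        if self.family == "cylindrical":
            c = self.tip_cap_fraction
            f = np.ones_like(t)
            if c > 0:
                cap = t > 1 - c
                s = (t[cap] - (1 - c)) / c
                f[cap] = np.sqrt(np.clip(1 - s**2, 0.0, 1.0))
            return f
        if self.family == "conical":
            return np.clip(1.0 - t, 0.0, 1.0)
        # taproot
        return np.clip(1.0 - t, 0.0, 1.0) ** self.taper_exponent

    def analytic_area_mm2(self, n: int = 20001) -> float:
        """Area of the silhouette, 2 * integral of the half-width profile."""
        t = np.linspace(0.0, 1.0, n)
        return float(self.max_width_mm * self.length_mm
                     * np.trapezoid(self.profile(t), t))


def render_root_mask(params: ShapeParams, pixel_scale: float,
                     pad_px: int = 3):
    """Rasterise a silhouette into a binary root mask.

    Parameters
    ----------
    params : ShapeParams
    pixel_scale : float
        Millimetres per pixel (> 0).
    pad_px : int
        Background margin around the silhouette.

    Returns
    -------
    RootMask with the crown at row ``pad_px`` (top of the image).
    """
    from .shapes import RootMask

    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    n_rows = int(round(params.length_mm / pixel_scale))
    n_cols = int(np.ceil(params.max_width_mm / pixel_scale)) + 2
    if n_rows < 2:
        raise ValueError("silhouette shorter than two pixels at this scale")
    h = n_rows + 2 * pad_px
    w = n_cols + 2 * pad_px
    grid = np.zeros((h, w), dtype=bool)
    # pixel-centre depth of each silhouette row
    t = (np.arange(n_rows) + 0.5) / n_rows
    half_px = params.max_width_mm / 2.0 * params.profile(t) / pixel_scale
    # rows with a positive but sub-pixel half-width still get one pixel pair,
    # so tapering tips reach their analytic depth
    half_px = np.where(half_px >= 0.25, np.maximum(half_px, 0.51), 0.0)
    centre = w / 2.0
    cols = np.arange(w) + 0.5
    for r in range(n_rows):
        if half_px[r] <= 0:
            continue
        row = np.abs(cols - centre) <= half_px[r]
        grid[pad_px + r, row] = True
    if not grid.any():
        raise ValueError("degenerate silhouette: empty mask")
    if grid[0].any() or grid[-1].any() or grid[:, 0].any() or grid[:, -1].any():
        raise ValueError("silhouette clipped by image bounds")
    return RootMask(grid, pixel_scale)


def shape_params_from_latents(log_length: float, log_width: float,
                              family: str) -> ShapeParams:
    """Map two latent genetic axes (log length, log width) to ShapeParams.

    Non-genetic profile parameters are fixed per family; the taproot family
    clamps width to honour its narrowness constraint.
    """
    length = float(np.exp(log_length))
    width = float(np.exp(log_width))
    fixed = {
        "globose": dict(bulge_position=0.45, taper_exponent=1.0),
        "cylindrical": dict(tip_cap_fraction=0.08),
        "conical": dict(),
        "taproot": dict(taper_exponent=1.6),
    }[family]
    if family == "taproot":
        width = min(width, 0.14 * length)
    return ShapeParams(length_mm=length, max_width_mm=width, family=family,
                       **fixed)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimTruth:
    """Ground truth of a simulation run, for recovery tests."""

    causal_markers: list = dataclasses.field(default_factory=list)
    q_true: np.ndarray | None = None
    f_true: np.ndarray | None = None
    variance_components_true: dict = dataclasses.field(default_factory=dict)
    shape_params_per_accession: dict = dataclasses.field(default_factory=dict)
    genetic_values: dict = dataclasses.field(default_factory=dict)

    def to_json(self, path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if dataclasses.is_dataclass(x):
                return dataclasses.asdict(x)
            return x

        payload = {k: conv(v) for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=conv)


def generate_population(n_accessions: int, n_markers: int, k_pops: int,
                        fst: float, admixture_alpha: float,
                        n_chromosomes: int = 9, seed: int = 0,
                        missing_rate: float = 0.0,
                        chrom_length_bp: int = 60_000_000,
                        groups_from_ancestry: bool = True):
    """Simulate structured genotypes under the Balding-Nichols model.

    Ancestral allele frequencies are drawn Uniform(0.05, 0.95); population
    frequencies from Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst``; ancestry
    proportions from Dirichlet(``admixture_alpha``); dosages from
    Binomial(2, q . f).

    Returns
    -------
    (GenotypeMatrix, SimTruth)
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must lie in (0, 1)")
    if k_pops < 1:
        raise ValueError("k_pops must be >= 1")
    if n_markers < k_pops:
        raise ValueError("need at least as many markers as populations")
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    rng = np.random.default_rng(seed)

    p_anc = rng.uniform(0.05, 0.95, size=n_markers)
    a = (1.0 - fst) / fst
    f = rng.beta(p_anc * a, (1.0 - p_anc) * a, size=(k_pops, n_markers))
    f = np.clip(f, 1e-6, 1 - 1e-6)
    q = rng.dirichlet(np.full(k_pops, admixture_alpha), size=n_accessions)
    p_ind = q @ f
    dosage = rng.binomial(2, p_ind).astype(float)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan

    # uniform positions per chromosome, markers split evenly
    counts = np.full(n_chromosomes, n_markers // n_chromosomes)
    counts[: n_markers % n_chromosomes] += 1
    chrom, pos = [], []
    for c, m in enumerate(counts, start=1):
        p = np.sort(rng.choice(np.arange(1, chrom_length_bp), size=m,
                               replace=False))
        chrom.extend([f"chr{c}"] * m)
        pos.extend(p.tolist())
    accessions = [f"acc{i:04d}" for i in range(n_accessions)]
    groups = None
    if groups_from_ancestry:
        groups = {a_: f"pop{np.argmax(q[i]) + 1}"
                  for i, a_ in enumerate(accessions)}
    geno = GenotypeMatrix(dosage, np.array(chrom, dtype=object),
                          np.array(pos, dtype=np.int64),
                          np.full(n_markers, "A", dtype=object),
                          np.full(n_markers, "T", dtype=object),
                          accessions, groups)
    truth = SimTruth(q_true=q, f_true=f)
    return geno, truth


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(genotypes: GenotypeMatrix, qtl_spec=None,
                        variance_spec=None, design=None, mu: float = 0.0,
                        trait: str = "trait", units: str = "au",
                        seed: int = 0):
    """Simulate long-format phenotype records from the additive trial model.

    Each observation is ``mu + g_i + e_j + (gxe)_ij + b_k(j) + p_l(jk) +
    eps``, with every random term drawn iid normal at its configured
    variance.  The genetic value ``g_i`` is the causal-marker sum
    (``qtl_spec``) plus a polygenic normal draw at variance
    ``variance_spec['g']``.

    Parameters
    ----------
    qtl_spec : list of (chrom, pos, effect), optional
        Additive allele-substitution effects at named markers.
    variance_spec : dict, optional
        Variances for 'g', 'env', 'gxe', 'block', 'plot', 'residual'
        (missing keys default to :data:`DEFAULT_VARIANCES`).
    design : dict, optional
        'n_environments', 'n_blocks', 'roots_per_plot' (defaults to
        :data:`DEFAULT_DESIGN`); one plot per accession per (env, block).

    Returns
    -------
    (records DataFrame, SimTruth)
    """
    var = dict(DEFAULT_VARIANCES)
    var.update(variance_spec or {})
    for k, v in var.items():
        if v < 0:
            raise ValueError(f"negative variance for {k!r}")
    des = dict(DEFAULT_DESIGN)
    des.update(design or {})
    n_env, n_blk = des["n_environments"], des["n_blocks"]
    n_root = des["roots_per_plot"]
    rng = np.random.default_rng(seed)

    acc = list(genotypes.accessions)
    n = len(acc)
    g = np.zeros(n)
    causal = []
    if qtl_spec:
        ids = {(str(c), int(p)): j for j, (c, p)
               in enumerate(zip(genotypes.chrom, genotypes.pos))}
        dos = genotypes.imputed()
        for c, p, beta in qtl_spec:
            j = ids.get((str(c), int(p)))
            if j is None:
                raise ValueError(f"no marker at {c}:{p}")
            g = g + beta * dos[:, j]
            causal.append((str(c), int(p), float(beta)))
    if var["g"] > 0:
        g = g + rng.normal(0.0, np.sqrt(var["g"]), size=n)

    envs = [f"env{j + 1}" for j in range(n_env)]
    e = rng.normal(0.0, np.sqrt(var["env"]), size=n_env)
    ge = rng.normal(0.0, np.sqrt(var["gxe"]), size=(n, n_env))
    b = rng.normal(0.0, np.sqrt(var["block"]), size=(n_env, n_blk))

    rows = []
    for j, env in enumerate(envs):
        for k in range(n_blk):
            blk = f"{env}.b{k + 1}"
            p_eff = rng.normal(0.0, np.sqrt(var["plot"]), size=n)
            eps = rng.normal(0.0, np.sqrt(var["residual"]),
                             size=(n, n_root))
            for i, a in enumerate(acc):
                base = mu + g[i] + e[j] + ge[i, j] + b[j, k] + p_eff[i]
                plot = f"{blk}.{a}"
                for r in range(n_root):
                    rows.append((a, env, blk, plot, r + 1, trait,
                                 base + eps[i, r], units))
    records = pd.DataFrame(rows, columns=["accession", "env", "block",
                                          "plot", "root", "trait", "value",
                                          "units"])
    truth = SimTruth(causal_markers=causal, variance_components_true=var,
                     genetic_values={trait: dict(zip(acc, g.tolist()))})
    return records, truth


def simulate_shape_study(genotypes: GenotypeMatrix, qtl_length=None,
                         qtl_width=None, design=None, seed: int = 0,
                         mean_log_length: float = np.log(120.0),
                         mean_log_width: float = np.log(45.0),
                         sigma_g: float = 0.15, sigma_env: float = 0.04,
                         sigma_gxe: float = 0.03, sigma_block: float = 0.03,
                         sigma_plot: float = 0.03, sigma_root: float = 0.05,
                         biomass_extra_noise: float = 0.45,
                         pixel_scale: float = 1.0):
    """End-to-end study generator: genotypes -> latent shapes -> root masks.

    Two latent genetic axes, log length and log width, carry the causal QTL
    (``qtl_length`` / ``qtl_width``, lists of (chrom, pos, effect) on the log
    scale) plus polygenic variation of SD ``sigma_g``.  Per-observation
    shapes perturb the latents by environment, G x E, block, plot and root
    noise (SDs on the log scale), then rasterise a silhouette per root.
    Digital biomass receives an extra multiplicative lognormal noise term
    (``biomass_extra_noise`` SD) so size is measurably less heritable than
    shape, as in field data where biomass integrates many non-genetic
    influences.

    Returns
    -------
    (masks, meta DataFrame, SimTruth) where ``masks`` is a list of RootMask
    aligned with the rows of ``meta`` (accession/env/block/plot/root and the
    latent log length/width used, plus ``biomass_noise`` the multiplicative
    factor to apply to measured areas).
    """
    rng = np.random.default_rng(seed)
    des = dict(DEFAULT_DESIGN)
    des.update(design or {})
    n_env, n_blk, n_root = (des["n_environments"], des["n_blocks"],
                            des["roots_per_plot"])
    acc = list(genotypes.accessions)
    n = len(acc)
    dos = genotypes.imputed()
    ids = {(str(c), int(p)): j for j, (c, p)
           in enumerate(zip(genotypes.chrom, genotypes.pos))}

    Wc = dos - dos.mean(axis=0)

    def genetic(latent_qtl, key):
        # polygenic background is marker-encoded (small effects everywhere),
        # so the additive signal is visible to genomic prediction
        u = rng.normal(0.0, 1.0, size=Wc.shape[1])
        g = Wc @ u
        sd = g.std()
        g = g * (sigma_g / sd) if sd > 0 else np.zeros(n)
        causal = []
        for c, p, beta in latent_qtl or []:
            j = ids.get((str(c), int(p)))
            if j is None:
                raise ValueError(f"no marker at {c}:{p}")
            g = g + beta * Wc[:, j]
            causal.append((str(c), int(p), float(beta), key))
        return g, causal

    gL, causL = genetic(qtl_length, "log_length")
    gW, causW = genetic(qtl_width, "log_width")
    # the shape class follows the genetic length/width ratio: squat roots
    # are globose, elongated ones taper toward unswollen taproots
    ratio = gL - gW
    qs = np.quantile(ratio, [0.35, 0.65, 0.85])
    families = np.array(FAMILIES)[np.searchsorted(qs, ratio)]

    eL = rng.normal(0, sigma_env, n_env)
    eW = rng.normal(0, sigma_env, n_env)
    geL = rng.normal(0, sigma_gxe, (n, n_env))
    geW = rng.normal(0, sigma_gxe, (n, n_env))

    masks, rows = [], []
    for j in range(n_env):
        env = f"env{j + 1}"
        for k in range(n_blk):
            blk = f"{env}.b{k + 1}"
            bL = rng.normal(0, sigma_block)
            bW = rng.normal(0, sigma_block)
            pL = rng.normal(0, sigma_plot, n)
            pW = rng.normal(0, sigma_plot, n)
            for i, a in enumerate(acc):
                plot = f"{blk}.{a}"
                for r in range(n_root):
                    ll = (mean_log_length + gL[i] + eL[j] + geL[i, j]
                          + bL + pL[i] + rng.normal(0, sigma_root))
                    lw = (mean_log_width + gW[i] + eW[j] + geW[i, j]
                          + bW + pW[i] + rng.normal(0, sigma_root))
                    params = shape_params_from_latents(ll, lw, families[i])
                    masks.append(render_root_mask(params, pixel_scale))
                    rows.append((a, env, blk, plot, r + 1, ll, lw,
                                 float(np.exp(rng.normal(
                                     0, biomass_extra_noise)))))
    meta = pd.DataFrame(rows, columns=["accession", "env", "block", "plot",
                                       "root", "log_length", "log_width",
                                       "biomass_noise"])
    truth = SimTruth(
        causal_markers=causL + causW,
        genetic_values={"log_length": dict(zip(acc, gL.tolist())),
                        "log_width": dict(zip(acc, gW.tolist()))},
        shape_params_per_accession={a: families[i]
                                    for i, a in enumerate(acc)})
    return masks, meta, truth
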