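"""Image-based root shape phenotyping.

A binary silhouette (crown at the top, tip at the bottom, known mm-per-pixel
scale) is reduced to six traits: digital biomass (2-D mask area), length,
maximum width, width at half length, the natural log of the length-to-width
ratio, the tip angle, and a population-referenced contour PC score capturing
where along the root the swollen region sits.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import measure

#: Fractional depth stations for width profiles (t = 0, 0.01, ..., 1).
DEFAULT_STATIONS = 101


@dataclasses.dataclass
class RootMask:
    """Binary root silhouette with its physical scale.

    Row 0 is the crown (top) side; ``pixel_scale`` is mm per pixel.
    """

    grid: np.ndarray
    pixel_scale: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")

    def rotated180(self) -> "RootMask":
        return RootMask(self.grid[::-1, ::-1].copy(), self.pixel_scale)

    def to_png(self, path) -> None:
        Image.fromarray((self.grid * 255).astype(np.uint8), mode="L").save(
            str(path), format="PNG")

    @classmethod
    def from_png(cls, path, pixel_scale: float) -> "RootMask":
        arr = np.asarray(Image.open(str(path)).convert("L"))
        return cls(arr > 127, pixel_scale)


@dataclasses.dataclass
class Contour:
    """Cleaned component, closed contour polygon and crown/tip anchors.

    Anchors are (row, col) in sub-pixel edge coordinates: the column midpoint
    of the top/bottom foreground row span.
    """

    grid: np.ndarray            # cleaned, hole-filled component
    pixel_scale: float
    polygon: np.ndarray         # (k, 2) array of (row, col) vertices
    crown: tuple                # (row, col)
    tip: tuple                  # (row, col)


@dataclasses.dataclass
class WidthProfile:
    stations: np.ndarray        # fractional depths in [0, 1]
    widths_mm: np.ndarray
    length_mm: float
    max_width_mm: float
    width50_mm: float


@dataclasses.dataclass
class ShapeTraits:
    digital_biomass_mm2: float
    length_mm: float
    max_width_mm: float
    width50_mm: float
    lw_ratio_log: float
    tip_angle_deg: float
    contour_pc: float | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Contour extraction
# ---------------------------------------------------------------------------

def extract_contour(mask: RootMask) -> Contour:
    """Clean a mask and locate its outline and crown/tip anchors.

    Keeps the largest connected component (raising if several tie for
    largest), fills interior holes, and anchors the crown and tip at the
    midpoints of the top and bottom foreground row spans.
    """
    grid = mask.grid
    if not grid.any():
        raise ValueError("empty mask")
    labels, n = ndimage.label(grid)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        best = np.argmax(sizes)
        if np.sum(sizes == sizes[best]) > 1:
            raise ValueError(
                f"{int(np.sum(sizes == sizes[best]))} equal-size largest "
                "components; cannot choose one")
        grid = labels == best + 1
    grid = ndimage.binary_fill_holes(grid)

    rows = np.where(grid.any(axis=1))[0]
    top, bottom = rows[0], rows[-1]
    crown = (float(top), _row_mid(grid[top]))
    tip = (float(bottom), _row_mid(grid[bottom]))

    padded = np.pad(grid.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    polygon = max(contours, key=len) - 1.0
    return Contour(grid=grid, pixel_scale=mask.pixel_scale, polygon=polygon,
                   crown=crown, tip=tip)


def _row_mid(row: np.ndarray) -> float:
    cols = np.where(row)[0]
    # midpoint of the span in pixel-edge coordinates
    return (cols[0] + cols[-1] + 1) / 2.0


def _row_extent_px(row: np.ndarray) -> float:
    cols = np.where(row)[0]
    if cols.size == 0:
        return 0.0
    return float(cols[-1] - cols[0] + 1)


# ---------------------------------------------------------------------------
# Width profile and traits
# ---------------------------------------------------------------------------

def width_profile(contour: Contour,
                  stations: int = DEFAULT_STATIONS) -> WidthProfile:
    """Widths at fixed fractional depths from crown to tip.

    Length is the vertical crown-to-tip distance; the width at station ``t``
    is the horizontal foreground extent at the row nearest depth
    ``crown + t * length``; the maximum width scans every row.
    """
    if stations < 11:
        raise ValueError("need at least 11 stations")
    grid, scale = contour.grid, contour.pixel_scale
    top, bottom = int(contour.crown[0]), int(contour.tip[0])
    span = bottom - top
    if span < 1:
        raise ValueError("zero-length root")
    length_mm = (span + 1) * scale

    t = np.linspace(0.0, 1.0, stations)
    rows = top + np.round(t * span).astype(int)
    widths = np.array([_row_extent_px(grid[r]) for r in rows]) * scale
    all_widths = np.array([_row_extent_px(grid[r])
                           for r in range(top, bottom + 1)]) * scale
    return WidthProfile(stations=t, widths_mm=widths,
                        length_mm=float(length_mm),
                        max_width_mm=float(all_widths.max()),
                        width50_mm=float(widths[stations // 2]))


def tip_angle(contour: Contour) -> float:
    """Interior angle at the tip, subtended by the contour points 10% of the
    root length above the tip anchor.

    Returns degrees in (0, 180].
    """
    grid, scale = contour.grid, contour.pixel_scale
    top, bottom = int(contour.crown[0]), int(contour.tip[0])
    length_px = bottom - top + 1
    if length_px <= 10:
        raise ValueError("root too short for tip angle (need > 10 px length)")
    h_px = 0.1 * length_px
    row = int(round(bottom - h_px))
    cols = np.where(grid[row])[0]
    if cols.size == 0:
        raise ValueError("no foreground at the tip-angle reference row")
    # outer pixel edges of the span; ties toward the outermost column
    left = (row, float(cols[0]))
    right = (row, float(cols[-1] + 1))
    tip = (float(bottom), contour.tip[1])
    v1 = np.array([left[0] - tip[0], left[1] - tip[1]])
    v2 = np.array([right[0] - tip[0], right[1] - tip[1]])
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def measure_traits(mask: RootMask,
                   stations: int = DEFAULT_STATIONS) -> ShapeTraits:
    """All per-root traits except the population-referenced contour PC."""
    contour = extract_contour(mask)
    prof = width_profile(contour, stations)
    area = float(contour.grid.sum()) * mask.pixel_scale ** 2
    return ShapeTraits(
        digital_biomass_mm2=area,
        length_mm=prof.length_mm,
        max_width_mm=prof.max_width_mm,
        width50_mm=prof.width50_mm,
        lw_ratio_log=float(np.log(prof.length_mm / prof.max_width_mm)),
        tip_angle_deg=tip_angle(contour),
    )


# ---------------------------------------------------------------------------
# Contour PCA
# ---------------------------------------------------------------------------

def contour_pca(profiles, reference_loadings: dict | None = None):
    """Size-independent contour score from width-profile PCA.

    Each profile is normalised to ``widths / max(widths)`` at its fixed
    fractional stations, the normalised profiles are column-centred and
    decomposed by SVD, and the PC1 score is returned per profile.  The sign
    is fixed so positive scores go with crown-ward (t < 0.5) mass.  With
    ``reference_loadings`` (as returned here) profiles are projected onto an
    existing shape space instead of refitting.

    Returns
    -------
    (scores, loadings, pct_variance) where loadings is a dict with keys
    'mean', 'pc1', 'stations' suitable for JSON storage and reprojection.
    """
    profiles = list(profiles)
    S = {len(p.widths_mm) for p in profiles}
    if len(S) != 1:
        raise ValueError("profiles have differing station counts")
    X = np.array([p.widths_mm / max(p.widths_mm.max(), 1e-12)
                  for p in profiles])
    t = profiles[0].stations

    if reference_loadings is not None:
        mean = np.asarray(reference_loadings["mean"])
        pc1 = np.asarray(reference_loadings["pc1"])
        if mean.shape[0] != X.shape[1]:
            raise ValueError("reference loadings station count mismatch")
        scores = (X - mean) @ pc1
        return scores, reference_loadings, reference_loadings.get("pct", 0.0)

    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles to fit a shape space")
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s ** 2).sum())
    if total <= 1e-20:
        zeros = np.zeros(len(profiles))
        loadings = {"mean": mean.tolist(), "pc1": vt[0].tolist(),
                    "stations": t.tolist(), "pct": 0.0}
        return zeros, loadings, 0.0
    pc1 = vt[0]
    scores = Xc @ pc1
    crown_mass = Xc[:, t < 0.5].sum(axis=1) - Xc[:, t > 0.5].sum(axis=1)
    if np.dot(scores, crown_mass) < 0:
        pc1 = -pc1
        scores = -scores
    pct = float(100.0 * s[0] ** 2 / total)
    loadings = {"mean": mean.tolist(), "pc1": pc1.tolist(),
                "stations": t.tolist(), "pct": pct}
    return scores, loadings, pct


def save_loadings(loadings: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(loadings, fh)


def load_loadings(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Outlier filter
# ---------------------------------------------------------------------------

def outlier_filter(table: pd.DataFrame, sd_threshold: float = 3.0,
                   trait_col: str = "trait", value_col: str = "value"):
    """Single-pass z-score outlier removal per trait.

    Observations with |z| strictly greater than ``sd_threshold`` (z from the
    unfiltered mean and SD of that trait) are removed; a zero SD removes
    nothing.

    Returns
    -------
    (filtered table, removal log) -- the log records the index, trait, value
    and z of every removed row.
    """
    removed = []
    keep_mask = np.ones(len(table), dtype=bool)
    for trait, sub in table.groupby(trait_col):
        if len(sub) < 3:
            continue
        v = sub[value_col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            continue
        z = (v - v.mean()) / sd
        bad = np.abs(z) > sd_threshold
        for idx, val, zz in zip(sub.index[bad], v[bad], z[bad]):
            removed.append({"index": idx, trait_col: trait,
                            value_col: val, "z": zz})
            keep_mask[table.index.get_loc(idx)] = False
    log = pd.DataFrame(removed,
                       columns=["index", trait_col, value_col, "z"])
    return table[keep_mask], log


def traits_table(masks, ids=None, stations: int = DEFAULT_STATIONS,
                 fit_contour_space: bool = True,
                 reference_loadings: dict | None = None):
    """Measure a collection of masks into a long trait table.

    Returns
    -------
    (long DataFrame with accession-level ids, loadings dict) -- the contour
    PC is fit across the whole collection (one population-level shape space)
    unless ``reference_loadings`` is given.
    """
    ids = list(ids) if ids is not None else list(range(len(masks)))
    rows, profiles = [], []
    for mask in masks:
        contour = extract_contour(mask)
        prof = width_profile(contour, stations)
        profiles.append(prof)
        area = float(contour.grid.sum()) * mask.pixel_scale ** 2
        rows.append({
            "digital_biomass_mm2": area,
            "length_mm": prof.length_mm,
            "max_width_mm": prof.max_width_mm,
            "width50_mm": prof.width50_mm,
            "lw_ratio_log": float(np.log(prof.length_mm
                                         / prof.max_width_mm)),
            "tip_angle_deg": tip_angle(contour),
        })
    loadings = reference_loadings
    if fit_contour_space or reference_loadings is not None:
        scores, loadings, _ = contour_pca(profiles, reference_loadings)
        for r, s in zip(rows, scores):
            r["contour_pc"] = float(s)
    wide = pd.DataFrame(rows, index=pd.Index(ids, name="id"))
    return wide, loadings
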