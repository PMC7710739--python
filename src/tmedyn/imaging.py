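"""Lymphocyte detection and TIL density on histology-like images.

The detector follows the classic H&E nuclei-counting recipe: global Otsu
segmentation of dark nuclei with size filters (minShape 50, maxShape 800,
failureRegion 2000; over-size components between maxShape and
failureRegion are split by watershed on the distance transform), a fixed
36-dimensional shape/intensity/texture feature vector per candidate, a
C-type radial-kernel SVM with probability outputs, the published score and
size filters (lymphocyte: probability >= 0.97 and area in [60, 150];
non-lymphocyte: probability <= 0.1; large cell: area >= Q3 of cells larger
than 200 px), tile-wise processing of large images with global coordinate
reconstruction, and TIL density = lymphocyte count / tissue area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed
from sklearn.svm import SVC

from .io import CohortError

__all__ = [
    "CellCandidate",
    "TILQuantification",
    "segment_nuclei",
    "extract_features",
    "train_classifier",
    "train_default_classifier",
    "classify_candidates",
    "filter_lymphocytes",
    "tile_process",
    "tissue_area_pixels",
    "compute_density",
    "label_candidates_from_truth",
    "FEATURE_NAMES",
]

MIN_SHAPE = 50
MAX_SHAPE = 800
FAILURE_REGION = 2000
LYMPH_AREA_GATE = (60, 150)
LYMPH_PROB_MIN = 0.97
NONLYMPH_PROB_MAX = 0.1
LARGE_CELL_MIN_AREA = 200
TILE_SIZE = 2050
DEFAULT_UM_PER_PX = 0.5  # 20x convention


@dataclass
class CellCandidate:
    """One segmented nucleus candidate in global pixel coordinates."""

    x: float
    y: float
    area: int
    features: np.ndarray | None = None  # 36-vector, filled by extract_features
    probability: float | None = None  # P(lymphocyte)
    label: str | None = None  # predicted class


@dataclass
class TILQuantification:
    lymphocyte_count: int
    large_cell_count: int
    tissue_area_px: float
    tissue_area_mm2: float
    density_per_mm2: float
    um_per_px: float


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _to_gray(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        return rgb2gray(image)
    gray = image.astype(float)
    if gray.max() > 1.0:
        gray = gray / 255.0
    return gray


def _split_watershed(mask: np.ndarray) -> np.ndarray:
    """Split one over-sized component by watershed on its distance
    transform; returns a label image over the mask footprint."""
    distance = ndimage.distance_transform_edt(mask)
    coords = peak_local_max(distance, labels=mask, min_distance=5,
                            exclude_border=False)
    if len(coords) < 2:
        return mask.astype(int)
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    return watershed(-distance, markers, mask=mask)


def segment_nuclei(
    image: np.ndarray,
    min_shape: int = MIN_SHAPE,
    max_shape: int = MAX_SHAPE,
    failure_region: int = FAILURE_REGION,
    offset: tuple[int, int] = (0, 0),
) -> list[CellCandidate]:
    """Global-Otsu nuclei segmentation with size filters.

    Components below ``min_shape`` are discarded, components above
    ``failure_region`` are treated as segmentation failures and dropped,
    and components in ``(max_shape, failure_region]`` are split by
    watershed on the distance transform with the resulting pieces
    re-filtered (pieces that still exceed ``max_shape`` after one split
    are kept — repeated splitting would fragment genuinely large nuclei).
    ``offset`` shifts centroids into global coordinates (x = col, y = row).
    """
    gray = _to_gray(image)
    inverted = 1.0 - gray
    if np.allclose(inverted.max(), inverted.min()):
        return []  # uniform image: no foreground/background separation
    threshold = threshold_otsu(inverted)
    mask = inverted > threshold
    if mask.mean() > 0.25:
        # the global threshold separated slide background from tissue, not
        # tissue from nuclei (nuclei are sparse); re-threshold within the
        # tissue. A guard rejects the split when it only carves texture
        # noise (threshold not clearly above the tissue intensity mode).
        tissue_values = inverted[mask]
        t2 = threshold_otsu(tissue_values)
        med = np.median(tissue_values)
        robust_sd = 1.4826 * np.median(np.abs(tissue_values - med))
        if t2 > med + 3.0 * max(robust_sd, 1e-6):
            mask = inverted > t2
        else:
            return []
    labeled = sk_label(mask, connectivity=2)

    candidates: list[CellCandidate] = []
    off_x, off_y = offset

    def add_component(component_mask: np.ndarray, bbox_top: int, bbox_left: int) -> None:
        area = int(component_mask.sum())
        if area < min_shape or area > failure_region:
            return
        if area > max_shape:
            pieces = _split_watershed(component_mask)
            for piece_id in range(1, pieces.max() + 1):
                piece = pieces == piece_id
                piece_area = int(piece.sum())
                if piece_area < min_shape or piece_area > failure_region:
                    continue
                ys, xs = np.nonzero(piece)
                candidates.append(
                    CellCandidate(
                        x=float(bbox_left + xs.mean() + off_x),
                        y=float(bbox_top + ys.mean() + off_y),
                        area=piece_area,
                    )
                )
            return
        ys, xs = np.nonzero(component_mask)
        candidates.append(
            CellCandidate(
                x=float(bbox_left + xs.mean() + off_x),
                y=float(bbox_top + ys.mean() + off_y),
                area=area,
            )
        )

    for region in regionprops(labeled):
        top, left, bottom, right = region.bbox
        add_component(region.image, top, left)
    return candidates


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

_SHAPE_FEATURES = [
    "area", "perimeter", "eccentricity", "solidity", "extent",
    "major_axis_length", "minor_axis_length", "aspect_ratio",
    "equivalent_diameter", "circularity", "convexity_deficiency", "radius_sd",
]
_INTENSITY_FEATURES = [
    f"{stat}_{ch}"
    for ch in ("r", "g", "b")
    for stat in ("mean", "sd", "q10", "q50", "q90", "min")
]
_TEXTURE_FEATURES = [
    "gradient_mean", "gradient_sd", "intensity_range",
    "laplacian_sd", "local_sd_mean", "histogram_entropy",
]
FEATURE_NAMES: list[str] = _SHAPE_FEATURES + _INTENSITY_FEATURES + _TEXTURE_FEATURES
assert len(FEATURE_NAMES) == 36


def _candidate_mask(candidate: CellCandidate, image_shape, pad: int = 2):
    """Re-derive the local nucleus mask around a candidate centroid."""
    radius = int(np.ceil(np.sqrt(candidate.area / np.pi))) + 6
    cy, cx = int(round(candidate.y)), int(round(candidate.x))
    top = max(cy - radius, 0)
    left = max(cx - radius, 0)
    bottom = min(cy + radius + 1, image_shape[0])
    right = min(cx + radius + 1, image_shape[1])
    return top, left, bottom, right


def extract_features(candidates: list[CellCandidate], image: np.ndarray) -> np.ndarray:
    """Fixed 36-vector per candidate (shape, per-channel intensity, texture).

    Shape features come from the re-segmented nucleus mask around the
    candidate; intensity features are per-RGB-channel statistics over the
    nucleus pixels; texture features summarize local gradient and contrast.
    Candidates outside the image raise an error.
    """
    gray = _to_gray(image)
    if image.ndim == 3:
        channels = [image[:, :, c].astype(float) / 255.0 for c in range(3)]
    else:
        channels = [gray, gray, gray]
    h, w = gray.shape
    out = np.zeros((len(candidates), 36))
    for i, cand in enumerate(candidates):
        if not (0 <= cand.x < w and 0 <= cand.y < h):
            raise CohortError(f"candidate at ({cand.x:.0f},{cand.y:.0f}) outside image")
        top, left, bottom, right = _candidate_mask(cand, gray.shape)
        window = gray[top:bottom, left:right]
        inv = 1.0 - window
        try:
            local_mask = inv > threshold_otsu(inv)
        except ValueError:
            local_mask = np.zeros_like(inv, dtype=bool)
        lab = sk_label(local_mask, connectivity=2)
        cy, cx = int(round(cand.y)) - top, int(round(cand.x)) - left
        cy = np.clip(cy, 0, lab.shape[0] - 1)
        cx = np.clip(cx, 0, lab.shape[1] - 1)
        target = lab[cy, cx]
        if target == 0 and lab.max() > 0:
            # centroid fell on background (irregular shape): take largest
            target = np.argmax(np.bincount(lab[lab > 0]))
        mask = lab == target if target > 0 else local_mask

        feats: list[float] = []
        props = regionprops(mask.astype(int))
        if props:
            p = props[0]
            perimeter = max(p.perimeter, 1e-6)
            minor = p.axis_minor_length
            major = max(p.axis_major_length, 1e-6)
            ys, xs = np.nonzero(mask)
            radii = np.sqrt((ys - ys.mean()) ** 2 + (xs - xs.mean()) ** 2)
            feats += [
                float(p.area), float(perimeter), float(p.eccentricity),
                float(p.solidity), float(p.extent), float(major),
                float(minor), float(minor / major),
                float(p.equivalent_diameter_area),
                float(4 * np.pi * p.area / perimeter**2),
                float(1.0 - p.solidity),
                float(radii.std()),
            ]
        else:
            feats += [float(cand.area)] + [0.0] * 11

        pix = mask if mask.any() else np.ones_like(mask, dtype=bool)
        for ch in channels:
            v = ch[top:bottom, left:right][pix]
            feats += [
                float(v.mean()), float(v.std()),
                float(np.quantile(v, 0.1)), float(np.quantile(v, 0.5)),
                float(np.quantile(v, 0.9)), float(v.min()),
            ]

        gy, gx = np.gradient(window)
        gmag = np.hypot(gy, gx)[pix]
        lap = ndimage.laplace(window)[pix]
        local_sd = ndimage.generic_filter(window, np.std, size=3)[pix]
        v = window[pix]
        hist, _ = np.histogram(v, bins=16, range=(0, 1), density=False)
        prob = hist / max(hist.sum(), 1)
        entropy = float(-(prob[prob > 0] * np.log2(prob[prob > 0])).sum())
        feats += [
            float(gmag.mean()), float(gmag.std()), float(v.max() - v.min()),
            float(lap.std()), float(local_sd.mean()), entropy,
        ]
        out[i] = feats
        cand.features = out[i]
    return out


# ---------------------------------------------------------------------------
# classification and filtering
# ---------------------------------------------------------------------------

def train_classifier(
    features: np.ndarray, labels: list[str], seed: int = 0
) -> SVC:
    """C-type radial-kernel SVM with probability outputs.

    Labels are ``"lymphocyte"`` / ``"other"``; both classes must be
    present with at least 10 examples each.
    """
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise CohortError("train_classifier: both classes must be present")
    for c in classes:
        if labels.count(c) < 10:
            raise CohortError(f"train_classifier: fewer than 10 examples of {c!r}")
    model = SVC(C=1.0, kernel="rbf", gamma="scale", probability=True,
                random_state=seed)
    import warnings

    with warnings.catch_warnings():
        # sklearn 1.9 deprecation chatter about probability=True; the
        # Platt-scaled probability output is exactly what is wanted here
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(np.asarray(features), labels)
    return model


def train_default_classifier(
    seed: int = 0,
    n_images: int = 6,
    image_size: int = 600,
    n_lymphocytes: int = 50,
    n_other: int = 20,
) -> SVC:
    """Train the shipped synthetic-nuclei classifier.

    Pools candidates from several synthetic training images (a few hundred
    cells per class, the order of magnitude of a hand-marked training
    set), labels them against the planted truth and fits the radial SVM.
    """
    from .simulate import simulate_histology_image

    feats, labels = [], []
    for i in range(n_images):
        image, truth = simulate_histology_image(
            image_size, image_size, n_lymphocytes, n_other, seed=seed * 1000 + i
        )
        cands = segment_nuclei(image)
        feats.append(extract_features(cands, image))
        labels += label_candidates_from_truth(cands, truth)
    return train_classifier(np.vstack(feats), labels, seed=seed)


def classify_candidates(
    candidates: list[CellCandidate], model: SVC, image: np.ndarray | None = None
) -> list[CellCandidate]:
    """Attach lymphocyte probability and predicted label to candidates."""
    if not candidates:
        return candidates
    if any(c.features is None for c in candidates):
        if image is None:
            raise CohortError("classify_candidates: features missing and no image given")
        extract_features(candidates, image)
    feats = np.vstack([c.features for c in candidates])
    lymph_col = list(model.classes_).index("lymphocyte")
    probs = model.predict_proba(feats)[:, lymph_col]
    preds = model.predict(feats)
    for cand, prob, pred in zip(candidates, probs, preds):
        cand.probability = float(prob)
        cand.label = str(pred)
    return candidates


def filter_lymphocytes(
    candidates: list[CellCandidate],
    prob_min: float = LYMPH_PROB_MIN,
    nonlymph_prob_max: float = NONLYMPH_PROB_MAX,
    area_gate: tuple[int, int] = LYMPH_AREA_GATE,
) -> tuple[list[CellCandidate], list[CellCandidate], list[CellCandidate]]:
    """Apply the published score/size filters.

    Returns (lymphocytes, non_lymphocytes, large_cells):
    * lymphocyte — predicted lymphocyte, area in the [60, 150] gate and
      probability >= 0.97;
    * non-lymphocyte — probability <= 0.1;
    * large cell — not predicted lymphocyte and area >= the third quartile
      of areas among cells larger than 200 px.
    Candidates between the cutoffs fall in a deliberate dead zone.
    """
    for c in candidates:
        if c.probability is None:
            raise CohortError("filter_lymphocytes: probabilities not computed")
    lo, hi = area_gate
    lymphocytes = [
        c for c in candidates
        if c.label == "lymphocyte" and lo <= c.area <= hi and c.probability >= prob_min
    ]
    non_lymphocytes = [c for c in candidates if c.probability <= nonlymph_prob_max]
    big = [c.area for c in candidates if c.area > LARGE_CELL_MIN_AREA]
    if big:
        q3 = float(np.quantile(big, 0.75))
        large_cells = [
            c for c in candidates if c.label != "lymphocyte" and c.area >= q3
        ]
    else:
        large_cells = []
    return lymphocytes, non_lymphocytes, large_cells


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def tile_process(
    image: np.ndarray,
    model: SVC | None = None,
    tile_size: int = TILE_SIZE,
    overlap: int = 64,
    **segment_kwargs,
) -> list[CellCandidate]:
    """Tile-wise segmentation (and classification when ``model`` given)
    with global coordinate reconstruction.

    Tiles are read with a small overlap so nuclei straddling a boundary
    are seen whole by at least one tile; a cell is kept only by the tile
    that owns its centroid (centroid inside the tile's core region),
    which resolves border duplicates.
    """
    h = image.shape[0]
    w = image.shape[1]
    candidates: list[CellCandidate] = []
    for top in range(0, h, tile_size):
        for left in range(0, w, tile_size):
            core_bottom = min(top + tile_size, h)
            core_right = min(left + tile_size, w)
            read_top = max(top - overlap, 0)
            read_left = max(left - overlap, 0)
            read_bottom = min(core_bottom + overlap, h)
            read_right = min(core_right + overlap, w)
            tile = image[read_top:read_bottom, read_left:read_right]
            found = segment_nuclei(tile, offset=(read_left, read_top), **segment_kwargs)
            owned = [
                c for c in found
                if left <= c.x < core_right and top <= c.y < core_bottom
            ]
            if model is not None and owned:
                # features must be computed on the tile (local coords)
                local = [
                    CellCandidate(x=c.x - read_left, y=c.y - read_top, area=c.area)
                    for c in owned
                ]
                extract_features(local, tile)
                for c, lc in zip(owned, local):
                    c.features = lc.features
                classify_candidates(owned, model)
            candidates.extend(owned)
    return candidates


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def tissue_area_pixels(image: np.ndarray) -> float:
    """Tissue pixels = pixels darker than the Otsu background-vs-tissue
    threshold of the grayscale image. A uniform image counts as all
    tissue when dark (< 0.9) and as no tissue otherwise."""
    gray = _to_gray(image)
    if np.allclose(gray.max(), gray.min()):
        return float(gray.size) if gray.mean() < 0.9 else 0.0
    threshold = threshold_otsu(gray)
    return float((gray < threshold).sum())


def compute_density(
    lymphocyte_count: int,
    image: np.ndarray,
    um_per_px: float = DEFAULT_UM_PER_PX,
    large_cell_count: int = 0,
    tissue_px: float | None = None,
) -> TILQuantification:
    """TIL density = lymphocyte count / tissue area (cells per mm^2)."""
    if tissue_px is None:
        tissue_px = tissue_area_pixels(image)
    if tissue_px <= 0:
        raise CohortError("compute_density: zero tissue area")
    area_mm2 = tissue_px * (um_per_px**2) / 1e6
    return TILQuantification(
        lymphocyte_count=int(lymphocyte_count),
        large_cell_count=int(large_cell_count),
        tissue_area_px=float(tissue_px),
        tissue_area_mm2=float(area_mm2),
        density_per_mm2=float(lymphocyte_count / area_mm2),
        um_per_px=float(um_per_px),
    )


# ---------------------------------------------------------------------------
# truth matching (synthetic training sets)
# ---------------------------------------------------------------------------

def label_candidates_from_truth(
    candidates: list[CellCandidate], truth: pd.DataFrame, max_dist: float = 8.0
) -> list[str]:
    """Label candidates by nearest planted cell (for training on synthetic
    images). Candidates with no truth record within ``max_dist`` pixels
    are labeled ``"other"``."""
    if truth.empty:
        return ["other"] * len(candidates)
    tx = truth["x"].to_numpy()
    ty = truth["y"].to_numpy()
    types = truth["cell_type"].to_numpy()
    labels = []
    for c in candidates:
        d2 = (tx - c.x) ** 2 + (ty - c.y) ** 2
        j = int(np.argmin(d2))
        if d2[j] <= max_dist**2:
            labels.append("lymphocyte" if types[j] == "lymphocyte" else "other")
        else:
            labels.append("other")
    return labels
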