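"""Nuclear-image quantification: integrated intensity and co-occurrence texture.

* Integrated intensity is the paper-style per-nucleus statistic: total
  in-mask fluorescence divided by the number of in-mask voxels (an in-mask
  mean, in arbitrary units per voxel).
* Texture of punctate FISH signal is summarized by gray-level co-occurrence
  (GLCM) descriptors; in-mask intensities are rescaled to 32 gray levels,
  distance-1 offsets in 4 directions (2D) are accumulated, symmetrized and
  normalized, and Haralick entropy (-sum p log2 p, in bits) is reported
  alongside contrast, homogeneity and energy.
* Group comparisons are Welch t-tests gated by a Shapiro-Wilk normality
  check; categorical phenotype proportions use a Pearson chi-square without
  continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_LEVELS = 32
#: distance-1 2D offsets: E, S, SE, SW (symmetrization adds the reverses)
DEFAULT_OFFSETS_2D = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class NucleusImage:
    """Masked intensity array (2D or 3D) with acquisition metadata."""

    intensities: np.ndarray
    mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensities.shape != self.mask.shape:
            raise ValueError("intensity and mask shapes differ")
        if not self.mask.any():
            raise ValueError("empty mask")

    @classmethod
    def from_tiff(
        cls, image_path: str | Path, mask_path: str | Path | None = None, **metadata
    ) -> "NucleusImage":
        """Load a (multi-page) TIFF; without a mask file, fall back to Otsu."""
        import tifffile

        img = np.asarray(tifffile.imread(str(image_path)), dtype=float)
        if mask_path is not None:
            mask = np.asarray(tifffile.imread(str(mask_path))) > 0
        else:
            from skimage.filters import threshold_otsu

            warnings.warn(
                f"no mask for {image_path}; using Otsu-threshold fallback",
                stacklevel=2,
            )
            mask = img > threshold_otsu(img)
        return cls(img, mask, metadata)


def integrated_intensity(image: NucleusImage) -> float:
    """In-mask intensity sum divided by in-mask voxel count."""
    voxels = image.mask.sum()
    return float(image.intensities[image.mask].sum() / voxels)


def group_fold_change(values_mutant, values_control) -> tuple[float, float]:
    """(mean(mutant)/mean(control), two-sided Welch t-test p)."""
    a = np.asarray(values_mutant, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    ratio = a.mean() / b.mean()
    t = stats.ttest_ind(a, b, equal_var=False)
    p = 1.0 if np.isnan(t.pvalue) else float(t.pvalue)
    return float(ratio), p


# -- gray-level co-occurrence -------------------------------------------------


@dataclass
class GLCMatrix:
    """Normalized symmetric gray-level co-occurrence matrix."""

    levels: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.levels, self.levels):
            raise ValueError("matrix shape must be levels x levels")
        if (self.matrix < 0).any():
            raise ValueError("negative co-occurrence mass")
        if not np.isclose(self.matrix.sum(), 1.0):
            raise ValueError("matrix must be normalized to sum 1")


def quantize_levels(image: NucleusImage, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Min-max rescale in-mask intensities to integer gray levels [0, levels)."""
    vals = image.intensities[image.mask]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(image.intensities.shape, dtype=np.intp)
    if hi > lo:
        scaled = (image.intensities - lo) / (hi - lo)
        q = np.clip((scaled * levels).astype(np.intp), 0, levels - 1)
    return q


def _accumulate_2d(
    q: np.ndarray, mask: np.ndarray, levels: int, offsets
) -> np.ndarray:
    acc = np.zeros((levels, levels), dtype=float)
    n_pairs = 0
    for dr, dc in offsets:
        r0 = max(0, -dr)
        r1 = q.shape[0] - max(0, dr)
        c0 = max(0, -dc)
        c1 = q.shape[1] - max(0, dc)
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        m = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ai, bi = a[m], b[m]
        np.add.at(acc, (ai, bi), 1.0)
        np.add.at(acc, (bi, ai), 1.0)  # symmetric
        n_pairs += 2 * ai.size
    if n_pairs == 0:
        raise ValueError("mask has no in-mask neighboring pixel pairs")
    return acc


def compute_glcm(
    image: NucleusImage,
    levels: int = DEFAULT_LEVELS,
    offsets=DEFAULT_OFFSETS_2D,
) -> GLCMatrix:
    """Masked, symmetrized, offset-averaged co-occurrence matrix.

    Only pixel pairs with BOTH ends inside the mask are counted. 3D stacks
    are handled per z-slice with 2D offsets (offsets across anisotropic z
    are ill-defined), accumulating over slices.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = quantize_levels(image, levels)
    if q.ndim == 2:
        acc = _accumulate_2d(q, image.mask, levels, offsets)
    elif q.ndim == 3:
        acc = np.zeros((levels, levels), dtype=float)
        any_pairs = False
        for z in range(q.shape[0]):
            if image.mask[z].sum() < 2:
                continue
            try:
                acc += _accumulate_2d(q[z], image.mask[z], levels, offsets)
                any_pairs = True
            except ValueError:
                continue
        if not any_pairs:
            raise ValueError("no in-mask neighboring pixel pairs in any slice")
    else:
        raise ValueError("only 2D images or 3D stacks are supported")
    return GLCMatrix(levels, acc / acc.sum())


def haralick_entropy(glcm: GLCMatrix) -> float:
    """Haralick entropy -sum p log2 p in bits (0 log 0 = 0)."""
    p = glcm.matrix[glcm.matrix > 0]
    return float(-(p * np.log2(p)).sum())


def haralick_features(glcm: GLCMatrix) -> dict:
    """Core Haralick descriptor set: entropy, contrast, homogeneity, energy."""
    i, j = np.indices(glcm.matrix.shape)
    p = glcm.matrix
    return {
        "entropy": haralick_entropy(glcm),
        "contrast": float((p * (i - j) ** 2).sum()),
        "homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "energy": float((p**2).sum()),
    }


def intensity_scatter(nuclei) -> pd.DataFrame:
    """Per-nucleus in-mask (mean, max) intensity — the FISH scatter coordinates."""
    rows = []
    for k, nuc in enumerate(nuclei):
        vals = nuc.intensities[nuc.mask]
        rows.append(
            {
                "nucleus": nuc.metadata.get("embryo_id", k)
                if hasattr(nuc, "metadata")
                else k,
                "mean_intensity": float(vals.mean()),
                "max_intensity": float(vals.max()),
            }
        )
    return pd.DataFrame(rows).set_index("nucleus")


# -- group statistics ---------------------------------------------------------


@dataclass
class GroupComparison:
    normal_a: bool
    normal_b: bool
    shapiro_p_a: float
    shapiro_p_b: float
    t_statistic: float
    p_value: float

    @property
    def normality_ok(self) -> bool:
        return self.normal_a and self.normal_b


def compare_groups(values_a, values_b, normality_alpha: float = 0.05) -> GroupComparison:
    """Welch t-test with a Shapiro-Wilk normality gate per group.

    Non-normal data is flagged (the t-test is still reported).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 values per group")
    sw_a = stats.shapiro(a).pvalue if np.ptp(a) > 0 else 1.0
    sw_b = stats.shapiro(b).pvalue if np.ptp(b) > 0 else 1.0
    t = stats.ttest_ind(a, b, equal_var=False)
    p = 1.0 if np.isnan(t.pvalue) else float(t.pvalue)
    stat = 0.0 if np.isnan(t.statistic) else float(t.statistic)
    return GroupComparison(
        normal_a=sw_a >= normality_alpha,
        normal_b=sw_b >= normality_alpha,
        shapiro_p_a=float(sw_a),
        shapiro_p_b=float(sw_b),
        t_statistic=stat,
        p_value=p,
    )


def proportion_test(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("both margins must be positive")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def summarize_proportion(successes: int, trials: int) -> int:
    """Integer percent (half away from zero), e.g. 39/206 -> 19."""
    if trials <= 0:
        raise ValueError("trials must be > 0")
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    from mztkit.waves import round_half_away

    return round_half_away(100.0 * successes / trials)
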