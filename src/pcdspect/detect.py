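"""Task-based low-contrast detectability with an EFROC matched-filter observer.

The observer is a unit-sum binary disk template matched to the known signal
radius; convolving it with a decomposed material map yields, at every pixel,
the local mean over the disk (computed by FFT convolution).  Detection is
unknown-location: the true-positive score of a signal-present image is the
maximum response inside an acceptance region around the known target center,
and false-positive marks are strict 8-neighborhood local maxima of the
signal-absent response that exceed a high percentile of the in-mask response
distribution, searched over (i) a uniform background region and (ii) the
region containing the thick non-target inserts.

Detectability is summarized by the area under the exponentially transformed
free-response ROC curve,

    A_FE = (1/I) sum_i exp(-(1/N) sum_j H(y_j - x_i)),

with H the Heaviside step (1/2 at ties), x the TP scores, y the pooled FP
scores, and N the number of signal-absent images; its standard error uses
the Hanley–McNeil AUC variance with Q1 = A/(2-A), Q2 = 2A^2/(1+A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .decomp import DecompModel, decompose, to_features
from .detector import (DetectorConfig, DRFMatrix, SharingKernel,
                       ThresholdConfig, apply_sharing, expected_bin_counts,
                       fit_sharing_kernel, rebin, sample_poisson)
from .phantom import PhantomBundle, build_lcd_phantom, remove_insert
from .physics import Spectrum

DEFAULT_ACCEPTANCE_RADIUS_MM = 4.0  # 2x the 2 mm signal radius
DEFAULT_FP_PERCENTILE = 95.0


@dataclass(frozen=True)
class DiskTemplate:
    """Binary disk of given radius at a pixel pitch, normalized to unit sum."""

    radius: float  # mm
    pitch: float   # mm per pixel

    @property
    def weights(self) -> np.ndarray:
        n = int(np.ceil(self.radius / self.pitch))
        coords = (np.arange(-n, n + 1)) * self.pitch
        mask = coords[None, :] ** 2 + coords[:, None] ** 2 <= self.radius ** 2
        if not mask.any():
            raise ValueError("template support is empty at this pitch")
        return mask / mask.sum()

    @property
    def support_size(self) -> int:
        return int(np.round(1.0 / self.weights.max()))


@dataclass
class ResponseMap:
    """Matched-filter response with a validity mask excluding the border band."""

    values: np.ndarray
    valid: np.ndarray
    pitch: float


@dataclass
class ScoreSet:
    tp: np.ndarray          # I true-positive scores
    fp: np.ndarray          # J pooled false-positive scores
    n_absent: int           # N signal-absent images

    def __post_init__(self) -> None:
        self.tp = np.atleast_1d(np.asarray(self.tp, dtype=float))
        self.fp = np.asarray(self.fp, dtype=float).ravel()
        if self.tp.size < 1 or self.n_absent < 1:
            raise ValueError("need at least one TP score and one absent image")
        if not (np.all(np.isfinite(self.tp)) and np.all(np.isfinite(self.fp))):
            raise ValueError("scores must be finite")


@dataclass
class EFROCResult:
    a_fe: float
    sigma: float
    n_tp: int
    n_fp: int
    n_absent: int
    sweep: dict = field(default_factory=dict)


def matched_filter(image: np.ndarray, template: DiskTemplate) -> ResponseMap:
    """Local disk mean at every pixel via FFT convolution.

    Pixels within one template radius of the image border are marked invalid.
    """
    w = template.weights
    if w.shape[0] > image.shape[0] or w.shape[1] > image.shape[1]:
        raise ValueError("template larger than image")
    resp = signal.fftconvolve(image, w, mode="same")
    band = int(np.ceil(template.radius / template.pitch))
    valid = np.zeros(image.shape, dtype=bool)
    valid[band:image.shape[0] - band, band:image.shape[1] - band] = True
    return ResponseMap(values=resp, valid=valid, pitch=template.pitch)


def tp_score(response: ResponseMap, target_center_mm: tuple[float, float],
             acceptance_radius_mm: float = DEFAULT_ACCEPTANCE_RADIUS_MM
             ) -> float:
    """Maximum response within the acceptance region around the known target."""
    ny, nx = response.values.shape
    x = (np.arange(nx) + 0.5) * response.pitch
    y = (np.arange(ny) + 0.5) * response.pitch
    cx, cy = target_center_mm
    region = ((x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2
              ) <= max(acceptance_radius_mm, response.pitch / 2) ** 2
    region &= response.valid
    if not region.any():
        raise ValueError("acceptance region has no valid pixels")
    return float(response.values[region].max())


def fp_scores(response: ResponseMap, search_masks: list[np.ndarray],
              percentile: float = DEFAULT_FP_PERCENTILE) -> np.ndarray:
    """Strict local maxima above the in-mask response percentile, pooled."""
    vals = response.values
    neigh = ndimage.maximum_filter(
        vals, footprint=np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], bool),
        mode="nearest")
    is_peak = vals > neigh
    scores = []
    for mask in search_masks:
        m = mask & response.valid
        if not m.any():
            raise ValueError("empty false-positive search mask")
        thresh = np.percentile(vals[m], percentile)
        sel = is_peak & m & (vals > thresh)
        scores.append(vals[sel])
    return np.concatenate(scores) if scores else np.empty(0)


def efroc_area(scores: ScoreSet) -> EFROCResult:
    """Nonparametric EFROC area estimate with Hanley–McNeil standard error."""
    x, y, n = scores.tp, scores.fp, scores.n_absent
    if y.size == 0:
        a = 1.0
    else:
        h = (y[None, :] > x[:, None]).astype(float) \
            + 0.5 * (y[None, :] == x[:, None])
        a = float(np.mean(np.exp(-h.sum(axis=1) / n)))
    sigma = hanley_mcneil_sigma(a, x.size, max(y.size, 1))
    return EFROCResult(a_fe=a, sigma=sigma, n_tp=x.size, n_fp=y.size,
                       n_absent=n)


def hanley_mcneil_sigma(auc: float, n_t: int, n_f: int) -> float:
    """Hanley–McNeil standard error of an AUC estimate."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if n_t < 1 or n_f < 1:
        raise ValueError("need at least one positive and one negative score")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1.0 - auc) + (n_t - 1) * (q1 - auc ** 2)
           + (n_f - 1) * (q2 - auc ** 2)) / (n_t * n_f)
    return float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# end-to-end task

def _search_masks(shape: tuple[int, int], pitch: float) -> list[np.ndarray]:
    """(i) uniform background region (left half), (ii) non-target insert region."""
    ny, nx = shape
    x = (np.arange(nx) + 0.5) * pitch
    y = (np.arange(ny) + 0.5) * pitch
    xx = np.broadcast_to(x[None, :], shape)
    yy = np.broadcast_to(y[:, None], shape)
    background = (xx >= 5) & (xx < 45) & (yy >= 5) & (yy < 95)
    nontarget = (xx >= 55) & (xx < 95) & (yy >= 5) & (yy < 95)
    return [background, nontarget]


def run_efroc_task(task: str, model: DecompModel, dose_mas: float,
                   spectrum: Spectrum, drf: DRFMatrix,
                   thresholds: ThresholdConfig,
                   detector_config: DetectorConfig = DetectorConfig(),
                   r: int = 10, seed_base: int = 0,
                   acceptance_radius_mm: float = DEFAULT_ACCEPTANCE_RADIUS_MM,
                   fp_percentile: float = DEFAULT_FP_PERCENTILE
                   ) -> EFROCResult:
    """EFROC area for one LCD task, model, and dose.

    R paired signal-present/absent acquisitions are simulated; each pair
    shares its Poisson seed so that score differences are signal-driven.
    Scoring runs on the decomposed map of the task's target material.
    """
    if task not in ("al_lcd", "pmma_lcd"):
        raise ValueError(f"unknown LCD task {task!r}")
    present = build_lcd_phantom(task)
    absent = remove_insert(present, present.signal_insert_index)
    target = present.signal_insert
    material = target.material

    kernel = fit_sharing_kernel(detector_config)
    mean_stacks = {}
    for name, bundle in (("present", present), ("absent", absent)):
        mean = expected_bin_counts(bundle.maps, spectrum, drf, thresholds,
                                   exposure_mas=dose_mas)
        mean_stacks[name] = apply_sharing(mean, kernel)

    template = DiskTemplate(radius=target.radius, pitch=1.0)
    tp = np.empty(r)
    fp_all = []
    for i in range(r):
        seed = seed_base + i
        maps = {}
        for name, mean in mean_stacks.items():
            macro = rebin(sample_poisson(mean, seed))
            feats = to_features(macro, macro)
            maps[name] = decompose(model, feats).material_map(material)
        resp_p = matched_filter(maps["present"], template)
        tp[i] = tp_score(resp_p, target.center_xy, acceptance_radius_mm)
        resp_a = matched_filter(maps["absent"], template)
        masks = _search_masks(resp_a.values.shape, resp_a.pitch)
        fp_all.append(fp_scores(resp_a, masks, fp_percentile))
    fp = np.concatenate(fp_all) if fp_all else np.empty(0)
    result = efroc_area(ScoreSet(tp=tp, fp=fp, n_absent=r))
    result.sweep = {"task": task, "model": model.kind, "dose_mAs": dose_mas,
                    "R": r, "seed_base": seed_base,
                    "acceptance_radius_mm": acceptance_radius_mm,
                    "fp_percentile": fp_percentile}
    return result
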