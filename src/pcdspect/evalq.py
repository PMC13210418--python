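"""Per-insert quantitative accuracy: ROI means, bias, and RMSE.

For each insert, the estimated thickness is the mean of the decomposed map
of the insert's material over a circular ROI shrunk by a margin (default
2 mm) to exclude boundary/partial-volume pixels.  Across N independent noise
realizations,

    bias  = mean_i(t_hat_i - t_true)              (signed, mm)
    RMSE  = sqrt(mean_i((t_hat_i - t_true)^2))    (mm)

so that RMSE^2 = bias^2 + var(t_hat) — the usual bias/variance split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import InsertSpec, PhantomBundle, ThicknessMaps

DEFAULT_ROI_MARGIN_MM = 2.0


@dataclass
class ROIMeasure:
    insert_id: int
    material: str
    t_true: float                 # mm
    estimates: np.ndarray         # per-realization ROI means, mm

    def __post_init__(self) -> None:
        self.estimates = np.atleast_1d(np.asarray(self.estimates, dtype=float))
        if self.estimates.size < 1:
            raise ValueError("at least one realization is required")

    @property
    def n(self) -> int:
        return self.estimates.size


@dataclass
class AccuracyRecord:
    insert_id: int
    material: str
    t_true: float
    bias: float
    rmse: float
    std: float
    n_realizations: int
    sweep: dict = field(default_factory=dict)


def roi_mean(maps: ThicknessMaps, insert: InsertSpec,
             margin: float = DEFAULT_ROI_MARGIN_MM) -> float:
    """Mean of the insert's material map over the margin-shrunk disk."""
    r = insert.radius - margin
    if r <= 0:
        raise ValueError("ROI margin leaves no interior pixels")
    x, y = maps.pixel_centers()
    cx, cy = insert.center_xy
    mask = ((x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2) <= r ** 2
    if not mask.any():
        raise ValueError("ROI contains no pixel centers")
    return float(maps.material_map(insert.material)[mask].mean())


def bias(measure: ROIMeasure) -> float:
    """Signed systematic error: mean(t_hat_i - t_true)."""
    return float(np.mean(measure.estimates - measure.t_true))


def rmse(measure: ROIMeasure) -> float:
    """Root of the mean squared deviation from the true thickness."""
    return float(np.sqrt(np.mean((measure.estimates - measure.t_true) ** 2)))


def measure_inserts(decomposed: list[ThicknessMaps], bundle: PhantomBundle,
                    margin: float = DEFAULT_ROI_MARGIN_MM,
                    sweep: dict | None = None) -> list[AccuracyRecord]:
    """Aggregate ROI statistics per insert across noise realizations.

    The true thickness is background plus the insert's delta in the insert's
    own material channel.
    """
    from .phantom import BACKGROUND_AL_MM, BACKGROUND_PMMA_MM

    records = []
    for idx, ins in enumerate(bundle.inserts):
        bg = BACKGROUND_AL_MM if ins.material == "Al" else BACKGROUND_PMMA_MM
        t_true = bg + ins.delta_thickness
        est = np.array([roi_mean(m, ins, margin) for m in decomposed])
        meas = ROIMeasure(insert_id=idx, material=ins.material,
                          t_true=t_true, estimates=est)
        records.append(AccuracyRecord(
            insert_id=idx, material=ins.material, t_true=t_true,
            bias=bias(meas), rmse=rmse(meas),
            std=float(np.std(est, ddof=0)), n_realizations=meas.n,
            sweep=dict(sweep or {})))
    return records
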