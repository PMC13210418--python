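"""Digital Al/PMMA slab phantoms with circular inserts.

Three phantoms are provided, all on a 0.1 mm micro-pixel grid:

* ``quant`` — a 150x150 mm LucAl-style plate (uniform 4.1 mm Al + 83 mm PMMA
  background) carrying ten r=12.5 mm disks: five add extra Al
  (0.5/1.0/1.5/2.0/2.5 mm) and five add extra PMMA (2/4/6/8/10 mm).  Used for
  per-insert bias/RMSE evaluation.
* ``al_lcd`` / ``pmma_lcd`` — 100x100 mm low-contrast-detectability phantoms
  with r=2.0 mm disks: one faint signal disk (0.1 mm of the target material)
  and four thick non-target disks of the opposing material (10 mm PMMA for
  the Al task, 2.5 mm Al for the PMMA task), on the same LucAl background.

Layouts are deterministic.  Coordinates are pixel centers, x rightward /
y downward, and a pixel belongs to a disk iff its center lies within the
radius (binary rasterization, no anti-aliasing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

BACKGROUND_AL_MM = 4.1
BACKGROUND_PMMA_MM = 83.0

QUANT_SIZE_MM = 150.0
LCD_SIZE_MM = 100.0
QUANT_INSERT_RADIUS_MM = 12.5
LCD_INSERT_RADIUS_MM = 2.0

AL_DELTAS_MM = (0.5, 1.0, 1.5, 2.0, 2.5)
PMMA_DELTAS_MM = (2.0, 4.0, 6.0, 8.0, 10.0)


@dataclass(frozen=True)
class InsertSpec:
    """One circular insert: where it sits and how much material it adds."""

    center_xy: tuple[float, float]  # mm
    radius: float                   # mm
    material: str                   # "Al" or "PMMA"
    delta_thickness: float          # mm added over the background

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("insert radius must be positive")
        if self.delta_thickness < 0:
            raise ValueError("delta thickness must be non-negative")
        if self.material not in ("Al", "PMMA"):
            raise ValueError("material must be 'Al' or 'PMMA'")


@dataclass
class ThicknessMaps:
    """Paired per-pixel Al and PMMA path-length images (mm)."""

    al_map: np.ndarray
    pmma_map: np.ndarray
    pitch: float  # mm per pixel; pixel (i, j) center at ((j+0.5)p, (i+0.5)p)

    def __post_init__(self) -> None:
        if self.al_map.shape != self.pmma_map.shape:
            raise ValueError("Al and PMMA maps must share a shape")
        if np.any(self.al_map < 0) or np.any(self.pmma_map < 0):
            raise ValueError("thicknesses must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.al_map.shape

    def material_map(self, material: str) -> np.ndarray:
        return self.al_map if material == "Al" else self.pmma_map

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates in mm as 1D arrays (columns, rows)."""
        ny, nx = self.shape
        x = (np.arange(nx) + 0.5) * self.pitch
        y = (np.arange(ny) + 0.5) * self.pitch
        return x, y

    def copy(self) -> "ThicknessMaps":
        return ThicknessMaps(self.al_map.copy(), self.pmma_map.copy(), self.pitch)


@dataclass
class PhantomBundle:
    maps: ThicknessMaps
    inserts: list[InsertSpec]
    phantom_kind: str  # "quant", "al_lcd", "pmma_lcd"
    signal_insert_index: int | None = None

    @property
    def signal_insert(self) -> InsertSpec:
        if self.signal_insert_index is None:
            raise ValueError("phantom has no designated signal insert")
        return self.inserts[self.signal_insert_index]


def _check_non_overlap(inserts: list[InsertSpec]) -> None:
    for i, a in enumerate(inserts):
        for b in inserts[i + 1:]:
            d = np.hypot(a.center_xy[0] - b.center_xy[0],
                         a.center_xy[1] - b.center_xy[1])
            # tangency is allowed: disk interiors must not intersect
            if d < a.radius + b.radius - 1e-9:
                raise ValueError("inserts overlap")


def _disk_mask(maps: ThicknessMaps, insert: InsertSpec) -> np.ndarray:
    x, y = maps.pixel_centers()
    cx, cy = insert.center_xy
    return ((x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2) <= insert.radius ** 2


def _stamp(maps: ThicknessMaps, insert: InsertSpec, sign: float = 1.0) -> None:
    mask = _disk_mask(maps, insert)
    maps.material_map(insert.material)[mask] += sign * insert.delta_thickness


def build_quant_phantom(pitch: float = 0.1) -> PhantomBundle:
    """Build the 150x150 mm quantitative-accuracy phantom.

    Layout: Al inserts in a row of five at y=50 mm, PMMA inserts at y=100 mm,
    both at x in {25, 50, 75, 100, 125} mm.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    n = QUANT_SIZE_MM / pitch
    if abs(n - round(n)) > 1e-9:
        raise ValueError("pitch must divide 150 mm evenly")
    n = int(round(n))
    maps = ThicknessMaps(
        al_map=np.full((n, n), BACKGROUND_AL_MM),
        pmma_map=np.full((n, n), BACKGROUND_PMMA_MM),
        pitch=pitch,
    )
    xs = (25.0, 50.0, 75.0, 100.0, 125.0)
    inserts = [InsertSpec((x, 50.0), QUANT_INSERT_RADIUS_MM, "Al", d)
               for x, d in zip(xs, AL_DELTAS_MM)]
    inserts += [InsertSpec((x, 100.0), QUANT_INSERT_RADIUS_MM, "PMMA", d)
                for x, d in zip(xs, PMMA_DELTAS_MM)]
    _check_non_overlap(inserts)
    for ins in inserts:
        _stamp(maps, ins)
    return PhantomBundle(maps=maps, inserts=inserts, phantom_kind="quant")


#: LCD layout: one signal disk on the left, four thick non-target disks on a
#: 2x2 grid in the right half; the remaining left half serves as the uniform
#: background false-positive search region.
LCD_SIGNAL_CENTER_MM = (25.0, 50.0)
LCD_NONTARGET_CENTERS_MM = ((65.0, 35.0), (85.0, 35.0), (65.0, 65.0), (85.0, 65.0))


def build_lcd_phantom(task: str, pitch: float = 0.1) -> PhantomBundle:
    """Build a low-contrast-detectability phantom for ``al_lcd`` or ``pmma_lcd``.

    Al task: the signal disk adds 0.1 mm Al, non-targets add 10.0 mm PMMA.
    PMMA task: the signal disk adds 0.1 mm PMMA, non-targets add 2.5 mm Al.
    """
    if task not in ("al_lcd", "pmma_lcd"):
        raise ValueError(f"unknown LCD task {task!r}")
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    n = LCD_SIZE_MM / pitch
    if abs(n - round(n)) > 1e-9:
        raise ValueError("pitch must divide 100 mm evenly")
    n = int(round(n))
    maps = ThicknessMaps(
        al_map=np.full((n, n), BACKGROUND_AL_MM),
        pmma_map=np.full((n, n), BACKGROUND_PMMA_MM),
        pitch=pitch,
    )
    if task == "al_lcd":
        signal = InsertSpec(LCD_SIGNAL_CENTER_MM, LCD_INSERT_RADIUS_MM, "Al", 0.1)
        nontargets = [InsertSpec(c, LCD_INSERT_RADIUS_MM, "PMMA", 10.0)
                      for c in LCD_NONTARGET_CENTERS_MM]
    else:
        signal = InsertSpec(LCD_SIGNAL_CENTER_MM, LCD_INSERT_RADIUS_MM, "PMMA", 0.1)
        nontargets = [InsertSpec(c, LCD_INSERT_RADIUS_MM, "Al", 2.5)
                      for c in LCD_NONTARGET_CENTERS_MM]
    inserts = [signal] + nontargets
    _check_non_overlap(inserts)
    for ins in inserts:
        _stamp(maps, ins)
    return PhantomBundle(maps=maps, inserts=inserts, phantom_kind=task,
                         signal_insert_index=0)


def remove_insert(bundle: PhantomBundle, index: int) -> PhantomBundle:
    """Return a new bundle with the indexed insert's material delta subtracted.

    All other pixels are bit-identical to the input; re-adding the insert
    recovers the original maps exactly.
    """
    if not 0 <= index < len(bundle.inserts):
        raise IndexError("insert index out of range")
    maps = bundle.maps.copy()
    _stamp(maps, bundle.inserts[index], sign=-1.0)
    inserts = [ins for i, ins in enumerate(bundle.inserts) if i != index]
    return PhantomBundle(maps=maps, inserts=inserts,
                         phantom_kind=bundle.phantom_kind,
                         signal_insert_index=None)


# ---------------------------------------------------------------------------
# serialization

def save_phantom(bundle: PhantomBundle, path: str) -> None:
    """Write the bundle to HDF5: two float maps plus a JSON insert registry."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("al_map", data=bundle.maps.al_map)
        fh.create_dataset("pmma_map", data=bundle.maps.pmma_map)
        fh.attrs["pitch_mm"] = bundle.maps.pitch
        fh.attrs["phantom_kind"] = bundle.phantom_kind
        fh.attrs["signal_insert_index"] = (
            -1 if bundle.signal_insert_index is None else bundle.signal_insert_index)
        fh.attrs["inserts_json"] = json.dumps([
            {"center_xy": list(ins.center_xy), "radius": ins.radius,
             "material": ins.material, "delta_mm": ins.delta_thickness}
            for ins in bundle.inserts])


def load_phantom(path: str) -> PhantomBundle:
    import h5py

    with h5py.File(path, "r") as fh:
        maps = ThicknessMaps(fh["al_map"][()], fh["pmma_map"][()],
                             float(fh.attrs["pitch_mm"]))
        inserts = [InsertSpec(tuple(d["center_xy"]), d["radius"], d["material"],
                              d["delta_mm"])
                   for d in json.loads(fh.attrs["inserts_json"])]
        sig = int(fh.attrs["signal_insert_index"])
        return PhantomBundle(maps=maps, inserts=inserts,
                             phantom_kind=str(fh.attrs["phantom_kind"]),
                             signal_insert_index=None if sig < 0 else sig)


def registry_to_csv(bundle: PhantomBundle, path: str) -> None:
    """Export the ground-truth insert registry as CSV."""
    import pandas as pd

    pd.DataFrame([
        {"center_x": ins.center_xy[0], "center_y": ins.center_xy[1],
         "radius": ins.radius, "material": ins.material,
         "delta_mm": ins.delta_thickness}
        for ins in bundle.inserts
    ]).to_csv(path, index=False)
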