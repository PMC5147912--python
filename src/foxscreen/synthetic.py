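"""Synthetic two-channel translocation plates with planted ground truth.

Emulates one imaged field of a well from a GFP-reporter translocation assay:
elliptical DAPI-stained nuclei, an annular cytoplasm around each nucleus, and
the cell's total GFP split between the two compartments so that the planted
mean-intensity nucleus/cytoplasm ratio is exact before noise. A camera noise
stage (constant background, Poisson shot noise, Gaussian read noise, clipping,
16-bit quantization) is applied last, so noise-free renders carry the pure
compartment signal.

Per-cell translocation state is Bernoulli with a well-level fraction; the
nucleus/cytoplasm ratio of each cell is then drawn from a log-normal whose
median depends on the state (resting ~ 1, translocated ~ 3 by default,
straddling the 1.8 classification cutoff with realistic overlap). A
four-parameter logistic dose model maps compound concentration to the
well-level translocated fraction, which is what makes full image -> EC50
recovery experiments possible with known truth.

Also hosts the synthetic MTT viability absorbance-table generator used for
IC50 recovery experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImagePair, PlateLayout, conc_to_uM

__all__ = [
    "NoiseSpec",
    "StateDistributions",
    "CellSpec",
    "WellSpec",
    "TranslocationDoseModel",
    "GroundTruth",
    "PlateGroundTruth",
    "PlacementError",
    "translocation_fraction_at",
    "render_well",
    "render_plate",
    "render_screen",
    "rasterize_cell",
    "simulate_mtt_table",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping cell placement fails (field too dense)."""


@dataclass(frozen=True)
class NoiseSpec:
    """Camera/stain noise model: background offset, shot noise, read noise.

    All intensities are arbitrary fluorescence units mapped to a 16-bit
    camera; ``NoiseSpec.off()`` gives a clean render (quantization only).
    """

    background_level: float = 100.0
    read_noise_sd: float = 3.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")

    @classmethod
    def off(cls) -> "NoiseSpec":
        return cls(background_level=0.0, read_noise_sd=0.0, shot_noise=False)


@dataclass(frozen=True)
class StateDistributions:
    """Per-state log-normal N/C ratio distributions.

    Medians straddle the 1.8 classification threshold; sd_log 0.2 gives the
    two states ~5.5 log-sd of separation, i.e. a small but non-zero overlap.
    """

    median_resting: float = 1.0
    median_translocated: float = 3.0
    sd_log: float = 0.2

    def sample(self, translocated: bool, rng: np.random.Generator) -> float:
        med = self.median_translocated if translocated else self.median_resting
        return float(med * np.exp(rng.normal(0.0, self.sd_log)))


DEFAULT_STATES = StateDistributions()


@dataclass(frozen=True)
class CellSpec:
    """Planted state of one rendered cell (the per-cell ground truth)."""

    center: tuple[float, float]  # (row, col), px
    nucleus_axes: tuple[float, float]  # semi-axes (a, b), px
    orientation: float  # radians
    dapi_level: float  # a.u.
    gfp_total: float  # a.u., conserved across both compartments
    nc_ratio_true: float
    translocated: bool

    def __post_init__(self) -> None:
        if min(self.nucleus_axes) < 3:
            raise ValueError("nucleus semi-axes must be >= 3 px")
        if self.gfp_total <= 0:
            raise ValueError("gfp_total must be > 0")
        if self.nc_ratio_true <= 0:
            raise ValueError("nc_ratio_true must be > 0")
        if self.dapi_level < 0:
            raise ValueError("dapi_level must be >= 0")


@dataclass(frozen=True)
class WellSpec:
    """Parameters for rendering one field of a well."""

    n_cells: int = 150
    image_shape: tuple[int, int] = (560, 560)
    translocation_fraction: float = 0.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0.0 <= self.translocation_fraction <= 1.0):
            raise ValueError("translocation_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TranslocationDoseModel:
    """4PL mapping compound concentration (uM) -> well translocated fraction."""

    bottom_fraction: float = 0.05
    top_fraction: float = 0.95
    ec50: float = 1.5  # uM
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.bottom_fraction < self.top_fraction <= 1.0):
            raise ValueError("need 0 <= bottom_fraction < top_fraction <= 1")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")

    def fraction_at(self, conc_uM: float) -> float:
        return translocation_fraction_at(self, conc_uM)


def translocation_fraction_at(model: TranslocationDoseModel, conc: float) -> float:
    """Translocated fraction at a concentration (same unit as ``model.ec50``).

    ``bottom + (top - bottom) / (1 + (ec50/conc)^hill)``; the zero-dose limit
    is the bottom fraction.
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if conc == 0:
        return model.bottom_fraction
    span = model.top_fraction - model.bottom_fraction
    with np.errstate(over="ignore"):
        t = np.float64(model.ec50 / conc) ** np.float64(model.hill)  # inf at conc -> 0 is fine
    return float(model.bottom_fraction + span / (1.0 + t))


@dataclass
class GroundTruth:
    """Everything planted into one rendered well."""

    cells: list[CellSpec]
    spec: WellSpec
    cyt_thickness: int = 6

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def n_translocated(self) -> int:
        return sum(c.translocated for c in self.cells)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "row": c.center[0],
                "col": c.center[1],
                "axis_a": c.nucleus_axes[0],
                "axis_b": c.nucleus_axes[1],
                "orientation": c.orientation,
                "dapi_level": c.dapi_level,
                "gfp_total": c.gfp_total,
                "nc_ratio_true": c.nc_ratio_true,
                "translocated": c.translocated,
            }
            for c in self.cells
        ]
        return pd.DataFrame(rows)


@dataclass
class PlateGroundTruth:
    """Per-well ground truths plus the plate-level generative model."""

    wells: dict[str, GroundTruth]
    layout: PlateLayout
    model: TranslocationDoseModel | None = None
    planted_fractions: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for well, gt in self.wells.items():
            df = gt.to_frame()
            df.insert(0, "well", well)
            frames.append(df)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------- rendering


def _disk_structure(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.ogrid[-r : r + 1, -r : r + 1]
    return x * x + y * y <= r * r


def _cell_patch(
    cell: CellSpec, shape: tuple[int, int], cyt_thickness: int
) -> tuple[tuple[slice, slice], np.ndarray, np.ndarray]:
    """Nucleus/cytoplasm masks on a local patch around the cell."""
    half = int(np.ceil(max(cell.nucleus_axes) + cyt_thickness)) + 2
    r0 = max(int(np.floor(cell.center[0])) - half, 0)
    c0 = max(int(np.floor(cell.center[1])) - half, 0)
    r1 = min(int(np.ceil(cell.center[0])) + half + 1, shape[0])
    c1 = min(int(np.ceil(cell.center[1])) + half + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - cell.center[0]
    dc = cc - cell.center[1]
    ct, st = np.cos(cell.orientation), np.sin(cell.orientation)
    u = (dr * ct + dc * st) / cell.nucleus_axes[0]
    v = (-dr * st + dc * ct) / cell.nucleus_axes[1]
    nuc_patch = u * u + v * v <= 1.0
    dil_patch = ndimage.binary_dilation(nuc_patch, structure=_disk_structure(cyt_thickness))
    return (slice(r0, r1), slice(c0, c1)), nuc_patch, dil_patch & ~nuc_patch


def rasterize_cell(
    cell: CellSpec, shape: tuple[int, int], cyt_thickness: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Planted nucleus and cytoplasm masks for one cell on the full image.

    The cytoplasm is the annulus obtained by dilating the nucleus ellipse with
    a Euclidean disk of the given thickness. Used both by the renderer and as
    the planted-truth oracle in tests.
    """
    window, nuc_patch, cyt_patch = _cell_patch(cell, shape, cyt_thickness)
    nucleus = np.zeros(shape, dtype=bool)
    cyt = np.zeros(shape, dtype=bool)
    nucleus[window] = nuc_patch
    cyt[window] = cyt_patch
    return nucleus, cyt


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_sep: float,
    margin: float,
    max_tries_per_cell: int = 400,
) -> np.ndarray:
    """Hard-core rejection sampling of cell centers."""
    if n == 0:
        return np.empty((0, 2))
    lo = (margin, margin)
    hi = (shape[0] - margin, shape[1] - margin)
    if hi[0] <= lo[0] or hi[1] <= lo[1]:
        raise PlacementError(f"image {shape} too small for margin {margin}")
    centers = np.empty((n, 2))
    placed = 0
    sep2 = min_sep * min_sep
    for i in range(n):
        for _ in range(max_tries_per_cell):
            cand = rng.uniform(lo, hi)
            if placed == 0:
                break
            d2 = np.sum((centers[:placed] - cand) ** 2, axis=1)
            if d2.min() >= sep2:
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{n} after {max_tries_per_cell} tries: "
                f"field of {shape} is beyond the non-overlap density limit "
                f"(min separation {min_sep:.0f} px)"
            )
        centers[placed] = cand
        placed += 1
    return centers


def _apply_noise(signal: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Background + shot + read noise, clip at 0, quantize to 16-bit."""
    expected = signal + noise.background_level
    if noise.shot_noise:
        out = rng.poisson(expected).astype(np.float64)
    else:
        out = expected.astype(np.float64)
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd, size=out.shape)
    out = np.clip(np.rint(out), 0, 65535)
    return out.astype(np.uint16)


# defaults for the per-cell draws; semi-axes of 5-8 px correspond to a
# 10-16 px nuclear diameter at low magnification
_AXIS_RANGE = (5.0, 8.0)
_DAPI_LEVEL = 3000.0
_GFP_TOTAL = 2.0e5


def _draw_cells(
    rng: np.random.Generator,
    spec: WellSpec,
    states: StateDistributions,
    cyt_thickness: int,
) -> list[CellSpec]:
    max_r = _AXIS_RANGE[1] + cyt_thickness
    min_sep = 2 * max_r + 2  # planted cytoplasm annuli never touch
    margin = max_r + 2
    centers = _place_centers(rng, spec.n_cells, spec.image_shape, min_sep, margin)
    cells = []
    for i in range(spec.n_cells):
        axes = tuple(rng.uniform(*_AXIS_RANGE, size=2))
        orientation = float(rng.uniform(0.0, np.pi))
        dapi = float(_DAPI_LEVEL * rng.uniform(0.85, 1.15))
        gfp_total = float(_GFP_TOTAL * np.exp(rng.normal(0.0, 0.15)))
        translocated = bool(rng.random() < spec.translocation_fraction)
        ratio = states.sample(translocated, rng)
        cells.append(
            CellSpec(
                center=(float(centers[i, 0]), float(centers[i, 1])),
                nucleus_axes=(float(axes[0]), float(axes[1])),
                orientation=orientation,
                dapi_level=dapi,
                gfp_total=gfp_total,
                nc_ratio_true=ratio,
                translocated=translocated,
            )
        )
    return cells


def render_well(
    spec: WellSpec,
    states: StateDistributions = DEFAULT_STATES,
    cyt_thickness: int = 6,
) -> tuple[ImagePair, GroundTruth]:
    """Render one field: DAPI nuclei + GFP split across compartments.

    For each cell the GFP pixel values are chosen so that, on the planted
    masks and before noise, mean(nucleus)/mean(cytoplasm) equals the cell's
    ``nc_ratio_true`` exactly and the summed GFP equals ``gfp_total``.
    Identical (spec, states) give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    cells = _draw_cells(rng, spec, states, cyt_thickness)

    dapi = np.zeros(spec.image_shape, dtype=np.float64)
    gfp = np.zeros(spec.image_shape, dtype=np.float64)
    for cell in cells:
        window, nuc, cyt = _cell_patch(cell, spec.image_shape, cyt_thickness)
        n_n = int(nuc.sum())
        n_c = int(cyt.sum())
        if n_n == 0 or n_c == 0:  # pragma: no cover - axes >= 3 guarantees both
            raise RuntimeError("degenerate cell rasterization")
        r = cell.nc_ratio_true
        cyt_val = cell.gfp_total / (r * n_n + n_c)
        dapi[window][nuc] += cell.dapi_level
        gfp_patch = gfp[window]
        gfp_patch[nuc] += r * cyt_val
        gfp_patch[cyt] += cyt_val

    pair = ImagePair(_apply_noise(dapi, spec.noise, rng), _apply_noise(gfp, spec.noise, rng))
    return pair, GroundTruth(cells=cells, spec=spec, cyt_thickness=cyt_thickness)


def _well_seed(plate_seed: int, well: str) -> int:
    """Deterministic per-well seed from (plate seed, well id)."""
    ss = np.random.SeedSequence([int(plate_seed), *well.encode("ascii")])
    return int(ss.generate_state(1)[0] % (2**31))


def _render_wells(
    layout: PlateLayout,
    fractions: Mapping[str, float],
    base_spec: WellSpec,
    seed: int,
    states: StateDistributions,
    cyt_thickness: int,
) -> tuple[dict[str, ImagePair], dict[str, GroundTruth]]:
    pairs: dict[str, ImagePair] = {}
    truths: dict[str, GroundTruth] = {}
    for entry in layout.entries():
        if entry.role == "empty":
            continue
        if entry.well not in fractions:
            raise ValueError(f"no translocation fraction for well {entry.well}")
        spec = dataclasses.replace(
            base_spec,
            translocation_fraction=float(fractions[entry.well]),
            n_cells=0 if entry.role == "blank" else base_spec.n_cells,
            seed=_well_seed(seed, entry.well),
        )
        pairs[entry.well], truths[entry.well] = render_well(spec, states, cyt_thickness)
    return pairs, truths


def render_plate(
    layout: PlateLayout,
    model: TranslocationDoseModel,
    base_spec: WellSpec,
    seed: int,
    states: StateDistributions = DEFAULT_STATES,
    cyt_thickness: int = 6,
) -> tuple[dict[str, ImagePair], PlateGroundTruth]:
    """Render a plate: negatives at the model bottom fraction, positives at
    the top fraction, compound wells per the dose model (concentrations are
    converted to uM, the unit of ``model.ec50``)."""
    fractions: dict[str, float] = {}
    for entry in layout.entries():
        if entry.role == "negative":
            fractions[entry.well] = model.bottom_fraction
        elif entry.role == "positive":
            fractions[entry.well] = model.top_fraction
        elif entry.role == "compound":
            fractions[entry.well] = model.fraction_at(conc_to_uM(entry.conc, entry.conc_unit))
        elif entry.role == "blank":
            fractions[entry.well] = 0.0
        elif entry.role == "empty":
            continue
        else:  # pragma: no cover - PlateLayout already validates roles
            raise ValueError(f"unknown well role {entry.role!r}")
    pairs, truths = _render_wells(layout, fractions, base_spec, seed, states, cyt_thickness)
    return pairs, PlateGroundTruth(truths, layout, model=model, planted_fractions=fractions)


def render_screen(
    layout: PlateLayout,
    activities: Mapping[str, float],
    base_spec: WellSpec,
    seed: int,
    bottom_fraction: float = 0.05,
    top_fraction: float = 0.95,
    states: StateDistributions = DEFAULT_STATES,
    cyt_thickness: int = 6,
) -> tuple[dict[str, ImagePair], PlateGroundTruth]:
    """Render a single-dose screening plate with planted per-compound activity.

    ``activities`` maps compound id -> activity on the 0..1 scale relative to
    the control window; a compound well's translocated fraction is
    ``bottom + activity * (top - bottom)``.
    """
    span = top_fraction - bottom_fraction
    fractions: dict[str, float] = {}
    for entry in layout.entries():
        if entry.role == "negative":
            fractions[entry.well] = bottom_fraction
        elif entry.role == "positive":
            fractions[entry.well] = top_fraction
        elif entry.role == "compound":
            act = float(activities[entry.compound])
            fractions[entry.well] = float(np.clip(bottom_fraction + act * span, 0.0, 1.0))
        elif entry.role == "blank":
            fractions[entry.well] = 0.0
    pairs, truths = _render_wells(layout, fractions, base_spec, seed, states, cyt_thickness)
    return pairs, PlateGroundTruth(truths, layout, planted_fractions=fractions)


# ----------------------------------------------------------- MTT viability


def simulate_mtt_table(
    ic50: float,
    concentrations: np.ndarray | list[float],
    conc_unit: str = "uM",
    hill: float = 1.0,
    replicates: int = 3,
    vehicle_absorbance: float = 1.0,
    blank_absorbance: float = 0.08,
    noise_frac: float = 0.05,
    n_vehicle: int = 6,
    n_blank: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic MTT absorbance table (570 nm reads) for IC50 recovery runs.

    Viability follows a decreasing 4PL (100% -> 0%) with the given midpoint;
    absorbance is blank + viability * (vehicle - blank) plus Gaussian noise
    with sd ``noise_frac`` of the vehicle signal. Columns: well, role,
    compound, conc, conc_unit, absorbance.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    rng = np.random.default_rng(seed)
    concs = np.asarray(list(concentrations), dtype=float)
    sd = noise_frac * vehicle_absorbance
    window = vehicle_absorbance - blank_absorbance
    rows = []
    w = 0

    def _add(role, compound, conc, absorbance):
        nonlocal w
        rows.append(
            {
                "well": f"W{w:03d}",
                "role": role,
                "compound": compound,
                "conc": conc,
                "conc_unit": conc_unit if conc is not None else None,
                "absorbance": float(max(absorbance, 0.0)),
            }
        )
        w += 1

    for _ in range(n_vehicle):
        _add("vehicle", None, None, vehicle_absorbance + rng.normal(0.0, sd))
    for _ in range(n_blank):
        _add("blank", None, None, blank_absorbance + rng.normal(0.0, sd))
    for conc in concs:
        viability = 1.0 - 1.0 / (1.0 + (ic50 / conc) ** hill)
        for _ in range(replicates):
            a = blank_absorbance + viability * window + rng.normal(0.0, sd)
            _add("treated", "cpd", float(conc), a)
    return pd.DataFrame(rows)
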