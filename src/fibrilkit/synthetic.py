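"""Synthetic ThT traces, AFM fibril fields, and amide-I spectra with ground truth.

Every generator is a deterministic function of its spec (which carries the
seed), so generate-then-analyze round trips are reproducible and every
pipeline stage can be validated against known truth without instrument data.

Noise is additive Gaussian throughout, with magnitudes expressed relative to
the signal scale (fraction of sigmoid amplitude for kinetics, nm for AFM
pixel noise, fraction of peak absorbance for spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .afm import DEFAULT_PIXEL_SIZE_NM, HeightMap
from .errors import ValidationError
from .ftir import AMIDE_I_WINDOW, BandAssignment, Spectrum
from .kinetics import KineticTrace, boltzmann_model

__all__ = [
    "KineticsSpec",
    "FibrilFieldSpec",
    "SpectrumSpec",
    "SyntheticField",
    "make_kinetics",
    "make_fibril_field",
    "make_spectrum",
    "kinetics_spec_from_reference",
    "spectrum_spec_from_reference",
]


def _default_time_grid() -> np.ndarray:
    # 0-200 min at 2-min sampling covers lag times of ~17-67 min and
    # half-times of ~20-80 min with both plateaus well resolved
    return np.arange(0.0, 201.0, 2.0)


@dataclass(frozen=True)
class KineticsSpec:
    """Ground truth for a set of replicate ThT traces.

    ``noise_sd`` is the Gaussian noise standard deviation as a fraction of
    the sigmoid amplitude ``|y2 - y1|``.
    """

    y1: float = 0.0
    y2: float = 1.0
    t_lag: float = 66.93
    t_half: float = 79.42
    noise_sd: float = 0.02
    time_grid: np.ndarray = field(default_factory=_default_time_grid)
    n_replicates: int = 3
    seed: int = 0
    condition: str = "control"

    def __post_init__(self) -> None:
        if not self.t_half > self.t_lag > 0:
            raise ValidationError("require t_half > t_lag > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValidationError("need at least one replicate")


@dataclass(frozen=True)
class FibrilFieldSpec:
    """Ground truth for one synthetic AFM fibril field.

    Objects are flat-topped rods (cylinder projections) with anti-aliased
    edges.  With probability ``association_prob`` a fibril gets a parallel
    partner laid alongside with partial overlap (heights add where they
    overlap, emulating lateral association); with probability
    ``cluster_prob`` it is replaced by a dense bundle of overlapping rods
    (emulating large fibril clusters).  Distinct objects never touch, so the
    generator's per-object truth table matches what segmentation sees.

    Defaults emulate a 5 um, 1024 x 1024 px scan of needle-like insulin
    fibrils (widths 15-30 nm, heights 4-12 nm).
    """

    size_px: int = 1024
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM
    n_fibrils: int = 120
    length_range_nm: tuple[float, float] = (100.0, 600.0)
    width_range_nm: tuple[float, float] = (15.0, 30.0)
    height_range_nm: tuple[float, float] = (4.0, 12.0)
    association_prob: float = 0.2
    cluster_prob: float = 0.05
    noise_sd_nm: float = 0.3
    seed: int = 0
    source_id: str = "synthetic"

    def __post_init__(self) -> None:
        for name in ("length_range_nm", "width_range_nm", "height_range_nm"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValidationError(f"{name} must be positive and ordered")
        for name in ("association_prob", "cluster_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.noise_sd_nm < 0:
            raise ValidationError("noise_sd_nm must be nonnegative")
        if self.size_px < 16:
            raise ValidationError("field must be at least 16 px")


def _default_band_centers() -> dict[str, float]:
    return {
        "random_helix": 1652.0,
        "beta_sheet": 1628.0,
        "beta_turn": 1672.0,
        "side_chain": 1612.0,
    }


def _default_band_sigmas() -> dict[str, float]:
    return {
        "random_helix": 7.0,
        "beta_sheet": 7.0,
        "beta_turn": 7.0,
        "side_chain": 5.0,
    }


@dataclass(frozen=True)
class SpectrumSpec:
    """Ground truth for one synthetic amide-I spectrum.

    ``fractions`` are the per-class area fractions (summing to 1) of one
    Gaussian band per secondary-structure class; ``noise_sd`` is a fraction
    of the peak absorbance; ``baseline_slope`` adds a linear drift in
    absorbance units per cm^-1.
    """

    fractions: dict[str, float] = field(
        default_factory=lambda: {
            "random_helix": 0.525,
            "beta_sheet": 0.191,
            "beta_turn": 0.239,
            "side_chain": 0.045,
        }
    )
    centers: dict[str, float] = field(default_factory=_default_band_centers)
    sigmas: dict[str, float] = field(default_factory=_default_band_sigmas)
    baseline_slope: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.fractions.values()):
            raise ValidationError("fractions must be nonnegative")
        assignment = BandAssignment()
        for cls, center in self.centers.items():
            if assignment.classify(center) != cls:
                raise ValidationError(
                    f"center {center} cm^-1 lies outside the {cls} interval"
                )
        if any(s <= 0 for s in self.sigmas.values()):
            raise ValidationError("sigmas must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")


def make_kinetics(spec: KineticsSpec) -> list[KineticTrace]:
    """Replicate ThT traces: the Boltzmann sigmoid plus seeded Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.time_grid, dtype=float)
    clean = boltzmann_model(t, spec.y1, spec.y2, spec.t_lag, spec.t_half)
    sd = spec.noise_sd * abs(spec.y2 - spec.y1)
    traces = []
    for rep in range(spec.n_replicates):
        noise = rng.normal(0.0, sd, size=t.size) if sd > 0 else np.zeros(t.size)
        traces.append(
            KineticTrace(
                times=t,
                intensities=clean + noise,
                condition=spec.condition,
                replicate=rep,
            )
        )
    return traces


def kinetics_spec_from_reference(
    row: pd.Series | dict, seed: int = 0, noise_sd: float = 0.02, **kwargs
) -> KineticsSpec:
    """Build a KineticsSpec from one reference-table row (t_lag/t_half columns)."""
    return KineticsSpec(
        y1=0.0,
        y2=1.0,
        t_lag=float(row["t_lag_min"]),
        t_half=float(row["t_half_min"]),
        noise_sd=noise_sd,
        seed=seed,
        condition=str(row["condition"]),
        **kwargs,
    )


# --- fibril field rendering -------------------------------------------------


def _render_rod(
    shape: tuple[int, int],
    center: tuple[float, float],
    angle: float,
    length_px: float,
    width_px: float,
    height: float,
    aa_px: float = 1.0,
) -> np.ndarray:
    """Rasterize one flat-topped rod into a patch of the given shape.

    Height profile: ``height`` inside the rod, falling linearly to 0 over an
    ``aa_px``-wide anti-aliased rim (distance to the rod's center segment).
    """
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    cy, cx = center
    dx, dy = np.cos(angle), np.sin(angle)
    half = length_px / 2.0
    # projection of each pixel onto the rod axis, clamped to the segment
    px, py = cols - cx, rows - cy
    s = np.clip(px * dx + py * dy, -half, half)
    dist = np.hypot(px - s * dx, py - s * dy)
    profile = np.clip((width_px / 2.0 + aa_px - dist) / aa_px, 0.0, 1.0)
    return height * profile


@dataclass(frozen=True)
class SyntheticField:
    """A rendered fibril field plus its per-object ground truth.

    ``truth`` has one row per placed object: ``object_id``, ``kind``
    (fibril / associated_pair / cluster), ``n_rods``, ``max_height_nm``
    (pre-noise maximum of the rendered object).
    """

    heightmap: HeightMap
    truth: pd.DataFrame


def make_fibril_field(spec: FibrilFieldSpec) -> SyntheticField:
    """Render a synthetic AFM fibril field with a per-object truth table.

    Each object (single fibril, laterally associated pair, or cluster) is
    rendered into its own patch; overlapping rods within one object add
    their heights.  Objects are placed by rejection sampling so that no two
    objects touch (3-px margin); placements that cannot be accommodated
    after 40 tries are skipped, so dense specs may yield fewer objects than
    requested.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size_px
    field_arr = np.zeros((n, n))
    occupied = np.zeros((n, n), dtype=bool)
    margin = 3
    records = []
    object_id = 0

    for _ in range(spec.n_fibrils):
        u = rng.uniform()
        if u < spec.cluster_prob:
            kind = "cluster"
        elif u < spec.cluster_prob + spec.association_prob:
            kind = "associated_pair"
        else:
            kind = "fibril"

        length = rng.uniform(*spec.length_range_nm) / spec.pixel_size
        width = rng.uniform(*spec.width_range_nm) / spec.pixel_size
        base_angle = rng.uniform(0.0, np.pi)

        if kind == "fibril":
            rods = [(0.0, 0.0, base_angle, length, width,
                     rng.uniform(*spec.height_range_nm))]
        elif kind == "associated_pair":
            # partner laid alongside, offset by ~0.6 widths: the overlap strip
            # sums the two heights, emulating lateral association
            off = 0.6 * width
            perp = base_angle + np.pi / 2.0
            h1 = rng.uniform(*spec.height_range_nm)
            h2 = rng.uniform(*spec.height_range_nm)
            shift = rng.uniform(-0.2, 0.2) * length
            rods = [
                (0.0, 0.0, base_angle, length, width, h1),
                (off * np.sin(perp) + shift * np.sin(base_angle),
                 off * np.cos(perp) + shift * np.cos(base_angle),
                 base_angle, length, width, h2),
            ]
        else:
            # dense bundle of shorter rods around a common center
            k = int(rng.integers(4, 8))
            rods = []
            radius = 0.2 * length
            for _ in range(k):
                dy = rng.uniform(-radius, radius)
                dx = rng.uniform(-radius, radius)
                ang = base_angle + rng.uniform(-0.5, 0.5)
                rods.append(
                    (dy, dx, ang, 0.7 * length, width,
                     rng.uniform(*spec.height_range_nm))
                )

        # patch large enough for every rod at any in-patch orientation
        extent = max(r[3] for r in rods) + max(r[4] for r in rods) + 6
        extent += 2 * max(max(abs(r[0]), abs(r[1])) for r in rods)
        p = int(np.ceil(extent))
        patch = np.zeros((p, p))
        pc = (p - 1) / 2.0
        for dy, dx, ang, rl, rw, rh in rods:
            patch += _render_rod((p, p), (pc + dy, pc + dx), ang, rl, rw, rh)
        if patch.max() <= 0:
            continue

        placed = False
        for _ in range(40):
            r0 = int(rng.integers(0, max(n - p, 1)))
            c0 = int(rng.integers(0, max(n - p, 1)))
            r1, c1 = min(r0 + p, n), min(c0 + p, n)
            ra, rb = max(r0 - margin, 0), min(r1 + margin, n)
            ca, cb = max(c0 - margin, 0), min(c1 + margin, n)
            if not occupied[ra:rb, ca:cb].any():
                field_arr[r0:r1, c0:c1] += patch[: r1 - r0, : c1 - c0]
                occupied[ra:rb, ca:cb] = True
                placed = True
                break
        if not placed:
            continue
        object_id += 1
        records.append(
            {
                "object_id": object_id,
                "kind": kind,
                "n_rods": len(rods),
                "max_height_nm": float(patch.max()),
            }
        )

    if spec.noise_sd_nm > 0:
        field_arr = field_arr + rng.normal(0.0, spec.noise_sd_nm, size=field_arr.shape)

    truth = pd.DataFrame.from_records(
        records, columns=["object_id", "kind", "n_rods", "max_height_nm"]
    )
    hmap = HeightMap(
        heights=field_arr, pixel_size=spec.pixel_size, source_id=spec.source_id
    )
    return SyntheticField(heightmap=hmap, truth=truth)


# --- spectra ----------------------------------------------------------------


def make_spectrum(spec: SpectrumSpec, step: float = 1.0) -> Spectrum:
    """Sum of per-class Gaussian bands + linear baseline + seeded noise.

    The clean band areas match ``spec.fractions`` exactly (total area 1
    before baseline and noise) on a ``step`` cm^-1 grid over the amide-I
    window.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = AMIDE_I_WINDOW
    w = np.arange(lo, hi + step / 2.0, step)
    a = np.zeros_like(w)
    for cls, frac in spec.fractions.items():
        if frac <= 0:
            continue
        c, s = spec.centers[cls], spec.sigmas[cls]
        height = frac / (s * np.sqrt(2.0 * np.pi))
        a += height * np.exp(-0.5 * ((w - c) / s) ** 2)
    a = a + spec.baseline_slope * (w - lo)
    if spec.noise_sd > 0:
        a = a + rng.normal(0.0, spec.noise_sd * a.max(), size=w.size)
    return Spectrum(wavenumbers=w, absorbance=a)


def spectrum_spec_from_reference(
    row: pd.Series | dict, seed: int = 0, noise_sd: float = 0.01, **kwargs
) -> SpectrumSpec:
    """SpectrumSpec from a structure-reference row; the reported-class
    percentages are scaled to leave the residual share to side chains."""
    helix = float(row["random_helix_pct"])
    sheet = float(row["beta_sheet_pct"])
    turn = float(row["beta_turn_pct"])
    side = max(100.0 - helix - sheet - turn, 0.0)
    total = helix + sheet + turn + side
    fractions = {
        "random_helix": helix / total,
        "beta_sheet": sheet / total,
        "beta_turn": turn / total,
        "side_chain": side / total,
    }
    return SpectrumSpec(fractions=fractions, seed=seed, noise_sd=noise_sd, **kwargs)
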