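"""Ground-truthed synthetic data for every stage of the pipeline.

Two generators:

* brightfield-like fields of dark, near-circular aggregates (filled
  ellipses) on a light background, with Gaussian blur and additive
  camera-like noise, plus the exact ground truth (center, semi-axes,
  orientation, continuous isoperimetric circularity) of every aggregate;
* rheograms — steady flow curves from the thixotropic Herschel-Bulkley
  law and oscillatory sweeps from the fractional Jeffrey model — with
  multiplicative lognormal noise of a given coefficient of variation
  (rheometer error scales with signal).

Everything is seeded: identical specs (including the seed) reproduce
identical outputs byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
from scipy import ndimage, special

from .errors import PlacementError
from .rheology import (
    FJMParams,
    FlowCurve,
    HBThixoParams,
    OscillatorySweep,
    fjm_moduli,
    hb_thixo_stress,
)

__all__ = [
    "SyntheticImageSpec",
    "GroundTruthAggregate",
    "RheoSimSpec",
    "generate_aggregate_image",
    "generate_flow_curve",
    "generate_oscillatory_sweep",
    "ellipse_circularity",
    "write_image_png",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "write_rheogram_csv",
]

_MAX_ATTEMPTS = 10_000  # rejection-sampling budget per aggregate


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for one synthetic brightfield field.

    Defaults emulate a 4x/10x brightfield field of stirred-suspension
    hiPSC aggregates: 1024 x 1024 px, dark aggregates (intensity 60) on a
    light background (200), optical blur of 1.5 px.
    """

    width_px: int = 1024
    height_px: int = 1024
    n_aggregates: int = 10
    radius_range_px: tuple[float, float] = (20.0, 100.0)
    aspect_ratio_range: tuple[float, float] = (1.0, 1.0)
    foreground_intensity: int = 60
    background_intensity: int = 200
    blur_sigma_px: float = 1.5
    noise_sd: float = 10.0
    min_separation_px: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.foreground_intensity < self.background_intensity <= 255:
            raise ValueError(
                "aggregates are dark on light: need "
                "0 <= foreground < background <= 255"
            )
        rmin, rmax = self.radius_range_px
        if not 0 < rmin <= rmax:
            raise ValueError("radius range must satisfy 0 < min <= max")
        amin, amax = self.aspect_ratio_range
        if not 1.0 <= amin <= amax:
            raise ValueError("aspect ratios must satisfy 1 <= min <= max")
        if self.blur_sigma_px < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma_px and noise_sd must be non-negative")
        if self.n_aggregates < 0:
            raise ValueError("n_aggregates must be non-negative")


@dataclass(frozen=True)
class GroundTruthAggregate:
    """True geometry of one rendered ellipse.

    ``true_circularity`` is the continuous isoperimetric score
    4*pi*A/P^2 of the ellipse (1 for a disk, below 1 otherwise).
    """

    center: tuple[float, float]  # (row, col)
    semi_major_px: float
    semi_minor_px: float
    orientation_rad: float
    true_circularity: float


def ellipse_circularity(semi_major: float, semi_minor: float) -> float:
    """Continuous isoperimetric circularity 4*pi*A/P^2 of an ellipse.

    Area is pi*a*b; the perimeter uses the complete elliptic integral of
    the second kind, so the value is exact (1.0 for a == b).
    """
    a, b = float(semi_major), float(semi_minor)
    if not 0 < b <= a:
        raise ValueError("need semi_major >= semi_minor > 0")
    area = np.pi * a * b
    ecc2 = 1.0 - (b / a) ** 2
    perimeter = 4.0 * a * special.ellipe(ecc2)
    return float(4.0 * np.pi * area / perimeter**2)


def generate_aggregate_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, list[GroundTruthAggregate]]:
    """Render a synthetic brightfield field with exact ground truth.

    Aggregates are filled ellipses placed by rejection sampling so that
    bounding circles are separated by at least ``min_separation_px`` and
    every ellipse lies fully inside the frame.  The field is blurred with
    a Gaussian of ``blur_sigma_px``, additive Gaussian noise of sd
    ``noise_sd`` is added, and the result is clipped and quantised to
    8-bit.  Raises :class:`~aggrheo.errors.PlacementError` when a feasible
    placement cannot be found within the attempt budget.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    rmin, rmax = spec.radius_range_px
    amin, amax = spec.aspect_ratio_range

    placed: list[GroundTruthAggregate] = []
    for _ in range(spec.n_aggregates):
        ok = False
        for attempt in range(_MAX_ATTEMPTS):
            # the stated radius is the geometric-mean radius sqrt(a*b) so
            # that the rendered area matches a disk of that radius
            radius = rng.uniform(rmin, rmax)
            aspect = rng.uniform(amin, amax)
            a = radius * np.sqrt(aspect)
            b = radius / np.sqrt(aspect)
            theta = rng.uniform(0.0, np.pi)
            row = rng.uniform(a, h - 1 - a)
            col = rng.uniform(a, w - 1 - a)
            if row < a or col < a:  # frame smaller than the ellipse
                continue
            if all(
                np.hypot(row - g.center[0], col - g.center[1])
                >= a + g.semi_major_px + spec.min_separation_px
                for g in placed
            ):
                placed.append(
                    GroundTruthAggregate(
                        center=(float(row), float(col)),
                        semi_major_px=float(a),
                        semi_minor_px=float(b),
                        orientation_rad=float(theta),
                        true_circularity=ellipse_circularity(a, b),
                    )
                )
                ok = True
                break
        if not ok:
            raise PlacementError(
                placed=len(placed),
                requested=spec.n_aggregates,
                attempts=_MAX_ATTEMPTS,
            )

    field = np.full((h, w), float(spec.background_intensity))
    rows, cols = np.mgrid[0:h, 0:w]
    for g in placed:
        r0, c0 = g.center
        win = int(np.ceil(g.semi_major_px)) + 2
        rs = slice(max(0, int(r0) - win), min(h, int(r0) + win + 1))
        cs = slice(max(0, int(c0) - win), min(w, int(c0) + win + 1))
        dr = rows[rs, cs] - r0
        dc = cols[rs, cs] - c0
        ct, st = np.cos(g.orientation_rad), np.sin(g.orientation_rad)
        u = dr * ct + dc * st
        v = -dr * st + dc * ct
        inside = (u / g.semi_major_px) ** 2 + (v / g.semi_minor_px) ** 2 <= 1.0
        block = field[rs, cs]
        block[inside] = float(spec.foreground_intensity)
        field[rs, cs] = block

    if spec.blur_sigma_px > 0:
        field = ndimage.gaussian_filter(field, spec.blur_sigma_px)
    if spec.noise_sd > 0:
        field = field + rng.normal(0.0, spec.noise_sd, size=field.shape)
    image = np.clip(np.rint(field), 0, 255).astype(np.uint8)
    return image, placed


# ---------------------------------------------------------------------------
# rheogram simulation


@dataclass(frozen=True)
class RheoSimSpec:
    """Recipe for one simulated rheometer observation series.

    ``model`` selects the forward model: ``"hb_thixo"`` (steady flow
    curve; abscissa are shear rates in 1/s) or ``"fjm"`` (frequency
    sweep; abscissa are angular frequencies in rad/s).  ``noise_cv`` is
    the coefficient of variation of multiplicative lognormal noise.
    """

    model: str
    parameters: HBThixoParams | FJMParams
    abscissa_values: tuple[float, ...]
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("hb_thixo", "fjm"):
            raise ValueError("model must be 'hb_thixo' or 'fjm'")
        expected = HBThixoParams if self.model == "hb_thixo" else FJMParams
        if not isinstance(self.parameters, expected):
            raise TypeError(f"model {self.model!r} needs {expected.__name__}")
        x = np.asarray(self.abscissa_values, dtype=float)
        if x.size == 0 or np.any(x <= 0):
            raise ValueError("abscissa values must be strictly positive")
        d = np.diff(x)
        if x.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("abscissa values must be strictly monotone")
        if not 0.0 <= self.noise_cv < 1.0:
            raise ValueError("noise_cv must be in [0, 1)")
        object.__setattr__(self, "abscissa_values", tuple(float(v) for v in x))


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of
    variation ``cv``."""
    if cv == 0.0:
        return np.ones(n)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=n)


def generate_flow_curve(spec: RheoSimSpec) -> FlowCurve:
    """Simulate a steady flow curve from the thixotropic Herschel-Bulkley
    law, with multiplicative lognormal noise of CV ``noise_cv``."""
    if spec.model != "hb_thixo":
        raise ValueError("generate_flow_curve requires model 'hb_thixo'")
    rng = np.random.default_rng(spec.seed)
    rates = np.asarray(spec.abscissa_values)
    stress = hb_thixo_stress(rates, spec.parameters)
    stress = stress * _lognormal_factors(rng, spec.noise_cv, rates.size)
    return FlowCurve(shear_rates=rates, stresses=stress, corrected=False)


def generate_oscillatory_sweep(spec: RheoSimSpec) -> OscillatorySweep:
    """Simulate a frequency sweep from the fractional Jeffrey model, with
    independent multiplicative lognormal noise on G' and G''."""
    if spec.model != "fjm":
        raise ValueError("generate_oscillatory_sweep requires model 'fjm'")
    rng = np.random.default_rng(spec.seed)
    w = np.asarray(spec.abscissa_values)
    gp, gpp = fjm_moduli(w, spec.parameters)
    gp = gp * _lognormal_factors(rng, spec.noise_cv, w.size)
    gpp = gpp * _lognormal_factors(rng, spec.noise_cv, w.size)
    return OscillatorySweep(
        abscissa=w, g_prime=gp, g_double_prime=gpp, mode="frequency"
    )


# ---------------------------------------------------------------------------
# plain-text I/O


def write_image_png(image: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit single-channel PNG."""
    if image.dtype != np.uint8 or image.ndim != 2:
        raise ValueError("image must be a 2-D uint8 array")
    iio.imwrite(Path(path), image)


def write_ground_truth_csv(
    truths: list[GroundTruthAggregate], path: str | Path
) -> None:
    rows = [
        {
            "id": i,
            "row": g.center[0],
            "col": g.center[1],
            "semi_major_px": g.semi_major_px,
            "semi_minor_px": g.semi_minor_px,
            "orientation_rad": g.orientation_rad,
            "true_circularity": g.true_circularity,
        }
        for i, g in enumerate(truths)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "id", "row", "col", "semi_major_px", "semi_minor_px",
            "orientation_rad", "true_circularity",
        ],
    ).to_csv(path, index=False)


def read_ground_truth_csv(path: str | Path) -> list[GroundTruthAggregate]:
    df = pd.read_csv(path)
    return [
        GroundTruthAggregate(
            center=(float(r.row), float(r.col)),
            semi_major_px=float(r.semi_major_px),
            semi_minor_px=float(r.semi_minor_px),
            orientation_rad=float(r.orientation_rad),
            true_circularity=float(r.true_circularity),
        )
        for r in df.itertuples()
    ]


def write_rheogram_csv(
    data: FlowCurve | OscillatorySweep, spec: RheoSimSpec, path: str | Path
) -> None:
    """Write a rheogram CSV plus a JSON sidecar with the generating
    parameters and seed (``<path>.json``)."""
    path = Path(path)
    if isinstance(data, FlowCurve):
        df = pd.DataFrame(
            {"abscissa": data.shear_rates, "value1": data.stresses}
        )
    else:
        df = pd.DataFrame(
            {
                "abscissa": data.abscissa,
                "value1": data.g_prime,
                "value2": data.g_double_prime,
            }
        )
    df.to_csv(path, index=False)
    sidecar = {
        "model": spec.model,
        "parameters": asdict(spec.parameters),
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
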