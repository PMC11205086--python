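"""Synthetic wound outlines and simulated rater annotations.

Generates chronic-ulcer-like blob outlines (a radial harmonic perturbation of
an anisotropically scaled circle) at photographic resolution, plus noisy
manual halving lines and jittered wound borders, so the full two-round,
multi-assessor study design can be exercised end to end without any image
downloads.

Randomness contract: one master seed; every per-image and per-(image, rater,
round) stream is derived through ``numpy.random.SeedSequence`` with a fixed
namespace tuple, so adding raters or rounds never perturbs existing draws.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import shapely
from PIL import Image

from .errors import InvalidOutlineError
from .geometry import (
    BinaryMask,
    HalvingLine,
    HalvingOutcome,
    OrientedBox,
    WoundOutline,
    halve,
    min_area_box_of_points,
    rasterize_outline,
)

__all__ = [
    "WoundShapeParams",
    "RaterNoiseParams",
    "StudyBundle",
    "generate_wound",
    "sample_wound_params",
    "generate_wound_set",
    "simulate_rater_line",
    "jitter_outline",
    "generate_study",
    "estimate_sigma_offset",
]

_TAU = 2.0 * np.pi


@dataclass(frozen=True)
class WoundShapeParams:
    """Parameters of one synthetic wound outline.

    The border is r(theta) = R (1 + sum_j a_j cos((j+2) theta + phi_j)),
    sampled at ``n_vertices`` angles, stretched by ``elongation`` along x,
    rotated and centered in the image.  Harmonics start at j = 2: the 0th
    harmonic is a scale change and the 1st mostly a translation, neither of
    which adds shape.
    """

    base_radius: float
    elongation: float = 1.0
    harmonic_amplitudes: tuple[float, ...] = ()
    rotation: float = 0.0  # radians
    image_size: tuple[int, int] = (768, 768)
    seed: int = 0
    n_vertices: int = 192
    long_axis_target: float | None = None  # rescale so the box long axis hits this

    def __post_init__(self):
        if self.elongation < 1.0:
            raise ValueError("elongation must be >= 1")
        if float(np.abs(self.harmonic_amplitudes).sum()) >= 0.35:
            raise ValueError(
                "sum of |harmonic amplitudes| must stay below 0.35 "
                "(keeps the outline simple)"
            )


@dataclass(frozen=True)
class RaterNoiseParams:
    """Noise model for simulated manual annotations.

    A rater's halving line is the true (algorithmic) line rotated about its
    midpoint by N(0, sigma_angle deg) and shifted along the box long axis by
    N(0, sigma_offset * length_L) px.  Round-1 wound borders get smooth
    radial jitter of RMS ``sigma_outline`` px.  Round-2 lines (drawn without
    the border on screen) use all sigmas scaled by ``round2_scale``.

    Defaults are calibrated so that simulated manual deviations land in the
    2-3% median band typical of human assessors.
    """

    sigma_angle: float = 3.0  # degrees
    sigma_offset: float = 0.022  # fraction of the box length_L
    sigma_outline: float = 3.0  # px RMS radial jitter
    round2_scale: float = 1.5

    def __post_init__(self):
        if min(self.sigma_angle, self.sigma_offset, self.sigma_outline) < 0:
            raise ValueError("noise sigmas must be >= 0")


def _rng(*entropy) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _outline_from_radii(params: WoundShapeParams, amps: np.ndarray,
                        phases: np.ndarray) -> np.ndarray:
    theta = np.linspace(0.0, _TAU, params.n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for j, (a, phi) in enumerate(zip(amps, phases)):
        r += a * np.cos((j + 2) * theta + phi)
    x = params.base_radius * params.elongation * r * np.cos(theta)
    y = params.base_radius * r * np.sin(theta)
    c, s = np.cos(params.rotation), np.sin(params.rotation)
    w, h = params.image_size
    return np.column_stack(
        [c * x - s * y + w / 2.0, s * x + c * y + h / 2.0]
    )


def generate_wound(params: WoundShapeParams) -> WoundOutline:
    """Deterministically generate one simple wound outline.

    If the sampled harmonics self-intersect, amplitudes are damped and the
    outline regenerated (up to 10 attempts).
    """
    rng = _rng(params.seed, 3)
    amps = np.asarray(params.harmonic_amplitudes, dtype=float)
    phases = rng.uniform(0.0, _TAU, size=amps.size)
    w, h = params.image_size
    center = np.array([w / 2.0, h / 2.0])
    for _ in range(10):
        verts = _outline_from_radii(params, amps, phases)
        if params.long_axis_target is not None:
            # rescale about the image center so the measured box long axis
            # lands on the target (+1 px pad absorbs the center-extent shrink
            # of the later pixel-center box)
            box = min_area_box_of_points(verts)
            scale = (params.long_axis_target + 1.0) / box.length_L
            verts = center + (verts - center) * scale
        if shapely.Polygon(verts).is_valid:
            return WoundOutline(verts, params.image_size)
        amps = amps * 0.6
    raise InvalidOutlineError("could not generate a simple outline in 10 attempts")


def sample_wound_params(
    rng: np.random.Generator,
    image_size: tuple[int, int] = (768, 768),
    long_axis_range: tuple[float, float] = (250.0, 500.0),
    elongation_range: tuple[float, float] = (1.2, 2.5),
    n_harmonics: int = 4,
    amplitude_max: float = 0.07,
) -> WoundShapeParams:
    """Draw realistic shape parameters for one wound."""
    elong = float(rng.uniform(*elongation_range))
    target = float(rng.uniform(*long_axis_range))
    amps = rng.uniform(0.0, amplitude_max, size=n_harmonics)
    # base radius chosen near the target; generate_wound rescales exactly
    base = target / (2.0 * elong * (1.0 + amps.sum()))
    return WoundShapeParams(
        base_radius=base,
        elongation=elong,
        harmonic_amplitudes=tuple(amps),
        rotation=float(rng.uniform(0.0, np.pi)),
        image_size=image_size,
        seed=int(rng.integers(2**31)),
        long_axis_target=target,
    )


def generate_wound_set(
    n_images: int,
    seed: int,
    image_size: tuple[int, int] = (768, 768),
    **kwargs,
) -> list[WoundOutline]:
    """The study's wound panel: ``n_images`` independent outlines."""
    outlines = []
    for i in range(n_images):
        rng = _rng(seed, 0, i)
        outlines.append(
            generate_wound(sample_wound_params(rng, image_size=image_size, **kwargs))
        )
    return outlines


def simulate_rater_line(
    truth: HalvingLine,
    box: OrientedBox,
    noise: RaterNoiseParams,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> HalvingLine:
    """One simulated manual halving line.

    Rotates the true line about its midpoint by a Gaussian angle and shifts
    it along the box's long axis by a Gaussian offset; zero noise returns the
    truth exactly.
    """
    ang = np.deg2rad(rng.normal(0.0, noise.sigma_angle * scale))
    off = rng.normal(0.0, noise.sigma_offset * scale) * box.length_L
    mid = truth.endpoints.mean(axis=0)
    c, s = np.cos(ang), np.sin(ang)
    rot = np.array([[c, -s], [s, c]])
    pts = (truth.endpoints - mid) @ rot.T + mid + off * box.long_axis
    return HalvingLine(endpoints=pts, source="manual")


def jitter_outline(
    outline: WoundOutline, sigma: float, rng: np.random.Generator
) -> WoundOutline:
    """Smooth radial jitter of a wound border (RMS about ``sigma`` px).

    Low-order harmonic noise keeps the jittered border simple; vertices are
    clipped to the image bounds.
    """
    if sigma == 0:
        return outline
    v = outline.vertices
    centroid = v.mean(axis=0)
    d = v - centroid
    radii = np.hypot(d[:, 0], d[:, 1])
    theta = np.arctan2(d[:, 1], d[:, 0])
    amps = rng.normal(0.0, sigma / np.sqrt(2.0), size=4)
    phases = rng.uniform(0.0, _TAU, size=4)
    w, h = outline.image_size
    for _ in range(10):
        noise = sum(a * np.cos(j * theta + p)
                    for j, (a, p) in enumerate(zip(amps, phases)))
        new_r = np.maximum(radii + noise, 1.0)
        verts = centroid + d / radii[:, None] * new_r[:, None]
        verts[:, 0] = np.clip(verts[:, 0], 0.0, w)
        verts[:, 1] = np.clip(verts[:, 1], 0.0, h)
        if shapely.Polygon(verts).is_valid:
            return WoundOutline(verts, outline.image_size)
        amps = amps * 0.7
    raise InvalidOutlineError("could not jitter outline into a simple polygon")


# ---------------------------------------------------------------------------
# full study bundles
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    """In-memory synthetic study: VIA projects, ground truth, rendered images."""

    round1: dict
    round2: dict
    manifest: dict
    images: dict[str, np.ndarray] = field(default_factory=dict)
    out_dir: Path | None = None


def _poly_region(vertices, assessor: str, rnd: int, name: str = "polygon") -> dict:
    return {
        "shape_attributes": {
            "name": name,
            "all_points_x": [float(p[0]) for p in vertices],
            "all_points_y": [float(p[1]) for p in vertices],
        },
        "region_attributes": {"assessor": assessor, "round": rnd},
    }


def _render_image(mask: BinaryMask) -> np.ndarray:
    img = np.empty(mask.grid.shape + (3,), dtype=np.uint8)
    img[...] = (205, 180, 165)  # skin-toned background
    img[mask.grid] = (150, 60, 55)  # wound bed
    return img


def generate_study(
    n_images: int = 20,
    n_raters: int = 6,
    noise: RaterNoiseParams | None = None,
    seed: int = 0,
    out_dir=None,
    image_size: tuple[int, int] = (768, 768),
    write_images: bool = True,
    **wound_kwargs,
) -> StudyBundle:
    """Emulate the full two-round annotation study.

    Produces one VIA project per round (round 1: per-rater jittered outlines
    plus halving lines; round 2: halving lines only), a ground-truth manifest
    (true outline, true line, true split per image) and flat rendered PNGs.
    Presentation order is shuffled per rater and round, seeded.
    """
    if n_images < 1 or n_raters < 1:
        raise ValueError("need at least one image and one rater")
    noise = noise if noise is not None else RaterNoiseParams()
    w, h = image_size
    r1meta: dict = {}
    r2meta: dict = {}
    images: dict[str, np.ndarray] = {}
    manifest: dict = {
        "seed": seed,
        "n_images": n_images,
        "n_raters": n_raters,
        "image_size": [w, h],
        "noise": asdict(noise),
        "images": [],
        "presentation_order": {},
    }
    for i in range(n_images):
        rng_i = _rng(seed, 0, i)
        params = sample_wound_params(rng_i, image_size=image_size, **wound_kwargs)
        outline = generate_wound(params)
        mask = rasterize_outline(outline)
        outcome = halve(mask)
        image_id = f"wound_{i:03d}"
        filename = f"{image_id}.png"
        images[image_id] = _render_image(mask)
        fa = {"width": w, "height": h}
        entry1 = {"filename": filename, "size": -1, "file_attributes": dict(fa),
                  "regions": []}
        entry2 = {"filename": filename, "size": -1, "file_attributes": dict(fa),
                  "regions": []}
        for r in range(n_raters):
            aid = f"A{r + 1}"
            rng1 = _rng(seed, 1, i, r, 1)
            jittered = jitter_outline(outline, noise.sigma_outline, rng1)
            line1 = simulate_rater_line(outcome.line, outcome.box, noise, rng1)
            entry1["regions"].append(_poly_region(jittered.vertices, aid, 1))
            entry1["regions"].append(
                _poly_region(line1.endpoints, aid, 1, name="polyline")
            )
            rng2 = _rng(seed, 1, i, r, 2)
            line2 = simulate_rater_line(
                outcome.line, outcome.box, noise, rng2, scale=noise.round2_scale
            )
            entry2["regions"].append(
                _poly_region(line2.endpoints, aid, 2, name="polyline")
            )
        r1meta[filename] = entry1
        r2meta[filename] = entry2
        manifest["images"].append(
            {
                "image_id": image_id,
                "filename": filename,
                "outline": outline.vertices.tolist(),
                "line": outcome.line.endpoints.tolist(),
                "n_selected": outcome.split.n_selected,
                "fraction_side1": outcome.split.fraction_side1,
                "abs_deviation": outcome.split.abs_deviation,
                "box": {
                    "center": outcome.box.center.tolist(),
                    "long_axis": outcome.box.long_axis.tolist(),
                    "length_L": outcome.box.length_L,
                    "width_W": outcome.box.width_W,
                    "area_B": outcome.box.area_B,
                },
            }
        )
    ids = [img["image_id"] for img in manifest["images"]]
    for r in range(n_raters):
        aid = f"A{r + 1}"
        manifest["presentation_order"][aid] = {
            str(rnd): [ids[j] for j in _rng(seed, 2, r, rnd).permutation(len(ids))]
            for rnd in (1, 2)
        }
    bundle = StudyBundle(
        round1={"_via_img_metadata": r1meta},
        round2={"_via_img_metadata": r2meta},
        manifest=manifest,
        images=images,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "round1.json").write_text(json.dumps(bundle.round1, indent=1))
        (out / "round2.json").write_text(json.dumps(bundle.round2, indent=1))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        if write_images:
            img_dir = out / "images"
            img_dir.mkdir(exist_ok=True)
            for image_id, arr in images.items():
                Image.fromarray(arr).save(img_dir / f"{image_id}.png")
        bundle.out_dir = out
    return bundle


def estimate_sigma_offset(deviations_pct, outcome: HalvingOutcome) -> float:
    """Recover the axial-offset noise scale from observed split deviations.

    Near the halving position the one-side percentage is locally linear in
    the line's axial offset with slope 100 * (local pixel density) / A, so
    each absolute deviation maps back to an absolute offset; under the
    half-normal model sigma = mean(|offset|) * sqrt(pi / 2).  Returned as a
    fraction of the box length, matching ``RaterNoiseParams.sigma_offset``.
    """
    c = outcome.profile.cumulative
    A = outcome.profile.total_A
    n0 = outcome.split.n_selected
    n_strips = len(c)
    lo = max(n0 - 5, 1)
    hi = min(n0 + 5, n_strips)
    slope = (c[hi - 1] - c[lo - 1]) / (hi - lo)  # wound px per 1-px strip
    if slope <= 0:
        raise ValueError("flat strip profile at the halving position")
    offsets = np.asarray(list(deviations_pct), dtype=float) * A / (100.0 * slope)
    sigma_px = offsets.mean() * np.sqrt(np.pi / 2.0)
    return float(sigma_px / outcome.box.length_L)
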