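"""Synthetic CT-like bone phantoms with known ground truth.

A phantom slice emulates what the fracture-detection chain sees in an
axial pelvic CT image: bright, smooth, closed bone cross-sections
(cortical shell plus slightly darker medullary interior) lying on a
darker soft-tissue body region, with optional fracture gaps cut through
the bone, additive Gaussian noise, and bright table-like artifacts
outside the body.  Every slice carries per-bone ground-truth masks and
fracture annotations so each downstream stage can be tested against
known truth.

Bone outlines are ellipses perturbed by low-order harmonics — smooth
closed curves that mimic iliac-wing cross-sections without an anatomical
atlas.  Fracture gaps are straight cuts of controllable width through
the full bone cross-section, perpendicular to the local shell tangent,
which is how gap-type fractures present in axial slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import io as pfio

__all__ = [
    "BoneSpec",
    "PhantomSpec",
    "PhantomSlice",
    "render_phantom",
    "phantom_suite",
    "write_suite",
]

SOFT_TISSUE = 0.25  # gray level of the body region
AIR = 0.0
ARTIFACT_INTENSITY = 0.85
MEDULLARY_DROP = 0.05  # interior is this much darker than the cortical shell


@dataclass(frozen=True)
class BoneSpec:
    """One bone cross-section.

    ``fracture_gaps`` is a list of ``(angle_rad, width_px)`` pairs; each
    gap is a straight cut of the given width through the whole bone at
    the given angular position on the outline.
    """

    center: tuple[float, float]  # (row, col)
    radius: float  # characteristic (major) radius, px
    thickness: float  # cortical shell thickness, px
    intensity: float  # cortical gray level in [0, 1]
    shape: str = "ring"  # "ring" (ellipse) or "iliac" (perturbed blob)
    axis_ratio: float = 0.8  # minor/major semi-axis
    orientation: float = 0.0  # radians
    harmonics: tuple[tuple[int, float, float], ...] = ()  # (k, amplitude, phase)
    fracture_gaps: tuple[tuple[float, float], ...] = ()

    def validate(self) -> None:
        if self.radius <= 0 or self.thickness <= 0:
            raise ValueError("radius and thickness must be positive")
        if not 0.0 < self.intensity <= 1.0:
            raise ValueError("intensity must be in (0, 1]")
        for ang, width in self.fracture_gaps:
            if width < 0:
                raise ValueError("gap width must be >= 0")
            if not 0.0 <= ang < 2 * np.pi:
                raise ValueError("gap angle must be in [0, 2*pi)")
            if width >= 2 * np.pi * (self.radius - self.thickness):
                raise ValueError("gap width >= shell circumference")


@dataclass(frozen=True)
class PhantomSpec:
    image_height: int = 384
    image_width: int = 384
    bones: tuple[BoneSpec, ...] = ()
    noise_sigma: float = 0.02  # additive Gaussian noise, gray levels
    artifact_count: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 128 or self.image_width < 128:
            raise ValueError("image dimensions must be >= 128")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for bone in self.bones:
            bone.validate()
            if self.noise_sigma > 0 and (
                bone.intensity - SOFT_TISSUE
            ) < 3 * self.noise_sigma:
                raise ValueError(
                    "bone intensity must exceed background by >= 3x noise_sigma"
                )


@dataclass
class PhantomSlice:
    """Rendered slice plus ground truth."""

    image: np.ndarray  # float64 in [0, 1]
    bone_masks: list[np.ndarray]  # full bone cross-section, gaps excluded
    shell_masks: list[np.ndarray]  # cortical shell only, gaps excluded
    fracture_truth: list[dict]  # per bone: {"fractured": bool, "gaps": [...]}
    spec: PhantomSpec = field(repr=False, default=None)

    @property
    def fractured(self) -> bool:
        return any(t["fractured"] for t in self.fracture_truth)


def _outline_radius(bone: BoneSpec, theta: np.ndarray) -> np.ndarray:
    """Polar radius of the bone outline at angle ``theta`` (image frame)."""
    a = bone.radius
    b = bone.radius * bone.axis_ratio
    t = theta - bone.orientation
    r = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
    pert = np.ones_like(theta)
    for k, amp, phase in bone.harmonics:
        pert += amp * np.cos(k * t + phase)
    return r * pert


def _body_ellipse(height: int, width: int) -> np.ndarray:
    rr, cc = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2, (width - 1) / 2
    ry, rx = 0.46 * height, 0.44 * width
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


def render_phantom(spec: PhantomSpec) -> PhantomSlice:
    """Render a phantom slice deterministically from its spec.

    Raises ``ValueError`` for invalid specs, overlapping bones, or a gap
    wide enough to consume the whole shell.
    """
    spec.validate()
    h, w = spec.image_height, spec.image_width
    # independent streams so e.g. disabling artifacts leaves the noise
    # field (and hence the rest of the image) bit-identical
    art_seed, noise_seed = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(art_seed)
    rng_noise = np.random.default_rng(noise_seed)

    image = np.full((h, w), AIR)
    body = _body_ellipse(h, w)
    image[body] = SOFT_TISSUE

    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    bone_masks: list[np.ndarray] = []
    shell_masks: list[np.ndarray] = []
    truth: list[dict] = []

    for bone in spec.bones:
        dy = rr - bone.center[0]
        dx = cc - bone.center[1]
        dist = np.hypot(dy, dx)
        theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
        r_out = _outline_radius(bone, theta)

        full = dist <= r_out
        shell = full & (dist >= r_out - bone.thickness)
        interior = full & ~shell

        if any((full & m).any() for m in bone_masks):
            raise ValueError("overlapping bones in phantom spec")

        # Cut gaps as straight fracture planes: a band of the stated
        # width along the chord perpendicular to the radial direction at
        # the gap angle, at 0.35 of the local outline radius from the
        # center.  A fracture line crosses the whole cross-section, so a
        # single gap fully severs the bone (and its cortical shell) into
        # two fragments, as gap-type fractures present in axial slices.
        gap_region = np.zeros((h, w), dtype=bool)
        for ang, width in bone.fracture_gaps:
            if width <= 0:
                continue
            r_gap = float(_outline_radius(bone, np.array([ang]))[0])
            proj = dy * np.sin(ang) + dx * np.cos(ang)
            gap_region |= full & (np.abs(proj - 0.35 * r_gap) <= width / 2.0)

        image[interior & ~gap_region] = bone.intensity - MEDULLARY_DROP
        image[shell & ~gap_region] = bone.intensity
        image[gap_region] = SOFT_TISSUE

        bone_masks.append(full & ~gap_region)
        shell_masks.append(shell & ~gap_region)
        severing = [
            {"angle": float(ang), "width": float(width)}
            for ang, width in bone.fracture_gaps
            if width > 0
        ]
        truth.append({"fractured": bool(severing), "gaps": severing})

    # Table-like bright bars, outside the body (hence outside the bones'
    # convex hull, since every bone lies inside the body ellipse).  Bars
    # keep a safety margin from the body so they never touch it.
    body_margin = ndimage.binary_dilation(body, iterations=5)
    for i in range(spec.artifact_count):
        bar = np.zeros((h, w), dtype=bool)
        if i % 2 == 0:  # vertical bar near left/right border
            col = int(rng.integers(4, 14)) if i % 4 == 0 else w - int(rng.integers(8, 18))
            bar[h // 8 : h - h // 8, col : col + 5] = True
        else:  # horizontal bar near top/bottom border
            row = int(rng.integers(4, 14)) if i % 4 == 1 else h - int(rng.integers(8, 18))
            bar[row : row + 5, w // 8 : w - w // 8] = True
        bar &= ~body_margin
        image[bar] = ARTIFACT_INTENSITY

    if spec.noise_sigma > 0:
        image = image + rng_noise.normal(0.0, spec.noise_sigma, size=(h, w))
    image = np.clip(image, 0.0, 1.0)

    return PhantomSlice(
        image=image,
        bone_masks=bone_masks,
        shell_masks=shell_masks,
        fracture_truth=truth,
        spec=spec,
    )


def _random_bone(
    rng: np.random.Generator,
    center: tuple[float, float],
    radius_range: tuple[float, float],
    gaps: tuple[tuple[float, float], ...] = (),
) -> BoneSpec:
    nharm = int(rng.integers(1, 3))
    harmonics = tuple(
        (int(rng.integers(2, 4)), float(rng.uniform(0.02, 0.06)), float(rng.uniform(0, 2 * np.pi)))
        for _ in range(nharm)
    )
    return BoneSpec(
        center=center,
        radius=float(rng.uniform(*radius_range)),
        thickness=float(rng.uniform(5.0, 8.0)),
        intensity=float(rng.uniform(0.85, 0.95)),
        axis_ratio=float(rng.uniform(0.7, 0.95)),
        orientation=float(rng.uniform(0, np.pi)),
        harmonics=harmonics,
        fracture_gaps=gaps,
    )


def make_slice_spec(
    seed: int,
    fractured: bool,
    image_size: int = 384,
    gap_width_range: tuple[float, float] = (6.0, 14.0),
    noise_sigma: float = 0.02,
) -> PhantomSpec:
    """Draw one randomized slice spec (two well-separated bones)."""
    rng = np.random.default_rng(seed)
    h = w = image_size
    jitter = lambda: float(rng.uniform(-12, 12))  # noqa: E731
    c1 = (h * 0.5 + jitter(), w * 0.30 + jitter())
    c2 = (h * 0.5 + jitter(), w * 0.72 + jitter())
    gaps: tuple[tuple[float, float], ...] = ()
    if fractured:
        n_gaps = int(rng.integers(1, 3))
        gaps = tuple(
            (float(rng.uniform(0, 2 * np.pi)), float(rng.uniform(*gap_width_range)))
            for _ in range(n_gaps)
        )
    bones = (
        _random_bone(rng, c1, (45.0, 56.0), gaps),
        _random_bone(rng, c2, (26.0, 34.0)),
    )
    return PhantomSpec(
        image_height=h,
        image_width=w,
        bones=bones,
        noise_sigma=noise_sigma,
        artifact_count=2,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def phantom_suite(
    n_fractured: int,
    n_intact: int,
    seed: int,
    image_size: int = 384,
    gap_width_range: tuple[float, float] = (6.0, 14.0),
    noise_sigma: float = 0.02,
) -> list[PhantomSlice]:
    """Generate a labeled suite of fractured and intact slices.

    Fractured slices come first.  All per-slice randomness derives
    reproducibly from ``seed``.
    """
    if n_fractured < 0 or n_intact < 0:
        raise ValueError("counts must be >= 0")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_fractured + n_intact)
    slices = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        spec = make_slice_spec(
            child_seed,
            fractured=i < n_fractured,
            image_size=image_size,
            gap_width_range=gap_width_range,
            noise_sigma=noise_sigma,
        )
        slices.append(render_phantom(spec))
    return slices


def write_suite(slices: list[PhantomSlice], outdir: str | Path) -> Path:
    """Write slice PNGs, per-bone mask PNGs, and a ground-truth sidecar.

    Returns the path of the JSON sidecar.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, sl in enumerate(slices):
        image_file = f"slice{i:04d}.png"
        pfio.write_image(outdir / image_file, sl.image)
        bones = []
        for b, (mask, truth) in enumerate(zip(sl.bone_masks, sl.fracture_truth)):
            mask_file = f"slice{i:04d}_bone{b}_mask.png"
            pfio.write_image(outdir / mask_file, mask.astype(np.float64))
            bones.append(
                {"mask_file": mask_file, "fractured": truth["fractured"], "gaps": truth["gaps"]}
            )
        entries.append(
            {"image_file": image_file, "fractured": sl.fractured, "bones": bones}
        )
    sidecar = outdir / "truth.json"
    pfio.write_json(sidecar, {"slices": entries})
    return sidecar
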