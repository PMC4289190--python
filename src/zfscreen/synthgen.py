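"""Synthetic brightfield larva images with exact ground truth.

The renderer is parametric-geometric: a larva is a Bezier-like spine
(integrated heading curve) with a tapering width profile, a head disk and a
yolk sac, drawn dark on a bright noisy background with a mild illumination
gradient. Phenotype classes modulate the geometry and color the way the real
defects present: a downward/upward tail bend, a whole-body upward arc
(lordosis-like), a shortened tail, a near-black granular yolk (necrosis), a
large pale blob around the anteroventral region (edema), a saturated red
spot in the pericardial area (hemostasis), a dark irregular round mass
(dead), or a circular chorion ring enclosing a curled embryo (unhatched).
Parameter ranges per class are disjoint, so labels are exact by
construction, and the painted-pixel mask is returned for localization tests.

Per-concentration plates draw death and teratogenicity from log-logistic
dose-response curves, giving known LC50/EC50 ground truth for recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from zfscreen.pipeline import (
    NON_GATE_TERMS,
    UP_CURVED_EITHER,
    UP_CURVED_FISH,
    UP_CURVED_TAIL,
    VOCABULARY,
    validate_label_set,
    write_manifest,
)

#: classes the renderer knows how to draw; "Up Curved Tail/Fish" renders as
#: one of its two constituents chosen at random.
RENDERABLE_CLASSES = tuple(VOCABULARY)

_DEFECT_CHOICES = tuple(
    t for t in NON_GATE_TERMS if t not in ("Normal", UP_CURVED_EITHER)
)


@dataclass(frozen=True)
class PhenotypeParams:
    """Geometric/chromatic knobs of one rendered larva.

    Angles are in degrees with the image convention that positive tail_angle
    bends the tail upward (toward smaller rows). Lengths are fractions of
    the canvas.
    """

    body_len_frac: float = 0.55
    tail_angle: float = 0.0
    body_arc: float = 0.0
    tail_len_frac: float = 1.0
    necrosed_yolk: bool = False
    edema_radius: float = 0.0
    hemostasis_radius: float = 0.0
    chorion: bool = False
    dead: bool = False
    center_jitter: tuple[float, float] = (0.0, 0.0)


#: per-class sampling intervals, deliberately disjoint between classes.
_CLASS_RANGES = {
    "Normal": {},
    "Down Curved Tail": {"tail_angle": (-65.0, -40.0)},
    "Up Curved Tail": {"tail_angle": (40.0, 65.0)},
    "Up Curved Fish": {"body_arc": (35.0, 55.0)},
    "Short Tail": {"tail_len_frac": (0.40, 0.55)},
    "Necrosed Yolk Sac": {"necrosed_yolk": True},
    "Edema": {"edema_radius": (13.0, 17.0)},
    "Hemostasis": {"hemostasis_radius": (6.0, 9.0)},
    "Dead": {"dead": True},
    "Chorion": {"chorion": True},
}

#: thresholds used to read the label set back off the parameters; they sit
#: between the Normal jitter band and the defect ranges above.
_TAIL_ANGLE_THRESHOLD = 30.0
_BODY_ARC_THRESHOLD = 25.0
_SHORT_TAIL_THRESHOLD = 0.75


def class_params(
    name: str, rng: np.random.Generator, jitter: float = 4.0
) -> PhenotypeParams:
    """Sample phenotype parameters for one vocabulary class."""
    if name == UP_CURVED_EITHER:
        name = UP_CURVED_TAIL if rng.random() < 0.5 else UP_CURVED_FISH
    if name not in _CLASS_RANGES:
        raise ValueError(f"unknown class {name!r}")
    kw: dict = {
        "body_len_frac": float(rng.uniform(0.50, 0.60)),
        "tail_angle": float(rng.uniform(-8.0, 8.0)),
        "body_arc": float(rng.uniform(0.0, 8.0)),
        "tail_len_frac": float(rng.uniform(0.92, 1.0)),
        "center_jitter": (float(rng.uniform(-jitter, jitter)), float(rng.uniform(-jitter, jitter))),
    }
    for key, rng_or_flag in _CLASS_RANGES[name].items():
        if isinstance(rng_or_flag, tuple):
            kw[key] = float(rng.uniform(*rng_or_flag))
        else:
            kw[key] = rng_or_flag
    return PhenotypeParams(**kw)


def labels_for(params: PhenotypeParams) -> frozenset[str]:
    """Ground-truth label set implied by the rendering parameters."""
    if params.dead:
        return frozenset({"Dead"})
    if params.chorion:
        return frozenset({"Chorion"})
    labels = set()
    if params.tail_angle <= -_TAIL_ANGLE_THRESHOLD:
        labels.add("Down Curved Tail")
    if params.tail_angle >= _TAIL_ANGLE_THRESHOLD:
        labels.add(UP_CURVED_TAIL)
    if params.body_arc >= _BODY_ARC_THRESHOLD:
        labels.add(UP_CURVED_FISH)
    if params.tail_len_frac <= _SHORT_TAIL_THRESHOLD:
        labels.add("Short Tail")
    if params.necrosed_yolk:
        labels.add("Necrosed Yolk Sac")
    if params.edema_radius > 0:
        labels.add("Edema")
    if params.hemostasis_radius > 0:
        labels.add("Hemostasis")
    if UP_CURVED_TAIL in labels or UP_CURVED_FISH in labels:
        labels.add(UP_CURVED_EITHER)
    if not labels:
        labels.add("Normal")
    return frozenset(labels)


def _paint(canvas: np.ndarray, mask: np.ndarray, color: tuple[float, float, float]) -> None:
    canvas[mask] = color


def _disk(rr: np.ndarray, cc: np.ndarray, center: tuple[float, float], radius: float) -> np.ndarray:
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _spine(params: PhenotypeParams, canvas: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample spine points and their half-widths.

    The heading starts horizontal (head at the left) and accumulates the
    whole-body arc along the spine plus the tail bend over the final 45%.
    """
    n = 120
    t = np.linspace(0.0, 1.0, n)
    length = params.body_len_frac * canvas
    tail_start = 0.55
    tail_scale = np.where(t > tail_start, (t - tail_start) / (1 - tail_start), 0.0)
    heading = np.deg2rad(-params.body_arc * t - params.tail_angle * tail_scale)
    # shorten the tail by compressing arc length past the bend point
    seg = np.full(n, length / (n - 1))
    seg[t > tail_start] *= params.tail_len_frac
    seg[0] = 0.0
    dr = np.cumsum(seg * np.sin(heading))
    dc = np.cumsum(seg * np.cos(heading))
    r0 = canvas / 2 - dr.mean() + params.center_jitter[0]
    c0 = canvas / 2 - dc.mean() + params.center_jitter[1]
    pts = np.stack([r0 + dr, c0 + dc], axis=1)
    widths = np.interp(t, [0.0, 0.12, 0.45, 1.0], [4.5, 5.5, 3.0, 1.2]) * (canvas / 256)
    return pts, widths


def _thick_curve_mask(
    shape: tuple[int, int], pts: np.ndarray, widths: np.ndarray
) -> np.ndarray:
    """Pixels within the varying half-width of the polyline (disk union)."""
    r_lo = max(int(pts[:, 0].min() - widths.max() - 2), 0)
    r_hi = min(int(pts[:, 0].max() + widths.max() + 3), shape[0])
    c_lo = max(int(pts[:, 1].min() - widths.max() - 2), 0)
    c_hi = min(int(pts[:, 1].max() + widths.max() + 3), shape[1])
    mask = np.zeros(shape, dtype=bool)
    if r_hi <= r_lo or c_hi <= c_lo:
        return mask
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    d2 = (rr[:, :, None] - pts[None, None, :, 0]) ** 2 + (
        cc[:, :, None] - pts[None, None, :, 1]
    ) ** 2
    mask[r_lo:r_hi, c_lo:c_hi] = (d2 <= (widths[None, None, :] ** 2)).any(axis=2)
    return mask


def render_fish(
    params: PhenotypeParams,
    canvas: int = 256,
    noise: float = 3.0,
    rng: np.random.Generator | None = None,
    return_mask: bool = False,
):
    """Render one larva; returns (image, labels) or (image, labels, mask).

    The image is uint8 RGB with a bright noisy background and a mild
    illumination gradient; ``mask`` marks every painted object pixel.
    """
    if canvas < 128:
        raise ValueError("canvas must be >= 128 px")
    rng = rng or np.random.default_rng(0)
    labels = labels_for(params)
    validate_label_set(labels)

    img = np.empty((canvas, canvas, 3), dtype=np.float64)
    base = np.array([228.0, 224.0, 216.0])
    grad = np.linspace(-8.0, 8.0, canvas)[None, :, None]
    img[:] = base[None, None, :]
    img += grad
    mask = np.zeros((canvas, canvas), dtype=bool)
    rr, cc = np.mgrid[0:canvas, 0:canvas]
    center = (canvas / 2 + params.center_jitter[0], canvas / 2 + params.center_jitter[1])

    if params.dead:
        # irregular dark necrotic mass
        phi = np.arctan2(rr - center[0], cc - center[1])
        rad = (canvas / 256) * 30.0 * (
            1.0
            + 0.22 * np.sin(3 * phi + rng.uniform(0, 2 * np.pi))
            + 0.12 * np.sin(7 * phi + rng.uniform(0, 2 * np.pi))
        )
        blob = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= rad**2
        _paint(img, blob, (52.0, 47.0, 44.0))
        img[blob] += rng.normal(0.0, 9.0, size=(int(blob.sum()), 3))
        mask |= blob
    elif params.chorion:
        # dark ring enclosing a curled embryo
        ring_r = (canvas / 256) * 46.0
        d = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
        ring = np.abs(d - ring_r) <= 2.5
        interior = d < ring_r - 2.5
        img[interior] -= 14.0
        _paint(img, ring, (96.0, 92.0, 88.0))
        theta = np.linspace(0.3, 4.4, 90)
        spiral_r = np.linspace(0.62, 0.18, 90) * ring_r
        pts = np.stack(
            [center[0] + spiral_r * np.sin(theta), center[1] + spiral_r * np.cos(theta)],
            axis=1,
        )
        widths = np.interp(np.linspace(0, 1, 90), [0, 0.2, 1.0], [6.0, 5.0, 2.0]) * (canvas / 256)
        body = _thick_curve_mask((canvas, canvas), pts, widths)
        _paint(img, body, (74.0, 68.0, 62.0))
        head = _disk(rr, cc, tuple(pts[0]), 7.0 * canvas / 256)
        _paint(img, head, (70.0, 64.0, 58.0))
        mask |= ring | body | head
    else:
        pts, widths = _spine(params, canvas)
        body = _thick_curve_mask((canvas, canvas), pts, widths)
        _paint(img, body, (76.0, 70.0, 62.0))
        head_c = tuple(pts[6])
        head = _disk(rr, cc, head_c, 7.5 * canvas / 256)
        _paint(img, head, (70.0, 64.0, 58.0))
        eye = _disk(rr, cc, (head_c[0] - 2.0, head_c[1] - 1.0), 2.2 * canvas / 256)
        _paint(img, eye, (30.0, 28.0, 26.0))
        yolk_c = (pts[24, 0] + 7.0 * canvas / 256, pts[24, 1])
        yolk = ((rr - yolk_c[0]) / (9.0 * canvas / 256)) ** 2 + (
            (cc - yolk_c[1]) / (12.0 * canvas / 256)
        ) ** 2 <= 1.0
        if params.necrosed_yolk:
            _paint(img, yolk, (38.0, 34.0, 30.0))
            img[yolk] += rng.normal(0.0, 14.0, size=(int(yolk.sum()), 3))
        else:
            _paint(img, yolk, (120.0, 104.0, 82.0))
        mask |= body | head | eye | yolk
        if params.edema_radius > 0:
            ed_c = (yolk_c[0] + 4.0 * canvas / 256, yolk_c[1] - 4.0 * canvas / 256)
            ed = _disk(rr, cc, ed_c, params.edema_radius * canvas / 256)
            halo = ed & ~(body | head | yolk)
            img[halo] = 0.45 * img[halo] + 0.55 * np.array([196.0, 194.0, 188.0])
            # visible edema boundary
            edge = ed & ~_disk(rr, cc, ed_c, (params.edema_radius - 1.6) * canvas / 256)
            img[edge & ~(body | head | yolk)] = (150.0, 146.0, 140.0)
            mask |= ed
        if params.hemostasis_radius > 0:
            hem_c = (pts[18, 0] + 3.0 * canvas / 256, pts[18, 1] + 2.0 * canvas / 256)
            hem = _disk(rr, cc, hem_c, params.hemostasis_radius * canvas / 256)
            _paint(img, hem, (150.0, 32.0, 36.0))
            mask |= hem

    if noise > 0:
        img += rng.normal(0.0, noise, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    if return_mask:
        return img, labels, mask
    return img, labels


def generate_classification_set(
    n_per_class: int,
    classes: tuple[str, ...] = RENDERABLE_CLASSES,
    canvas: int = 256,
    seed: int = 0,
    noise: float = 3.0,
    out_dir: str | Path | None = None,
    session: int = 1,
    split: str = "LS",
):
    """Render a labeled image set; returns (images, manifest DataFrame).

    With ``out_dir`` the images are also written as PNGs next to a
    ``manifest.csv`` (same schema as real-data manifests). Each image gets
    its own RNG substream, so the set is reproducible per image.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    for name in classes:
        if name not in RENDERABLE_CLASSES:
            raise ValueError(f"unknown class {name!r}")
    images: list[np.ndarray] = []
    rows = []
    root = np.random.SeedSequence(seed & 0x7FFFFFFF)
    streams = root.spawn(len(classes) * n_per_class)
    k = 0
    for name in classes:
        for i in range(n_per_class):
            rng = np.random.default_rng(streams[k])
            params = class_params(name, rng)
            img, labels = render_fish(params, canvas=canvas, noise=noise, rng=rng)
            fname = f"{split}_{name.replace(' ', '').replace('/', '-')}_{i:03d}.png"
            images.append(img)
            rows.append(
                {
                    "filename": fname,
                    "labels": frozenset(labels),
                    "session": session,
                    "split": split,
                }
            )
            k += 1
    frame = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, row in zip(images, frame.itertuples()):
            Image.fromarray(img).save(out / row.filename)
        write_manifest(frame, out / "manifest.csv")
    return images, frame


@dataclass(frozen=True)
class PlateSpec:
    """A dose-response plate: compound, doses and true log-logistic curves.

    Defaults emulate a caffeine-like exposure: doses 0–7 mM in batches of 25
    embryos, survival midpoint log10 LC50 = 0.82 and teratogenicity midpoint
    log10 EC50 = -0.9 (steep lethality, shallow teratogenicity).
    """

    compound: str = "compound-A"
    concentrations: tuple[float, ...] = (0.0, 0.5, 1.0, 3.0, 5.0, 7.0)
    n_per_conc: int = 25
    log_lc50: float = 0.82
    log_ec50: float = -0.9
    hill_surv: float = 6.0
    hill_terat: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.concentrations) < 4 or 0.0 not in self.concentrations:
            raise ValueError("need >= 4 concentrations including a control (0)")
        if self.n_per_conc < 5:
            raise ValueError("need >= 5 embryos per concentration")


def _logistic_up(logc: np.ndarray, log_x50: float, hill: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (hill * (log_x50 - logc)))


def plate_truth_curves(spec: PlateSpec, conc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(p_dead, p_abnormal_among_survivors) at each concentration; 0 at control."""
    conc = np.asarray(conc, dtype=float)
    p_dead = np.zeros_like(conc)
    p_abn = np.zeros_like(conc)
    nz = conc > 0
    p_dead[nz] = _logistic_up(np.log10(conc[nz]), spec.log_lc50, spec.hill_surv)
    p_abn[nz] = _logistic_up(np.log10(conc[nz]), spec.log_ec50, spec.hill_terat)
    return p_dead, p_abn


def generate_plate(
    spec: PlateSpec,
    out_dir: str | Path | None = None,
    render: bool = False,
    canvas: int = 256,
    noise: float = 3.0,
):
    """Simulate one plate; returns (images or None, truth manifest DataFrame).

    Each embryo dies with the survival-curve probability at its dose;
    survivors are abnormal with the teratogenicity-curve probability, the
    defect drawn uniformly among the non-lethal defect classes. Images are
    rendered only on request (label-level studies don't need pixels).
    """
    rng = np.random.default_rng(spec.seed & 0x7FFFFFFF)
    rows = []
    images: list[np.ndarray] | None = [] if (render or out_dir is not None) else None
    p_dead_all, p_abn_all = plate_truth_curves(spec, np.asarray(spec.concentrations))
    k = 0
    for conc, p_dead, p_abn in zip(spec.concentrations, p_dead_all, p_abn_all):
        for i in range(spec.n_per_conc):
            if rng.random() < p_dead:
                cls = "Dead"
            elif rng.random() < p_abn:
                cls = str(rng.choice(_DEFECT_CHOICES))
            else:
                cls = "Normal"
            params = class_params(cls, rng)
            labels = labels_for(params)
            fname = f"{spec.compound}_{conc:g}_{i:03d}.png"
            rows.append(
                {
                    "filename": fname,
                    "labels": labels,
                    "session": 1,
                    "split": "VS",
                    "compound": spec.compound,
                    "concentration": conc,
                }
            )
            if images is not None:
                img, _ = render_fish(params, canvas=canvas, noise=noise, rng=rng)
                images.append(img)
            k += 1
    frame = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, row in zip(images, frame.itertuples()):
            Image.fromarray(img).save(out / row.filename)
        write_manifest(frame, out / "manifest.csv")
    return images, frame
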