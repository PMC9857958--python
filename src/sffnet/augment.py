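"""Seeded geometric augmentation (rotation, scaling, translation).

Training and validation patches are expanded with random affine copies;
held-out test patches are never augmented — the expander refuses them
outright, so evaluation can only ever see unmodified patches.

Each augmented copy is fully determined by ``(spec.seed, the source
patch's identifiers, draw_index)``: the transform parameters are drawn
from a generator seeded with exactly that triple, so re-running a
pipeline reproduces every copy bit for bit regardless of iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .semi_sp import ROIPatch

__all__ = ["AugmentSpec", "geometric_transform", "random_geometric", "expand_dataset"]


@dataclass(frozen=True)
class AugmentSpec:
    """Parameter ranges for one family of random geometric transforms.

    ``max_translation`` is a fraction of the patch side; ``scale_range`` is
    multiplicative; ``rotation_range_deg`` is the symmetric angle bound.
    Defaults are mild: the phantom/lesion geometry should be perturbed, not
    destroyed.
    """

    max_translation: float = 0.1
    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_range_deg: float = 15.0
    copies_per_image: int = 3
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range must satisfy 0 < lo <= hi")
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")
        if self.max_translation < 0:
            raise ValueError("max_translation must be >= 0")


def _patch_key(patch: ROIPatch) -> int:
    prov = patch.provenance
    ident = "|".join(
        str(prov.get(k, "")) for k in ("patient_id", "lesion_id", "slice_index")
    )
    return zlib.crc32(f"{ident}|{patch.strategy}".encode())


def _rng_for(spec: AugmentSpec, patch: ROIPatch, draw_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(_patch_key(patch), draw_index))
    )


def geometric_transform(
    pixels: np.ndarray,
    rotation_deg: float,
    scale: float,
    shift: tuple[float, float],
) -> np.ndarray:
    """Rotate, then scale (about the patch center), then translate.

    The three elementary transforms are composed into a single affine map
    and resampled once with bilinear interpolation and zero fill, so no
    intermediate interpolation artifacts accumulate.  ``shift`` is
    (rows, cols) in pixels.
    """
    n = pixels.shape[0]
    angle = np.deg2rad(rotation_deg)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    matrix = rot.T / scale  # output->input map: inverse of (rot * scale)
    center = (n - 1) / 2.0
    offset = center - matrix @ (np.array([center, center]) + np.asarray(shift))
    out = ndimage.affine_transform(
        pixels.astype(np.float64),
        matrix,
        offset=offset,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def random_geometric(patch: ROIPatch, spec: AugmentSpec, draw_index: int = 0) -> ROIPatch:
    """One seeded random affine copy of a patch.

    Parameters are drawn from the generator keyed by ``(spec.seed, patch
    identifiers, draw_index)`` and applied by :func:`geometric_transform`.
    """
    rng = _rng_for(spec, patch, draw_index)
    n = patch.pixels.shape[0]
    angle = rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg)
    scale = rng.uniform(*spec.scale_range)
    shift = rng.uniform(-spec.max_translation * n, spec.max_translation * n, size=2)
    out = geometric_transform(patch.pixels, angle, scale, (shift[0], shift[1]))
    prov = dict(patch.provenance)
    prov.update(
        {
            "augmented": True,
            "draw_index": draw_index,
            "augment_seed": spec.seed,
            "transform": {
                "rotation_deg": float(angle),
                "scale": float(scale),
                "shift_rows": float(shift[0]),
                "shift_cols": float(shift[1]),
            },
        }
    )
    return ROIPatch(out, patch.strategy, prov)


def expand_dataset(
    patches: list[ROIPatch],
    spec: AugmentSpec,
    target_per_class: dict[str, int] | None = None,
) -> list[ROIPatch]:
    """Originals plus ``copies_per_image`` augmented copies of each patch.

    ``target_per_class`` optionally grows each class to an absolute count
    instead (class-dependent expansion): after the uniform copies, extra
    augmented copies are drawn round-robin over that class's source
    patches with increasing draw indices until the target is met.  Raises
    if any input carries a test-split provenance flag: the held-out set
    must stay untouched.
    """
    for p in patches:
        if p.provenance.get("split") == "test":
            raise ValueError(
                "refusing to augment test-split patches "
                f"(lesion {p.provenance.get('lesion_id')!r})"
            )
    out: list[ROIPatch] = list(patches)
    for p in patches:
        for k in range(spec.copies_per_image):
            out.append(random_geometric(p, spec, draw_index=k))
    if target_per_class:
        by_class: dict[str, list[ROIPatch]] = {}
        counts: dict[str, int] = {}
        for p in patches:
            label = p.provenance.get("class_label")
            by_class.setdefault(label, []).append(p)
        for p in out:
            label = p.provenance.get("class_label")
            counts[label] = counts.get(label, 0) + 1
        for label, target in target_per_class.items():
            sources = by_class.get(label)
            if not sources:
                raise ValueError(f"no source patches of class {label!r} to expand")
            i = 0
            while counts.get(label, 0) < target:
                src = sources[i % len(sources)]
                draw = spec.copies_per_image + i // len(sources)
                out.append(random_geometric(src, spec, draw_index=draw))
                counts[label] = counts.get(label, 0) + 1
                i += 1
    return out
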