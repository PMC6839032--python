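"""Dataset assembly: synthetic scenes -> aligned training samples on disk or in memory.

Each sample couples a rendered root image with its training targets
(binary class masks and feature heat maps, both at half the image side —
the network's output resolution, with coordinates scaled by 0.5).
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
from PIL import Image

from .core import ArchitectureParams, RootSystem
from .rsml import write_rsml
from .synthetic import generate_architecture, render_image
from .targets import render_class_masks, render_heatmaps
from .train import Sample

__all__ = ["make_sample", "make_dataset", "save_dataset"]

#: ground-truth stroke width at native resolution, px
STROKE_WIDTH_NATIVE = 8.0


def make_sample(params: ArchitectureParams) -> tuple[Sample, RootSystem]:
    """Generate one scene and its aligned training targets."""
    rs = generate_architecture(params)
    img = render_image(rs, params)  # (H, W, 3) in [0, 1]
    w, h = params.image_size
    out_shape = (h // 2, w // 2)
    masks = render_class_masks(
        rs, out_shape, stroke_width=STROKE_WIDTH_NATIVE / 2.0, scale=0.5
    )
    heats = render_heatmaps(rs, out_shape, sigma=1.0, scale=0.5)
    image_chw = np.ascontiguousarray(img.transpose(2, 0, 1)).astype(np.float32)
    return Sample(image=image_chw, masks=masks, heats=heats), rs


def make_dataset(
    n: int, params: ArchitectureParams, seed: int | None = None
) -> tuple[list[Sample], list[RootSystem]]:
    """Generate ``n`` samples, one deterministic substream per scene."""
    base = params.rng_seed if seed is None else seed
    samples, systems = [], []
    i = 0
    while len(samples) < n and i < 4 * n + 32:
        p = replace(
            params,
            rng_seed=int(
                np.random.SeedSequence([base, i]).generate_state(1)[0] % (2**31)
            ),
        )
        i += 1
        try:
            s, rs = make_sample(p)
        except RuntimeError:  # over-constrained scene; try the next substream
            continue
        samples.append(s)
        systems.append(rs)
    if len(samples) < n:
        raise RuntimeError(f"could only generate {len(samples)}/{n} scenes")
    return samples, systems


def _save_png(path: Path, arr: np.ndarray) -> None:
    a = np.clip(np.asarray(arr), 0.0, 1.0)
    if a.ndim == 3 and a.shape[0] in (1, 3):  # channel-first -> channel-last
        a = a.transpose(1, 2, 0)
    if a.ndim == 3 and a.shape[2] == 1:
        a = a[..., 0]
    Image.fromarray((a * 255).astype(np.uint8)).save(str(path))


def save_dataset(
    out_dir: str | Path,
    n: int,
    params: ArchitectureParams,
    seed: int | None = None,
    val_fraction: float = 0.2,
) -> Path:
    """Write ``n`` image/RSML/target triples plus a train/val manifest.

    Layout: ``images/{i}.png``, ``rsml/{i}.rsml``, ``targets/{i}_mask1.png``
    etc., and ``manifest.json`` listing the split.  Deterministic for a
    fixed seed.
    """
    out = Path(out_dir)
    for sub in ("images", "rsml", "targets"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    samples, systems = make_dataset(n, params, seed=seed)
    names = []
    for i, (s, rs) in enumerate(zip(samples, systems)):
        name = f"{i:04d}"
        names.append(name)
        _save_png(out / "images" / f"{name}.png", s.image)
        write_rsml(
            rs,
            {"label": name, "size": params.image_size},
            out / "rsml" / f"{name}.rsml",
        )
        _save_png(out / "targets" / f"{name}_mask1.png", s.masks.order1)
        _save_png(out / "targets" / f"{name}_mask2.png", s.masks.order2)
        _save_png(out / "targets" / f"{name}_seed.png", s.heats.seed)
        _save_png(out / "targets" / f"{name}_tip1.png", s.heats.tip1)
        _save_png(out / "targets" / f"{name}_tip2.png", s.heats.tip2)
    n_val = int(round(n * val_fraction))
    manifest = {
        "n": n,
        "style": params.style,
        "image_size": list(params.image_size),
        "train": names[: n - n_val],
        "val": names[n - n_val :],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
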