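"""File I/O: NPZ bundles (lossless), 16-bit TIFF images, JSON logs.

NPZ is the lossless container for complex fields, stacks and checkpoints;
TIFF carries intensity-like images quantized to 16 bits with the scale
recorded in the image description, giving a round-trip error bounded by
2^-16 of the range.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .optics import IlluminationSet
from .simulator import ComplexField, FPMStack
from .tissue import STAIN_CHANNELS, StainBundle

__all__ = [
    "save_stack", "load_stack",
    "save_field", "load_field",
    "save_bundle", "load_bundle",
    "write_tiff16", "read_tiff16",
    "save_json", "load_json",
    "save_state", "load_state",
]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dict__") and not isinstance(obj, (str, bytes)):
        try:
            json.dumps(obj)
            return obj
        except TypeError:
            return repr(obj)
    return obj


def save_json(path, payload: dict):
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


# -- stacks ------------------------------------------------------------------

def save_stack(path, stack: FPMStack):
    np.savez(path, images=stack.images, wavevectors=stack.illumination.wavevectors,
             gain=stack.gain, noise_sd=stack.noise_sd,
             meta=json.dumps(_jsonable(stack.meta)))


def load_stack(path) -> FPMStack:
    with np.load(path, allow_pickle=False) as z:
        return FPMStack(z["images"], IlluminationSet(z["wavevectors"]),
                        gain=float(z["gain"]), noise_sd=float(z["noise_sd"]),
                        meta=json.loads(str(z["meta"])))


def save_stack_tiff(path, stack: FPMStack):
    """Multi-page TIFF of the raw intensities plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.images.astype(np.float32))
    save_json(path.with_suffix(".json"),
              {"wavevectors": stack.illumination.wavevectors,
               "gain": stack.gain, "noise_sd": stack.noise_sd, "meta": stack.meta})


# -- complex fields ----------------------------------------------------------

def save_field(path, field: ComplexField, **extra_arrays):
    np.savez(path, amplitude=field.amplitude, phase=field.phase,
             pixel_size=field.pixel_size, **extra_arrays)


def load_field(path) -> ComplexField:
    with np.load(path, allow_pickle=False) as z:
        return ComplexField(z["amplitude"], z["phase"], float(z["pixel_size"]))


# -- 16-bit TIFF --------------------------------------------------------------

def write_tiff16(path, image: np.ndarray):
    """Quantize to uint16 recording (lo, hi) in the description tag."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    scale = hi - lo if hi > lo else 1.0
    quant = np.round((image - lo) / scale * 65535).astype(np.uint16)
    tifffile.imwrite(path, quant, description=json.dumps({"lo": lo, "hi": hi}))


def read_tiff16(path) -> np.ndarray:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        desc = page.tags.get("ImageDescription")
        arr = page.asarray().astype(float)
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                lo, hi = meta["lo"], meta["hi"]
                scale = hi - lo if hi > lo else 1.0
                return arr / 65535.0 * scale + lo
            except (ValueError, KeyError):
                pass
        return arr / 65535.0


# -- stain bundles -------------------------------------------------------------

def save_bundle(directory, bundle: StainBundle, sample_id: str):
    """Paired-TIFF layout: {id}_input.tif plus one TIFF per stain channel."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_tiff16(directory / f"{sample_id}_input.tif", bundle.interface)
    for name in STAIN_CHANNELS:
        write_tiff16(directory / f"{sample_id}_{name}.tif", getattr(bundle, name))


def load_bundle(directory, sample_id: str) -> StainBundle:
    directory = Path(directory)
    arrays = {"interface": read_tiff16(directory / f"{sample_id}_input.tif")}
    for name in STAIN_CHANNELS:
        arrays[name] = read_tiff16(directory / f"{sample_id}_{name}.tif")
    clip = {k: np.clip(v, 0.0, 1.0) for k, v in arrays.items()}
    return StainBundle(**clip)


def list_bundle_ids(directory) -> list:
    directory = Path(directory)
    return sorted(p.name[:-len("_input.tif")]
                  for p in directory.glob("*_input.tif"))


# -- model checkpoints ---------------------------------------------------------

def save_state(path, module, config: dict | None = None):
    """NPZ checkpoint of a module's state dict plus a JSON config blob."""
    state = module.state_dict()
    np.savez(path, __config__=json.dumps(_jsonable(config or {})),
             **{k: v for k, v in state.items()})


def load_state(path) -> tuple:
    """Returns (state dict, config dict)."""
    with np.load(path, allow_pickle=False) as z:
        config = json.loads(str(z["__config__"]))
        state = {k: z[k] for k in z.files if k != "__config__"}
    return state, config
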