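"""Reading and writing multichannel TIFF stacks and tabular results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .config import ChannelMapConfig
from .errors import FormatError
from .zstack import ZStack

_AXES = "CZYX"


def write_stack(stack: ZStack, path: str | Path) -> None:
    """Write a ZStack as a float32 multichannel TIFF (axes CZYX).

    Channel roles and the z-spacing travel in the shaped-TIFF metadata so a
    round-trip read recovers them without external configuration.
    """
    roles = sorted(stack.channels)
    data = np.stack([stack.channels[r] for r in roles]).astype(np.float32)
    tifffile.imwrite(
        path, data,
        metadata={
            "axes": _AXES,
            "channel_roles": roles,
            "z_step_um": stack.z_step,
            "pixel_size_um": stack.pixel_size,
            "glyx_metadata": json.dumps(stack.metadata, default=str),
        })


def read_stack(path: str | Path,
               channels: ChannelMapConfig | None = None,
               z_step_default: float = 0.2) -> ZStack:
    """Read a multichannel TIFF into a ZStack.

    Channel roles are taken from the file's own metadata when present
    (stacks written by :func:`write_stack`), else mapped by index from the
    ``channels`` configuration.  The z-spacing resolves from metadata first,
    then ``z_step_default``.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = (tf.shaped_metadata or [{}])[0]

    if data.ndim == 3:
        data = data[np.newaxis]
    if data.ndim != 4:
        raise FormatError(
            f"expected a (C, Z, Y, X) stack, got {data.ndim} axes")

    roles = meta.get("channel_roles")
    if roles is not None:
        if len(roles) != data.shape[0]:
            raise FormatError(
                f"channel axis has {data.shape[0]} planes but metadata "
                f"names {len(roles)} roles")
        channel_map = {role: data[i] for i, role in enumerate(roles)}
    else:
        channels = channels or ChannelMapConfig()
        mapping = {"membrane": channels.membrane, "probe": channels.probe}
        if channels.nuclei is not None:
            mapping["nuclei"] = channels.nuclei
        for role, idx in mapping.items():
            if idx >= data.shape[0]:
                raise FormatError(
                    f"channel axis has {data.shape[0]} planes; role "
                    f"{role!r} maps to missing index {idx}")
        channel_map = {role: data[idx] for role, idx in mapping.items()}

    if "probe" not in channel_map:
        raise FormatError("stack lacks a probe channel")

    z_step = float(meta.get("z_step_um", z_step_default))
    pixel_size = float(meta.get("pixel_size_um", 0.1))
    metadata = {}
    if "glyx_metadata" in meta:
        try:
            metadata = json.loads(meta["glyx_metadata"])
        except (TypeError, ValueError):
            metadata = {}
    return ZStack(channels={k: np.asarray(v, dtype=float)
                            for k, v in channel_map.items()},
                  z_step=z_step, pixel_size=pixel_size, metadata=metadata)
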