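"""OME-TIFF stack and CSV table I/O."""

from __future__ import annotations

import numpy as np
import tifffile

from .synthetic import ImageStack


def write_stack(stack: ImageStack, path) -> None:
    """Write a single-channel stack as OME-TIFF with physical voxel sizes
    (micrometre units in the metadata, as OME expects)."""
    vx, vy, vz = stack.voxel_size
    tifffile.imwrite(
        path,
        np.asarray(stack.data, dtype=np.float32),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": vx / 1000.0, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": vy / 1000.0, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": vz / 1000.0, "PhysicalSizeZUnit": "µm",
            "Name": stack.channel,
        },
    )


def read_stack(path, channel: str = "",
               default_voxel_size=(69.4, 69.4, 100.0)) -> ImageStack:
    """Read an OME-TIFF stack; voxel sizes fall back to the microscope
    defaults when the metadata lacks them."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        voxel = list(default_voxel_size)
        name = channel
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                for i, key in enumerate(("PhysicalSizeX", "PhysicalSizeY",
                                         "PhysicalSizeZ")):
                    if px.get(key):
                        voxel[i] = float(px.get(key)) * 1000.0
            img = root.find(".//ome:Image", ns)
            if not name and img is not None and img.get("Name"):
                name = img.get("Name")
    if data.ndim == 2:
        data = data[None, :, :]
    return ImageStack(data=data, voxel_size=tuple(voxel), channel=name or "")
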