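"""Minimal MetaImage (.mha) reader/writer.

Supports the single-file, uncompressed variant only, which is all this
package needs for exchanging scalar 3D volumes.
"""

from __future__ import annotations

import os

import numpy as np

_MET_TO_DTYPE = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_UINT": np.uint32,
    "MET_INT": np.int32,
    "MET_ULONG": np.uint64,
    "MET_LONG": np.int64,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_DTYPE_TO_MET = {np.dtype(v): k for k, v in _MET_TO_DTYPE.items()}


def read_mha(path: str | os.PathLike) -> np.ndarray:
    """Read an uncompressed local-data .mha file into a 3D array (x, y, z order)."""
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated MetaImage header")
            key, _, value = line.decode("ascii", "replace").partition("=")
            key, value = key.strip(), value.strip()
            header[key] = value
            if key == "ElementDataFile":
                break
        if header.get("ElementDataFile") != "LOCAL":
            raise ValueError(f"{path}: only ElementDataFile = LOCAL is supported")
        if header.get("CompressedData", "False").lower() == "true":
            raise ValueError(f"{path}: compressed MetaImage data is not supported")
        ndim = int(header.get("NDims", "3"))
        if ndim != 3:
            raise ValueError(f"{path}: expected NDims = 3, got {ndim}")
        dims = tuple(int(d) for d in header["DimSize"].split())
        dtype = _MET_TO_DTYPE.get(header.get("ElementType", ""))
        if dtype is None:
            raise ValueError(f"{path}: unsupported ElementType {header.get('ElementType')!r}")
        count = int(np.prod(dims))
        data = np.fromfile(fh, dtype=dtype, count=count)
    if data.size != count:
        raise ValueError(f"{path}: expected {count} voxels, read {data.size}")
    # MetaImage stores x fastest; reshape in z,y,x then transpose to x,y,z.
    return np.ascontiguousarray(data.reshape(dims[::-1]).transpose(2, 1, 0))


def write_mha(path: str | os.PathLike, volume: np.ndarray) -> None:
    """Write a 3D array to an uncompressed local-data .mha file."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    met_type = _DTYPE_TO_MET.get(volume.dtype)
    if met_type is None:
        volume = volume.astype(np.float64)
        met_type = "MET_DOUBLE"
    header = "\n".join(
        [
            "ObjectType = Image",
            "NDims = 3",
            "BinaryData = True",
            "BinaryDataByteOrderMSB = False",
            "CompressedData = False",
            f"DimSize = {volume.shape[0]} {volume.shape[1]} {volume.shape[2]}",
            f"ElementType = {met_type}",
            "ElementDataFile = LOCAL",
            "",
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(volume.transpose(2, 1, 0)).tobytes())
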