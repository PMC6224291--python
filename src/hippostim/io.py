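"""Small file-format helpers: NRRD label volumes and SWC morphologies.

Both formats are simple enough to read and write directly; the functions here
stick to the subset the package produces (3-D uint8 raw-encoded NRRD, and
one-sample-per-compartment SWC).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_nrrd", "read_nrrd", "write_swc", "read_swc"]

_NRRD_TYPES = {
    "uint8": np.uint8,
    "unsigned char": np.uint8,
    "int16": np.int16,
    "uint16": np.uint16,
    "int32": np.int32,
    "float": np.float32,
    "double": np.float64,
}


def write_nrrd(path, data: np.ndarray, spacings, origin=(0.0, 0.0, 0.0)) -> None:
    """Write a 3-D array as a detached-header-free NRRD0004 file.

    ``spacings`` and ``origin`` are per-axis and recorded in micrometres.
    Data is written raw, little-endian, C (row-major) order.
    """
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("write_nrrd expects a 3-D array")
    spacings = np.broadcast_to(np.asarray(spacings, float), (3,))
    origin = np.asarray(origin, float)
    name = {np.dtype(np.uint8): "uint8", np.dtype(np.int16): "int16",
            np.dtype(np.uint16): "uint16", np.dtype(np.int32): "int32",
            np.dtype(np.float32): "float", np.dtype(np.float64): "double"}.get(data.dtype)
    if name is None:
        raise ValueError(f"unsupported dtype for NRRD: {data.dtype}")
    header = [
        "NRRD0004",
        "# hippostim label volume (units: micrometer)",
        f"type: {name}",
        "dimension: 3",
        f"sizes: {data.shape[0]} {data.shape[1]} {data.shape[2]}",
        f"spacings: {spacings[0]:.9g} {spacings[1]:.9g} {spacings[2]:.9g}",
        f"axis mins: {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}",
        "encoding: raw",
        "endian: little",
        "",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        # NRRD convention: fastest axis first; C-order array -> write transposed
        fh.write(np.ascontiguousarray(data.T).astype(data.dtype.newbyteorder("<")).tobytes())


def read_nrrd(path):
    """Read an NRRD file written by :func:`write_nrrd`.

    Returns ``(data, spacings, origin)``.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    head, _, body = raw.partition(b"\n\n")
    fields = {}
    lines = head.decode("ascii").splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ValueError(f"{path}: not an NRRD file")
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        fields[key.strip().lower()] = val.strip()
    if fields.get("encoding", "raw") != "raw":
        raise ValueError("only raw encoding is supported")
    dtype = np.dtype(_NRRD_TYPES[fields["type"]]).newbyteorder(
        "<" if fields.get("endian", "little") == "little" else ">")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    spacings = np.array([float(s) for s in fields.get("spacings", "1 1 1").split()])
    origin = np.array([float(s) for s in fields.get("axis mins", "0 0 0").split()])
    n = int(np.prod(sizes))
    data = np.frombuffer(body[: n * dtype.itemsize], dtype=dtype)
    if data.size != n:
        raise ValueError("NRRD payload shorter than header sizes")
    # stored fastest-axis-first
    data = data.reshape(sizes[::-1]).T
    return np.ascontiguousarray(data), spacings, origin


# --------------------------------------------------------------------------
# SWC

def write_swc(path, morphology) -> None:
    """Write a morphology as SWC (type codes 1 soma, 2 axon, 3 dendrite).

    Sample 1 is the root compartment's proximal point; sample ``i + 2`` is
    compartment i's distal point, so the file round-trips exactly.
    """
    m = morphology
    n = len(m.parent)
    lines = ["# hippostim SWC export", "# id type x y z radius parent"]
    r0 = m.diam[0] / 2.0
    p0 = m.prox[0]
    lines.append(f"1 {int(m.region[0])} {p0[0]:.6g} {p0[1]:.6g} {p0[2]:.6g} {r0:.6g} -1")
    for i in range(n):
        d = m.dist[i]
        par = 1 if m.parent[i] < 0 else int(m.parent[i]) + 2
        lines.append(
            f"{i + 2} {int(m.region[i])} {d[0]:.6g} {d[1]:.6g} {d[2]:.6g} "
            f"{m.diam[i] / 2.0:.6g} {par}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path):
    """Read an SWC file back into a :class:`~hippostim.cablenet.Morphology`."""
    from .cablenet.morphology import Morphology

    ids, types, xyz, radius, parents = [], [], [], [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        ids.append(int(parts[0]))
        types.append(int(parts[1]))
        xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
        radius.append(float(parts[5]))
        parents.append(int(parts[6]))
    idx = {s: k for k, s in enumerate(ids)}
    xyz = np.asarray(xyz)
    roots = [k for k, p in enumerate(parents) if p == -1]
    if len(roots) != 1:
        raise ValueError("SWC must contain exactly one root sample")
    root = roots[0]
    # compartments = all non-root samples, in file order
    comp_of_sample = {}
    parent_c, prox, dist, diam, region = [], [], [], [], []
    for k in range(len(ids)):
        if k == root:
            continue
        ci = len(parent_c)
        comp_of_sample[k] = ci
        pk = idx[parents[k]]
        parent_c.append(-1 if pk == root else comp_of_sample[pk])
        prox.append(xyz[pk])
        dist.append(xyz[k])
        diam.append(2.0 * radius[k])
        region.append(types[k])
    return Morphology(
        parent=np.asarray(parent_c, int),
        prox=np.asarray(prox, float),
        dist=np.asarray(dist, float),
        diam=np.asarray(diam, float),
        region=np.asarray(region, int),
    )
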