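"""Plain-text configuration I/O: XYZ (with box metadata) and minimal PDB.

The XYZ comment line carries the orthorhombic box as ``box: Lx Ly Lz``;
multi-frame files simply concatenate frames.  PDB output writes a CRYST1
record and ATOM records — enough for visualisation, nothing more.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_xyz", "read_xyz", "write_pdb", "read_pdb"]


def write_xyz(path, coords, labels, box=None, append: bool = False) -> None:
    """Write one frame (or, with ``coords.ndim == 3``, many frames) of XYZ."""
    coords = np.asarray(coords, dtype=float)
    frames = coords[None] if coords.ndim == 2 else coords
    comment = "" if box is None else "box: " + " ".join(f"{b:.8f}" for b in np.asarray(box))
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for frame in frames:
            fh.write(f"{frame.shape[0]}\n{comment}\n")
            for lab, (x, y, z) in zip(labels, frame):
                fh.write(f"{lab} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path):
    """Read all frames; returns ``(coords (F, N, 3), labels, box or None)``."""
    frames, labels, box = [], None, None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        if comment.strip().startswith("box:"):
            box = np.array([float(v) for v in comment.split()[1:4]])
        block = lines[i + 2 : i + 2 + n]
        labels = [ln.split()[0] for ln in block]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    return np.asarray(frames, dtype=float), labels, box


def write_pdb(path, coords, labels, box) -> None:
    """Minimal PDB: CRYST1 plus ATOM records (orthorhombic, angles 90°)."""
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float)
    with open(path, "w") as fh:
        fh.write(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for i, (lab, (x, y, z)) in enumerate(zip(labels, coords), start=1):
            name = lab[:4]
            fh.write(
                f"ATOM  {i:5d} {name:<4s} MOL A{1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {lab[:2]:>2s}\n"
            )
        fh.write("END\n")


def read_pdb(path):
    """Read a minimal PDB written by :func:`write_pdb`; returns (coords, labels, box)."""
    coords, labels, box = [], [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
            elif line.startswith(("ATOM", "HETATM")):
                labels.append(line[12:16].strip())
                coords.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
    return np.asarray(coords, dtype=float), labels, box
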