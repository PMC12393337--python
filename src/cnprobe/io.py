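"""Plain-text I/O: sweep/spectrum CSV, multi-frame XYZ, charge and label tables.

Sweep and spectrum CSVs carry ``# key=value`` metadata header lines followed
by a normal CSV table.  Trajectories use the standard multi-frame XYZ layout
(element x y z per atom, Angstrom); a thin adapter accepts an MDAnalysis
Universe so standard MD trajectory formats can be analyzed with the same
machinery.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import BandFit
from .spectra import RawSweep, Spectrum

__all__ = [
    "write_sweep_csv", "read_sweep_csv",
    "write_spectrum_csv", "read_spectrum_csv", "write_jcamp",
    "write_xyz", "read_xyz",
    "write_charge_table", "read_charge_table",
    "write_labels", "read_labels",
    "write_fit_json", "read_fit_json",
    "trajectory_from_universe",
]


def _write_meta_csv(path, meta: dict, frame: pd.DataFrame) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, index=False)


def _read_meta_csv(path) -> tuple[dict, pd.DataFrame]:
    path = Path(path)
    meta: dict = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                try:
                    parsed: object = json.loads(value.strip())
                except json.JSONDecodeError:
                    parsed = value.strip()
                meta[key.strip()] = parsed
    return meta, pd.read_csv(path, skiprows=skip)


def write_sweep_csv(sweep: RawSweep, path) -> None:
    frame = pd.DataFrame({
        "wavenumber_cm1": sweep.wavenumber,
        "v_ref_V": sweep.v_ref,
        "v_bal_V": sweep.v_bal,
    })
    if sweep.has_quadrature:
        frame["v_ref_q_V"] = sweep.v_ref_q
        frame["v_bal_q_V"] = sweep.v_bal_q
    _write_meta_csv(path, sweep.meta, frame)


def read_sweep_csv(path) -> RawSweep:
    meta, frame = _read_meta_csv(path)
    return RawSweep(
        frame["wavenumber_cm1"].to_numpy(float),
        frame["v_ref_V"].to_numpy(float),
        frame["v_bal_V"].to_numpy(float),
        frame["v_ref_q_V"].to_numpy(float) if "v_ref_q_V" in frame else None,
        frame["v_bal_q_V"].to_numpy(float) if "v_bal_q_V" in frame else None,
        meta,
    )


def write_spectrum_csv(spec: Spectrum, path) -> None:
    frame = pd.DataFrame({
        "wavenumber_cm1": spec.wavenumber,
        "absorbance_OD": spec.absorbance,
    })
    if spec.se is not None:
        frame["se_OD"] = spec.se
    meta = dict(spec.meta)
    meta["history"] = json.dumps(spec.history)
    _write_meta_csv(path, meta, frame)


def read_spectrum_csv(path) -> Spectrum:
    meta, frame = _read_meta_csv(path)
    history = meta.pop("history", [])
    if isinstance(history, str):
        history = json.loads(history)
    return Spectrum(
        frame["wavenumber_cm1"].to_numpy(float),
        frame["absorbance_OD"].to_numpy(float),
        frame["se_OD"].to_numpy(float) if "se_OD" in frame else None,
        history=list(history),
        meta=meta,
    )


def write_jcamp(spec: Spectrum, path, title: str = "cnprobe spectrum") -> None:
    """Minimal JCAMP-DX (XYPOINTS) export of an absorbance spectrum."""
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##FIRSTX={spec.wavenumber[0]:.6g}",
        f"##LASTX={spec.wavenumber[-1]:.6g}",
        f"##NPOINTS={spec.wavenumber.size}",
        "##XYPOINTS=(XY..XY)",
    ]
    lines += [f"{x:.6f}, {y:.8g}" for x, y in zip(spec.wavenumber, spec.absorbance)]
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(coords: np.ndarray, elements: Sequence[str], path,
              comment: str = "") -> None:
    """Multi-frame XYZ: n_atoms / comment / element x y z, one block per frame."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_frames, n_atoms, _ = coords.shape
    with Path(path).open("w") as fh:
        for i in range(n_frames):
            fh.write(f"{n_atoms}\n")
            fh.write(f"{comment} frame={i}\n")
            for el, (x, y, z) in zip(elements, coords[i]):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> tuple[np.ndarray, list[str]]:
    """Read a multi-frame XYZ file -> (coords (n_frames, n_atoms, 3), elements)."""
    frames: list[np.ndarray] = []
    elements: list[str] = []
    with Path(path).open() as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n_atoms = int(lines[i].strip())
        block = lines[i + 2: i + 2 + n_atoms]
        if len(block) < n_atoms:
            raise ValueError("truncated XYZ frame")
        frame = np.empty((n_atoms, 3))
        frame_elements = []
        for j, line in enumerate(block):
            parts = line.split()
            frame_elements.append(parts[0])
            frame[j] = [float(p) for p in parts[1:4]]
        if not frames:
            elements = frame_elements
        frames.append(frame)
        i += 2 + n_atoms
        while i < len(lines) and not lines[i].strip():
            i += 1
    if not frames:
        raise ValueError("no frames in XYZ file")
    return np.stack(frames), elements


def write_charge_table(charges: pd.DataFrame, path) -> None:
    charges[["atom_index", "charge_e", "role"]].to_csv(path, index=False)


def read_charge_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"atom_index", "charge_e", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"charge table must have columns {sorted(required)}")
    return df


def write_labels(labels: np.ndarray, path) -> None:
    pd.DataFrame({
        "frame_index": np.arange(len(labels)),
        "state": np.where(np.asarray(labels, dtype=bool), "bonded", "free"),
    }).to_csv(path, index=False)


def read_labels(path) -> np.ndarray:
    df = pd.read_csv(path)
    return (df["state"] == "bonded").to_numpy()


def write_fit_json(fits: Sequence[BandFit], path, meta: dict | None = None) -> None:
    payload = {"fits": [f.to_dict() for f in fits], "meta": meta or {}}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def read_fit_json(path) -> list[BandFit]:
    payload = json.loads(Path(path).read_text())
    fits = []
    for d in payload["fits"]:
        d = dict(d)
        d["window"] = tuple(d["window"])
        fits.append(BandFit(**d))
    return fits


def trajectory_from_universe(universe) -> tuple[np.ndarray, list[str]]:
    """Adapter: extract (coords, elements) from an MDAnalysis Universe.

    Lets trajectories in any format MDAnalysis reads (XTC/DCD/PDB/XYZ, ...)
    feed :func:`cnprobe.fields.analyze_trajectory`; the caller supplies the
    charge table separately.
    """
    coords = np.stack([universe.atoms.positions.copy().astype(float)
                       for _ in universe.trajectory])
    try:
        elements = [str(e) for e in universe.atoms.elements]
    except Exception:  # no element topology attribute: fall back to names
        elements = [str(n)[0] for n in universe.atoms.names]
    return coords, elements
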