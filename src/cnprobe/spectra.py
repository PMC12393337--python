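"""Core containers for dual-channel laser sweeps and absorbance spectra.

A :class:`RawSweep` holds the demodulated per-wavenumber voltages of one
dual-beam acquisition: the reference-channel monitor voltage ``v_ref`` and the
balanced-detector difference voltage ``v_bal``.  A :class:`Spectrum` holds
decadic absorbance (OD) on the same wavenumber grid together with an
append-only processing history, so every derived spectrum records how it was
made.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["RawSweep", "Spectrum", "GridMismatchError", "check_same_grid"]


class GridMismatchError(ValueError):
    """Raised when two objects carry different wavenumber grids."""


def _as_1d(x: Any) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D array, got shape {arr.shape}")
    return arr


def check_same_grid(a: np.ndarray, b: np.ndarray, what: str = "wavenumber grid") -> None:
    if a.shape != b.shape or not np.array_equal(a, b):
        raise GridMismatchError(f"{what}s differ")


@dataclass
class RawSweep:
    """One dual-channel sweep: wavenumber grid plus channel voltages.

    Parameters
    ----------
    wavenumber : array, cm^-1, strictly increasing
    v_ref : array, V
        Reference (monitor) channel.
    v_bal : array, V
        Balanced (difference) channel.
    v_ref_q, v_bal_q : array or None, V
        Optional lock-in quadrature components.  When present, phase
        correction is a true rotation of the (in-phase, quadrature) pair.
    meta : dict
        Free-form provenance: pathlength_um, cell_id, seed, ...
    """

    wavenumber: np.ndarray
    v_ref: np.ndarray
    v_bal: np.ndarray
    v_ref_q: np.ndarray | None = None
    v_bal_q: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber = _as_1d(self.wavenumber)
        self.v_ref = _as_1d(self.v_ref)
        self.v_bal = _as_1d(self.v_bal)
        n = self.wavenumber.size
        if self.v_ref.size != n or self.v_bal.size != n:
            raise ValueError("wavenumber, v_ref and v_bal must have equal length")
        if n >= 2 and not np.all(np.diff(self.wavenumber) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        for attr in ("v_ref_q", "v_bal_q"):
            q = getattr(self, attr)
            if q is not None:
                q = _as_1d(q)
                if q.size != n:
                    raise ValueError(f"{attr} length mismatch")
                setattr(self, attr, q)

    @property
    def has_quadrature(self) -> bool:
        return self.v_ref_q is not None and self.v_bal_q is not None

    def copy(self) -> "RawSweep":
        return RawSweep(
            self.wavenumber.copy(),
            self.v_ref.copy(),
            self.v_bal.copy(),
            None if self.v_ref_q is None else self.v_ref_q.copy(),
            None if self.v_bal_q is None else self.v_bal_q.copy(),
            dict(self.meta),
        )


@dataclass
class Spectrum:
    """Absorbance (decadic OD) versus wavenumber with processing history."""

    wavenumber: np.ndarray
    absorbance: np.ndarray
    se: np.ndarray | None = None
    history: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber = _as_1d(self.wavenumber)
        self.absorbance = _as_1d(self.absorbance)
        if self.absorbance.size != self.wavenumber.size:
            raise ValueError("wavenumber and absorbance must have equal length")
        if self.se is not None:
            self.se = _as_1d(self.se)
            if self.se.size != self.wavenumber.size:
                raise ValueError("se length mismatch")

    @property
    def step(self) -> float:
        return float(np.mean(np.diff(self.wavenumber)))

    def with_absorbance(self, absorbance: np.ndarray, step: str, **params: Any) -> "Spectrum":
        """Return a new Spectrum with updated data and one appended history record."""
        new = Spectrum(
            self.wavenumber,
            np.asarray(absorbance, dtype=float),
            self.se,
            list(self.history) + [{"step": step, **params}],
            dict(self.meta),
        )
        return new

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.wavenumber >= lo) & (self.wavenumber <= hi)

    def copy(self) -> "Spectrum":
        return replace(
            self,
            wavenumber=self.wavenumber.copy(),
            absorbance=self.absorbance.copy(),
            se=None if self.se is None else self.se.copy(),
            history=list(self.history),
            meta=dict(self.meta),
        )
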