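"""Bond-projected Coulomb electric fields and hydrogen-bond classification.

For each trajectory frame the electric field of the environment's point
charges is evaluated at the nitrile carbon and nitrogen, averaged, and
projected on the C->N unit vector:

    F = 1/2 (E(r_C) + E(r_N)) . n_hat,     n_hat = (r_N - r_C)/|r_N - r_C|

with E(p) = sum_i k_e q_i (p - r_i)/|p - r_i|^3, a direct point-charge sum
(no periodic images, no induced dipoles).  Fields are reported in MV/cm using
k_e e / A^2 = 14.3996 V/A = 1439.96 MV/cm.  Sign convention: a positive
charge beyond N on the bond axis yields negative F (field pointing N->C), so
hydrogen-bond donors at the nitrile nitrogen produce negative projected
fields.

Hydrogen bonding is assigned geometrically: a donor qualifies when the
heavy-atom N...D distance is <= 4.0 A and the angle between D->H and D->N at
the donor is <= 30 deg (both cutoffs inclusive; the angle vertex is
configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COULOMB_MV_PER_CM",
    "ProbeGeometry",
    "HBondCriteria",
    "DonorCandidate",
    "HBondAssignment",
    "FieldSummary",
    "field_at_point",
    "projected_field",
    "classify_hbond",
    "donor_candidates_from_charges",
    "analyze_trajectory",
]

#: k_e * e / A^2 in MV/cm (14.3996 V/A, 1 V/A = 100 MV/cm)
COULOMB_MV_PER_CM = 1439.96


class SingularityError(ValueError):
    """Evaluation point coincides with a charged atom."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Indices of the nitrile carbon and nitrogen; bond axis runs C -> N."""

    carbon_index: int
    nitrogen_index: int

    def __post_init__(self) -> None:
        if self.carbon_index == self.nitrogen_index:
            raise ValueError("carbon and nitrogen indices must differ")

    def axis(self, frame: np.ndarray) -> np.ndarray:
        r_c = frame[self.carbon_index]
        r_n = frame[self.nitrogen_index]
        bond = r_n - r_c
        length = float(np.linalg.norm(bond))
        if not 1.0 <= length <= 1.4:
            raise ValueError(
                f"C-N distance {length:.3f} A outside the [1.0, 1.4] A sanity band"
            )
        return bond / length


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (cutoffs inclusive)."""

    distance_cutoff_A: float = 4.0  # nitrile N to donor heavy atom
    angle_cutoff_deg: float = 30.0
    angle_vertex: str = "donor"  # 'donor': angle(D->H, D->N); 'hydrogen': angle(H->D, H->N)
    donor_elements: tuple[str, ...] = ("N", "O")

    def __post_init__(self) -> None:
        if self.distance_cutoff_A <= 0 or self.angle_cutoff_deg <= 0:
            raise ValueError("cutoffs must be > 0")
        if self.angle_vertex not in ("donor", "hydrogen"):
            raise ValueError("angle_vertex must be 'donor' or 'hydrogen'")


@dataclass(frozen=True)
class DonorCandidate:
    """A potential hydrogen-bond donor: heavy atom plus its attached hydrogen."""

    donor_index: int
    hydrogen_index: int | None
    element: str = "O"
    label: str = ""


@dataclass
class HBondAssignment:
    bonded: bool
    donor: DonorCandidate | None
    distance_A: float
    angle_deg: float


@dataclass
class FieldSummary:
    """State-resolved field statistics of one analyzed trajectory."""

    bonded_mean_MVcm: float
    bonded_sd_MVcm: float
    free_mean_MVcm: float
    free_sd_MVcm: float
    populations: dict
    overall_mean_MVcm: float
    replicate_means_MVcm: list
    aggregate_mean_MVcm: float  # mean of replicate means
    histogram_edges_MVcm: np.ndarray
    histogram_counts: np.ndarray
    n_frames: int
    criteria: HBondCriteria = field(default_factory=HBondCriteria)


def field_at_point(positions: np.ndarray, charges: np.ndarray, point: np.ndarray,
                   exclude: Sequence[int] | np.ndarray | None = None) -> np.ndarray:
    """Coulomb field vector (MV/cm) at ``point`` from non-excluded point charges."""
    pos = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    if pos.shape[0] != q.shape[0]:
        raise ValueError("positions and charges length mismatch")
    mask = np.ones(pos.shape[0], dtype=bool)
    if exclude is not None:
        mask[np.asarray(exclude, dtype=int)] = False
    d = np.asarray(point, dtype=float) - pos[mask]
    r = np.linalg.norm(d, axis=1)
    tiny = r < 1e-9
    if np.any(tiny):
        idx = np.flatnonzero(mask)[tiny][0]
        raise SingularityError(f"evaluation point coincides with atom {idx}")
    contrib = (q[mask] / r**3)[:, None] * d
    return COULOMB_MV_PER_CM * contrib.sum(axis=0)


def projected_field(frame: np.ndarray, charges: np.ndarray, probe: ProbeGeometry,
                    exclude: Sequence[int] | None = None,
                    mode: str = "atom_average") -> float:
    """Bond-projected scalar field (MV/cm) at the probe.

    ``mode='atom_average'`` (default) averages the fields at the carbon and
    nitrogen; ``mode='midpoint'`` evaluates at the bond midpoint.  The probe
    atoms themselves are always excluded in addition to ``exclude``.
    """
    frame = np.asarray(frame, dtype=float)
    excl = {probe.carbon_index, probe.nitrogen_index}
    if exclude is not None:
        excl.update(int(i) for i in exclude)
    excl = sorted(excl)
    n_hat = probe.axis(frame)
    if mode == "atom_average":
        e = 0.5 * (field_at_point(frame, charges, frame[probe.carbon_index], excl)
                   + field_at_point(frame, charges, frame[probe.nitrogen_index], excl))
    elif mode == "midpoint":
        mid = 0.5 * (frame[probe.carbon_index] + frame[probe.nitrogen_index])
        e = field_at_point(frame, charges, mid, excl)
    else:
        raise ValueError("mode must be 'atom_average' or 'midpoint'")
    return float(e @ n_hat)


def classify_hbond(frame: np.ndarray, probe: ProbeGeometry,
                   donors: Sequence[DonorCandidate],
                   criteria: HBondCriteria | None = None) -> HBondAssignment:
    """Geometric hydrogen-bond state of one frame; nearest qualifying donor wins."""
    if criteria is None:
        criteria = HBondCriteria()
    frame = np.asarray(frame, dtype=float)
    r_n = frame[probe.nitrogen_index]
    best: HBondAssignment | None = None
    nearest = HBondAssignment(False, None, float("inf"), float("nan"))
    for cand in donors:
        if cand.element not in criteria.donor_elements:
            continue
        if cand.hydrogen_index is None:
            raise ValueError(f"donor candidate {cand.label or cand.donor_index} has no hydrogen")
        r_d = frame[cand.donor_index]
        r_h = frame[cand.hydrogen_index]
        dist = float(np.linalg.norm(r_n - r_d))
        if criteria.angle_vertex == "donor":
            v1, v2 = r_h - r_d, r_n - r_d
        else:
            v1, v2 = r_d - r_h, r_n - r_h
        cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if dist < nearest.distance_A:
            nearest = HBondAssignment(False, cand, dist, angle)
        # cutoffs are inclusive; the epsilons guard against rounding at the
        # boundary (e.g. an exactly-30 deg construction evaluating to 30+2e-15)
        if (dist <= criteria.distance_cutoff_A + 1e-9
                and angle <= criteria.angle_cutoff_deg + 1e-9):
            if best is None or dist < best.distance_A:
                best = HBondAssignment(True, cand, dist, angle)
    return best if best is not None else nearest


def donor_candidates_from_charges(charges: pd.DataFrame) -> list[DonorCandidate]:
    """Pair donor_D / donor_H rows of a generator charge table into candidates."""
    d_idx = charges.loc[charges["role"] == "donor_D", "atom_index"].to_numpy(int)
    h_idx = charges.loc[charges["role"] == "donor_H", "atom_index"].to_numpy(int)
    if d_idx.size != h_idx.size:
        raise ValueError("unpaired donor_D / donor_H entries in charge table")
    return [DonorCandidate(int(d), int(h), "O", f"donor{k}")
            for k, (d, h) in enumerate(zip(d_idx, h_idx))]


def _replicate_slices(n_frames: int, replicates) -> list[slice]:
    if replicates is None:
        return [slice(0, n_frames)]
    if isinstance(replicates, int):
        if replicates < 1:
            raise ValueError("replicates must be >= 1")
        bounds = np.linspace(0, n_frames, replicates + 1).astype(int)
    else:
        bounds = np.asarray(list(replicates), dtype=int)
        if bounds[0] != 0 or bounds[-1] != n_frames or np.any(np.diff(bounds) <= 0):
            raise ValueError(
                f"replicate boundaries must ascend from 0 to n_frames={n_frames}"
            )
    return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def analyze_trajectory(coords: np.ndarray, charges: pd.DataFrame,
                       probe: ProbeGeometry,
                       donors: Sequence[DonorCandidate] | None = None,
                       criteria: HBondCriteria | None = None,
                       replicates=None,
                       bin_width_MVcm: float = 2.0,
                       mode: str = "atom_average") -> tuple[pd.DataFrame, FieldSummary]:
    """Per-frame projected fields + H-bond states, and their summary.

    ``replicates`` is either a replicate count (equal split) or explicit
    boundary indices ``[0, ..., n_frames]``; the aggregate field is the mean
    of replicate means.  Atoms whose charge-table role starts with ``probe``
    are excluded from the Coulomb sum (solute-exclusion convention).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3:
        raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
    if criteria is None:
        criteria = HBondCriteria()
    if donors is None:
        donors = donor_candidates_from_charges(charges)
    charges = charges.sort_values("atom_index")
    if not np.array_equal(charges["atom_index"].to_numpy(), np.arange(coords.shape[1])):
        raise ValueError("charge table must cover atoms 0..n_atoms-1 exactly once")
    q = charges["charge_e"].to_numpy(float)
    exclude = charges.loc[charges["role"].str.startswith("probe"),
                          "atom_index"].to_numpy(int)

    n_frames = coords.shape[0]
    rep_slices = _replicate_slices(n_frames, replicates)

    records = []
    for i in range(n_frames):
        f = projected_field(coords[i], q, probe, exclude=exclude, mode=mode)
        hb = classify_hbond(coords[i], probe, donors, criteria)
        records.append({
            "frame": i,
            "field_MVcm": f,
            "hbond": hb.bonded,
            "donor": (hb.donor.label or str(hb.donor.donor_index)) if (hb.bonded and hb.donor) else "",
            "dist_A": hb.distance_A,
            "angle_deg": hb.angle_deg,
        })
    table = pd.DataFrame.from_records(records)

    fields = table["field_MVcm"].to_numpy()
    bonded = table["hbond"].to_numpy(bool)
    p_b = float(bonded.mean())

    def _stats(x: np.ndarray) -> tuple[float, float]:
        if x.size == 0:
            return float("nan"), float("nan")
        return float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0

    b_mean, b_sd = _stats(fields[bonded])
    f_mean, f_sd = _stats(fields[~bonded])
    rep_means = [float(fields[s].mean()) for s in rep_slices]
    lo = np.floor(fields.min() / bin_width_MVcm) * bin_width_MVcm
    hi = np.ceil(fields.max() / bin_width_MVcm) * bin_width_MVcm
    edges = np.arange(lo, hi + bin_width_MVcm / 2, bin_width_MVcm)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width_MVcm])
    counts, edges = np.histogram(fields, bins=edges)

    summary = FieldSummary(
        bonded_mean_MVcm=b_mean,
        bonded_sd_MVcm=b_sd,
        free_mean_MVcm=f_mean,
        free_sd_MVcm=f_sd,
        populations={"bonded": p_b, "free": 1.0 - p_b},
        overall_mean_MVcm=float(fields.mean()),
        replicate_means_MVcm=rep_means,
        aggregate_mean_MVcm=float(np.mean(rep_means)),
        histogram_edges_MVcm=edges,
        histogram_counts=counts,
        n_frames=n_frames,
        criteria=criteria,
    )
    return table, summary
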