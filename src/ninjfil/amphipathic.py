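"""Hydrophobic-face assignment, belt height and helix hydrophobic moments.

A membrane-rupturing filament is expected to segregate its surface into a
hydrophilic face and a hydrophobic, membrane-apposed face whose axial
extent (the "hydrophobic belt") matches bilayer thickness -- around 26 A
for the plasma membrane. This module projects residue side-chain centroids
into cylindrical coordinates about the filament axis, finds the planar cut
through the axis that best separates mean hydrophobicity between the two
half-planes, and measures the belt's height along the axis. It also
computes the Eisenberg-style helical hydrophobic moment of a sequence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import AssemblyModel, _BACKBONE_ATOMS, estimate_screw
from .errors import DegenerateGeometryError, InvalidModelError
from .scales import KYTE_DOOLITTLE, HydrophobicityScale

FACE_HYDROPHOBIC = "hydrophobic"
FACE_HYDROPHILIC = "hydrophilic"


@dataclass
class FaceProfile:
    """Per-residue cylindrical coordinates, hydrophobicity and face labels.

    ``records`` columns: subunit, res_id, res_name, azimuth_deg (in
    [0, 360) about the filament axis), z (A along the axis), hydrophobicity,
    face. The two faces partition the azimuth circle into the half-planes
    [split, split+180) and its complement.
    """

    records: pd.DataFrame
    split_azimuth_deg: float
    mean_h_hydrophobic: float
    mean_h_hydrophilic: float
    degenerate: bool
    axis_direction: np.ndarray
    axis_point: np.ndarray
    basis: tuple = field(default=None)

    @property
    def hydrophobic_center_azimuth_deg(self) -> float:
        """Azimuth of the centre of the hydrophobic half-plane."""
        return (self.split_azimuth_deg + 90.0) % 360.0


def _side_chain_centroids(assembly: AssemblyModel) -> pd.DataFrame:
    """Per (subunit, residue) side-chain centroid; CA fallback for Gly/CA-only."""
    rows = []
    for s in range(assembly.n_subunits):
        sl = assembly._slice(s)
        sub = assembly.atoms[sl]
        sub_coords = assembly.coords[sl]
        for res_id in np.unique(sub.res_id):
            mask = sub.res_id == res_id
            names = sub.atom_name[mask]
            coords = sub_coords[mask]
            side = ~np.isin(names, list(_BACKBONE_ATOMS))
            if side.any():
                centroid = coords[side].mean(axis=0)
            else:
                ca = names == "CA"
                if not ca.any():
                    continue
                centroid = coords[ca][0]
            rows.append(
                {
                    "subunit": s,
                    "res_id": int(res_id),
                    "res_name": str(sub.res_name[mask][0]),
                    "x": centroid[0],
                    "y": centroid[1],
                    "z_lab": centroid[2],
                }
            )
    return pd.DataFrame(rows)


def assign_faces(
    assembly: AssemblyModel,
    scale: HydrophobicityScale | None = None,
    grid_step_deg: float = 1.0,
    degenerate_tol: float = 1e-6,
) -> FaceProfile:
    """Split the filament surface into hydrophobic and hydrophilic half-planes.

    Each residue's side-chain centroid is projected to (azimuth, z) about
    the filament axis; a 1-degree grid search finds the dividing plane
    through the axis maximising the difference in mean hydrophobicity
    between the two halves. The higher-mean half is labelled hydrophobic.
    A profile whose best split separates the means by less than
    ``degenerate_tol`` (e.g. a homopolymer) is flagged degenerate.
    """
    if scale is None:
        scale = KYTE_DOOLITTLE
    if assembly.n_subunits < 2:
        raise InvalidModelError("face assignment needs >= 2 subunits to define an axis")
    sym = assembly.symmetry if assembly.symmetry is not None else estimate_screw(assembly)
    a, p = sym.axis_direction, sym.axis_point

    cent = _side_chain_centroids(assembly)
    xyz = cent[["x", "y", "z_lab"]].to_numpy() - p
    z = xyz @ a
    radial = xyz - np.outer(z, a)
    radii = np.linalg.norm(radial, axis=1)
    if radii.max() < 1e-6:
        raise DegenerateGeometryError("all residues lie on the filament axis")

    # deterministic in-plane basis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ a) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ a) * a
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    azimuth = np.degrees(np.arctan2(radial @ e2, radial @ e1)) % 360.0

    h = np.array([scale.of3(rn) for rn in cent["res_name"]])

    best_split, best_diff = None, 0.0
    for split in np.arange(0.0, 180.0, grid_step_deg):
        in_a = (azimuth - split) % 360.0 < 180.0
        if not in_a.any() or in_a.all():
            continue
        diff = h[in_a].mean() - h[~in_a].mean()
        if best_split is None or abs(diff) > abs(best_diff):
            best_diff, best_split = diff, float(split)
    if best_split is None:
        raise DegenerateGeometryError("no azimuthal split separates the residues")
    if best_diff < 0:  # hydrophobic face is the half starting at split
        best_split = (best_split + 180.0) % 360.0
        best_diff = -best_diff

    in_phob = (azimuth - best_split) % 360.0 < 180.0
    records = cent[["subunit", "res_id", "res_name"]].copy()
    records["azimuth_deg"] = azimuth
    records["z"] = z
    records["hydrophobicity"] = h
    records["face"] = np.where(in_phob, FACE_HYDROPHOBIC, FACE_HYDROPHILIC)
    return FaceProfile(
        records=records,
        split_azimuth_deg=best_split,
        mean_h_hydrophobic=float(h[in_phob].mean()),
        mean_h_hydrophilic=float(h[~in_phob].mean()),
        degenerate=bool(best_diff < degenerate_tol),
        axis_direction=a,
        axis_point=p,
        basis=(e1, e2),
    )


def hydrophobic_face_normal(
    assembly: AssemblyModel, scale: HydrophobicityScale | None = None
) -> np.ndarray:
    """Lab-frame unit vector from the filament axis through the hydrophobic face."""
    profile = assign_faces(assembly, scale=scale)
    if profile.degenerate:
        raise DegenerateGeometryError(
            "face assignment is degenerate; supply an explicit face normal"
        )
    e1, e2 = profile.basis
    c = math.radians(profile.hydrophobic_center_azimuth_deg)
    return math.cos(c) * e1 + math.sin(c) * e2


@dataclass
class BeltMeasurement:
    """Axial extent of the hydrophobic belt."""

    z_min: float
    z_max: float
    height: float
    contributing_residues: list


def hydrophobic_belt_height(
    profile: FaceProfile,
    threshold: float = 1.8,
    trim_fraction: float = 0.025,
) -> BeltMeasurement:
    """Axial height of the hydrophobic belt on the hydrophobic face.

    Takes hydrophobic-face residues with hydrophobicity >= ``threshold``,
    trims the top and bottom ``trim_fraction`` of their z-values to guard
    against single-residue outliers (set 0 for exact constructions), and
    returns z_max - z_min of the remainder. The default threshold 1.8
    (Kyte-Doolittle units) admits Ala and the stronger hydrophobics.
    """
    rec = profile.records
    sel = rec[(rec["face"] == FACE_HYDROPHOBIC) & (rec["hydrophobicity"] >= threshold)]
    if sel.empty:
        warnings.warn("no residues qualify for the hydrophobic belt; height is 0")
        return BeltMeasurement(z_min=0.0, z_max=0.0, height=0.0, contributing_residues=[])
    z = sel["z"].to_numpy()
    if trim_fraction > 0:
        lo, hi = np.quantile(z, [trim_fraction, 1.0 - trim_fraction])
        keep = (z >= lo) & (z <= hi)
        sel = sel[keep]
        z = z[keep]
    residues = list(zip(sel["subunit"].tolist(), sel["res_id"].tolist()))
    return BeltMeasurement(
        z_min=float(z.min()),
        z_max=float(z.max()),
        height=float(z.max() - z.min()),
        contributing_residues=residues,
    )


@dataclass
class AmphipathicityResult:
    """Mean hydrophobicity and helical hydrophobic moment of a segment."""

    segment: tuple | None
    mean_hydrophobicity: float
    mu_h: float
    moment_azimuth_deg: float


def hydrophobic_moment(
    sequence: str,
    scale: HydrophobicityScale | None = None,
    delta: float = 100.0,
    center: bool = True,
    segment: tuple | None = None,
) -> AmphipathicityResult:
    """Helical hydrophobic moment of a sequence.

    mu_H = | sum_k H_k exp(i k delta) | / N with delta the per-residue turn
    angle (100 degrees for an ideal alpha-helix). By default H is
    mean-centred before the sum, which makes mu_H exactly zero for any
    homopolymer regardless of length; ``center=False`` gives the raw
    Eisenberg sum. ``mean_hydrophobicity`` is always the uncentred mean.
    """
    if scale is None:
        scale = KYTE_DOOLITTLE
    if len(sequence) < 4:
        raise InvalidModelError("sequence must have at least 4 residues")
    h = np.empty(len(sequence))
    for k, letter in enumerate(sequence):
        try:
            h[k] = scale.of1(letter)
        except KeyError:
            raise InvalidModelError(
                f"non-standard residue {letter!r} at position {k}"
            ) from None
    mean_h = float(h.mean())
    hc = h - mean_h if center else h
    phases = np.exp(1j * np.radians(delta) * np.arange(len(h)))
    total = np.sum(hc * phases)
    return AmphipathicityResult(
        segment=segment,
        mean_hydrophobicity=mean_h,
        mu_h=float(abs(total)) / len(h),
        moment_azimuth_deg=float(np.degrees(np.angle(total)) % 360.0),
    )
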