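"""Analogue-quality screening and analogue geography.

For each fossil sample the squared chord distance to every modern calibration
sample is computed by full scan. The minimum distance measures analogue
quality; samples are flagged "good" when their best analogue is closer than
twice the mean analogue distance of a user-supplied reference set (e.g.
late-Holocene samples from a nearby core, which by construction have good
modern analogues). The geographic fingerprint of a fossil sample is the
analogue-quality-weighted mean latitude/longitude of its n most similar
modern samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (AssemblageTable, ClimateTable, chord_distance_matrix,
                 harmonise_taxa, percentages)


def _proportion_matrices(fossil: AssemblageTable, calibration: AssemblageTable):
    if calibration.unit != "percent":
        calibration = percentages(calibration)
    if fossil.unit != "percent":
        fossil = percentages(fossil)
    fossil = harmonise_taxa(fossil, calibration)
    return fossil.proportions().to_numpy(), calibration.proportions().to_numpy()


@dataclass
class AnalogueReport:
    """Per-fossil-sample analogue diagnostics.

    ``neighbor_indices``/``neighbor_distances`` hold the ``n_neighbors``
    nearest calibration samples (sorted by distance); ``good`` is filled by
    :func:`analogue_threshold`.
    """

    sample_ids: list
    calibration_ids: list
    d_min: np.ndarray
    neighbor_indices: np.ndarray  # (n_fossil, n_neighbors)
    neighbor_distances: np.ndarray
    good: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"d_min": self.d_min}, index=self.sample_ids)
        for j in range(self.neighbor_indices.shape[1]):
            out[f"analogue_{j + 1}"] = [self.calibration_ids[i]
                                        for i in self.neighbor_indices[:, j]]
            out[f"scd_{j + 1}"] = self.neighbor_distances[:, j]
        if self.good is not None:
            out["good_analogue"] = self.good
        return out


def analogue_distances(fossil: AssemblageTable, calibration: AssemblageTable,
                       n_neighbors: int = 5) -> AnalogueReport:
    """Exact nearest-analogue squared chord distances (full scan)."""
    if len(calibration) == 0:
        raise ValueError("empty calibration set")
    if n_neighbors > len(calibration):
        raise ValueError(f"n_neighbors={n_neighbors} exceeds calibration size")
    Pf, Pc = _proportion_matrices(fossil, calibration)
    D = chord_distance_matrix(Pf, Pc)
    order = np.argsort(D, axis=1, kind="stable")[:, :n_neighbors]
    nd = np.take_along_axis(D, order, axis=1)
    return AnalogueReport(
        sample_ids=list(fossil.sample_ids),
        calibration_ids=list(calibration.sample_ids),
        d_min=D.min(axis=1),
        neighbor_indices=order,
        neighbor_distances=nd,
    )


def analogue_threshold(report: AnalogueReport, reference_distances) -> np.ndarray:
    """Good-analogue flags: d_min < 2 x mean(reference distances).

    Exact matches (d_min = 0) are always good, which keeps the rule sensible
    in the degenerate all-zero reference case.
    """
    ref = np.asarray(reference_distances, dtype=float)
    if ref.size == 0:
        raise ValueError("reference_distances must be non-empty")
    threshold = 2.0 * ref.mean()
    good = (report.d_min < threshold) | (report.d_min == 0)
    report.good = good
    return good


def analogue_geography(fossil: AssemblageTable, calibration: AssemblageTable,
                       climate_table: ClimateTable, n: int = 5,
                       weighting: str = "inverse") -> pd.DataFrame:
    """Quality-weighted mean position of the n most similar modern samples.

    Weights are 1/d (``inverse``, the default) or 1 - d/2 (``complement``);
    a zero-distance analogue receives all the weight (shared equally among
    exact matches). Longitudes are averaged arithmetically.
    """
    if not climate_table.has_coordinates:
        raise ValueError("climate table has no lat/lon columns")
    if weighting not in ("inverse", "complement"):
        raise ValueError(f"unknown weighting {weighting!r}")
    report = analogue_distances(fossil, calibration, n_neighbors=n)
    coords = climate_table.data.loc[list(calibration.sample_ids), ["lat", "lon"]].to_numpy()
    lat = np.empty(len(report.sample_ids))
    lon = np.empty(len(report.sample_ids))
    for i, (idx, d) in enumerate(zip(report.neighbor_indices, report.neighbor_distances)):
        exact = d <= 1e-12
        if exact.any():
            w = exact.astype(float)
        elif weighting == "inverse":
            w = 1.0 / d
        else:
            w = np.clip(1.0 - d / 2.0, 0.0, None)
            if w.sum() <= 0:
                w = np.ones_like(d)
        lat[i] = float(np.average(coords[idx, 0], weights=w))
        lon[i] = float(np.average(coords[idx, 1], weights=w))
    return pd.DataFrame({"lat": lat, "lon": lon, "d_min": report.d_min},
                        index=report.sample_ids)
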