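"""Containers and compositional primitives for pollen assemblage data.

The central objects are :class:`AssemblageTable` (a samples x taxa matrix of
pollen counts or percentages, optionally depth-indexed for fossil sequences)
and :class:`ClimateTable` (per-sample July/January mean temperature and
coordinates for a modern calibration set).

Percentages follow the standard convention for boreal pollen diagrams: the
percentage base is the sum of all terrestrial pollen and spores; aquatic taxa
and other non-pollen palynomorphs are expressed relative to the same sum (and
may therefore jointly exceed 100%); exotic marker grains added for
concentration estimates are excluded from all downstream computation.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TERRESTRIAL = "terrestrial"
SPORE = "spore"
AQUATIC = "aquatic"
MARKER = "marker"
VALID_GROUPS = (TERRESTRIAL, SPORE, AQUATIC, MARKER)

#: groups entering the percentage denominator (the "pollen sum")
POLLEN_SUM_GROUPS = (TERRESTRIAL, SPORE)

SAMPLE_COLUMN = "sample_id"
DEPTH_COLUMN = "depth_m"
CLIMATE_COLUMNS = ("t_jul", "t_jan", "lat", "lon")


class AssemblageTable:
    """Samples x taxa table of pollen counts or percentages.

    Parameters
    ----------
    counts : DataFrame
        Rows are samples (index = sample ids), columns are taxa. Values are
        non-negative reals; half grains (e.g. 220.5) are allowed.
    groups : mapping, optional
        Taxon name -> group tag, one of ``terrestrial``, ``spore``,
        ``aquatic``, ``marker``. Unlisted taxa default to ``terrestrial``.
    depths : array-like, optional
        Sample depths in metres, strictly increasing (fossil sequences).
    unit : {"counts", "percent"}
    """

    def __init__(self, counts, groups=None, depths=None, unit="counts"):
        data = pd.DataFrame(counts).astype(float).copy()
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise ValueError("assemblage table must have at least one sample and one taxon")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon names: {dups}")
        neg = data.lt(0).any(axis=1)
        if neg.any():
            rows = data.index[neg].tolist()
            raise ValueError(f"negative counts in rows: {rows}")
        if unit not in ("counts", "percent"):
            raise ValueError(f"unknown unit {unit!r}")

        groups = dict(groups or {})
        unknown = set(groups) - set(data.columns)
        if unknown:
            raise ValueError(f"group map names unknown taxa: {sorted(unknown)}")
        bad = {t: g for t, g in groups.items() if g not in VALID_GROUPS}
        if bad:
            raise ValueError(f"invalid group tags: {bad}; valid: {VALID_GROUPS}")
        self._groups = {t: groups.get(t, TERRESTRIAL) for t in data.columns}
        if not any(g in POLLEN_SUM_GROUPS for g in self._groups.values()):
            raise ValueError("table needs at least one terrestrial pollen or spore taxon")

        if depths is not None:
            depths = np.asarray(depths, dtype=float)
            if depths.shape != (len(data),):
                raise ValueError("depths must have one value per sample")
            bad_rows = np.where(np.diff(depths) <= 0)[0]
            if bad_rows.size:
                offending = [
                    f"{data.index[i]!r} (depth {depths[i]}) -> {data.index[i + 1]!r} (depth {depths[i + 1]})"
                    for i in bad_rows
                ]
                raise ValueError("depths not strictly increasing at rows: " + "; ".join(offending))
        self._data = data
        self._depths = depths
        self.unit = unit

    # -- basic access -----------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self):
        return self._data.index

    @property
    def depths(self):
        return None if self._depths is None else self._depths.copy()

    @property
    def taxa(self) -> list[str]:
        return list(self._data.columns)

    @property
    def groups(self) -> dict[str, str]:
        return dict(self._groups)

    def taxa_in_groups(self, *groups: str) -> list[str]:
        return [t for t in self._data.columns if self._groups[t] in groups]

    def pollen_matrix(self) -> pd.DataFrame:
        """Terrestrial pollen + spore columns (the reconstruction response)."""
        return self._data[self.taxa_in_groups(*POLLEN_SUM_GROUPS)].copy()

    def proportions(self) -> pd.DataFrame:
        """Pollen-sum taxa rescaled to row proportions (for SCD / MLRC)."""
        m = self.pollen_matrix()
        rowsum = m.sum(axis=1)
        if (rowsum <= 0).any():
            rows = m.index[rowsum <= 0].tolist()
            raise ValueError(f"zero terrestrial pollen+spore sum in rows: {rows}")
        return m.div(rowsum, axis=0)

    def __len__(self):
        return len(self._data)

    def __eq__(self, other):
        if not isinstance(other, AssemblageTable):
            return NotImplemented
        if self.unit != other.unit or self._groups != other._groups:
            return False
        if not self._data.equals(other._data):
            return False
        if (self._depths is None) != (other._depths is None):
            return False
        if self._depths is not None and not np.array_equal(self._depths, other._depths):
            return False
        return True

    def __repr__(self):
        d = "" if self._depths is None else ", depth-indexed"
        return (
            f"AssemblageTable({len(self)} samples x {len(self.taxa)} taxa, "
            f"unit={self.unit!r}{d})"
        )


class ClimateTable:
    """Per-sample climate values (and optional coordinates) for calibration.

    Requires ``t_jul`` and ``t_jan`` columns (degrees Celsius) with no missing
    values and ``t_jan <= t_jul`` per sample; ``lat``/``lon`` (decimal degrees)
    are optional but needed for analogue geography.
    """

    def __init__(self, data: pd.DataFrame):
        data = pd.DataFrame(data).copy()
        for col in ("t_jul", "t_jan"):
            if col not in data.columns:
                raise ValueError(f"climate table missing column {col!r}")
        if data[["t_jul", "t_jan"]].isna().any().any():
            raise ValueError("missing climate values")
        bad = data.index[data["t_jan"] > data["t_jul"] + 1e-9].tolist()
        if bad:
            raise ValueError(f"t_jan exceeds t_jul in rows: {bad}")
        if data.index.has_duplicates:
            raise ValueError("duplicate sample ids in climate table")
        self._data = data

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self):
        return self._data.index

    def variable(self, name: str) -> np.ndarray:
        return self._data[name].to_numpy(dtype=float)

    @property
    def has_coordinates(self) -> bool:
        return {"lat", "lon"}.issubset(self._data.columns)

    def __len__(self):
        return len(self._data)

    def __eq__(self, other):
        if not isinstance(other, ClimateTable):
            return NotImplemented
        return self._data.equals(other._data)


# -- file I/O -------------------------------------------------------------

def write_assemblage(table: AssemblageTable, path, groups_path=None) -> None:
    """Write a table to CSV (RFC-4180, UTF-8) plus a YAML sidecar.

    The sidecar stores the taxon-group map and the value unit so the
    round trip ``read_assemblage(write_assemblage(t)) == t`` is exact.
    """
    path = Path(path)
    df = table.data.copy()
    df.insert(0, SAMPLE_COLUMN, table.sample_ids)
    if table.depths is not None:
        df.insert(1, DEPTH_COLUMN, table.depths)
    df.to_csv(path, index=False)
    if groups_path is None:
        groups_path = path.with_suffix(".groups.yaml")
    with open(groups_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"unit": table.unit, "groups": table.groups}, fh)


def read_assemblage(path, groups_path=None, unit=None) -> AssemblageTable:
    """Read a CSV assemblage table, with optional YAML taxon-group sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    if SAMPLE_COLUMN not in df.columns:
        raise ValueError(f"{path}: missing {SAMPLE_COLUMN!r} column")
    df = df.set_index(SAMPLE_COLUMN)
    depths = None
    if DEPTH_COLUMN in df.columns:
        depths = df.pop(DEPTH_COLUMN).to_numpy(dtype=float)
    groups: Mapping[str, str] = {}
    if groups_path is None:
        candidate = path.with_suffix(".groups.yaml")
        groups_path = candidate if candidate.exists() else None
    if groups_path is not None:
        with open(groups_path, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh) or {}
        groups = meta.get("groups", meta if isinstance(meta, dict) else {})
        if unit is None:
            unit = meta.get("unit")
    return AssemblageTable(df, groups=groups, depths=depths, unit=unit or "counts")


def write_climate(table: ClimateTable, path) -> None:
    df = table.data.copy()
    df.insert(0, SAMPLE_COLUMN, table.sample_ids)
    df.to_csv(path, index=False)


def read_climate(path) -> ClimateTable:
    df = pd.read_csv(path)
    if SAMPLE_COLUMN not in df.columns:
        raise ValueError(f"{path}: missing {SAMPLE_COLUMN!r} column")
    return ClimateTable(df.set_index(SAMPLE_COLUMN))


# -- compositional primitives ---------------------------------------------

def percentages(table: AssemblageTable) -> AssemblageTable:
    """Convert counts to percentages of the terrestrial pollen + spore sum.

    Aquatic / NPP taxa are expressed relative to the same denominator, so a
    sample's full row may sum to more than 100. Marker grains are dropped.
    Idempotent on tables already on the percent scale.
    """
    base_taxa = table.taxa_in_groups(*POLLEN_SUM_GROUPS)
    keep_taxa = [t for t in table.taxa if table.groups[t] != MARKER]
    base = table.data[base_taxa].sum(axis=1)
    zero = base <= 0
    if zero.any():
        rows = table.data.index[zero].tolist()
        raise ValueError(f"all-zero terrestrial pollen+spore sum in rows: {rows}")
    pct = table.data[keep_taxa].div(base, axis=0) * 100.0
    groups = {t: g for t, g in table.groups.items() if t in keep_taxa}
    return AssemblageTable(pct, groups=groups, depths=table.depths, unit="percent")


def concentration(count, markers_counted, markers_added, volume_cm3):
    """Absolute concentration (grains / cm^3) from exotic marker counts.

    concentration = count * markers_added / (markers_counted * volume)
    """
    count = np.asarray(count, dtype=float)
    if np.any(np.asarray(markers_counted) <= 0):
        raise ValueError("markers_counted must be > 0 (concentration undefined)")
    if np.any(np.asarray(volume_cm3) <= 0):
        raise ValueError("volume_cm3 must be > 0")
    out = count * markers_added / (np.asarray(markers_counted, dtype=float) * volume_cm3)
    return float(out) if out.ndim == 0 else out


def squared_chord_distance(p, q) -> float:
    """Squared chord distance d = sum_k (sqrt(p_k) - sqrt(q_k))^2 in [0, 2].

    ``p`` and ``q`` are proportion vectors over the identical taxon list, each
    summing to 1.
    """
    if isinstance(p, pd.Series) and isinstance(q, pd.Series):
        if not p.index.equals(q.index):
            raise ValueError("mismatched taxon lists")
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("mismatched taxon lists (unequal length)")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("proportions must be non-negative")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} does not sum to 1 (sum={v.sum():.6g})")
    return float(((np.sqrt(p) - np.sqrt(q)) ** 2).sum())


def chord_distance_matrix(P, Q) -> np.ndarray:
    """Pairwise squared chord distances between rows of two proportion matrices."""
    from scipy.spatial.distance import cdist

    D = cdist(np.sqrt(np.asarray(P, dtype=float)), np.sqrt(np.asarray(Q, dtype=float)),
              metric="sqeuclidean")
    return np.maximum(D, 0.0)


def ap_nap_ratio(table: AssemblageTable, ap_taxa: Iterable[str],
                 include_spores_in_nap: bool = False) -> pd.DataFrame:
    """Arboreal / non-arboreal pollen ratio per sample.

    NAP is terrestrial pollen not listed in ``ap_taxa``; spores are excluded
    from NAP by default (set ``include_spores_in_nap`` to change). Samples
    with zero NAP get ``ratio = +inf`` and ``nap_is_zero = True``.
    """
    ap_taxa = list(ap_taxa)
    if not ap_taxa:
        raise ValueError("ap_taxa must not be empty")
    terrestrial = set(table.taxa_in_groups(TERRESTRIAL))
    missing = [t for t in ap_taxa if t not in terrestrial]
    if missing:
        raise ValueError(f"ap_taxa not terrestrial pollen taxa of this table: {missing}")
    nap_groups = (TERRESTRIAL, SPORE) if include_spores_in_nap else (TERRESTRIAL,)
    nap_taxa = [t for t in table.taxa_in_groups(*nap_groups) if t not in ap_taxa]
    ap = table.data[ap_taxa].sum(axis=1)
    nap = table.data[nap_taxa].sum(axis=1) if nap_taxa else pd.Series(0.0, index=table.data.index)
    with np.errstate(divide="ignore"):
        ratio = np.where(nap.to_numpy() > 0, ap.to_numpy() / np.where(nap > 0, nap, 1.0), np.inf)
    return pd.DataFrame({"ratio": ratio, "nap_is_zero": nap.to_numpy() <= 0},
                        index=table.data.index)


def harmonise_taxa(fossil: AssemblageTable, reference: AssemblageTable,
                   renormalise: bool = False) -> AssemblageTable:
    """Align a fossil table to a calibration table's taxon list.

    Taxa are matched by exact name after case folding. Fossil taxa without a
    calibration counterpart are dropped with a warning; calibration taxa
    absent from the fossil table become zero columns. By default percentages
    are NOT renormalised after dropping (set ``renormalise`` to rescale the
    pollen-sum taxa back to 100).
    """
    ref_by_fold = {t.casefold(): t for t in reference.taxa}
    mapping = {}
    dropped = []
    for t in fossil.taxa:
        hit = ref_by_fold.get(t.casefold())
        if hit is None:
            dropped.append(t)
        else:
            mapping[t] = hit
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} fossil taxa without calibration match: {dropped}",
            stacklevel=2,
        )
    out = pd.DataFrame(0.0, index=fossil.data.index, columns=reference.taxa)
    for src, dst in mapping.items():
        out[dst] = fossil.data[src].to_numpy()
    result = AssemblageTable(out, groups=reference.groups, depths=fossil.depths,
                             unit=fossil.unit)
    if renormalise and fossil.unit == "percent":
        base_taxa = result.taxa_in_groups(*POLLEN_SUM_GROUPS)
        base = result.data[base_taxa].sum(axis=1)
        if (base <= 0).any():
            raise ValueError("cannot renormalise: zero pollen sum after harmonisation")
        rescaled = result.data.div(base, axis=0) * 100.0
        result = AssemblageTable(rescaled, groups=reference.groups,
                                 depths=fossil.depths, unit="percent")
    return result
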