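"""Readers and writers for detection/non-detection histories and covariates.

Detection data are binary records y[i, j, k] over sites i, repeat visits j
and species k.  The on-disk formats are plain CSV: a *long* format with one
row per (site, visit, species) record, and a *wide* format with one row per
site x visit and one column per species.  Unequal numbers of visits per site
are supported and represented in memory by a site x visit mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DetectionData",
    "read_detections",
    "write_detections_long",
    "write_detections_wide",
    "standardize_covariates",
    "destandardize_covariates",
]


@dataclass
class DetectionData:
    """Binary detection histories with site/visit/species axes.

    Attributes
    ----------
    y : ndarray of shape (S, J, K)
        Detection (1) / non-detection (0); 0 wherever the visit mask is off.
    visit_mask : ndarray of shape (S, J), bool
        True where the visit was actually conducted.  Sites may have fewer
        than J visits; the likelihood skips masked cells.
    site_ids, species_ids : lists of labels in axis order.
    site_covariates, visit_covariates : optional DataFrames
        Site covariates indexed like sites; visit covariates carry columns
        of shape (S*J,) in site-major order (reshaped internally).
    """

    y: np.ndarray
    visit_mask: np.ndarray
    site_ids: list = field(default_factory=list)
    species_ids: list = field(default_factory=list)
    site_covariates: pd.DataFrame | None = None
    visit_covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.ndim != 3:
            raise ValueError("y must be a (sites, visits, species) array")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary")
        self.y = self.y.astype(np.uint8)
        self.visit_mask = np.asarray(self.visit_mask, dtype=bool)
        if self.visit_mask.shape != self.y.shape[:2]:
            raise ValueError("visit_mask must have shape (sites, visits)")
        if (self.y[~self.visit_mask].sum()) > 0:
            raise ValueError("detections recorded at masked (unconducted) visits")
        if not self.site_ids:
            self.site_ids = list(range(1, self.n_sites + 1))
        if not self.species_ids:
            self.species_ids = [f"sp{k + 1}" for k in range(self.n_species)]

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_visits(self) -> int:
        return self.y.shape[1]

    @property
    def n_species(self) -> int:
        return self.y.shape[2]

    @property
    def visits_per_site(self) -> np.ndarray:
        return self.visit_mask.sum(axis=1)

    def detected(self) -> np.ndarray:
        """Per-species indicator of at least one detection anywhere."""
        return self.y.any(axis=(0, 1))

    def drop_undetected(self) -> tuple["DetectionData", list]:
        """Remove all-zero species columns.

        Observed-but-never-detected species are indistinguishable from
        augmented pseudo-species, so they must not count towards the number
        of observed species before augmentation.  Returns the reduced data
        and the ids of the dropped species.
        """
        keep = self.detected()
        dropped = [s for s, k in zip(self.species_ids, keep) if not k]
        sub = DetectionData(
            y=self.y[:, :, keep],
            visit_mask=self.visit_mask,
            site_ids=list(self.site_ids),
            species_ids=[s for s, k in zip(self.species_ids, keep) if k],
            site_covariates=self.site_covariates,
            visit_covariates=self.visit_covariates,
        )
        return sub, dropped

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_sites):
            for j in range(self.n_visits):
                if not self.visit_mask[i, j]:
                    continue
                for k in range(self.n_species):
                    rows.append(
                        (self.site_ids[i], j + 1, self.species_ids[k], int(self.y[i, j, k]))
                    )
        return pd.DataFrame(rows, columns=["site", "visit", "species", "y"])

    def to_wide(self) -> pd.DataFrame:
        long = self.to_long()
        wide = long.pivot_table(
            index=["site", "visit"], columns="species", values="y", aggfunc="first"
        )
        wide = wide.reindex(columns=self.species_ids)
        return wide.reset_index()


def write_detections_long(data: DetectionData, path) -> None:
    data.to_long().to_csv(path, index=False)


def write_detections_wide(data: DetectionData, path) -> None:
    data.to_wide().to_csv(path, index=False)


def read_detections(path, drop_undetected: bool = True) -> DetectionData:
    """Read a long-format detection CSV (columns site, visit, species, y).

    Species order follows first appearance in the file; visits are indexed
    1..J and sites with fewer visits get masked cells.  All-zero species are
    dropped (reported via a warning) unless ``drop_undetected=False``.
    """
    df = pd.read_csv(path)
    required = {"site", "visit", "species", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"detection CSV must have columns {sorted(required)}")
    bad = ~df["y"].isin([0, 1])
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:10]
        raise ValueError(f"non-binary detection values at file rows {rows}")
    dup = df.duplicated(subset=["site", "visit", "species"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]
        raise ValueError(f"duplicate (site, visit, species) keys at file rows {rows}")

    site_ids = list(pd.unique(df["site"]))
    species_ids = list(pd.unique(df["species"]))
    J = int(df["visit"].max())
    S, K = len(site_ids), len(species_ids)
    site_idx = {s: i for i, s in enumerate(site_ids)}
    sp_idx = {s: k for k, s in enumerate(species_ids)}

    y = np.zeros((S, J, K), dtype=np.uint8)
    mask = np.zeros((S, J), dtype=bool)
    i = df["site"].map(site_idx).to_numpy()
    j = df["visit"].to_numpy(dtype=int) - 1
    k = df["species"].map(sp_idx).to_numpy()
    y[i, j, k] = df["y"].to_numpy(dtype=np.uint8)
    mask[i, j] = True

    data = DetectionData(y=y, visit_mask=mask, site_ids=site_ids, species_ids=species_ids)
    if drop_undetected:
        data, dropped = data.drop_undetected()
        if dropped:
            warnings.warn(
                f"dropped {len(dropped)} species with no detections: "
                f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                stacklevel=2,
            )
    return data


def standardize_covariates(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize numeric columns to mean 0 and (population) variance 1.

    Returns the standardized table and a metadata frame with the original
    mean and scale per column, sufficient to back-transform coefficients or
    the covariates themselves.
    """
    out = table.copy()
    meta = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        mu = x.mean()
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"covariate column {col!r} has zero variance")
        out[col] = (x - mu) / sd
        meta[col] = {"mean": mu, "scale": sd}
    return out, pd.DataFrame(meta).T


def destandardize_covariates(table: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`standardize_covariates` using its metadata."""
    out = table.copy()
    for col in table.columns:
        out[col] = table[col] * meta.loc[col, "scale"] + meta.loc[col, "mean"]
    return out
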