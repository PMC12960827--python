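"""Core in-memory containers shared across the pipeline.

A :class:`Parcellation` describes the cortical regions (labels, networks at two
granularities, hemispheres and spherical centroids), a :class:`ParcellatedRun`
is one subject's region-by-time BOLD matrix, a :class:`RegionalMap` is a scalar
value per region, and a :class:`ReceptorPanel` holds regional neurotransmitter
receptor densities with their effect/type annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "ParcellatedRun",
    "RegionalMap",
    "ReceptorPanel",
]


@dataclass
class Parcellation:
    """Region labels, network assignments and unit-sphere centroids.

    Attributes
    ----------
    region_ids:
        Integer labels ``1..R``.
    network17, network7:
        Fine- and coarse-grained network label per region. Every fine label
        maps to exactly one coarse label via ``map17to7``.
    hemisphere:
        ``"L"`` or ``"R"`` per region.
    centroids:
        ``(R, 3)`` unit-norm coordinates on the sphere.
    map17to7:
        Lookup merging fine subnetwork names into their principal network.
    """

    region_ids: np.ndarray
    network17: np.ndarray
    network7: np.ndarray
    hemisphere: np.ndarray
    centroids: np.ndarray
    map17to7: dict = field(default_factory=dict)
    name: str = "synthetic"

    def __post_init__(self) -> None:
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        self.network17 = np.asarray(self.network17, dtype=object)
        self.network7 = np.asarray(self.network7, dtype=object)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        self.centroids = np.asarray(self.centroids, dtype=float)
        R = self.n_regions
        if R < 2:
            raise ValueError("parcellation needs at least 2 regions")
        if self.centroids.shape != (R, 3):
            raise ValueError("centroids must be (R, 3)")
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("centroids must lie on the unit sphere")
        if not self.map17to7:
            self.map17to7 = dict(zip(self.network17, self.network7))
        for lab17, lab7 in zip(self.network17, self.network7):
            if self.map17to7.get(lab17) != lab7:
                raise ValueError(
                    f"fine network {lab17!r} maps inconsistently to {lab7!r}"
                )
        if R >= 4:
            hemis = set(self.hemisphere)
            if hemis != {"L", "R"}:
                raise ValueError("both hemispheres must be populated for R >= 4")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def aligned_centroids(self) -> np.ndarray:
        """Centroids with the left hemisphere reflected onto the right sphere.

        Each hemisphere lives on its own spherical registration space; the
        sagittal mirror puts homotopic regions at nearby coordinates, which is
        the space in which inter-region geodesics are meaningful.
        """
        out = self.centroids.copy()
        out[self.hemisphere == "L", 0] *= -1.0
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "network17": self.network17,
                "network7": self.network7,
                "hemisphere": self.hemisphere,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "synthetic") -> "Parcellation":
        required = {"region_id", "network17", "network7", "hemisphere", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        return cls(
            region_ids=df["region_id"].to_numpy(),
            network17=df["network17"].to_numpy(),
            network7=df["network7"].to_numpy(),
            hemisphere=df["hemisphere"].to_numpy(),
            centroids=df[["x", "y", "z"]].to_numpy(float),
            name=name,
        )


@dataclass
class ParcellatedRun:
    """One subject's region-by-time BOLD matrix plus acquisition metadata."""

    subject_id: str
    tr_s: float
    data: np.ndarray
    age: Optional[float] = None
    run_label: str = "run-1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("run data must be a 2-D region x time matrix")
        if self.data.shape[1] < 2:
            raise ValueError("run needs at least 2 timepoints")
        if not np.isfinite(self.data).all():
            raise ValueError("run data contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "ParcellatedRun":
        return replace(self, data=data)


@dataclass
class RegionalMap:
    """A scalar value per region, tied to a parcellation by name."""

    values: np.ndarray
    parcellation_ref: str = "synthetic"
    label: str = ""
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValueError("regional map needs at least 2 regions")
        if not np.isfinite(self.values).all():
            raise ValueError("regional map contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


#: Receptor effect/type annotations (13 PET-derived receptor density maps).
RECEPTOR_ANNOTATIONS = pd.DataFrame(
    [
        ("a4b2", "excitatory", "ionotropic"),
        ("M1", "excitatory", "metabotropic"),
        ("D1", "excitatory", "metabotropic"),
        ("D2", "inhibitory", "metabotropic"),
        ("GABAa", "inhibitory", "ionotropic"),
        ("GABAa-bz", "inhibitory", "ionotropic"),
        ("mGluR5", "excitatory", "metabotropic"),
        ("NMDA", "excitatory", "ionotropic"),
        ("5HT1a", "inhibitory", "metabotropic"),
        ("5HT1b", "inhibitory", "metabotropic"),
        ("5HT2a", "excitatory", "metabotropic"),
        ("5HT4", "excitatory", "metabotropic"),
        ("5HT6", "excitatory", "metabotropic"),
    ],
    columns=["receptor", "effect", "type"],
)

RECEPTOR_NAMES = tuple(RECEPTOR_ANNOTATIONS["receptor"])


@dataclass
class ReceptorPanel:
    """Region x receptor density matrix with effect/type annotations."""

    densities: pd.DataFrame
    annotations: pd.DataFrame = field(
        default_factory=lambda: RECEPTOR_ANNOTATIONS.copy()
    )
    parcellation_ref: str = "synthetic"

    def __post_init__(self) -> None:
        if list(self.densities.columns) != list(self.annotations["receptor"]):
            raise ValueError("density columns must match annotation receptors")
        if (self.densities.to_numpy() < 0).any():
            raise ValueError("receptor densities must be non-negative")

    @property
    def n_receptors(self) -> int:
        return self.densities.shape[1]

    def receptors_with(self, column: str, value: str) -> list:
        mask = self.annotations[column] == value
        return list(self.annotations.loc[mask, "receptor"])
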