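"""Atlas parcellations, anatomical target sets, and file I/O.

The pipeline works on a gray-matter parcellation in the style of the combined
Harvard-Oxford (cortical + subcortical) and AAL (cerebellar) atlas: an integer
label volume in which voxel value ``p >= 1`` marks membership of parcel ``p``
and 0 is background, accompanied by a parcel table naming each parcel and
assigning it a hemisphere, lobe and anatomical group.  The shipped default
table has 132 parcels (91 cortical, 15 subcortical, 26 cerebellar).

Connectomes are dense symmetric nonnegative ``N x N`` edge-weight matrices
(structural connectivity from diffusion tractography between the same
parcels); volumes are 3D T1-weighted-style scans.  Readers validate and
reject rather than silently repair.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AtlasParcellation",
    "TargetSet",
    "ConnectivityGraph",
    "VolumeScan",
    "AtlasError",
    "GraphValidationError",
    "AsymmetricMatrixError",
    "NegativeWeightError",
    "NonzeroDiagonalError",
    "load_atlas",
    "default_parcel_table",
    "default_target_config",
    "build_target_sets",
    "read_connectivity",
    "write_connectivity",
    "read_volume",
    "write_volume",
    "read_rv_table",
    "write_rv_table",
]

SYMMETRY_TOL = 1e-8

REQUIRED_TABLE_COLUMNS = ("parcel_id", "name", "hemisphere", "group")


class AtlasError(ValueError):
    """Invalid parcellation input (labels, table, or their mismatch)."""


class GraphValidationError(ValueError):
    """Base class for connectivity-matrix invariant violations."""


class AsymmetricMatrixError(GraphValidationError):
    pass


class NegativeWeightError(GraphValidationError):
    pass


class NonzeroDiagonalError(GraphValidationError):
    pass


@dataclass
class AtlasParcellation:
    """Integer label volume plus parcel table; parcel masks are derived.

    ``label_volume`` holds parcel ids (0 = background).  ``parcel_table`` has
    columns ``parcel_id`` (>= 1, unique), ``name``, ``hemisphere``
    (left/right/midline), ``lobe`` (optional) and ``group``
    (cortical/subcortical/cerebellar).
    """

    label_volume: np.ndarray
    parcel_table: pd.DataFrame
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        lv = np.asarray(self.label_volume)
        if not np.issubdtype(lv.dtype, np.integer):
            if not np.allclose(lv, np.round(lv)):
                raise AtlasError("label volume has non-integer voxel values")
            lv = np.round(lv).astype(np.int32)
        self.label_volume = lv
        tab = self.parcel_table
        missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in tab.columns]
        if missing:
            raise AtlasError(f"parcel table missing columns: {missing}")
        ids = tab["parcel_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            dup = tab["parcel_id"][tab["parcel_id"].duplicated()].tolist()
            raise AtlasError(f"duplicate parcel ids in table: {dup}")
        if (ids < 1).any():
            raise AtlasError("parcel ids must be >= 1 (0 is background)")
        in_volume = np.unique(lv)
        in_volume = in_volume[in_volume != 0]
        unknown = np.setdiff1d(in_volume, ids)
        if unknown.size:
            raise AtlasError(
                f"labels present in volume but absent from table: {unknown.tolist()}"
            )

    @property
    def parcel_ids(self) -> np.ndarray:
        return self.parcel_table["parcel_id"].to_numpy()

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_table)

    def mask(self, parcel_id: int) -> np.ndarray:
        """Binary mask M_p: 1 where the label volume equals ``parcel_id``."""
        return self.label_volume == int(parcel_id)

    def masks(self) -> dict[int, np.ndarray]:
        return {int(p): self.mask(p) for p in self.parcel_ids}

    def summary(self) -> dict:
        counts = self.parcel_table["group"].value_counts().to_dict()
        return {
            "n_parcels": self.n_parcels,
            "group_counts": counts,
            "shape": tuple(self.label_volume.shape),
            "n_labeled_voxels": int((self.label_volume != 0).sum()),
        }

    def name_of(self, parcel_id: int) -> str:
        row = self.parcel_table.loc[self.parcel_table["parcel_id"] == parcel_id]
        if row.empty:
            raise AtlasError(f"unknown parcel id {parcel_id}")
        r = row.iloc[0]
        return f"{r['name']} ({r['hemisphere']})"


@dataclass(frozen=True)
class TargetSet:
    """A named anatomical target: a set of parcel ids within one atlas."""

    name: str
    parcel_ids: frozenset[int]
    lateralized: bool = True

    def __len__(self) -> int:
        return len(self.parcel_ids)


@dataclass
class ConnectivityGraph:
    """Dense structural connectivity matrix for one imaging session."""

    matrix: np.ndarray
    node_ids: np.ndarray
    subject_id: str = ""
    session_id: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.node_ids = np.asarray(self.node_ids)
        validate_graph_strict(self.matrix)
        if self.matrix.shape[0] != len(self.node_ids):
            raise GraphValidationError(
                f"matrix size {self.matrix.shape[0]} != node count {len(self.node_ids)}"
            )

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class VolumeScan:
    """A 3D scan with its affine and session metadata."""

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = ""
    session_id: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.voxels.ndim}D")
        if not np.isfinite(self.voxels).all():
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)


def validate_graph_strict(m: np.ndarray, tol: float = SYMMETRY_TOL) -> None:
    """Raise a distinct error for each violated connectivity invariant."""
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise GraphValidationError(f"matrix must be square, got shape {m.shape}")
    resid = np.abs(m - m.T).max() if m.size else 0.0
    if resid > tol:
        raise AsymmetricMatrixError(f"asymmetry {resid:.3g} exceeds tolerance {tol:g}")
    if (m < 0).any():
        raise NegativeWeightError(f"{int((m < 0).sum())} negative edge weights")
    if m.size and np.abs(np.diag(m)).max() > 0:
        raise NonzeroDiagonalError("diagonal entries must be zero")


# ---------------------------------------------------------------------------
# atlas loading

def _read_parcel_table(table_path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(table_path)
    return tab


def load_atlas(label_path: str | Path, table_path: str | Path) -> AtlasParcellation:
    """Load a parcellation from a NIfTI label volume and a parcel-table CSV."""
    img = nib.load(str(label_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise AtlasError(f"label volume must be 3D, got {data.ndim}D")
    tab = _read_parcel_table(table_path)
    return AtlasParcellation(label_volume=data, parcel_table=tab, affine=img.affine)


def default_parcel_table() -> pd.DataFrame:
    """The shipped 132-parcel table (91 cortical + 15 subcortical + 26 cerebellar)."""
    with resources.files("parcelcam").joinpath("data/hoa_aal_parcels.csv").open() as f:
        return pd.read_csv(f)


def default_target_config() -> dict:
    """The shipped MTL / DMN target-set configuration."""
    with resources.files("parcelcam").joinpath("data/targets.yaml").open() as f:
        return yaml.safe_load(f)


def build_target_sets(
    atlas: AtlasParcellation | pd.DataFrame, config: dict | None = None
) -> list[TargetSet]:
    """Resolve named region lists into parcel-id target sets.

    ``config`` follows the shipped ``targets.yaml`` layout: a ``target_sets``
    mapping of set name to ``{lateralized: bool, regions: [names...]}``.  A
    region name matches every parcel-table row bearing that name, so bilateral
    structures resolve to left and right parcels.
    """
    table = atlas.parcel_table if isinstance(atlas, AtlasParcellation) else atlas
    if config is None:
        config = default_target_config()
    sets_cfg = config.get("target_sets", {})
    out: list[TargetSet] = []
    names_available = table["name"].unique().tolist()
    for set_name, spec in sets_cfg.items():
        ids: set[int] = set()
        for region in spec.get("regions", []):
            rows = table.loc[table["name"] == region, "parcel_id"]
            if rows.empty:
                hint = difflib.get_close_matches(region, names_available, n=3)
                raise AtlasError(
                    f"target set {set_name!r}: region {region!r} not in atlas; "
                    f"closest names: {hint}"
                )
            ids.update(int(p) for p in rows)
        out.append(
            TargetSet(
                name=set_name,
                parcel_ids=frozenset(ids),
                lateralized=bool(spec.get("lateralized", True)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# connectivity / volume / table I/O

def read_connectivity(
    path: str | Path,
    node_ids: np.ndarray | None = None,
    subject_id: str = "",
    session_id: str = "",
    label: str = "",
) -> ConnectivityGraph:
    """Read a dense connectivity matrix from CSV (header row = node ids).

    Validation is strict: asymmetry beyond 1e-8, negative weights, or a
    nonzero diagonal each raise their own error class; nothing is repaired.
    """
    df = pd.read_csv(path)
    m = df.to_numpy(dtype=float)
    header_ids = np.array([int(c) for c in df.columns])
    if node_ids is None:
        node_ids = header_ids
    elif not np.array_equal(np.asarray(node_ids), header_ids):
        raise GraphValidationError("CSV header node ids do not match expected node_ids")
    return ConnectivityGraph(
        matrix=m, node_ids=node_ids,
        subject_id=subject_id, session_id=session_id, label=label,
    )


def write_connectivity(g: ConnectivityGraph, path: str | Path) -> None:
    df = pd.DataFrame(g.matrix, columns=[str(int(i)) for i in g.node_ids])
    df.to_csv(path, index=False, float_format="%.10g")


def read_volume(
    path: str | Path, subject_id: str = "", session_id: str = "", label: str = ""
) -> VolumeScan:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got {data.ndim}D")
    return VolumeScan(
        voxels=data, affine=img.affine,
        subject_id=subject_id, session_id=session_id, label=label,
    )


def write_volume(v: VolumeScan, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(v.voxels, dtype=np.float32), v.affine), str(path))


RV_COLUMNS = ["session_id", "subject_id", "class_label", "parcel_id", "rv"]


def write_rv_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a relevance-value table (one row per session, parcel, class)."""
    missing = [c for c in RV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"RV table missing columns: {missing}")
    table.to_csv(path, index=False, float_format="%.17g")


def read_rv_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"session_id": str, "subject_id": str, "class_label": str}
    )
    missing = [c for c in RV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"RV table missing columns: {missing}")
    return df
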