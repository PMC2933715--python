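"""Virtual-embryo expression tables and model-bundle serialization.

A virtual embryo is a per-cell, per-time table of concentrations for a set
of species (transcription factor proteins and target mRNAs) on a common
cell grid, optionally with 3D cell-surface coordinates. The canonical
on-disk form is a wide delimited table with header
``cell_id,time[,x,y,z],<species...>``; a long form
``cell_id,time,species,value`` is accepted on read and available on write.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nede import TuningParams

__all__ = [
    "VirtualEmbryo",
    "ModelBundle",
    "EmbryoDataError",
    "ModelIOError",
    "read_embryo_table",
    "write_embryo_table",
    "normalize_concentrations",
    "save_model",
    "load_model",
]

_BUNDLE_FORMAT_VERSION = "nodeinfer-bundle-1"


class EmbryoDataError(ValueError):
    """Malformed or incomplete expression table."""


class ModelIOError(ValueError):
    """Unreadable or incompatible serialized model bundle."""


@dataclass
class VirtualEmbryo:
    """Concentration tensor with geometry.

    conc has shape (n_species, n_times, n_cells); times are strictly
    increasing; every (species, time, cell) triple has a finite value.
    """

    cell_ids: np.ndarray                 # (E,) integer labels
    times: np.ndarray                    # (T,) strictly increasing
    species: list[str]
    conc: np.ndarray                     # (S, T, E)
    coords: np.ndarray | None = None     # (E, 3) or None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.species = list(self.species)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    def validate(self) -> None:
        S, T, E = len(self.species), self.times.size, self.cell_ids.size
        if len(self.species) != len(set(self.species)):
            raise EmbryoDataError("species names must be unique")
        if S == 0:
            raise EmbryoDataError("at least one species is required")
        if self.conc.shape != (S, T, E):
            raise EmbryoDataError(
                f"conc shape {self.conc.shape} != (species, times, cells) = {(S, T, E)}")
        if not np.all(np.isfinite(self.conc)):
            raise EmbryoDataError("non-finite concentration values present")
        if T > 1 and not np.all(np.diff(self.times) > 0):
            raise EmbryoDataError("times must be strictly increasing")
        if self.coords is not None and self.coords.shape != (E, 3):
            raise EmbryoDataError(f"coords shape {self.coords.shape} != ({E}, 3)")

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    @property
    def n_times(self) -> int:
        return self.times.size

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise EmbryoDataError(f"species {name!r} not in {self.species}") from None

    def get(self, name: str) -> np.ndarray:
        """(T, E) concentration matrix for one species."""
        return self.conc[self.species_index(name)]

    def subset_times(self, times) -> "VirtualEmbryo":
        """Embryo restricted to the given time values (must all be present)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = []
        for t in times:
            hit = np.flatnonzero(np.isclose(self.times, t))
            if hit.size == 0:
                raise EmbryoDataError(f"time {t} not in grid {self.times}")
            idx.append(hit[0])
        idx = sorted(set(idx))
        return VirtualEmbryo(cell_ids=self.cell_ids, times=self.times[idx],
                             species=self.species, conc=self.conc[:, idx, :],
                             coords=self.coords)

    def subset_species(self, names) -> "VirtualEmbryo":
        idx = [self.species_index(n) for n in names]
        return VirtualEmbryo(cell_ids=self.cell_ids, times=self.times,
                             species=[self.species[i] for i in idx],
                             conc=self.conc[idx], coords=self.coords)

    def equals(self, other: "VirtualEmbryo", rtol: float = 0.0, atol: float = 0.0) -> bool:
        return (list(self.species) == list(other.species)
                and np.array_equal(self.cell_ids, other.cell_ids)
                and np.allclose(self.times, other.times, rtol=rtol, atol=atol)
                and np.allclose(self.conc, other.conc, rtol=rtol, atol=atol))


_COORD_COLS = ["x", "y", "z"]


def _read_table(path) -> pd.DataFrame:
    # comma/tab auto-detection from the header; round-trip float parsing
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_embryo_table(path, species: list[str] | None = None) -> VirtualEmbryo:
    """Load a virtual embryo from a wide or long delimited table.

    The dialect is auto-detected from the header: a table with exactly the
    columns ``cell_id,time,species,value`` (plus optional coordinates) is
    long; anything else with ``cell_id`` and ``time`` is wide, its remaining
    non-coordinate columns being species. Missing (cell, time) combinations,
    duplicated entries and non-numeric values are hard errors.
    """
    df = _read_table(path)
    cols = list(df.columns)
    if "cell_id" not in cols or "time" not in cols:
        raise EmbryoDataError(f"header must contain cell_id and time; got {cols}")
    long_form = "species" in cols and "value" in cols
    if long_form:
        df = df.rename(columns={})
        wide = df.pivot_table(index=["cell_id", "time"], columns="species",
                              values="value", aggfunc="count")
        if (wide.to_numpy() > 1).any():
            raise EmbryoDataError("duplicate (cell, time, species) entries")
        coord_df = None
        if all(c in cols for c in _COORD_COLS):
            coord_df = df.groupby("cell_id")[_COORD_COLS].first()
        df = df.pivot(index=["cell_id", "time"], columns="species",
                      values="value").reset_index()
        df.columns.name = None
        if coord_df is not None:
            df = df.merge(coord_df.reset_index(), on="cell_id")
    else:
        if df.duplicated(subset=["cell_id", "time"]).any():
            raise EmbryoDataError("duplicate (cell, time) rows in wide table")
    has_coords = all(c in df.columns for c in _COORD_COLS)
    sp_cols = [c for c in df.columns
               if c not in ("cell_id", "time") and c not in _COORD_COLS]
    if species is not None:
        missing = [s for s in species if s not in sp_cols]
        if missing:
            raise EmbryoDataError(f"requested species not in table: {missing}")
        sp_cols = list(species)
    if not sp_cols:
        raise EmbryoDataError("no species columns found")

    for c in sp_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise EmbryoDataError(
                f"non-numeric concentration for species {c!r} at table row {row + 2}")
        df[c] = vals

    cell_ids = np.sort(df["cell_id"].unique())
    times = np.sort(df["time"].unique().astype(float))
    full = pd.MultiIndex.from_product([cell_ids, times], names=["cell_id", "time"])
    indexed = df.set_index(["cell_id", "time"])
    missing_pairs = full.difference(indexed.index)
    if len(missing_pairs) > 0:
        gaps = ", ".join(str(tuple(m)) for m in list(missing_pairs)[:10])
        raise EmbryoDataError(
            f"{len(missing_pairs)} missing (cell, time) combinations; first: {gaps}")
    indexed = indexed.loc[full]
    nan_cells = indexed[sp_cols].isna()
    if nan_cells.to_numpy().any():
        first = nan_cells.stack()[lambda s: s].index[0]
        raise EmbryoDataError(f"missing concentration value at {first}")

    S, T, E = len(sp_cols), times.size, cell_ids.size
    conc = np.empty((S, T, E))
    for si, sp in enumerate(sp_cols):
        # full index is (cell-major, time-minor): reshape then transpose
        conc[si] = indexed[sp].to_numpy().reshape(E, T).T
    coords = None
    if has_coords:
        coords = indexed[_COORD_COLS].to_numpy().reshape(E, T, 3)[:, 0, :]
    return VirtualEmbryo(cell_ids=cell_ids, times=times, species=sp_cols,
                         conc=conc, coords=coords)


def write_embryo_table(embryo: VirtualEmbryo, path, dialect: str = "wide") -> None:
    """Write a virtual embryo as a wide or long CSV (>= 17 significant digits)."""
    if not embryo.species:
        raise EmbryoDataError("cannot write an embryo with an empty species list")
    if dialect not in ("wide", "long"):
        raise EmbryoDataError(f"unknown dialect {dialect!r}")
    E, T = embryo.n_cells, embryo.n_times
    cell_rep = np.repeat(embryo.cell_ids, T)
    time_rep = np.tile(embryo.times, E)
    if dialect == "wide":
        data = {"cell_id": cell_rep, "time": time_rep}
        if embryo.coords is not None:
            for j, c in enumerate(_COORD_COLS):
                data[c] = np.repeat(embryo.coords[:, j], T)
        for si, sp in enumerate(embryo.species):
            data[sp] = embryo.conc[si].T.reshape(-1)  # cell-major, time-minor
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    else:
        frames = []
        for si, sp in enumerate(embryo.species):
            frames.append(pd.DataFrame({
                "cell_id": cell_rep, "time": time_rep,
                "species": sp, "value": embryo.conc[si].T.reshape(-1)}))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                    float_format="%.17g")


def normalize_concentrations(embryo: VirtualEmbryo,
                             mode: str = "minmax_per_species") -> VirtualEmbryo:
    """Affinely map each species' concentrations onto [0, 1].

    mode 'none' returns the input unchanged; 'minmax_per_species' rescales
    each species over all (time, cell) entries. A species constant over the
    whole grid maps to all zeros (it carries no regression information).
    """
    if mode == "none":
        return embryo
    if mode != "minmax_per_species":
        raise EmbryoDataError(f"unknown normalization mode {mode!r}")
    conc = embryo.conc.copy()
    for si in range(conc.shape[0]):
        lo, hi = conc[si].min(), conc[si].max()
        conc[si] = (conc[si] - lo) / (hi - lo) if hi > lo else 0.0
    return VirtualEmbryo(cell_ids=embryo.cell_ids, times=embryo.times,
                         species=embryo.species, conc=conc, coords=embryo.coords)


# ---------------------------------------------------------------------------
# model bundles

@dataclass
class ModelBundle:
    """A full collection of local linearized models over the fitted grid.

    One local model per (time, cell) anchor: slope coefficients per factor,
    intercept, and the anchor concentration vector about which the model is
    linearized. ``kind`` distinguishes the dynamic family (response =
    smoothed target derivative), the static spatial-correlation family
    (response = target level) and the general time-series family.
    """

    kind: str                       # node | spatial_corr | general_timeseries
    tuning: TuningParams
    target: str
    factors: list[str]
    fit_times: np.ndarray           # (Tf,) time values of the fitted grid
    anchor_t: np.ndarray            # (K,) fit-time indices
    anchor_e: np.ndarray            # (K,) cell positions (0-based)
    anchor_x: np.ndarray            # (K, p)
    coeffs: np.ndarray              # (K, p)
    intercept: np.ndarray           # (K,)
    h_used: np.ndarray              # (K,) realized bandwidth per anchor
    anchor_dydt: np.ndarray | None = None   # (K,) smoothed derivative at anchors
    response_kind: str = "derivative"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fit_times = np.asarray(self.fit_times, dtype=float)
        for name in ("anchor_t", "anchor_e"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        for name in ("anchor_x", "coeffs", "intercept", "h_used"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.anchor_dydt is not None:
            self.anchor_dydt = np.asarray(self.anchor_dydt, dtype=float)
        K = self.anchor_t.size
        p = len(self.factors)
        if not (self.anchor_e.shape == (K,) and self.anchor_x.shape == (K, p)
                and self.coeffs.shape == (K, p) and self.intercept.shape == (K,)):
            raise ModelIOError("inconsistent bundle array shapes")

    @property
    def n_models(self) -> int:
        return self.anchor_t.size

    def predict(self, i: int, x: np.ndarray) -> float:
        """Evaluate local model i at factor concentrations x (= intercept at anchor)."""
        x = np.asarray(x, dtype=float)
        return float(self.coeffs[i] @ (x - self.anchor_x[i]) + self.intercept[i])

    def select(self, t_index: int) -> np.ndarray:
        """Row indices of all local models anchored at fit-time index t_index."""
        return np.flatnonzero(self.anchor_t == t_index)


_ARRAY_FIELDS = ["fit_times", "anchor_t", "anchor_e", "anchor_x", "coeffs",
                 "intercept", "h_used", "anchor_dydt"]


def save_model(bundle: ModelBundle, path) -> None:
    """Serialize a bundle: JSON for .json, HDF5 for .h5/.hdf5."""
    path = str(path)
    if path.endswith(".json"):
        doc = {"format": _BUNDLE_FORMAT_VERSION, "kind": bundle.kind,
               "tuning": bundle.tuning.to_dict(), "target": bundle.target,
               "factors": list(bundle.factors),
               "response_kind": bundle.response_kind, "meta": bundle.meta}
        for name in _ARRAY_FIELDS:
            arr = getattr(bundle, name)
            doc[name] = None if arr is None else np.asarray(arr).tolist()
        with open(path, "w") as fh:
            json.dump(doc, fh)
    elif path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["format"] = _BUNDLE_FORMAT_VERSION
            fh.attrs["kind"] = bundle.kind
            fh.attrs["target"] = bundle.target
            fh.attrs["factors"] = json.dumps(list(bundle.factors))
            fh.attrs["tuning"] = json.dumps(bundle.tuning.to_dict())
            fh.attrs["response_kind"] = bundle.response_kind
            fh.attrs["meta"] = json.dumps(bundle.meta)
            for name in _ARRAY_FIELDS:
                arr = getattr(bundle, name)
                if arr is not None:
                    fh.create_dataset(name, data=np.asarray(arr))
    else:
        raise ModelIOError(f"unsupported model extension for {path!r} "
                           "(use .json, .h5 or .hdf5)")


def load_model(path) -> ModelBundle:
    """Inverse of :func:`save_model`; errors on truncation or version mismatch."""
    path = str(path)
    fields: dict = {}
    if path.endswith(".json"):
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except (json.JSONDecodeError, OSError) as exc:
            raise ModelIOError(f"cannot read model bundle {path!r}: {exc}") from exc
        if doc.get("format") != _BUNDLE_FORMAT_VERSION:
            raise ModelIOError(
                f"bundle format {doc.get('format')!r} != {_BUNDLE_FORMAT_VERSION!r}")
        fields = {"kind": doc["kind"], "tuning": TuningParams.from_dict(doc["tuning"]),
                  "target": doc["target"], "factors": doc["factors"],
                  "response_kind": doc["response_kind"], "meta": doc.get("meta", {})}
        for name in _ARRAY_FIELDS:
            val = doc.get(name)
            fields[name] = None if val is None else np.asarray(val)
    elif path.endswith((".h5", ".hdf5")):
        import h5py

        try:
            fh = h5py.File(path, "r")
        except OSError as exc:
            raise ModelIOError(f"cannot read model bundle {path!r}: {exc}") from exc
        with fh:
            if fh.attrs.get("format") != _BUNDLE_FORMAT_VERSION:
                raise ModelIOError(
                    f"bundle format {fh.attrs.get('format')!r} != "
                    f"{_BUNDLE_FORMAT_VERSION!r}")
            fields = {"kind": fh.attrs["kind"],
                      "tuning": TuningParams.from_dict(json.loads(fh.attrs["tuning"])),
                      "target": fh.attrs["target"],
                      "factors": json.loads(fh.attrs["factors"]),
                      "response_kind": fh.attrs["response_kind"],
                      "meta": json.loads(fh.attrs["meta"])}
            for name in _ARRAY_FIELDS:
                fields[name] = fh[name][...] if name in fh else None
    else:
        raise ModelIOError(f"unsupported model extension for {path!r}")
    return ModelBundle(**fields)
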