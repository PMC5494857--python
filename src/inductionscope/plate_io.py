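"""Reading, validating and writing microtiter-plate time-series datasets.

The canonical on-disk representation is a pair of tidy UTF-8 CSV files:

* a long-format time-series file with columns
  ``plate_id,well_id,time_h,channel,value`` where the ``scattered_light``
  channel is mandatory and further channels (e.g. ``fbfp``) are optional;
* a per-well metadata file with columns
  ``plate_id,well_id,strain,product,temperature_C,inducer_conc_uM,
  induction_time_h,induced,is_reference,mtp_format,device_id`` plus the
  optional columns ``filling_volume_uL,shaking_frequency_rpm,
  shaking_diameter_mm,final_expression``.

Floats are serialized with 17 significant digits so a write→load round trip
is exact. Times are hours throughout; a reader flag converts from minutes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from inductionscope.errors import PlateFormatError, PlateValidationError

logger = logging.getLogger(__name__)

SCATTERED_LIGHT = "scattered_light"
TIMESERIES_COLUMNS = ["plate_id", "well_id", "time_h", "channel", "value"]
METADATA_COLUMNS = [
    "plate_id",
    "well_id",
    "strain",
    "product",
    "temperature_C",
    "inducer_conc_uM",
    "induction_time_h",
    "induced",
    "is_reference",
    "mtp_format",
    "device_id",
]
METADATA_OPTIONAL = [
    "filling_volume_uL",
    "shaking_frequency_rpm",
    "shaking_diameter_mm",
    "final_expression",
]
MTP_FORMATS = ("well48", "well96")

#: 17 significant digits: lossless text round trip for IEEE-754 doubles.
FLOAT_FORMAT = "%.17g"


@dataclass
class CultureMetadata:
    """Static description of one well: strain, induction settings, device.

    Invariants enforced on construction: ``induced`` is false exactly when
    no inducer was added, and a reference well is never induced.
    """

    plate_id: str
    well_id: str
    strain: str = ""
    product: str = ""
    temperature: float = 30.0
    inducer_conc: float = 0.0
    induction_time: float | None = None
    induced: bool = False
    is_reference: bool = False
    mtp_format: str = "well48"
    device_id: str = ""
    filling_volume: float | None = None
    shaking_frequency: float | None = None
    shaking_diameter: float | None = None

    def __post_init__(self) -> None:
        if self.inducer_conc < 0:
            raise PlateValidationError(
                f"{self.plate_id}/{self.well_id}: inducer_conc must be >= 0"
            )
        if self.induction_time is not None and self.induction_time < 0:
            raise PlateValidationError(
                f"{self.plate_id}/{self.well_id}: induction_time must be >= 0"
            )
        if self.induced != (self.inducer_conc > 0):
            raise PlateValidationError(
                f"{self.plate_id}/{self.well_id}: induced flag inconsistent with "
                f"inducer_conc={self.inducer_conc}"
            )
        if self.is_reference and self.induced:
            raise PlateValidationError(
                f"{self.plate_id}/{self.well_id}: a reference well cannot be induced"
            )
        if self.mtp_format not in MTP_FORMATS:
            raise PlateValidationError(
                f"{self.plate_id}/{self.well_id}: mtp_format must be one of {MTP_FORMATS}"
            )


@dataclass
class CultureRecord:
    """One well's time series: scattered light plus optional fluorescence.

    ``times`` are hours, strictly increasing; every signal vector has the
    same length as ``times`` and contains only finite values. Scattered
    light is non-negative (arbitrary units). ``final_expression`` is the
    endpoint product measurement (final fluorescence or offline enzyme
    activity) when available.
    """

    metadata: CultureMetadata
    times: np.ndarray
    scattered_light: np.ndarray
    fluorescence_channels: dict[str, np.ndarray] = field(default_factory=dict)
    final_expression: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.scattered_light = np.asarray(self.scattered_light, dtype=float)
        where = f"{self.metadata.plate_id}/{self.metadata.well_id}"
        if self.times.ndim != 1 or self.times.size < 3:
            raise PlateValidationError(f"{where}: need a 1-D time vector of >= 3 points")
        if not np.all(np.isfinite(self.times)) or np.any(np.diff(self.times) <= 0):
            raise PlateValidationError(f"{where}: times must be finite and strictly increasing")
        if self.scattered_light.shape != self.times.shape:
            raise PlateValidationError(f"{where}: scattered_light length != times length")
        if not np.all(np.isfinite(self.scattered_light)) or np.any(self.scattered_light < 0):
            raise PlateValidationError(f"{where}: scattered_light must be finite and >= 0")
        self.fluorescence_channels = {
            name: np.asarray(vals, dtype=float)
            for name, vals in self.fluorescence_channels.items()
        }
        for name, vals in self.fluorescence_channels.items():
            if vals.shape != self.times.shape or not np.all(np.isfinite(vals)):
                raise PlateValidationError(f"{where}: channel {name!r} invalid length or values")

    @property
    def well(self) -> str:
        return f"{self.metadata.plate_id}/{self.metadata.well_id}"


@dataclass
class PlateDataset:
    """A collection of cultures with unique (plate_id, well_id) pairs."""

    cultures: list[CultureRecord]
    dataset_id: str = ""

    def __post_init__(self) -> None:
        keys = [(c.metadata.plate_id, c.metadata.well_id) for c in self.cultures]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise PlateValidationError(f"duplicate (plate_id, well_id) pairs: {dupes}")

    def __len__(self) -> int:
        return len(self.cultures)

    def __iter__(self):
        return iter(self.cultures)

    def get(self, plate_id: str, well_id: str) -> CultureRecord:
        for c in self.cultures:
            if c.metadata.plate_id == plate_id and c.metadata.well_id == well_id:
                return c
        raise KeyError(f"{plate_id}/{well_id} not in dataset")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_str(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return str(value)


def _parse_bool(value, where: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise PlateValidationError(f"{where}: cannot parse boolean {value!r}")


def _metadata_from_row(row: pd.Series) -> CultureMetadata:
    where = f"{row['plate_id']}/{row['well_id']}"
    conc = _opt_float(row.get("inducer_conc_uM"))
    return CultureMetadata(
        plate_id=str(row["plate_id"]),
        well_id=str(row["well_id"]),
        strain=_opt_str(row.get("strain")),
        product=_opt_str(row.get("product")),
        temperature=float(row.get("temperature_C", 30.0)),
        inducer_conc=0.0 if conc is None else conc,
        induction_time=_opt_float(row.get("induction_time_h")),
        induced=_parse_bool(row["induced"], where),
        is_reference=_parse_bool(row["is_reference"], where),
        mtp_format=str(row["mtp_format"]),
        device_id=_opt_str(row.get("device_id")),
        filling_volume=_opt_float(row.get("filling_volume_uL")),
        shaking_frequency=_opt_float(row.get("shaking_frequency_rpm")),
        shaking_diameter=_opt_float(row.get("shaking_diameter_mm")),
    )


def load_plate_csv(
    path,
    metadata_path,
    time_unit: str = "hours",
    dataset_id: str = "",
) -> PlateDataset:
    """Load a long-format time-series CSV plus its per-well metadata CSV.

    One :class:`CultureRecord` is built per (plate_id, well_id) present in
    the time-series file; its times are sorted ascending with all channels
    co-sorted. Rows with non-finite signal values are dropped with a logged
    count. Loading is invariant to the row order of the input.

    Parameters
    ----------
    path, metadata_path
        Time-series and metadata CSV paths.
    time_unit
        ``"hours"`` (default) or ``"minutes"``; minutes are converted to
        hours on load.
    dataset_id
        Identifier stored on the returned dataset (defaults to the
        time-series file stem).
    """
    if time_unit not in ("hours", "minutes"):
        raise ValueError(f"time_unit must be 'hours' or 'minutes', got {time_unit!r}")
    try:
        ts = pd.read_csv(
            path,
            dtype={"plate_id": str, "well_id": str, "channel": str},
            float_precision="round_trip",
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise PlateFormatError(f"cannot parse time-series file {path}: {exc}") from exc
    missing = [c for c in TIMESERIES_COLUMNS if c not in ts.columns]
    if missing:
        raise PlateFormatError(f"{path}: missing mandatory column(s) {missing}")

    meta_df = pd.read_csv(
        metadata_path, dtype={"plate_id": str, "well_id": str}, float_precision="round_trip"
    )
    missing = [c for c in METADATA_COLUMNS if c not in meta_df.columns]
    if missing:
        raise PlateFormatError(f"{metadata_path}: missing mandatory column(s) {missing}")
    meta_by_well = {}
    for _, row in meta_df.iterrows():
        key = (str(row["plate_id"]), str(row["well_id"]))
        if key in meta_by_well:
            raise PlateValidationError(f"{metadata_path}: duplicate metadata row for {key}")
        meta_by_well[key] = row

    ts = ts.copy()
    ts["time_h"] = pd.to_numeric(ts["time_h"], errors="coerce")
    ts["value"] = pd.to_numeric(ts["value"], errors="coerce")
    if ts["time_h"].isna().any():
        raise PlateValidationError(f"{path}: non-numeric time values")
    n_bad = int((~np.isfinite(ts["value"])).sum())
    if n_bad:
        logger.warning("%s: dropped %d rows with non-finite signal values", path, n_bad)
        ts = ts[np.isfinite(ts["value"])]
    if time_unit == "minutes":
        ts["time_h"] = ts["time_h"] / 60.0

    dup = ts.duplicated(subset=["plate_id", "well_id", "time_h", "channel"])
    if dup.any():
        first = ts[dup].iloc[0]
        raise PlateValidationError(
            f"{path}: duplicate row for ({first['plate_id']}, {first['well_id']}, "
            f"t={first['time_h']}, {first['channel']})"
        )

    cultures: list[CultureRecord] = []
    for key, group in ts.groupby(["plate_id", "well_id"], sort=False):
        key = (str(key[0]), str(key[1]))
        if key not in meta_by_well:
            raise PlateValidationError(f"no metadata row for well {key}")
        row = meta_by_well[key]
        wide = group.pivot(index="time_h", columns="channel", values="value").sort_index()
        if SCATTERED_LIGHT not in wide.columns:
            raise PlateValidationError(f"{key}: no '{SCATTERED_LIGHT}' channel")
        if wide[SCATTERED_LIGHT].isna().any():
            raise PlateValidationError(
                f"{key}: '{SCATTERED_LIGHT}' not observed at every time point"
            )
        channels = {}
        for name in wide.columns:
            if name == SCATTERED_LIGHT:
                continue
            if wide[name].isna().any():
                raise PlateValidationError(f"{key}: channel {name!r} not on the common time grid")
            channels[str(name)] = wide[name].to_numpy()
        cultures.append(
            CultureRecord(
                metadata=_metadata_from_row(row),
                times=wide.index.to_numpy(),
                scattered_light=wide[SCATTERED_LIGHT].to_numpy(),
                fluorescence_channels=channels,
                final_expression=_opt_float(row.get("final_expression")),
            )
        )
    # deterministic order regardless of input row order
    cultures.sort(key=lambda c: (c.metadata.plate_id, c.metadata.well_id))
    if not dataset_id:
        dataset_id = str(path)
    return PlateDataset(cultures=cultures, dataset_id=dataset_id)


def write_plate_csv(dataset: PlateDataset, path, metadata_path) -> None:
    """Write a dataset back to the canonical CSV pair.

    ``load_plate_csv(*write_plate_csv(...))`` reproduces all numeric fields
    exactly (17-significant-digit serialization) and all metadata fields.
    An empty dataset yields header-only files.
    """
    ts_rows = []
    meta_rows = []
    for c in sorted(dataset.cultures, key=lambda c: (c.metadata.plate_id, c.metadata.well_id)):
        m = c.metadata
        for name, vals in [(SCATTERED_LIGHT, c.scattered_light)] + sorted(
            c.fluorescence_channels.items()
        ):
            for t, v in zip(c.times, vals):
                ts_rows.append((m.plate_id, m.well_id, t, name, v))
        meta_rows.append(
            {
                "plate_id": m.plate_id,
                "well_id": m.well_id,
                "strain": m.strain,
                "product": m.product,
                "temperature_C": m.temperature,
                "inducer_conc_uM": m.inducer_conc,
                "induction_time_h": m.induction_time,
                "induced": m.induced,
                "is_reference": m.is_reference,
                "mtp_format": m.mtp_format,
                "device_id": m.device_id,
                "filling_volume_uL": m.filling_volume,
                "shaking_frequency_rpm": m.shaking_frequency,
                "shaking_diameter_mm": m.shaking_diameter,
                "final_expression": c.final_expression,
            }
        )
    ts_df = pd.DataFrame(ts_rows, columns=TIMESERIES_COLUMNS)
    ts_df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    meta_df = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS + METADATA_OPTIONAL)
    meta_df.to_csv(metadata_path, index=False, float_format=FLOAT_FORMAT)


def od_from_scattered_light(sl, proportionality_factor: float = 4.0):
    """Convert a scattered-light reading (a.u.) to an OD600 estimate.

    Scattered light is only a biomass proxy; for a device with a known
    proportionality between the two scales, OD600 ≈ SL / factor. The
    default factor of 4 matches a BioLector-type setup where a reading of
    20 a.u. corresponds to an optical density of about 5.
    """
    sl = np.asarray(sl, dtype=float)
    if proportionality_factor <= 0:
        raise ValueError("proportionality_factor must be > 0")
    if np.any(sl < 0):
        raise ValueError("scattered light must be >= 0")
    out = sl / proportionality_factor
    return float(out) if out.ndim == 0 else out
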