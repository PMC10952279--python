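"""Delimited-text readers and writers for every pipeline table.

All interfaces are plain delimited text (comma by default, tab accepted) so
intermediate results stay inspectable; tables are small (at most 448
regions x 5 bands).  Regions are matched by label, never by row order.
Floats are written at full precision, so write -> read round-trips exactly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bandpower import Band, BandPowerTable, BandScheme, RegionTimeSeries
from .markers import MarkerSet, ResectionMask
from .normative import AbnormalityMap, NormativeMap

__all__ = [
    "read_time_series",
    "write_time_series",
    "read_band_power_table",
    "write_band_power_table",
    "read_normative_map",
    "write_normative_map",
    "read_abnormality_map",
    "write_abnormality_map",
    "read_volumes",
    "write_volumes",
    "read_mask",
    "write_mask",
    "read_marker_table",
    "write_marker_table",
    "read_outcomes",
    "write_outcomes",
    "band_scheme_from_config",
]


def _float_repr(v: float) -> str:
    """Shortest round-tripping float representation."""
    return repr(float(v))


def _read_csv(path: str | Path, **kw) -> pd.DataFrame:
    """Read comma- or tab-delimited text, sniffing the delimiter from the
    header line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if ("\t" in header and "," not in header) else ","
    try:
        return pd.read_csv(path, sep=sep, comment="#",
                           float_precision="round_trip", **kw)
    except Exception as exc:  # pragma: no cover - message wrapping
        raise ValueError(f"could not parse {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")


# -- region time series -------------------------------------------------------

def read_time_series(path: str | Path, fs: float) -> RegionTimeSeries:
    """First column = region id, remaining columns = samples."""
    df = _read_csv(path, header=None)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected a region id column plus samples")
    region_ids = [str(r) for r in df.iloc[:, 0]]
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    return RegionTimeSeries(region_ids=region_ids, data=data, fs=fs)


def write_time_series(ts: RegionTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.data)
    df.insert(0, "region", ts.region_ids)
    df.to_csv(path, index=False, header=False, float_format=_float_repr)


# -- band power tables --------------------------------------------------------

def read_band_power_table(path: str | Path) -> BandPowerTable:
    """Schema: subject,region,<band1>,...; row sums are validated to 1."""
    df = _read_csv(path)
    _require_columns(df, ["subject", "region"], path)
    band_names = [c for c in df.columns if c not in ("subject", "region")]
    if not band_names:
        raise ValueError(f"{path}: no band columns found")
    subjects = df["subject"].unique()
    if len(subjects) != 1:
        raise ValueError(f"{path}: expected one subject per table, found {list(subjects)}")
    try:
        return BandPowerTable(
            subject_id=str(subjects[0]),
            region_ids=[str(r) for r in df["region"]],
            band_names=band_names,
            values=df[band_names].to_numpy(dtype=float),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_band_power_table(table: BandPowerTable, path: str | Path) -> None:
    df = pd.DataFrame(table.values, columns=table.band_names)
    df.insert(0, "region", table.region_ids)
    df.insert(0, "subject", table.subject_id)
    df.to_csv(path, index=False, float_format=_float_repr)


# -- normative maps -----------------------------------------------------------

def read_normative_map(path: str | Path) -> NormativeMap:
    """Long format region,band,mu,sigma with a ``# n_controls=N`` header."""
    n_controls = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "n_controls=" in line:
                n_controls = int(line.split("n_controls=")[1].strip())
            if not line.startswith("#"):
                break
    if n_controls is None:
        raise ValueError(f"{path}: missing '# n_controls=N' header line")
    df = _read_csv(path)
    _require_columns(df, ["region", "band", "mu", "sigma"], path)
    region_ids = list(dict.fromkeys(str(r) for r in df["region"]))
    band_names = list(dict.fromkeys(str(b) for b in df["band"]))
    mu = np.full((len(region_ids), len(band_names)), np.nan)
    sigma = np.full_like(mu, np.nan)
    ridx = {r: i for i, r in enumerate(region_ids)}
    bidx = {b: j for j, b in enumerate(band_names)}
    for row in df.itertuples():
        i, j = ridx[str(row.region)], bidx[str(row.band)]
        mu[i, j], sigma[i, j] = row.mu, row.sigma
    if np.isnan(mu).any() or np.isnan(sigma).any():
        raise ValueError(f"{path}: incomplete region x band grid")
    return NormativeMap(
        region_ids=region_ids, band_names=band_names, mu=mu, sigma=sigma,
        n_controls=n_controls,
    )


def write_normative_map(norm: NormativeMap, path: str | Path) -> None:
    rows = []
    for i, r in enumerate(norm.region_ids):
        for j, b in enumerate(norm.band_names):
            rows.append((r, b, norm.mu[i, j], norm.sigma[i, j]))
    df = pd.DataFrame(rows, columns=["region", "band", "mu", "sigma"])
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format=_float_repr)
    Path(path).write_text(f"# n_controls={norm.n_controls}\n" + buf.getvalue())


# -- abnormality maps ---------------------------------------------------------

def read_abnormality_map(path: str | Path, subject_id: str | None = None) -> AbnormalityMap:
    df = _read_csv(path)
    _require_columns(df, ["region", "max_abs_z", "argmax_band"], path)
    return AbnormalityMap(
        subject_id=subject_id or Path(path).stem,
        region_ids=[str(r) for r in df["region"]],
        max_abs_z=df["max_abs_z"].to_numpy(dtype=float),
        argmax_band=[str(b) for b in df["argmax_band"]],
    )


def write_abnormality_map(abn: AbnormalityMap, path: str | Path) -> None:
    pd.DataFrame(
        {"region": abn.region_ids, "max_abs_z": abn.max_abs_z, "argmax_band": abn.argmax_band}
    ).to_csv(path, index=False, float_format=_float_repr)


# -- resection volumes and masks ----------------------------------------------

def read_volumes(path: str | Path) -> tuple[dict, dict]:
    df = _read_csv(path)
    _require_columns(df, ["region", "pre_volume", "post_volume"], path)
    pre = {str(r.region): float(r.pre_volume) for r in df.itertuples()}
    post = {str(r.region): float(r.post_volume) for r in df.itertuples()}
    return pre, post


def write_volumes(pre: dict, post: dict, path: str | Path) -> None:
    pd.DataFrame(
        {"region": list(pre), "pre_volume": list(pre.values()),
         "post_volume": [post[r] for r in pre]}
    ).to_csv(path, index=False, float_format=_float_repr)


def read_mask(path: str | Path) -> ResectionMask:
    df = _read_csv(path)
    _require_columns(df, ["region", "status"], path)
    return ResectionMask(
        region_ids=[str(r) for r in df["region"]],
        status=[str(s) for s in df["status"]],
    )


def write_mask(mask: ResectionMask, path: str | Path) -> None:
    pd.DataFrame({"region": mask.region_ids, "status": mask.status}).to_csv(
        path, index=False
    )


# -- markers and outcomes -----------------------------------------------------

def read_marker_table(path: str | Path) -> list[MarkerSet]:
    df = _read_csv(path)
    _require_columns(df, ["subject", "MA_R", "D_RS", "AC_R"], path)
    return [
        MarkerSet(str(r.subject), float(r.MA_R), float(r.D_RS), float(r.AC_R))
        for r in df.itertuples()
    ]


def write_marker_table(markers: list[MarkerSet], path: str | Path) -> None:
    pd.DataFrame(
        {"subject": [m.subject_id for m in markers],
         "MA_R": [m.ma_r for m in markers],
         "D_RS": [m.d_rs for m in markers],
         "AC_R": [m.ac_r for m in markers]}
    ).to_csv(path, index=False, float_format=_float_repr)


def read_outcomes(path: str | Path) -> dict:
    df = _read_csv(path)
    _require_columns(df, ["subject", "outcome"], path)
    return {str(r.subject): str(r.outcome) for r in df.itertuples()}


def write_outcomes(outcomes: dict, path: str | Path) -> None:
    pd.DataFrame({"subject": list(outcomes), "outcome": list(outcomes.values())}).to_csv(
        path, index=False
    )


# -- band scheme configuration ------------------------------------------------

def band_scheme_from_config(path: str | Path) -> BandScheme:
    """Load a band scheme from YAML::

        bands:
          - {name: delta, low: 1, high: 4}
          - {name: gamma, low: 30, high: 80, exclusions: [[47.5, 52.5]]}
    """
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or "bands" not in cfg:
        raise ValueError(f"{path}: expected a mapping with a 'bands' list")
    bands = []
    for entry in cfg["bands"]:
        bands.append(
            Band(
                name=str(entry["name"]),
                low=float(entry["low"]),
                high=float(entry["high"]),
                exclusions=tuple(
                    (float(lo), float(hi)) for lo, hi in entry.get("exclusions", [])
                ),
            )
        )
    return BandScheme(bands=tuple(bands))
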