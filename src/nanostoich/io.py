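"""Reading and writing multi-channel ion-count image stacks.

Two on-disk layouts are supported:

* a multi-page TIFF (one uint16/uint32 page per channel) next to a YAML
  sidecar ``<stem>.yaml`` listing channel order and acquisition metadata;
* a directory of whitespace-delimited integer matrices named
  ``<species_label>.txt`` with a ``stack.yaml`` sidecar.

Counts are kept as unsigned integers throughout.  Files containing
non-integer or negative pixel values are rejected rather than rounded:
the downstream Poisson counting-error model is only valid on raw counts.
The vendor raw format (.im) is not parsed; convert externally.

The experiment manifest is a TSV with columns ``sample_id``, ``run_type``,
``path``, ``exposure_concentration_uM``, ``is_control`` (and optionally
``mask_path``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .channels import REQUIRED_CHANNELS, ChannelSpec, channel
from .errors import InvalidCountsError, MissingChannelError

RUN_TYPES = ("pt_run", "n_run")


@dataclass
class IonCountMap:
    """A single channel's 2-D grid of raw ion counts.

    Pixel coordinates are 0-based, row-major, origin at top-left; a pixel
    is addressed ``(row, col)``, matching raster-scan acquisition order.

    Parameters
    ----------
    channel : ChannelSpec
        The detected species.
    counts : ndarray of uint
        Non-negative integer counts, shape ``(rows, cols)``.
    pixel_size : float
        Pixel edge length in μm.
    dwell_time : float
        Dwell time per pixel in ms.
    """

    channel: ChannelSpec
    counts: np.ndarray
    pixel_size: float
    dwell_time: float

    def __post_init__(self):
        self.counts = _validate_counts(self.counts, self.channel.species_label)
        if self.counts.ndim != 2 or min(self.counts.shape) < 1:
            raise ValueError("counts must be a non-empty 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (μm)")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive (ms)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total(self) -> int:
        """Total counts over the frame."""
        return int(self.counts.sum(dtype=np.int64))


def _validate_counts(arr, label: str) -> np.ndarray:
    """Coerce to uint32, rejecting negative or non-integral values."""
    arr = np.asarray(arr)
    if arr.dtype.kind == "f":
        bad = ~np.isfinite(arr) | (arr != np.floor(arr)) | (arr < 0)
        if bad.any():
            coords = list(zip(*np.nonzero(bad)))
            raise InvalidCountsError(label, coords)
        arr = arr.astype(np.int64)
    if arr.dtype.kind not in "iu":
        raise InvalidCountsError(label, [])
    if arr.dtype.kind == "i" and (arr < 0).any():
        coords = list(zip(*np.nonzero(arr < 0)))
        raise InvalidCountsError(label, coords)
    return arr.astype(np.uint32)


@dataclass
class AcquisitionStack:
    """Co-registered ion-count maps from one acquisition run of one sample.

    Parameters
    ----------
    sample_id : str
    run_type : {"pt_run", "n_run"}
        ``pt_run`` must contain 194Pt and 12C2; ``n_run`` must contain
        12C14N, 12C15N and 12C2.
    maps : dict
        species_label -> :class:`IonCountMap`; all maps share grid
        dimensions, pixel size and dwell time.
    exposure_concentration : float
        Drug exposure concentration in μM; 0 for controls.
    is_control : bool
    metadata : dict
        Free-form extras (e.g. sub-pixel registration residual).
    """

    sample_id: str
    run_type: str
    maps: dict[str, IonCountMap]
    exposure_concentration: float = 0.0
    is_control: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.run_type not in RUN_TYPES:
            raise ValueError(f"run_type must be one of {RUN_TYPES}")
        for required in REQUIRED_CHANNELS[self.run_type]:
            if required not in self.maps:
                raise MissingChannelError(required, self.run_type)
        shapes = {m.shape for m in self.maps.values()}
        meta = {(m.pixel_size, m.dwell_time) for m in self.maps.values()}
        if len(shapes) != 1 or len(meta) != 1:
            raise ValueError("all maps in a stack must share dims, pixel_size, dwell_time")
        if self.is_control and self.exposure_concentration != 0:
            raise ValueError("a control stack must have exposure_concentration 0")
        if self.exposure_concentration < 0:
            raise ValueError("exposure_concentration must be ≥ 0 μM")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.maps.values())).shape

    @property
    def pixel_size(self) -> float:
        return next(iter(self.maps.values())).pixel_size

    @property
    def dwell_time(self) -> float:
        return next(iter(self.maps.values())).dwell_time

    @property
    def channel_order(self) -> tuple[str, ...]:
        return tuple(self.maps)

    def channel(self, species_label: str) -> IonCountMap:
        try:
            return self.maps[species_label]
        except KeyError:
            raise MissingChannelError(species_label, self.run_type) from None

    def with_counts(self, new_counts: Mapping[str, np.ndarray]) -> "AcquisitionStack":
        """Copy of the stack with some channels' count grids replaced."""
        maps = {
            lbl: IonCountMap(m.channel, new_counts.get(lbl, m.counts),
                             m.pixel_size, m.dwell_time)
            for lbl, m in self.maps.items()
        }
        return AcquisitionStack(self.sample_id, self.run_type, maps,
                                self.exposure_concentration, self.is_control,
                                dict(self.metadata))


def _sidecar_dict(stack: AcquisitionStack) -> dict:
    return {
        "sample_id": stack.sample_id,
        "run_type": stack.run_type,
        "channels": [
            {"species_label": m.channel.species_label,
             "nominal_mass": m.channel.nominal_mass,
             "role": m.channel.role}
            for m in stack.maps.values()
        ],
        "pixel_size_um": float(stack.pixel_size),
        "dwell_time_ms": float(stack.dwell_time),
        "exposure_concentration_uM": float(stack.exposure_concentration),
        "is_control": bool(stack.is_control),
    }


def write_stack(stack: AcquisitionStack, path: str | os.PathLike) -> Path:
    """Write a stack to ``path``.

    A path ending in ``.tif``/``.tiff`` produces a multi-page TIFF in the
    stack's declared channel order plus a ``<stem>.yaml`` sidecar;
    any other path is treated as a directory of ``<species_label>.txt``
    integer matrices with a ``stack.yaml`` sidecar.  The result is
    re-readable by :func:`read_stack` with bit-identical counts.
    """
    path = Path(path)
    side = _sidecar_dict(stack)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        pages = np.stack([m.counts for m in stack.maps.values()])
        tifffile.imwrite(path, pages.astype(np.uint32),
                         photometric="minisblack")
        path.with_suffix(".yaml").write_text(yaml.safe_dump(side, sort_keys=False))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for lbl, m in stack.maps.items():
            np.savetxt(path / f"{lbl}.txt", m.counts, fmt="%d")
        (path / "stack.yaml").write_text(yaml.safe_dump(side, sort_keys=False))
    return path


def read_stack(path: str | os.PathLike,
               manifest_entry: Mapping | None = None) -> AcquisitionStack:
    """Read a stack written by :func:`write_stack`.

    Parameters
    ----------
    path
        Multi-page TIFF (with ``<stem>.yaml`` sidecar) or directory of
        per-channel text matrices (with ``stack.yaml`` sidecar).
    manifest_entry
        Optional mapping overriding ``sample_id``, ``run_type``,
        ``exposure_concentration_uM`` and ``is_control`` from the sidecar
        (the manifest is authoritative when both are present).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        side = yaml.safe_load((path / "stack.yaml").read_text())
        loader = lambda lbl: np.loadtxt(path / f"{lbl}.txt", ndmin=2)
    else:
        side = yaml.safe_load(path.with_suffix(".yaml").read_text())
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        order = [c["species_label"] for c in side["channels"]]
        page_of = dict(zip(order, pages))
        loader = lambda lbl: page_of[lbl]

    entry = dict(manifest_entry or {})
    sample_id = str(entry.get("sample_id", side["sample_id"]))
    run_type = str(entry.get("run_type", side["run_type"]))
    conc = float(entry.get("exposure_concentration_uM",
                           side.get("exposure_concentration_uM", 0.0)))
    is_control = bool(entry.get("is_control", side.get("is_control", False)))

    maps: dict[str, IonCountMap] = {}
    for chan in side["channels"]:
        lbl = chan["species_label"]
        spec = ChannelSpec(lbl, int(chan["nominal_mass"]), chan["role"])
        maps[lbl] = IonCountMap(spec, loader(lbl),
                                float(side["pixel_size_um"]),
                                float(side["dwell_time_ms"]))
    return AcquisitionStack(sample_id, run_type, maps, conc, is_control)


MANIFEST_COLUMNS = ("sample_id", "run_type", "path",
                    "exposure_concentration_uM", "is_control")


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read the experiment manifest TSV.

    Relative ``path`` (and ``mask_path``) entries are resolved against the
    manifest's own directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    df["is_control"] = df["is_control"].astype(bool)
    base = path.parent
    for col in ("path", "mask_path"):
        if col in df.columns:
            df[col] = [str((base / p)) if not os.path.isabs(str(p)) else str(p)
                       for p in df[col]]
    return df


def write_manifest(df: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def make_channel_map(species_label: str, counts: np.ndarray,
                     pixel_size: float, dwell_time: float) -> IonCountMap:
    """Convenience constructor using the canonical channel table."""
    return IonCountMap(channel(species_label), counts, pixel_size, dwell_time)
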