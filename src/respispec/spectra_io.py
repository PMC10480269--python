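"""Reading and writing time-resolved spectra.

Two on-disk representations are supported so simulated cubes and real
spectrometer-software exports flow through the same recovery pipeline:

``frames_tsv``
    One two-column tab-delimited text file per frame (wavelength_nm,
    intensity_counts), with '#'-prefixed header lines carrying the frame
    index, the acquisition time in seconds and an ISO timestamp.
    Zero-padded frame indices make lexicographic filename order equal time
    order.  Mirrors typical vendor exports and stays greppable.

``cube``
    A single HDF5 container holding the intensity matrix, both axes and
    the acquisition metadata; fast and lossless.

Both formats round-trip the float64 data bit-exactly.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .acquisition import TimeResolvedSpectra

__all__ = [
    "SpectraFormatError",
    "SpectraFileSet",
    "write_frames",
    "read_frames",
    "write_cube",
    "read_cube",
]

_EPOCH = _dt.datetime(2000, 1, 1, tzinfo=_dt.timezone.utc)
_FRAME_GLOB = "frame_*.tsv"


class SpectraFormatError(ValueError):
    """A spectra file or fileset violates the expected format."""


@dataclass
class SpectraFileSet:
    """Handle to an on-disk spectra container."""

    format: str  # "frames_tsv" or "cube"
    paths: list[Path] = field(default_factory=list)

    @property
    def directory(self) -> Path:
        return self.paths[0].parent if self.paths else Path(".")


def write_frames(spectra: TimeResolvedSpectra, directory) -> SpectraFileSet:
    """Write one text file per frame into ``directory`` (created if needed)."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create frame directory {directory}: {exc}") from exc
    paths = []
    width = max(6, len(str(max(spectra.n_frames - 1, 0))))
    for k in range(spectra.n_frames):
        t = spectra.time_axis[k]
        stamp = (_EPOCH + _dt.timedelta(seconds=float(t))).isoformat()
        path = directory / f"frame_{k:0{width}d}.tsv"
        lines = [
            f"# frame {k}",
            f"# time_s {t:.17g}",
            f"# timestamp {stamp}",
            "# wavelength_nm\tintensity_counts",
        ]
        lines.extend(
            f"{wl:.17g}\t{iv:.17g}"
            for wl, iv in zip(spectra.wavelength_axis, spectra.intensities[k])
        )
        try:
            path.write_text("\n".join(lines) + "\n")
        except OSError as exc:
            raise OSError(f"cannot write frame file {path}: {exc}") from exc
        paths.append(path)
    return SpectraFileSet(format="frames_tsv", paths=paths)


def _parse_frame(path: Path) -> tuple[float | None, np.ndarray, np.ndarray]:
    time_s = None
    wl, iv = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("time_s "):
                time_s = float(body.split()[1])
            elif body.startswith("timestamp ") and time_s is None:
                stamp = _dt.datetime.fromisoformat(body.split(None, 1)[1])
                time_s = (stamp - _EPOCH).total_seconds()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SpectraFormatError(
                f"{path}: expected 2 tab-separated columns, got {len(parts)}"
            )
        wl.append(float(parts[0]))
        iv.append(float(parts[1]))
    if not wl:
        raise SpectraFormatError(f"{path}: no data rows")
    return time_s, np.array(wl), np.array(iv)


def read_frames(
    source, sample_rate: float | None = None, metadata: dict | None = None
) -> TimeResolvedSpectra:
    """Assemble a cube from per-frame text files.

    ``source`` is a :class:`SpectraFileSet` or a directory containing
    ``frame_*.tsv`` files.  The time axis comes from the per-frame
    timestamps; when the files carry none, ``sample_rate`` must be given
    and a uniform axis 0, 1/rate, 2/rate, ... is used.
    """
    if isinstance(source, SpectraFileSet):
        paths = sorted(source.paths)
    else:
        paths = sorted(Path(source).glob(_FRAME_GLOB))
    if not paths:
        raise SpectraFormatError(f"no frame files found in {source}")

    times, grid, rows = [], None, []
    for path in paths:
        t, wl, iv = _parse_frame(path)
        if grid is None:
            grid = wl
        elif len(wl) != len(grid) or not np.array_equal(wl, grid):
            raise SpectraFormatError(
                f"{path}: wavelength grid differs from the first frame's"
            )
        times.append(t)
        rows.append(iv)

    if any(t is None for t in times):
        if sample_rate is None:
            raise SpectraFormatError(
                "frames carry no timestamps and no sample_rate was given"
            )
        time_axis = np.arange(len(rows)) / sample_rate
    else:
        time_axis = np.array(times)
        if len(time_axis) >= 2 and np.any(np.diff(time_axis) <= 0):
            raise SpectraFormatError("frame timestamps are not strictly increasing")
    return TimeResolvedSpectra(
        intensities=np.vstack(rows),
        time_axis=time_axis,
        wavelength_axis=grid,
        metadata=metadata or {},
    )


def write_cube(spectra: TimeResolvedSpectra, path) -> SpectraFileSet:
    """Write the cube to a single HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("intensities", data=spectra.intensities)
        f.create_dataset("time_s", data=spectra.time_axis)
        f.create_dataset("wavelength_nm", data=spectra.wavelength_axis)
        f.attrs["metadata_json"] = json.dumps(spectra.metadata, default=str)
    return SpectraFileSet(format="cube", paths=[path])


def read_cube(path) -> TimeResolvedSpectra:
    """Read a cube container written by :func:`write_cube`."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            missing = {"intensities", "time_s", "wavelength_nm"} - set(f.keys())
            if missing:
                raise SpectraFormatError(
                    f"{path}: cube missing datasets {sorted(missing)}"
                )
            metadata = json.loads(f.attrs.get("metadata_json", "{}"))
            return TimeResolvedSpectra(
                intensities=f["intensities"][()],
                time_axis=f["time_s"][()],
                wavelength_axis=f["wavelength_nm"][()],
                metadata=metadata,
            )
    except OSError as exc:
        raise SpectraFormatError(f"{path}: not a readable cube container ({exc})") from exc


def read_any(path, sample_rate: float | None = None) -> TimeResolvedSpectra:
    """Read either format: a cube file or a directory of frame files."""
    path = Path(path)
    if path.is_dir():
        return read_frames(path, sample_rate=sample_rate)
    return read_cube(path)
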