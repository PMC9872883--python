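"""Readers/writers for Mueller stacks, map sets, interferograms and tables.

Conventions declared in every header: pixel coordinates are row-major with
the origin top-left, 0-based; Mueller pages are ordered f11, f12, ..., f44;
Stokes files use the conventional S0-based naming (S0 = intensity, which the
in-memory convention indexes S1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import MuellerMap
from .geometry import MeasurementGeometry
from .holography import Interferogram, ProbeState
from .maps import OBSERVABLES, AnisotropyMapSet

FORMAT_VERSION = "mmtomo-1"

_PAGE_NAMES = [f"f{i}{k}" for i in range(1, 5) for k in range(1, 5)]


class FormatError(ValueError):
    """Raised when a file does not match the declared dialect."""


def _header(geometry: MeasurementGeometry, **extra) -> dict:
    h = {
        "version": FORMAT_VERSION,
        "pixel_convention": "row-major, origin top-left, 0-based",
        "wavelength_um": geometry.wavelength,
        "thickness_um": geometry.thickness,
    }
    h.update(extra)
    return h


def _geometry_from(meta: dict) -> MeasurementGeometry:
    return MeasurementGeometry(
        wavelength=float(meta.get("wavelength_um", 0.6328)),
        thickness=float(meta.get("thickness_um", 40.0)),
    )


# ---------------------------------------------------------------------------
# Mueller maps
# ---------------------------------------------------------------------------

def write_mueller_tiff(mm: MuellerMap, path: str | Path) -> None:
    """16-page float32 multi-page TIFF, page order f11..f44 row-major."""
    pages = np.ascontiguousarray(
        mm.data.reshape(mm.shape + (16,)).transpose(2, 0, 1).astype(np.float32)
    )
    meta = _header(mm.geometry, pages=_PAGE_NAMES, normalized=mm.normalized)
    tifffile.imwrite(str(path), pages, description=json.dumps(meta))


def read_mueller_tiff(path: str | Path) -> MuellerMap:
    with tifffile.TiffFile(str(path)) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description
    if pages.ndim != 3 or pages.shape[0] != 16:
        n = pages.shape[0] if pages.ndim == 3 else 1
        raise FormatError(
            f"{path}: expected 16 pages ordered {_PAGE_NAMES[0]}..{_PAGE_NAMES[-1]}, "
            f"found {n}"
        )
    meta = json.loads(desc) if desc else {}
    data = np.moveaxis(pages.astype(float), 0, -1).reshape(pages.shape[1:] + (4, 4))
    return MuellerMap(
        data,
        geometry=_geometry_from(meta),
        normalized=bool(meta.get("normalized", True)),
    )


def write_mueller_npz(mm: MuellerMap, path: str | Path) -> None:
    """Compressed archive of the 16 named float32 element arrays."""
    arrays = {
        name: mm.data[..., i // 4, i % 4].astype(np.float32)
        for i, name in enumerate(_PAGE_NAMES)
    }
    meta = _header(mm.geometry, normalized=mm.normalized)
    np.savez_compressed(str(path), meta=json.dumps(meta), **arrays)


def read_mueller_npz(path: str | Path) -> MuellerMap:
    with np.load(str(path), allow_pickle=False) as z:
        missing = [n for n in _PAGE_NAMES if n not in z]
        if missing:
            raise FormatError(f"{path}: missing element arrays {missing}")
        meta = json.loads(str(z["meta"])) if "meta" in z else {}
        grids = [z[n].astype(float) for n in _PAGE_NAMES]
    data = np.stack(grids, axis=-1).reshape(grids[0].shape + (4, 4))
    return MuellerMap(
        data,
        geometry=_geometry_from(meta),
        normalized=bool(meta.get("normalized", True)),
    )


def read_mueller(path: str | Path) -> MuellerMap:
    """Dispatch on suffix: .tif/.tiff or .npz."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return read_mueller_tiff(path)
    if suffix == ".npz":
        return read_mueller_npz(path)
    raise FormatError(f"unsupported Mueller stack format: {suffix!r}")


def write_mueller(mm: MuellerMap, path: str | Path) -> None:
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        write_mueller_tiff(mm, path)
    elif suffix == ".npz":
        write_mueller_npz(mm, path)
    else:
        raise FormatError(f"unsupported Mueller stack format: {suffix!r}")


# ---------------------------------------------------------------------------
# anisotropy map sets
# ---------------------------------------------------------------------------

def write_mapset_tiff(ms: AnisotropyMapSet, path: str | Path) -> None:
    """5-page float32 TIFF: the four observables plus the validity mask."""
    pages = np.stack(
        [ms.observable(n).astype(np.float32) for n in OBSERVABLES]
        + [ms.valid.astype(np.float32)]
    )
    meta = _header(
        ms.geometry,
        pages=list(OBSERVABLES) + ["valid"],
        phase_plane=ms.phase_plane,
    )
    tifffile.imwrite(str(path), pages, description=json.dumps(meta))


def read_mapset_tiff(path: str | Path) -> AnisotropyMapSet:
    with tifffile.TiffFile(str(path)) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description
    if pages.ndim != 3 or pages.shape[0] != 5:
        raise FormatError(f"{path}: expected 5 pages (4 observables + validity mask)")
    meta = json.loads(desc) if desc else {}
    return AnisotropyMapSet(
        phi_l=pages[0].astype(float),
        phi_circ=pages[1].astype(float),
        delta_l=pages[2].astype(float),
        delta_circ=pages[3].astype(float),
        valid=pages[4] > 0.5,
        phase_plane=float(meta.get("phase_plane", float("nan"))),
        geometry=_geometry_from(meta),
    )


# ---------------------------------------------------------------------------
# interferograms
# ---------------------------------------------------------------------------

def write_interferogram(ig: Interferogram, path: str | Path) -> None:
    """16-bit grayscale PNG/TIFF plus a JSON sidecar with the scale factor,
    carrier, probe and analyzer metadata."""
    import imageio.v3 as iio

    peak = float(ig.intensity.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    img = np.round(ig.intensity * scale).astype(np.uint16)
    iio.imwrite(str(path), img)
    sidecar = {
        "version": FORMAT_VERSION,
        "probe": ig.probe.value,
        "analyzer_deg": ig.analyzer,
        "carrier_cpp": list(ig.carrier),
        "ref_amplitude": ig.ref_amplitude,
        "intensity_scale": scale,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_interferogram(path: str | Path) -> Interferogram:
    import imageio.v3 as iio

    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar for {path}")
    meta = json.loads(sidecar_path.read_text())
    img = iio.imread(str(path)).astype(float) / float(meta["intensity_scale"])
    return Interferogram(
        img,
        carrier=tuple(meta["carrier_cpp"]),
        probe=ProbeState(meta["probe"]),
        analyzer=int(meta["analyzer_deg"]),
        ref_amplitude=float(meta.get("ref_amplitude", 1.0)),
    )


# ---------------------------------------------------------------------------
# tables and manifests
# ---------------------------------------------------------------------------

MOMENT_COLUMNS = ["sample_id", "class", "observable", "phase_plane", "Z1", "Z2", "Z3", "Z4"]


def moments_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=MOMENT_COLUMNS)


def write_moments_csv(rows: list[dict] | pd.DataFrame, path: str | Path) -> None:
    df = rows if isinstance(rows, pd.DataFrame) else moments_table(rows)
    df.to_csv(path, index=False)


def read_moments_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MOMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_manifest(manifest: dict, path: str | Path) -> None:
    manifest = dict(manifest)
    manifest.setdefault("version", FORMAT_VERSION)
    if "seed" not in manifest:
        raise ValueError("every manifest must record the seed of its run")
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
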