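"""Standard-format I/O: multi-page TIFF volumes with JSON sidecars, raw-scan
containers, metrics/graph CSV tables.

TIFF tags alone under-specify anisotropic 3D voxel spacing, so every volume,
mask, or map is written alongside a ``<name>.json`` sidecar carrying the
spacing, axis convention, and provenance metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .recon import OCTVolume, RawSpectralScan, SpectrometerSpec
from .segment import VesselMask

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_map",
    "save_raw_scan",
    "load_raw_scan",
    "save_metrics_table",
    "save_graph_csv",
]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, list)):
        return [_jsonable(o) for o in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _write_sidecar(path: Path, payload: dict) -> None:
    path.with_suffix(".json").write_text(json.dumps(_jsonable(payload), indent=2))


def save_volume(volume: OCTVolume, path) -> Path:
    """Write an (x, y, z) volume as a z-paged float32 TIFF + JSON sidecar."""
    path = Path(path)
    # pages along z: page p is the (x, y) slice at depth p
    pages = np.transpose(volume.intensity, (2, 1, 0)).astype(np.float32)
    tifffile.imwrite(path, pages)
    _write_sidecar(path, {
        "kind": "oct_volume",
        "axes_file": "ZYX",
        "axes_memory": "XYZ",
        "shape_xyz": volume.shape,
        "voxel_spacing_um": volume.voxel_spacing,
        "meta": volume.meta,
    })
    return path


def load_volume(path) -> OCTVolume:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    intensity = np.transpose(pages, (2, 1, 0)).astype(float)
    return OCTVolume(
        intensity=intensity,
        voxel_spacing=tuple(sidecar["voxel_spacing_um"]),
        meta=sidecar.get("meta", {}),
    )


def save_mask(mask: VesselMask, path) -> Path:
    """Write a binary mask as an 8-bit (0/255) TIFF + JSON sidecar."""
    path = Path(path)
    m = mask.mask
    if m.ndim == 3:
        pages = np.transpose(m, (2, 1, 0))
    else:
        pages = m.T
    tifffile.imwrite(path, (pages.astype(np.uint8)) * 255)
    _write_sidecar(path, {
        "kind": "vessel_mask",
        "ndim": m.ndim,
        "shape": m.shape,
        "voxel_spacing_um": mask.voxel_spacing,
        "meta": mask.meta,
    })
    return path


def load_mask(path) -> VesselMask:
    path = Path(path)
    pages = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar.get("ndim", pages.ndim) == 3:
        if pages.ndim == 2:
            pages = pages[None]
        m = np.transpose(pages, (2, 1, 0)) > 0
    else:
        m = pages.T > 0
    return VesselMask(mask=m, voxel_spacing=tuple(sidecar["voxel_spacing_um"]), meta=sidecar.get("meta", {}))


def save_map(values: np.ndarray, path, spacing=None, meta=None) -> Path:
    """Write a 2D float map (e.g. thickness in um) as TIFF + sidecar."""
    path = Path(path)
    arr = values.values if hasattr(values, "values") else np.asarray(values)
    tifffile.imwrite(path, arr.T.astype(np.float32))
    _write_sidecar(path, {"kind": "map", "shape_xy": arr.shape,
                          "voxel_spacing_um": spacing, "meta": meta or {}})
    return path


def save_raw_scan(scan: RawSpectralScan, prefix) -> Path:
    """Write a raw scan as ``<prefix>.npy`` (A-lines x samples, float64) plus
    a ``<prefix>.json`` header with the wavelength grid parameters."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), scan.spectra)
    s = scan.spectrometer
    header = {
        "kind": "raw_spectral_scan",
        "n_alines": scan.n_alines,
        "spectrometer": {
            "lambda_min_nm": s.lambda_min_nm,
            "lambda_max_nm": s.lambda_max_nm,
            "n_samples": s.n_samples,
            "center_nm": s.center_nm,
            "fwhm_nm": s.fwhm_nm,
        },
        "repeat_index": scan.repeat_index,
        "meta": scan.meta,
    }
    prefix.with_suffix(".json").write_text(json.dumps(_jsonable(header), indent=2))
    return prefix.with_suffix(".npy")


def load_raw_scan(prefix) -> RawSpectralScan:
    prefix = Path(prefix)
    spectra = np.load(prefix.with_suffix(".npy"))
    header = json.loads(prefix.with_suffix(".json").read_text())
    spec = SpectrometerSpec(**header["spectrometer"])
    return RawSpectralScan(
        spectra=spectra,
        spectrometer=spec,
        repeat_index=header.get("repeat_index", 0),
        meta=header.get("meta", {}),
    )


def save_metrics_table(table: pd.DataFrame, path) -> Path:
    """Tidy per-chip metrics CSV (one row per chip per day per metric)."""
    path = Path(path)
    cols = [c for c in ("chip", "condition", "day", "metric", "value") if c in table.columns]
    table[cols + [c for c in table.columns if c not in cols]].to_csv(path, index=False)
    return path


def save_graph_csv(graph, prefix) -> tuple[Path, Path]:
    """Write a skeleton graph as a node/edge CSV pair."""
    prefix = Path(prefix)
    nodes, edges = [], []
    for i, (n, d) in enumerate(graph.graph.nodes(data=True)):
        pos = d.get("pos_um", [np.nan] * len(graph.voxel_spacing))
        nodes.append({"node": i, "kind": d.get("kind", ""),
                      **{f"pos_{ax}_um": p for ax, p in zip("xyz", pos)}})
    index = {n: i for i, n in enumerate(graph.graph.nodes)}
    for a, b, d in graph.graph.edges(data=True):
        edges.append({"node_a": index[a], "node_b": index[b],
                      "length_um": d["length_um"], "n_voxels": d.get("n_voxels", 0)})
    npath = prefix.parent / (prefix.name + "_nodes.csv")
    epath = prefix.parent / (prefix.name + "_edges.csv")
    pd.DataFrame(nodes).to_csv(npath, index=False)
    pd.DataFrame(edges).to_csv(epath, index=False)
    return npath, epath
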