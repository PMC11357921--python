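"""File interfaces: 4-D DWI NIfTI volumes, b-value tables, parameter maps.

On-disk conventions:

* DWI series: 4-D NIfTI, spatial axes then b-value axis, paired with a
  tab-separated b-table with columns ``b_s_mm2`` and ``nex``;
* parameter maps: one 3-D NIfTI per map (D, alpha, beta, ADC,
  fit_status, rss) plus a JSON sidecar recording the fit configuration
  and package version;
* cohort/enrollment tables: CSV via pandas.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .model_fitting import BValueScheme, DWISeries, FitConfig, ParameterMaps

__all__ = [
    "load_btable",
    "save_btable",
    "load_dwi",
    "save_dwi",
    "save_maps",
    "load_maps",
]

MAP_NAMES = ("D", "alpha", "beta", "adc", "fit_status", "rss")


def load_btable(path) -> BValueScheme:
    table = pd.read_csv(path, sep="\t")
    required = {"b_s_mm2", "nex"}
    if not required.issubset(table.columns):
        raise ValueError(f"b-table must have columns {sorted(required)}")
    return BValueScheme(b_values=table["b_s_mm2"].to_numpy(),
                        nex=table["nex"].to_numpy())


def save_btable(scheme: BValueScheme, path) -> None:
    pd.DataFrame({"b_s_mm2": scheme.b_values, "nex": scheme.nex}).to_csv(
        path, sep="\t", index=False
    )


def load_dwi(dwi_path, btable_path, mask_path=None) -> DWISeries:
    """Read a 4-D DWI NIfTI plus its b-table (and optional mask NIfTI)."""
    img = nib.load(str(dwi_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D DWI volume, got shape {data.shape}")
    scheme = load_btable(btable_path)
    if data.shape[-1] != len(scheme):
        raise ValueError(
            f"DWI has {data.shape[-1]} volumes but b-table lists {len(scheme)}"
        )
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
    else:
        mask = np.ones(data.shape[:-1], dtype=bool)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWISeries(signal=data, mask=mask, scheme=scheme, spacing=spacing)


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_dwi(series: DWISeries, dwi_path, btable_path, mask_path=None) -> None:
    aff = _affine(series.spacing)
    nib.save(nib.Nifti1Image(series.signal.astype(np.float32), aff), str(dwi_path))
    save_btable(series.scheme, btable_path)
    if mask_path is not None:
        nib.save(nib.Nifti1Image(series.mask.astype(np.uint8), aff), str(mask_path))


def save_maps(maps: ParameterMaps, out_dir, config: FitConfig | None = None,
              spacing=(1.0, 1.0, 1.0)) -> None:
    """Write one 3-D NIfTI per map plus a JSON config sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(spacing)
    for name in MAP_NAMES:
        arr = getattr(maps, name)
        dtype = np.int8 if name == "fit_status" else np.float32
        nib.save(nib.Nifti1Image(np.asarray(arr).astype(dtype), aff),
                 str(out / f"{name}.nii.gz"))
    sidecar = {"software": "ctrwdwi", "maps": list(MAP_NAMES)}
    if config is not None:
        sidecar["fit_config"] = asdict(config)
    from importlib.metadata import version, PackageNotFoundError

    try:
        sidecar["version"] = version("ctrwdwi")
    except PackageNotFoundError:
        sidecar["version"] = "unknown"
    (out / "fit_config.json").write_text(json.dumps(sidecar, indent=2))


def load_maps(out_dir) -> ParameterMaps:
    out = Path(out_dir)
    arrays = {}
    for name in MAP_NAMES:
        arr = np.asarray(nib.load(str(out / f"{name}.nii.gz")).get_fdata())
        arrays[name] = arr.astype(np.int8) if name == "fit_status" else arr
    return ParameterMaps(**arrays)
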