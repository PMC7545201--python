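"""File I/O: spectra and metadata CSVs, binned-matrix/mask export,
model/ensemble JSON, and sha256 digests for provenance."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .processing import BinnedMatrix, Spectrum
from .simulate import GroundTruth

log = logging.getLogger(__name__)

__all__ = [
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_cohort",
    "read_spectra",
    "write_binned_matrix",
    "read_binned_matrix",
    "write_json",
    "file_digest",
]


def write_spectrum_csv(s: Spectrum, path) -> Path:
    """Two-column CSV, ppm descending (plotting convention)."""
    path = Path(path)
    asc = s.ascending()
    df = pd.DataFrame({"ppm": asc.ppm[::-1], "intensity": asc.intensity[::-1]})
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_spectrum_csv(path, sample_id: str, matrix: str) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"ppm", "intensity"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'ppm' and 'intensity'")
    ppm = df["ppm"].to_numpy(dtype=float)
    intensity = df["intensity"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(intensity))
    if bad.size:
        raise ValueError(
            f"{path}, line {bad[0] + 2}: non-finite intensity for sample {sample_id!r}"
        )
    d = np.diff(ppm)
    if not (np.all(d > 0) or np.all(d < 0)):
        step = np.flatnonzero(np.sign(d) != np.sign(d[0]))
        lineno = (int(step[0]) + 2) if step.size else 2
        raise ValueError(f"{path}, line {lineno}: ppm axis not monotonic")
    return Spectrum(ppm=ppm, intensity=intensity, sample_id=sample_id, matrix=matrix)


def write_cohort(
    spectra: list[Spectrum],
    metadata: pd.DataFrame,
    truth: GroundTruth | None,
    out_dir,
) -> dict[str, Path]:
    """Write per-sample spectra plus metadata (and ground truth) CSVs."""
    out_dir = Path(out_dir)
    spectra_dir = out_dir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for s in spectra:
        written[s.sample_id] = write_spectrum_csv(s, spectra_dir / f"{s.sample_id}.csv")
    meta_path = out_dir / "metadata.csv"
    metadata.to_csv(meta_path, index=False)
    written["metadata"] = meta_path
    if truth is not None:
        gt_path = out_dir / "ground_truth.csv"
        truth.table.to_csv(gt_path, index=False)
        written["ground_truth"] = gt_path
    return written


def read_spectra(spectra_dir, metadata_path) -> tuple[list[Spectrum], pd.DataFrame]:
    """Load a cohort: one spectrum CSV per metadata row, in metadata order.

    Spectrum files present in the directory but absent from the metadata
    are ignored with a warning.
    """
    spectra_dir = Path(spectra_dir)
    metadata = pd.read_csv(metadata_path)
    required = {"sample_id", "group", "matrix"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    spectra = []
    for _, row in metadata.iterrows():
        path = spectra_dir / f"{row.sample_id}.csv"
        if not path.exists():
            raise FileNotFoundError(
                f"no spectrum file for sample_id {row.sample_id!r} "
                f"(expected {path})"
            )
        spectra.append(read_spectrum_csv(path, str(row.sample_id), str(row.matrix)))
    known = {str(sid) for sid in metadata["sample_id"]}
    extra = [p.name for p in spectra_dir.glob("*.csv") if p.stem not in known]
    if extra:
        warnings.warn(
            f"ignoring {len(extra)} spectrum file(s) not in metadata: {extra}",
            stacklevel=2,
        )
    return spectra, metadata


def write_binned_matrix(m: BinnedMatrix, out_dir) -> dict[str, Path]:
    """Binned matrix as CSV (rows=samples, columns=bin labels) plus a mask
    CSV with per-bin exclusion reasons."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix_path = out_dir / "binned_matrix.csv"
    df = m.to_frame()
    df.index.name = "sample_id"
    df.insert(0, "group", m.groups)
    df.to_csv(matrix_path, float_format="%.10g")
    mask_path = out_dir / "bin_mask.csv"
    pd.DataFrame(
        {
            "bin": m.bin_labels,
            "ppm_lo": [lo for lo, _ in m.bin_edges],
            "ppm_hi": [hi for _, hi in m.bin_edges],
            "excluded": m.excluded,
            "reason": ["" if r is None else r for r in m.excluded_reason],
        }
    ).to_csv(mask_path, index=False)
    return {"matrix": matrix_path, "mask": mask_path}


def read_binned_matrix(out_dir, matrix: str) -> BinnedMatrix:
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "binned_matrix.csv", index_col="sample_id")
    groups = df.pop("group").tolist()
    mask = pd.read_csv(out_dir / "bin_mask.csv")
    edges = list(zip(mask["ppm_lo"], mask["ppm_hi"]))
    reasons = np.array(
        [None if (isinstance(r, float) and np.isnan(r)) or r == "" else r for r in mask["reason"]],
        dtype=object,
    )
    return BinnedMatrix(
        values=df.to_numpy(dtype=float),
        bin_edges=edges,
        sample_ids=[str(i) for i in df.index],
        groups=[str(g) for g in groups],
        matrix=matrix,
        excluded_reason=reasons,
        stages=["bin", "exclude"],
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")
    return path


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
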