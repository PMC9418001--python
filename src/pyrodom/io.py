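"""CSV readers/writers for the pipeline's on-disk formats.

Peak lists are two-column CSVs (mz, intensity), one file per sample,
accompanied by a metadata CSV (sample_id, condition, depth, replicate).
An optional mzML ingestion hook is provided for centroided spectra when
pyteomics is installed; it is not required by the pipeline.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .peaks import PeakList

__all__ = ["read_metadata", "read_peaklists", "peaklist_from_mzml"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path)
    required = {"sample_id", "condition"}
    if not required.issubset(md.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    if md["sample_id"].duplicated().any():
        raise ValueError("metadata sample_id values must be unique")
    return md


def read_peaklists(peakdir: str | Path, metadata: pd.DataFrame) -> list[PeakList]:
    """Load one ``<sample_id>.csv`` peak list per metadata row."""
    peakdir = Path(peakdir)
    out = []
    for row in metadata.itertuples(index=False):
        p = peakdir / f"{row.sample_id}.csv"
        if not p.exists():
            raise FileNotFoundError(f"peak list not found: {p}")
        df = pd.read_csv(p)
        out.append(
            PeakList(
                sample_id=row.sample_id,
                peaks=df[["mz", "intensity"]],
                condition=getattr(row, "condition", None),
                depth=getattr(row, "depth", None),
            )
        )
    return out


def peaklist_from_mzml(path: str | Path, sample_id: str, **meta) -> PeakList:
    """Read the first centroided spectrum of an mzML file as a peak list."""
    try:
        from pyteomics import mzml as _mzml
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("mzML ingestion requires the 'pyteomics' package") from exc
    with _mzml.read(str(path)) as reader:
        spec = next(iter(reader))
    df = pd.DataFrame(
        {"mz": spec["m/z array"], "intensity": spec["intensity array"]}
    )
    df = df[df["intensity"] > 0]
    return PeakList(sample_id=sample_id, peaks=df, **meta)
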