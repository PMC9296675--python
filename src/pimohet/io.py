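"""Readers and writers for the documented plain-file interfaces.

Expression comes as TSV (probe_id + one column per sample; GEO
series-matrix-like files are tolerated by skipping '!'-prefixed header
lines), probe maps as two-column TSV, sample sheets / scores / clinical /
survival / per-section values as CSV, images as TIFF or PNG with optional
single-channel PNG masks.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .histoquant import SectionImage
from .sigscore import ProbeExpressionMatrix


def read_expression_tsv(
    expr_path: str | Path,
    probe_map_path: str | Path | None = None,
    sample_sheet: pd.DataFrame | None = None,
) -> ProbeExpressionMatrix:
    """Probe x sample TSV (first column probe_id).  Lines starting with '!'
    (GEO series-matrix headers) are skipped.  Kit labels are taken from the
    sample sheet when given."""
    with open(expr_path) as fh:
        text = "".join(line for line in fh if not line.startswith("!"))
    values = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0, float_precision="round_trip")
    values.index = values.index.astype(str)
    probe_map = read_probe_map_tsv(probe_map_path) if probe_map_path else None
    kit = None
    if sample_sheet is not None and "kit" in sample_sheet.columns:
        kit = sample_sheet.set_index("sample_id")["kit"].reindex(values.columns)
    return ProbeExpressionMatrix(values=values, probe_map=probe_map, kit=kit)


def read_probe_map_tsv(path: str | Path) -> pd.Series:
    """Two-column TSV probe_id -> gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError("probe map must have two columns (probe_id, gene_id)")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="gene_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str})
    need = {"sample_id", "patient_id", "order_label"}
    if not need <= set(df.columns):
        raise DataError(f"sample sheet needs columns {sorted(need)}")
    return df


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"section_id", "rater_id", "score"}
    if not need <= set(df.columns):
        raise DataError(f"scores table needs columns {sorted(need)}")
    return df


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip").set_index("patient_id")
    if not {"time", "event"} <= set(df.columns):
        raise DataError("survival table needs columns time, event")
    return df


def read_values_csv(path: str | Path, value_col: str | None = None, index_col: str | None = None) -> pd.Series:
    """Single-value-per-row CSV: first column ids, ``value_col`` (default:
    second column) the value."""
    df = pd.read_csv(path, float_precision="round_trip")
    idx = index_col or df.columns[0]
    col = value_col or df.columns[1]
    s = df.set_index(idx)[col].astype(float)
    s.index = s.index.astype(str)
    return s


def read_mask_png(path: str | Path) -> np.ndarray:
    from PIL import Image

    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise DataError(f"{path}: mask must be single-channel")
    return arr > 0


def read_section_image(
    image_path: str | Path,
    section_kind: str,
    pixel_size_um: float = 1.0,
    tissue_mask_path: str | Path | None = None,
    lesion_mask_path: str | Path | None = None,
) -> SectionImage:
    """TIFF/PNG RGB section plus optional single-channel PNG masks."""
    path = Path(image_path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    else:
        from PIL import Image

        pixels = np.asarray(Image.open(path).convert("RGB"))
    return SectionImage(
        pixels=pixels,
        section_kind=section_kind,  # type: ignore[arg-type]
        section_id=path.stem,
        pixel_size_um=pixel_size_um,
        tissue_mask=read_mask_png(tissue_mask_path) if tissue_mask_path else None,
        lesion_mask=read_mask_png(lesion_mask_path) if lesion_mask_path else None,
    )
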