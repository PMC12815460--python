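"""Readers and writers for the package's table and image formats.

Conventions: comma-separated UTF-8 CSV (TSV accepted where noted), lines
starting with ``#`` carry ``key=value`` metadata or comments, decimal
point, and units baked into column names (``ligand_total_uM``,
``volume_ml``, ``time_min``...).  Every writer's output is readable by
the matching reader to an equal in-memory value.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .coloc_imaging import ChannelImage, TwoChannelImage
from .equilibrium import TitrationPoint, TitrationSeries
from .errors import TableParseError, TableSchemaError
from .nmr_mapping import AtomGroup, AttenuationProfile, CSPProfile, PeakList, Resonance
from .proteolysis import BandMeasurement, DigestionTimeCourse
from .sec_quant import Chromatogram

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_peaklist",
    "write_peaklist",
    "read_assignment_list",
    "read_chromatogram_csv",
    "write_chromatogram_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_two_channel_tiff",
    "write_two_channel_tiff",
    "load_source_data",
    "write_json",
]

_TITRATION_COLUMNS = ["ligand_total_uM", "response_ppm"]
_PEAKLIST_COLUMNS = [
    "residue_number",
    "residue_type",
    "atom_group",
    "shift_h_ppm",
    "shift_x_ppm",
    "intensity",
]
_CHROM_COLUMNS = ["volume_ml", "a280_AU"]
_TIMECOURSE_COLUMNS = ["time_min", "full_length_AU", "cleaved_AU"]


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _read_table(path: str | Path, required: list[str], sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableParseError(f"{path}: file not found")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        frame = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise TableSchemaError(f"{path}: file is empty") from None
    except (pd.errors.ParserError, ValueError) as exc:
        raise TableParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableSchemaError(
            f"{path}: missing required columns {missing}; available: {list(frame.columns)}"
        )
    if frame.empty:
        raise TableSchemaError(f"{path}: table has no data rows")
    return frame


def _require_numeric(frame: pd.DataFrame, columns: list[str], path: Path) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            # +2: 1-based plus header line (comment lines shift this, but it names the row)
            row = int(bad.idxmax()) + 2
            raise TableParseError(
                f"{path}: non-numeric value in column '{col}' near line {row}"
            )
        frame[col] = converted
    return frame


def read_titration_csv(
    path: str | Path, protein_total: float | None = None, label: str | None = None
) -> TitrationSeries:
    """Read a titration series; protein_total/label from args or # headers."""
    path = Path(path)
    meta = _read_metadata(path)
    frame = _read_table(path, _TITRATION_COLUMNS)
    frame = _require_numeric(frame, _TITRATION_COLUMNS, path)
    if protein_total is None:
        if "protein_total_uM" not in meta:
            raise TableSchemaError(
                f"{path}: protein_total not given and no '# protein_total_uM=' header"
            )
        protein_total = float(meta["protein_total_uM"])
    if label is None:
        label = meta.get("label", "")
    points = tuple(
        TitrationPoint(ligand_total=float(l), response=float(r))
        for l, r in zip(frame["ligand_total_uM"], frame["response_ppm"])
    )
    return TitrationSeries(protein_total=protein_total, points=points, label=label)


def write_titration_csv(series: TitrationSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# protein_total_uM={series.protein_total!r}\n")
        fh.write(f"# label={series.label}\n")
        fh.write(",".join(_TITRATION_COLUMNS) + "\n")
        for p in series.points:
            fh.write(f"{p.ligand_total!r},{p.response!r}\n")


def read_peaklist(path: str | Path, condition_label: str | None = None) -> PeakList:
    """Read a peak list CSV/TSV with the standard six-column layout."""
    path = Path(path)
    meta = _read_metadata(path)
    frame = _read_table(path, _PEAKLIST_COLUMNS)
    frame = _require_numeric(
        frame, ["residue_number", "shift_h_ppm", "shift_x_ppm", "intensity"], path
    )
    label = condition_label or meta.get("condition", path.stem)
    resonances = tuple(
        Resonance(
            residue_number=int(row.residue_number),
            residue_type=str(row.residue_type),
            atom_group=AtomGroup(row.atom_group),
            shift_h=float(row.shift_h_ppm),
            shift_x=float(row.shift_x_ppm),
            intensity=float(row.intensity),
        )
        for row in frame.itertuples()
    )
    return PeakList(condition_label=label, resonances=resonances)


def write_peaklist(plist: PeakList, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# condition={plist.condition_label}\n")
        fh.write(sep.join(_PEAKLIST_COLUMNS) + "\n")
        for r in plist.resonances:
            fh.write(
                sep.join(
                    [
                        str(r.residue_number),
                        r.residue_type,
                        r.atom_group.value,
                        repr(r.shift_h),
                        repr(r.shift_x),
                        repr(r.intensity),
                    ]
                )
                + "\n"
            )


_ASSIGNMENT_RE = re.compile(
    r"^(?P<type>[A-Z])(?P<number>\d+)(?P<atoms>[A-Z0-9]*-?[A-Z0-9]*)$"
)


def read_assignment_list(path: str | Path, condition_label: str | None = None) -> PeakList:
    """Read a whitespace-separated assignment-style peak list.

    Expected rows: ``label w1 w2 height`` with labels like ``I377CD1-HD1``
    (Ile-d1 methyl) or ``G70N-H`` (backbone amide); w1 is the X-dimension
    (15N/13C) shift and w2 the 1H shift, the usual assignment-list order.
    Lines starting with ``#`` or a non-residue word are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise TableParseError(f"{path}: file not found")
    resonances = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            match = _ASSIGNMENT_RE.match(parts[0])
            if match is None:
                continue  # column header or unassigned peak
            if len(parts) < 4:
                raise TableParseError(
                    f"{path}: line {lineno}: expected 'label w1 w2 height'"
                )
            try:
                w1, w2, height = (float(x) for x in parts[1:4])
            except ValueError as exc:
                raise TableParseError(f"{path}: line {lineno}: {exc}") from exc
            atoms = match.group("atoms").upper()
            group = (
                AtomGroup.ile_d1_methyl if "CD1" in atoms else AtomGroup.backbone_amide
            )
            resonances.append(
                Resonance(
                    residue_number=int(match.group("number")),
                    residue_type=match.group("type"),
                    atom_group=group,
                    shift_h=w2,
                    shift_x=w1,
                    intensity=height,
                )
            )
    if not resonances:
        raise TableSchemaError(f"{path}: no assignable peaks found")
    return PeakList(condition_label=condition_label or path.stem, resonances=tuple(resonances))


def read_chromatogram_csv(path: str | Path, label: str | None = None) -> Chromatogram:
    path = Path(path)
    meta = _read_metadata(path)
    frame = _read_table(path, _CHROM_COLUMNS)
    frame = _require_numeric(frame, _CHROM_COLUMNS, path)
    return Chromatogram(
        volumes=frame["volume_ml"].to_numpy(),
        absorbance=frame["a280_AU"].to_numpy(),
        label=label or meta.get("label", path.stem),
    )


def write_chromatogram_csv(chrom: Chromatogram, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# label={chrom.label}\n")
        fh.write(",".join(_CHROM_COLUMNS) + "\n")
        for v, a in zip(chrom.volumes, chrom.absorbance):
            fh.write(f"{float(v)!r},{float(a)!r}\n")


def read_timecourse_csv(path: str | Path, condition_label: str | None = None) -> DigestionTimeCourse:
    path = Path(path)
    meta = _read_metadata(path)
    frame = _read_table(path, _TIMECOURSE_COLUMNS)
    frame = _require_numeric(frame, _TIMECOURSE_COLUMNS, path)
    measurements = tuple(
        BandMeasurement(time=float(t), full_length=float(f), cleaved=float(c))
        for t, f, c in zip(
            frame["time_min"], frame["full_length_AU"], frame["cleaved_AU"]
        )
    )
    return DigestionTimeCourse(
        condition_label=condition_label or meta.get("condition", path.stem),
        measurements=measurements,
    )


def write_timecourse_csv(tc: DigestionTimeCourse, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# condition={tc.condition_label}\n")
        fh.write(",".join(_TIMECOURSE_COLUMNS) + "\n")
        for m in tc.measurements:
            fh.write(f"{m.time!r},{m.full_length!r},{m.cleaved!r}\n")


def read_two_channel_tiff(
    path: str | Path, pixel_size: float, second_path: str | Path | None = None
) -> TwoChannelImage:
    """Read a two-page TIFF (receptor, arrestin) or a pair of single-page TIFFs."""
    data = tifffile.imread(str(path))
    if second_path is not None:
        receptor = np.asarray(data, dtype=float)
        arrestin = np.asarray(tifffile.imread(str(second_path)), dtype=float)
    else:
        data = np.asarray(data, dtype=float)
        if data.ndim != 3 or data.shape[0] != 2:
            raise TableSchemaError(
                f"{path}: expected a 2-page TIFF (receptor, arrestin), got shape {data.shape}"
            )
        receptor, arrestin = data[0], data[1]
    return TwoChannelImage(
        receptor=ChannelImage(pixels=receptor, pixel_size=pixel_size),
        arrestin=ChannelImage(pixels=arrestin, pixel_size=pixel_size),
    )


def write_two_channel_tiff(img: TwoChannelImage, path: str | Path) -> None:
    stack = np.stack([img.receptor.pixels, img.arrestin.pixels]).astype(np.float32)
    tifffile.imwrite(str(path), stack)


def write_json(obj: Mapping, path: str | Path) -> None:
    def default(value):
        if isinstance(value, (np.floating, np.integer)):
            return value.item()
        if isinstance(value, np.ndarray):
            return value.tolist()
        if isinstance(value, (set, frozenset)):
            return sorted(value)
        raise TypeError(f"not JSON serializable: {type(value)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def load_source_data(
    path: str | Path,
    table_kind: str,
    column_map: Mapping[str, str] | None = None,
    protein_total: float | None = None,
):
    """Load a published figure source-data table into module-native form.

    ``table_kind`` is one of ``"titration"`` (-> TitrationSeries; needs
    ``protein_total``), ``"intensity_ratios"`` or ``"csp"`` (-> DataFrame
    with canonical columns ready for thresholding).  ``column_map`` maps
    canonical names to the file's actual column names, absorbing any
    published layout.
    """
    path = Path(path)
    canonical = {
        "titration": ["ligand_total_uM", "response_ppm"],
        "intensity_ratios": ["residue_number", "ratio"],
        "csp": ["residue_number", "csp_ppm"],
    }
    if table_kind not in canonical:
        raise TableSchemaError(
            f"unknown table_kind {table_kind!r}; expected one of {sorted(canonical)}"
        )
    column_map = dict(column_map or {})
    required_actual = [column_map.get(c, c) for c in canonical[table_kind]]
    frame = _read_table(path, required_actual)
    frame = frame.rename(columns={v: k for k, v in column_map.items()})
    frame = _require_numeric(frame, canonical[table_kind], path)
    if table_kind == "titration":
        if protein_total is None:
            meta = _read_metadata(path)
            if "protein_total_uM" not in meta:
                raise TableSchemaError(f"{path}: protein_total required for titration tables")
            protein_total = float(meta["protein_total_uM"])
        points = tuple(
            TitrationPoint(ligand_total=float(l), response=float(r))
            for l, r in zip(frame["ligand_total_uM"], frame["response_ppm"])
        )
        return TitrationSeries(protein_total=protein_total, points=points, label=path.stem)
    return frame[canonical[table_kind]].copy()
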