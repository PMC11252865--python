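"""CSV / image / YAML interfaces shared by the CLI pipeline.

Tabular inputs and outputs are plain CSV.  Output files written by the
pipeline carry provenance header lines of the form ``# key=value`` (config
hash, seed) which readers here skip transparently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import MalformedRecordError
from .geometry import OpenedRingLandmarks, PrestretchMarks, RingSpecimen
from .histology import MASSON_STAIN_OD, TrichromeImage
from .tensile import ForceDisplacementCurve, TensileSpecimen

MARK_COLS = [f"m{i}" for i in range(1, 7)]


def write_csv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a DataFrame with optional ``# key=value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# --- tensile -------------------------------------------------------------


def write_force_displacement_csv(path, curve: ForceDisplacementCurve, meta=None) -> None:
    df = pd.DataFrame(
        {"displacement_mm": curve.displacement, "force_N": curve.force}
    )
    write_csv(df, path, meta)


def read_force_displacement_csv(path, specimen: TensileSpecimen) -> ForceDisplacementCurve:
    df = read_csv(path)
    for col in ("displacement_mm", "force_N"):
        if col not in df.columns:
            raise MalformedRecordError(f"{path}: missing column {col!r}")
    return ForceDisplacementCurve(
        df["displacement_mm"].to_numpy(), df["force_N"].to_numpy(), specimen
    )


def write_tensile_metadata_csv(path, specimens: list[TensileSpecimen], meta=None) -> None:
    df = pd.DataFrame(
        [
            {
                "specimen_id": s.specimen_id,
                "group": s.group,
                "region": s.region,
                "direction": s.direction,
                "w0_mm": s.width_w0,
                "l0_mm": s.gauge_length_l0,
                "t0_mm": s.thickness_t0,
            }
            for s in specimens
        ]
    )
    write_csv(df, path, meta)


def read_tensile_metadata_csv(path) -> dict[str, TensileSpecimen]:
    df = read_csv(path)
    out = {}
    for _, row in df.iterrows():
        out[str(row["specimen_id"])] = TensileSpecimen(
            width_w0=float(row["w0_mm"]),
            gauge_length_l0=float(row["l0_mm"]),
            thickness_t0=float(row["t0_mm"]),
            direction=str(row["direction"]),
            region=str(row["region"]),
            group=str(row["group"]),
            specimen_id=str(row["specimen_id"]),
        )
    return out


# --- rings and landmarks -------------------------------------------------


def write_rings_csv(path, rings: list[RingSpecimen], meta=None) -> None:
    df = pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "group": r.group,
                "region": r.region,
                "inner_perimeter_mm": r.inner_perimeter,
                "outer_perimeter_mm": r.outer_perimeter,
            }
            for r in rings
        ]
    )
    write_csv(df, path, meta)


def read_rings_csv(path) -> list[RingSpecimen]:
    df = read_csv(path)
    return [
        RingSpecimen(
            inner_perimeter=float(row["inner_perimeter_mm"]),
            outer_perimeter=float(row["outer_perimeter_mm"]),
            region=str(row["region"]),
            group=str(row["group"]),
            specimen_id=str(row["specimen_id"]),
        )
        for _, row in df.iterrows()
    ]


def write_landmarks_csv(path, landmarks: dict, rings_meta: dict | None = None, meta=None) -> None:
    """``landmarks`` maps specimen_id -> OpenedRingLandmarks; ``rings_meta``
    optionally maps specimen_id -> (group, region)."""
    rows = []
    for sid, lm in landmarks.items():
        group, region = (rings_meta or {}).get(sid, ("", ""))
        for point, (x, y) in (
            ("vertex", lm.vertex),
            ("end_A", lm.end_a),
            ("end_B", lm.end_b),
        ):
            rows.append(
                {
                    "specimen_id": sid,
                    "group": group,
                    "region": region,
                    "point": point,
                    "x_mm": x,
                    "y_mm": y,
                }
            )
    write_csv(pd.DataFrame(rows), path, meta)


def read_landmarks_csv(path) -> dict[str, tuple[OpenedRingLandmarks, str, str]]:
    df = read_csv(path)
    out = {}
    for sid, sub in df.groupby("specimen_id"):
        pts = {
            str(row["point"]): (float(row["x_mm"]), float(row["y_mm"]))
            for _, row in sub.iterrows()
        }
        lm = OpenedRingLandmarks(
            vertex=pts["vertex"], end_a=pts["end_A"], end_b=pts["end_B"]
        )
        group = str(sub["group"].iloc[0]) if "group" in sub else ""
        region = str(sub["region"].iloc[0]) if "region" in sub else ""
        out[str(sid)] = (lm, group, region)
    return out


# --- pre-stretch marks ---------------------------------------------------


def write_marks_csv(path, marks: dict, groups: dict | None = None, meta=None) -> None:
    """``marks`` maps specimen_id -> PrestretchMarks."""
    rows = []
    for sid, mk in marks.items():
        for config, pos in (
            ("in_vivo", mk.in_vivo_positions),
            ("ex_vivo", mk.ex_vivo_positions),
        ):
            row = {"specimen_id": sid, "group": (groups or {}).get(sid, ""), "config": config}
            row.update(dict(zip(MARK_COLS, pos)))
            rows.append(row)
    write_csv(pd.DataFrame(rows), path, meta)


def read_marks_csv(path) -> dict[str, tuple[PrestretchMarks, str]]:
    df = read_csv(path)
    out = {}
    for sid, sub in df.groupby("specimen_id"):
        by_cfg = {
            str(row["config"]): tuple(float(row[c]) for c in MARK_COLS)
            for _, row in sub.iterrows()
        }
        marks = PrestretchMarks(by_cfg["in_vivo"], by_cfg["ex_vivo"])
        group = str(sub["group"].iloc[0]) if "group" in sub else ""
        out[str(sid)] = (marks, group)
    return out


# --- histology -----------------------------------------------------------


def write_trichrome_png(path, image: TrichromeImage) -> None:
    import imageio.v3 as iio

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, image.rgb)


def read_trichrome_image(path, sidecar_yaml) -> TrichromeImage:
    import imageio.v3 as iio

    with open(sidecar_yaml) as fh:
        side = yaml.safe_load(fh)
    stain = np.asarray(side.get("stain_matrix", MASSON_STAIN_OD), dtype=float)
    rgb = iio.imread(path)
    if rgb.ndim == 3 and rgb.shape[2] == 4:
        rgb = rgb[..., :3]
    return TrichromeImage(
        rgb=rgb, pixel_size_mm=float(side["pixel_size_mm"]), stain_matrix=stain
    )


def write_histology_sidecar(path, pixel_size_mm: float, stain_matrix=None) -> None:
    side = {"pixel_size_mm": float(pixel_size_mm)}
    if stain_matrix is not None:
        side["stain_matrix"] = np.asarray(stain_matrix, dtype=float).tolist()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(side, fh)
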