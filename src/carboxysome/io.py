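"""Reading and writing the interchange tables.

Poses travel as TSV (`carboxysome_id  x_A  y_A  z_A  rot_deg  tilt_deg
psi_deg`, intrinsic ZYZ Euler angles in degrees, coordinates in A),
peptide measurements as CSV. Every table written here starts with a
``#`` comment carrying the tool version and a config hash, which readers
skip. A minimal STAR importer maps RELION-style particle tables onto the
pose schema.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import POSE_COLUMNS, QUANT_COLUMNS, TRUTH_COLUMNS


def _header(config_hash: str | None) -> str:
    tag = f" config={config_hash}" if config_hash else ""
    return f"# carboxysome v{__version__}{tag}\n"


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t",
                config_hash: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        df.to_csv(fh, sep=sep, index=False)
    return path


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def write_poses(poses: pd.DataFrame, path, config_hash=None) -> Path:
    return write_table(poses[POSE_COLUMNS], path, "\t", config_hash)


def write_truth(truth: pd.DataFrame, path, config_hash=None) -> Path:
    return write_table(truth[TRUTH_COLUMNS], path, "\t", config_hash)


def write_quant(quant: pd.DataFrame, path, config_hash=None) -> Path:
    return write_table(quant[QUANT_COLUMNS], path, ",", config_hash)


def read_poses(path: str | Path) -> pd.DataFrame:
    df = read_table(path, "\t")
    issues = validate_poses(df)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise ValueError("; ".join(i.message for i in errors))
    return df


def read_quant(path: str | Path) -> pd.DataFrame:
    df = read_table(path, ",")
    issues = validate_quant(df)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise ValueError("; ".join(i.message for i in errors))
    return df


# ---------------------------------------------------------------- validation

@dataclass
class Issue:
    severity: str  # "error" | "warning"
    message: str
    row: int | None = None


@dataclass
class ValidationReport:
    path: str | None
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)


def validate_poses(df: pd.DataFrame) -> list[Issue]:
    issues: list[Issue] = []
    for col in POSE_COLUMNS:
        if col not in df.columns:
            issues.append(Issue("error", f"missing column {col!r}"))
    if issues:
        return issues
    coords = df[["x_A", "y_A", "z_A"]].to_numpy()
    bad = ~np.isfinite(coords).all(axis=1)
    for idx in np.flatnonzero(bad):
        issues.append(Issue("warning", "non-finite coordinate", int(idx)))
    return issues


def validate_quant(df: pd.DataFrame) -> list[Issue]:
    issues: list[Issue] = []
    for col in QUANT_COLUMNS:
        if col not in df.columns:
            issues.append(Issue("error", f"missing column {col!r}"))
    if issues:
        return issues
    for idx in df.index[df["heavy_area"] <= 0]:
        issues.append(Issue("warning", "heavy_area <= 0", int(idx)))
    for idx in df.index[df["light_area"] < 0]:
        issues.append(Issue("warning", "negative light_area", int(idx)))
    for idx in df.index[df["spike_pmol"] <= 0]:
        issues.append(Issue("warning", "non-positive spike_pmol", int(idx)))
    return issues


def validate_file(path: str | Path, kind: str) -> ValidationReport:
    """Validate a pose TSV (`kind="poses"`) or quant CSV (`kind="quant"`)."""
    path = Path(path)
    if not path.is_file():
        return ValidationReport(str(path),
                                [Issue("error", f"file not found: {path}")])
    if kind == "poses":
        df = read_table(path, "\t")
        return ValidationReport(str(path), validate_poses(df))
    if kind == "quant":
        df = read_table(path, ",")
        return ValidationReport(str(path), validate_quant(df))
    raise ValueError(f"unknown table kind {kind!r}")


# -------------------------------------------------------------- STAR import

_STAR_COORDS = ("_rlnCoordinateX", "_rlnCoordinateY", "_rlnCoordinateZ")
_STAR_ANGLES = ("_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi")
_STAR_GROUPS = ("_rlnTomoName", "_rlnMicrographName", "_rlnImageName")


def read_star_block(path: str | Path) -> pd.DataFrame:
    """Parse the first loop_ table of a STAR file into a DataFrame."""
    names: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                if rows:
                    break
                continue
            if line == "loop_":
                in_loop = True
                names, rows = [], []
                continue
            if line.startswith("_"):
                if in_loop:
                    names.append(line.split()[0])
                continue
            if in_loop and names:
                fields = shlex.split(line)
                if len(fields) == len(names):
                    rows.append(fields)
    if not names or not rows:
        raise ValueError(f"no loop_ particle table found in {path}")
    df = pd.DataFrame(rows, columns=names)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if not converted.isna().any():
            df[col] = converted
    return df


def read_star_poses(path: str | Path,
                    pixel_size_A: float | None = None) -> pd.DataFrame:
    """Import a RELION-style particle STAR file as a pose table.

    Coordinates are assumed to be in pixels when ``pixel_size_A`` is
    given (and are multiplied by it), otherwise in A. The tomogram or
    micrograph name becomes the carboxysome id.
    """
    star = read_star_block(path)
    missing = [c for c in _STAR_COORDS + _STAR_ANGLES
               if c not in star.columns]
    if missing:
        raise ValueError(f"STAR file lacks required columns: {missing}")
    scale = pixel_size_A if pixel_size_A else 1.0
    group = next((c for c in _STAR_GROUPS if c in star.columns), None)
    return pd.DataFrame({
        "carboxysome_id": star[group] if group else "star_000",
        "x_A": star["_rlnCoordinateX"].astype(float) * scale,
        "y_A": star["_rlnCoordinateY"].astype(float) * scale,
        "z_A": star["_rlnCoordinateZ"].astype(float) * scale,
        "rot_deg": star["_rlnAngleRot"].astype(float),
        "tilt_deg": star["_rlnAngleTilt"].astype(float),
        "psi_deg": star["_rlnAnglePsi"].astype(float),
    })
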