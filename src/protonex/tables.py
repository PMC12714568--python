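"""Reading and writing of profile tables and run configuration.

All tables are plain tab-separated text with a header row; missing SDs are the
literal ``NA``.  The three kinds are:

* ``r1rho``:   probe, field_mhz, ph, power_hz, offset_hz, r1rho, r1rho_sd
* ``cest``:    probe, field_mhz, ph, b1_hz, offset_ppm, intensity, intensity_sd
* ``phseries``: ph, p_es2, sd

``field_mhz`` is the Larmor frequency of the observed nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import pandas as pd

from .fitting import CEST_COLUMNS, R1RHO_COLUMNS
from .thermo import PHPopulationPoint

PHSERIES_COLUMNS = ["ph", "p_es2", "sd"]

_SCHEMAS = {
    "r1rho": R1RHO_COLUMNS,
    "cest": CEST_COLUMNS,
    "phseries": PHSERIES_COLUMNS,
}
_TEXT_COLUMNS = {"probe"}


class SchemaError(ValueError):
    """Raised when a table is missing columns or has unparseable cells."""


def read_profile_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a profile table.

    Columns are checked against the schema for ``kind`` and coerced to numeric
    types (``NA`` becoming missing values); a missing column or a non-numeric
    cell raises :class:`SchemaError` naming the offender.  Row order is
    preserved; Windows line endings and trailing blank lines are tolerated.
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {list(_SCHEMAS)}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, skip_blank_lines=True)
    df.columns = [c.strip() for c in df.columns]
    expected = _SCHEMAS[kind]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    df = df[expected].copy()
    for col in expected:
        if col in _TEXT_COLUMNS:
            df[col] = df[col].str.strip()
            continue
        raw = df[col].str.strip()
        vals = pd.to_numeric(raw.replace("NA", pd.NA), errors="coerce")
        bad = vals.isna() & raw.notna() & (raw != "NA")
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path.name}: non-numeric value {raw[row]!r} in column "
                f"{col!r} at row {row}"
            )
        df[col] = vals.astype(float)
    return df


def write_profile_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a validated table as tab-separated text with ``NA`` for missing SDs."""
    expected = _SCHEMAS[kind]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write table: missing column(s) {missing}")
    df[expected].to_csv(path, sep="\t", index=False, na_rep="NA")


def phseries_to_points(df: pd.DataFrame) -> list[PHPopulationPoint]:
    return [
        PHPopulationPoint(
            ph=float(r.ph),
            p_es2=float(r.p_es2),
            sd=None if pd.isna(r.sd) else float(r.sd),
        )
        for r in df.itertuples()
    ]


def points_to_phseries(points: Sequence[PHPopulationPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ph": [p.ph for p in points],
            "p_es2": [p.p_es2 for p in points],
            "sd": [p.sd for p in points],
        }
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Configuration of an end-to-end analysis run.

    Parsed from plain ``key = value`` text; unknown keys are rejected with a
    message listing the valid ones.  Every run writes its resolved configuration
    beside its outputs.
    """

    r1rho_path: str = ""
    outdir: str = "protonex_run"
    ph_values: list[float] = field(default_factory=list)
    exclude_ph: list[float] = field(default_factory=list)
    mc_iter: int = 100
    n_starts: int = 4
    seed: int = 0
    kconf_es1: float = 0.01
    pka_es1: float = 7.5
    pka_scan_start: float = 5.5
    pka_scan_stop: float = 8.5
    pka_scan_step: float = 0.1

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dc_fields(cls)]

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        kw = {}
        known = cls.field_names()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(
                    f"line {lineno}: unknown key {key!r}; valid keys: {known}"
                )
            kw[key] = val
        return cls(**{k: _coerce(cls, k, v) for k, v in kw.items()})

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, list):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    def validate(self) -> None:
        if not self.r1rho_path:
            raise ValueError("r1rho_path is required")
        if not self.ph_values:
            raise ValueError("ph_values must list at least one pH")
        if self.mc_iter < 0 or self.n_starts < 1:
            raise ValueError("mc_iter must be >= 0 and n_starts >= 1")


def _coerce(cls, key: str, raw: str):
    ftype = {f.name: f.type for f in dc_fields(cls)}[key]
    if "list" in str(ftype):
        raw = raw.strip()
        return [float(x) for x in raw.split(",") if x.strip()] if raw else []
    if "int" in str(ftype):
        return int(raw)
    if "float" in str(ftype):
        return float(raw)
    return raw
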