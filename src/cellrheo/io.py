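"""CSV dialects for rheology curves.

Frequency sweeps carry columns ``omega_rad_per_s, g_storage_pa,
g_loss_pa`` (or ``freq_hz`` with the conversion ``omega = 2*pi*f``);
creep curves carry ``time_s, creep_compliance_per_pa``.  Comma
delimiter, ``#`` comment prefix for embedded metadata (seeds, specs).
Write/read round-trips preserve 12 significant digits.
"""

from __future__ import annotations

import io as _io
import os
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .model import CreepCurve, ModulusCurve, ValidationError

__all__ = [
    "DataFormatError",
    "read_modulus_csv",
    "read_creep_csv",
    "write_modulus_csv",
    "write_creep_csv",
]

TWO_PI = 2.0 * np.pi


class DataFormatError(ValueError):
    """A CSV file violates the expected rheology-table dialect."""


def _read_table(path, expected: dict) -> pd.DataFrame:
    if isinstance(path, (str, os.PathLike)) and not os.path.exists(path):
        raise DataFormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise DataFormatError("empty file (no header row)") from None
    if df.empty:
        raise DataFormatError("file contains a header but no data rows")
    missing = [c for c in expected["required"] if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"missing column(s) {missing}; found {list(df.columns)}"
        )
    for col in expected["required"]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            raise DataFormatError(
                f"non-numeric value in column {col!r} at data row {int(bad[0]) + 1}"
            )
        df[col] = numeric.astype(float)
    return df


def _check_positive(df: pd.DataFrame, col: str, strict: bool = True) -> None:
    vals = df[col].to_numpy()
    bad = np.flatnonzero(vals <= 0 if strict else vals < 0)
    if bad.size:
        kind = "non-positive" if strict else "negative"
        raise DataFormatError(
            f"{kind} value in column {col!r} at data row {int(bad[0]) + 1}"
        )


def read_modulus_csv(path, frequency_unit: str = "rad/s") -> ModulusCurve:
    """Read a frequency sweep.

    With ``frequency_unit="rad/s"`` the file must carry
    ``omega_rad_per_s``; with ``"hz"`` it must carry ``freq_hz``, which
    is converted via ``omega = 2*pi*f``.  Rows are sorted by frequency;
    duplicate frequencies are rejected.
    """
    unit = frequency_unit.lower()
    if unit not in ("rad/s", "hz"):
        raise ValidationError("frequency_unit must be 'rad/s' or 'hz'")
    freq_col = "omega_rad_per_s" if unit == "rad/s" else "freq_hz"
    df = _read_table(path, {"required": [freq_col, "g_storage_pa", "g_loss_pa"]})
    for col in (freq_col, "g_storage_pa", "g_loss_pa"):
        _check_positive(df, col)
    if df[freq_col].duplicated().any():
        row = int(df.index[df[freq_col].duplicated()][0]) + 1
        raise DataFormatError(f"duplicate frequency at data row {row}")
    df = df.sort_values(freq_col, kind="stable")
    omega = df[freq_col].to_numpy()
    if unit == "hz":
        omega = TWO_PI * omega
    return ModulusCurve(
        omega=omega,
        storage=df["g_storage_pa"].to_numpy(),
        loss=df["g_loss_pa"].to_numpy(),
    )


def read_creep_csv(path) -> CreepCurve:
    """Read a creep curve (``time_s, creep_compliance_per_pa``)."""
    df = _read_table(path, {"required": ["time_s", "creep_compliance_per_pa"]})
    _check_positive(df, "time_s", strict=False)
    _check_positive(df, "creep_compliance_per_pa", strict=False)
    if df["time_s"].duplicated().any():
        row = int(df.index[df["time_s"].duplicated()][0]) + 1
        raise DataFormatError(f"duplicate time at data row {row}")
    df = df.sort_values("time_s", kind="stable")
    return CreepCurve(
        times=df["time_s"].to_numpy(),
        compliance=df["creep_compliance_per_pa"].to_numpy(),
    )


def _write(path, df: pd.DataFrame, comments: Optional[Iterable[str]]) -> None:
    buf = _io.StringIO()
    for line in comments or ():
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=False, float_format="%.12g")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def write_modulus_csv(
    path, curve: ModulusCurve, comments: Optional[Iterable[str]] = None
) -> None:
    """Write a frequency sweep; ``comments`` become ``#``-prefixed header
    lines (seed and spec provenance)."""
    _write(
        path,
        pd.DataFrame(
            {
                "omega_rad_per_s": curve.omega,
                "g_storage_pa": curve.storage,
                "g_loss_pa": curve.loss,
            }
        ),
        comments,
    )


def write_creep_csv(
    path, curve: CreepCurve, comments: Optional[Iterable[str]] = None
) -> None:
    """Write a creep curve; see :func:`write_modulus_csv`."""
    _write(
        path,
        pd.DataFrame(
            {"time_s": curve.times, "creep_compliance_per_pa": curve.compliance}
        ),
        comments,
    )
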