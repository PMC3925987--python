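"""Reading and writing the package's delimited-text formats.

Two file kinds exist, both plain CSV with a header:

* population files: one row per stratum, columns ``m,p,r_u,rr``;
* subject panels: columns ``id,E,D,PV1..PVm`` plus optional categorical
  confounder columns (any column not named id/E/D/PV*).

Validation errors name the offending line (header = line 1).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .population import StratifiedPopulation
from .simulate import SubjectPanel

__all__ = [
    "read_population",
    "read_subject_panel",
    "write_subject_panel",
]

logger = logging.getLogger(__name__)


def read_population(path: str | Path) -> StratifiedPopulation:
    """Read a stratified population from a ``m,p,r_u,rr`` CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    required = ["m", "p", "r_u", "rr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if len(df) < 2:
        raise ValidationError(f"{path}: a population needs more than one stratum")
    for col in required:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric '{col}' on line {bad[0] + 2}"
            )
    try:
        return StratifiedPopulation(
            m=df["m"].to_numpy(float),
            p=df["p"].to_numpy(float),
            r_u=df["r_u"].to_numpy(float),
            rr=df["rr"].to_numpy(float),
            name=path.stem,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def _check_binary(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[~vals.isin((0, 1))]
    if len(bad):
        raise ValidationError(
            f"{path}: column '{col}' must be 0/1; first offense on line {bad[0] + 2}"
        )
    return vals.to_numpy(np.int8)


def read_subject_panel(
    path: str | Path, pv_columns: list[str] | None = None
) -> SubjectPanel:
    """Read a subject panel CSV (``id,E,D,PV1..PVm[,confounders...]``).

    PV columns are auto-detected by the ``PV`` name prefix unless given
    explicitly; every remaining non-id column is kept as a categorical
    confounder.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    for col in ("E", "D"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column '{col}'")
    if len(df) == 0:
        raise ValidationError(f"{path}: no subject rows")
    e = _check_binary(df, "E", path)
    d = _check_binary(df, "D", path)
    if pv_columns is None:
        pv_columns = [c for c in df.columns if c.startswith("PV")]
    else:
        missing = [c for c in pv_columns if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing PV column(s) {missing}")
    pv = None
    if pv_columns:
        pv = np.column_stack([_check_binary(df, c, path) for c in pv_columns])
    extra = [c for c in df.columns if c not in ("id", "E", "D", *pv_columns)]
    conf = df[extra].reset_index(drop=True) if extra else None
    logger.info(
        "read %s: n=%d subjects, m=%d PVs, %d confounder column(s)",
        path, len(df), 0 if pv is None else pv.shape[1], len(extra),
    )
    return SubjectPanel(e=e, d=d, pv=pv, confounders=conf)


def write_subject_panel(panel: SubjectPanel, path: str | Path) -> None:
    """Write a panel as ``id,E,D,PV1..PVm[,confounders]`` CSV."""
    panel.to_frame().to_csv(path, index=False)
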