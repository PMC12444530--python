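"""Dataset and feature-table I/O.

CSV files are RFC-4180, UTF-8, '.' decimal.  A dataset CSV carries columns
``name, smiles, state, minus_dcH`` where ``minus_dcH`` is the positive
magnitude of the standard combustion enthalpy in kJ·mol⁻¹ and ``state`` is
one of solid/liquid/gas/unknown.  ``.smi`` files hold one record per line,
``SMILES<whitespace>name``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .descriptors import FEATURE_COLUMNS
from .errors import EnthalpographError, SchemaError
from .graphs import parse_smiles

logger = logging.getLogger(__name__)

STATES = ("solid", "liquid", "gas", "unknown")
DATASET_COLUMNS = ("name", "smiles", "state", "minus_dcH")
FEATURE_TABLE_COLUMNS = ("name", "smiles") + FEATURE_COLUMNS


@dataclass(frozen=True)
class DatasetRecord:
    name: str
    smiles: str
    state: str = "unknown"
    minus_dcH: float | None = None


def read_dataset(path, strict: bool = False) -> tuple[list[DatasetRecord], list[str]]:
    """Read and validate a dataset CSV.

    Returns (records, rejections); each rejection message carries the CSV
    line number.  In strict mode the first invalid row raises
    :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype={"name": str, "smiles": str})
    missing = [c for c in ("name", "smiles") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    records: list[DatasetRecord] = []
    rejections: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            smiles = row["smiles"]
            if not isinstance(smiles, str) or not smiles.strip():
                raise SchemaError(f"line {line}: empty SMILES")
            parse_smiles(smiles)
            state = str(row.get("state", "unknown") or "unknown").strip().lower()
            if state in ("", "nan"):
                state = "unknown"
            if state not in STATES:
                raise SchemaError(f"line {line}: unknown state {state!r}")
            target = row.get("minus_dcH")
            if target is not None and pd.notna(target):
                target = float(target)
                if target <= 0:
                    raise SchemaError(
                        f"line {line}: minus_dcH must be positive, got {target}"
                    )
            else:
                target = None
            records.append(
                DatasetRecord(
                    name=str(row["name"]), smiles=smiles.strip(), state=state,
                    minus_dcH=target,
                )
            )
        except EnthalpographError as exc:
            msg = str(exc) if str(exc).startswith("line") else f"line {line}: {exc}"
            if strict:
                raise SchemaError(msg) from exc
            rejections.append(msg)
            logger.warning("rejected row: %s", msg)
    return records, rejections


def write_feature_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in FEATURE_TABLE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    return df


def read_smi(path) -> list[tuple[str, str]]:
    """(name, SMILES) pairs from a .smi file (``SMILES<ws>name`` per line)."""
    out = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else smiles
        out.append((name, smiles))
    return out


def write_smi(pairs: list[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, smiles in pairs:
            fh.write(f"{smiles}\t{name}\n")
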