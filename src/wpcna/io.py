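"""Plain-text readers and writers for pipeline inputs and outputs.

Interchange formats are deliberately simple: TSV for the intensity matrix
(first column peptide id, one column per animal, blank or NA cells =
missing), CSV for per-animal metadata and entry logs, JSON for the
simulation ground truth and run manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_intensity_table",
    "write_intensity_table",
    "read_metadata",
    "write_metadata",
    "read_entry_logs",
    "write_entry_logs",
    "write_truth",
    "read_truth",
]


def read_intensity_table(path: str | Path) -> pd.DataFrame:
    """Read a peptides x animals log2-intensity table (TSV or CSV).

    Duplicate peptide ids and non-numeric cells are parse errors naming
    the offending row/column.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    dupes = raw.index[raw.index.duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate peptide id(s) in {path.name}: {list(dupes)}")
    X = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "") \
            & (raw[col].str.upper().str.strip() != "NA")
        if bad.any():
            pid = raw.index[bad][0]
            raise ValueError(
                f"non-numeric cell in {path.name} at peptide {pid!r}, "
                f"animal {col!r}: {raw.loc[pid, col]!r}"
            )
        X[col] = converted
    X.index.name = "peptide_id"
    X.columns.name = "animal_id"
    return X


def write_intensity_table(X: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    X.to_csv(path, sep=sep, na_rep="NA")


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path).set_index("animal_id")
    required = {"genotype", "exposure", "group"}
    missing = required - set(md.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return md


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path)


def read_entry_logs(path: str | Path) -> pd.DataFrame:
    logs = pd.read_csv(path)
    required = {"animal_id", "day", "CE", "IE", "TE"}
    missing = required - set(logs.columns)
    if missing:
        raise ValueError(f"entry log missing columns: {sorted(missing)}")
    return logs


def write_entry_logs(entry_logs: pd.DataFrame, path: str | Path) -> None:
    entry_logs.to_csv(path, index=False)


def write_truth(study, path: str | Path) -> None:
    """Persist a simulated study's ground truth as JSON."""
    payload = {
        "modules": study.truth_modules.to_dict(),
        "factors": {
            m: [float(v) for v in study.factors.loc[m]] for m in study.factors.index
        },
        "animals": list(study.factors.columns),
        "true_index": {k: float(v) for k, v in study.true_index.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
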