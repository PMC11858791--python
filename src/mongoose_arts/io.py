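"""CSV round-tripping for the study tables, derived tables and fit outputs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

TABLE_NAMES = ("focals", "weights", "demography", "relatedness", "litters")
DERIVED_NAMES = ("events", "transitions", "weight_changes", "dyads", "siring_trials")


def read_tables(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read the five raw study tables from a directory of CSV files."""
    path = Path(path)
    out = {}
    for name in TABLE_NAMES:
        out[name] = pd.read_csv(path / f"{name}.csv", keep_default_na=False, na_values=[])
    return out


def write_derived(derived, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in DERIVED_NAMES:
        getattr(derived, name).to_csv(path / f"{name}.csv", index=False)
    (path / "processing_log.txt").write_text("\n".join(derived.log) + "\n")


def read_derived(path: str | Path) -> dict[str, pd.DataFrame]:
    path = Path(path)
    return {name: pd.read_csv(path / f"{name}.csv") for name in DERIVED_NAMES}


def draws_frame(draws) -> pd.DataFrame:
    """Long-format posterior draws (chain, iteration, parameter, value)."""
    rows = []
    for name in draws.all_names():
        arr = draws.named(name)
        for chain in range(arr.shape[0]):
            rows.append(
                pd.DataFrame(
                    {
                        "chain": chain,
                        "iteration": range(arr.shape[1]),
                        "parameter": name,
                        "value": arr[chain],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def write_results(results, path: str | Path, prefix: str = "") -> None:
    """Write draws.csv and summary.csv (plus transition extras when present)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    draws_frame(results.draws).to_csv(path / f"{prefix}draws.csv", index=False)
    results.summary().to_csv(path / f"{prefix}summary.csv", index=False)
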