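"""Published reference data shipped with the package.

``wildebeest_growth.csv`` is the tail-hair growth table for 11 GPS-collared
blue wildebeest from the Serengeti field study this estimator was developed
for: shave (collaring) and collection (recapture) dates, regrown length,
season/lactation day counts and the printed net growth rate.  Dates are in
the table's original dd/mm/yyyy format; printed rates are truncated to 3 dp
(the table's display convention).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import HairRecord, parse_date

__all__ = ["load_wildebeest_growth", "wildebeest_hair_records"]


def load_wildebeest_growth() -> pd.DataFrame:
    """The reference growth table as printed (one row per animal)."""
    with resources.files("isolag.data").joinpath("wildebeest_growth.csv").open() as fh:
        return pd.read_csv(fh, dtype={"id": str})


def wildebeest_hair_records() -> dict[str, HairRecord]:
    """The reference table as :class:`HairRecord` objects (no segment values)."""
    df = load_wildebeest_growth()
    out: dict[str, HairRecord] = {}
    for _, row in df.iterrows():
        out[row["id"]] = HairRecord(
            animal_id=row["id"],
            start_date=parse_date(row["start_date"]),
            end_date=parse_date(row["end_date"]),
            length_mm=float(row["length_mm"]),
            days_dry=float(row["days_dry"]),
            days_wet=float(row["days_wet"]),
            days_lactating=float(row["days_lactating"]),
        )
    return out
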