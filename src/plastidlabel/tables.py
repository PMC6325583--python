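"""Reproduce the published rate tables from their printed input columns.

Each packaged fixture holds one table's *input* cells (pool contents,
labeled fractions, radiotracer incorporations, carbon/C2 counts) together
with the *printed* derived cells.  ``reproduce_table`` recomputes every
derived cell with the rates module, rounds to the precision each printed
cell shows (round-half-even), and reports a cell-by-cell diff.

A handful of printed cells cannot be recomputed from the printed inputs
(the source evidently carried unrounded intermediates); these are listed
in ``printed_anomalies.csv`` and are flagged as known anomalies rather
than failures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .mid import DomainError
from .rates import (
    c2_content,
    carbon_content,
    decimals_of,
    incorporation_rate,
    round_printed,
    specific_radioactivity_fa,
    specific_radioactivity_lipid,
    turnover_rate,
)

TABLE_FILES = {
    2: "table2_bicarbonate_lipids.csv",
    3: "table3_bicarbonate_mid.csv",
    5: "table5_acetate_fa.csv",
    6: "table6_acetate_mid.csv",
}


def _read_packaged(name: str) -> pd.DataFrame:
    text = resources.files("plastidlabel.data").joinpath(name).read_text()
    body = "".join(l for l in text.splitlines(keepends=True) if not l.startswith("#"))
    return pd.read_csv(io.StringIO(body), dtype=str)


def load_table(table_id: int) -> pd.DataFrame:
    """Printed-table fixture as strings (printed precision preserved)."""
    if table_id not in TABLE_FILES:
        raise DomainError(f"unknown table id {table_id}; known: {sorted(TABLE_FILES)}")
    return _read_packaged(TABLE_FILES[table_id])


def known_anomalies() -> pd.DataFrame:
    return _read_packaged("printed_anomalies.csv")


@dataclass
class TableDiff:
    """Cell-by-cell comparison of recomputed vs printed derived values."""

    table_id: int
    cells: pd.DataFrame  # row, column, printed, recomputed, rounded, match, known_anomaly

    @property
    def ok(self) -> bool:
        """True iff every printed cell matches or is a documented anomaly."""
        if self.cells.empty:
            return True
        return bool((self.cells["match"] | self.cells["known_anomaly"]).all())

    def report(self) -> str:
        lines = [f"Table {self.table_id}: {len(self.cells)} derived cells"]
        for _, c in self.cells.iterrows():
            status = (
                "ok"
                if c["match"]
                else ("KNOWN ANOMALY" if c["known_anomaly"] else "MISMATCH")
            )
            lines.append(
                f"  {c['row']:<28} {c['column']:<30} printed={c['printed']:<8} "
                f"recomputed={c['rounded']:<8} {status}"
            )
        lines.append("all cells accounted for" if self.ok else "UNEXPLAINED MISMATCHES")
        return "\n".join(lines)


def _cell(row_key, column, printed, recomputed, anomalies, table_id):
    if printed is None or (isinstance(printed, float) and pd.isna(printed)):
        return None  # nd cells are excluded from the diff
    printed = str(printed).strip()
    rounded = round_printed(recomputed, decimals_of(printed))
    match = abs(rounded - float(printed)) < 1e-12
    known = bool(
        (
            (anomalies["table"] == str(table_id))
            & (anomalies["row"] == row_key)
            & (anomalies["column"] == column)
        ).any()
    )
    return {
        "row": row_key,
        "column": column,
        "printed": printed,
        "recomputed": recomputed,
        "rounded": rounded,
        "match": match,
        "known_anomaly": known,
    }


def reproduce_table(table_id: int) -> TableDiff:
    """Recompute one table's derived columns and diff against the print."""
    fixture = load_table(table_id)
    anomalies = known_anomalies()
    cells = []

    for _, row in fixture.iterrows():
        if table_id == 2:
            key = row["lipid"]
            cc = carbon_content(float(row["content_nmol"]), int(row["carbon_number"]))
            cells.append(_cell(key, "printed_carbon_content", row["printed_carbon_content"], cc, anomalies, 2))
            sr = specific_radioactivity_lipid(float(row["incorporation_pmol"]), cc)
            cells.append(_cell(key, "printed_specific_radioactivity", row["printed_specific_radioactivity"], sr, anomalies, 2))
        elif table_id == 5:
            key = row["fatty_acid"]
            cc = c2_content(float(row["content_nmol"]), int(row["c2_units"]))
            cells.append(_cell(key, "printed_c2_content", row["printed_c2_content"], cc, anomalies, 5))
            sr = specific_radioactivity_fa(float(row["incorporation_pmol"]), cc)
            cells.append(_cell(key, "printed_specific_radioactivity", row["printed_specific_radioactivity"], sr, anomalies, 5))
        else:  # 3 and 6: labeled-fraction tables
            if table_id == 3:
                key = f"{row['pool']}:{row['condition']}"
            else:
                key = row["fatty_acid"]
            if pd.isna(row["labeled_pct"]):
                continue  # nd
            pct = float(row["labeled_pct"])
            inc = incorporation_rate(float(row["content_nmol"]), pct)
            cells.append(_cell(key, "printed_incorporation", row["printed_incorporation"], inc, anomalies, table_id))
            k = turnover_rate(pct)
            cells.append(_cell(key, "printed_turnover", row["printed_turnover"], k, anomalies, table_id))

    cells = [c for c in cells if c is not None]
    frame = pd.DataFrame(
        cells,
        columns=["row", "column", "printed", "recomputed", "rounded", "match", "known_anomaly"],
    )
    return TableDiff(table_id=table_id, cells=frame)


def reproduce_all() -> dict[int, TableDiff]:
    return {tid: reproduce_table(tid) for tid in TABLE_FILES}
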