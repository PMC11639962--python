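"""Screening products: activity classification, ranking and reporting.

A sample is *active* when its EC50 is determined (not ND) and falls
strictly below the activity threshold, 50 ug/mL by default (the boundary
is configurable).  Actives are ranked ascending by EC50 (rank 1 =
strongest inhibitor), with lexicographic sample-id tie-breaking, and the
screen report is a table of rank, display names, EC50, cell viability and
sample number, with screened/active counts in a footer.

A transcription of the published 11-hit screening table ships with the
package as a worked fixture (``load_table1``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import EC50Result

__all__ = [
    "ACTIVITY_THRESHOLD_UG_ML",
    "ScreenRecord",
    "classify_active",
    "rank_actives",
    "screen_report",
    "load_table1",
    "records_from_table",
]

#: EC50 below this (strictly) counts as high aggregation-inhibitory activity.
ACTIVITY_THRESHOLD_UG_ML = 50.0


@dataclass
class ScreenRecord:
    """One sample's screening outcome (a report row)."""

    sample_id: str
    ec50: float = float("nan")
    ec50_sd: float = float("nan")
    nd_flag: bool = False
    viability_pct: float = float("nan")
    display_names: tuple[str, ...] = ()
    viability_stars: str = ""
    active: bool | None = None
    rank: int | None = None


def classify_active(record: ScreenRecord | EC50Result,
                    threshold: float = ACTIVITY_THRESHOLD_UG_ML,
                    inclusive: bool = False) -> bool:
    """True iff the EC50 is determined and below the threshold.

    The default boundary is strict (``EC50 == threshold`` is inactive);
    set ``inclusive=True`` to admit the boundary.
    """
    if isinstance(record, EC50Result):
        nd, ec50 = record.nd_flag, record.ec50_mean
    else:
        nd, ec50 = record.nd_flag, record.ec50
    if nd or not np.isfinite(ec50):
        return False
    return ec50 <= threshold if inclusive else ec50 < threshold


def rank_actives(records: list[ScreenRecord],
                 threshold: float = ACTIVITY_THRESHOLD_UG_ML,
                 inclusive: bool = False) -> list[ScreenRecord]:
    """Classify and rank: actives sorted ascending by EC50 (ties broken by
    sample id) with ranks 1..K; inactives follow unranked.

    Idempotent and invariant to the input order.
    """
    classified = [replace(r, active=classify_active(r, threshold, inclusive), rank=None)
                  for r in records]
    actives = sorted((r for r in classified if r.active),
                     key=lambda r: (r.ec50, r.sample_id))
    inactives = sorted((r for r in classified if not r.active),
                       key=lambda r: r.sample_id)
    for i, r in enumerate(actives, start=1):
        r.rank = i
    return actives + inactives


REPORT_COLUMNS = ["Activity Rank", "Name(s)", "EC50 (ug/mL)", "Cell Viability (%)", "Number"]


def screen_report(records: list[ScreenRecord], n_screened: int | None = None,
                  path: str | Path | None = None, fmt: str = "csv"
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Build the screen report table (active, ranked samples only).

    Returns the table plus footer lines counting screened and active
    samples (active percentage rounded to the nearest integer).  When
    ``path`` is given the report is written as CSV (footer as ``#``
    comment lines) or Markdown.
    """
    ranked = [r for r in records if r.rank is not None]
    ranked.sort(key=lambda r: r.rank)
    table = pd.DataFrame([{
        "Activity Rank": r.rank,
        "Name(s)": "; ".join(r.display_names) if r.display_names else r.sample_id,
        "EC50 (ug/mL)": r.ec50,
        "Cell Viability (%)": r.viability_pct,
        "Number": r.sample_id,
    } for r in ranked], columns=REPORT_COLUMNS)
    n_total = n_screened if n_screened is not None else len(records)
    n_active = len(ranked)
    pct = round(100.0 * n_active / n_total) if n_total else 0
    footer = [
        f"samples screened: {n_total}",
        f"active samples (EC50 below threshold): {n_active} ({pct}%)",
    ]
    if path is not None:
        path = Path(path)
        if fmt == "csv":
            text = table.to_csv(index=False) + "".join(f"# {line}\n" for line in footer)
        elif fmt == "markdown":
            text = table.to_markdown(index=False) + "\n\n" + \
                "\n".join(f"*{line}*" for line in footer) + "\n"
        else:
            raise ValueError(f"unknown report format {fmt!r}")
        try:
            path.write_text(text)
        except OSError as exc:
            raise OSError(f"could not write screen report to {path}: {exc}") from exc
    return table, footer


def load_table1() -> pd.DataFrame:
    """The packaged 11-hit screening table (transcribed fixture):
    activity_rank, japanese_name, scientific_name, ec50_ug_ml,
    viability_pct, sample_id."""
    with resources.files("mshts.data").joinpath("table1.csv").open("rb") as fh:
        return pd.read_csv(fh)


def records_from_table(df: pd.DataFrame,
                       viability_stars: dict[str, str] | None = None
                       ) -> list[ScreenRecord]:
    """Build ScreenRecords from a table with columns ``sample_id``,
    ``ec50_ug_ml`` and optionally ``viability_pct`` and name columns.

    ``viability_stars`` (sample_id -> significance stars from a Welch test
    against the aggregation-only group) is attached verbatim when supplied;
    the report never infers viability significance from the values alone.
    """
    viability_stars = viability_stars or {}
    records = []
    name_cols = [c for c in ("japanese_name", "scientific_name") if c in df.columns]
    ec50_col = "ec50_ug_ml" if "ec50_ug_ml" in df.columns else "ec50_mean"
    for row in df.itertuples(index=False):
        d = row._asdict()
        raw = d[ec50_col]
        nd = bool(d.get("nd_flag", False))
        if isinstance(raw, str) and raw.strip().upper() == "ND":
            nd, ec50 = True, float("nan")
        else:
            ec50 = float(raw)
            nd = nd or not np.isfinite(ec50)
        records.append(ScreenRecord(
            sample_id=str(d["sample_id"]),
            ec50=ec50,
            ec50_sd=float(d.get("ec50_sd", float("nan"))),
            nd_flag=nd,
            viability_pct=float(d.get("viability_pct", float("nan"))),
            display_names=tuple(str(d[c]) for c in name_cols),
            viability_stars=viability_stars.get(str(d["sample_id"]), ""),
        ))
    return records
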