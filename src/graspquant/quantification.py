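"""Occurrence tables and top-k coverage statistics.

A grasp *instance* is one labeled segmentation run.  Instances are
tabulated per activity (ADL) and in TOTAL per finger, with percentages
reported to one decimal under round-half-up — the convention that
reproduces every printed cell of the reference occurrence tables
shipped as fixtures.  Coverage answers the prosthesis-design question:
how many of the most frequent grasps cover more than a given share
(default 80%) of all instances?
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from graspquant.segmentation import GraspPosture
from graspquant.taxonomy import DISPLAY_NAMES, check_finger, finger_grasps

TOTAL_SCOPE = "TOTAL"


def percentage(count: int, total: int) -> float:
    """Share of ``count`` in ``total`` as a one-decimal percent, half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OccurrenceTable:
    """Instance counts per (scope, grasp) for one finger.

    ``rows`` has columns ``scope`` (an ADL name or ``TOTAL``),
    ``grasp``, ``count`` and ``percent`` (one decimal, computed within
    its scope).  Within every scope the counts sum to the scope total
    by construction.
    """

    finger: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        check_finger(self.finger)
        required = {"scope", "grasp", "count", "percent"}
        if not required.issubset(self.rows.columns):
            raise ValueError(f"rows must have columns {sorted(required)}")
        if (self.rows["count"] < 0).any():
            raise ValueError("counts must be non-negative")

    def scope(self, scope: str = TOTAL_SCOPE) -> pd.DataFrame:
        return self.rows[self.rows["scope"] == scope].reset_index(drop=True)

    def grand_total(self, scope: str = TOTAL_SCOPE) -> int:
        return int(self.scope(scope)["count"].sum())


@dataclass(frozen=True)
class CoverageResult:
    """Descending-count ordering and cumulative shares for one finger."""

    finger: str
    grasps: tuple[str, ...]
    counts: tuple[int, ...]
    cumulative_shares: tuple[float, ...]  # exact percents, not rounded
    threshold: float
    k_min: int

    def __post_init__(self) -> None:
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if np.any(np.diff(self.cumulative_shares) < -1e-12):
            raise ValueError("cumulative shares must be non-decreasing")


def _scope_rows(finger: str, scope: str, counts: dict[str, int]) -> list[dict]:
    total = sum(counts.values())
    rows = []
    for grasp in sorted(counts):
        n = counts[grasp]
        rows.append(
            {
                "finger": finger,
                "scope": scope,
                "grasp": grasp,
                "count": int(n),
                "percent": percentage(n, total) if total > 0 else 0.0,
            }
        )
    return rows


def tabulate(
    labeled_by_adl: dict[str, list[GraspPosture]], finger: str
) -> OccurrenceTable:
    """Count labeled postures per ADL and in TOTAL.

    One posture = one instance.  Every label must belong to the
    finger's training subset.
    """
    check_finger(finger)
    allowed = set(finger_grasps(finger))
    per_adl: dict[str, dict[str, int]] = {}
    total_counts: dict[str, int] = {}
    for adl, postures in labeled_by_adl.items():
        counts: dict[str, int] = {}
        for p in postures:
            if p.label is None or p.label not in allowed:
                raise ValueError(
                    f"label {p.label!r} not in the {finger} finger subset"
                )
            counts[p.label] = counts.get(p.label, 0) + 1
            total_counts[p.label] = total_counts.get(p.label, 0) + 1
        per_adl[adl] = counts

    rows: list[dict] = []
    for adl in labeled_by_adl:
        rows.extend(_scope_rows(finger, adl, per_adl[adl]))
    rows.extend(_scope_rows(finger, TOTAL_SCOPE, total_counts))
    return OccurrenceTable(finger=finger, rows=pd.DataFrame(rows))


def table_from_counts(
    finger: str, counts: dict[str, int] | list[tuple[str, int]]
) -> OccurrenceTable:
    """An OccurrenceTable (TOTAL scope only) from explicit counts.

    Accepts a list of (grasp, count) pairs so that tables with repeated
    grasp rows — as printed in one reference table — round-trip
    verbatim; duplicate names are kept as distinct rows.
    """
    check_finger(finger)
    if isinstance(counts, dict):
        pairs = sorted(counts.items())
    else:
        pairs = list(counts)
    total = sum(c for _, c in pairs)
    rows = [
        {
            "finger": finger,
            "scope": TOTAL_SCOPE,
            "grasp": g,
            "count": int(c),
            "percent": percentage(c, total) if total > 0 else 0.0,
        }
        for g, c in pairs
    ]
    return OccurrenceTable(finger=finger, rows=pd.DataFrame(rows))


def top_k_coverage(
    table: OccurrenceTable, threshold: float = 80.0, scope: str = TOTAL_SCOPE
) -> CoverageResult:
    """Smallest k such that the k most frequent grasps exceed ``threshold``%.

    Rows are ordered by descending count with alphabetical tie-break;
    cumulative shares are exact (unrounded) percents of the scope total.
    """
    sub = table.scope(scope)
    total = int(sub["count"].sum())
    if total <= 0:
        raise ValueError(f"scope {scope!r} has no instances")
    ordered = sub.sort_values(
        ["count", "grasp"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    counts = ordered["count"].to_numpy()
    cum = np.cumsum(counts) * 100.0 / total
    above = np.flatnonzero(cum > threshold)
    k_min = int(above[0]) + 1 if above.size else len(counts)
    return CoverageResult(
        finger=table.finger,
        grasps=tuple(ordered["grasp"]),
        counts=tuple(int(c) for c in counts),
        cumulative_shares=tuple(float(c) for c in cum),
        threshold=threshold,
        k_min=k_min,
    )


# -- reference fixtures (printed occurrence tables) --------------------

_TABLE_FINGERS = {
    3: "index", 4: "index", 5: "middle", 6: "middle",
    7: "ring", 8: "ring", 9: "little", 10: "little",
}


def load_printed_table(number: int) -> pd.DataFrame:
    """Load a packaged reference occurrence table (numbers 3-10).

    Odd-numbered fixtures are per-finger totals (scope ``TOTAL``);
    even-numbered ones are per-ADL.  Columns: ``scope``, ``grasp``,
    ``count``, ``printed_percent`` (NaN where the source prints none).
    Rows are kept exactly as printed, including one duplicated grasp
    row in table 5.
    """
    if number not in _TABLE_FINGERS:
        raise ValueError("reference tables are numbered 3..10")
    ref = resources.files("graspquant") / "data" / "tables" / f"table{number:02d}.csv"
    with ref.open() as fh:
        df = pd.read_csv(fh, comment="#")
    df["count"] = df["count"].astype(int)
    return df


def printed_table_finger(number: int) -> str:
    return _TABLE_FINGERS[number]


def printed_total_table(number: int) -> OccurrenceTable:
    """A total-scope OccurrenceTable built from a printed totals fixture."""
    if number not in (3, 5, 7, 9):
        raise ValueError("totals tables are 3, 5, 7 and 9")
    df = load_printed_table(number)
    key = {v: k for k, v in DISPLAY_NAMES.items()}
    pairs = [(key[g], int(c)) for g, c in zip(df["grasp"], df["count"])]
    return table_from_counts(_TABLE_FINGERS[number], pairs)


def report(
    tables: list[OccurrenceTable],
    coverages: list[CoverageResult],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the occurrence CSV and coverage JSON; deterministic layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "occurrences.csv"
    cols = ["finger", "scope", "grasp", "count", "percent"]
    if tables:
        df = pd.concat([t.rows for t in tables], ignore_index=True)[cols]
    else:
        df = pd.DataFrame(columns=cols)
    df.to_csv(csv_path, index=False, float_format="%.1f")

    json_path = out / "coverage.json"
    payload = {
        c.finger: {
            "threshold_percent": c.threshold,
            "k_min": c.k_min,
            "grasps": list(c.grasps),
            "counts": list(c.counts),
            "cumulative_shares": [round(s, 6) for s in c.cumulative_shares],
        }
        for c in coverages
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return csv_path, json_path
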