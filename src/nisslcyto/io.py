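"""Readers and writers for profile and ratings files.

Dialects (all UTF-8, comma-separated, LF endings, quoting only when needed):

* profiles CSV — one row per cell, columns named after the profile fields,
  ``accessory_flags`` as a ``;``-joined token list, empty = no flags; an
  optional leading ``cell_id`` column is preserved.
* profiles JSON — a list of objects with the same keys.
* ratings CSV — wide format: first column ``cell_id``, one column per rater,
  an empty cell is a missing rating; tokens are exactly the five rating
  categories.  An optional YAML sidecar provides per-rater experience tags
  and per-unit test tags.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .profiles import CytologicalProfile, validate_profile
from .reliability import RatingsTable, ReliabilityReport
from .vocab import RATING_LABELS


class ParseError(ValueError):
    """A data file does not conform to its dialect."""


# -- profiles --------------------------------------------------------------


def read_profiles_csv(path) -> list[tuple[str, CytologicalProfile]]:
    """Read ``(cell_id, profile)`` pairs; row number is the id fallback."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for i, row in enumerate(df.to_dict(orient="records")):
        cell_id = row.pop("cell_id", None) or f"cell-{i + 1}"
        try:
            out.append((cell_id, validate_profile(row)))
        except ValueError as exc:
            raise ParseError(f"{path}, row {i + 2}: {exc}") from exc
    return out


def write_profiles_csv(profiles, path) -> None:
    """Write ``(cell_id, profile)`` pairs (or bare profiles) to CSV."""
    rows = []
    for i, item in enumerate(profiles):
        if isinstance(item, CytologicalProfile):
            cell_id, profile = f"cell-{i + 1}", item
        else:
            cell_id, profile = item
        rows.append({"cell_id": cell_id, **profile.to_record()})
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def read_profiles_json(path) -> list[tuple[str, CytologicalProfile]]:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    out = []
    for i, obj in enumerate(data):
        cell_id = obj.pop("cell_id", None) or f"cell-{i + 1}"
        try:
            out.append((cell_id, validate_profile(obj)))
        except ValueError as exc:
            raise ParseError(f"{path}, object {i}: {exc}") from exc
    return out


# -- ratings ---------------------------------------------------------------


def read_ratings_csv(path, sidecar=None) -> RatingsTable:
    """Read a wide ratings CSV, validating tokens with row/column context."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns.empty or df.columns[0] != "cell_id":
        raise ParseError(f"{path}: first column must be 'cell_id'")
    if df["cell_id"].duplicated().any():
        dupes = df["cell_id"][df["cell_id"].duplicated()].tolist()
        raise ParseError(f"{path}: duplicate cell_id {dupes}")
    values = df.set_index("cell_id")
    allowed = set(RATING_LABELS)
    for col in values.columns:
        for cell_id, token in values[col].items():
            token = token.strip()
            if token and token not in allowed:
                raise ParseError(
                    f"{path}: unknown token {token!r} "
                    f"(cell_id {cell_id!r}, rater column {col!r})"
                )
    values = values.apply(lambda s: s.str.strip()).replace("", pd.NA)

    rater_experience: dict = {}
    unit_test: dict = {}
    if sidecar is not None:
        with open(sidecar, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh) or {}
        rater_experience = dict(meta.get("rater_experience", {}))
        unit_test = dict(meta.get("unit_test", {}))
    return RatingsTable(
        values=values, rater_experience=rater_experience, unit_test=unit_test
    )


def write_ratings_csv(table: RatingsTable, path, sidecar=None) -> None:
    df = table.values.copy()
    df.index.name = "cell_id"
    df.to_csv(path, na_rep="", lineterminator="\n")
    if sidecar is not None:
        meta = {
            "rater_experience": dict(table.rater_experience),
            "unit_test": dict(table.unit_test),
        }
        with open(sidecar, "w", encoding="utf-8") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)


# -- reports ---------------------------------------------------------------


def write_report_json(report: ReliabilityReport, path) -> None:
    """Deterministic JSON (sorted keys, no timestamps)."""
    Path(path).write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def format_report_text(report: ReliabilityReport) -> str:
    """Human-readable summary (alpha and agreement to two decimals)."""
    lines = [
        f"Krippendorff's alpha (nominal): {report.alpha:.2f}",
        f"  observed disagreement D_o = {report.D_o:.4f}",
        f"  expected disagreement D_e = {report.D_e:.4f}",
        f"  pairable pairs n = {report.n:.0f}",
    ]
    if report.percent_agreement_mean is not None:
        lines.append(
            "Mean pairwise percent agreement: "
            f"{report.percent_agreement_mean:.2f} +/- "
            f"{report.percent_agreement_sem:.2f} (SEM across rater pairs)"
        )
    if report.disagreement_ranking:
        lines.append("Most common disagreements:")
        for (a, b), count in report.disagreement_ranking[:5]:
            lines.append(f"  {a}-{b}: {count:.0f} pairs")
    return "\n".join(lines) + "\n"
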