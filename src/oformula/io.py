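"""CSV/JSON readers and writers for biometry, IOL designs and reports.

Conventions: comma-separated UTF-8 CSV with a mandatory header row, dot
decimals, fixed units (mm and diopters, no unit columns).  Optional columns
may be empty.  Validation is two-tier: structural problems (missing columns,
unparsable numbers) raise; physiologically implausible values are returned
as per-row diagnostics so a partly dirty file can still be inspected.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import pandas as pd

from .biometry import BiometryRecord, validate_record
from .eye import IOLDesign, IOLPowerEntry

__all__ = [
    "BiometryReadError",
    "RowDiagnostic",
    "read_biometry",
    "write_biometry",
    "read_design",
    "write_design",
    "write_report",
]

REQUIRED_COLUMNS = (
    "al_display", "cct", "aqd", "lt", "ata_depth", "le_depth", "nuclear_grade",
    "r_ant_steep", "r_ant_flat", "r_post_steep", "r_post_flat",
)
OPTIONAL_COLUMNS = (
    "eye_id", "e_ant", "e_post", "postop_refraction_se", "measured_iol_depth",
    "implanted_power",
)


class BiometryReadError(ValueError):
    pass


@dataclass(frozen=True)
class RowDiagnostic:
    row: int  # 0-based data row
    eye_id: str
    message: str


def read_biometry(path, strict: bool = False):
    """Read a biometry CSV -> (records, diagnostics).

    Raises :class:`BiometryReadError` for missing required columns or
    unparsable numerics; range violations become :class:`RowDiagnostic`
    entries (or raise, when ``strict``).  Row order is preserved.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise BiometryReadError(f"missing required column(s): {', '.join(missing)}")
    records, diagnostics = [], []
    for i, row in df.iterrows():
        eye_id = str(row["eye_id"]) if "eye_id" in df.columns and not pd.isna(row.get("eye_id")) \
            else f"row{i}"
        kwargs = {"eye_id": eye_id}
        try:
            for col in REQUIRED_COLUMNS:
                kwargs[col] = float(row[col])
            for col in ("e_ant", "e_post"):
                kwargs[col] = float(row[col]) if col in df.columns and not pd.isna(row[col]) else 0.0
            for col in ("postop_refraction_se", "measured_iol_depth", "implanted_power"):
                if col in df.columns and not pd.isna(row[col]):
                    kwargs[col] = float(row[col])
        except (TypeError, ValueError) as exc:
            raise BiometryReadError(f"row {i} ({eye_id}): unparsable value: {exc}") from None
        if any(math.isnan(kwargs[c]) for c in REQUIRED_COLUMNS):
            raise BiometryReadError(f"row {i} ({eye_id}): missing required value")
        rec = BiometryRecord(**kwargs)
        for msg in validate_record(rec):
            diagnostics.append(RowDiagnostic(row=i, eye_id=eye_id, message=msg))
        records.append(rec)
    if strict and diagnostics:
        lines = "; ".join(f"row {d.row}: {d.message}" for d in diagnostics[:10])
        raise BiometryReadError(f"{len(diagnostics)} range violation(s): {lines}")
    return records, diagnostics


def write_biometry(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_design(path) -> IOLDesign:
    """Load an IOL design table from JSON (header + per-power geometry)."""
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("name", "power_step", "entries"):
        if key not in payload:
            raise ValueError(f"design JSON missing key '{key}'")
    entries = []
    for i, e in enumerate(payload["entries"]):
        try:
            entries.append(
                IOLPowerEntry(
                    labeled_power=float(e["power"]),
                    r_front=float(e["r_front_mm"]),
                    r_back=float(e["r_back_mm"]),
                    thickness=float(e["thickness_mm"]),
                    n_iol=float(e["n"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"design entry {i} invalid: {exc}") from None
    return IOLDesign(name=str(payload["name"]), entries=entries,
                     power_step=float(payload["power_step"]))


def write_design(design: IOLDesign, path) -> None:
    payload = {
        "name": design.name,
        "power_step": design.power_step,
        "entries": [
            {
                "power": e.labeled_power,
                "r_front_mm": e.r_front if math.isfinite(e.r_front) else "inf",
                "r_back_mm": e.r_back if math.isfinite(e.r_back) else "-inf",
                "thickness_mm": e.thickness,
                "n": e.n_iol,
            }
            for e in design.entries
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def _fmt_stats_block(stats_by_formula: dict) -> list:
    lines = [
        f"{'Formula':<22}{'ME±SD (D)':>16}{'MAE (D)':>10}{'MedAE (D)':>11}"
        f"{'±0.25D%':>9}{'±0.50D%':>9}{'±1.00D%':>9}"
    ]
    for name, s in stats_by_formula.items():
        lines.append(
            f"{name:<22}{s.me:+.3f} ± {s.sd:.3f}{s.mae:>10.3f}{s.medae:>11.3f}"
            f"{s.pct_025:>9.1f}{s.pct_050:>9.1f}{s.pct_100:>9.1f}"
        )
    return lines


def write_report(report: dict, json_path, text_path=None) -> None:
    """Persist an evaluation report.

    ``report`` maps block name ("raw", "zero_adjusted", subgroup blocks, ...)
    -> {formula label -> ErrorStats}; the JSON round-trips numerically and the
    optional text table mirrors the clinical presentation (Mean ± SD,
    MAE, MedAE, band percentages to one decimal).  Empty subgroups are
    written as n = 0 rows.
    """
    payload = {}
    for block, stats in report.items():
        payload[block] = {
            name: (asdict(s) if not isinstance(s, dict) else s) for name, s in stats.items()
        }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    if text_path is not None:
        lines = []
        for block, stats in report.items():
            lines.append(f"== {block} ==")
            if not stats:
                lines.append("  n=0")
            else:
                lines.extend(_fmt_stats_block(stats))
            lines.append("")
        with open(text_path, "w") as fh:
            fh.write("\n".join(lines))
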