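"""Metagenomic-bin curation by collection temperature.

Bins are kept only when a confirmed collection temperature lies inside the
hot-spring range (42–90 °C, both bounds inclusive); a missing temperature
always excludes, even when the ecosystem-subtype label matches — the
conservative stance of working only with confirmed hot samples.  Manually
curated temperatures (e.g. recovered from the underlying study) override the
recorded metadata value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_T_MIN = 42.0
DEFAULT_T_MAX = 90.0


@dataclass
class CurationReport:
    """Partition of the input bins into kept and excluded (with reasons)."""

    kept: list = field(default_factory=list)
    excluded: list = field(default_factory=list)   # (bin_id, reason)
    warnings: list = field(default_factory=list)
    t_min: float = DEFAULT_T_MIN
    t_max: float = DEFAULT_T_MAX

    @property
    def excluded_ids(self) -> list:
        return [b for b, _ in self.excluded]

    def reason(self, bin_id: str) -> str | None:
        for b, r in self.excluded:
            if b == bin_id:
                return r
        return None


def merge_curated_temperatures(metadata: pd.DataFrame,
                               overrides: dict | None,
                               report: CurationReport | None = None) -> pd.DataFrame:
    """Attach a ``curated_temperature_c`` column from per-bin overrides.

    Overrides are keyed by bin_id; an override for an unknown bin is a
    warning, not an error.  Rows without an override keep NaN in the curated
    column and fall back to the recorded temperature downstream.
    """
    out = metadata.copy()
    out["curated_temperature_c"] = np.nan
    overrides = overrides or {}
    known = set(out["bin_id"])
    for bin_id, temp in overrides.items():
        if bin_id not in known:
            msg = f"temperature override for unknown bin {bin_id!r} ignored"
            log.warning(msg)
            if report is not None:
                report.warnings.append(msg)
            continue
        mask = out["bin_id"] == bin_id
        recorded = out.loc[mask, "temperature_c"]
        if recorded.notna().any() and not np.isclose(recorded.dropna(), temp).all():
            msg = (f"override {temp} conflicts with recorded temperature "
                   f"{recorded.dropna().iloc[0]} for bin {bin_id}; curated value wins")
            log.warning(msg)
            if report is not None:
                report.warnings.append(msg)
        out.loc[mask, "curated_temperature_c"] = temp
    return out


def effective_temperature(metadata: pd.DataFrame) -> pd.Series:
    """Curated value where present, recorded value otherwise (NaN = missing)."""
    if "curated_temperature_c" in metadata.columns:
        return metadata["curated_temperature_c"].fillna(metadata["temperature_c"])
    return metadata["temperature_c"]


def curate_bins(metadata: pd.DataFrame,
                t_min: float = DEFAULT_T_MIN,
                t_max: float = DEFAULT_T_MAX,
                require_subtype: str | None = None,
                overrides: dict | None = None) -> CurationReport:
    """Classify every bin as kept or excluded.

    Kept iff the effective temperature exists and ``t_min <= T <= t_max``
    (inclusive at both bounds) and, when ``require_subtype`` is given, the
    ecosystem subtype matches exactly.  Every input bin lands in exactly one
    of kept/excluded, so the report partitions the input.
    """
    report = CurationReport(t_min=t_min, t_max=t_max)
    if overrides:
        metadata = merge_curated_temperatures(metadata, overrides, report)
    temps = effective_temperature(metadata)
    for (_, row), temp in zip(metadata.iterrows(), temps):
        bin_id = row["bin_id"]
        if require_subtype is not None and row["ecosystem_subtype"] != require_subtype:
            report.excluded.append((bin_id, "wrong_subtype"))
        elif pd.isna(temp):
            report.excluded.append((bin_id, "missing_temperature"))
        elif temp < t_min:
            report.excluded.append((bin_id, "below_min"))
        elif temp > t_max:
            report.excluded.append((bin_id, "above_max"))
        else:
            report.kept.append(bin_id)
    return report
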