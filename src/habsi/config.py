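"""Structured configuration for every tunable rule threshold.

All thresholds that the detection and classification rules use live here, so
a site can adapt the rules (the hospital's own rule book is a local consensus
adaptation of NHSN definitions) without touching code.  Defaults are the
values the package's documentation and tests assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .organisms import DEFAULT_COMMENSAL_CODES

__all__ = ["RulesConfig", "load_config"]


@dataclass(frozen=True)
class RulesConfig:
    # healthcare-associated rule: first positive blood specimen this long
    # after admission of the (merged) episode, inclusive
    min_hai_hours: float = 48.0
    # re-admission linkage window (calendar days, inclusive)
    readmit_gap_days: int = 2

    # vital-sign screening; fever is strictly > fever_c
    fever_c: float = 38.0
    hypothermia_c: float = 36.0
    adult_hr_bpm: int = 90
    adult_rr_pm: int = 20
    infant_hr_bpm: int = 180
    infant_rr_pm: int = 60
    infant_age_days: int = 365  # age band for pediatric thresholds

    # commensal corroboration: same commensal in >=2 separate draws with
    # log-ins <= commensal_window_days apart, plus a sign flag within
    # +/- sign_window_hours of the first draw
    commensal_window_days: int = 2
    sign_window_hours: float = 24.0

    # laboratory recall day: report revisions later than recall_days after
    # the final report are logged but never applied
    recall_days: int = 7

    # clinical-sepsis pathway
    csep_blood_window_hours: float = 48.0
    csep_abx_hours: float = 48.0
    csep_nonblood_window_days: int = 7

    # deduplication
    polymicrobial_hours: float = 48.0
    persistent_days: int = 14

    # classification
    secondary_window_days: int = 7
    line_lookback_hours: float = 48.0

    commensal_codes: frozenset[str] = field(default_factory=lambda: DEFAULT_COMMENSAL_CODES)

    def with_updates(self, **kwargs) -> "RulesConfig":
        return replace(self, **kwargs)


def load_config(path: Path | str | None = None, **overrides) -> RulesConfig:
    """Load a :class:`RulesConfig` from a YAML mapping, applying overrides.

    Unknown keys are rejected so typos do not silently fall back to defaults.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    known = {f.name for f in fields(RulesConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "commensal_codes" in data:
        data["commensal_codes"] = frozenset(data["commensal_codes"])
    return RulesConfig(**data)
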