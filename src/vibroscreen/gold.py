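"""Dual-axis clinical gold standard: keyword severity mapping and tiers.

Narrative psychiatric diagnoses are quantified on two independent 1–5
severity axes (depression, anxiety) by matching severity-defining
keywords; the highest-severity match wins, and text with no match is
subclinical (level 1).  Severity >= 3 defines the high-risk binary gold
label, and severities group into three actionable tiers:
{1, 2} → tier 1 (asymptomatic/mild, routine follow-up), {3} → tier 2
(moderate, adjustment or follow-up), {4, 5} → tier 3 (severe, referral
to specialty care).  By construction tier >= 2 coincides exactly with
the high-risk binarization.
"""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = [
    "DEFAULT_KEYWORD_MAP",
    "severity_from_keywords",
    "binarize_high_risk",
    "to_tier",
    "load_keyword_map",
    "HIGH_RISK_CUTOFF",
]

HIGH_RISK_CUTOFF = 3

#: severity level -> example diagnostic keywords (case-insensitive substrings)
DEFAULT_KEYWORD_MAP: dict[int, tuple[str, ...]] = {
    5: ("severe depression with psychotic symptoms", "mood disorder",
        "phantosmia", "suicidal ideation", "panic attacks"),
    4: ("depressive episode", "mixed anxiety-depressive disorder",
        "severe anxiety"),
    3: ("depressive state", "anxious depressive state",
        "emotional and behavioral disorders", "adjustment disorder"),
    2: ("sleep disorder", "emotional disorders in children", "mild anxiety"),
    1: ("psychological consultation", "no significant abnormality"),
}


def _validate_map(keyword_map: dict[int, tuple[str, ...]]) -> None:
    for level in range(1, 6):
        if not keyword_map.get(level):
            raise ValueError(f"keyword map must define >= 1 keyword for level {level}")


def severity_from_keywords(
    diagnosis_text: str,
    keyword_map: dict[int, tuple[str, ...]] | None = None,
) -> int:
    """Map a narrative diagnosis to a 1–5 severity level.

    Matching is case-insensitive substring search; when several keywords
    match, the highest severity wins (clinical grading takes the worst
    finding).  Text with no match is level 1 by definition, not an
    error.
    """
    if not diagnosis_text or not diagnosis_text.strip():
        raise ValueError("diagnosis text is empty")
    keyword_map = keyword_map or DEFAULT_KEYWORD_MAP
    _validate_map(keyword_map)
    text = diagnosis_text.lower()
    for level in sorted(keyword_map, reverse=True):
        if any(kw.lower() in text for kw in keyword_map[level]):
            return level
    return 1


def _check_severity(severity: int) -> int:
    severity = int(severity)
    if not (1 <= severity <= 5):
        raise ValueError(f"severity must be in 1..5, got {severity}")
    return severity


def binarize_high_risk(severity: int) -> bool:
    """High-risk gold label: positive iff severity >= 3."""
    return _check_severity(severity) >= HIGH_RISK_CUTOFF


def to_tier(severity: int) -> int:
    """Three-tier gold grouping: {1,2}→1, {3}→2, {4,5}→3."""
    severity = _check_severity(severity)
    if severity <= 2:
        return 1
    if severity == 3:
        return 2
    return 3


def load_keyword_map(path: str | Path) -> dict[int, tuple[str, ...]]:
    """Load a YAML keyword map (``level: [keyword, ...]``) and validate it."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    keyword_map = {int(level): tuple(words) for level, words in raw.items()}
    _validate_map(keyword_map)
    return keyword_map
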