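"""Compliance-report assembly and (de)serialization.

All distances are millimetres; negative distances mean the X-ray field
boundary lies outside the detector.  Values are kept at full precision in the
JSON report and displayed at 0.1 mm in the text rendering, with a 0.01 mm
internal rounding for the tabulated columns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

from .errors import ConfigurationError
from .geometry import (
    ComplianceLimits,
    FieldMeasurement,
    SideVerdict,
    check_compliance,
)

SIGN_CONVENTION = (
    "Distances in mm; negative = X-ray field boundary beyond the detector edge."
)


@dataclass(frozen=True)
class ComplianceReport:
    """Per-view measurement table plus per-ruleset verdicts and metadata."""

    measurements: tuple[FieldMeasurement, ...]
    reference_view: str | None
    verdicts: tuple[SideVerdict, ...]
    sid_mm: float
    limits: ComplianceLimits
    ruleset: str
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sign_convention": SIGN_CONVENTION,
            "sid_mm": self.sid_mm,
            "ruleset": self.ruleset,
            "reference_view": self.reference_view,
            "limits": asdict(self.limits),
            "measurements": [asdict(m) for m in self.measurements],
            "verdicts": [asdict(v) for v in self.verdicts],
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ComplianceReport":
        text = Path(source).read_text() if isinstance(source, Path) else source
        d = json.loads(text)
        return cls(
            measurements=tuple(FieldMeasurement(**m) for m in d["measurements"]),
            reference_view=d["reference_view"],
            verdicts=tuple(SideVerdict(**v) for v in d["verdicts"]),
            sid_mm=d["sid_mm"],
            limits=ComplianceLimits(**d["limits"]),
            ruleset=d["ruleset"],
            metadata=d["metadata"],
        )

    def to_text(self) -> str:
        lines = [
            "slitfield compliance report",
            SIGN_CONVENTION,
            f"SID = {self.sid_mm:.1f} mm, ruleset = {self.ruleset}, "
            f"reference view = {self.reference_view or '(none)'}",
            "",
            f"{'view':<22}{'side':<12}{'x_edge':>8}{'x_fov':>8}{'diff':>8}",
        ]
        for m in self.measurements:
            diff = f"{m.difference_mm:+.1f}" if m.difference_mm is not None else "-"
            lines.append(
                f"{m.view:<22}{m.side:<12}{m.x_edge:>8.1f}{m.x_fov:>8.1f}{diff:>8}"
            )
        lines.append("")
        for v in self.verdicts:
            status = "PASS" if v.passed else "FAIL"
            note = f" ({v.note})" if v.note else ""
            lines.append(
                f"{v.rule} {v.side}: overhang {v.overhang_mm:.1f} mm vs "
                f"limit {v.limit_mm:.1f} mm -> {status}{note}"
            )
        return "\n".join(lines)


def build_report(
    measurements: list[FieldMeasurement],
    sid_mm: float,
    limits: ComplianceLimits | None = None,
    ruleset: str = "MQSA",
    reference_view: str | None = None,
    metadata: dict | None = None,
) -> ComplianceReport:
    """Assemble a report: pick the reference view, compute per-view
    differences, and run the compliance checks on the latest measurement of
    each side."""
    if not measurements:
        raise ConfigurationError("no measurements to report")
    if limits is None:
        limits = ComplianceLimits()

    ref = None
    if reference_view is not None:
        for m in measurements:
            if m.view == reference_view:
                ref = m
                break
        if ref is None:
            raise ConfigurationError(f"reference view {reference_view!r} not found")
    elif len(measurements) > 1:
        # default: the full-field mammography view, if one is labelled as such
        for m in measurements:
            if "mammo" in m.view.lower():
                ref = m
                break

    rows = []
    for m in measurements:
        if ref is not None and m.side == ref.side:
            rows.append(replace(m, difference_mm=round(m.x_fov - ref.x_fov, 2)))
        else:
            rows.append(m)

    per_side = {m.side: m for m in measurements}
    verdicts = check_compliance(per_side, sid_mm, limits, ruleset)

    meta = dict(metadata or {})
    meta.setdefault("timestamp", datetime.now(timezone.utc).isoformat())
    meta.setdefault(
        "config_hash",
        hashlib.sha256(
            json.dumps(
                {"sid": sid_mm, "limits": asdict(limits), "ruleset": ruleset},
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
    )
    return ComplianceReport(
        measurements=tuple(rows),
        reference_view=ref.view if ref is not None else None,
        verdicts=tuple(verdicts),
        sid_mm=sid_mm,
        limits=limits,
        ruleset=ruleset.upper(),
        metadata=meta,
    )
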