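"""ADME activity screen for herbal compounds.

Compounds are retained when oral bioavailability (OB) and drug-likeness
(DL) both clear their thresholds — the standard TCMSP screen, OB >= 30%
and DL >= 0.18 by default. Compounds that pass but later turn out to have
no known targets are still reported as active; they simply contribute no
edges downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .io import CompoundRecord

__all__ = ["AdmeThresholds", "ScreenEntry", "ScreenReport", "ScreenSummary",
           "filter_active_compounds", "screen_summary"]


@dataclass(frozen=True)
class AdmeThresholds:
    """Activity thresholds: OB in percent, DL dimensionless.

    ``inclusive=True`` reads the thresholds as ``>=`` (the conventional
    reading); ``False`` makes them strict.
    """

    ob_min: float = 30.0
    dl_min: float = 0.18
    inclusive: bool = True

    def __post_init__(self):
        if self.ob_min < 0:
            raise ValidationError(f"ob_min must be >= 0, got {self.ob_min}")
        if not 0 <= self.dl_min <= 1:
            raise ValidationError(f"dl_min must be in [0, 1], got {self.dl_min}")


@dataclass(frozen=True)
class ScreenEntry:
    mol_id: str
    ob: float
    dl: float
    passed: bool
    failed_criteria: tuple[str, ...]  # subset of ("ob", "dl")


@dataclass
class ScreenReport:
    thresholds: AdmeThresholds
    entries: list[ScreenEntry] = field(default_factory=list)


@dataclass(frozen=True)
class ScreenSummary:
    n_total: int
    n_active: int
    n_failed_ob: int
    n_failed_dl: int
    n_failed_both: int


def filter_active_compounds(
    records: list[CompoundRecord], thresholds: AdmeThresholds | None = None
) -> tuple[list[CompoundRecord], ScreenReport]:
    """Apply the OB/DL activity screen.

    Returns the active subset (input order preserved) and a per-compound
    report naming the failing criterion for every rejected record. Every
    input record's ``is_active`` flag is set as a side effect.
    """
    thr = thresholds or AdmeThresholds()
    report = ScreenReport(thresholds=thr)
    active: list[CompoundRecord] = []
    for rec in records:
        if thr.inclusive:
            ob_ok, dl_ok = rec.ob >= thr.ob_min, rec.dl >= thr.dl_min
        else:
            ob_ok, dl_ok = rec.ob > thr.ob_min, rec.dl > thr.dl_min
        failed = tuple(c for c, ok in (("ob", ob_ok), ("dl", dl_ok)) if not ok)
        rec.is_active = not failed
        if rec.is_active:
            active.append(rec)
        report.entries.append(
            ScreenEntry(rec.mol_id, rec.ob, rec.dl, rec.is_active, failed)
        )
    return active, report


def screen_summary(report: ScreenReport) -> ScreenSummary:
    """Tally the screen into disjoint buckets that sum to the total."""
    n_ob = sum(1 for e in report.entries if e.failed_criteria == ("ob",))
    n_dl = sum(1 for e in report.entries if e.failed_criteria == ("dl",))
    n_both = sum(1 for e in report.entries if e.failed_criteria == ("ob", "dl"))
    n_active = sum(1 for e in report.entries if e.passed)
    return ScreenSummary(
        n_total=len(report.entries),
        n_active=n_active,
        n_failed_ob=n_ob,
        n_failed_dl=n_dl,
        n_failed_both=n_both,
    )
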