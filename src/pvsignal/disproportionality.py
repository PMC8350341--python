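"""Reporting odds ratio (ROR) disproportionality analysis.

For a drug group and a PT case definition, reports cross-classify as

              case    non-case
    exposed     a        b
    unexposed   c        d

and the ROR is the cross-product ratio a·d / (b·c) with the Woolf 95%
interval exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d)). A signal is
declared when the lower CI bound exceeds 1 with at least two exposed
cases. No continuity correction is applied: tables with a zero cell (or
a < 2) are reported as not estimable, the "-" convention of SRS papers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .event_dictionary import PtSet, reports_with_events
from .srs_store import SrsDatabase, reports_exposed

Z_95 = 1.96  # conventional normal quantile for 95% intervals

MIN_CASES_FOR_SIGNAL = 2


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching how SRS tables print estimates."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # exposed cases
    b: int  # exposed non-cases
    c: int  # unexposed cases
    d: int  # unexposed non-cases

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @classmethod
    def from_margins(cls, a: int, n_exposed: int, n_cases: int, n_total: int) -> "ContingencyTable":
        """Build the table from the margins a printed report gives:
        exposed cases, drug-group total, case total, database total."""
        b = n_exposed - a
        c = n_cases - a
        d = n_total - n_exposed - c
        return cls(a=a, b=b, c=c, d=d)


@dataclass(frozen=True)
class RorResult:
    ror: float | None
    ci_low: float | None
    ci_high: float | None
    n_cases: int  # = a
    estimable: bool
    signal: bool


def build_contingency(db: SrsDatabase, drug_group: list[str], pt_set: PtSet,
                      contains: bool = False) -> ContingencyTable:
    """Report-level 2×2 for one drug group versus one case definition.

    Expects a database already filtered to suspected drugs (the extra
    involvement filter inside ``reports_exposed`` makes this harmless to
    call either way).
    """
    all_ids = db.report_ids()
    exposed = reports_exposed(db, drug_group, contains=contains)
    cases = reports_with_events(db, pt_set) if len(pt_set) else set()
    a = len(exposed & cases)
    b = len(exposed) - a
    c = len(cases) - a
    d = len(all_ids) - len(exposed) - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def compute_ror(t: ContingencyTable) -> RorResult:
    """Point estimate and Woolf 95% CI; not estimable when any cell is 0
    or there are fewer than two exposed cases."""
    if min(t.a, t.b, t.c, t.d) == 0 or t.a < MIN_CASES_FOR_SIGNAL:
        return RorResult(ror=None, ci_low=None, ci_high=None,
                         n_cases=t.a, estimable=False, signal=False)
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    ci_low = math.exp(math.log(ror) - Z_95 * se)
    ci_high = math.exp(math.log(ror) + Z_95 * se)
    signal = ci_low > 1.0
    return RorResult(ror=ror, ci_low=ci_low, ci_high=ci_high,
                     n_cases=t.a, estimable=True, signal=signal)


@dataclass(frozen=True)
class SignalRow:
    group_label: str
    query_label: str
    table: ContingencyTable
    result: RorResult


def signal_table(db: SrsDatabase, groups: dict[str, list[str]],
                 pt_sets: dict[str, PtSet], contains: bool = False) -> list[SignalRow]:
    """One row per (drug group, case definition), in config order."""
    if not groups or not pt_sets:
        raise ValueError("groups and queries must be non-empty")
    rows = []
    for glabel, patterns in groups.items():
        for qlabel, pt_set in pt_sets.items():
            t = build_contingency(db, patterns, pt_set, contains=contains)
            rows.append(SignalRow(glabel, qlabel, t, compute_ror(t)))
    return rows
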