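"""Association between antenatal interview items and postpartum depression risk.

The postpartum depression outcome is the Edinburgh Postnatal Depression
Scale total binarized at >= 9 (the validated community cutoff for
suspected postpartum depression in Japan).  Per contact period the
analysis reports, for every interview item: a crude odds ratio from a
univariate logistic fit and an adjusted odds ratio from one joint
multivariable fit over all retained items, each with Wald 95% CIs.
Items with fewer than ``min_exposed`` risk-positive records are excluded
up front (sparse cells make the fits meaningless), with the count
recorded in the output table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import ParameterError
from .schema import Cohort, Record
from .stats import fit_crude, fit_logistic_ml


@dataclass
class EpdsAnalysisConfig:
    epds_threshold: int = 9
    min_exposed: int = 5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (1 <= self.epds_threshold <= 30):
            raise ParameterError("epds_threshold must lie in 1-30")
        if self.min_exposed < 1:
            raise ParameterError("min_exposed must be >= 1")


@dataclass
class AssociationRow:
    item_id: str
    cor: Optional[float] = None
    cci: tuple[Optional[float], Optional[float]] = (None, None)
    cp: Optional[float] = None
    aor: Optional[float] = None
    aci: tuple[Optional[float], Optional[float]] = (None, None)
    ap: Optional[float] = None
    separation: bool = False
    excluded_reason: Optional[str] = None


@dataclass
class AssociationTable:
    period: str
    rows: list[AssociationRow]
    n_used: int

    def row(self, item_id: str) -> AssociationRow:
        for r in self.rows:
            if r.item_id == item_id:
                return r
        raise KeyError(item_id)

    def as_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "item_id": r.item_id,
                    "cOR": r.cor, "cCI_low": r.cci[0], "cCI_high": r.cci[1], "cP": r.cp,
                    "aOR": r.aor, "aCI_low": r.aci[0], "aCI_high": r.aci[1], "aP": r.ap,
                    "excluded_reason": r.excluded_reason,
                }
            )
        return pd.DataFrame(recs).set_index("item_id")


def binarize_epds(epds_total: int, threshold: int = 9) -> int:
    """1 iff the scale total reaches the suspected-depression cutoff."""
    if not (0 <= epds_total <= 30):
        raise ParameterError(f"epds_total {epds_total} outside 0-30")
    return int(epds_total >= threshold)


def _epds_outcome(threshold: int):
    def outcome(rec: Record) -> Optional[int]:
        if rec.epds_total is None:
            return None
        return binarize_epds(rec.epds_total, threshold)

    return outcome


def exclude_sparse_items(
    cohort: Cohort, items: Sequence[str], min_exposed: int = 5
) -> tuple[list[str], list[tuple[str, int]]]:
    """Split items into (kept, excluded-with-counts) by risk-positive count.

    The count is taken among records with an observed depression-scale
    total, i.e. the analysis population.
    """
    analyzed = [r for r in cohort if r.epds_total is not None]
    kept, excluded = [], []
    for item in items:
        exposed = sum(1 for r in analyzed if r.indicators.get(item) == 1)
        if exposed < min_exposed:
            excluded.append((item, exposed))
        else:
            kept.append(item)
    return kept, excluded


def crude_and_adjusted_ors(
    cohort: Cohort,
    items: Sequence[str],
    config: Optional[EpdsAnalysisConfig] = None,
) -> AssociationTable:
    """Build the per-period association table (crude + one joint adjusted fit)."""
    config = config or EpdsAnalysisConfig()
    outcome = _epds_outcome(config.epds_threshold)
    kept, excluded = exclude_sparse_items(cohort, items, config.min_exposed)
    if not kept:
        raise ParameterError("no items left after sparse-item exclusion")

    crude = fit_crude(cohort, outcome, kept)
    adjusted = fit_logistic_ml(cohort, outcome, kept)

    rows = []
    for item in items:
        if item in kept:
            c = crude.term(item)
            a = adjusted.term(item)
            rows.append(
                AssociationRow(
                    item_id=item,
                    cor=c.odds_ratio, cci=(c.ci_low, c.ci_high), cp=c.p_value,
                    aor=a.odds_ratio, aci=(a.ci_low, a.ci_high), ap=a.p_value,
                    separation=c.separation or a.separation,
                )
            )
        else:
            count = dict(excluded)[item]
            rows.append(AssociationRow(item_id=item, excluded_reason=f"sparse: {count} exposed"))
    return AssociationTable(period=cohort.period.value, rows=rows, n_used=adjusted.n_used)
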