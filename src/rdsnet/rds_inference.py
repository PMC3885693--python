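"""Population inference from a respondent-driven sample.

In chain-referral sampling, well-connected people are over-sampled because
many recruitment paths lead to them: inclusion probability is roughly
proportional to degree.  The Volz-Heckathorn (RDS-II) estimator corrects
this by weighting each respondent by the reciprocal of their reported
degree; for a category A the estimated population share is

    p_A = (sum_{i in A} 1/d_i) / (sum_i 1/d_i).

The diary degree (censored sum of travel and location contacts) is the only
network-size measure the survey collects, so it is the default weighting
variable; any other positive column can be substituted.  Seeds are included
by default.

Composition curves track sample shares per recruitment wave and cumulatively
in recruitment order — the standard visual check of whether the sample
composition has stabilised ("reached equilibrium") and stopped depending on
the choice of seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .diary import measures_frame
from .forest import RecruitmentForest
from .records import ParticipantRecord


@dataclass
class VHEstimate:
    variable: str
    categories: list
    raw_proportions: dict
    vh_proportions: dict
    weights: dict = field(repr=False, default_factory=dict)
    n_used: int = 0
    excluded: int = 0
    degree_source: str = "degree"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.categories,
                "raw": [self.raw_proportions[c] for c in self.categories],
                "vh": [self.vh_proportions[c] for c in self.categories],
            }
        )


def _attribute_and_degree(
    records: Iterable[ParticipantRecord],
    attribute: Union[str, Callable],
    degree_source: Union[str, Mapping],
    include_seeds: bool,
) -> pd.DataFrame:
    records = list(records)
    df = measures_frame(records)
    if df.empty:
        raise ValueError("no completed records")
    if callable(attribute):
        attr = pd.Series({r.pid: attribute(r) for r in records if r.completed})
        attr.name = getattr(attribute, "__name__", "attribute")
    else:
        attr = df[attribute]
    if isinstance(degree_source, str):
        deg = df[degree_source]
    else:
        deg = pd.Series(dict(degree_source))
    out = pd.DataFrame({"value": attr, "degree": deg.reindex(attr.index)})
    if not include_seeds:
        seed_pids = {r.pid for r in records if r.is_seed}
        out = out[~out.index.isin(seed_pids)]
    return out


def vh_estimate(
    records: Iterable[ParticipantRecord],
    attribute: Union[str, Callable],
    degree_source: Union[str, Mapping] = "degree",
    include_seeds: bool = True,
) -> VHEstimate:
    """Volz-Heckathorn proportion estimate for a categorical attribute.

    ``attribute`` is a measures-frame column name or a callable mapping a
    record to a category.  Respondents with a missing category or a
    non-positive/missing degree are excluded and counted.
    """
    df = _attribute_and_degree(records, attribute, degree_source, include_seeds)
    usable = df[(df["value"].notna()) & (df["degree"] > 0)]
    excluded = len(df) - len(usable)
    if usable.empty:
        raise ValueError("no usable respondents: all degrees missing or non-positive")

    inv = 1.0 / usable["degree"].astype(float)
    weights = inv / inv.sum()
    categories = sorted(usable["value"].unique(), key=str)
    raw = usable["value"].value_counts(normalize=True)
    vh = weights.groupby(usable["value"]).sum()
    name = attribute if isinstance(attribute, str) else getattr(attribute, "__name__", "attribute")
    deg_name = degree_source if isinstance(degree_source, str) else "custom"
    return VHEstimate(
        variable=name,
        categories=list(categories),
        raw_proportions={c: float(raw.get(c, 0.0)) for c in categories},
        vh_proportions={c: float(vh.get(c, 0.0)) for c in categories},
        weights=weights.to_dict(),
        n_used=int(len(usable)),
        excluded=int(excluded),
        degree_source=deg_name,
    )


def recruitment_order(forest: RecruitmentForest) -> list:
    """Deterministic proxy for enrollment order: wave-major, then pid."""
    return sorted(forest.wave, key=lambda pid: (forest.wave[pid], pid))


def composition_curves(
    records: Iterable[ParticipantRecord],
    forest: RecruitmentForest,
    attribute: Union[str, Callable],
    degree_source: Union[str, Mapping] = "degree",
) -> dict:
    """Sample composition per wave and over increasing sample size.

    Returns ``{"by_wave": DataFrame, "by_sample_size": DataFrame}``.  For a
    categorical attribute the per-wave table holds one proportion column per
    category; the sample-size table holds, after each additional respondent
    in recruitment order, the cumulative raw share and the cumulative
    VH-weighted share per category.  Numeric attributes get means instead.
    """
    df = _attribute_and_degree(records, attribute, degree_source, include_seeds=True)
    df = df[df["value"].notna()].copy()
    df["wave"] = [forest.wave.get(pid) for pid in df.index]
    df = df[df["wave"].notna()]
    if df.empty:
        raise ValueError("no completed records with wave assignments")

    numeric = pd.api.types.is_numeric_dtype(df["value"]) and df["value"].nunique() > 6

    by_wave_rows = []
    for wave, sub in df.groupby("wave"):
        row = {"wave": int(wave), "n": len(sub)}
        if numeric:
            row["mean"] = float(sub["value"].mean())
        else:
            shares = sub["value"].value_counts(normalize=True)
            for cat, share in shares.items():
                row[f"p_{cat}"] = float(share)
        by_wave_rows.append(row)
    by_wave = pd.DataFrame(by_wave_rows).sort_values("wave").reset_index(drop=True)

    order = [pid for pid in recruitment_order(forest) if pid in df.index]
    sub = df.loc[order]
    inv = np.where(sub["degree"] > 0, 1.0 / sub["degree"].astype(float), np.nan)
    rows = []
    if numeric:
        csum = sub["value"].astype(float).cumsum()
        for i in range(len(sub)):
            rows.append({"n": i + 1, "mean": float(csum.iloc[i] / (i + 1))})
    else:
        cats = sorted(sub["value"].unique(), key=str)
        indicators = {c: (sub["value"] == c).to_numpy(float) for c in cats}
        inv_c = np.nancumsum(inv)
        for i in range(len(sub)):
            row = {"n": i + 1}
            for c in cats:
                ind = indicators[c][: i + 1]
                row[f"raw_{c}"] = float(ind.mean())
                w = inv[: i + 1]
                denom = np.nansum(w)
                row[f"vh_{c}"] = float(np.nansum(w * ind) / denom) if denom > 0 else float("nan")
            rows.append(row)
    by_size = pd.DataFrame(rows)
    return {"by_wave": by_wave, "by_sample_size": by_size}
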