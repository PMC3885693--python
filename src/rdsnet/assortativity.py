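"""Assortativity of attributes along recruitment chains.

Respondents recruit people they know, so attributes of linked respondents
are correlated.  This module enumerates ordered participant pairs at every
tree distance within a recruitment component and computes classical
correlation coefficients on them: Pearson's r for counts and continuous
attributes, the phi coefficient (Pearson on 0/1 codes) for binary ones, and
Spearman's rank correlation for ordinal ones.

Two pair orientations are supported.  ``directed`` keeps only
ancestor-to-descendant pairs, so at distance 1 each pair is (recruiter,
recruited) — the natural frame for recruiter-vs-recruit tables.  For larger
distances many pairs meet only through a common ancestor and have no natural
direction, so distance profiles default to ``symmetrized`` mode, in which
every unordered pair enters twice, once per orientation; the estimate is
then invariant under swapping pair members, and inference is based on the
number of unordered pairs.

Confidence intervals use the Fisher z transform.  Pairs sharing individuals
are not independent, so these intervals (and p-values) are approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diary import measures_frame
from .forest import RecruitmentForest
from .records import EDUCATION_LEVELS, ParticipantRecord

STATISTICS = ("pearson", "phi", "spearman")


class UndefinedCorrelationError(ValueError):
    """Raised when a margin has zero variance or too few complete pairs."""


@dataclass
class DistancePairs:
    """Ordered within-component pairs at a given tree distance.

    ``distance`` is an integer d >= 1, or the string ``"{d}+"`` when the
    pair set lumps all distances >= d together.
    """

    distance: Union[int, str]
    pairs: list = field(default_factory=list)
    orientation_mode: str = "symmetrized"


@dataclass
class CorrelationResult:
    statistic: str
    estimate: float
    ci_low: float
    ci_high: float
    n_pairs: int
    df: int
    p: float
    distance: Union[int, str, None] = None
    n_dropped: int = 0
    orientation_mode: str = "symmetrized"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)


def _undirected_distances(forest: RecruitmentForest) -> dict:
    """pid -> {pid: tree distance} within the same component (BFS per node)."""
    und = forest.graph.to_undirected(as_view=True)
    return {n: nx.single_source_shortest_path_length(und, n) for n in und.nodes}


def pairs_at_distance(
    forest: RecruitmentForest,
    d: int,
    orientation_mode: str = "symmetrized",
    lump: bool = False,
) -> DistancePairs:
    """Enumerate ordered pairs whose unique tree path has length d.

    With ``lump=True`` all pairs at distance >= d are pooled (the tail
    bucket of a distance profile).  In ``directed`` mode only pairs where
    the first member is an ancestor of the second are kept.
    """
    if d < 1:
        raise ValueError("distance must be >= 1")
    if orientation_mode not in ("directed", "symmetrized"):
        raise ValueError(f"unknown orientation_mode {orientation_mode!r}")

    keep = (lambda dist: dist >= d) if lump else (lambda dist: dist == d)
    pairs = []
    if orientation_mode == "directed":
        g = forest.graph
        for node in g.nodes:
            depth = {node: 0}
            frontier = [node]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in g.successors(u):
                        depth[v] = depth[u] + 1
                        if keep(depth[v]):
                            pairs.append((node, v))
                        nxt.append(v)
                frontier = nxt
    else:
        dist = _undirected_distances(forest)
        for i, dmap in dist.items():
            for j, dij in dmap.items():
                if i != j and keep(dij):
                    pairs.append((i, j))
    pairs.sort()
    label = f"{d}+" if lump else d
    return DistancePairs(distance=label, pairs=pairs, orientation_mode=orientation_mode)


def _fisher_ci(r: float, n_eff: int, level: float = 0.95) -> tuple[float, float]:
    if n_eff <= 3 or abs(r) >= 1.0:
        return float("nan"), float("nan")
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n_eff - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    return math.tanh(z - zcrit * se), math.tanh(z + zcrit * se)


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a)


def pair_correlation(
    pairs: DistancePairs,
    values: Mapping[str, object],
    statistic: str = "pearson",
) -> CorrelationResult:
    """Correlation between pair members' attribute values.

    ``values`` maps pid to the attribute (numeric; binary coded truthy or
    0/1; ordinal as numeric codes for Spearman).  Pairs with either value
    missing are dropped and counted in ``n_dropped``.  Inference uses the
    number of unordered pairs: in symmetrized mode each unordered pair
    appears twice but contributes once to the degrees of freedom.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")

    xs, ys = [], []
    n_dropped = 0
    for i, j in pairs.pairs:
        vi, vj = values.get(i), values.get(j)
        if vi is None or vj is None or _isnan(vi) or _isnan(vj):
            n_dropped += 1
            continue
        xs.append(float(vi))
        ys.append(float(vj))
    x = np.asarray(xs)
    y = np.asarray(ys)
    n_ordered = x.size
    n_eff = n_ordered // 2 if pairs.orientation_mode == "symmetrized" else n_ordered
    if n_eff < 3:
        raise UndefinedCorrelationError(
            f"only {n_eff} complete pairs at distance {pairs.distance}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"zero variance on a margin at distance {pairs.distance}"
        )

    if statistic == "spearman":
        x, y = _rank(x), _rank(y)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))

    df = n_eff - 2
    if statistic == "phi":
        # chi-square test of association on the 2x2 table: chi2 = n * phi^2
        chi2 = n_eff * r * r
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt(df / (1 - r * r))
            p = float(2 * stats.t.sf(abs(t), df))
    ci_low, ci_high = _fisher_ci(r, n_eff)
    return CorrelationResult(
        statistic=statistic,
        estimate=r,
        ci_low=ci_low,
        ci_high=ci_high,
        n_pairs=n_eff,
        df=df,
        p=p,
        distance=pairs.distance,
        n_dropped=n_dropped,
        orientation_mode=pairs.orientation_mode,
    )


def _isnan(v) -> bool:
    try:
        return math.isnan(float(v))
    except (TypeError, ValueError):
        return False


def distance_profile(
    forest: RecruitmentForest,
    values: Mapping[str, object],
    statistic: str = "pearson",
    max_d: int = 5,
    orientation_mode: str = "symmetrized",
) -> list[CorrelationResult]:
    """Correlation at each tree distance 1..max_d-1 plus a >=max_d lump.

    Distances with fewer than 3 complete pairs, or a degenerate margin,
    yield a result with NaN estimate rather than an exception, so profiles
    over sparse forests stay plottable.
    """
    if max_d < 1:
        raise ValueError("max_d must be >= 1")
    out = []
    specs = [(d, False) for d in range(1, max_d)] + [(max_d, True)]
    for d, lump in specs:
        pairs = pairs_at_distance(forest, d, orientation_mode, lump=lump)
        try:
            out.append(pair_correlation(pairs, values, statistic))
        except UndefinedCorrelationError:
            out.append(
                CorrelationResult(
                    statistic=statistic,
                    estimate=float("nan"),
                    ci_low=float("nan"),
                    ci_high=float("nan"),
                    n_pairs=len(pairs.pairs)
                    // (2 if orientation_mode == "symmetrized" else 1),
                    df=0,
                    p=float("nan"),
                    distance=pairs.distance,
                    orientation_mode=orientation_mode,
                )
            )
    return out


#: (row label, measures_frame column, statistic) for the recruiter-recruit table.
LINKED_PAIR_ROWS = (
    ("age", "age", "pearson"),
    ("gender", "gender_code", "phi"),
    ("education", "education_code", "spearman"),
    ("log_degree", "log_degree", "pearson"),
    ("log_household", "log_household", "pearson"),
    ("log_eating", "log_eating", "pearson"),
    ("log_symptoms", "log_symptoms", "pearson"),
    ("two_plus_symptoms", "two_plus_code", "phi"),
)


def _coded_frame(records: Iterable[ParticipantRecord], **kwargs) -> pd.DataFrame:
    df = measures_frame(records, **kwargs)
    if df.empty:
        raise ValueError("no completed records")
    df = df.assign(
        gender_code=df["gender"].map({"female": 0.0, "male": 1.0}),
        education_code=df["education"].map(
            {lvl: i for i, lvl in enumerate(EDUCATION_LEVELS)}
        ),
        log_symptoms=np.log1p(df["symptom_count"].astype(float)),
        two_plus_code=df["two_plus_symptoms"].astype(float),
    )
    return df


def linked_pair_report(
    records: Iterable[ParticipantRecord],
    forest: RecruitmentForest,
    household_filter_cap: Optional[int] = 500,
    orientation_mode: str = "directed",
    **derive_kwargs,
) -> pd.DataFrame:
    """Recruiter-vs-recruit correlations for the standard attribute set.

    One row per attribute: age (r), gender (phi), education (rank), and
    log-transformed degree, household size, contacts while eating and
    symptom count, plus the two-or-more-symptoms indicator.  Respondents
    reporting a household size above ``household_filter_cap`` are excluded
    (set it to None to keep them).
    """
    df = _coded_frame(records, **derive_kwargs)
    if household_filter_cap is not None:
        df = df[(df["household_size"].isna()) | (df["household_size"] <= household_filter_cap)]
    pairs = pairs_at_distance(forest, 1, orientation_mode)
    rows = []
    for label, column, statistic in LINKED_PAIR_ROWS:
        values = df[column].to_dict()
        try:
            res = pair_correlation(pairs, values, statistic)
            rows.append(
                {
                    "attribute": label,
                    "statistic": statistic,
                    "estimate": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "df": res.df,
                    "p": res.p,
                    "n_pairs": res.n_pairs,
                    "n_dropped": res.n_dropped,
                }
            )
        except UndefinedCorrelationError as exc:
            rows.append(
                {"attribute": label, "statistic": statistic,
                 "estimate": float("nan"), "ci_low": float("nan"),
                 "ci_high": float("nan"), "df": 0, "p": float("nan"),
                 "n_pairs": 0, "n_dropped": 0, "note": str(exc)}
            )
    return pd.DataFrame(rows)
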