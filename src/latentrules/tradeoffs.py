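"""Time-based trade-offs: willingness to travel extra minutes.

For a RUM segment the trade-off between an attribute and travel time is the
coefficient ratio, reported as positive minutes of extra travel accepted per
unit (or per stated attribute level) of improvement.  For an RRM segment the
trade-off is alternative- and choice-set dependent:

    sum_{j != i} -beta_t / (1 + 1/exp[beta_t (t_j - t_i)])
    ---------------------------------------------------------
    sum_{j != i} -beta_r / (1 + 1/exp[beta_r (r_j - r_i)])

where each term is ``-beta * logistic(beta * difference)``, ``t`` the
attribute of interest and ``r`` travel time.  At zero differences the
logistic factors cancel and the ratio collapses to ``beta_t / beta_r``.

The "Value of Clean Ride" (VCR) is the RUM trade-off for the pollution
exposure attributes, in minutes per ppb of NO2.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .modelspec import RRM, RUM

__all__ = [
    "TradeoffQuery",
    "tradeoff_rum",
    "tradeoff_rrm",
    "value_of_clean_ride",
    "tradeoff_table",
    "single_competitor_config",
]


class TradeoffError(ValueError):
    pass


@dataclass(frozen=True)
class TradeoffQuery:
    """Coefficient pair plus competitor-difference configuration (RRM)."""

    beta_t: float
    beta_r: float
    rule: str = RRM
    delta_t: tuple[float, ...] = ()
    delta_r: tuple[float, ...] = ()
    attribute_scale: float = 1.0

    def __post_init__(self):
        if self.rule == RRM:
            if len(self.delta_t) != len(self.delta_r) or len(self.delta_t) < 1:
                raise TradeoffError("RRM query needs equal-length, nonempty delta_t/delta_r")


def tradeoff_rum(beta_attr: float, beta_time: float, scale: float = 1.0) -> float:
    """Willingness to travel extra, |beta_attr * scale / beta_time| minutes.

    Reported as positive minutes regardless of coefficient signs (a positive
    amenity coefficient over a negative time coefficient still means minutes
    the rider would accept to gain the amenity).
    """
    if beta_time == 0:
        raise TradeoffError("travel-time coefficient must be nonzero")
    return abs(beta_attr * scale / beta_time)


def tradeoff_rrm(query: TradeoffQuery) -> float:
    """Signed RRM trade-off, term-by-term as printed (logistic weights)."""
    if query.rule != RRM:
        raise TradeoffError("tradeoff_rrm requires an RRM query")
    bt, br = query.beta_t, query.beta_r
    dt = np.asarray(query.delta_t, dtype=float) * 1.0
    dr = np.asarray(query.delta_r, dtype=float)
    num = np.sum(-bt * expit(bt * dt))
    den = np.sum(-br * expit(br * dr))
    if abs(den) < 1e-300:
        raise TradeoffError("trade-off denominator numerically zero")
    return float(num / den)


def _find_coef(result, segment: int, name: str) -> float:
    seg = result.spec.segments[segment]
    if name not in seg.attributes:
        raise TradeoffError(f"segment {segment} has no coefficient for {name!r}")
    return float(result.params.beta[segment][seg.attributes.index(name)])


def value_of_clean_ride(result, segment: int, mean_attr: str = "mean_exposure",
                        max_attr: str = "max_exposure",
                        time_attr: str = "travel_time") -> dict[str, float]:
    """VCR in min/ppb for mean and maximum exposure of a RUM segment."""
    if result.spec.segments[segment].rule != RUM:
        raise TradeoffError("value_of_clean_ride is defined for RUM segments")
    bt = _find_coef(result, segment, time_attr)
    out = {}
    for key, attr in (("mean", mean_attr), ("max", max_attr)):
        out[key] = tradeoff_rum(_find_coef(result, segment, attr), bt)
    return out


def single_competitor_config(reference_time: float = 20.0):
    """Default RRM difference configuration, documented in table headers.

    One competitor: the considered route is worse by one unit of the
    attribute (``t_j - t_i = -scale``) and the competitor departs at the
    reference travel time, so ``r_j - r_i = reference_time - t`` at grid
    value ``t``.
    """

    def config(t: float, scale: float):
        return (-scale,), (reference_time - t,)

    config.description = (
        f"single competitor; attribute difference t_j-t_i = -scale; "
        f"time difference r_j-r_i = {reference_time} - grid value"
    )
    return config


@dataclass
class TradeoffTable:
    """Per-segment trade-off rows with one column per travel-time grid value
    for RRM segments and a single constant column for RUM segments."""

    frame: pd.DataFrame
    config_description: str

    def to_csv(self, path) -> None:
        buf = io.StringIO()
        buf.write(f"# RRM difference configuration: {self.config_description}\n")
        self.frame.to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def tradeoff_table(result, travel_time_grid=(20, 25, 30, 35, 40),
                   attribute_rows=None, time_attr: str = "travel_time",
                   delta_config=None) -> TradeoffTable:
    """Build the trade-off comparison across segments.

    attribute_rows : list of (label, attribute_name, scale); defaults to every
        non-time attribute of every segment at unit scale.
    delta_config : callable (grid_value, scale) -> (delta_t, delta_r) for RRM
        columns; defaults to :func:`single_competitor_config`.
    Values are reported as positive willingness-to-travel minutes.
    """
    if delta_config is None:
        delta_config = single_competitor_config(reference_time=min(travel_time_grid))
    if attribute_rows is None:
        seen = []
        for seg in result.spec.segments:
            for a in seg.attributes:
                if a != time_attr and a not in seen:
                    seen.append(a)
        attribute_rows = [(a, a, 1.0) for a in seen]

    rows = []
    for s, seg in enumerate(result.spec.segments):
        if time_attr not in seg.attributes:
            continue  # no travel-time coefficient: no time trade-off defined
        bt_time = _find_coef(result, s, time_attr)
        for label, attr, scale in attribute_rows:
            if attr not in seg.attributes:
                continue
            b_attr = _find_coef(result, s, attr)
            row = {"segment": f"seg{s + 1}", "rule": seg.rule, "attribute": label}
            if seg.rule == RUM:
                val = tradeoff_rum(b_attr, bt_time, scale)
                for t in travel_time_grid:
                    row[f"t{t}"] = val
            else:
                for t in travel_time_grid:
                    dt, dr = delta_config(t, scale)
                    q = TradeoffQuery(beta_t=b_attr, beta_r=bt_time, rule=RRM,
                                      delta_t=tuple(dt), delta_r=tuple(dr),
                                      attribute_scale=scale)
                    row[f"t{t}"] = abs(tradeoff_rrm(q))
            rows.append(row)
    frame = pd.DataFrame(rows)
    return TradeoffTable(frame=frame, config_description=getattr(
        delta_config, "description", "user-supplied difference configuration"))
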