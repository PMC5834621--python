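"""Comparison of unperturbed and bilayer end-to-end distances.

The relative difference

    delta = 100 * (<h>_bil - <h>_Theta) / <h>_bil   [percent]

measures how much the bilayer environment (intramolecular long-range plus
intermolecular interactions) stretches an acyl chain beyond its unperturbed
dimensions.  Bilayer averages are inputs (e.g. from published molecular
dynamics values); this package never computes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def relative_difference(h_theta: float, h_bil: float) -> float:
    """delta in percent; raises on non-positive bilayer distance."""
    if h_bil <= 0:
        raise ValueError("bilayer end-to-end distance must be positive")
    return 100.0 * (h_bil - h_theta) / h_bil


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (as in printed tables)."""
    f = 10.0 ** decimals
    return math.floor(abs(x) * f + 0.5) / f * (1.0 if x >= 0 else -1.0)


def _parse_value(v):
    """A float, or a (lo, hi) tuple for 'lo-hi' range strings, or None."""
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, (int, float)):
        return float(v)
    s = str(v).strip()
    if not s:
        return None
    if "-" in s[1:]:
        lo, hi = s.split("-", 1) if not s.startswith("-") else s[1:].split("-", 1)
        return (float(lo), float(hi))
    return float(s)


def _format_value(v, decimals=1):
    if v is None:
        return ""
    if isinstance(v, tuple):
        return f"{round_half_up(v[0], decimals):.{decimals}f}-" \
               f"{round_half_up(v[1], decimals):.{decimals}f}"
    return f"{round_half_up(v, decimals):.{decimals}f}"


@dataclass
class ComparisonRecord:
    chain: str
    h_theta: float
    h_theta_err: float | None
    h_bil: float | tuple            # nm; tuple = range over several bilayers
    context: str                    # which bilayer family the value refers to
    delta: float | tuple            # percent (raw, unrounded)

    @property
    def delta_display(self) -> str:
        return _format_value(self.delta)


def _delta_of(h_theta, h_bil):
    if isinstance(h_bil, tuple):
        return tuple(sorted(relative_difference(h_theta, v) for v in h_bil))
    return relative_difference(h_theta, h_bil)


def build_comparison_table(theta_results, bilayer_values: pd.DataFrame,
                           contexts=("16PC", "18PC")) -> list[ComparisonRecord]:
    """Join Theta-state estimates with bilayer values into delta records.

    ``theta_results``: mapping chain -> (estimate, error) or DataFrame with
    columns chain/h_theta_nm[/h_theta_err_nm].  ``bilayer_values``: DataFrame
    with a ``chain`` column and ``h_bil_<context>_nm`` columns whose entries
    may be numbers or 'lo-hi' range strings.  Raises KeyError for a bilayer
    chain with no matching Theta estimate.
    """
    if isinstance(theta_results, pd.DataFrame):
        theta = {
            str(r["chain"]): (float(r["h_theta_nm"]),
                              float(r.get("h_theta_err_nm", float("nan"))))
            for _, r in theta_results.iterrows()}
    else:
        theta = {k: (v if isinstance(v, tuple) else (v, None))
                 for k, v in dict(theta_results).items()}
    records: list[ComparisonRecord] = []
    for _, row in bilayer_values.iterrows():
        chain = str(row["chain"])
        if chain not in theta:
            raise KeyError(f"no Theta-state estimate for chain {chain!r}")
        ht, err = theta[chain]
        for ctx in contexts:
            col = f"h_bil_{ctx}_nm"
            if col not in bilayer_values.columns:
                continue
            hb = _parse_value(row[col])
            if hb is None:
                continue
            records.append(ComparisonRecord(
                chain=chain, h_theta=ht, h_theta_err=err, h_bil=hb,
                context=ctx, delta=_delta_of(ht, hb)))
    return records


def comparison_frame(records: list[ComparisonRecord]) -> pd.DataFrame:
    """Records as a tidy DataFrame (raw delta plus one-decimal display)."""
    return pd.DataFrame([{
        "chain": r.chain,
        "context": r.context,
        "h_theta_nm": r.h_theta,
        "h_theta_err_nm": r.h_theta_err,
        "h_bil_nm": _format_value(r.h_bil, 3),
        "delta_percent": r.delta if not isinstance(r.delta, tuple) else None,
        "delta_display": r.delta_display,
    } for r in records])


def write_comparison(records: list[ComparisonRecord], path) -> None:
    comparison_frame(records).to_csv(path, sep="\t", index=False)


def read_comparison(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def assert_decreasing_with_unsaturation(theta_by_chain: dict[str, float],
                                        chains) -> bool:
    """True iff <h>_Theta strictly decreases along the given chain order."""
    vals = [theta_by_chain[c] for c in chains]
    return all(a > b for a, b in zip(vals, vals[1:]))
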