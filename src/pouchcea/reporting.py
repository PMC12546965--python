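"""Deterministic tabular writers for results.

Rounding (costs and ICERs to whole dollars, QALYs to three decimals)
happens only here, at display time; upstream values stay unrounded.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .cea import CEAResult

_COLUMNS = ["strategy", "cost", "qaly", "delta_cost", "delta_qaly",
            "icer", "classification", "wtp"]


def report_table(results: Sequence[CEAResult]) -> pd.DataFrame:
    """Two rows per comparison (intervention, then comparator)."""
    rows = []
    for res in results:
        for j, name in enumerate(res.strategy_names):
            first = j == 0
            rows.append({
                "strategy": name,
                "cost": round(res.cost[j]),
                "qaly": round(res.qaly[j], 3),
                "delta_cost": round(res.delta_cost) if first else "",
                "delta_qaly": round(res.delta_qaly, 3) if first else "",
                "icer": (round(res.icer) if (first and res.icer is not None) else ""),
                "classification": res.classification if first else "",
                "wtp": round(res.wtp) if first else "",
            })
    return pd.DataFrame(rows, columns=_COLUMNS)


def report_csv(results: Sequence[CEAResult], path) -> None:
    report_table(results).to_csv(path, index=False)


def report_markdown(results: Sequence[CEAResult]) -> str:
    df = report_table(results)
    return df.to_markdown(index=False)
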