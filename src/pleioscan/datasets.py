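"""Bundled example tables.

``discovery_roster`` is the per-study descriptive roster of a published
multi-study Hispanic/Latino discovery design (sample size, female count and
phenotype means per contributing study); it drives the worked examples and
lets roster-level summaries be recomputed from the printed rows.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def discovery_roster() -> pd.DataFrame:
    with resources.files("pleioscan.data").joinpath(
        "discovery_roster.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["."])


def summarize_roster(roster: pd.DataFrame) -> dict[str, float]:
    """Totals across contributing studies: N, female N, female percent."""
    n = int(roster["n"].sum())
    n_female = int(roster["n_female"].sum())
    return {
        "n_total": n,
        "n_female": n_female,
        "pct_female": round(100.0 * n_female / n, 1),
    }
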